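"""Per-participant item-pair DTW distance matrices and the stacked long table.

For every retained participant the standardized scores of each unordered
item pair form two aligned short series (the participant's complete waves),
and the normalized symmetric2 DTW distance between them fills one cell of a
symmetric P x P matrix with zero diagonal — (P^2 - P)/2 = 1,891 unique
distances for the default 62-item catalog. The per-pair distances of all
participants stacked in long format, together with the pair's mean raw item
score (the severity covariate), are the unit of analysis for every
downstream network statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dtw import dtw_distance_batch
from .panel import StandardizedPanel

__all__ = ["DistanceMatrix", "participant_distances", "cohort_distances"]


@dataclass
class DistanceMatrix:
    """Symmetric matrix of normalized DTW distances for one participant."""

    participant: object
    D: np.ndarray
    item_ids: list[str]
    n_waves: int

    def n_unique(self) -> int:
        p = self.D.shape[0]
        return (p * p - p) // 2


def _pair_indices(n_items: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n_items, k=1)


def _participant_series(panel: StandardizedPanel, pi: int) -> np.ndarray:
    """Complete-wave z-score matrix (T x P) for participant index ``pi``."""
    z = panel.z_scores[pi]
    complete = ~np.isnan(z).any(axis=1)
    return z[complete]


def _pair_distances(series: np.ndarray, window: int, metric: str) -> np.ndarray:
    """Condensed vector of pairwise DTW distances among the columns of a
    T x P series matrix."""
    iu, ju = _pair_indices(series.shape[1])
    a = series.T[iu]  # (n_pairs, T)
    b = series.T[ju]
    return dtw_distance_batch(a, b, window=window, metric=metric)


def participant_distances(
    panel: StandardizedPanel,
    participant,
    window: int = 1,
    metric: str = "absolute",
) -> DistanceMatrix:
    """All pairwise item distances for one participant as a symmetric matrix."""
    pi = panel.cohort.participant_index(participant)
    series = _participant_series(panel, pi)
    p = series.shape[1]
    dvec = _pair_distances(series, window, metric)
    D = np.zeros((p, p))
    iu, ju = _pair_indices(p)
    D[iu, ju] = dvec
    D[ju, iu] = dvec
    return DistanceMatrix(
        participant=participant,
        D=D,
        item_ids=panel.catalog.item_ids,
        n_waves=series.shape[0],
    )


def cohort_distances(
    panel: StandardizedPanel,
    window: int = 1,
    metric: str = "absolute",
) -> pd.DataFrame:
    """Stacked long table of all participants' pairwise item distances.

    Columns: ``participant, item_i, item_j, distance, pair_mean_raw`` with
    one row per participant and unordered pair (i < j in catalog order);
    ``pair_mean_raw`` is the mean of the two items' per-participant raw
    score means. Deterministic and invariant to participant order.
    """
    cohort = panel.cohort
    if cohort.n_participants == 0:
        raise ValueError("empty cohort: no retained participants")
    item_ids = np.asarray(panel.catalog.item_ids)
    n_items = len(item_ids)
    iu, ju = _pair_indices(n_items)
    n_pairs = iu.size
    n_p = cohort.n_participants

    # Batch the DP across participants sharing a wave count (4 or 5):
    # far fewer, larger vectorized calls than per-participant loops.
    complete = ~np.isnan(panel.z_scores).any(axis=2)  # participants x waves
    wave_counts = complete.sum(axis=1)
    dist = np.empty((n_p, n_pairs))
    for t in np.unique(wave_counts):
        members = np.flatnonzero(wave_counts == t)
        series = np.empty((members.size, int(t), n_items))
        for k, pi in enumerate(members):
            series[k] = panel.z_scores[pi][complete[pi]]
        cols = series.transpose(0, 2, 1)  # (n_g, P, T)
        a = cols[:, iu, :].reshape(-1, int(t))
        b = cols[:, ju, :].reshape(-1, int(t))
        dvec = dtw_distance_batch(a, b, window=window, metric=metric)
        dist[members] = dvec.reshape(members.size, n_pairs)

    raw = panel.raw_item_means  # participants x items
    return pd.DataFrame(
        {
            "participant": np.repeat(np.asarray(cohort.participants, dtype=object), n_pairs),
            "item_i": np.tile(item_ids[iu], n_p),
            "item_j": np.tile(item_ids[ju], n_p),
            "distance": dist.ravel(),
            "pair_mean_raw": (0.5 * (raw[:, iu] + raw[:, ju])).ravel(),
            "raw_item_i": raw[:, iu].ravel(),
            "raw_item_j": raw[:, ju].ravel(),
        }
    )
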