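"""Data model, I/O, validation, and standardization for sparse symptom panels.

The panel holds Likert item scores from three self-report instruments —
the 30-item Inventory of Depressive Symptomatology (IDS, 0-3), the 21-item
Beck Anxiety Inventory (BAI, 0-3), and an 11-item Penn State Worry
Questionnaire (PSWQ, 0-4) — measured at up to five assessment waves
(years 0, 2, 4, 6, 9), together with per-wave anxiety-disorder (AD) and
major-depressive-disorder (MDD) diagnosis flags and participant covariates
(age, sex, education).

A wave is *complete* for a participant only when every catalog item is
non-missing at that wave; participants are retained only with four or more
complete waves, and incomplete waves of retained participants are dropped
wholly (never imputed). Item scores are group-level standardized — pooled
mean and SD per item over all participants and complete waves — before any
distance computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "Scale",
    "ItemDefinition",
    "ItemCatalog",
    "default_catalog",
    "PanelCohort",
    "StandardizedPanel",
    "PanelFormatError",
    "PanelValidationError",
    "load_panel",
    "write_panel",
    "standardize",
]

logger = logging.getLogger(__name__)

WAVE_YEARS = (0, 2, 4, 6, 9)
MIN_COMPLETE_WAVES = 4


class Scale(str, Enum):
    IDS = "IDS"
    BAI = "BAI"
    PSWQ = "PSWQ"


class PanelFormatError(ValueError):
    """Malformed input file (bad row, duplicate record, unknown item)."""


class PanelValidationError(ValueError):
    """Structurally valid input with out-of-contract values."""


@dataclass(frozen=True)
class ItemDefinition:
    """One questionnaire item: id, parent scale, and admissible score range."""

    item_id: str
    scale: Scale
    min_score: int
    max_score: int
    label: str = ""

    def __post_init__(self):
        if self.min_score >= self.max_score:
            raise ValueError(
                f"{self.item_id}: min_score must be < max_score "
                f"({self.min_score} >= {self.max_score})"
            )


_SCALE_RANGES = {Scale.IDS: (0, 3), Scale.BAI: (0, 3), Scale.PSWQ: (0, 4)}
_DEFAULT_COUNTS = {Scale.IDS: 30, Scale.BAI: 21, Scale.PSWQ: 11}


class ItemCatalog:
    """Ordered, unique collection of item definitions."""

    def __init__(self, items: list[ItemDefinition]):
        ids = [it.item_id for it in items]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate item ids in catalog: {dupes}")
        self.items = list(items)
        self._index = {it.item_id: k for k, it in enumerate(self.items)}

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def __contains__(self, item_id: str) -> bool:
        return item_id in self._index

    def __getitem__(self, item_id: str) -> ItemDefinition:
        return self.items[self._index[item_id]]

    def index(self, item_id: str) -> int:
        return self._index[item_id]

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    def scale_of(self, item_id: str) -> Scale:
        return self[item_id].scale

    def n_pairs(self) -> int:
        p = len(self)
        return (p * p - p) // 2


def default_catalog(counts: dict[Scale, int] | None = None) -> ItemCatalog:
    """Build the instrument catalog: 30 IDS + 21 BAI + 11 PSWQ = 62 items.

    ``counts`` overrides the number of items per scale, which the synthetic
    cohort generator uses to build reduced catalogs for fast simulation
    studies; score ranges per scale are fixed (IDS/BAI 0-3, PSWQ 0-4).
    """
    counts = dict(_DEFAULT_COUNTS if counts is None else counts)
    items = []
    for scale in (Scale.IDS, Scale.BAI, Scale.PSWQ):
        lo, hi = _SCALE_RANGES[scale]
        for k in range(1, counts.get(scale, 0) + 1):
            items.append(
                ItemDefinition(f"{scale.value}{k:02d}", scale, lo, hi)
            )
    return ItemCatalog(items)


@dataclass
class PanelCohort:
    """Scores, diagnosis flags, and covariates for a validated cohort.

    ``scores`` is participants x waves x items with NaN for missing;
    after validation every retained participant has >= 4 complete waves
    and each retained wave is complete (all items present).
    ``ad_flags``/``mdd_flags`` are participants x waves booleans; the
    wave-0 flag encodes a lifetime diagnosis before baseline.
    ``covariates`` is indexed by participant id with columns
    ``age`` (years), ``sex`` (0/1), ``education`` (ordinal 0/1/2).
    """

    participants: list
    waves: tuple
    catalog: ItemCatalog
    scores: np.ndarray
    ad_flags: np.ndarray
    mdd_flags: np.ndarray
    covariates: pd.DataFrame
    exclusions: dict = field(default_factory=dict)

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    @property
    def n_items(self) -> int:
        return len(self.catalog)

    def complete_wave_mask(self) -> np.ndarray:
        """Boolean participants x waves: wave complete (no missing item)."""
        return ~np.isnan(self.scores).any(axis=2)

    def participant_index(self, participant) -> int:
        try:
            return self.participants.index(participant)
        except ValueError:
            raise KeyError(f"participant {participant!r} not in cohort") from None


@dataclass
class StandardizedPanel:
    """Group-level z-scores plus the raw means needed for later adjustment."""

    cohort: PanelCohort
    z_scores: np.ndarray
    item_means: np.ndarray
    item_sds: np.ndarray
    raw_item_means: np.ndarray  # participant x item, over complete waves
    zero_variance_items: np.ndarray  # boolean per item

    @property
    def catalog(self) -> ItemCatalog:
        return self.cohort.catalog


def _validate_scores_long(df: pd.DataFrame, catalog: ItemCatalog) -> None:
    unknown = set(df["item"]) - set(catalog.item_ids)
    if unknown:
        raise PanelFormatError(f"unknown item ids: {sorted(unknown)[:5]}")
    dup = df.duplicated(subset=["participant", "wave", "item"])
    if dup.any():
        row = df[dup].iloc[0]
        raise PanelFormatError(
            f"duplicate record for participant={row['participant']!r} "
            f"wave={row['wave']!r} item={row['item']!r} (line {dup.idxmax() + 2})"
        )
    for item_id, grp in df.groupby("item", sort=False):
        it = catalog[item_id]
        bad = (grp["score"] < it.min_score) | (grp["score"] > it.max_score)
        if bad.any():
            line = grp.index[bad.to_numpy()][0] + 2  # +header +0-base
            raise PanelValidationError(
                f"score out of range [{it.min_score}, {it.max_score}] for "
                f"item {item_id} at line {line}: {grp.loc[line - 2, 'score']}"
            )


def load_panel(
    scores_path,
    covariates_path,
    catalog: ItemCatalog | None = None,
    waves: tuple = WAVE_YEARS,
    fmt: str = "long",
    delimiter: str = ",",
    min_complete_waves: int = MIN_COMPLETE_WAVES,
) -> PanelCohort:
    """Read, validate, and filter a panel from delimited text files.

    The scores file is long format (columns ``participant, wave, item,
    score``, missing scores as empty fields or absent rows) or wide format
    (one row per participant x wave, one column per item). The covariates
    file has columns ``participant, age, sex, education`` and, optionally,
    per-wave diagnosis columns ``ad_w{wave}`` / ``mdd_w{wave}``.

    Participants with fewer than ``min_complete_waves`` complete waves are
    excluded (counted in ``cohort.exclusions`` and logged); incomplete
    waves of retained participants are blanked out entirely.
    """
    catalog = catalog if catalog is not None else default_catalog()
    try:
        df = pd.read_csv(scores_path, sep=delimiter)
    except pd.errors.ParserError as exc:
        raise PanelFormatError(f"malformed scores file {scores_path}: {exc}") from exc

    if fmt == "wide":
        id_cols = ["participant", "wave"]
        missing = [c for c in id_cols if c not in df.columns]
        if missing:
            raise PanelFormatError(f"wide file lacks columns {missing}")
        df = df.melt(
            id_vars=id_cols, var_name="item", value_name="score"
        ).dropna(subset=["score"])
        df = df.reset_index(drop=True)
    elif fmt == "long":
        required = {"participant", "wave", "item", "score"}
        missing = required - set(df.columns)
        if missing:
            raise PanelFormatError(f"long file lacks columns {sorted(missing)}")
        df = df.dropna(subset=["score"]).reset_index(drop=True)
    else:
        raise ValueError(f"unknown format {fmt!r}; use 'long' or 'wide'")

    if not np.issubdtype(np.asarray(df["score"]).dtype, np.number):
        bad = df[pd.to_numeric(df["score"], errors="coerce").isna()].iloc[0]
        raise PanelFormatError(
            f"non-numeric score {bad['score']!r} for item {bad['item']!r}"
        )
    bad_waves = set(df["wave"]) - set(waves)
    if bad_waves:
        raise PanelFormatError(f"unknown wave labels: {sorted(bad_waves)}")
    _validate_scores_long(df, catalog)

    cov = pd.read_csv(covariates_path, sep=delimiter)
    if "participant" not in cov.columns:
        raise PanelFormatError(f"covariate file {covariates_path} lacks 'participant'")
    cov = cov.set_index("participant")
    for col in ("age", "sex", "education"):
        if col not in cov.columns:
            raise PanelFormatError(f"covariate file lacks column {col!r}")

    participants = list(pd.unique(df["participant"]))
    missing_cov = [p for p in participants if p not in cov.index]
    if missing_cov:
        raise PanelValidationError(
            f"participants without covariates: {missing_cov[:5]}"
        )

    n_p, n_w, n_i = len(participants), len(waves), len(catalog)
    scores = np.full((n_p, n_w, n_i), np.nan)
    p_idx = {p: k for k, p in enumerate(participants)}
    w_idx = {w: k for k, w in enumerate(waves)}
    rows = (
        df["participant"].map(p_idx).to_numpy(),
        df["wave"].map(w_idx).to_numpy(),
        df["item"].map(catalog.index).to_numpy(),
    )
    scores[rows] = df["score"].to_numpy(dtype=float)

    ad = np.zeros((n_p, n_w), dtype=bool)
    mdd = np.zeros((n_p, n_w), dtype=bool)
    for k, w in enumerate(waves):
        for arr, prefix in ((ad, "ad"), (mdd, "mdd")):
            col = f"{prefix}_w{w}"
            if col in cov.columns:
                arr[:, k] = (
                    cov.loc[participants, col].fillna(0).astype(float).to_numpy() > 0
                )

    complete = ~np.isnan(scores).any(axis=2)
    keep = complete.sum(axis=1) >= min_complete_waves
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info(
            "excluded %d participant(s) with < %d complete waves",
            n_excluded,
            min_complete_waves,
        )
    kept = [p for p, k in zip(participants, keep) if k]
    scores = scores[keep]
    # blank incomplete waves of retained participants wholly
    scores[~complete[keep]] = np.nan

    cohort = PanelCohort(
        participants=kept,
        waves=tuple(waves),
        catalog=catalog,
        scores=scores,
        ad_flags=ad[keep],
        mdd_flags=mdd[keep],
        covariates=cov.loc[kept, ["age", "sex", "education"]].copy(),
        exclusions={"too_few_complete_waves": n_excluded},
    )
    return cohort


def write_panel(cohort: PanelCohort, scores_path, covariates_path, delimiter=",",
                z_scores: np.ndarray | None = None) -> None:
    """Write a cohort back to long-format delimited text (round-trip safe).

    When ``z_scores`` is given (same shape as ``cohort.scores``) an extra
    ``z_score`` column is emitted alongside the raw scores.
    """
    recs = []
    item_ids = cohort.catalog.item_ids
    for pi, p in enumerate(cohort.participants):
        for wi, w in enumerate(cohort.waves):
            row = cohort.scores[pi, wi]
            if np.isnan(row).all():
                continue
            for ii, item in enumerate(item_ids):
                if np.isnan(row[ii]):
                    continue
                rec = {
                    "participant": p,
                    "wave": w,
                    "item": item,
                    "score": int(row[ii]),
                }
                if z_scores is not None:
                    rec["z_score"] = z_scores[pi, wi, ii]
                recs.append(rec)
    pd.DataFrame(recs).to_csv(scores_path, sep=delimiter, index=False)

    cov = cohort.covariates.copy()
    for k, w in enumerate(cohort.waves):
        cov[f"ad_w{w}"] = cohort.ad_flags[:, k].astype(int)
        cov[f"mdd_w{w}"] = cohort.mdd_flags[:, k].astype(int)
    cov.reset_index().rename(columns={"index": "participant"}).to_csv(
        covariates_path, sep=delimiter, index=False
    )


def standardize(cohort: PanelCohort, ddof: int = 1) -> StandardizedPanel:
    """Group-level z-scoring: pooled per-item mean and SD over all
    participants and complete waves.

    The pooled SD uses the sample (n-1) denominator. Items with zero pooled
    variance keep z = 0 everywhere (flagged, never dropped) so downstream
    distances stay defined. Per-participant raw item means — the severity
    covariate used by the edge and density adjustments — are computed from
    the raw scores before standardization.
    """
    scores = cohort.scores
    flat = scores.reshape(-1, cohort.n_items)
    means = np.nanmean(flat, axis=0)
    sds = np.nanstd(flat, axis=0, ddof=ddof)
    zero_var = sds == 0
    if zero_var.any():
        flagged = [cohort.catalog.item_ids[i] for i in np.flatnonzero(zero_var)]
        logger.warning(
            "items with zero pooled SD mapped to z = 0: %s", flagged
        )
    safe_sds = np.where(zero_var, 1.0, sds)
    z = (scores - means) / safe_sds
    z[..., zero_var] = np.where(
        np.isnan(scores[..., zero_var]), np.nan, 0.0
    )
    raw_means = np.nanmean(scores, axis=1)  # participant x item
    return StandardizedPanel(
        cohort=cohort,
        z_scores=z,
        item_means=means,
        item_sds=sds,
        raw_item_means=raw_means,
        zero_variance_items=zero_var,
    )
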