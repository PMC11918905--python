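"""Group-level symptom networks from the pairwise DTW distance table.

An edge between two items is drawn only when the pair's mean distance
across participants is *significantly smaller* than that of all remaining
pairs (one-sided). Two test modes are offered:

``ttest``
    independent-samples t-test of the focal pair's distances against the
    pooled distances of every other pair.
``adjusted`` (default)
    linear model of distance on an indicator for the focal pair plus the
    pair's mean raw item score, with a participant intercept — item pairs
    whose scores both stay near zero yield trivially small distances, and
    the raw-score covariate guards against crowning those as edges. Because
    every participant contributes every pair (a balanced design), the
    participant intercepts are absorbed exactly by within-participant
    centering, and the per-pair coefficient, standard error, and one-sided
    p-value are obtained by Frisch-Waugh projection — numerically identical
    to ordinary least squares with participant dummies, but vectorized over
    all (P^2-P)/2 pairs at once.

Node centrality is the mean *inverted* distance between an item and its
connected neighbors; network density is a participant's mean inverted
distance over all pairs. Inversion is linear by default (reference minus
distance, so group contrasts and the quadratic stability regression are
invariant to the affine choice), with the reciprocal available.

Subgroup networks inherit the node layout (Fruchterman-Reingold) and the
edge-weight scale from the whole-group network so plots stay comparable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "invert_distances",
    "test_edges",
    "centrality",
    "network_density",
    "build_network",
    "DensityEstimate",
    "SymptomNetwork",
]

logger = logging.getLogger(__name__)

EDGE_MODES = ("ttest", "adjusted")
EDGE_ADJUST = ("pair_mean", "item_means")
INVERT_MODES = ("linear", "reciprocal")


def invert_distances(
    d: np.ndarray, mode: str = "linear", reference: float | None = None
) -> np.ndarray:
    """Map distances to a similarity scale where larger = more connected.

    ``linear``: ``reference - d`` with ``reference`` defaulting to the
    maximum observed distance (result >= 0). ``reciprocal``: ``1 / d``
    with a small floor to keep zero distances finite.
    """
    d = np.asarray(d, dtype=float)
    if mode == "linear":
        ref = float(np.max(d)) if reference is None else float(reference)
        return ref - d
    if mode == "reciprocal":
        return 1.0 / np.maximum(d, 1e-9)
    raise ValueError(f"unknown inversion mode {mode!r}; choose from {INVERT_MODES}")


def _factorize_pairs(table: pd.DataFrame):
    pair_key = table["item_i"].astype(str) + "\x00" + table["item_j"].astype(str)
    pair_codes, pair_uniques = pd.factorize(pair_key, sort=False)
    part_codes, part_uniques = pd.factorize(table["participant"], sort=False)
    first = np.unique(pair_codes, return_index=True)[1]
    pairs = list(zip(table["item_i"].iloc[first], table["item_j"].iloc[first]))
    return pair_codes, pairs, part_codes, len(part_uniques)


def _edge_ttest(y, pair_codes, n_pairs):
    """Vectorized one-sided pooled-variance t-test: each pair vs the rest."""
    n = np.bincount(pair_codes, minlength=n_pairs).astype(float)
    s = np.bincount(pair_codes, weights=y, minlength=n_pairs)
    ss = np.bincount(pair_codes, weights=y * y, minlength=n_pairs)
    n_tot, s_tot, ss_tot = y.size, y.sum(), (y * y).sum()

    m1 = s / n
    m2 = (s_tot - s) / (n_tot - n)
    sse1 = ss - n * m1**2
    sse2 = (ss_tot - ss) - (n_tot - n) * m2**2
    df = n_tot - 2.0
    sp2 = (sse1 + sse2) / df
    se = np.sqrt(sp2 * (1.0 / n + 1.0 / (n_tot - n)))
    effect = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / se
    p = stats.t.cdf(t, df)  # one-sided: focal mean smaller
    return effect, p, se == 0


def _edge_adjusted(y, pair_codes, n_pairs, part_codes, n_parts, covariates):
    """Per-pair OLS with participant fixed effects via Frisch-Waugh.

    Model per focal pair p: distance ~ 1{pair==p} + covariates + participant
    intercepts. Balanced designs make the participant intercepts equivalent
    to within-participant centering; the focal indicator and the outcome are
    then residualized on the centered covariates, giving exact OLS estimates
    for all pairs in a handful of array operations.
    """
    # within-participant centering absorbs intercept + participant effects
    part_n = np.bincount(part_codes).astype(float)
    y_t = y - (np.bincount(part_codes, weights=y) / part_n)[part_codes]
    C = np.empty((y.size, covariates.shape[1]))
    for k in range(covariates.shape[1]):
        c = covariates[:, k]
        C[:, k] = c - (np.bincount(part_codes, weights=c) / part_n)[part_codes]

    ctc = C.T @ C
    cty = C.T @ y_t
    try:
        gamma = np.linalg.solve(ctc, cty)
    except np.linalg.LinAlgError:
        gamma = np.linalg.lstsq(ctc, cty, rcond=None)[0]
    e_y = y_t - C @ gamma  # outcome residualized on covariates + participant

    n_obs = np.bincount(pair_codes, minlength=n_pairs).astype(float)
    k_pair = n_obs / y.size  # centered indicator: 1 - k on focal rows, -k off
    # C' x_p per pair (centered C has zero column sums, so no -k correction)
    ctx = np.stack(
        [np.bincount(pair_codes, weights=C[:, k], minlength=n_pairs)
         for k in range(C.shape[1])]
    )  # (k_cov, n_pairs)
    sol = np.linalg.solve(ctc, ctx) if np.linalg.matrix_rank(ctc) == ctc.shape[0] \
        else np.linalg.lstsq(ctc, ctx, rcond=None)[0]
    xtx = n_obs * (1 - k_pair) ** 2 + (y.size - n_obs) * k_pair**2
    exx = xtx - np.einsum("kp,kp->p", ctx, sol)  # e_x' e_x per pair
    exy = np.bincount(pair_codes, weights=e_y, minlength=n_pairs)  # e_x' e_y

    with np.errstate(divide="ignore", invalid="ignore"):
        beta = exy / exx
    eyy = float(e_y @ e_y)
    df = y.size - n_parts - covariates.shape[1] - 1
    rss = eyy - beta**2 * exx
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss / df / exx)
        t = beta / se
    p = stats.t.cdf(t, df)
    degenerate = ~np.isfinite(t)
    return beta, p, degenerate


def test_edges(
    table: pd.DataFrame,
    alpha: float = 1e-4,
    mode: str = "adjusted",
    adjust: str = "pair_mean",
) -> pd.DataFrame:
    """Contrast every item pair's distances against all remaining pairs.

    Returns one row per unordered pair with columns ``item_i, item_j,
    mean_distance, effect, p_value, significant``; ``significant`` requires
    both ``p_value < alpha`` and a focal mean *below* the rest (the effect,
    a mean difference or model coefficient, is negative).
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if mode not in EDGE_MODES:
        raise ValueError(f"unknown mode {mode!r}; choose from {EDGE_MODES}")
    if adjust not in EDGE_ADJUST:
        raise ValueError(f"unknown adjust {adjust!r}; choose from {EDGE_ADJUST}")
    pair_codes, pairs, part_codes, n_parts = _factorize_pairs(table)
    if n_parts < 2:
        raise ValueError("edge testing needs at least 2 participants")
    n_pairs = len(pairs)
    y = table["distance"].to_numpy(dtype=float)

    if mode == "ttest":
        effect, p, degenerate = _edge_ttest(y, pair_codes, n_pairs)
    else:
        if adjust == "pair_mean":
            cov = table[["pair_mean_raw"]].to_numpy(dtype=float)
        else:
            # one covariate per member item's raw mean
            if not {"raw_item_i", "raw_item_j"} <= set(table.columns):
                raise ValueError(
                    "adjust='item_means' needs raw_item_i/raw_item_j columns "
                    "(produced by cohort_distances)"
                )
            cov = table[["raw_item_i", "raw_item_j"]].to_numpy(dtype=float)
        logger.info("edge adjustment covariate coding: %s", adjust)
        effect, p, degenerate = _edge_adjusted(
            y, pair_codes, n_pairs, part_codes, n_parts, cov
        )

    p = np.where(degenerate, 1.0, p)
    mean_d = np.bincount(pair_codes, weights=y, minlength=n_pairs) / np.bincount(
        pair_codes, minlength=n_pairs
    )
    return pd.DataFrame(
        {
            "item_i": [a for a, _ in pairs],
            "item_j": [b for _, b in pairs],
            "mean_distance": mean_d,
            "effect": effect,
            "p_value": p,
            "significant": (p < alpha) & (effect < 0),
            "degenerate": degenerate,
        }
    )


def centrality(
    table: pd.DataFrame,
    edges: pd.DataFrame,
    invert: str = "linear",
    reference: float | None = None,
) -> pd.DataFrame:
    """Per-item centrality: mean inverted distance to connected neighbors.

    Items with no significant edge get centrality 0 on the inverted scale
    and are flagged isolated. A z-standardized centrality column supports
    ranked bar plots.
    """
    items = sorted(set(table["item_i"]) | set(table["item_j"]))
    pair_mean = table.groupby(["item_i", "item_j"], sort=False)["distance"].mean()
    if reference is None and invert == "linear":
        reference = float(table["distance"].max())

    neighbor_inv: dict[str, list[float]] = {it: [] for it in items}
    for _, row in edges[edges["significant"]].iterrows():
        d = pair_mean[(row["item_i"], row["item_j"])]
        v = float(invert_distances(np.array([d]), invert, reference)[0])
        neighbor_inv[row["item_i"]].append(v)
        neighbor_inv[row["item_j"]].append(v)

    cent = np.array(
        [np.mean(neighbor_inv[it]) if neighbor_inv[it] else 0.0 for it in items]
    )
    sd = cent.std(ddof=0)
    z = (cent - cent.mean()) / sd if sd > 0 else np.zeros_like(cent)
    return pd.DataFrame(
        {
            "item": items,
            "centrality": cent,
            "std_centrality": z,
            "isolated": [not neighbor_inv[it] for it in items],
        }
    )


@dataclass
class DensityEstimate:
    """Covariate-adjusted mean network density for one group."""

    group: object
    adjusted_density: float
    standard_error: float
    n_participants: int
    covariates: tuple = ()


def participant_density(
    table: pd.DataFrame, invert: str = "linear", reference: float | None = None
) -> pd.Series:
    """Per-participant density: mean inverted distance over all item pairs."""
    if reference is None and invert == "linear":
        reference = float(table["distance"].max())
    inv = invert_distances(table["distance"].to_numpy(), invert, reference)
    return (
        pd.Series(inv, index=table["participant"].to_numpy(), name="density")
        .groupby(level=0, sort=False)
        .mean()
    )


def network_density(
    table: pd.DataFrame,
    covariates: pd.DataFrame,
    grouping: pd.Series,
    invert: str = "linear",
    reference: float | None = None,
) -> tuple[list[DensityEstimate], pd.DataFrame, pd.Series]:
    """Adjusted mean network density per group, with pairwise comparisons.

    Per-participant densities (mean inverted distance over all pairs) are
    modeled on mean symptom severity, age, sex, education, and the grouping
    factor; adjusted group means are predictions at the grand covariate
    means with delta-method standard errors. Returns the estimates, a
    pairwise-comparison table, and the raw per-participant densities.
    """
    import statsmodels.api as sm

    dens = participant_density(table, invert, reference)
    severity = (
        table.set_index("participant")["pair_mean_raw"].groupby(level=0).mean()
    )
    df = pd.DataFrame({"density": dens, "severity": severity})
    df = df.join(covariates[["age", "sex", "education"]], how="inner")
    df["group"] = grouping.reindex(df.index)
    if df["group"].isna().any() or df[["age", "sex", "education"]].isna().any().any():
        raise ValueError("covariates or grouping missing for some participants")

    sizes = df["group"].value_counts()
    small = sizes[sizes < 2].index.tolist()
    if small:
        logger.warning("excluding groups with < 2 participants: %s", small)
        df = df[~df["group"].isin(small)]

    groups = sorted(df["group"].unique(), key=str)
    gdum = pd.get_dummies(df["group"], drop_first=False).astype(float)[groups]
    X = np.column_stack(
        [gdum.to_numpy(), df[["severity", "age", "sex", "education"]].to_numpy()]
    )
    names = [f"g_{g}" for g in groups] + ["severity", "age", "sex", "education"]
    fit = sm.OLS(df["density"].to_numpy(), X).fit()

    cov_names = ("severity", "age", "sex", "education")
    cov_means = df[list(cov_names)].mean().to_numpy()
    estimates = []
    for k, g in enumerate(groups):
        vec = np.zeros(X.shape[1])
        vec[k] = 1.0
        vec[len(groups):] = cov_means
        est = float(vec @ fit.params)
        se = float(np.sqrt(vec @ fit.cov_params() @ vec))
        estimates.append(
            DensityEstimate(
                group=g,
                adjusted_density=est,
                standard_error=se,
                n_participants=int(sizes[g]),
                covariates=cov_names,
            )
        )

    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            vec = np.zeros(X.shape[1])
            vec[i], vec[j] = 1.0, -1.0
            tt = fit.t_test(vec)
            rows.append(
                {
                    "group_a": groups[i],
                    "group_b": groups[j],
                    "difference": float(np.atleast_1d(tt.effect)[0]),
                    "p_value": float(np.atleast_1d(tt.pvalue).ravel()[0]),
                }
            )
    del names
    return estimates, pd.DataFrame(rows), dens


@dataclass
class SymptomNetwork:
    """Significance-filtered weighted item network with a fixed layout."""

    graph: nx.Graph
    layout: dict
    edge_scale: tuple
    alpha: float
    group: object = "all"
    meta: dict = field(default_factory=dict)

    def node_table(self) -> pd.DataFrame:
        rows = []
        for node, data in self.graph.nodes(data=True):
            rows.append(
                {
                    "item": node,
                    "scale": data.get("scale", ""),
                    "centrality": data.get("centrality", 0.0),
                    "x": self.layout[node][0],
                    "y": self.layout[node][1],
                }
            )
        return pd.DataFrame(rows)

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"item_i": u, "item_j": v, "weight": d["weight"], "p_value": d["p_value"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["item_i", "item_j", "weight", "p_value"])

    def to_graphml(self, path) -> None:
        g = self.graph.copy()
        for node in g.nodes:
            g.nodes[node]["x"] = float(self.layout[node][0])
            g.nodes[node]["y"] = float(self.layout[node][1])
        nx.write_graphml(g, path)

    def to_json(self, path) -> None:
        payload = nx.node_link_data(self.graph, edges="links")
        payload["layout"] = {n: list(map(float, xy)) for n, xy in self.layout.items()}
        payload["edge_scale"] = list(self.edge_scale)
        payload["alpha"] = self.alpha
        payload["group"] = str(self.group)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def build_network(
    edges: pd.DataFrame,
    centralities: pd.DataFrame,
    item_scales: dict | None = None,
    layout_source: SymptomNetwork | None = None,
    alpha: float = 1e-4,
    group: object = "all",
    seed: int = 0,
    layout_iterations: int = 100,
) -> SymptomNetwork:
    """Assemble the symptom network with a fixed Fruchterman-Reingold layout.

    The whole-group call computes the layout and the edge-weight scale;
    subgroup calls pass the whole-group network as ``layout_source`` and
    reuse both bit-identically, so subgroup plots are directly comparable.
    Edge weight is the magnitude of the test's effect (model coefficient).
    """
    g = nx.Graph()
    cent_map = dict(zip(centralities["item"], centralities["centrality"]))
    for item in centralities["item"]:
        g.add_node(
            item,
            centrality=float(cent_map[item]),
            scale=(item_scales or {}).get(item, ""),
        )
    for _, row in edges[edges["significant"]].iterrows():
        g.add_edge(
            row["item_i"],
            row["item_j"],
            weight=float(abs(row["effect"])),
            p_value=float(row["p_value"]),
        )

    if layout_source is not None:
        missing = set(g.nodes) - set(layout_source.layout)
        if missing:
            raise ValueError(f"layout source lacks nodes: {sorted(missing)[:5]}")
        layout = {n: layout_source.layout[n] for n in g.nodes}
        edge_scale = layout_source.edge_scale
    else:
        pos = nx.spring_layout(g, seed=seed, iterations=layout_iterations)
        layout = {n: (float(x), float(y)) for n, (x, y) in pos.items()}
        weights = [d["weight"] for _, _, d in g.edges(data=True)]
        edge_scale = (min(weights), max(weights)) if weights else (0.0, 0.0)

    return SymptomNetwork(
        graph=g,
        layout=layout,
        edge_scale=edge_scale,
        alpha=alpha,
        group=group,
    )


def plot_network(network: SymptomNetwork, path) -> None:
    """Static rendering: node size by centrality, color by scale, fixed layout."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"IDS": "#4477aa", "BAI": "#cc4444", "PSWQ": "#44aa66"}
    g = network.graph
    cents = np.array([g.nodes[n].get("centrality", 0.0) for n in g.nodes])
    span = cents.max() - cents.min() if len(cents) else 1.0
    sizes = 60 + 240 * (cents - cents.min()) / (span if span > 0 else 1.0)
    node_colors = [colors.get(str(g.nodes[n].get("scale", "")), "#999999") for n in g.nodes]
    lo, hi = network.edge_scale
    rng = hi - lo if hi > lo else 1.0
    widths = [0.3 + 2.7 * (d["weight"] - lo) / rng for _, _, d in g.edges(data=True)]

    fig, ax = plt.subplots(figsize=(8, 8))
    nx.draw_networkx(
        g,
        pos=network.layout,
        ax=ax,
        node_size=sizes,
        node_color=node_colors,
        width=widths,
        font_size=5,
        edge_color="#777777",
    )
    ax.set_axis_off()
    ax.set_title(f"Symptom network — {network.group} (alpha={network.alpha:g})")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
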