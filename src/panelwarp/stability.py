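"""Disease-state stability scoring and the density-stability relation.

A participant's stability score counts the diagnostic assessments (out of
5: the baseline interview, which covers lifetime diagnosis before
inclusion, plus 4 follow-up intervals) at which an anxiety disorder (AD)
and/or major depressive disorder (MDD) was present. Scores 0-1 indicate a
stable state of health, 2-3 an unstable disease state with transitions
between health and disorder, and 4-5 a stable disease state. The score is
a count, so reordering the assessments leaves it unchanged — the construct
is about how much time was spent diseased, not when.

The density-stability relation is fit in two steps, literally: network
density is residualized on mean symptom severity, age, sex, and education,
and the residuals are regressed on the stability score with linear and
quadratic terms. A negative quadratic coefficient indicates an inverted-U:
density peaks at mid-range (unstable) scores. A single joint model is
available as an option; the two differ slightly because the covariate
projection in the first step also absorbs any covariate-score overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .panel import PanelCohort, Scale

__all__ = [
    "Subgroup",
    "StabilityProfile",
    "stability_score",
    "stability_profiles",
    "QuadraticFit",
    "density_vs_stability",
    "severity_trajectories",
    "STABILITY_CLASSES",
]

STABILITY_CLASSES = {
    0: "stable_health",
    1: "stable_health",
    2: "unstable",
    3: "unstable",
    4: "stable_disease",
    5: "stable_disease",
}


class Subgroup(str, Enum):
    CONTROL = "control"
    AD_ONLY = "AD_only"
    MDD_ONLY = "MDD_only"
    COMORBID = "comorbid"


@dataclass
class StabilityProfile:
    participant: object
    stability_score: int
    diagnostic_subgroup: Subgroup
    stability_class: str


def stability_score(ad_flags, mdd_flags) -> StabilityProfile:
    """Score one participant from 5 per-assessment AD and MDD booleans.

    The first flag of each vector is the baseline interview (lifetime
    diagnosis before inclusion); the rest cover the follow-up intervals.
    The score is the count of assessments with AD and/or MDD present; the
    diagnostic subgroup follows from which disorders ever occurred.
    """
    ad = np.asarray(ad_flags)
    mdd = np.asarray(mdd_flags)
    if ad.shape != mdd.shape or ad.ndim != 1:
        raise ValueError("ad and mdd flags must be equal-length 1-D vectors")
    if np.any(pd.isna(ad)) or np.any(pd.isna(mdd)):
        raise ValueError("missing diagnosis flag: no partial stability scores")
    ad = ad.astype(bool)
    mdd = mdd.astype(bool)
    score = int((ad | mdd).sum())
    ad_ever, mdd_ever = bool(ad.any()), bool(mdd.any())
    if ad_ever and mdd_ever:
        sub = Subgroup.COMORBID
    elif ad_ever:
        sub = Subgroup.AD_ONLY
    elif mdd_ever:
        sub = Subgroup.MDD_ONLY
    else:
        sub = Subgroup.CONTROL
    return StabilityProfile(
        participant=None,
        stability_score=score,
        diagnostic_subgroup=sub,
        stability_class=STABILITY_CLASSES.get(score, "stable_disease"),
    )


def stability_profiles(cohort: PanelCohort) -> pd.DataFrame:
    """Stability scores and subgroups for every cohort participant."""
    rows = []
    for pi, p in enumerate(cohort.participants):
        prof = stability_score(cohort.ad_flags[pi], cohort.mdd_flags[pi])
        rows.append(
            {
                "participant": p,
                "stability_score": prof.stability_score,
                "subgroup": prof.diagnostic_subgroup.value,
                "stability_class": prof.stability_class,
            }
        )
    return pd.DataFrame(rows).set_index("participant")


@dataclass
class QuadraticFit:
    """Quadratic regression of adjusted density on the stability score."""

    beta_linear: float
    beta_quadratic: float
    p_linear: float
    p_quadratic: float
    adjusted_means: pd.DataFrame  # per score level: mean, se, n
    covariates: tuple
    scheme: str  # "two_step" or "joint"


def _check_design(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name a culprit: last column whose removal restores full rank
        # (prefer blaming a covariate over the intercept)
        for k in reversed(range(X.shape[1])):
            sub = np.delete(X, k, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                raise ValueError(f"collinear covariates in design: {names[k]!r}")
        raise ValueError("collinear covariates in design")


def density_vs_stability(
    densities: pd.Series,
    profiles: pd.DataFrame,
    covariates: pd.DataFrame,
    severity: pd.Series,
    scheme: str = "two_step",
) -> QuadraticFit:
    """Fit adjusted density as a quadratic function of the stability score.

    ``densities`` is the per-participant mean inverted distance;
    ``profiles`` must carry a ``stability_score`` column; ``severity`` is
    the per-participant mean symptom score (grand mean over all items).
    """
    import statsmodels.api as sm

    df = pd.DataFrame({"density": densities, "severity": severity})
    df = df.join(covariates[["age", "sex", "education"]], how="inner")
    df = df.join(profiles[["stability_score"]], how="inner").dropna()
    if df["stability_score"].nunique() < 3:
        raise ValueError(
            "need >= 3 distinct stability scores for a quadratic fit"
        )
    cov_names = ["severity", "age", "sex", "education"]
    Z = sm.add_constant(df[cov_names].to_numpy(), has_constant="add")
    _check_design(Z, ["const"] + cov_names)

    s = df["stability_score"].to_numpy(dtype=float)
    X = sm.add_constant(np.column_stack([s, s**2]), has_constant="add")

    if scheme == "two_step":
        resid = sm.OLS(df["density"].to_numpy(), Z).fit().resid
        fit = sm.OLS(resid, X).fit()
        outcome = resid
    elif scheme == "joint":
        XZ = np.column_stack([X, Z[:, 1:]])
        _check_design(XZ, ["const", "s", "s2"] + cov_names)
        fit = sm.OLS(df["density"].to_numpy(), XZ).fit()
        outcome = sm.OLS(df["density"].to_numpy(), Z).fit().resid
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    per_level = (
        pd.DataFrame({"score": s.astype(int), "resid": outcome})
        .groupby("score")["resid"]
        .agg(["mean", "sem", "count"])
        .rename(columns={"mean": "adjusted_density", "sem": "se", "count": "n"})
    )
    return QuadraticFit(
        beta_linear=float(fit.params[1]),
        beta_quadratic=float(fit.params[2]),
        p_linear=float(fit.pvalues[1]),
        p_quadratic=float(fit.pvalues[2]),
        adjusted_means=per_level,
        covariates=tuple(cov_names),
        scheme=scheme,
    )


def severity_trajectories(
    cohort: PanelCohort, grouping: pd.Series
) -> pd.DataFrame:
    """Mean instrument sum scores per group, wave, and instrument.

    Sum scores are computed over complete waves only; single-participant
    groups report a missing standard error rather than zero.
    """
    rows = []
    item_scales = np.array(
        [it.scale.value for it in cohort.catalog], dtype=object
    )
    groups = grouping.reindex(cohort.participants)
    for scale in Scale:
        cols = item_scales == scale.value
        if not cols.any():
            continue
        sums = cohort.scores[:, :, cols].sum(axis=2)  # NaN if wave incomplete
        for wi, wave in enumerate(cohort.waves):
            frame = pd.DataFrame(
                {"group": groups.to_numpy(), "sum_score": sums[:, wi]}
            ).dropna()
            agg = frame.groupby("group")["sum_score"].agg(["mean", "sem", "count"])
            for g, row in agg.iterrows():
                rows.append(
                    {
                        "group": g,
                        "wave": wave,
                        "instrument": scale.value,
                        "mean_sum_score": row["mean"],
                        "se": row["sem"] if row["count"] > 1 else np.nan,
                        "n": int(row["count"]),
                    }
                )
    return pd.DataFrame(rows)
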