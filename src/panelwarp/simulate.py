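"""Synthetic cohorts with known ground truth for every pipeline stage.

The generator emulates the structure of a longitudinal depression/anxiety
cohort: four diagnostic subgroups (controls, AD-only, MDD-only, comorbid)
assessed at years 0, 2, 4, 6, 9 on a 62-item catalog, with relapse and
remission over follow-up and an initial post-baseline drop in mean scores.

Item dynamics follow a latent-factor model. Five factors — mood,
cognitive anxiety, somatic arousal, worry, sleep — each drive a block of
items; a participant's item series is

    y_it = sqrt(c_i) * f_k(i),t + sqrt(1 - c_i) * u_it

with the factor path ``f`` and the item-specific noise ``u`` independent
stationary AR(1) processes, so ``y`` has unit variance and the coupling
``c_i`` is the variance share of the shared factor. Stronger coupling
means items fluctuate more in tandem, hence smaller pairwise DTW distances
and a denser network: the per-subgroup coupling (controls < AD < MDD <
comorbid by default) is the generating analog of the density ordering the
pipeline must recover. Worry items couple hardest within their factor, so
they cluster most tightly. Raw Likert scores are fixed-threshold
discretizations (round and clip) of the latent value plus a severity
offset that is highest at baseline and while a diagnosis is active.

Everything is driven by one seed; regenerating with the same configuration
is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import ItemCatalog, PanelCohort, Scale, default_catalog
from .stability import Subgroup

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate",
    "make_stability_scenario",
    "INVERTED_U_PROFILE",
    "FLAT_PROFILE",
]

FACTORS = ("mood", "cognitive_anxiety", "somatic_arousal", "worry", "sleep")

# fraction of each scale's items per factor, applied in catalog order
_SCALE_FACTOR_SPLIT = {
    Scale.IDS: (("sleep", 4 / 30), ("mood", 14 / 30),
                ("cognitive_anxiety", 6 / 30), ("somatic_arousal", 6 / 30)),
    Scale.BAI: (("somatic_arousal", 13 / 21), ("cognitive_anxiety", 8 / 21)),
    Scale.PSWQ: (("worry", 1.0),),
}

# worry items cluster hardest; other factors couple at the subgroup level
_FACTOR_WEIGHT = {
    "mood": 1.0,
    "cognitive_anxiety": 1.0,
    "somatic_arousal": 1.0,
    "worry": 1.35,
    "sleep": 0.8,
}


def item_factor_map(catalog: ItemCatalog) -> dict[str, str]:
    """Deterministic assignment of catalog items to latent factors."""
    mapping: dict[str, str] = {}
    by_scale: dict[Scale, list[str]] = {}
    for it in catalog:
        by_scale.setdefault(it.scale, []).append(it.item_id)
    for scale, ids in by_scale.items():
        split = _SCALE_FACTOR_SPLIT[scale]
        bounds = np.cumsum([frac for _, frac in split])
        bounds = np.rint(bounds / bounds[-1] * len(ids)).astype(int)
        start = 0
        for (factor, _), stop in zip(split, bounds):
            for item_id in ids[start:stop]:
                mapping[item_id] = factor
            start = stop
    return mapping


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    ``n_per_subgroup`` defaults to the cohort proportions of a large
    naturalistic depression/anxiety panel (360/158/265/866) scaled by 1/3.
    ``coupling`` is the latent-factor variance share per subgroup and is
    the generating ground truth for the density ordering. ``transitions``
    gives (onset, remission) probabilities of the per-wave disease chain;
    the baseline assessment of every patient subgroup is diagnosis-positive
    (lifetime diagnosis before inclusion).
    """

    n_per_subgroup: dict = field(
        default_factory=lambda: {
            Subgroup.CONTROL: 120,
            Subgroup.AD_ONLY: 53,
            Subgroup.MDD_ONLY: 88,
            Subgroup.COMORBID: 289,
        }
    )
    waves: tuple = (0, 2, 4, 6, 9)
    catalog: ItemCatalog = field(default_factory=default_catalog)
    coupling: dict = field(
        default_factory=lambda: {
            Subgroup.CONTROL: 0.08,
            Subgroup.AD_ONLY: 0.45,
            Subgroup.MDD_ONLY: 0.48,
            Subgroup.COMORBID: 0.75,
        }
    )
    severity_offset: dict = field(
        default_factory=lambda: {
            Subgroup.CONTROL: 0.0,
            Subgroup.AD_ONLY: 0.20,
            Subgroup.MDD_ONLY: 0.22,
            Subgroup.COMORBID: 0.35,
        }
    )
    transitions: dict = field(
        default_factory=lambda: {
            Subgroup.AD_ONLY: (0.10, 0.55),
            Subgroup.MDD_ONLY: (0.08, 0.65),
            Subgroup.COMORBID: (0.40, 0.30),
        }
    )
    baseline_extra: float = 0.2  # extra severity at wave 0 -> post-baseline drop
    disease_boost: float = 0.15  # extra severity while diagnosis active
    ar_coef: float = 0.4
    factor_weights: dict = field(default_factory=lambda: dict(_FACTOR_WEIGHT))
    item_base: dict = field(
        default_factory=lambda: {Scale.IDS: 1.2, Scale.BAI: 1.1, Scale.PSWQ: 1.8}
    )
    noise_sd: float = 1.0
    missing_wave_prob: float = 0.15
    item_factors: dict | None = None  # item id -> factor, overrides the map
    item_weights: dict | None = None  # item id -> coupling multiplier
    seed: int = 0

    def n_total(self) -> int:
        return sum(self.n_per_subgroup.values())


@dataclass
class GroundTruth:
    """Generating quantities needed to score pipeline recovery."""

    subgroup: pd.Series  # participant -> Subgroup value
    coupling: pd.Series  # participant -> factor variance share
    item_factor: dict  # item id -> factor name
    states: np.ndarray  # participants x waves disease-active booleans
    stability_scores: pd.Series
    config: GeneratorConfig


def _ar1_paths(rng, shape, a: float) -> np.ndarray:
    """Stationary AR(1) paths, unit marginal variance; shape (..., T)."""
    out = np.empty(shape)
    out[..., 0] = rng.standard_normal(shape[:-1])
    innov_sd = np.sqrt(1.0 - a * a)
    for t in range(1, shape[-1]):
        out[..., t] = a * out[..., t - 1] + innov_sd * rng.standard_normal(shape[:-1])
    return out


def _disease_chain(rng, subgroup: Subgroup, cfg: GeneratorConfig, n_waves: int):
    if subgroup == Subgroup.CONTROL:
        return np.zeros(n_waves, dtype=bool)
    onset, remit = cfg.transitions[subgroup]
    state = np.empty(n_waves, dtype=bool)
    state[0] = True  # lifetime diagnosis before baseline
    for t in range(1, n_waves):
        p = 1.0 - remit if state[t - 1] else onset
        state[t] = rng.random() < p
    return state


def _covariates(rng, participants) -> pd.DataFrame:
    n = len(participants)
    return pd.DataFrame(
        {
            "age": np.clip(rng.normal(41.5, 13.2, n), 18, 65).round(1),
            "sex": (rng.random(n) < 0.664).astype(int),
            "education": rng.choice(3, size=n, p=(0.033, 0.554, 0.413)),
        },
        index=pd.Index(participants, name="participant"),
    )


def _render_scores(
    rng,
    cfg: GeneratorConfig,
    couplings: np.ndarray,
    severity: np.ndarray,  # participants x waves latent severity offset
) -> np.ndarray:
    """Latent factor model -> discretized Likert scores (p x w x items)."""
    catalog = cfg.catalog
    factors = dict(item_factor_map(catalog))
    if cfg.item_factors:
        factors.update(cfg.item_factors)
    n_p, n_w = severity.shape
    n_i = len(catalog)
    f_idx = np.array([FACTORS.index(factors[it.item_id]) for it in catalog])
    weights = np.array(
        [
            cfg.item_weights.get(it.item_id, cfg.factor_weights[factors[it.item_id]])
            if cfg.item_weights is not None
            else cfg.factor_weights[factors[it.item_id]]
            for it in catalog
        ]
    )
    base = np.array([cfg.item_base[it.scale] for it in catalog])
    lo = np.array([it.min_score for it in catalog], dtype=float)
    hi = np.array([it.max_score for it in catalog], dtype=float)

    fpaths = _ar1_paths(rng, (n_p, len(FACTORS), n_w), cfg.ar_coef)
    noise = _ar1_paths(rng, (n_p, n_i, n_w), cfg.ar_coef) * cfg.noise_sd

    c = np.clip(couplings[:, None] * weights[None, :], 0.0, 0.97)  # p x items
    shared = fpaths[:, f_idx, :]  # p x items x w
    latent = (
        np.sqrt(c)[..., None] * shared + np.sqrt(1.0 - c)[..., None] * noise
    )
    latent = latent.transpose(0, 2, 1)  # p x w x items
    raw = base[None, None, :] + latent + severity[:, :, None]
    return np.clip(np.rint(raw), lo[None, None, :], hi[None, None, :])


def _assemble_cohort(
    rng,
    cfg: GeneratorConfig,
    participants: list,
    subgroups: list,
    couplings: np.ndarray,
    states: np.ndarray,
    ad: np.ndarray,
    mdd: np.ndarray,
) -> tuple[PanelCohort, GroundTruth]:
    n_w = len(cfg.waves)
    offsets = np.array(
        [cfg.severity_offset[s] for s in subgroups]
    )
    severity = (
        offsets[:, None]
        + cfg.disease_boost * states
        + np.concatenate(
            [[cfg.baseline_extra], np.zeros(n_w - 1)]
        )[None, :]
    )
    scores = _render_scores(rng, cfg, couplings, severity)

    # a fraction of participants miss one follow-up wave (4 complete waves)
    miss = rng.random(len(participants)) < cfg.missing_wave_prob
    miss_wave = rng.integers(1, n_w, size=len(participants))
    scores[miss, miss_wave[miss], :] = np.nan

    cohort = PanelCohort(
        participants=list(participants),
        waves=tuple(cfg.waves),
        catalog=cfg.catalog,
        scores=scores,
        ad_flags=ad,
        mdd_flags=mdd,
        covariates=_covariates(rng, participants),
        exclusions={"too_few_complete_waves": 0},
    )
    idx = pd.Index(participants, name="participant")
    factors = dict(item_factor_map(cfg.catalog))
    if cfg.item_factors:
        factors.update(cfg.item_factors)
    truth = GroundTruth(
        subgroup=pd.Series([s.value for s in subgroups], index=idx),
        coupling=pd.Series(couplings, index=idx),
        item_factor=factors,
        states=states,
        stability_scores=pd.Series(states.sum(axis=1), index=idx),
        config=cfg,
    )
    return cohort, truth


def generate(cfg: GeneratorConfig) -> tuple[PanelCohort, GroundTruth]:
    """Simulate a full cohort under the configured study conditions."""
    for sub, n in cfg.n_per_subgroup.items():
        if n < 2:
            raise ValueError(f"n per subgroup must be >= 2, got {n} for {sub}")
    factors = dict(item_factor_map(cfg.catalog))
    if cfg.item_factors:
        factors.update(cfg.item_factors)
    unknown = set(factors.values()) - set(FACTORS)
    if unknown:
        raise ValueError(f"invalid factor assignment: {sorted(unknown)}")

    rng = np.random.default_rng(cfg.seed)
    n_w = len(cfg.waves)
    participants, subgroups = [], []
    for sub in (Subgroup.CONTROL, Subgroup.AD_ONLY, Subgroup.MDD_ONLY, Subgroup.COMORBID):
        n = cfg.n_per_subgroup.get(sub, 0)
        for k in range(n):
            participants.append(f"{sub.value}_{k:04d}")
            subgroups.append(sub)

    n_p = len(participants)
    states = np.zeros((n_p, n_w), dtype=bool)
    ad = np.zeros((n_p, n_w), dtype=bool)
    mdd = np.zeros((n_p, n_w), dtype=bool)
    for pi, sub in enumerate(subgroups):
        chain = _disease_chain(rng, sub, cfg, n_w)
        states[pi] = chain
        if sub in (Subgroup.AD_ONLY, Subgroup.COMORBID):
            ad[pi] = chain
        if sub in (Subgroup.MDD_ONLY, Subgroup.COMORBID):
            mdd[pi] = chain

    couplings = np.array([cfg.coupling[s] for s in subgroups], dtype=float)
    return _assemble_cohort(rng, cfg, participants, subgroups, couplings, states, ad, mdd)


# stability-score distribution of the emulated cohort (scores 0..5)
_SCORE_PROPORTIONS = np.array([360, 374, 249, 252, 220, 194], dtype=float)

# coupling-vs-score profiles for the stability scenarios: density peaking at
# mid (unstable) scores, and its flat null
INVERTED_U_PROFILE = {0: 0.10, 1: 0.33, 2: 0.58, 3: 0.62, 4: 0.33, 5: 0.12}
FLAT_PROFILE = {s: 0.35 for s in range(6)}


def make_stability_scenario(
    cfg: GeneratorConfig,
    target_profile: dict[int, float],
    n_participants: int | None = None,
) -> tuple[PanelCohort, GroundTruth]:
    """Cohort whose coupling is a chosen function of the stability score.

    ``target_profile`` maps stability scores (subset of 0..5) to coupling
    strengths — the generating density profile. Scores are drawn from the
    emulated cohort's score distribution restricted to the profile's keys;
    disease flags are constructed with exactly that many positive
    assessments (baseline positive whenever the score is nonzero, matching
    a lifetime diagnosis). An inverted-U profile peaking at mid scores is
    the scenario behind the quadratic-shape recovery test; a flat profile
    is its null.
    """
    keys = sorted(target_profile)
    if not keys or not set(keys) <= set(range(6)):
        raise ValueError("target_profile keys must be a non-empty subset of 0..5")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_total() if n_participants is None else n_participants
    n_w = len(cfg.waves)

    p = _SCORE_PROPORTIONS[keys]
    scores_drawn = rng.choice(keys, size=n, p=p / p.sum())
    participants = [f"s{scores_drawn[k]}_{k:04d}" for k in range(n)]

    states = np.zeros((n, n_w), dtype=bool)
    subgroups = []
    for pi, s in enumerate(scores_drawn):
        if s > 0:
            states[pi, 0] = True  # lifetime diagnosis at baseline
            extra = rng.choice(n_w - 1, size=s - 1, replace=False) + 1
            states[pi, extra] = True
            subgroups.append(Subgroup.COMORBID)
        else:
            subgroups.append(Subgroup.CONTROL)
    ad = states.copy()
    mdd = states.copy()

    couplings = np.array([target_profile[s] for s in scores_drawn], dtype=float)
    return _assemble_cohort(
        rng, cfg, participants, subgroups, couplings, states, ad, mdd
    )
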