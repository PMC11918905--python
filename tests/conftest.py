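import numpy as np
import pandas as pd
import pytest

from panelwarp import GeneratorConfig, Scale, default_catalog, generate, standardize
from panelwarp.stability import Subgroup


@pytest.fixture(scope="session")
def small_catalog():
    """6-item catalog (3 IDS, 2 BAI, 1 PSWQ) for fast unit tests."""
    return default_catalog({Scale.IDS: 3, Scale.BAI: 2, Scale.PSWQ: 1})


@pytest.fixture(scope="session")
def homogeneous_catalog():
    """Single-scale catalog: items are exchangeable, so a zero-coupling
    cohort is a true null for the edge test."""
    return default_catalog({Scale.IDS: 20, Scale.BAI: 0, Scale.PSWQ: 0})


@pytest.fixture(scope="session")
def sim_cohort():
    """Small simulated cohort with all four subgroups (session-cached)."""
    cfg = GeneratorConfig(
        seed=42,
        n_per_subgroup={
            Subgroup.CONTROL: 20,
            Subgroup.AD_ONLY: 8,
            Subgroup.MDD_ONLY: 10,
            Subgroup.COMORBID: 30,
        },
        catalog=default_catalog({Scale.IDS: 6, Scale.BAI: 4, Scale.PSWQ: 2}),
    )
    return generate(cfg)


@pytest.fixture(scope="session")
def sim_panel(sim_cohort):
    cohort, _ = sim_cohort
    return standardize(cohort)


def write_long_panel(tmp_path, catalog, records, covariates):
    """Helper: write long-format score and covariate CSVs; returns paths."""
    scores = tmp_path / "scores.csv"
    cov = tmp_path / "covariates.csv"
    pd.DataFrame(records, columns=["participant", "wave", "item", "score"]).to_csv(
        scores, index=False
    )
    pd.DataFrame(covariates).to_csv(cov, index=False)
    return scores, cov


def full_records(participants, waves, catalog, score_fn):
    """All item scores for the given participants/waves via score_fn(p, w, item)."""
    recs = []
    for p in participants:
        for w in waves:
            for it in catalog:
                recs.append((p, w, it.item_id, score_fn(p, w, it)))
    return recs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
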