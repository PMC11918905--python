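"""Panel I/O, validation, the complete-wave inclusion rule, standardization."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from panelwarp import (
    ItemDefinition,
    Scale,
    default_catalog,
    load_panel,
    standardize,
    write_panel,
)
from panelwarp.panel import PanelFormatError, PanelValidationError

from conftest import full_records, write_long_panel

WAVES = (0, 2, 4, 6, 9)


def _covs(participants):
    return {
        "participant": list(participants),
        "age": [40.0] * len(participants),
        "sex": [1] * len(participants),
        "education": [2] * len(participants),
    }


class TestCatalog:
    def test_default_composition(self):
        cat = default_catalog()
        assert len(cat) == 62
        by_scale = {s: sum(it.scale == s for it in cat) for s in Scale}
        assert by_scale == {Scale.IDS: 30, Scale.BAI: 21, Scale.PSWQ: 11}
        for it in cat:
            assert (it.min_score, it.max_score) == (
                (0, 4) if it.scale == Scale.PSWQ else (0, 3)
            )
        assert cat.n_pairs() == 1891

    def test_bad_range_rejected(self):
        with pytest.raises(ValueError, match="min_score"):
            ItemDefinition("X1", Scale.IDS, 3, 3)


class TestLoadPanel:
    def test_minimal_valid_long_input(self, small_catalog, tmp_path):
        recs = full_records(["p1", "p2"], WAVES, small_catalog, lambda p, w, it: 1)
        scores, cov = write_long_panel(tmp_path, small_catalog, recs, _covs(["p1", "p2"]))
        cohort = load_panel(scores, cov, catalog=small_catalog)
        assert cohort.n_participants == 2
        assert cohort.exclusions["too_few_complete_waves"] == 0

    def test_three_wave_participant_excluded(self, small_catalog, tmp_path):
        recs = full_records(["keep"], WAVES, small_catalog, lambda p, w, it: 1)
        recs += full_records(["drop"], WAVES[:3], small_catalog, lambda p, w, it: 1)
        scores, cov = write_long_panel(
            tmp_path, small_catalog, recs, _covs(["keep", "drop"])
        )
        cohort = load_panel(scores, cov, catalog=small_catalog)
        assert cohort.participants == ["keep"]
        assert cohort.exclusions["too_few_complete_waves"] == 1

    def test_wave_missing_one_item_is_incomplete(self, small_catalog, tmp_path):
        # 5 waves but one wave lacks one item -> still 4 complete -> retained,
        # and the incomplete wave is blanked wholly
        recs = full_records(["p1"], WAVES, small_catalog, lambda p, w, it: 1)
        recs = [r for r in recs if not (r[1] == 4 and r[2] == "IDS01")]
        scores, cov = write_long_panel(tmp_path, small_catalog, recs, _covs(["p1"]))
        cohort = load_panel(scores, cov, catalog=small_catalog)
        assert cohort.n_participants == 1
        assert cohort.complete_wave_mask().sum() == 4
        assert np.isnan(cohort.scores[0, WAVES.index(4)]).all()

    def test_out_of_range_score_names_item_and_line(self, small_catalog, tmp_path):
        recs = full_records(["p1"], WAVES, small_catalog, lambda p, w, it: 1)
        bad_idx = next(i for i, r in enumerate(recs) if r[2] == "IDS02")
        recs[bad_idx] = (recs[bad_idx][0], recs[bad_idx][1], "IDS02", 4)
        scores, cov = write_long_panel(tmp_path, small_catalog, recs, _covs(["p1"]))
        with pytest.raises(PanelValidationError, match=r"IDS02 at line \d+"):
            load_panel(scores, cov, catalog=small_catalog)

    def test_duplicate_record_rejected(self, small_catalog, tmp_path):
        recs = full_records(["p1"], WAVES, small_catalog, lambda p, w, it: 1)
        recs.append(recs[0])
        scores, cov = write_long_panel(tmp_path, small_catalog, recs, _covs(["p1"]))
        with pytest.raises(PanelFormatError, match="duplicate"):
            load_panel(scores, cov, catalog=small_catalog)

    def test_unknown_item_rejected(self, small_catalog, tmp_path):
        recs = full_records(["p1"], WAVES, small_catalog, lambda p, w, it: 1)
        recs.append(("p1", 0, "HAM01", 1))
        scores, cov = write_long_panel(tmp_path, small_catalog, recs, _covs(["p1"]))
        with pytest.raises(PanelFormatError, match="unknown item"):
            load_panel(scores, cov, catalog=small_catalog)

    def test_exclusion_order_independent(self, small_catalog, tmp_path, rng):
        recs = full_records(["a", "b"], WAVES, small_catalog, lambda p, w, it: 1)
        recs += full_records(["c"], WAVES[:2], small_catalog, lambda p, w, it: 1)
        perm = list(recs)
        rng.shuffle(perm)
        d1 = tmp_path / "one"; d1.mkdir()
        d2 = tmp_path / "two"; d2.mkdir()
        s1, c1 = write_long_panel(d1, small_catalog, recs, _covs(["a", "b", "c"]))
        s2, c2 = write_long_panel(d2, small_catalog, perm, _covs(["a", "b", "c"]))
        k1 = load_panel(s1, c1, catalog=small_catalog)
        k2 = load_panel(s2, c2, catalog=small_catalog)
        assert sorted(k1.participants) == sorted(k2.participants) == ["a", "b"]

    def test_roundtrip_exact(self, sim_cohort, tmp_path):
        cohort, _ = sim_cohort
        write_panel(cohort, tmp_path / "s.csv", tmp_path / "c.csv")
        back = load_panel(tmp_path / "s.csv", tmp_path / "c.csv",
                          catalog=cohort.catalog)
        assert back.participants == cohort.participants
        np.testing.assert_array_equal(back.scores, cohort.scores)
        np.testing.assert_array_equal(back.ad_flags, cohort.ad_flags)
        np.testing.assert_array_equal(back.mdd_flags, cohort.mdd_flags)

    def test_wide_format(self, small_catalog, tmp_path):
        rows = []
        for p in ("p1", "p2"):
            for w in WAVES:
                row = {"participant": p, "wave": w}
                row.update({it.item_id: 2 for it in small_catalog})
                rows.append(row)
        wide = tmp_path / "wide.csv"
        pd.DataFrame(rows).to_csv(wide, index=False)
        cov = tmp_path / "cov.csv"
        pd.DataFrame(_covs(["p1", "p2"])).to_csv(cov, index=False)
        cohort = load_panel(wide, cov, catalog=small_catalog, fmt="wide")
        assert cohort.n_participants == 2
        assert np.nanmax(cohort.scores) == 2


class TestStandardize:
    def test_pooled_moments(self, small_catalog, tmp_path):
        # one item takes values 0,1,2,3 with equal frequency across the pool
        recs = full_records(
            ["p1", "p2"], (0, 2, 4, 6), small_catalog,
            lambda p, w, it: ((0, 2, 4, 6).index(w) if it.item_id == "IDS01" else 1),
        )
        scores, cov = write_long_panel(tmp_path, small_catalog, recs, _covs(["p1", "p2"]))
        panel = standardize(load_panel(scores, cov, catalog=small_catalog))
        k = 0  # IDS01 position
        assert panel.item_means[k] == pytest.approx(1.5)
        # sample SD (n-1) of {0,0,1,1,2,2,3,3}
        expected_sd = np.std([0, 0, 1, 1, 2, 2, 3, 3], ddof=1)
        assert panel.item_sds[k] == pytest.approx(expected_sd)

    def test_z_scores_have_zero_mean_unit_sd(self, sim_panel):
        flat = sim_panel.z_scores.reshape(-1, sim_panel.z_scores.shape[-1])
        keep = ~sim_panel.zero_variance_items
        np.testing.assert_allclose(np.nanmean(flat, axis=0)[keep], 0, atol=1e-8)
        np.testing.assert_allclose(
            np.nanstd(flat, axis=0, ddof=1)[keep], 1, atol=1e-8
        )

    def test_constant_item_flagged_z_zero(self, small_catalog, tmp_path, caplog):
        recs = full_records(
            ["p1", "p2"], WAVES, small_catalog,
            lambda p, w, it: 0 if it.item_id == "BAI01" else (1 + WAVES.index(w) % 2),
        )
        scores, cov = write_long_panel(tmp_path, small_catalog, recs, _covs(["p1", "p2"]))
        with caplog.at_level("WARNING"):
            panel = standardize(load_panel(scores, cov, catalog=small_catalog))
        k = small_catalog.index("BAI01")
        assert panel.zero_variance_items[k]
        np.testing.assert_array_equal(panel.z_scores[..., k], 0)
        assert "zero pooled SD" in caplog.text

    def test_idempotent(self, sim_cohort):
        cohort, _ = sim_cohort
        panel = standardize(cohort)
        again = standardize(
            dataclasses.replace(cohort, scores=panel.z_scores)
        )
        mask = ~np.isnan(panel.z_scores)
        np.testing.assert_allclose(
            again.z_scores[mask], panel.z_scores[mask], atol=1e-8
        )

    def test_raw_means_precede_standardization(self, sim_panel):
        cohort = sim_panel.cohort
        pi = 0
        expected = np.nanmean(cohort.scores[pi], axis=0)
        np.testing.assert_allclose(sim_panel.raw_item_means[pi], expected)
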