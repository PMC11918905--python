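"""Edge tests vs reference fits, centrality, adjusted density, layouts."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from panelwarp import (
    GeneratorConfig,
    Scale,
    build_network,
    centrality,
    cohort_distances,
    default_catalog,
    generate,
    invert_distances,
    network_density,
    participant_density,
    standardize,
)
from panelwarp import network as nw

edge_tests = nw.test_edges  # alias: module-level test_* names confuse pytest
from panelwarp.stability import Subgroup


@pytest.fixture(scope="module")
def small_table():
    """Distance table from a small cohort with real factor structure."""
    cat = default_catalog({Scale.IDS: 8, Scale.BAI: 0, Scale.PSWQ: 0})
    cfg = GeneratorConfig(
        seed=21, catalog=cat,
        n_per_subgroup={Subgroup.CONTROL: 40},
        coupling={Subgroup.CONTROL: 0.4},
    )
    cohort, _ = generate(cfg)
    return cohort_distances(standardize(cohort)), cohort


class TestEdgeTestAgainstReferenceFits:
    def test_adjusted_matches_ols_with_participant_dummies(self, small_table):
        table, _ = small_table
        res = edge_tests(table, alpha=0.01, mode="adjusted")
        y = table["distance"].to_numpy()
        parts = pd.get_dummies(table["participant"], drop_first=True).to_numpy(float)
        for k in [0, 7, 20]:  # spot-check pairs against the full OLS
            row = res.iloc[k]
            focal = (
                (table["item_i"] == row["item_i"])
                & (table["item_j"] == row["item_j"])
            ).to_numpy(float)
            X = sm.add_constant(
                np.column_stack([focal, table["pair_mean_raw"].to_numpy(), parts])
            )
            fit = sm.OLS(y, X).fit()
            assert row["effect"] == pytest.approx(fit.params[1], rel=1e-6)
            # one-sided p from the reference two-sided t-test
            p_ref = stats.t.cdf(fit.tvalues[1], fit.df_resid)
            assert row["p_value"] == pytest.approx(p_ref, rel=1e-5)

    def test_ttest_matches_scipy(self, small_table):
        table, _ = small_table
        res = edge_tests(table, alpha=0.01, mode="ttest")
        y = table["distance"].to_numpy()
        for k in [1, 13]:
            row = res.iloc[k]
            focal = (
                (table["item_i"] == row["item_i"])
                & (table["item_j"] == row["item_j"])
            ).to_numpy()
            ref = stats.ttest_ind(y[focal], y[~focal], alternative="less")
            assert row["p_value"] == pytest.approx(ref.pvalue, rel=1e-8)

    def test_item_means_coding_runs(self, small_table):
        table, _ = small_table
        res = edge_tests(table, mode="adjusted", adjust="item_means")
        assert res["p_value"].between(0, 1).all()

    def test_significant_edges_are_below_rest_mean(self, small_table):
        table, _ = small_table
        res = edge_tests(table, alpha=0.05)
        grand = table["distance"].mean()
        sig = res[res["significant"]]
        assert len(sig) > 0
        assert (sig["mean_distance"] < grand).all()

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.1])
    def test_alpha_bounds(self, small_table, alpha):
        with pytest.raises(ValueError, match="alpha"):
            edge_tests(small_table[0], alpha=alpha)

    def test_requires_two_participants(self, small_table):
        table, _ = small_table
        one = table[table["participant"] == table["participant"].iloc[0]]
        with pytest.raises(ValueError, match="2 participants"):
            edge_tests(one)

    def test_null_pair_is_nonsignificant(self):
        # distances drawn from one exchangeable distribution: no pair should
        # stand out at a strict alpha
        rng = np.random.default_rng(0)
        parts = [f"p{i}" for i in range(60)]
        items = [f"I{k}" for k in range(6)]
        rows = []
        for p in parts:
            for a in range(6):
                for b in range(a + 1, 6):
                    rows.append((p, items[a], items[b], rng.gamma(2, 1), 1.0))
        table = pd.DataFrame(
            rows, columns=["participant", "item_i", "item_j", "distance", "pair_mean_raw"]
        )
        res = edge_tests(table, alpha=1e-4)
        assert not res["significant"].any()


class TestCentrality:
    def test_isolated_item_flagged_and_lowest(self, small_table):
        table, _ = small_table
        edges = edge_tests(table, alpha=0.05)
        cents = centrality(table, edges)
        iso = cents[cents["isolated"]]
        if len(iso):
            assert (iso["centrality"] == 0).all()
            assert iso["std_centrality"].max() <= cents["std_centrality"].min() + 1e-12 \
                or (cents.loc[~cents["isolated"], "centrality"] > 0).all()

    def test_ranking_invariant_to_row_order(self, small_table):
        table, _ = small_table
        edges = edge_tests(table, alpha=0.05)
        c1 = centrality(table, edges)
        shuffled = table.sample(frac=1, random_state=1)
        c2 = centrality(shuffled, edge_tests(shuffled, alpha=0.05))
        m1 = dict(zip(c1["item"], c1["centrality"]))
        m2 = dict(zip(c2["item"], c2["centrality"]))
        for item in m1:
            assert m1[item] == pytest.approx(m2[item])


class TestDensity:
    def test_linear_inversion_antimonotone(self, small_table):
        table, _ = small_table
        d1 = participant_density(table, reference=5.0)
        scaled = table.assign(distance=table["distance"] * 1.5)
        d2 = participant_density(scaled, reference=5.0)
        assert (d2 < d1).all()

    def test_reciprocal_inversion(self):
        d = np.array([0.5, 2.0])
        np.testing.assert_allclose(invert_distances(d, "reciprocal"), [2.0, 0.5])

    def test_age_location_shift_leaves_group_differences(self, small_table):
        table, cohort = small_table
        rng = np.random.default_rng(2)
        grouping = pd.Series(
            rng.choice(["x", "y"], size=cohort.n_participants),
            index=cohort.participants,
        )
        est1, comp1, _ = network_density(table, cohort.covariates, grouping)
        shifted = cohort.covariates.assign(age=cohort.covariates["age"] + 100)
        est2, comp2, _ = network_density(table, shifted, grouping)
        assert comp1["difference"].iloc[0] == pytest.approx(
            comp2["difference"].iloc[0]
        )

    def test_identical_groups_similar_density(self, small_table):
        table, cohort = small_table
        # arbitrary halves of one homogeneous cohort
        half = cohort.n_participants // 2
        grouping = pd.Series(
            ["a"] * half + ["b"] * (cohort.n_participants - half),
            index=cohort.participants,
        )
        est, comp, _ = network_density(table, cohort.covariates, grouping)
        assert comp["p_value"].iloc[0] > 0.01

    def test_small_group_excluded(self, small_table, caplog):
        table, cohort = small_table
        grouping = pd.Series("big", index=pd.Index(cohort.participants))
        grouping.iloc[0] = "lonely"
        with caplog.at_level("WARNING"):
            est, _, _ = network_density(table, cohort.covariates, grouping)
        assert [e.group for e in est] == ["big"]
        assert "lonely" in caplog.text


class TestBuildNetwork:
    def test_subgroup_inherits_layout_bitwise(self, small_table):
        table, _ = small_table
        edges = edge_tests(table, alpha=0.05)
        cents = centrality(table, edges)
        whole = build_network(edges, cents, seed=3)
        sub_edges = edges.assign(significant=edges["significant"] & (edges["p_value"] < 1e-6))
        sub = build_network(sub_edges, cents, layout_source=whole, group="sub")
        for node in sub.graph.nodes:
            assert sub.layout[node] == whole.layout[node]
        assert sub.edge_scale == whole.edge_scale

    def test_same_seed_same_layout(self, small_table):
        table, _ = small_table
        edges = edge_tests(table, alpha=0.05)
        cents = centrality(table, edges)
        n1 = build_network(edges, cents, seed=9)
        n2 = build_network(edges, cents, seed=9)
        assert n1.layout == n2.layout

    def test_empty_edge_set_exports(self, small_table, tmp_path):
        table, _ = small_table
        edges = edge_tests(table, alpha=0.05).assign(significant=False)
        cents = centrality(table, edges)
        net = build_network(edges, cents)
        assert net.graph.number_of_edges() == 0
        net.to_graphml(tmp_path / "empty.graphml")
        net.to_json(tmp_path / "empty.json")
        assert (tmp_path / "empty.graphml").exists()

    def test_layout_source_must_cover_nodes(self, small_table):
        table, _ = small_table
        edges = edge_tests(table, alpha=0.05)
        cents = centrality(table, edges)
        whole = build_network(edges, cents)
        extra = pd.concat(
            [cents, pd.DataFrame([{"item": "NEW", "centrality": 0.0,
                                   "std_centrality": 0.0, "isolated": True}])],
            ignore_index=True,
        )
        with pytest.raises(ValueError, match="lacks nodes"):
            build_network(edges, extra, layout_source=whole)
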