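import numpy as np
import pandas as pd
import pytest

from metaexpr.coexpression_screen import (
    correlation_to_index,
    genomewide_smd,
    screen_and_intersect,
    top_correlate,
)
from metaexpr.effect_size import smd_from_cohort
from metaexpr.meta_pool import pool_random_dl
from metaexpr.synthetic_data import SimConfig, simulate_cohorts

from conftest import make_cohort


@pytest.fixture(scope="module")
def small_bundle():
    cfg = SimConfig(
        n_cohorts=5, n_genes=40, n_case=15, n_ctrl=15,
        partner_loadings={"P1": 0.9, "P2": 0.3}, theta=2.0, tau=0.5, seed=77,
    )
    return simulate_cohorts(cfg)


class TestGenomewideSmd:
    def test_agrees_with_per_gene_pooling(self, small_bundle):
        """Dual route: the vectorized table must equal explicit per-cohort
        effect computation followed by DL pooling, gene by gene."""
        cohorts, _ = small_bundle
        table = genomewide_smd(cohorts, min_k=3)
        for gene in ["IDX", "P1", "G00005"]:
            effects = [smd_from_cohort(c, gene) for c in cohorts]
            expected = pool_random_dl(effects)
            assert table.loc[gene, "smd"] == pytest.approx(expected.pooled, abs=1e-10)
            assert table.loc[gene, "ci_low"] == pytest.approx(expected.ci_low, abs=1e-10)

    def test_gene_below_min_k_omitted(self, small_bundle):
        cohorts, _ = small_bundle
        trimmed = [c for c in cohorts[:2]]
        extra = cohorts[2].values.drop(index="G00001")
        from metaexpr.expression_io import ExpressionCohort

        trimmed.append(
            ExpressionCohort(cohorts[2].cohort_id, extra, cohorts[2].groups)
        )
        table = genomewide_smd(trimmed, min_k=3)
        assert "G00001" not in table.index
        assert table.attrs["n_omitted"] >= 1

    def test_constant_gene_skipped_as_degenerate(self):
        cohorts = []
        for k in range(3):
            rng = np.random.default_rng(k)
            case, ctrl = rng.normal(1, 1, (2, 10)), rng.normal(0, 1, (2, 10))
            case[1] = ctrl[1] = 5.0  # flat gene in every cohort
            cohorts.append(make_cohort(case, ctrl, genes=["GA", "FLAT"], cohort_id=f"C{k}"))
        table = genomewide_smd(cohorts, min_k=2)
        assert "FLAT" not in table.index
        assert "GA" in table.index

    def test_planted_gene_flagged_up(self, small_bundle):
        cohorts, truth = small_bundle
        table = genomewide_smd(cohorts, min_k=3)
        assert table.loc["IDX", "smd"] > 1.0
        null_genes = truth.index[
            (truth["lambda"] == 0) & (truth["true_smd_mean"] == 0)
        ]
        null_genes = [g for g in null_genes if g in table.index]
        assert (table.loc[null_genes, "smd"].abs() > 1).mean() < 0.05


class TestCorrelationToIndex:
    def test_equal_correlation_pools_to_itself(self):
        # two cohorts whose sample correlation with the index is exactly 0.5
        cohorts = []
        for k in range(2):
            rng = np.random.default_rng(k + 1)
            n = 20
            x = rng.standard_normal(n)
            e = rng.standard_normal(n)
            # orthogonalize, standardize, then mix at exactly r = 0.5
            x = (x - x.mean()) / x.std()
            e = e - e @ x / (x @ x) * x
            e = (e - e.mean()) / e.std()
            y = 0.5 * x + np.sqrt(0.75) * e
            mat = np.vstack([x, y])
            cohorts.append(
                make_cohort(mat[:, :10], mat[:, 10:], genes=["IDX", "GY"],
                            cohort_id=f"C{k}")
            )
        table = correlation_to_index(cohorts, "IDX", min_k=2)
        assert table.loc["GY", "r_pooled"] == pytest.approx(0.5, abs=1e-9)
        # CI symmetric in z space around atanh(0.5)
        z_lo = np.arctanh(table.loc["GY", "r_ci_low"])
        z_hi = np.arctanh(table.loc["GY", "r_ci_high"])
        assert (z_lo + z_hi) / 2 == pytest.approx(np.arctanh(0.5), abs=1e-9)

    def test_self_correlation_is_clamped_and_flagged(self, small_bundle):
        cohorts, _ = small_bundle
        table = correlation_to_index(cohorts, "IDX", min_k=3)
        assert table.loc["IDX", "r_pooled"] > 0.999
        assert table.loc["IDX", "r_pooled"] < 1.0
        assert bool(table.loc["IDX", "degenerate_corr"])

    def test_matches_manual_fisher_pooling(self, small_bundle):
        cohorts, _ = small_bundle
        table = correlation_to_index(cohorts, "IDX", min_k=3)
        gene = "P1"
        zs, vs = [], []
        for c in cohorts:
            r = np.corrcoef(
                c.values.loc[gene].to_numpy(), c.values.loc["IDX"].to_numpy()
            )[0, 1]
            zs.append(np.arctanh(r))
            vs.append(1.0 / (len(c.samples) - 3))
        expected = pool_random_dl(
            [
                __import__("metaexpr").StudyEffect(f"c{i}", z, v, 5, 5)
                for i, (z, v) in enumerate(zip(zs, vs))
            ]
        )
        assert np.arctanh(table.loc[gene, "r_pooled"]) == pytest.approx(
            expected.pooled, abs=1e-10
        )

    def test_loading_recovered_as_correlation(self, small_bundle):
        cohorts, truth = small_bundle
        table = correlation_to_index(cohorts, "IDX", min_k=3)
        assert table.loc["P1", "r_pooled"] == pytest.approx(0.9, abs=0.08)
        assert table.loc["P2", "r_pooled"] == pytest.approx(0.3, abs=0.15)

    def test_index_absent_everywhere_errors(self, small_bundle):
        cohorts, _ = small_bundle
        with pytest.raises(ValueError, match="absent"):
            correlation_to_index(cohorts, "NOPE")


class TestScreenAndIntersect:
    def test_empty_tables_give_zero_counts(self):
        empty_smd = pd.DataFrame(columns=["smd", "k"]).astype(float)
        empty_corr = pd.DataFrame(columns=["r_pooled", "p_r", "k"]).astype(float)
        _, counts = screen_and_intersect(empty_smd, empty_corr)
        assert all(v == 0 for v in counts.values())

    def test_hand_built_table_matches_rule_by_rule(self):
        smd = pd.DataFrame(
            {"smd": [2.0, -2.0, 2.0, -2.0, 0.5, 1.0]},
            index=["up_pos", "dn_neg", "up_only", "dn_only", "corr_only", "edge"],
        )
        corr = pd.DataFrame(
            {
                "r_pooled": [0.9, -0.9, 0.1, -0.1, 0.9, 0.9],
                "p_r": [0.001, 0.001, 0.5, 0.5, 0.001, 0.001],
            },
            index=smd.index,
        )
        rec, counts = screen_and_intersect(smd, corr)
        assert bool(rec.loc["up_pos", "up_and_pos"])
        assert bool(rec.loc["dn_neg", "down_and_neg"])
        assert not rec.loc["up_only", "up_and_pos"]
        assert not rec.loc["dn_only", "down_and_neg"]
        assert not rec.loc["corr_only", "up"]
        assert not rec.loc["edge", "up"]  # smd exactly 1.0: strict inequality
        assert counts == {
            "up": 2, "down": 2, "pos_corr": 3, "neg_corr": 1,
            "up_and_pos": 1, "down_and_neg": 1,
        }

    def test_smd_exactly_one_is_not_up(self):
        smd = pd.DataFrame({"smd": [1.0]}, index=["edge"])
        corr = pd.DataFrame({"r_pooled": [0.9], "p_r": [0.001]}, index=["edge"])
        rec, _ = screen_and_intersect(smd, corr)
        assert not rec.loc["edge", "up"]
        assert not rec.loc["edge", "up_and_pos"]

    def test_intersections_are_contained_in_their_parents(self, small_bundle):
        cohorts, _ = small_bundle
        rec, _ = screen_and_intersect(
            genomewide_smd(cohorts, min_k=3),
            correlation_to_index(cohorts, "IDX", min_k=3),
        )
        assert (rec["up_and_pos"] <= rec["up"]).all()
        assert (rec["up_and_pos"] <= rec["pos_corr"]).all()
        assert (rec["down_and_neg"] <= rec["down"]).all()

    def test_cohort_reordering_leaves_flags_unchanged(self, small_bundle):
        cohorts, _ = small_bundle
        def flags(cs):
            rec, _ = screen_and_intersect(
                genomewide_smd(cs, min_k=3), correlation_to_index(cs, "IDX", min_k=3)
            )
            return rec[["up", "down", "pos_corr", "neg_corr"]]
        pd.testing.assert_frame_equal(flags(cohorts), flags(cohorts[::-1]))


class TestTopCorrelate:
    def test_strong_partner_beats_weak(self, small_bundle):
        cohorts, _ = small_bundle
        rec, _ = screen_and_intersect(
            genomewide_smd(cohorts, min_k=3),
            correlation_to_index(cohorts, "IDX", min_k=3),
        )
        assert top_correlate(rec, "IDX") == "P1"

    def test_tie_breaks_lexicographically(self):
        smd = pd.DataFrame({"smd": [2.0, 2.0]}, index=["ZZ", "AA"])
        corr = pd.DataFrame(
            {"r_pooled": [0.8, 0.8], "p_r": [0.001, 0.001]}, index=["ZZ", "AA"]
        )
        rec, _ = screen_and_intersect(smd, corr)
        assert top_correlate(rec, "IDX") == "AA"

    def test_no_qualifying_genes_errors(self):
        smd = pd.DataFrame({"smd": [0.0]}, index=["GA"])
        corr = pd.DataFrame({"r_pooled": [0.1], "p_r": [0.9]}, index=["GA"])
        rec, _ = screen_and_intersect(smd, corr)
        with pytest.raises(ValueError):
            top_correlate(rec, "IDX")
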