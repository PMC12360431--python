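"""NB Wald test, dispersion estimation, BH adjustment, DEG set assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from orthodev import diffexpr
from orthodev.containers import CountMatrix, make_design
from orthodev.diffexpr import DEThresholds, bh_adjust

from conftest import nb_counts


def two_group_matrix(rng, mu_pc, mu_g, dispersion=0.05, n=3):
    design = make_design("sp", stages=("PC", "G"), n_replicates=n)
    mu = np.column_stack([np.tile(mu_pc, (n, 1)).T, np.tile(mu_g, (n, 1)).T])
    counts = nb_counts(rng, mu, dispersion, mu.shape)
    genes = [f"sp|g{i:04d}" for i in range(len(mu_pc))]
    return CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=design.index), design=design
    )


class TestBH:
    def test_hand_stepped_example(self):
        assert np.allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])

    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=200)
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_statsmodels_and_properties(self, pvals):
        p = np.array(pvals)
        ours = bh_adjust(p)
        _, theirs, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(ours, theirs, atol=1e-12)
        assert (ours >= p - 1e-15).all() and (ours <= 1).all()
        # order invariance
        perm = np.random.default_rng(0).permutation(len(p))
        assert np.allclose(bh_adjust(p[perm]), ours[perm], atol=1e-15)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestDispersion:
    def test_poisson_counts_hit_the_floor(self, rng):
        design = make_design("sp")
        mu = np.exp(rng.normal(5, 0.5, 300))
        counts = rng.poisson(mu[:, None], (300, 9))
        cm = CountMatrix(
            counts=pd.DataFrame(
                counts, index=[f"sp|g{i}" for i in range(300)], columns=design.index
            ),
            design=design,
        )
        disp = diffexpr.estimate_dispersion(cm, pd.Series(1.0, index=cm.samples))
        assert np.median(disp) < 0.01

    def test_nb_truth_recovered_in_range(self, rng):
        design = make_design("sp")
        mu = np.exp(rng.normal(5, 1, 2000))
        counts = nb_counts(rng, mu[:, None], 0.1, (2000, 9))
        cm = CountMatrix(
            counts=pd.DataFrame(
                counts, index=[f"sp|g{i}" for i in range(2000)], columns=design.index
            ),
            design=design,
        )
        disp = diffexpr.estimate_dispersion(cm, pd.Series(1.0, index=cm.samples))
        assert 0.05 <= np.median(disp) <= 0.2

    def test_constant_gene_floors_without_error(self):
        design = make_design("sp")
        counts = np.full((2, 9), 7)
        counts[1] = np.arange(9) + 1
        cm = CountMatrix(
            counts=pd.DataFrame(counts, index=["sp|a", "sp|b"], columns=design.index),
            design=design,
        )
        disp = diffexpr.estimate_dispersion(cm, pd.Series(1.0, index=cm.samples))
        assert disp["sp|a"] >= diffexpr.DISPERSION_FLOOR

    def test_single_replicate_stage_instructs_pooling(self):
        design = make_design("sp").iloc[[0, 3, 4, 6, 7]]
        counts = np.ones((3, 5), dtype=int)
        cm = CountMatrix(
            counts=pd.DataFrame(
                counts, index=["sp|a", "sp|b", "sp|c"], columns=design.index
            ),
            design=design,
        )
        with pytest.raises(ValueError, match="pooled dispersion"):
            diffexpr.estimate_dispersion(cm, pd.Series(1.0, index=cm.samples))


class TestDETest:
    def test_null_no_calls_at_large_counts(self, rng):
        mu = np.full(100, 500.0)
        cm = two_group_matrix(rng, mu, mu)
        res = diffexpr.de_test(cm, "PCvsG")
        assert np.abs(res["log2fc"]).mean() < 0.3
        assert res["is_deg"].mean() < 0.05

    def test_planted_fold_change_sensitivity_and_fdr(self, rng):
        n_de, n_null = 500, 1500
        mu_pc = np.full(n_de + n_null, 200.0)
        mu_g = mu_pc.copy()
        mu_g[:n_de] *= 2.0**3
        cm = two_group_matrix(rng, mu_pc, mu_g, dispersion=0.05)
        res = diffexpr.de_test(cm, "PCvsG")
        called = res["is_deg"].to_numpy()
        sensitivity = called[:n_de].mean()
        fdr = called[n_de:].sum() / max(called.sum(), 1)
        assert sensitivity >= 0.9
        assert fdr <= 0.1
        assert (res.loc[called & (res["log2fc"] > 0), "up_stage"] == "G").all()

    def test_pvalues_match_independent_wald_evaluation(self, rng):
        mu = np.exp(rng.normal(5, 1, 20))
        cm = two_group_matrix(rng, mu, mu, dispersion=0.1)
        factors = pd.Series(1.0, index=cm.samples)
        disp = diffexpr.estimate_dispersion(cm, factors)
        res = diffexpr.de_test(cm, "PCvsG", factors, disp)
        # brute-force re-evaluation, one gene at a time
        pc_cols = cm.samples_for_stage("PC")
        g_cols = cm.samples_for_stage("G")
        for gene in cm.genes:
            m_pc = cm.counts.loc[gene, pc_cols].mean()
            m_g = cm.counts.loc[gene, g_cols].mean()
            lfc = np.log2(m_g + 0.5) - np.log2(m_pc + 0.5)
            a = disp[gene]
            se = np.sqrt(
                (m_pc + a * m_pc**2) / 3 / ((m_pc + 0.5) * np.log(2)) ** 2
                + (m_g + a * m_g**2) / 3 / ((m_g + 0.5) * np.log(2)) ** 2
            )
            p = 2 * stats.norm.sf(abs(lfc / se))
            assert res.loc[gene, "log2fc"] == pytest.approx(lfc, abs=1e-12)
            assert res.loc[gene, "p"] == pytest.approx(p, abs=1e-12)

    def test_all_zero_gene_kept_with_unit_p(self, rng):
        mu = np.full(30, 50.0)
        cm = two_group_matrix(rng, mu, mu)
        counts = cm.counts.copy()
        counts.iloc[0] = 0
        cm = CountMatrix(counts=counts, design=cm.design)
        res = diffexpr.de_test(cm, "PCvsG")
        assert res.iloc[0]["p"] == 1.0 and not res.iloc[0]["is_deg"]

    def test_unknown_comparison_rejected(self, flat_count_matrix):
        with pytest.raises(ValueError, match="comparison"):
            diffexpr.de_test(flat_count_matrix, "PCvsS")

    def test_boundary_modes_configurable(self, rng):
        mu_pc = np.full(50, 100.0)
        mu_g = mu_pc * 2.0  # planted log2fc exactly 1
        cm = two_group_matrix(rng, mu_pc, mu_g, dispersion=1e-4)
        inclusive = diffexpr.de_test(
            cm, "PCvsG", thresholds=DEThresholds(lfc_inclusive=True)
        )
        strict = diffexpr.de_test(
            cm, "PCvsG", thresholds=DEThresholds(lfc_inclusive=False)
        )
        assert inclusive["is_deg"].sum() >= strict["is_deg"].sum()


class TestDegSets:
    def make_results(self):
        def frame(comparison, rows):
            df = pd.DataFrame(
                rows, columns=["gene", "log2fc", "p", "padj", "is_deg", "up_stage"]
            ).set_index("gene")
            df["comparison"] = comparison
            return df

        r1 = frame(
            "PCvsG",
            [
                ("g1", 2.0, 0.001, 0.01, True, "G"),
                ("g2", -2.0, 0.001, 0.01, True, "PC"),
                ("g3", 0.1, 0.5, 0.9, False, "none"),
            ],
        )
        r2 = frame(
            "GvsS",
            [
                ("g1", -2.0, 0.001, 0.01, True, "G"),
                ("g2", 0.0, 0.9, 0.9, False, "none"),
                ("g3", 3.0, 0.001, 0.01, True, "S"),
            ],
        )
        return {"PCvsG": r1, "GvsS": r2}

    def test_empty_results_all_empty(self):
        empty = pd.DataFrame(
            columns=["log2fc", "p", "padj", "is_deg", "up_stage"],
            index=pd.Index([], name="gene"),
        )
        empty["is_deg"] = empty["is_deg"].astype(bool)
        sets = diffexpr.deg_sets({"PCvsG": empty})
        assert sets.union == set()

    def test_gene_up_in_g_in_both_comparisons_counted_once(self):
        sets = diffexpr.deg_sets(self.make_results())
        assert "g1" in sets.up[("PCvsG", "G")]
        assert "g1" in sets.up[("GvsS", "G")]
        assert sets.total == 3

    def test_sets_match_brute_force_filter(self):
        results = self.make_results()
        sets = diffexpr.deg_sets(results)
        for comparison, res in results.items():
            for stage in set(res["up_stage"]) - {"none"}:
                brute = set(
                    res.index[(res["is_deg"]) & (res["up_stage"] == stage)]
                )
                assert sets.up[(comparison, stage)] == brute
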