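"""Moderated t-test, variance prior, normalization, DEG rule and ORA."""

import math
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

import bsig
from bsig.degs import VariancePrior, trigamma_inverse
from bsig.errors import AnalysisError, ConsistencyError


def _study(values, n_a=3, n_b=3, subset="naive"):
    genes = [f"g{i}" for i in range(values.shape[0])]
    cols = [f"HC{i}_{subset}" for i in range(1, n_a + 1)] + [
        f"SLE{i}_{subset}" for i in range(1, n_b + 1)
    ]
    matrix = bsig.ExpressionMatrix(pd.DataFrame(values, index=genes, columns=cols))
    sheet = bsig.SampleSheet(
        pd.DataFrame(
            {
                "sample_id": cols,
                "donor_id": [c.split("_")[0] for c in cols],
                "group": ["HC"] * n_a + ["SLE"] * n_b,
                "subset": [subset] * (n_a + n_b),
            }
        )
    )
    return matrix, sheet


class TestNormalizePercentile:
    def test_column_at_zero_percentile_unchanged(self):
        # first sample's sorted values (-2, -1, 0, 0) have 75th percentile 0
        values = np.array([[-1.0, 5.0], [0.0, 6.0], [0.0, 7.0], [-2.0, 8.0]])
        matrix, _ = _study(values, n_a=1, n_b=1)
        out = bsig.normalize_percentile(matrix, 75.0)
        np.testing.assert_allclose(out.data.iloc[:, 0], matrix.data.iloc[:, 0])

    def test_shift_invariance(self, tiny_matrix):
        matrix, _ = tiny_matrix
        shifted = matrix.data.copy()
        shifted.iloc[:, 0] += 3.7
        a = bsig.normalize_percentile(matrix).values
        b = bsig.normalize_percentile(bsig.ExpressionMatrix(shifted)).values
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_percentile_matches_sort_and_interpolate_oracle(self):
        column = np.array([1.0, 2.0, 3.0, 4.0])
        # oracle: order statistics with linear interpolation at index (n-1)*q
        q = 0.75
        pos = (len(column) - 1) * q
        lo, frac = int(pos), pos - int(pos)
        ordered = np.sort(column)
        expected = ordered[lo] + frac * (ordered[lo + 1] - ordered[lo])
        assert expected == 3.25
        # the 4 values form one sample's column (normalization is per sample)
        values = np.column_stack([column, np.zeros(4)])
        matrix, _ = _study(values, n_a=1, n_b=1)
        out = bsig.normalize_percentile(matrix, 75.0)
        np.testing.assert_allclose(out.data.iloc[:, 0], column - expected)


class TestFoldChange:
    def test_signed_convention(self, tiny_matrix):
        matrix, sheet = tiny_matrix
        fc = bsig.fold_change(matrix, sheet, "naive")
        assert fc["GA"] == pytest.approx(4.0)  # +2 log2
        assert fc["GB"] == pytest.approx(1.0)  # no change
        assert fc["GC"] == pytest.approx(-2.0)  # -1 log2 -> -1/r

    def test_downregulation_reported_as_negative_magnitude(self):
        # linear ratio 1/1.164 must come back as the signed value -1.164
        diff = -math.log2(1.164)
        matrix, sheet = _study(np.array([[0.0] * 3 + [diff] * 3]))
        fc = bsig.fold_change(matrix, sheet, "naive")
        assert fc.iloc[0] == pytest.approx(-1.164, rel=1e-12)
        assert (fc.abs() >= 1).all()

    def test_missing_subset_is_an_error(self, tiny_matrix):
        matrix, sheet = tiny_matrix
        with pytest.raises(AnalysisError, match="memory"):
            bsig.fold_change(matrix, sheet, "memory")


class TestVariancePrior:
    def test_trigamma_inverse_matches_series_oracle(self):
        # trigamma(2) by its defining series sum_{k>=0} 1/(2+k)^2
        y = sum(1.0 / (2.0 + k) ** 2 for k in range(2_000_000))
        y += 1.0 / 2_000_002  # tail integral correction
        assert trigamma_inverse(y) == pytest.approx(2.0, abs=1e-6)
        # and the exact closed form pi^2/6 - 1
        assert trigamma_inverse(math.pi**2 / 6 - 1) == pytest.approx(2.0, abs=1e-8)

    def test_identical_variances_give_infinite_d0(self):
        prior = bsig.fit_variance_prior(np.full(100, 0.3), 6)
        assert math.isinf(prior.d0)
        assert prior.s0_sq == pytest.approx(0.3, rel=1e-12)

    def test_too_few_genes_advises_ordinary_t(self):
        with pytest.raises(AnalysisError, match="ordinary t-test"):
            bsig.fit_variance_prior(np.full(5, 0.3), 6)

    def test_recovers_simulated_prior(self):
        rng = np.random.default_rng(0)
        d0, s0_sq, df = 4.0, 0.05, 6
        sigma_sq = s0_sq * d0 / rng.chisquare(d0, size=5000)
        s_sq = sigma_sq * rng.chisquare(df, size=5000) / df
        prior = bsig.fit_variance_prior(s_sq, df)
        assert prior.d0 == pytest.approx(d0, rel=0.15)
        assert prior.s0_sq == pytest.approx(s0_sq, rel=0.15)


class TestModeratedT:
    def test_degenerate_prior_equals_classical_pooled_t(self):
        rng = np.random.default_rng(1)
        values = rng.normal(8, 1, size=(20, 8))
        matrix, sheet = _study(values, n_a=4, n_b=4)
        res = bsig.moderated_t_test(matrix, sheet, "naive", prior=VariancePrior(0.0, 1.0))
        t_ref, p_ref = sps.ttest_ind(values[:, 4:], values[:, :4], axis=1, equal_var=True)
        np.testing.assert_allclose(res["t_mod"], t_ref, atol=1e-12)
        np.testing.assert_allclose(res["p"], p_ref, atol=1e-12)

    def test_shared_variance_with_fitted_prior_gives_no_shrinkage_change(self):
        rng = np.random.default_rng(2)
        base = rng.normal(0, 1, size=8)
        values = np.vstack([base + i for i in range(50)])  # same spread per gene
        matrix, sheet = _study(values, n_a=4, n_b=4)
        res = bsig.moderated_t_test(matrix, sheet, "naive", prior="fit")
        prior = bsig.fit_variance_prior(res["s_sq"], res["df_resid"])
        assert math.isinf(prior.d0)
        # posterior variance equals each gene's own s_sq (they are all equal)
        np.testing.assert_allclose(prior.s0_sq, res["s_sq"], rtol=1e-10)

    def test_two_gene_hand_instance_matches_arithmetic_oracle(self):
        xa = np.array([[1.0, 2.0, 3.0], [5.0, 5.5, 6.0]])
        xb = np.array([[2.5, 3.0, 3.5], [4.0, 4.5, 5.0]])
        matrix, sheet = _study(np.hstack([xa, xb]))
        d0, s0_sq = 4.0, 0.5
        res = bsig.moderated_t_test(matrix, sheet, "naive", prior=VariancePrior(d0, s0_sq))
        for g in range(2):
            ma = (xa[g, 0] + xa[g, 1] + xa[g, 2]) / 3.0
            mb = (xb[g, 0] + xb[g, 1] + xb[g, 2]) / 3.0
            ss = sum((v - ma) ** 2 for v in xa[g]) + sum((v - mb) ** 2 for v in xb[g])
            s_sq = ss / 4.0
            s_post = (d0 * s0_sq + 4.0 * s_sq) / (d0 + 4.0)
            t = (mb - ma) / math.sqrt(s_post * (1.0 / 3.0 + 1.0 / 3.0))
            assert res["t_mod"].iloc[g] == pytest.approx(t, abs=1e-12)
            assert res["df_total"].iloc[g] == 8.0
            assert res["p"].iloc[g] == pytest.approx(2 * sps.t.sf(abs(t), 8), abs=1e-12)

    def test_group_with_single_sample_rejected(self):
        matrix, sheet = _study(np.ones((3, 4)), n_a=1, n_b=3)
        with pytest.raises(AnalysisError, match=">= 2 samples"):
            bsig.moderated_t_test(matrix, sheet, "naive")

    def test_shrinkage_lies_between_gene_and_prior_variance(self, small_study):
        (matrix, sheet, _), _ = small_study
        res = bsig.moderated_t_test(matrix, sheet, "plasmablast", prior="fit")
        prior = bsig.fit_variance_prior(res["s_sq"], res["df_resid"])
        s_post = (prior.d0 * prior.s0_sq + res["df_resid"] * res["s_sq"]) / (
            prior.d0 + res["df_resid"]
        )
        lo = np.minimum(res["s_sq"], prior.s0_sq)
        hi = np.maximum(res["s_sq"], prior.s0_sq)
        assert ((s_post >= lo - 1e-12) & (s_post <= hi + 1e-12)).all()


def test_moderated_t_matches_limma_oracle(tmp_path):
    """Independent cross-check of the whole empirical-Bayes pipeline
    (prior moment fit + posterior t) against Bioconductor limma."""
    matrix, sheet, _ = bsig.simulate_expression_study(
        bsig.SimulationConfig(n_genes=400, seed=7)
    )
    cols = sheet.samples(subset="naive")
    matrix.select_samples(cols).data.to_csv(tmp_path / "mat.tsv", sep="\t")
    script = textwrap.dedent(
        f"""
        suppressMessages(library(limma))
        x <- as.matrix(read.delim('{tmp_path / "mat.tsv"}', row.names=1))
        group <- factor(rep(c('HC','SLE'), each=4), levels=c('HC','SLE'))
        fit <- eBayes(lmFit(x, model.matrix(~group)))
        out <- data.frame(t=fit$t[,2], p=fit$p.value[,2], d0=fit$df.prior, s0=fit$s2.prior)
        write.csv(out, '{tmp_path / "limma.csv"}')
        """
    )
    (tmp_path / "check.R").write_text(script)
    subprocess.run(["Rscript", str(tmp_path / "check.R")], check=True, capture_output=True)
    ref = pd.read_csv(tmp_path / "limma.csv", index_col=0)
    res = bsig.moderated_t_test(matrix, sheet, "naive", prior="fit")
    prior = bsig.fit_variance_prior(res["s_sq"], res["df_resid"])
    assert prior.d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-8)
    assert prior.s0_sq == pytest.approx(ref["s0"].iloc[0], rel=1e-8)
    np.testing.assert_allclose(res["t_mod"], ref["t"], atol=1e-10)
    np.testing.assert_allclose(res["p"], ref["p"], atol=1e-10)


class TestCallDegs:
    @staticmethod
    def _stats(p, fc):
        return pd.DataFrame(
            {"p": p, "fc_signed": fc}, index=[f"g{i}" for i in range(len(p))]
        )

    def test_threshold_rule(self):
        res = bsig.call_degs(self._stats([0.04, 0.04, 0.04, 0.2], [4.139, 1.5, -2.5, 3.0]))
        assert res.up_genes == ["g0"]
        assert res.down_genes == ["g2"]
        assert set(res.up_genes).isdisjoint(res.down_genes)

    @given(
        st.lists(
            st.tuples(st.floats(0, 1), st.floats(-8, 8).map(lambda d: float(2**d))),
            min_size=1,
            max_size=30,
        ),
        st.floats(0.001, 0.5),
    )
    def test_halving_p_threshold_never_grows_either_list(self, rows, p_thresh):
        p = [r[0] for r in rows]
        fc = [r[1] if r[1] >= 1 else -1 / r[1] for r in rows]
        wide = bsig.call_degs(self._stats(p, fc), p_thresh=p_thresh)
        narrow = bsig.call_degs(self._stats(p, fc), p_thresh=p_thresh / 2)
        assert set(narrow.up_genes) <= set(wide.up_genes)
        assert set(narrow.down_genes) <= set(wide.down_genes)

    def test_bh_adjustment_is_optional_and_more_conservative(self):
        p = list(np.linspace(0.001, 0.9, 20))
        fc = [3.0] * 20
        raw = bsig.call_degs(self._stats(p, fc))
        adj = bsig.call_degs(self._stats(p, fc), adjust="bh")
        assert set(adj.up_genes) <= set(raw.up_genes)


class TestOraFisher:
    def test_empty_deg_list_gives_p_one(self):
        bg = [f"g{i}" for i in range(10)]
        sets = [bsig.GeneSet("S", "", tuple(bg[:4]))]
        table = bsig.ora_fisher([], bg, sets)
        assert table["p"].iloc[0] == pytest.approx(1.0)

    def test_full_overlap_matches_hypergeometric_closed_form(self):
        bg = [f"g{i}" for i in range(20)]
        sets = [bsig.GeneSet("S", "", tuple(bg[:5]))]
        table = bsig.ora_fisher(bg[:5], bg, sets)
        assert table["p"].iloc[0] == pytest.approx(1 / math.comb(20, 5), rel=1e-9)

    def test_set_disjoint_from_background_skipped_with_warning(self):
        bg = ["a", "b", "c", "d"]
        sets = [bsig.GeneSet("S", "", ("x", "y"))]
        with pytest.warns(UserWarning, match="skipped"):
            table = bsig.ora_fisher(["a"], bg, sets)
        assert table.empty

    def test_deg_outside_background_rejected(self):
        with pytest.raises(ConsistencyError, match="not in background"):
            bsig.ora_fisher(["z"], ["a", "b"], [bsig.GeneSet("S", "", ("a",))])
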