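"""Signature score recipe, normalization conventions, group comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import bsig
from bsig.errors import AnalysisError
from bsig.signatures import ScoreTable


def _linear_matrix(values, genes, cols):
    return bsig.ExpressionMatrix(pd.DataFrame(values, index=genes, columns=cols))


class TestMaxNormalizeRows:
    def test_single_gene_linear_values(self):
        m = _linear_matrix([[2.0, 4.0]], ["g"], ["s1", "s2"])
        out, missing = bsig.max_normalize_rows(
            m, bsig.GeneSet("S", "", ("g",)), scale="linear"
        )
        np.testing.assert_allclose(out.values, [[0.5, 1.0]])
        assert missing == []

    def test_constant_row_becomes_all_ones(self):
        m = _linear_matrix([[3.0, 3.0, 3.0]], ["g"], ["a", "b", "c"])
        out, _ = bsig.max_normalize_rows(m, bsig.GeneSet("S", "", ("g",)), scale="linear")
        np.testing.assert_allclose(out.values, 1.0)

    @given(st.floats(0.01, 100.0))
    def test_row_scale_invariance(self, c):
        m = _linear_matrix([[1.0, 2.0, 5.0]], ["g"], ["a", "b", "c"])
        scaled = _linear_matrix([[c, 2 * c, 5 * c]], ["g"], ["a", "b", "c"])
        gs = bsig.GeneSet("S", "", ("g",))
        a, _ = bsig.max_normalize_rows(m, gs, scale="linear")
        b, _ = bsig.max_normalize_rows(scaled, gs, scale="linear")
        np.testing.assert_allclose(a.values, b.values, rtol=1e-12)

    def test_no_member_present_is_an_error(self):
        m = _linear_matrix([[1.0, 2.0]], ["g"], ["a", "b"])
        with pytest.raises(AnalysisError, match="no member"):
            bsig.max_normalize_rows(m, bsig.GeneSet("S", "", ("other",)), scale="linear")

    def test_nonpositive_row_maximum_names_the_gene(self):
        m = _linear_matrix([[-1.0, -2.0], [1.0, 2.0]], ["bad", "ok"], ["a", "b"])
        with pytest.raises(AnalysisError, match="bad"):
            bsig.max_normalize_rows(m, bsig.GeneSet("S", "", ("bad", "ok")), scale="linear")


class TestSignatureScore:
    def test_hand_arithmetic_oracle(self):
        # gene1 (1,2,4), gene2 (3,3,1) -> scores (0.25+1, 0.5+1, 1+1/3)
        m = _linear_matrix([[1.0, 2.0, 4.0], [3.0, 3.0, 1.0]], ["g1", "g2"], ["a", "b", "c"])
        table = bsig.signature_score(m, bsig.GeneSet("S", "", ("g1", "g2")), scale="linear")
        np.testing.assert_allclose(table.scores, [1.25, 1.5, 1.0 + 1.0 / 3.0])
        assert table.n_used == 2

    def test_identical_samples_score_the_set_size(self):
        m = _linear_matrix([[2.0, 2.0], [7.0, 7.0]], ["g1", "g2"], ["a", "b"])
        table = bsig.signature_score(m, bsig.GeneSet("S", "", ("g1", "g2")), scale="linear")
        np.testing.assert_allclose(table.scores, 2.0)

    def test_sample_attaining_every_maximum_scores_the_bound(self):
        m = _linear_matrix([[1.0, 4.0], [2.0, 8.0]], ["g1", "g2"], ["lo", "hi"])
        table = bsig.signature_score(m, bsig.GeneSet("S", "", ("g1", "g2")), scale="linear")
        assert table.scores["hi"] == pytest.approx(2.0)
        assert table.scores["hi"] > table.scores["lo"]

    def test_scores_bounded_by_usable_gene_count(self, small_study):
        (matrix, sheet, truth), _ = small_study
        gs = truth.gene_sets()[0]
        table = bsig.signature_score(matrix, gs)
        assert ((table.scores >= 0) & (table.scores <= len(gs))).all()

    def test_absent_set_member_changes_count_not_scores(self, small_study):
        (matrix, _, truth), _ = small_study
        gs = truth.gene_sets()[0]
        padded = bsig.GeneSet(gs.name, gs.description, gs.members + ("NOT_ON_ARRAY",))
        a = bsig.signature_score(matrix, gs)
        b = bsig.signature_score(matrix, padded)
        np.testing.assert_allclose(a.scores, b.scores)
        assert b.n_used == a.n_used and b.missing == ["NOT_ON_ARRAY"]

    def test_log2_input_is_exponentiated_first(self):
        log2 = _linear_matrix([[1.0, 2.0]], ["g"], ["a", "b"])  # 2 and 4 linear
        table = bsig.signature_score(log2, bsig.GeneSet("S", "", ("g",)), scale="log2")
        np.testing.assert_allclose(table.scores, [0.5, 1.0])


class TestMinNormalizeGene:
    def test_values_relative_to_minimum(self):
        m = _linear_matrix([[2.0, 4.0, 8.0]], ["g"], ["a", "b", "c"])
        out = bsig.min_normalize_gene(m, "g", scale="linear")
        np.testing.assert_allclose(out, [1.0, 2.0, 4.0])

    def test_minimum_is_exactly_one_for_any_positive_row(self):
        rng = np.random.default_rng(4)
        m = _linear_matrix([rng.uniform(0.1, 50, size=6)], ["g"], list("abcdef"))
        out = bsig.min_normalize_gene(m, "g", scale="linear")
        assert out.min() == 1.0

    def test_absent_gene_is_an_error(self):
        m = _linear_matrix([[1.0, 2.0]], ["g"], ["a", "b"])
        with pytest.raises(AnalysisError, match="missing"):
            bsig.min_normalize_gene(m, "missing", scale="linear")


def _score_table(cell_values):
    rows = []
    scores = {}
    for (subset, group), vals in cell_values.items():
        for i, v in enumerate(vals, start=1):
            sid = f"{group}{i}_{subset}"
            rows.append((sid, f"{group}{i}", group, subset))
            scores[sid] = v
    sheet = bsig.SampleSheet(
        pd.DataFrame(rows, columns=["sample_id", "donor_id", "group", "subset"])
    )
    table = ScoreTable(set_name="S", scores=pd.Series(scores), n_used=5)
    return table, sheet


class TestCompareScores:
    def _cells(self, sep_cell=None, sep=0.0):
        base = [0.0, 0.1, -0.1, 0.05]
        cells = {}
        for subset in ("naive", "memory", "plasmablast"):
            for group in ("HC", "SLE"):
                shift = sep if (subset, group) == sep_cell else 0.0
                cells[(subset, group)] = [v + shift for v in base]
        return cells

    def test_all_equal_scores_give_f_zero_p_one(self):
        table, sheet = _score_table(
            {(s, g): [1.0] * 4 for s in ("naive", "memory", "plasmablast") for g in ("HC", "SLE")}
        )
        res = bsig.compare_scores(table, sheet)
        assert res["anova"] == {"F": 0.0, "p": 1.0}
        assert (res["subset_contrasts"]["tukey_p"] == 1.0).all()

    def test_ten_sd_separation_is_tukey_significant(self):
        # within-cell SD ~0.085; a +10 shift is >100 SDs
        table, sheet = _score_table(self._cells(("plasmablast", "SLE"), sep=10.0))
        res = bsig.compare_scores(table, sheet)
        contrasts = res["subset_contrasts"].set_index("subset")
        assert contrasts.loc["plasmablast", "tukey_p"] < 0.001
        assert contrasts.loc["naive", "tukey_p"] > 0.05

    def test_permuting_samples_within_a_cell_changes_nothing(self):
        cells = self._cells(("memory", "SLE"), sep=2.0)
        table, sheet = _score_table(cells)
        res1 = bsig.compare_scores(table, sheet)["subset_contrasts"]
        cells[("naive", "HC")] = list(reversed(cells[("naive", "HC")]))
        table2, sheet2 = _score_table(cells)
        res2 = bsig.compare_scores(table2, sheet2)["subset_contrasts"]
        pd.testing.assert_frame_equal(res1, res2)

    def test_empty_cell_is_an_error_naming_the_cell(self):
        cells = self._cells()
        cells[("memory", "SLE")] = [1.0]
        table, sheet = _score_table(cells)
        with pytest.raises(AnalysisError, match="memory.*SLE"):
            bsig.compare_scores(table, sheet)
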