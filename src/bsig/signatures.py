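"""Gene-set signature scoring and group comparisons.

The signature score is a plain normalized sum: on the linear intensity
scale, each gene row of the set is divided by its maximum across samples
(so every usable gene's maximum is exactly 1), and each sample's score is
the sum of its normalized values. The score is therefore bounded by the
number of usable set genes, and a sample attaining the maximum for every
gene scores exactly that bound.

Scores default to linear intensities (2**log2) because a ratio-to-max on
log2 values would be offset-sensitive; the scale used is recorded in the
result. The row maximum defaults to spanning all samples jointly so all
subset/group cells share one comparable score axis; a per-subset span is
available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ExpressionMatrix, GeneSet, SampleSheet, GROUPS, SUBSETS
from .errors import AnalysisError

__all__ = [
    "ScoreTable",
    "max_normalize_rows",
    "signature_score",
    "min_normalize_gene",
    "compare_scores",
]


@dataclass
class ScoreTable:
    """Per-sample signature scores for one gene set."""

    set_name: str
    scores: pd.Series  # indexed by sample id
    n_used: int
    missing: list[str] = field(default_factory=list)
    scale: str = "linear"
    span: str = "all"

    def to_frame(self, sheet: SampleSheet | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"sample_id": self.scores.index, "score": self.scores.to_numpy()})
        df.insert(0, "set_name", self.set_name)
        df["n_genes_used"] = self.n_used
        if sheet is not None:
            df = df.merge(sheet.table, on="sample_id", how="left")
        return df


def _to_linear(matrix: ExpressionMatrix, scale: str) -> pd.DataFrame:
    if scale == "log2":
        return np.exp2(matrix.data)
    if scale == "linear":
        return matrix.data.copy()
    raise AnalysisError(f"scale must be 'log2' or 'linear', got {scale!r}")


def max_normalize_rows(
    matrix: ExpressionMatrix,
    gene_set: GeneSet,
    scale: str = "log2",
    span: str = "all",
    sheet: SampleSheet | None = None,
) -> tuple[ExpressionMatrix, list[str]]:
    """Divide each set-member row by its maximum so the maximum becomes 1.

    scale='log2' (default) maps values to linear intensities first.
    span='all' takes the maximum across every sample jointly;
    span='per_subset' (requires sheet) re-normalizes within each subset.
    Missing set members are reported in the second return value, never
    imputed. A retained row whose maximum is <= 0 is an error.
    """
    present = [g for g in gene_set.members if g in matrix]
    missing = [g for g in gene_set.members if g not in matrix]
    if not present:
        raise AnalysisError(f"no member of set {gene_set.name!r} is present in the matrix")
    linear = _to_linear(matrix.select_genes(present), scale)

    def _norm(block: pd.DataFrame) -> pd.DataFrame:
        row_max = block.max(axis=1)
        bad = row_max[row_max <= 0]
        if len(bad):
            raise AnalysisError(
                f"gene {bad.index[0]!r} has row maximum <= 0; "
                "scores need positive linear intensities"
            )
        return block.div(row_max, axis=0)

    if span == "all":
        out = _norm(linear)
    elif span == "per_subset":
        if sheet is None:
            raise AnalysisError("span='per_subset' requires a sample sheet")
        pieces = []
        for subset in SUBSETS:
            cols = [s for s in sheet.samples(subset=subset) if s in linear.columns]
            if cols:
                pieces.append(_norm(linear[cols]))
        out = pd.concat(pieces, axis=1)[[c for c in linear.columns]]
    else:
        raise AnalysisError(f"span must be 'all' or 'per_subset', got {span!r}")
    return ExpressionMatrix(out), missing


def signature_score(
    matrix: ExpressionMatrix,
    gene_set: GeneSet,
    scale: str = "log2",
    span: str = "all",
    sheet: SampleSheet | None = None,
) -> ScoreTable:
    """Per-sample signature score: sum of max-normalized set-gene values."""
    normalized, missing = max_normalize_rows(matrix, gene_set, scale=scale, span=span, sheet=sheet)
    scores = normalized.data.sum(axis=0)
    scores.name = gene_set.name
    n_used = normalized.shape[0]
    assert ((scores >= 0) & (scores <= n_used + 1e-9)).all()
    if span == "all":
        assert np.allclose(normalized.data.max(axis=1), 1.0)
    return ScoreTable(
        set_name=gene_set.name,
        scores=scores,
        n_used=n_used,
        missing=missing,
        scale=scale,
        span=span,
    )


def min_normalize_gene(
    matrix: ExpressionMatrix, gene_id: str, scale: str = "log2"
) -> pd.Series:
    """Single-gene display convention: divide the gene's linear values by
    their minimum across samples, so the minimum maps to exactly 1."""
    if gene_id not in matrix:
        raise AnalysisError(f"gene {gene_id!r} absent from matrix")
    row = _to_linear(matrix.select_genes([gene_id]), scale).iloc[0]
    if (row <= 0).any():
        raise AnalysisError(f"gene {gene_id!r} has non-positive linear values")
    return row / row.min()


def compare_scores(score_table: ScoreTable, sheet: SampleSheet) -> dict:
    """Compare scores across the subset x group design.

    One-way ANOVA across the six (subset, group) cells, Tukey HSD adjusted
    p-values for all pairwise cell comparisons, and per-subset HC-vs-SLE
    contrasts (both the Tukey-adjusted pair and an unadjusted pooled
    two-sample t-test). Standard routines (scipy, statsmodels) do the
    distributional work.
    """
    sheet = SampleSheet(
        sheet.table[sheet.table["sample_id"].isin(score_table.scores.index)]
    )
    cells: dict[tuple[str, str], np.ndarray] = {}
    for subset in SUBSETS:
        for group in GROUPS:
            ids = score_table.scores.index.intersection(sheet.samples(subset=subset, group=group))
            vals = score_table.scores.loc[ids].to_numpy()
            if len(vals) < 2:
                raise AnalysisError(f"cell (subset={subset}, group={group}) has < 2 samples")
            cells[(subset, group)] = vals

    all_vals = np.concatenate(list(cells.values()))
    labels = np.concatenate(
        [[f"{s}:{g}"] * len(v) for (s, g), v in cells.items()]
    )

    if np.ptp(all_vals) == 0:
        anova = {"F": 0.0, "p": 1.0}
        tukey = pd.DataFrame(
            [
                {"group1": a, "group2": b, "meandiff": 0.0, "p_adj": 1.0}
                for i, a in enumerate(sorted(set(labels)))
                for b in sorted(set(labels))[i + 1:]
            ]
        )
    else:
        F, p = stats.f_oneway(*cells.values())
        anova = {"F": float(F), "p": float(p)}
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        res = pairwise_tukeyhsd(all_vals, labels)
        tukey = pd.DataFrame(
            res.summary().data[1:], columns=[c.replace("-", "_") for c in res.summary().data[0]]
        ).rename(columns={"p_adj": "p_adj"})
        tukey = tukey[["group1", "group2", "meandiff", "p_adj"]]
        tukey["p_adj"] = tukey["p_adj"].astype(float)

    contrasts = []
    for subset in SUBSETS:
        a, b = cells[(subset, "HC")], cells[(subset, "SLE")]
        if np.ptp(np.concatenate([a, b])) == 0:
            t_stat, t_p = 0.0, 1.0
        else:
            t_stat, t_p = stats.ttest_ind(b, a, equal_var=True)
        la, lb = f"{subset}:HC", f"{subset}:SLE"
        pair = tukey[
            ((tukey["group1"] == la) & (tukey["group2"] == lb))
            | ((tukey["group1"] == lb) & (tukey["group2"] == la))
        ]
        contrasts.append(
            {
                "set_name": score_table.set_name,
                "subset": subset,
                "mean_HC": float(a.mean()),
                "mean_SLE": float(b.mean()),
                "t": float(t_stat),
                "t_p": float(t_p),
                "tukey_p": float(pair["p_adj"].iloc[0]),
            }
        )
    return {
        "anova": anova,
        "tukey": tukey,
        "subset_contrasts": pd.DataFrame(contrasts),
    }
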