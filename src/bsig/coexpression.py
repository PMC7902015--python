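"""The "similar entities" screen: correlation of candidate gene profiles
to an anchor gene (FOXM1 in the motivating study) with selection inside a
closed correlation band, default [0.6, 1.0].

Profiles are correlated across all samples jointly (all subsets and both
groups), so a module elevated only in one stratum is picked up through
its shared cross-sample pattern. Pearson correlation is the default
metric; Spearman is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ExpressionMatrix
from .errors import AnalysisError

__all__ = ["SimilarityResult", "profile_correlation", "find_similar_entities"]


@dataclass
class SimilarityResult:
    """Outcome of the similar-entities screen for one anchor."""

    anchor_gene: str
    r: pd.Series  # per candidate, sorted descending; NaN-r candidates excluded
    selected: list[str]
    r_min: float
    r_max: float


def profile_correlation(
    matrix: ExpressionMatrix,
    anchor_gene: str,
    candidates,
    method: str = "pearson",
) -> pd.Series:
    """Correlation of each candidate's per-sample profile with the anchor's.

    Candidates (or an anchor) with zero variance have undefined
    correlation and come back as NaN with a warning.
    """
    if anchor_gene not in matrix:
        raise AnalysisError(f"anchor gene {anchor_gene!r} absent from matrix")
    candidates = list(candidates)
    sub = matrix.select_genes(candidates)
    if matrix.shape[1] < 3:
        raise AnalysisError("profile correlation needs >= 3 samples")
    anchor = matrix.data.loc[anchor_gene].to_numpy()
    X = sub.values
    if method == "spearman":
        anchor = stats.rankdata(anchor)
        X = np.apply_along_axis(stats.rankdata, 1, X)
    elif method != "pearson":
        raise AnalysisError(f"method must be 'pearson' or 'spearman', got {method!r}")

    a = anchor - anchor.mean()
    a_norm = np.sqrt((a**2).sum())
    Xc = X - X.mean(axis=1, keepdims=True)
    x_norm = np.sqrt((Xc**2).sum(axis=1))
    if a_norm == 0:
        warnings.warn(f"anchor {anchor_gene!r} has zero variance; all r undefined",
                      stacklevel=2)
        return pd.Series(np.nan, index=candidates, name="r")
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc @ a) / (x_norm * a_norm)
    r = np.where(x_norm == 0, np.nan, np.clip(r, -1.0, 1.0))
    if np.isnan(r).any():
        flat = [candidates[i] for i in np.flatnonzero(np.isnan(r))]
        warnings.warn(f"zero-variance candidates with undefined r: {flat[:5]}",
                      stacklevel=2)
    return pd.Series(r, index=candidates, name="r")


def find_similar_entities(
    matrix: ExpressionMatrix,
    anchor_gene: str,
    candidates,
    r_min: float = 0.6,
    r_max: float = 1.0,
    method: str = "pearson",
) -> SimilarityResult:
    """Select candidates whose correlation to the anchor lies in the closed
    interval [r_min, r_max], sorted by descending r.

    The anchor itself, when among the candidates, always satisfies r = 1
    and is selected whenever r_max = 1.
    """
    candidates = list(candidates)
    if not candidates:
        raise AnalysisError("candidate list is empty")
    if r_min > r_max:
        raise AnalysisError("r_min must be <= r_max")
    r = profile_correlation(matrix, anchor_gene, candidates, method=method)
    r = r.dropna().sort_values(ascending=False, kind="mergesort")
    selected = r[(r >= r_min) & (r <= r_max)].index.tolist()
    return SimilarityResult(
        anchor_gene=anchor_gene, r=r, selected=selected, r_min=r_min, r_max=r_max
    )
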