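"""Normalization, fold change, the empirical-Bayes moderated t-test, DEG
calling, and Fisher's-exact over-representation.

The moderated t-test shrinks each gene's pooled two-sample variance toward
a common prior estimated across genes. The prior is a scaled-inverse-
chi-square with d0 degrees of freedom and scale s0^2; under it the sample
variance s_g^2 is marginally s0^2 * F(df_g, d0), so (d0, s0^2) are
estimated by matching the mean and variance of log s_g^2 to their
digamma/trigamma expressions. The posterior variance

    s~_g^2 = (d0 * s0^2 + df_g * s_g^2) / (d0 + df_g)

replaces s_g^2 in the t statistic, which is referred to Student-t with
df_g + d0 degrees of freedom (Normal when d0 is infinite).

Fold changes use the signed linear convention: r = 2**(mean_SLE - mean_HC),
reported as r when r >= 1 and as -1/r otherwise, so down-regulation is a
negative magnitude and |fc| >= 1 always.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .datamodel import DEGResult, ExpressionMatrix, GeneSet, SampleSheet
from .errors import AnalysisError, ConsistencyError

__all__ = [
    "VariancePrior",
    "normalize_percentile",
    "fold_change",
    "trigamma_inverse",
    "fit_variance_prior",
    "moderated_t_test",
    "call_degs",
    "ora_fisher",
]


@dataclass(frozen=True)
class VariancePrior:
    """Scaled-inverse-chi-square variance prior (d0, s0^2).

    d0 = inf encodes full shrinkage to s0^2; d0 = 0 is the degenerate
    no-shrinkage limit under which the moderated t reduces to the
    classical pooled t-test.
    """

    d0: float
    s0_sq: float

    def __post_init__(self):
        if self.d0 < 0 or math.isnan(self.d0):
            raise AnalysisError("prior degrees of freedom d0 must be >= 0")
        if not (self.s0_sq > 0):
            raise AnalysisError("prior scale s0_sq must be > 0")


def normalize_percentile(matrix: ExpressionMatrix, percentile: float = 75.0) -> ExpressionMatrix:
    """Percentile-shift normalization: per sample, subtract that sample's
    given percentile of log2 values so the percentile becomes 0.

    The percentile is linear interpolation between order statistics. This
    is the conventional per-array location normalization for one-color
    arrays; it is shift-equivariant, so adding a constant to one array and
    renormalizing is a no-op.
    """
    if not (0 < percentile <= 100):
        raise AnalysisError("percentile must lie in (0, 100]")
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise AnalysisError("cannot normalize an empty matrix")
    shifts = np.percentile(matrix.values, percentile, axis=0)
    return ExpressionMatrix(matrix.data - shifts)


def _group_columns(
    matrix: ExpressionMatrix, sheet: SampleSheet, subset: str, group_a: str, group_b: str
) -> tuple[np.ndarray, np.ndarray]:
    samples_a = [s for s in sheet.samples(subset=subset, group=group_a) if s in matrix.data.columns]
    samples_b = [s for s in sheet.samples(subset=subset, group=group_b) if s in matrix.data.columns]
    if not samples_a or not samples_b:
        raise AnalysisError(
            f"subset {subset!r} needs samples in both {group_a!r} and {group_b!r}"
        )
    return matrix.data[samples_a].to_numpy(), matrix.data[samples_b].to_numpy()


def _signed_fc(diff_log2: np.ndarray) -> np.ndarray:
    r = np.exp2(diff_log2)
    return np.where(r >= 1.0, r, -1.0 / r)


def fold_change(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    subset: str,
    group_a: str = "HC",
    group_b: str = "SLE",
) -> pd.Series:
    """Signed linear fold change of group_b over group_a within a subset."""
    xa, xb = _group_columns(matrix, sheet, subset, group_a, group_b)
    diff = xb.mean(axis=1) - xa.mean(axis=1)
    return pd.Series(_signed_fc(diff), index=matrix.data.index, name="fc_signed")


def trigamma_inverse(y: float, rel_tol: float = 1e-8, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by monotone Newton iteration.

    trigamma is strictly decreasing and convex on (0, inf), so Newton from
    the asymptotic start x = 0.5 + 1/y converges monotonically.
    """
    if not (y > 0):
        raise AnalysisError("trigamma_inverse requires y > 0")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(special.polygamma(1, x))
        tetra = float(special.polygamma(2, x))
        step = tri * (1.0 - tri / y) / tetra
        x += step
        if abs(step) < rel_tol * x:
            return x
    return x  # pragma: no cover - convergence is a handful of iterations


def fit_variance_prior(s_sq, df_resid) -> VariancePrior:
    """Estimate (d0, s0^2) by moment matching on log sample variances.

    With z_g = log s_g^2 and e_g = z_g - digamma(df_g/2) + log(df_g/2):
    E[e_g] = log s0^2 - digamma(d0/2) + log(d0/2) and
    Var[z_g] = trigamma(df_g/2) + trigamma(d0/2). The excess of the
    empirical variance of z over the mean residual trigamma term is
    inverted through the trigamma function to give d0. A non-positive
    excess means the variances are underdispersed relative to any finite
    d0; then d0 = inf and s0^2 is the geometric mean of the variances
    (identical variances come back unchanged).
    """
    s_sq = np.asarray(s_sq, dtype=float)
    df = np.broadcast_to(np.asarray(df_resid, dtype=float), s_sq.shape)
    ok = (df >= 1) & (s_sq > 0) & np.isfinite(s_sq)
    if ok.sum() < 10:
        raise AnalysisError(
            f"only {int(ok.sum())} usable genes (need >= 10); "
            "use an ordinary t-test instead"
        )
    s_sq, df = s_sq[ok], df[ok]
    z = np.log(s_sq)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    mean_e = float(e.mean())
    excess = float(np.var(z, ddof=1) - np.mean(special.polygamma(1, df / 2.0)))
    if excess <= 0:
        return VariancePrior(d0=math.inf, s0_sq=float(math.exp(z.mean())))
    d0 = 2.0 * trigamma_inverse(excess)
    s0_sq = math.exp(mean_e + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    return VariancePrior(d0=d0, s0_sq=s0_sq)


def moderated_t_test(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    subset: str,
    prior: VariancePrior | str = "fit",
    group_a: str = "HC",
    group_b: str = "SLE",
) -> pd.DataFrame:
    """Per-gene moderated two-sample t-test of group_b vs group_a.

    Returns one row per gene with columns mean_a, mean_b, s_sq, df_resid,
    fc_signed, t_mod, df_total, p. prior='fit' estimates the variance
    prior from this matrix's pooled variances.
    """
    xa, xb = _group_columns(matrix, sheet, subset, group_a, group_b)
    n_a, n_b = xa.shape[1], xb.shape[1]
    if n_a < 2 or n_b < 2:
        raise AnalysisError(
            f"each group needs >= 2 samples in subset {subset!r} "
            f"(got {group_a}={n_a}, {group_b}={n_b})"
        )
    mean_a = xa.mean(axis=1)
    mean_b = xb.mean(axis=1)
    df_resid = n_a + n_b - 2
    ss = ((xa - mean_a[:, None]) ** 2).sum(axis=1) + ((xb - mean_b[:, None]) ** 2).sum(axis=1)
    s_sq = ss / df_resid

    if isinstance(prior, str):
        if prior != "fit":
            raise AnalysisError(f"prior must be a VariancePrior or 'fit', got {prior!r}")
        prior = fit_variance_prior(s_sq, df_resid)

    if math.isinf(prior.d0):
        s_post = np.full_like(s_sq, prior.s0_sq)
        df_total = math.inf
    else:
        s_post = (prior.d0 * prior.s0_sq + df_resid * s_sq) / (prior.d0 + df_resid)
        df_total = df_resid + prior.d0

    diff = mean_b - mean_a
    se = np.sqrt(s_post * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, diff / se, np.where(diff == 0, 0.0, np.inf * np.sign(diff)))
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)

    return pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "s_sq": s_sq,
            "df_resid": float(df_resid),
            "fc_signed": _signed_fc(diff),
            "t_mod": t_mod,
            "df_total": df_total,
            "p": p,
        },
        index=matrix.data.index,
    )


def call_degs(
    stats_table: pd.DataFrame,
    p_thresh: float = 0.05,
    fc_thresh: float = 2.0,
    contrast: str = "",
    adjust: str | None = None,
) -> DEGResult:
    """Apply the DEG rule: p below threshold and signed fold change beyond
    +/- fc_thresh (>2-fold up or <0.5-fold down at the default).

    No multiple-testing correction by default; adjust='bh' switches the
    p-value column to Benjamini-Hochberg adjusted values before calling.
    """
    if len(stats_table) == 0:
        raise AnalysisError("empty statistics table")
    if not (0 < p_thresh <= 1):
        raise AnalysisError("p_thresh must lie in (0, 1]")
    if fc_thresh < 1:
        raise AnalysisError("fc_thresh must be >= 1")
    stats_table = stats_table.copy()
    pvals = stats_table["p"].to_numpy()
    if adjust is not None:
        if adjust != "bh":
            raise AnalysisError(f"unknown adjustment {adjust!r}")
        from statsmodels.stats.multitest import multipletests

        pvals = multipletests(pvals, method="fdr_bh")[1]
        stats_table["p_adj"] = pvals
    fc = stats_table["fc_signed"].to_numpy()
    up = (pvals < p_thresh) & (fc >= fc_thresh)
    down = (pvals < p_thresh) & (fc <= -fc_thresh)
    stats_table["call"] = np.where(up, "up", np.where(down, "down", "ns"))
    return DEGResult(
        contrast=contrast,
        stats=stats_table,
        p_thresh=p_thresh,
        fc_thresh=fc_thresh,
        up_genes=stats_table.index[up].tolist(),
        down_genes=stats_table.index[down].tolist(),
    )


def ora_fisher(
    deg_genes,
    background,
    sets,
    p_thresh: float = 0.01,
) -> pd.DataFrame:
    """One-sided Fisher's exact over-representation of each gene set among
    the DEGs, against the given background universe.

    Set members absent from the background are dropped; a set with no
    member in the background is skipped with a warning. Returns one row
    per tested set with the 2x2 counts, p, -log10 p and a significance
    flag at p_thresh.
    """
    deg = set(deg_genes)
    bg = set(background)
    if not deg <= bg:
        extra = sorted(deg - bg)
        raise ConsistencyError(f"DEG genes not in background: {extra[:5]}")
    rows = []
    for gs in sets:
        if isinstance(gs, GeneSet):
            name, members = gs.name, gs.member_set & bg
        else:  # (name, iterable) pair
            name, members = gs[0], set(gs[1]) & bg
        if not members:
            warnings.warn(f"gene set {name!r} has no members in background; skipped",
                          stacklevel=2)
            continue
        a = len(deg & members)
        b = len(deg) - a
        c = len(members) - a
        d = len(bg) - len(deg) - c
        p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1]
        rows.append(
            {
                "set_name": name,
                "set_size": len(members),
                "deg_size": len(deg),
                "overlap": a,
                "background_size": len(bg),
                "p": float(p),
                "neg_log10_p": float(-np.log10(p)) if p > 0 else math.inf,
                "significant": bool(p < p_thresh),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["set_name", "set_size", "deg_size", "overlap",
                 "background_size", "p", "neg_log10_p", "significant"],
    )
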