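"""Detection of transcriptionally selected genes (TDSGs).

A gene is called TDSG when (a) its expression differs between typical upland
and lowland genotypes (Welch t-test, p < .05 on log2(FPKM+1)) and (b) its
between-individual variance — the residual variance after removing random
origin and ecotype effects — falls at or below a data-driven cutoff obtained
from the ranked-variance curve (two fitted lines: top 1% of genes and bottom
80% of genes; the cutoff is the variance at their intersection rank).

The expression selection index contrasts expression variance ratios against
neutral sequence variation:

    SI = 1 - (V_w * D_xy) / (V_b * pi)

with V_w / V_b the within- and between-ecotype expression variance components
and pi / D_xy computed from the gene's neutral (intron) SNPs. SI > 0 indicates
directional selection on expression; SI <= 1 always.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .expression_stats import variance_components, _group_design

logger = logging.getLogger("ecodiverge")

__all__ = [
    "log_fpkm",
    "between_ecotype_ttest",
    "between_individual_variance",
    "variance_cutoff",
    "call_tdsg",
    "selection_index",
    "expression_variance_components",
    "tdsg_table",
]


def log_fpkm(expr, pseudocount: float = 1.0):
    """log2(FPKM + pc): the variance-stabilizing scale used throughout."""
    return np.log2(np.asarray(expr, dtype=float) + pseudocount)


def between_ecotype_ttest(x, ecotype, log: bool = True):
    """Welch two-sample t-test per gene between ecotypes.

    ``x``: genes x samples (FPKM if ``log``, else already transformed);
    ``ecotype``: label per sample. Returns p-values per gene. Groups with a
    single sample are an error.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if log:
        x = log_fpkm(x)
    labels = np.asarray(ecotype)
    levels = np.unique(labels)
    if len(levels) != 2:
        raise ValueError("expected exactly two ecotypes")
    a = x[:, labels == levels[0]]
    b = x[:, labels == levels[1]]
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each ecotype needs >= 2 samples for the t-test")
    res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    return np.asarray(res.pvalue)


def between_individual_variance(x, origin, log: bool = True):
    """Residual variance after removing origin and ecotype group effects.

    Origins are nested within ecotype, so the pooled within-origin variance
    (the ANOVA residual mean square of the origin grouping) is exactly the
    between-individual component left once both random factors are absorbed;
    negative estimates cannot occur. ``x``: genes x samples FPKM (log2(x+1)
    applied when ``log``).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if log:
        x = log_fpkm(x)
    labels = np.asarray(origin)
    levels, inv = np.unique(labels, return_inverse=True)
    counts = np.bincount(inv)
    N = counts.sum()
    if N - len(levels) < 1:
        raise ValueError("no residual degrees of freedom")
    onehot = (inv[:, None] == np.arange(len(levels))[None, :]).astype(float)
    gsum = x @ onehot
    ssw = (x ** 2).sum(axis=1) - (gsum ** 2 / counts).sum(axis=1)
    return np.maximum(ssw / (N - len(levels)), 0.0)


def variance_cutoff(biv, top_frac: float = 0.01, bottom_frac: float = 0.80):
    """Low-variance cutoff from the ranked between-individual variances.

    Variances are sorted descending against rank; a least-squares line is fit
    through the top ``top_frac`` of genes and another through the bottom
    ``bottom_frac``; the cutoff is the variance at the rank where the lines
    intersect. If the lines are parallel or intersect outside the rank range,
    the documented fallback is the variance at the boundary of the bottom
    segment (warning logged).

    Returns ``(cutoff, info)`` with diagnostic fit parameters. Requires
    >= 200 genes.
    """
    v = np.sort(np.asarray(biv, dtype=float))[::-1]
    n = v.size
    if n < 200:
        raise ValueError("variance cutoff needs >= 200 genes")
    r = np.arange(n, dtype=float)
    m1 = max(2, int(np.floor(top_frac * n + 0.5)))
    m2 = max(2, int(np.floor(bottom_frac * n + 0.5)))
    k1, b1 = np.polyfit(r[:m1], v[:m1], 1)
    k2, b2 = np.polyfit(r[n - m2:], v[n - m2:], 1)
    info = {"slope_top": k1, "intercept_top": b1,
            "slope_bottom": k2, "intercept_bottom": b2,
            "n": n, "fallback": False}
    if np.isclose(k1, k2):
        x_star = np.nan
    else:
        x_star = (b2 - b1) / (k1 - k2)
    if not np.isfinite(x_star) or not (0 <= x_star <= n - 1):
        logger.warning("ranked-variance lines parallel or intersection out of "
                       "range; falling back to bottom-segment boundary")
        info["fallback"] = True
        rank = n - m2
    else:
        rank = int(np.floor(x_star + 0.5))
    info["rank"] = rank
    cutoff = float(v[rank])
    logger.info("between-individual variance cutoff %.4g at rank %d of %d",
                cutoff, rank, n)
    return cutoff, info


def call_tdsg(t_p, biv, cutoff, alpha: float = 0.05):
    """TDSG iff t-test p < alpha AND between-individual variance <= cutoff."""
    t_p = np.asarray(t_p, dtype=float)
    biv = np.asarray(biv, dtype=float)
    flags = (t_p < alpha) & (biv <= cutoff)
    logger.info("TDSG call: p < %g and variance <= %.4g -> %d genes",
                alpha, cutoff, int(flags.sum()))
    return flags


def selection_index(vw, vb, pi, dxy):
    """SI = 1 - (V_w * D_xy) / (V_b * pi); nan when pi <= 0 or V_b <= 0."""
    vw = np.asarray(vw, dtype=float)
    vb = np.asarray(vb, dtype=float)
    pi = np.asarray(pi, dtype=float)
    dxy = np.asarray(dxy, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        si = 1.0 - (vw * dxy) / (vb * pi)
    si = np.where((pi > 0) & (vb > 0), si, np.nan)
    return si if si.ndim else float(si)


def expression_variance_components(x, ecotype, log: bool = True):
    """(V_b, V_w) per gene from the two-ecotype one-way decomposition.

    V_b is the raw (unclamped) method-of-moments between-ecotype component;
    genes with V_b <= 0 later yield a missing selection index.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if log:
        x = log_fpkm(x)
    _, inv, counts = _group_design(ecotype)
    vb, vw = variance_components(x, inv, counts)
    return vb, vw


def tdsg_table(expr: pd.DataFrame, metadata, neutral_pi: pd.Series,
               neutral_dxy: pd.Series, alpha: float = 0.05) -> pd.DataFrame:
    """Full TDSG scan for one condition's expression matrix.

    ``metadata`` is a :class:`~ecodiverge.datatypes.SampleMetadata`; only
    typical genotypes enter the tests. ``neutral_pi`` / ``neutral_dxy`` are
    per-gene intron-SNP statistics used by the selection index.
    """
    samples = [s for s in expr.columns]
    typical = metadata.typical(samples)
    use = [s for s, t in zip(samples, typical) if t]
    x = expr[use].to_numpy(dtype=float)
    eco = metadata.ecotype_of(use)
    origin = metadata.origin_of(use)

    t_p = between_ecotype_ttest(x, eco, log=True)
    biv = between_individual_variance(x, origin, log=True)
    cutoff, info = variance_cutoff(biv)
    flags = call_tdsg(t_p, biv, cutoff, alpha=alpha)
    vb, vw = expression_variance_components(x, eco, log=True)

    pi = neutral_pi.reindex(expr.index).to_numpy(dtype=float)
    dxy = neutral_dxy.reindex(expr.index).to_numpy(dtype=float)
    si = selection_index(vw, vb, pi, dxy)

    out = pd.DataFrame({
        "t_p": t_p, "biv": biv, "cutoff": cutoff, "tdsg": flags,
        "vb_expr": vb, "vw_expr": vw, "si": si,
    }, index=expr.index)
    out.attrs["cutoff_info"] = info
    return out
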