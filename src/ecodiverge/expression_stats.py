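"""Expression diversity, expression Q_ST and drought-response calling.

Q_ST for a quantitative value (trait or per-gene expression) is
``V_B / (V_B + 2 V_W)`` with variance components from one-way ANOVA method of
moments; negative between-group components are clamped to zero. Permutation
p-values use the add-one correction ``(1 + #{perm >= obs}) / (1 + n_perm)``
and, for matrices, one shared label permutation per iteration across genes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("ecodiverge")

__all__ = [
    "expression_diversity",
    "ed_matrix",
    "cv_matrix",
    "variance_components",
    "qst",
    "qst_matrix",
    "call_deg",
    "deg_welch",
    "call_drg",
    "qst_fst_correlation",
    "condition_shift_test",
]


def expression_diversity(values) -> float:
    """E_d = sum_i |E_i - E_p| / ((n - 1) * E_p), E_p the mean.

    Scale-invariant; zero for constant vectors; nan (flagged missing) for
    zero-mean genes.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("expression diversity needs n >= 2")
    ep = v.mean()
    if ep <= 0:
        return float("nan")
    return float(np.abs(v - ep).sum() / ((v.size - 1) * ep))


def ed_matrix(expr: pd.DataFrame) -> pd.Series:
    """Row-wise E_d of a genes x samples matrix (nan for zero-mean genes)."""
    x = expr.to_numpy(dtype=float)
    ep = x.mean(axis=1)
    n = x.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        ed = np.abs(x - ep[:, None]).sum(axis=1) / ((n - 1) * ep)
    ed[ep <= 0] = np.nan
    return pd.Series(ed, index=expr.index, name="ed")


def cv_matrix(expr: pd.DataFrame) -> pd.Series:
    """Row-wise coefficient of variation (sd / mean, ddof=1)."""
    x = expr.to_numpy(dtype=float)
    mean = x.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = x.std(axis=1, ddof=1) / mean
    cv[mean <= 0] = np.nan
    return pd.Series(cv, index=expr.index, name="cv")


# ---------------------------------------------------------------------------
# Q_ST
# ---------------------------------------------------------------------------

def _group_design(labels):
    labels = np.asarray(labels)
    levels, inv = np.unique(labels, return_inverse=True)
    if len(levels) < 2:
        raise ValueError("Q_ST needs at least two groups")
    counts = np.bincount(inv)
    if counts.min() < 2:
        raise ValueError("Q_ST needs >= 2 samples per group")
    return levels, inv, counts


def variance_components(x: np.ndarray, inv: np.ndarray, counts: np.ndarray):
    """Method-of-moments one-way ANOVA components, vectorized over rows.

    Returns ``(V_B, V_W)`` per row; V_B is *not* clamped here so callers that
    need the raw component (e.g. the selection index) can decide.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    k = counts.size
    N = counts.sum()
    onehot = (inv[:, None] == np.arange(k)[None, :]).astype(float)
    gsum = x @ onehot
    gmean = gsum / counts
    grand = x.mean(axis=1, keepdims=True)
    ssb = (counts * (gmean - grand) ** 2).sum(axis=1)
    ssw = (x ** 2).sum(axis=1) - (gsum ** 2 / counts).sum(axis=1)
    msb = ssb / (k - 1)
    msw = ssw / (N - k)
    n0 = (N - (counts ** 2).sum() / N) / (k - 1)
    vb = (msb - msw) / n0
    return vb, msw


def _qst_from_components(vb, vw):
    vb = np.maximum(np.asarray(vb, dtype=float), 0.0)
    vw = np.asarray(vw, dtype=float)
    den = vb + 2.0 * vw
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(den > 0, vb / den, 0.0)
    return q


def _qst_raw_score(vb, vw):
    """Unclamped Q_ST used only to rank permutations.

    Clamping V_B at zero puts a point mass of observed Q_ST values at 0 and
    would make permutation p-values pile up at 1 under the null; the raw
    component (a monotone function of the ANOVA F-ratio) breaks those ties,
    so p-values are exactly uniform under label exchangeability.
    """
    vb = np.asarray(vb, dtype=float)
    vw = np.asarray(vw, dtype=float)
    den = vb + 2.0 * vw
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(den > 0, vb / den, -np.inf)
    return s


def qst(values, labels, n_perm: int = 1000, seed: int | None = 0):
    """Q_ST of one value vector, with permutation p-value.

    Returns ``(qst, p)``; ``p`` is the add-one-corrected fraction of label
    permutations with Q_ST >= observed.
    """
    q, p = qst_matrix(np.atleast_2d(values), labels, n_perm=n_perm, seed=seed)
    return float(q[0]), float(p[0])


def qst_matrix(x, labels, n_perm: int = 1000, seed: int | None = 0):
    """Vectorized Q_ST + permutation p per row of a genes x samples matrix."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    _, inv, counts = _group_design(labels)
    vb, vw = variance_components(x, inv, counts)
    q_obs = _qst_from_components(vb, vw)
    if n_perm <= 0:
        return q_obs, np.full(q_obs.shape, np.nan)
    s_obs = _qst_raw_score(vb, vw)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(x.shape[0], dtype=int)
    for _ in range(n_perm):
        perm = rng.permutation(inv)
        vb_p, vw_p = variance_components(x, perm, counts)
        exceed += _qst_raw_score(vb_p, vw_p) >= s_obs
    p = (1.0 + exceed) / (1.0 + n_perm)
    return q_obs, p


# ---------------------------------------------------------------------------
# differential expression (CK vs DT)
# ---------------------------------------------------------------------------

def call_deg(ck, dt, alpha: float = 0.05, lfc: float = 1.0,
             pseudocount: float = 1.0):
    """Per-genotype differential expression between conditions.

    ``ck`` / ``dt``: FPKM arrays of matching shape (genes x genotypes), one
    pooled sample per genotype and condition. The fold-change criterion is
    strict: ``|log2((dt+pc)/(ck+pc))| > lfc``. Without replicates the p-value
    is an exact conditional (binomial) test on the rounded pseudocounted
    values — the classic test for a ratio of two Poisson intensities.

    Returns ``(deg_flags, log2fc, p)`` with the shape of the inputs.
    """
    ck = np.asarray(ck, dtype=float)
    dt = np.asarray(dt, dtype=float)
    x = np.round(ck + pseudocount)
    y = np.round(dt + pseudocount)
    log2fc = np.log2((dt + pseudocount) / (ck + pseudocount))
    n = x + y
    with np.errstate(invalid="ignore"):
        lo = stats.binom.cdf(np.minimum(x, y), n, 0.5)
        hi = stats.binom.sf(np.minimum(x, y) - 1, n, 0.5)
    p = np.minimum(1.0, 2.0 * np.minimum(lo, hi))
    deg = (np.abs(log2fc) > lfc) & (p < alpha)
    return deg, log2fc, p


def deg_welch(ck_reps, dt_reps, alpha: float = 0.05, lfc: float = 1.0,
              pseudocount: float = 1.0):
    """Replicated variant: Welch t-test on log2(FPKM + pc) per gene.

    ``ck_reps`` / ``dt_reps``: genes x replicates. Returns
    ``(deg_flags, log2fc, p)`` per gene.
    """
    lck = np.log2(np.asarray(ck_reps, dtype=float) + pseudocount)
    ldt = np.log2(np.asarray(dt_reps, dtype=float) + pseudocount)
    res = stats.ttest_ind(ldt, lck, axis=1, equal_var=False)
    log2fc = ldt.mean(axis=1) - lck.mean(axis=1)
    deg = (np.abs(log2fc) > lfc) & (res.pvalue < alpha)
    return deg, log2fc, res.pvalue


def call_drg(expr_ck: pd.DataFrame, expr_dt: pd.DataFrame,
             alpha: float = 0.05, lfc: float = 1.0,
             pseudocount: float = 1.0) -> pd.DataFrame:
    """Drought-responsive genes.

    DRG iff (a) DEG between CK and DT in at least one genotype and (b) the
    paired t-test across genotypes on log2(FPKM + pc) has p < alpha.
    Returns a per-gene table with ``deg_count``, ``paired_p`` and ``drg``.
    """
    common = [s for s in expr_ck.columns if s in set(expr_dt.columns)]
    ck = expr_ck[common].to_numpy(dtype=float)
    dt = expr_dt[common].to_numpy(dtype=float)
    deg, _, _ = call_deg(ck, dt, alpha=alpha, lfc=lfc, pseudocount=pseudocount)
    deg_count = deg.sum(axis=1)
    res = stats.ttest_rel(np.log2(dt + pseudocount),
                          np.log2(ck + pseudocount), axis=1)
    drg = (deg_count >= 1) & (res.pvalue < alpha)
    logger.info("DRG call: |log2FC| > %g and per-genotype p < %g in >= 1 "
                "genotype, paired-t p < %g -> %d genes",
                lfc, alpha, alpha, int(drg.sum()))
    return pd.DataFrame({
        "gene_id": expr_ck.index,
        "deg_count": deg_count,
        "paired_p": res.pvalue,
        "drg": drg,
    }).set_index("gene_id")


def qst_fst_correlation(qst_values: pd.Series, fst_values: pd.Series):
    """Pearson correlation of per-gene expression Q_ST against F_ST.

    Genes missing either value are dropped; fewer than 3 overlapping genes is
    an error. Returns ``(r, p, n)``.
    """
    df = pd.concat([pd.Series(qst_values, name="q"),
                    pd.Series(fst_values, name="f")], axis=1).dropna()
    if len(df) < 3:
        raise ValueError("need >= 3 genes with both Q_ST and F_ST defined")
    r, p = stats.pearsonr(df["q"], df["f"])
    return float(r), float(p), len(df)


def condition_shift_test(values_ck, values_dt):
    """Wilcoxon signed-rank comparison of a per-gene statistic between
    conditions (reporting utility for C.V. / E_d contrasts).

    Returns ``(statistic, p, median_difference)`` over genes with both values.
    """
    a = np.asarray(values_ck, dtype=float)
    b = np.asarray(values_dt, dtype=float)
    ok = ~np.isnan(a) & ~np.isnan(b)
    res = stats.wilcoxon(b[ok], a[ok])
    return float(res.statistic), float(res.pvalue), float(np.median(b[ok] - a[ok]))
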