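"""Trait-level divergence, trait-correlated gene sets, enrichment tests and
the drought-tolerance / productivity trade-off analysis.

A trait is called divergently selected when its Q_ST exceeds the neutral
genomic F_ST band (bootstrap mean +- z * SE over intergenic SNPs).
Trait-correlated genes are defined by per-gene Pearson correlation (p < .05
among typical genotypes, within condition); trade-off genes are those
significantly (BH FDR < .05) and oppositely correlated with RWC under drought
and tiller number under control conditions.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import false_discovery_control

from .expression_stats import qst_matrix

logger = logging.getLogger("ecodiverge")

__all__ = [
    "trait_qst_profile",
    "gene_trait_correlation",
    "trait_correlated_genes",
    "ratio_vs_qst_correlation",
    "tradeoff_genes",
    "fisher_enrichment",
    "rwc_direction_consistency",
]


def trait_qst_profile(traits: pd.DataFrame, ecotype, neutral_mean: float,
                      neutral_se: float, n_perm: int = 1000,
                      seed: int | None = 0, z: float = 1.96) -> pd.DataFrame:
    """Per-trait Q_ST vs the neutral F_ST interval.

    ``ecotype``: label per sample (row of ``traits``). A trait is flagged
    ``divergent`` when its Q_ST exceeds ``neutral_mean + z * neutral_se``.
    Returns a table (trait, qst, qst_p, neutral_upper, divergent).
    """
    x = traits.to_numpy(dtype=float).T  # traits x samples
    q, p = qst_matrix(x, ecotype, n_perm=n_perm, seed=seed)
    upper = neutral_mean + z * neutral_se
    out = pd.DataFrame({
        "trait": traits.columns, "qst": q, "qst_p": p,
        "neutral_upper": upper, "divergent": q > upper,
    })
    logger.info("trait Q_ST profile: %d of %d traits above neutral F_ST "
                "upper bound %.4f", int(out["divergent"].sum()), len(out),
                upper)
    return out


def gene_trait_correlation(expr: pd.DataFrame, trait_values) -> pd.DataFrame:
    """Vectorized per-gene Pearson correlation against one trait vector.

    Constant genes (or a constant trait) yield missing r/p (logged). Returns
    a per-gene table (r, p, q) with Benjamini-Hochberg q-values over the
    non-missing genes.
    """
    x = expr.to_numpy(dtype=float)
    y = np.asarray(trait_values, dtype=float)
    n = y.size
    if n < 3:
        raise ValueError("need >= 3 samples for correlation")
    xm = x - x.mean(axis=1, keepdims=True)
    ym = y - y.mean()
    xs = np.sqrt((xm ** 2).sum(axis=1))
    ys = np.sqrt((ym ** 2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xm @ ym) / (xs * ys)
    r[(xs == 0)] = np.nan
    if ys == 0:
        r[:] = np.nan
    n_const = int(np.isnan(r).sum())
    if n_const:
        logger.info("gene-trait correlation: %d constant gene(s)/trait "
                    "excluded", n_const)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isnan(r)] = np.nan
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = false_discovery_control(p[ok], method="bh")
    return pd.DataFrame({"r": r, "p": p, "q": q}, index=expr.index)


def trait_correlated_genes(expr: pd.DataFrame, traits: pd.DataFrame,
                           typical_mask=None, alpha: float = 0.05) -> dict:
    """Per-trait correlation tables among typical genotypes.

    ``expr`` columns and ``traits`` rows must share sample names; only
    samples with ``typical_mask`` True are used (all when None). Returns
    ``{trait: per-gene DataFrame(r, p, q, correlated)}``.
    """
    samples = [s for s in expr.columns if s in traits.index]
    if typical_mask is not None:
        tm = pd.Series(np.asarray(typical_mask, dtype=bool),
                       index=expr.columns)
        samples = [s for s in samples if tm[s]]
    sub = expr[samples]
    out = {}
    for t in traits.columns:
        tab = gene_trait_correlation(sub, traits.loc[samples, t])
        tab["correlated"] = tab["p"] < alpha
        out[t] = tab
    return out


def ratio_vs_qst_correlation(trait_sets: dict, tdsg_genes, trait_qst: pd.Series):
    """Correlate per-trait TDSG enrichment ratios with trait Q_ST.

    ``ratio(trait) = |trait-correlated genes ∩ TDSGs| / |TDSGs|``. Returns
    ``(r, p, table)``; r/p are missing when ratios are constant across traits
    or fewer than 3 traits overlap.
    """
    tdsg_genes = set(tdsg_genes)
    if not tdsg_genes:
        raise ValueError("empty TDSG set")
    rows = []
    for t, tab in trait_sets.items():
        if t not in trait_qst.index:
            continue
        corr = set(tab.index[tab["correlated"].fillna(False)])
        rows.append((t, len(corr & tdsg_genes) / len(tdsg_genes),
                     float(trait_qst[t])))
    table = pd.DataFrame(rows, columns=["trait", "ratio", "qst"])
    if len(table) < 3 or table["ratio"].nunique() == 1 or \
            table["qst"].nunique() == 1:
        return float("nan"), float("nan"), table
    r, p = stats.pearsonr(table["ratio"], table["qst"])
    return float(r), float(p), table


def tradeoff_genes(rwc_table: pd.DataFrame, nt_table: pd.DataFrame,
                   fdr: float = 0.05) -> pd.Series:
    """Genes oppositely correlated with RWC-DT and NT-CK at BH FDR < ``fdr``.

    Both q-values must pass and the correlation signs must be opposite.
    Returns a boolean Series over the common gene index.
    """
    common = rwc_table.index.intersection(nt_table.index)
    a = rwc_table.loc[common]
    b = nt_table.loc[common]
    flags = (a["q"] < fdr) & (b["q"] < fdr) & \
        (np.sign(a["r"]) == -np.sign(b["r"])) & \
        (a["r"] != 0) & (b["r"] != 0)
    out = flags.fillna(False)
    logger.info("trade-off genes (FDR < %g, opposite signs): %d",
                fdr, int(out.sum()))
    return out


def fisher_enrichment(set_a, set_b, universe, alternative: str = "two-sided") -> dict:
    """Fisher's exact test of overlap between two gene sets in a universe.

    2x2 table: membership in A x membership in B over ``universe``. Returns
    a record with the counts, the odds ratio ``(a*d)/(b*c)`` (inf when only
    ``b*c`` is zero, nan for an empty margin) and the exact p-value.
    """
    universe = set(universe)
    A = set(set_a) & universe
    B = set(set_b) & universe
    a = len(A & B)
    b = len(A - B)
    c = len(B - A)
    d = len(universe) - a - b - c
    if len(A) == 0 or len(B) == 0 or len(A) == len(universe) or \
            len(B) == len(universe):
        orr = float("nan")
    elif b * c == 0:
        orr = float("inf") if a * d > 0 else float("nan")
    else:
        orr = (a * d) / (b * c)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    return {"a": a, "b": b, "c": c, "d": d, "n": len(universe),
            "odds_ratio": orr, "p": float(p), "alternative": alternative}


def rwc_direction_consistency(genes, rwc_r: pd.Series,
                              mean_diff: pd.Series,
                              alternative: str = "two-sided") -> dict:
    """Association between RWC-correlation sign and ecotype expression bias.

    For each gene in ``genes``: classify by (sign of its correlation with
    RWC under drought, sign of upland-minus-lowland mean expression); genes
    with a zero in either sign are excluded (logged). Fisher test of the
    resulting 2x2 sign table; a positive association means positively
    RWC-correlated genes tend to be more expressed in upland plants.
    """
    genes = [g for g in genes if g in rwc_r.index and g in mean_diff.index]
    sr = np.sign(rwc_r.loc[genes].to_numpy(dtype=float))
    sd = np.sign(mean_diff.loc[genes].to_numpy(dtype=float))
    ok = (sr != 0) & (sd != 0) & ~np.isnan(sr) & ~np.isnan(sd)
    excluded = len(genes) - int(ok.sum())
    if excluded:
        logger.info("RWC direction consistency: %d gene(s) with zero sign "
                    "excluded", excluded)
    sr, sd = sr[ok], sd[ok]
    a = int(((sr > 0) & (sd > 0)).sum())
    b = int(((sr > 0) & (sd < 0)).sum())
    c = int(((sr < 0) & (sd > 0)).sum())
    d = int(((sr < 0) & (sd < 0)).sum())
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    orr = (a * d) / (b * c) if b * c else (float("inf") if a * d else float("nan"))
    return {"a": a, "b": b, "c": c, "d": d, "p": float(p), "odds_ratio": orr,
            "n": int(ok.sum()), "excluded": excluded}
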