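"""Weighted co-expression network: adjacency, TOM, modules, hubs.

The network is unsigned: adjacency ``a_ij = |cor(i, j)|^softpower``. The
topological overlap matrix rewards shared neighborhoods,

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),

with connectivities ``k`` = row sums minus the diagonal and TOM_ii = 1.
Modules come from average-linkage hierarchical clustering of ``1 - TOM``; the
tree is cut either at a fixed height or — the default — at the midpoint of
the largest gap in the sorted merge heights (a deterministic elbow rule that
plays the role of a dynamic tree cut); clusters below the minimum size become
unassigned background (module 0). Close modules are merged when their
eigengenes correlate above ``1 - merge_distance``. Every step is
deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger("ecodiverge")

__all__ = [
    "NetworkConfig",
    "ModuleAssignment",
    "adjacency",
    "tom",
    "detect_modules",
    "module_eigengene",
    "merge_modules",
    "module_trait_correlation",
    "hub_genes",
]


@dataclass
class NetworkConfig:
    """Tunable network parameters (defaults: the standard unsigned recipe)."""

    softpower: float = 6.0
    min_module_size: int = 30
    merge_distance: float = 0.20
    edge_threshold: float = 0.01
    hub_fraction: float = 0.15
    cut_method: str = "gap"  # 'gap' (largest-gap elbow) or 'height'
    cut_height: float | None = None  # used when cut_method == 'height'

    def __post_init__(self) -> None:
        if self.softpower < 1:
            raise ValueError("softpower must be >= 1")
        for f in ("merge_distance", "hub_fraction"):
            v = getattr(self, f)
            if not 0 < v < 1:
                raise ValueError(f"{f} must be in (0, 1)")


@dataclass
class ModuleAssignment:
    """Gene -> module labels (0 = unassigned background) plus eigengenes."""

    labels: pd.Series  # index = gene ids, values = int module labels
    eigengenes: dict  # module label -> np.ndarray over samples

    @property
    def modules(self) -> list:
        return sorted(m for m in self.labels.unique() if m != 0)

    def genes_in(self, module: int) -> pd.Index:
        return self.labels.index[self.labels == module]


def adjacency(expr: pd.DataFrame, softpower: float = 6.0) -> np.ndarray:
    """Unsigned adjacency |Pearson r|^softpower over a genes x samples matrix."""
    x = np.asarray(expr, dtype=float)
    r = np.corrcoef(x)
    a = np.abs(np.clip(r, -1.0, 1.0)) ** softpower
    np.fill_diagonal(a, 1.0)
    return a


def tom(a: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of an adjacency matrix (unsigned)."""
    a = np.asarray(a, dtype=float)
    k = a.sum(axis=0) - np.diag(a)
    shared = a @ a - a * np.diag(a)[None, :] - np.diag(a)[:, None] * a \
        + np.diag(a)[:, None] * np.diag(a)[None, :] * np.eye(len(a))
    # shared_ij = sum_{u != i, j} a_iu a_uj  (subtract the u=i and u=j terms)
    num = shared + a
    den = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(t, 1.0)
    return np.clip(t, 0.0, 1.0)


def _cut_height_largest_gap(heights: np.ndarray) -> float:
    """Midpoint of the largest gap between consecutive merge heights."""
    hs = np.sort(heights)
    if hs.size == 1:
        return float(hs[0] / 2)
    gaps = np.diff(hs)
    j = int(np.argmax(gaps))  # ties -> lowest gap, deterministic
    return float((hs[j] + hs[j + 1]) / 2)


def detect_modules(tom_matrix: np.ndarray, config: NetworkConfig,
                   gene_ids=None, expr: pd.DataFrame | None = None) -> ModuleAssignment:
    """Average-linkage clustering of 1 - TOM with a size-filtered tree cut.

    Clusters smaller than ``min_module_size`` become background (label 0);
    surviving modules are renumbered 1..K by decreasing size (ties by first
    gene). Eigengenes are filled in when ``expr`` is provided.
    """
    t = np.asarray(tom_matrix, dtype=float)
    n = t.shape[0]
    if gene_ids is None:
        gene_ids = pd.RangeIndex(n)
    d = 1.0 - t
    np.fill_diagonal(d, 0.0)
    z = hierarchy.linkage(squareform(d, checks=False), method="average")
    if config.cut_method == "height":
        if config.cut_height is None:
            raise ValueError("cut_method='height' needs cut_height")
        h = config.cut_height
    elif config.cut_method == "gap":
        h = _cut_height_largest_gap(z[:, 2])
    else:
        raise ValueError(f"unknown cut_method {config.cut_method!r}")
    raw = hierarchy.fcluster(z, t=h, criterion="distance")

    sizes = pd.Series(raw).value_counts()
    keep = [c for c in sizes.index if sizes[c] >= config.min_module_size]
    # renumber by size desc, then by first occurrence for determinism
    first = {c: int(np.argmax(raw == c)) for c in keep}
    keep.sort(key=lambda c: (-sizes[c], first[c]))
    remap = {c: i + 1 for i, c in enumerate(keep)}
    labels = pd.Series([remap.get(c, 0) for c in raw], index=gene_ids)
    logger.info("module detection: cut height %.3f -> %d modules (min size %d)",
                h, len(keep), config.min_module_size)

    eigengenes = {}
    if expr is not None:
        for m in sorted(remap.values()):
            eigengenes[m] = module_eigengene(
                expr.loc[labels.index[labels == m]])
    return ModuleAssignment(labels, eigengenes)


def module_eigengene(expr_module: pd.DataFrame) -> np.ndarray:
    """First principal component of the per-gene z-scored module submatrix.

    Unit norm; sign oriented to correlate positively with the module's mean
    standardized profile. A 1-gene module returns that gene's normalized
    z-score profile.
    """
    x = np.atleast_2d(np.asarray(expr_module, dtype=float))
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    ref = z.mean(axis=0)
    if ref.std() > 0 and np.corrcoef(eig, ref)[0, 1] < 0:
        eig = -eig
    return eig / np.linalg.norm(eig)


def merge_modules(expr: pd.DataFrame, assignment: ModuleAssignment,
                  merge_distance: float = 0.20) -> ModuleAssignment:
    """Iteratively merge the closest eigengene pair below the threshold.

    Dissimilarity is ``1 - cor(eigengene_i, eigengene_j)`` (signed, as
    eigengene orientation is fixed by convention); the closest pair below
    ``merge_distance`` merges first, ties broken by (smaller label, larger
    label); eigengenes are recomputed after each merge.
    """
    labels = assignment.labels.copy()
    eigs = dict(assignment.eigengenes)
    while True:
        mods = sorted(m for m in labels.unique() if m != 0)
        if len(mods) < 2:
            break
        best = None
        for i, mi in enumerate(mods):
            for mj in mods[i + 1:]:
                dis = 1.0 - float(np.corrcoef(eigs[mi], eigs[mj])[0, 1])
                if dis < merge_distance and (best is None or dis < best[0]):
                    best = (dis, mi, mj)
        if best is None:
            break
        _, mi, mj = best
        labels[labels == mj] = mi
        eigs[mi] = module_eigengene(expr.loc[labels.index[labels == mi]])
        del eigs[mj]
        logger.info("merged modules %d <- %d (eigengene dissimilarity %.3f)",
                    mi, mj, best[0])
    # renumber contiguously by size
    mods = sorted((m for m in labels.unique() if m != 0),
                  key=lambda m: (-(labels == m).sum(), m))
    remap = {m: i + 1 for i, m in enumerate(mods)}
    labels = labels.map(lambda m: remap.get(m, 0))
    eigs = {remap[m]: e for m, e in eigs.items() if m in remap}
    return ModuleAssignment(labels, eigs)


def module_trait_correlation(assignment: ModuleAssignment,
                             traits: pd.DataFrame) -> pd.DataFrame:
    """Pearson r and p of each module eigengene against each trait column.

    Constant traits yield missing entries. Returns a long table
    (module, trait, r, p).
    """
    rows = []
    for m in assignment.modules:
        e = assignment.eigengenes[m]
        for t in traits.columns:
            v = traits[t].to_numpy(dtype=float)
            if np.std(v) == 0 or np.std(e) == 0:
                rows.append((m, t, np.nan, np.nan))
                continue
            r, p = stats.pearsonr(e, v)
            rows.append((m, t, float(r), float(p)))
    return pd.DataFrame(rows, columns=["module", "trait", "r", "p"])


def hub_genes(tom_matrix: np.ndarray, assignment: ModuleAssignment,
              config: NetworkConfig) -> pd.Series:
    """Hub flags: within-module edge count in the top ``hub_fraction``.

    An edge is a within-module pair with TOM >= ``edge_threshold``. The hub
    boundary is the ceil(hub_fraction * module size)-th largest edge count;
    all genes tied at the boundary are included.
    """
    t = np.asarray(tom_matrix, dtype=float)
    genes = assignment.labels.index
    hubs = pd.Series(False, index=genes)
    for m in assignment.modules:
        idx = np.flatnonzero((assignment.labels == m).to_numpy())
        sub = t[np.ix_(idx, idx)]
        edges = (sub >= config.edge_threshold).sum(axis=1) - 1  # drop self
        k = max(1, int(np.ceil(config.hub_fraction * len(idx))))
        boundary = np.sort(edges)[::-1][k - 1]
        hubs.iloc[idx] = edges >= boundary
        logger.info("module %d: hub edge-count boundary %d (top %d of %d, "
                    "edge threshold %.3g)", m, int(boundary), k, len(idx),
                    config.edge_threshold)
    return hubs
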