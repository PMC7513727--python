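"""Cis-element-altering SNPs in upstream regulatory windows.

A promoter SNP *gains* a motif when only the alternate-allele sequence carries
an occurrence of that motif overlapping the SNP, and *loses* it when only the
reference-allele sequence does. Scanning covers both strands by default
(PLACE-style motifs are strand-ambiguous); positions are reported relative to
the TSS (negative = upstream) and 0-based within the supplied window
otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import MotifLibrary, PromoterSet
from .expression_stats import qst

logger = logging.getLogger("ecodiverge")

__all__ = [
    "IUPAC",
    "CisAlteringSNP",
    "scan_motifs",
    "classify_snp",
    "scan_cis_altering_snps",
    "assign_haplotypes",
    "haplotype_vs_ecotype_qst",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
_BASE_IDX = {b: i for i, b in enumerate("ACGT")}


@dataclass
class CisAlteringSNP:
    """One (SNP, motif) gain/loss event in a gene's upstream window."""

    gene_id: str
    pos_tss: int  # position relative to TSS, negative upstream
    ref: str
    alt: str
    motif: str
    effect: str  # 'gain' or 'loss'
    strand: str  # strand of the motif occurrence


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _encode(seq: str) -> np.ndarray:
    out = np.full(len(seq), 4, dtype=np.int8)  # 4 = unknown base
    for b, i in _BASE_IDX.items():
        out[np.frombuffer(seq.upper().encode(), dtype=np.uint8) ==
            ord(b)] = i
    return out


def _motif_table(pattern: str) -> np.ndarray:
    """(L x 5) boolean table: allowed bases per motif position."""
    tab = np.zeros((len(pattern), 5), dtype=bool)
    for k, c in enumerate(pattern.upper()):
        for b in IUPAC[c]:
            tab[k, _BASE_IDX[b]] = True
    return tab


def _match_positions(codes: np.ndarray, tab: np.ndarray) -> np.ndarray:
    """Start offsets where the motif table matches (vectorized AND-scan)."""
    L = tab.shape[0]
    n = codes.size
    if n < L:
        return np.array([], dtype=int)
    ok = np.ones(n - L + 1, dtype=bool)
    for k in range(L):
        ok &= tab[k, codes[k:n - L + 1 + k]]
    return np.flatnonzero(ok)


def _compile_library(motifs: MotifLibrary) -> list:
    """Precompiled (name, forward table, reverse-complement table) triples."""
    out = []
    for name, pat in motifs.items():
        out.append((name, _motif_table(pat), _motif_table(_revcomp(pat)),
                    len(pat)))
    return out


def scan_motifs(sequence: str, motifs: MotifLibrary,
                both_strands: bool = True) -> pd.DataFrame:
    """All exact IUPAC occurrences of each motif in a sequence.

    Returns a table (motif, start, end, strand) with 0-based half-open
    intervals on the forward sequence; minus-strand rows are matches of the
    motif on the reverse complement, mapped back to forward coordinates. A
    palindromic motif therefore yields one record per strand over the same
    interval.
    """
    codes = _encode(sequence)
    rows = []
    for name, tab, rc, L in _compile_library(motifs):
        for off in _match_positions(codes, tab):
            rows.append((name, int(off), int(off) + L, "+"))
        if both_strands:
            for off in _match_positions(codes, rc):
                rows.append((name, int(off), int(off) + L, "-"))
    return pd.DataFrame(rows, columns=["motif", "start", "end", "strand"])


def classify_snp(sequence: str, pos: int, ref: str, alt: str,
                 motifs: MotifLibrary, both_strands: bool = True) -> list:
    """Gain/loss classification of one SNP against every motif.

    Builds the reference- and alternate-allele sequences, collects motif
    occurrences overlapping the SNP in each, and reports *gain* when only the
    alternate allele yields an occurrence, *loss* when only the reference
    does. Swapping ref and alt swaps the labels (antisymmetry). A SNP under a
    fully degenerate motif position matches under both alleles and yields no
    record. Returns a list of ``(motif, effect, strand)`` tuples.
    """
    return _classify_fast(_encode(sequence), pos, ref.upper(), alt.upper(),
                          _compile_library(motifs), both_strands)


def _classify_fast(codes: np.ndarray, pos: int, ref: str, alt: str,
                   library: list, both_strands: bool) -> list:
    """Core gain/loss comparison on an encoded sequence (no copies of the
    full promoter; only the +-Lmax window around the SNP is rebuilt)."""
    lmax = max(L for _, _, _, L in library)
    lo = max(0, pos - lmax + 1)
    hi = min(len(codes), pos + lmax)
    win_ref = codes[lo:hi].copy()
    win_alt = win_ref.copy()
    p_rel = pos - lo
    win_ref[p_rel] = _BASE_IDX.get(ref, 4)
    win_alt[p_rel] = _BASE_IDX.get(alt, 4)

    def hit(win, tab, L):
        for off in _match_positions(win, tab):
            if off <= p_rel < off + L:
                return True
        return False

    out = []
    for name, tab, rc, L in library:
        strands = (("+", tab), ("-", rc)) if both_strands else (("+", tab),)
        for strand, t in strands:
            in_ref = hit(win_ref, t, L)
            in_alt = hit(win_alt, t, L)
            if in_alt and not in_ref:
                out.append((name, "gain", strand))
            elif in_ref and not in_alt:
                out.append((name, "loss", strand))
    return out


def scan_cis_altering_snps(genotypes, promoters: PromoterSet,
                           motifs: MotifLibrary, regions: list,
                           both_strands: bool = True) -> pd.DataFrame:
    """Classify every upstream SNP of every gene with a stored promoter.

    Returns one row per (SNP, motif, strand) event: gene_id, site_index,
    pos (genomic, 0-based), pos_tss, ref, alt, motif, effect, strand.
    """
    sites = genotypes.sites
    tss = {r.gene_id: (r.tss, r.strand) for r in regions}
    library = _compile_library(motifs)
    encoded = {}
    rows = []
    upstream = sites[(sites["subregion"] == "upstream") &
                     sites["gene_id"].isin(promoters.sequences)]
    for j, site in upstream.iterrows():
        gid = site["gene_id"]
        if gid not in encoded:
            encoded[gid] = _encode(promoters.sequences[gid])
        seq = encoded[gid]
        rel = int(site["pos"]) - promoters.starts[gid]
        if not 0 <= rel < len(seq):
            continue
        events = _classify_fast(seq, rel, site["ref"], site["alt"],
                                library, both_strands)
        t, strand = tss.get(gid, (None, promoters.strands.get(gid, "+")))
        if t is None:
            pos_tss = rel - len(seq)
        else:
            pos_tss = (int(site["pos"]) - t) if strand == "+" \
                else (t - 1 - int(site["pos"]))
        for motif, effect, mstrand in events:
            rows.append({
                "gene_id": gid, "site_index": j, "pos": int(site["pos"]),
                "pos_tss": int(pos_tss), "ref": site["ref"],
                "alt": site["alt"], "motif": motif, "effect": effect,
                "strand": mstrand,
            })
    out = pd.DataFrame(rows, columns=["gene_id", "site_index", "pos",
                                      "pos_tss", "ref", "alt", "motif",
                                      "effect", "strand"])
    logger.info("cis-element scan: %d gain/loss events in %d genes",
                len(out), out["gene_id"].nunique() if len(out) else 0)
    return out


# ---------------------------------------------------------------------------
# haplotypes
# ---------------------------------------------------------------------------

def assign_haplotypes(codes: np.ndarray) -> np.ndarray:
    """Group samples by their unphased genotype vector over the given SNPs.

    ``codes``: (cis-altering SNPs x samples). Heterozygous vectors form their
    own groups; samples with any missing genotype get label -1. Returns an
    integer label per sample (labels ordered by first occurrence).
    """
    codes = np.atleast_2d(np.asarray(codes))
    n = codes.shape[1]
    labels = np.full(n, -1, dtype=int)
    seen = {}
    for s in range(n):
        vec = tuple(int(v) for v in codes[:, s])
        if any(v < 0 for v in vec):
            continue
        labels[s] = seen.setdefault(vec, len(seen))
    return labels


def haplotype_vs_ecotype_qst(values, hap_labels, ecotype_labels,
                             n_perm: int = 1000, seed: int | None = 0,
                             min_group: int = 3) -> dict:
    """Compare expression Q_ST between haplotypes with Q_ST between ecotypes.

    Haplotype groups smaller than ``min_group`` are excluded (logged). The
    record flags the gene when the haplotype Q_ST strictly exceeds the
    ecotype Q_ST *and* the 95th percentile of ecotype Q_ST under
    ecotype-label permutations — i.e. the haplotype grouping explains more
    divergence than the ecotype split could by chance. A haplotype grouping
    identical to the ecotype partition therefore never flags.
    """
    values = np.asarray(values, dtype=float)
    hap = np.asarray(hap_labels)
    eco = np.asarray(ecotype_labels)

    keep_groups = [g for g in np.unique(hap[hap >= 0])
                   if (hap == g).sum() >= min_group]
    dropped = len(np.unique(hap[hap >= 0])) - len(keep_groups)
    if dropped:
        logger.info("haplotype Q_ST: %d group(s) below %d samples excluded",
                    dropped, min_group)
    rec = {"qst_hap": np.nan, "qst_eco": np.nan, "p_eco_perm_q95": np.nan,
           "n_haplotypes": len(keep_groups), "flag": False}
    if len(keep_groups) < 2:
        return rec

    mask = np.isin(hap, keep_groups)
    q_hap, _ = qst(values[mask], hap[mask], n_perm=0)
    q_eco, _ = qst(values, eco, n_perm=0)

    # permuting labels over samples == permuting values under fixed labels,
    # so the permutation null is computed in one vectorized call
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(values.size) for _ in range(n_perm)])
    from .expression_stats import qst_matrix
    perm_q, _ = qst_matrix(values[perms], eco, n_perm=0)
    q95 = float(np.quantile(perm_q, 0.95))
    rec.update(qst_hap=float(q_hap), qst_eco=float(q_eco),
               p_eco_perm_q95=q95,
               flag=bool(q_hap > q_eco and q_hap > q95))
    return rec
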