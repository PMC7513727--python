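"""Seeded synthetic datasets with planted ground truth.

This module emulates the data the divergence-scan pipeline consumes: two
genetically differentiated ecotypes (upland / lowland) of a selfing crop, with

* a minority of highly differentiated genes (large allele-frequency contrasts),
* genes whose expression is under directional selection between ecotypes
  (shifted means, deflated within-ecotype variance),
* drought-responsive genes (planted log2 fold change between CK and DT),
* selective-sweep genes with ~10x deflated within-ecotype diversity,
* promoter SNPs that create or destroy planted cis-element motifs, and
* agronomic traits built from latent factors of planted-gene expression with a
  drought-tolerance (RWC-DT) vs tillering (NT-CK) trade-off.

Every output is a deterministic function of ``SimConfig.seed``. Planted flag
counts follow the config fractions exactly under round-half-up.

Allele-frequency divergence for highly differentiated and sweep genes is
planted on non-intron SNPs only; intron SNPs always stay neutral so that they
can serve as the neutral reference sequence for the expression selection
index. Sweep deflation, by contrast, applies to every SNP of the swept gene
(hitchhiking affects linked neutral sites).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datatypes import (
    GenotypeMatrix,
    GroundTruth,
    MotifLibrary,
    PromoterSet,
    SampleMetadata,
)

__all__ = [
    "SimConfig",
    "SimDataset",
    "gene_annotation",
    "plant_truth",
    "generate_genotypes",
    "generate_expression",
    "generate_promoters_and_motifs",
    "generate_traits",
    "generate_dataset",
]

_BASES = np.array(list("ACGT"))

# distinct RNG streams per stage, keyed off (seed, stream id)
_STREAMS = {
    "truth": 1,
    "genotypes": 2,
    "expression": 3,
    "promoters": 4,
    "traits": 5,
}

TRAIT_NAMES = [
    "PH", "NT", "FLL", "FLW", "NG", "100GW", "GY", "biomass", "HI",
    "fecundity", "RWC",
]

#: traits planted with an ecotype mean offset (divergently selected)
DIVERGENT_TRAITS = ["NT_CK", "NT_DT", "FLW_DT", "RWC_DT"]


def _rh(x: float) -> int:
    """Round half up (documented rounding rule for planted counts)."""
    return int(math.floor(x + 0.5))


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults describe the study conditions the pipeline is exercised on: 40
    typical upland + 50 typical lowland genotypes and a 2,000-gene candidate
    panel. Effect sizes are expressed on the log2-FPKM scale unless noted.
    """

    seed: int = 0
    n_upland: int = 40
    n_lowland: int = 50
    n_genes: int = 2000
    n_intergenic_snps: int = 3000
    snps_per_gene: int = 12

    # planted-gene fractions of n_genes (round-half-up)
    frac_hdg: float = 0.05
    frac_tdsg: float = 0.20
    frac_drg: float = 0.25
    frac_motif_altering: float = 0.10
    frac_sweep: float = 0.03  # per ecotype

    # co-expression structure (module genes are TDSG and DRG by construction)
    n_modules: int = 4
    module_size: int = 35
    module_factor_sd: float = 0.19
    module_noise_sd: float = 0.15

    # effect sizes
    effect_tdsg: float = 3.0  # ecotype mean shift, units of idiosyncratic SD
    drought_log2fc: float = 2.0
    trait_noise_sd: float = 0.5
    tradeoff_strength: float = 0.8
    trait_ecotype_offset: float = 1.5  # raw-trait-unit shift for divergent traits

    # expression noise model (log2 scale)
    baseline_mean: float = 3.5
    baseline_sd: float = 1.5
    sigma_neutral: float = 0.7
    sigma_tdsg: float = 0.25
    # kept small so the block correlation it induces leaves the nominal level
    # of the independent-samples t-test approximately valid
    origin_sd: float = 0.02
    n_origins_per_ecotype: int = 4

    # genotype model
    divergence_sd: float = 0.2  # neutral ecotype allele-frequency deviation
    hdg_freq_major: float = 0.9  # planted HDG frequencies: 0.9 vs 0.1
    sweep_minor_freq: float = 0.02
    missing_rate: float = 0.0

    # genome layout (bp)
    flank: int = 2000
    gene_body_len: int = 3000
    intron_span: tuple = (500, 2500)  # relative to gene body start
    gene_spacing: int = 10000
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        self.validate()

    # -- derived quantities -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.n_upland + self.n_lowland

    @property
    def chrom_length(self) -> int:
        return self.n_genes * self.gene_spacing + self.flank

    @property
    def region_len(self) -> int:
        return self.gene_body_len + 2 * self.flank

    def planted_counts(self) -> dict:
        n = self.n_genes
        return {
            "hdg": _rh(self.frac_hdg * n),
            "tdsg": _rh(self.frac_tdsg * n),
            "drg": _rh(self.frac_drg * n),
            "motif": _rh(self.frac_motif_altering * n),
            "sweep": _rh(self.frac_sweep * n),
            "module_genes": self.n_modules * self.module_size,
        }

    def validate(self) -> None:
        for f in ("frac_hdg", "frac_tdsg", "frac_drg", "frac_motif_altering",
                  "frac_sweep"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{f}={v} outside [0, 1]")
        if self.n_upland < 2 or self.n_lowland < 2:
            raise ConfigError("need at least 2 samples per ecotype")
        if self.snps_per_gene < 5:
            raise ConfigError("snps_per_gene must be >= 5 (2 upstream + 2 intron + body)")
        if not -1.0 <= self.tradeoff_strength <= 1.0:
            raise ConfigError("tradeoff_strength outside [-1, 1]")
        c = self.planted_counts()
        if c["module_genes"] > 0:
            if c["module_genes"] > min(c["tdsg"], c["drg"]):
                raise ConfigError(
                    "n_modules * module_size exceeds planted TDSG/DRG counts"
                )
        if c["tdsg"] + 2 * c["sweep"] + c["hdg"] > self.n_genes:
            raise ConfigError("planted gene sets exceed n_genes")
        if self.gene_spacing < self.region_len:
            raise ConfigError("gene_spacing smaller than gene region span")

    def null(self, **overrides) -> "SimConfig":
        """Copy of this config with every planted effect switched off."""
        base = replace(
            self,
            frac_hdg=0.0, frac_tdsg=0.0, frac_drg=0.0,
            frac_motif_altering=0.0, frac_sweep=0.0, n_modules=0,
            effect_tdsg=0.0, drought_log2fc=0.0, tradeoff_strength=0.0,
            trait_ecotype_offset=0.0, origin_sd=0.0,
        )
        return replace(base, **overrides) if overrides else base


def _rng(cfg: SimConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed), _STREAMS[stage]])


# ---------------------------------------------------------------------------
# gene annotation & ground truth
# ---------------------------------------------------------------------------

def gene_annotation(cfg: SimConfig) -> pd.DataFrame:
    """Deterministic gene models: one chromosome, evenly spaced bodies.

    Returns 0-based half-open ``start``/``end`` of the gene body; strands
    alternate so that strand-aware upstream windows are exercised.
    """
    i = np.arange(cfg.n_genes)
    start = i * cfg.gene_spacing + cfg.flank
    return pd.DataFrame({
        "gene_id": [f"g{k + 1:05d}" for k in i],
        "chrom": cfg.chrom,
        "start": start,
        "end": start + cfg.gene_body_len,
        "strand": np.where(i % 2 == 0, "+", "-"),
    })


def plant_truth(cfg: SimConfig) -> GroundTruth:
    """Draw the planted gene sets (pure function of the config).

    Couplings, chosen to mirror the structures the analysis looks for:
    module genes are TDSG and DRG; 70% of the HDGs and half of the
    motif-altering genes are drawn from the TDSG set; sweep genes are kept
    disjoint from TDSG and HDG sets so their intron SNPs stay interpretable.
    Module 0 is the designated trade-off gene set.
    """
    rng = _rng(cfg, "truth")
    n = cfg.n_genes
    c = cfg.planted_counts()
    ann = gene_annotation(cfg)

    order = rng.permutation(n)
    module = np.full(n, -1, dtype=int)
    n_mod = c["module_genes"]
    mod_genes = order[:n_mod]
    for m in range(cfg.n_modules):
        module[mod_genes[m * cfg.module_size:(m + 1) * cfg.module_size]] = m

    tdsg = np.zeros(n, dtype=bool)
    tdsg[order[:c["tdsg"]]] = True  # includes module genes

    drg = np.zeros(n, dtype=bool)
    drg[mod_genes] = True
    non_tdsg_pool = order[c["tdsg"]:]
    extra_drg = max(0, c["drg"] - n_mod)
    drg[non_tdsg_pool[:extra_drg]] = True

    hdg = np.zeros(n, dtype=bool)
    # strong HDG-TDSG coupling: transcriptionally selected genes sit in
    # clearly elevated-F_ST regions, as in real ecotype panels
    n_hdg_tdsg = min(_rh(0.7 * c["hdg"]), c["tdsg"])
    tdsg_idx = order[:c["tdsg"]]
    hdg[rng.choice(tdsg_idx, size=n_hdg_tdsg, replace=False)] = True
    rest = [g for g in non_tdsg_pool if not hdg[g]]
    hdg[np.array(rest[:c["hdg"] - n_hdg_tdsg], dtype=int)] = True

    sweep_pool = np.array([g for g in order if not tdsg[g] and not hdg[g]])
    sweep_up = np.zeros(n, dtype=bool)
    sweep_low = np.zeros(n, dtype=bool)
    sweep_up[sweep_pool[:c["sweep"]]] = True
    sweep_low[sweep_pool[c["sweep"]:2 * c["sweep"]]] = True

    motif = np.zeros(n, dtype=bool)
    n_motif_tdsg = min(c["motif"] // 2, c["tdsg"])
    motif[rng.choice(tdsg_idx, size=n_motif_tdsg, replace=False)] = True
    rest = [g for g in order if not tdsg[g] and not motif[g]]
    motif[np.array(rest[:c["motif"] - n_motif_tdsg], dtype=int)] = True

    # per-gene expression loadings for module genes (sign + magnitude)
    loading = np.zeros(n)
    loading[mod_genes] = rng.choice([-1.0, 1.0], size=n_mod) * rng.uniform(
        0.8, 1.0, size=n_mod
    )

    genes = pd.DataFrame({
        "gene_id": ann["gene_id"],
        "planted_hdg": hdg,
        "planted_tdsg": tdsg,
        "planted_drg": drg,
        "planted_sweep_upland": sweep_up,
        "planted_sweep_lowland": sweep_low,
        "planted_motif_gene": motif,
        "planted_module": module,
        "planted_tradeoff": module == 0,
        "planted_loading": loading,
    })
    return GroundTruth(genes=genes, snps=pd.DataFrame(
        columns=["site_index", "gene_id", "planted_motif_gain",
                 "planted_motif_loss", "motif"]))


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _subregion(pos, ann_row, cfg: SimConfig) -> str:
    bs, be, strand = ann_row.start, ann_row.end, ann_row.strand
    if pos < bs:
        return "upstream" if strand == "+" else "downstream"
    if pos >= be:
        return "downstream" if strand == "+" else "upstream"
    i0, i1 = cfg.intron_span
    return "intron" if bs + i0 <= pos < bs + i1 else "exon"


def generate_genotypes(cfg: SimConfig, truth: GroundTruth | None = None):
    """Simulate biallelic diploid genotypes for all gene regions + intergenic.

    Diploid genotypes are drawn Hardy-Weinberg within ecotype from planted
    per-ecotype allele frequencies (0/1/2 alternate-dosage coding). Returns
    ``(GenotypeMatrix, GroundTruth)``.
    """
    cfg.validate()
    if truth is None:
        truth = plant_truth(cfg)
    rng = _rng(cfg, "genotypes")
    ann = gene_annotation(cfg)

    chroms, positions, gene_ids, subregions = [], [], [], []
    for row in ann.itertuples(index=False):
        lo, hi = row.start - cfg.flank, row.end + cfg.flank
        if row.strand == "+":
            up_lo, up_hi = row.start - cfg.flank, row.start
        else:
            up_lo, up_hi = row.end, row.end + cfg.flank
        i0, i1 = cfg.intron_span
        pos = np.concatenate([
            rng.choice(np.arange(up_lo, up_hi), size=2, replace=False),
            rng.choice(np.arange(row.start + i0, row.start + i1), size=2,
                       replace=False),
            rng.choice(np.arange(lo, hi), size=cfg.snps_per_gene - 4,
                       replace=False),
        ])
        pos = np.unique(pos)
        positions.append(pos)
        gene_ids.extend([row.gene_id] * len(pos))
        subregions.extend(_subregion(p, row, cfg) for p in pos)
        chroms.extend([row.chrom] * len(pos))

    # intergenic SNPs live in the gaps between consecutive gene regions
    gap_len = cfg.gene_spacing - cfg.region_len
    total_gap = cfg.n_genes * gap_len
    n_ig = min(cfg.n_intergenic_snps, total_gap)
    flat = rng.choice(total_gap, size=n_ig, replace=False)
    ig_pos = (flat // gap_len) * cfg.gene_spacing + cfg.region_len + flat % gap_len
    ig_pos = np.sort(ig_pos)
    positions.append(ig_pos)
    gene_ids.extend(["."] * n_ig)
    subregions.extend(["intergenic"] * n_ig)
    chroms.extend([cfg.chrom] * n_ig)

    pos_all = np.concatenate(positions)
    sites = pd.DataFrame({
        "chrom": chroms,
        "pos": pos_all,
        "ref": "N", "alt": "N",
        "gene_id": gene_ids,
        "subregion": subregions,
    })
    sites = sites.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    m = len(sites)

    # reference / alternate bases (may be overridden for planted motif SNPs)
    ref_i = rng.integers(0, 4, size=m)
    alt_i = (ref_i + rng.integers(1, 4, size=m)) % 4
    sites["ref"] = _BASES[ref_i]
    sites["alt"] = _BASES[alt_i]

    # per-ecotype allele frequencies
    base = rng.uniform(0.1, 0.9, size=m)
    p_up = np.clip(base + rng.normal(0, cfg.divergence_sd, size=m), 0.01, 0.99)
    p_low = np.clip(base + rng.normal(0, cfg.divergence_sd, size=m), 0.01, 0.99)

    g = truth.genes.set_index("gene_id")
    gene_of = sites["gene_id"].to_numpy()
    sub = sites["subregion"].to_numpy()
    genic = gene_of != "."
    is_intron = sub == "intron"

    hdg_genes = set(g.index[g["planted_hdg"]])
    su_genes = set(g.index[g["planted_sweep_upland"]])
    sl_genes = set(g.index[g["planted_sweep_lowland"]])

    hdg_orient = {gid: rng.integers(0, 2) for gid in sorted(hdg_genes)}
    in_hdg = genic & np.isin(gene_of, list(hdg_genes)) & ~is_intron
    for j in np.nonzero(in_hdg)[0]:
        hi, lo = cfg.hdg_freq_major, 1.0 - cfg.hdg_freq_major
        if hdg_orient[gene_of[j]]:
            p_up[j], p_low[j] = hi, lo
        else:
            p_up[j], p_low[j] = lo, hi

    # sweeps push the swept ecotype toward the base-frequency-major allele:
    # within-ecotype diversity deflates ~10x while divergence stays moderate
    in_su = genic & np.isin(gene_of, list(su_genes))
    p_up[in_su] = np.where(base[in_su] < 0.5,
                           cfg.sweep_minor_freq, 1.0 - cfg.sweep_minor_freq)
    in_sl = genic & np.isin(gene_of, list(sl_genes))
    p_low[in_sl] = np.where(base[in_sl] < 0.5,
                            cfg.sweep_minor_freq, 1.0 - cfg.sweep_minor_freq)

    codes = np.empty((m, cfg.n_samples), dtype=np.int8)
    codes[:, :cfg.n_upland] = rng.binomial(
        2, p_up[:, None], size=(m, cfg.n_upland))
    codes[:, cfg.n_upland:] = rng.binomial(
        2, p_low[:, None], size=(m, cfg.n_lowland))
    if cfg.missing_rate > 0:
        miss = rng.random(codes.shape) < cfg.missing_rate
        codes[miss] = -1

    samples = sample_names(cfg)
    return GenotypeMatrix(codes, sites, samples), truth


def sample_names(cfg: SimConfig) -> list[str]:
    w = max(2, len(str(max(cfg.n_upland, cfg.n_lowland))))
    return [f"U{i + 1:0{w}d}" for i in range(cfg.n_upland)] + \
           [f"L{i + 1:0{w}d}" for i in range(cfg.n_lowland)]


def make_metadata(cfg: SimConfig) -> SampleMetadata:
    names = sample_names(cfg)
    eco = ["upland"] * cfg.n_upland + ["lowland"] * cfg.n_lowland
    k = cfg.n_origins_per_ecotype
    origin = [f"up{i % k + 1}" for i in range(cfg.n_upland)] + \
             [f"low{i % k + 1}" for i in range(cfg.n_lowland)]
    return SampleMetadata(pd.DataFrame({
        "sample": names, "ecotype": eco, "origin": origin,
        "typical": True,
    }))


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def generate_expression(cfg: SimConfig, truth: GroundTruth):
    """FPKM matrices for CK and DT plus sample metadata.

    Model (log2 scale), per gene g / sample s / condition c:

    ``x = mu_g + drg_g * log2fc * [c == DT] + tdsg_g * shift_g * e_s
    + origin_effect + loading_g * factor_{module(g), c, s} + sigma_g * eps``

    ``e_s`` is +-1/2 by ecotype; ``shift_g = effect_tdsg *
    sqrt(sigma_g^2 + origin_sd^2)`` (idiosyncratic within-ecotype SD units);
    module genes additionally load on a shared per-condition latent factor.
    FPKM = 2**x, hence strictly positive.
    """
    rng = _rng(cfg, "expression")
    meta = make_metadata(cfg)
    n, s = cfg.n_genes, cfg.n_samples
    g = truth.genes

    mu = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=n)
    tdsg = g["planted_tdsg"].to_numpy()
    drg = g["planted_drg"].to_numpy()
    module = g["planted_module"].to_numpy()
    loading = g["planted_loading"].to_numpy()

    sigma = np.where(tdsg, cfg.sigma_tdsg, cfg.sigma_neutral)
    sigma = np.where(module >= 0, cfg.module_noise_sd, sigma)

    e = np.where(np.array(meta.table["ecotype"]) == "upland", 0.5, -0.5)
    shift = cfg.effect_tdsg * np.sqrt(sigma ** 2 + cfg.origin_sd ** 2)
    dir_g = np.where(module >= 0, np.sign(loading),
                     rng.choice([-1.0, 1.0], size=n))
    eco_term = np.where(tdsg, shift * dir_g, 0.0)[:, None] * e[None, :]

    origins = meta.table["origin"].to_numpy()
    origin_levels = pd.unique(origins)
    origin_idx = pd.Categorical(origins, categories=origin_levels).codes
    origin_eff = rng.normal(0, cfg.origin_sd, size=(n, len(origin_levels)))
    origin_term = origin_eff[:, origin_idx]

    out = {}
    factors = {}
    for cond in ("CK", "DT"):
        x = mu[:, None] + eco_term + origin_term
        if cfg.n_modules > 0:
            f = rng.normal(0, cfg.module_factor_sd, size=(cfg.n_modules, s))
            factors[cond] = f
            sel = module >= 0
            x[sel] += loading[sel, None] * f[module[sel]]
        x += rng.normal(0, 1.0, size=(n, s)) * sigma[:, None]
        if cond == "DT":
            x[drg] += cfg.drought_log2fc
        fpkm = np.power(2.0, x)
        out[cond] = pd.DataFrame(fpkm, index=g["gene_id"], columns=meta.samples)
    return out["CK"], out["DT"], meta


# ---------------------------------------------------------------------------
# promoters & motifs
# ---------------------------------------------------------------------------

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def make_motif_library(cfg: SimConfig, rng=None, n_motifs: int = 24) -> MotifLibrary:
    """Synthetic PLACE-style motif table (IUPAC strings, ~20% degenerate)."""
    if rng is None:
        rng = _rng(cfg, "promoters")
    codes = list("ACGT")
    degen = list("RYSWKMN")
    motifs = {}
    for i in range(n_motifs):
        length = int(rng.integers(5, 9))
        if length > cfg.flank:
            raise ConfigError("motif longer than the upstream window")
        pat = [str(rng.choice(degen)) if rng.random() < 0.2
               else str(rng.choice(codes)) for _ in range(length)]
        # anchor first and last position to a concrete base (avoids ultra-
        # promiscuous patterns that match everywhere)
        pat[0] = str(rng.choice(codes))
        pat[-1] = str(rng.choice(codes))
        motifs[f"cis{i + 1:03d}"] = "".join(pat)
    return MotifLibrary(motifs)


def _matches(seq: str, pat: str) -> bool:
    return len(seq) == len(pat) and all(
        b in _IUPAC[p] for b, p in zip(seq, pat))


def _occurs_overlapping(seq: str, pat: str, pos: int) -> bool:
    L = len(pat)
    for o in range(max(0, pos - L + 1), min(len(seq) - L, pos) + 1):
        if _matches(seq[o:o + L], pat):
            return True
    return False


def generate_promoters_and_motifs(cfg: SimConfig, genotypes: GenotypeMatrix,
                                  truth: GroundTruth):
    """Random upstream sequences plus planted motif gains/losses.

    For each motif-altering gene one upstream SNP is chosen; either the
    reference sequence carries a motif occurrence that the alternate allele
    destroys (*loss*) or the alternate allele completes an occurrence absent
    from the reference (*gain*). The chosen SNP's ref/alt bases in
    ``genotypes.sites`` are finalized here so the VCF and FASTA agree;
    ``truth.snps`` is filled in place.

    Returns ``(PromoterSet, MotifLibrary)``.
    """
    rng = _rng(cfg, "promoters")
    ann = gene_annotation(cfg)
    motifs = make_motif_library(cfg, rng=rng)
    motif_names = list(motifs.motifs)

    sequences, starts, strands = {}, {}, {}
    sites = genotypes.sites
    snp_rows = []

    motif_gene = set(
        truth.genes.loc[truth.genes["planted_motif_gene"], "gene_id"])

    for k, row in enumerate(ann.itertuples(index=False)):
        if row.strand == "+":
            w_lo = row.start - cfg.flank
        else:
            w_lo = row.end
        seq = rng.integers(0, 4, size=cfg.flank)
        in_win = (sites["gene_id"] == row.gene_id) & \
                 (sites["subregion"] == "upstream")
        win_idx = np.flatnonzero(in_win.to_numpy())
        # reference sequence must carry the VCF reference alleles
        base_to_i = {b: i for i, b in enumerate("ACGT")}
        for j in win_idx:
            seq[sites.at[j, "pos"] - w_lo] = base_to_i[sites.at[j, "ref"]]

        if row.gene_id in motif_gene and len(win_idx) > 0:
            j = int(rng.choice(win_idx))
            rel = sites.at[j, "pos"] - w_lo
            name = motif_names[k % len(motif_names)]
            effect = "gain" if k % 2 == 0 else "loss"
            planted = _plant_motif(seq, rel, motifs.motifs[name], effect, rng)
            if planted is not None:
                ref_b, alt_b = planted
                sites.at[j, "ref"] = ref_b
                sites.at[j, "alt"] = alt_b
                snp_rows.append({
                    "site_index": j, "gene_id": row.gene_id,
                    "planted_motif_gain": effect == "gain",
                    "planted_motif_loss": effect == "loss",
                    "motif": name,
                })
        sequences[row.gene_id] = "".join(_BASES[seq])
        starts[row.gene_id] = w_lo
        strands[row.gene_id] = row.strand

    truth.snps = pd.DataFrame(
        snp_rows, columns=["site_index", "gene_id", "planted_motif_gain",
                           "planted_motif_loss", "motif"])
    return PromoterSet(sequences, starts, strands), motifs


def _plant_motif(seq: np.ndarray, rel: int, pat: str, effect: str, rng,
                 max_tries: int = 40):
    """Embed a motif instance so the SNP at ``rel`` toggles one occurrence.

    Mutates ``seq`` (integer codes) in place; returns ``(ref, alt)`` bases or
    None when no valid embedding exists (e.g. all SNP-overlapping motif
    positions are fully degenerate).
    """
    L = len(pat)
    n = len(seq)
    base_to_i = {b: i for i, b in enumerate("ACGT")}
    offsets = [o for o in range(max(0, rel - L + 1), min(n - L, rel) + 1)]
    rng.shuffle(offsets)
    for _ in range(max_tries):
        for o in offsets:
            k = rel - o  # motif position covering the SNP
            allowed = _IUPAC[pat[k]]
            if len(allowed) == 4:
                continue  # fully degenerate: no allele can toggle a match
            inst = [str(rng.choice(list(_IUPAC[c]))) for c in pat]
            match_b = str(rng.choice(list(allowed)))
            break_b = str(rng.choice([b for b in "ACGT" if b not in allowed]))
            inst[k] = match_b
            if effect == "gain":
                ref_b, alt_b = break_b, match_b
            else:
                ref_b, alt_b = match_b, break_b
            saved = seq[o:o + L].copy()
            seq[o:o + L] = [base_to_i[c] for c in inst]
            seq[rel] = base_to_i[ref_b]
            ref_s = "".join(_BASES[seq])
            alt_seq = seq.copy()
            alt_seq[rel] = base_to_i[alt_b]
            alt_s = "".join(_BASES[alt_seq])
            ok_ref = _occurs_overlapping(ref_s, pat, rel)
            ok_alt = _occurs_overlapping(alt_s, pat, rel)
            want = (False, True) if effect == "gain" else (True, False)
            if (ok_ref, ok_alt) == want:
                return ref_b, alt_b
            seq[o:o + L] = saved  # undo and retry
    return None


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=0)
    return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)


def _module_factors(cfg, truth, expr, meta, rng):
    """Latent factor estimates per module, derived from planted-gene expression.

    Returns ``(F, G)``: ``F[m]`` the loading-signed mean z-score profile of
    module m's genes (carries the ecotype channel), ``G[m]`` the same profile
    centered within ecotype (ecotype channel removed). Falls back to seeded
    noise factors when no modules are planted.
    """
    eco = np.array(meta.table["ecotype"])
    n_factors = max(cfg.n_modules, 4)
    F = np.empty((n_factors, len(eco)))
    logx = np.log2(expr.to_numpy() + 1.0)
    module = truth.genes["planted_module"].to_numpy()
    loading = truth.genes["planted_loading"].to_numpy()
    for m in range(n_factors):
        sel = np.flatnonzero(module == m)
        if len(sel) == 0:
            F[m] = rng.normal(0, 1, size=len(eco))
        else:
            z = np.apply_along_axis(_zscore, 1, logx[sel])
            F[m] = _zscore((np.sign(loading[sel])[:, None] * z).mean(axis=0))
    G = F.copy()
    for lab in ("upland", "lowland"):
        sel = eco == lab
        G[:, sel] -= G[:, sel].mean(axis=1, keepdims=True)
    G = np.apply_along_axis(
        lambda v: _zscore(v) if v.std() > 0 else v, 1, G)
    return F, G


# trait -> (weights on within-ecotype factors G1..G3, applies in CK, in DT)
_NEUTRAL_RECIPE = {
    "PH": {1: 0.5},
    "FLL": {1: 0.5, 2: 0.2},
    "FLW": {1: 0.3},
    "NG": {2: 0.6},
    "100GW": {3: 0.3},
    "GY": {2: 0.5, 3: 0.3},
    "biomass": {2: 0.5},
    "HI": {3: 0.4},
    "fecundity": {2: 0.4, 3: 0.2},
}

# affine scaling into plausible units: trait -> (CK mean, DT mean, scale)
_TRAIT_SCALE = {
    "PH": (100, 85, 15), "NT": (12, 8, 3), "FLL": (30, 26, 5),
    "FLW": (1.8, 1.5, 0.3), "NG": (120, 70, 25), "100GW": (2.5, 2.2, 0.4),
    "GY": (28, 14, 6), "biomass": (60, 38, 12), "HI": (0.45, 0.33, 0.06),
    "fecundity": (0.85, 0.6, 0.1), "RWC": (0.93, 0.55, 0.12),
}


def generate_traits(cfg: SimConfig, truth: GroundTruth,
                    expr_ck: pd.DataFrame, expr_dt: pd.DataFrame,
                    meta: SampleMetadata) -> pd.DataFrame:
    """Agronomic trait table (samples x trait_condition columns).

    Traits are linear combinations of latent factors derived from planted
    module-gene expression plus Gaussian noise. The trade-off pair loads with
    opposite signs on module 0's factor (RWC-DT: ``+tradeoff_strength``,
    NT-CK/DT: ``-tradeoff_strength``); NT, FLW-DT and RWC-DT additionally get
    ecotype mean offsets (upland: fewer tillers, wider flag leaves under
    drought, higher RWC under drought). ``RGY = GY_DT / GY_CK``.
    """
    rng = _rng(cfg, "traits")
    e = np.where(np.array(meta.table["ecotype"]) == "upland", 0.5, -0.5)
    nois = lambda: rng.normal(0, cfg.trait_noise_sd, size=len(e))
    tau, off = cfg.tradeoff_strength, cfg.trait_ecotype_offset

    factors = {}
    for cond, expr in (("CK", expr_ck), ("DT", expr_dt)):
        factors[cond] = _module_factors(cfg, truth, expr, meta, rng)

    raw = {}
    for cond in ("CK", "DT"):
        F, G = factors[cond]
        for t, recipe in _NEUTRAL_RECIPE.items():
            r = nois()
            for m, w in recipe.items():
                if m < len(G):
                    r = r + w * G[m]
            raw[f"{t}_{cond}"] = r
        raw[f"NT_{cond}"] = -tau * F[0] - off * e + nois()
        raw[f"RWC_{cond}"] = nois()
    raw["FLW_DT"] = raw["FLW_DT"] + off * e
    raw["RWC_DT"] = tau * factors["DT"][0][0] + off * e + nois()

    cols = {}
    for t in TRAIT_NAMES:
        mck, mdt, sc = _TRAIT_SCALE[t]
        for cond, mean in (("CK", mck), ("DT", mdt)):
            v = mean + sc * raw[f"{t}_{cond}"]
            if t in ("HI", "fecundity", "RWC"):
                v = np.clip(v, 0.02, 0.99)
            elif t == "GY":
                v = np.clip(v, 0.5, None)
            cols[f"{t}_{cond}"] = v
    cols["RGY"] = cols["GY_DT"] / cols["GY_CK"]
    return pd.DataFrame(cols, index=meta.samples)


# ---------------------------------------------------------------------------
# one-call bundle
# ---------------------------------------------------------------------------

@dataclass
class SimDataset:
    """Everything one synthetic study produces, in memory."""

    cfg: SimConfig
    annotation: pd.DataFrame
    genotypes: GenotypeMatrix
    truth: GroundTruth
    promoters: PromoterSet
    motifs: MotifLibrary
    expr_ck: pd.DataFrame
    expr_dt: pd.DataFrame
    metadata: SampleMetadata
    traits: pd.DataFrame
    divergent_traits: list = field(default_factory=lambda: list(DIVERGENT_TRAITS))


def generate_dataset(cfg: SimConfig) -> SimDataset:
    """Run all generator stages in their canonical order."""
    truth = plant_truth(cfg)
    genotypes, truth = generate_genotypes(cfg, truth)
    promoters, motifs = generate_promoters_and_motifs(cfg, genotypes, truth)
    expr_ck, expr_dt, meta = generate_expression(cfg, truth)
    traits = generate_traits(cfg, truth, expr_ck, expr_dt, meta)
    return SimDataset(cfg, gene_annotation(cfg), genotypes, truth, promoters,
                      motifs, expr_ck, expr_dt, meta, traits)
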