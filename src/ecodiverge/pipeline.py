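"""End-to-end orchestration: simulate -> popgen -> expression -> TDSG ->
cis-elements -> network -> association, with a joined per-gene master table
and a run manifest.

The pipeline can run from files (``PipelineConfig``) or directly on an
in-memory :class:`~ecodiverge.synthetic_data.SimDataset`
(:func:`analyze_dataset`), which is what the test-suite and the acceptance
script use. Every stochastic step (permutations, bootstraps) derives its
stream from the single global seed, so identical configurations give
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import association as assoc
from . import cis_elements as cis
from . import coexpression as coex
from . import expression_stats as es
from . import io as eio
from . import popgen as pg
from . import tdsg as td
from .coexpression import NetworkConfig
from .datatypes import GenotypeMatrix, SampleMetadata
from .synthetic_data import SimConfig, SimDataset, generate_dataset

logger = logging.getLogger("ecodiverge")

__all__ = ["AnalysisParams", "PipelineConfig", "PipelineResult",
           "analyze_dataset", "run_pipeline", "write_results"]


@dataclass
class AnalysisParams:
    """Thresholds and sizes for every analysis stage (defaults = the
    standard recipe: p < .05, |log2FC| > 1, 95th percentile, 5% tail,
    FDR < .05, 1,000 permutations)."""

    seed: int = 0
    n_perm: int = 1000
    alpha: float = 0.05
    lfc: float = 1.0
    fdr: float = 0.05
    hdg_quantile: float = 0.95
    dsg_tail: float = 0.05
    uniformity_window: int = 5_000_000
    n_boot: int = 1000
    flank: int = 2000
    network: NetworkConfig = field(default_factory=NetworkConfig)
    max_haplotype_genes: int = 20
    both_strands: bool = True


@dataclass
class PipelineConfig:
    """File-based run configuration (paths + parameter blocks)."""

    out_dir: str
    vcf: str | None = None
    gff: str | None = None
    fasta: str | None = None
    motifs: str | None = None
    expression_ck: str | None = None
    expression_dt: str | None = None
    metadata: str | None = None
    traits: str | None = None
    simulate: dict | None = None  # SimConfig overrides; None = use files
    params: AnalysisParams = field(default_factory=AnalysisParams)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        params = raw.pop("params", {}) or {}
        net = params.pop("network", {}) or {}
        ap = AnalysisParams(**params, network=NetworkConfig(**net))
        cfg = cls(**raw, params=ap)
        for f in ("vcf", "gff", "fasta", "motifs", "expression_ck",
                  "expression_dt", "metadata", "traits"):
            p = getattr(cfg, f)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{f}: {p}")
        return cfg


@dataclass
class PipelineResult:
    """All stage outputs, joined on gene ID in ``master``."""

    popgen: pd.DataFrame
    expression: pd.DataFrame
    tdsg_ck: pd.DataFrame
    tdsg_dt: pd.DataFrame
    cis_snps: pd.DataFrame
    haplotype_qst: pd.DataFrame
    modules: coex.ModuleAssignment | None
    module_traits: pd.DataFrame
    trait_qst: pd.DataFrame
    enrichment: pd.DataFrame
    tradeoff: pd.Series
    master: pd.DataFrame
    neutral_fst: tuple
    extras: dict


def _subseed(seed: int, k: int) -> int:
    """Derived stream seed, kept below 2**31."""
    return (seed * 1000003 + k) % (2 ** 31 - 1)


def analyze_dataset(ds: SimDataset | dict, params: AnalysisParams | None = None
                    ) -> PipelineResult:
    """Run every analysis stage on in-memory inputs.

    ``ds`` needs attributes/keys: annotation, genotypes, promoters, motifs,
    expr_ck, expr_dt, metadata, traits.
    """
    if params is None:
        params = AnalysisParams()
    get = (lambda k: ds[k]) if isinstance(ds, dict) else (lambda k: getattr(ds, k))
    annotation: pd.DataFrame = get("annotation")
    genotypes: GenotypeMatrix = get("genotypes")
    meta: SampleMetadata = get("metadata")
    expr_ck: pd.DataFrame = get("expr_ck")
    expr_dt: pd.DataFrame = get("expr_dt")
    traits: pd.DataFrame = get("traits")
    promoters = get("promoters")
    motifs = get("motifs")

    samples = genotypes.samples
    eco = meta.ecotype_of(samples)
    typ = meta.typical(samples)
    up = np.flatnonzero((eco == "upland") & typ)
    low = np.flatnonzero((eco == "lowland") & typ)

    # ---- popgen -----------------------------------------------------------
    regions = pg.build_gene_regions(annotation, flank=params.flank)
    pop = pg.popgen_table(genotypes, regions, up, low)
    neutral = pg.neutral_fst(genotypes, up, low, n_boot=params.n_boot,
                             seed=_subseed(params.seed, 1))
    hdg_flags, hdg_thr = pg.call_hdg(pop["fst"], params.hdg_quantile)
    pop["hdg"] = hdg_flags
    for ecotype in ("upland", "lowland"):
        flags, _ = pg.pi_dxy_scan(pop, ecotype, tail=params.dsg_tail)
        pop["u_dsg" if ecotype == "upland" else "l_dsg"] = flags

    genome_length = float(annotation["end"].max() + params.flank)
    uniformity = {}
    for flag in ("hdg", "u_dsg", "l_dsg"):
        sel = pop[pop[flag]]
        if len(sel):
            mid = (sel["start"] + sel["end"]).to_numpy() / 2.0
            uniformity[flag] = pg.density_uniformity_test(
                mid, genome_length, window=params.uniformity_window)

    # neutral (intron) per-gene stats for the selection index
    intron = _intron_stats(genotypes, up, low)

    # ---- expression stats -------------------------------------------------
    typ_samples = [s for s, t in zip(samples, typ) if t]
    eco_typ = meta.ecotype_of(typ_samples)
    expr = pd.DataFrame(index=expr_ck.index)
    for cond, mat in (("ck", expr_ck), ("dt", expr_dt)):
        expr[f"ed_{cond}"] = es.ed_matrix(mat)
        expr[f"cv_{cond}"] = es.cv_matrix(mat)
        q, p = es.qst_matrix(np.log2(mat[typ_samples].to_numpy() + 1.0),
                             eco_typ, n_perm=params.n_perm,
                             seed=_subseed(params.seed, 2))
        expr[f"qst_{cond}"] = q
        expr[f"qst_p_{cond}"] = p
    drg = es.call_drg(expr_ck, expr_dt, alpha=params.alpha, lfc=params.lfc)
    expr = expr.join(drg)

    # ---- TDSG -------------------------------------------------------------
    tdsg_ck = td.tdsg_table(expr_ck, meta, intron["pi"], intron["dxy"],
                            alpha=params.alpha)
    tdsg_dt = td.tdsg_table(expr_dt, meta, intron["pi"], intron["dxy"],
                            alpha=params.alpha)

    # ---- cis elements -----------------------------------------------------
    cis_snps = cis.scan_cis_altering_snps(genotypes, promoters, motifs,
                                          regions,
                                          both_strands=params.both_strands)

    # ---- co-expression network on drought-responsive TDSGs ----------------
    net_genes = tdsg_dt.index[(tdsg_dt["tdsg"]) &
                              (expr["drg"].reindex(tdsg_dt.index,
                                                   fill_value=False))]
    modules = None
    module_traits = pd.DataFrame(columns=["module", "trait", "r", "p"])
    hub = pd.Series(False, index=expr_ck.index)
    if len(net_genes) >= params.network.min_module_size:
        net_expr = np.log2(expr_dt.loc[net_genes, typ_samples] + 1.0)
        adj = coex.adjacency(net_expr, params.network.softpower)
        t = coex.tom(adj)
        modules = coex.detect_modules(t, params.network, gene_ids=net_genes,
                                      expr=net_expr)
        modules = coex.merge_modules(net_expr, modules,
                                     params.network.merge_distance)
        trait_rows = traits.loc[typ_samples]
        module_traits = coex.module_trait_correlation(modules, trait_rows)
        hub_net = coex.hub_genes(t, modules, params.network)
        hub = hub_net.reindex(expr_ck.index, fill_value=False)
    else:
        logger.warning("only %d drought-responsive TDSGs; network skipped",
                       len(net_genes))

    # ---- association ------------------------------------------------------
    trait_qst = assoc.trait_qst_profile(
        traits.loc[typ_samples], eco_typ, neutral[0], neutral[1],
        n_perm=params.n_perm, seed=_subseed(params.seed, 3))

    cond_expr = {"CK": expr_ck, "DT": expr_dt}
    trait_sets = {}
    for tname in traits.columns:
        cond = "DT" if tname.endswith("_DT") or tname == "RGY" else "CK"
        mat = cond_expr[cond][typ_samples]
        trait_sets[tname] = assoc.trait_correlated_genes(
            mat, traits.loc[typ_samples, [tname]])[tname]

    tdsg_dt_set = set(tdsg_dt.index[tdsg_dt["tdsg"]])
    tdsg_ck_set = set(tdsg_ck.index[tdsg_ck["tdsg"]])
    ratio_r, ratio_p, ratio_tab = assoc.ratio_vs_qst_correlation(
        trait_sets, tdsg_dt_set | tdsg_ck_set,
        trait_qst.set_index("trait")["qst"])

    tradeoff = assoc.tradeoff_genes(trait_sets["RWC_DT"], trait_sets["NT_CK"],
                                    fdr=params.fdr)

    universe = set(expr_ck.index)
    drg_set = set(expr.index[expr["drg"]])
    cis_genes = set(cis_snps["gene_id"]) if len(cis_snps) else set()
    tradeoff_set = set(tradeoff.index[tradeoff])
    enr_rows = []
    for name, A, B in [
        ("drg_in_tdsg_ck", drg_set, tdsg_ck_set),
        ("drg_in_tdsg_dt", drg_set, tdsg_dt_set),
        ("tradeoff_in_tdsg", tradeoff_set, tdsg_ck_set | tdsg_dt_set),
        ("cis_in_tdsg_ck", cis_genes, tdsg_ck_set),
        ("cis_in_tdsg_dt", cis_genes, tdsg_dt_set),
    ]:
        if A and B:
            rec = assoc.fisher_enrichment(A, B, universe)
            rec["comparison"] = name
            enr_rows.append(rec)

    d_tdsg_drg = sorted(tdsg_dt_set & drg_set)
    if d_tdsg_drg:
        lx = np.log2(expr_dt[typ_samples] + 1.0)
        mean_diff = lx.loc[:, eco_typ == "upland"].mean(axis=1) - \
            lx.loc[:, eco_typ == "lowland"].mean(axis=1)
        rwc_sig = trait_sets["RWC_DT"]
        sig_genes = [g for g in d_tdsg_drg
                     if g in rwc_sig.index and bool(rwc_sig.loc[g, "correlated"])]
        if sig_genes:
            rec = assoc.rwc_direction_consistency(
                sig_genes, rwc_sig["r"], mean_diff)
            rec["comparison"] = "rwc_direction_consistency"
            enr_rows.append(rec)
    enrichment = pd.DataFrame(enr_rows)

    # ---- haplotype vs ecotype Q_ST on hub/HDG cis genes -------------------
    hap_rows = []
    hdg_set = set(pop.loc[pop["hdg"], "gene_id"])
    candidates = [g for g in sorted(cis_genes)
                  if g in hdg_set and (g in tdsg_dt_set or hub.get(g, False))]
    eco_all_typ = np.asarray(eco_typ)
    for g in candidates[:params.max_haplotype_genes]:
        site_idx = cis_snps.loc[cis_snps["gene_id"] == g,
                                "site_index"].unique()
        codes = genotypes.codes[np.asarray(site_idx, dtype=int)][
            :, [samples.index(s) for s in typ_samples]]
        hap = cis.assign_haplotypes(codes)
        vals = np.log2(expr_dt.loc[g, typ_samples].to_numpy(dtype=float) + 1.0)
        rec = cis.haplotype_vs_ecotype_qst(
            vals, hap, eco_all_typ, n_perm=params.n_perm,
            seed=_subseed(params.seed, 4))
        rec["gene_id"] = g
        hap_rows.append(rec)
    haplotype_qst = pd.DataFrame(hap_rows)

    # ---- master join ------------------------------------------------------
    master = pop.set_index("gene_id").join(expr, how="outer")
    master = master.join(tdsg_ck.add_suffix("_ck_t"), how="left")
    master = master.join(tdsg_dt.add_suffix("_dt_t"), how="left")
    master["tdsg_ck"] = master.pop("tdsg_ck_t").fillna(False).astype(bool)
    master["tdsg_dt"] = master.pop("tdsg_dt_t").fillna(False).astype(bool)
    cis_count = (cis_snps.groupby("gene_id").size() if len(cis_snps)
                 else pd.Series(dtype=int))
    master["n_cis_snps"] = cis_count.reindex(master.index).fillna(0).astype(int)
    if modules is not None:
        master["module"] = modules.labels.reindex(master.index).fillna(0).astype(int)
    else:
        master["module"] = 0
    master["hub"] = hub.reindex(master.index, fill_value=False)

    extras = {
        "hdg_threshold": hdg_thr,
        "uniformity": uniformity,
        "ratio_vs_qst": {"r": ratio_r, "p": ratio_p},
        "ratio_table": ratio_tab,
        "trait_sets": trait_sets,
        "intron_stats": intron,
        "cutoff_ck": tdsg_ck.attrs.get("cutoff_info"),
        "cutoff_dt": tdsg_dt.attrs.get("cutoff_info"),
    }
    return PipelineResult(pop, expr, tdsg_ck, tdsg_dt, cis_snps,
                          haplotype_qst, modules, module_traits, trait_qst,
                          enrichment, tradeoff, master, neutral, extras)


def _intron_stats(genotypes: GenotypeMatrix, up, low) -> pd.DataFrame:
    """Per-gene neutral pi / dxy over intron SNPs (per-SNP normalization;
    only the ratio enters the selection index, so the common denominator
    cancels). pi is the mean of the two within-ecotype diversities."""
    sites = genotypes.sites
    mask = sites["subregion"] == "intron"
    rows = {}
    for gid, idx in sites.index[mask].groupby(sites.loc[mask, "gene_id"]).items():
        idx = np.asarray(idx)
        k = float(len(idx))
        a = genotypes.codes[idx][:, up]
        b = genotypes.codes[idx][:, low]
        try:
            pi = 0.5 * (pg.nucleotide_diversity(a, k) +
                        pg.nucleotide_diversity(b, k))
        except ValueError:
            continue
        rows[gid] = (pi, pg.dxy(a, b, k))
    df = pd.DataFrame.from_dict(rows, orient="index", columns=["pi", "dxy"])
    df.index.name = "gene_id"
    return df


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-level entry point: load (or simulate) inputs, analyze, write."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulate is not None:
        sim_cfg = SimConfig(**config.simulate)
        ds = generate_dataset(sim_cfg)
        _write_dataset(ds, out / "simulated")
    else:
        ds = {
            "annotation": eio.read_annotation(config.gff),
            "genotypes": eio.read_vcf(config.vcf),
            "promoters": eio.read_promoters(config.fasta),
            "motifs": eio.read_motifs(config.motifs),
            "expr_ck": eio.read_expression(config.expression_ck),
            "expr_dt": eio.read_expression(config.expression_dt),
            "metadata": eio.read_metadata(config.metadata),
            "traits": eio.read_traits(config.traits),
        }
    try:
        result = analyze_dataset(ds, config.params)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc
    write_results(result, out, config)
    return result


def _write_dataset(ds: SimDataset, out: Path):
    out.mkdir(parents=True, exist_ok=True)
    eio.write_vcf(ds.genotypes, out / "genotypes.vcf",
                  {ds.cfg.chrom: ds.cfg.chrom_length})
    eio.write_gff3(ds.annotation, out / "genes.gff3")
    eio.write_fasta(ds.promoters, out / "promoters.fasta")
    eio.write_motifs(ds.motifs, out / "motifs.tsv")
    eio.write_expression(ds.expr_ck, out / "expression_CK.tsv")
    eio.write_expression(ds.expr_dt, out / "expression_DT.tsv")
    eio.write_metadata(ds.metadata, out / "metadata.tsv")
    eio.write_traits(ds.traits, out / "traits.tsv")
    eio.write_tsv(ds.truth.genes, out / "truth_genes.tsv")
    eio.write_tsv(ds.truth.snps, out / "truth_snps.tsv")


def write_results(result: PipelineResult, out_dir, config: PipelineConfig | None = None):
    """Write all stage TSVs, the master table and the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    eio.write_tsv(result.popgen, out / "popgen.tsv")
    eio.write_tsv(result.expression.reset_index(), out / "expression.tsv")
    eio.write_tsv(result.tdsg_ck.reset_index(), out / "tdsg_CK.tsv")
    eio.write_tsv(result.tdsg_dt.reset_index(), out / "tdsg_DT.tsv")
    eio.write_tsv(result.cis_snps, out / "cis_snps.tsv")
    if len(result.haplotype_qst):
        eio.write_tsv(result.haplotype_qst, out / "haplotype_qst.tsv")
    eio.write_tsv(result.module_traits, out / "module_trait_correlation.tsv")
    eio.write_tsv(result.trait_qst, out / "trait_qst.tsv")
    if len(result.enrichment):
        eio.write_tsv(result.enrichment, out / "enrichment.tsv")
    eio.write_tsv(result.tradeoff.rename("tradeoff").reset_index(),
                  out / "tradeoff_genes.tsv")
    eio.write_tsv(result.master.reset_index(), out / "master.tsv")

    manifest = {
        "ecodiverge_version": __version__,
        "neutral_fst": {"mean": result.neutral_fst[0],
                        "se": result.neutral_fst[1],
                        "n_snps": result.neutral_fst[2]},
        "hdg_threshold": result.extras["hdg_threshold"],
    }
    if config is not None:
        payload = {
            "out_dir": str(config.out_dir),
            "simulate": config.simulate,
            "params": _params_dict(config.params),
        }
        manifest["seed"] = config.params.seed
        manifest["config_sha256"] = hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()
        manifest["params"] = payload["params"]
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=float)


def _params_dict(params: AnalysisParams) -> dict:
    d = asdict(params)
    return d
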