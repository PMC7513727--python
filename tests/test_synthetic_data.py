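"""Generator contracts: determinism, planted counts, planted effects."""

import re

import numpy as np
import pandas as pd
import pytest

from ecodiverge import SimConfig, generate_dataset
from ecodiverge.io import write_fasta, write_vcf
from ecodiverge.synthetic_data import ConfigError, plant_truth


def _tiny(**kw):
    base = dict(seed=3, n_genes=60, n_intergenic_snps=100, n_modules=0,
                frac_tdsg=0.2, frac_drg=0.25)
    base.update(kw)
    return SimConfig(**base)


class TestConfig:
    @pytest.mark.parametrize("field,value", [
        ("frac_hdg", -0.1), ("frac_tdsg", 1.5), ("frac_sweep", 2.0),
    ])
    def test_invalid_fractions_rejected(self, field, value):
        with pytest.raises(ConfigError):
            _tiny(**{field: value})

    def test_too_few_samples_rejected(self):
        with pytest.raises(ConfigError):
            _tiny(n_upland=1)

    def test_modules_must_fit_in_planted_sets(self):
        with pytest.raises(ConfigError):
            _tiny(n_modules=4, module_size=30, frac_tdsg=0.1)


class TestDeterminism:
    def test_identical_vcf_and_fasta_bytes(self, tmp_path):
        paths = []
        for run in ("a", "b"):
            ds = generate_dataset(_tiny(seed=5))
            v = tmp_path / f"{run}.vcf"
            f = tmp_path / f"{run}.fa"
            write_vcf(ds.genotypes, v)
            write_fasta(ds.promoters, f)
            paths.append((v.read_bytes(), f.read_bytes()))
        assert paths[0][0] == paths[1][0]
        assert paths[0][1] == paths[1][1]

    def test_different_seed_changes_output(self):
        a = generate_dataset(_tiny(seed=5))
        b = generate_dataset(_tiny(seed=6))
        assert not np.array_equal(a.genotypes.codes, b.genotypes.codes)


class TestPlantedCounts:
    def test_counts_follow_round_half_up(self):
        truth = plant_truth(SimConfig(seed=0, n_genes=1000, frac_hdg=0.05))
        assert truth.genes["planted_hdg"].sum() == 50

    def test_all_fractions_exact(self):
        cfg = SimConfig(seed=2, n_genes=500, frac_hdg=0.05, frac_tdsg=0.21,
                        frac_drg=0.3, frac_sweep=0.03,
                        frac_motif_altering=0.1, n_modules=2, module_size=30)
        g = plant_truth(cfg).genes
        assert g["planted_tdsg"].sum() == 105
        assert g["planted_drg"].sum() == 150
        assert g["planted_sweep_upland"].sum() == 15
        assert g["planted_sweep_lowland"].sum() == 15
        assert g["planted_motif_gene"].sum() == 50
        assert (g["planted_module"] >= 0).sum() == 60

    def test_module_genes_are_tdsg_and_drg(self):
        cfg = SimConfig(seed=2, n_genes=500, n_modules=2, module_size=30)
        g = plant_truth(cfg).genes
        mod = g["planted_module"] >= 0
        assert g.loc[mod, "planted_tdsg"].all()
        assert g.loc[mod, "planted_drg"].all()

    def test_zero_fractions_plant_nothing(self):
        g = plant_truth(_tiny().null()).genes
        flags = g.filter(like="planted_").drop(columns=["planted_module",
                                                        "planted_loading"])
        assert not flags.to_numpy().any()


class TestGenotypes:
    def test_zero_hdg_fraction_no_planted_differential(self):
        cfg = _tiny(frac_hdg=0.0, frac_sweep=0.0)
        ds = generate_dataset(cfg)
        sites = ds.genotypes.sites
        genic = sites["gene_id"] != "."
        codes = ds.genotypes.codes[genic.to_numpy()]
        up = codes[:, :cfg.n_upland].mean(axis=1) / 2
        low = codes[:, cfg.n_upland:].mean(axis=1) / 2
        d = pd.Series(np.abs(up - low),
                      index=sites.loc[genic, "gene_id"].to_numpy())
        # a planted gene would average |d| ~ 0.8 over its non-intron SNPs;
        # neutral per-gene means stay well below (sd(d) ~ sqrt(2)*0.2)
        assert d.groupby(level=0).mean().max() < 0.55

    def test_sweep_deflates_within_ecotype_diversity(self):
        cfg = SimConfig(seed=4, n_genes=200, n_modules=0, frac_sweep=0.05,
                        frac_tdsg=0.0, frac_drg=0.0, frac_hdg=0.0)
        ds = generate_dataset(cfg)
        g = ds.truth.genes.set_index("gene_id")
        sites = ds.genotypes.sites
        het = []
        for swept in (True, False):
            sel = sites["gene_id"].isin(
                g.index[g["planted_sweep_upland"] == swept])
            codes = ds.genotypes.codes[sel.to_numpy()][:, :cfg.n_upland]
            p = codes.mean(axis=1) / 2
            het.append((2 * p * (1 - p)).mean())
        assert het[0] < het[1] / 5  # ~10x deflation planted


class TestExpression:
    def test_fpkm_strictly_positive(self, small_dataset):
        assert (small_dataset.expr_ck.to_numpy() > 0).all()
        assert (small_dataset.expr_dt.to_numpy() > 0).all()

    def test_drought_shift_recovered(self, small_dataset):
        ds = small_dataset
        g = ds.truth.genes.set_index("gene_id")
        drg = g.index[g["planted_drg"]]
        lfc = np.log2(ds.expr_dt.loc[drg].to_numpy() /
                      ds.expr_ck.loc[drg].to_numpy())
        med = np.median(np.median(lfc, axis=1))
        assert abs(med - ds.cfg.drought_log2fc) < 0.3

    def test_zero_effect_tdsg_indistinguishable(self):
        cfg = _tiny(seed=9, n_genes=200, effect_tdsg=0.0)
        ds = generate_dataset(cfg)
        g = ds.truth.genes.set_index("gene_id")
        eco = ds.metadata.ecotype_of(ds.genotypes.samples)
        x = np.log2(ds.expr_ck.to_numpy() + 1)
        diff = x[:, eco == "upland"].mean(axis=1) - \
            x[:, eco == "lowland"].mean(axis=1)
        sd = np.where(g["planted_tdsg"], cfg.sigma_tdsg, cfg.sigma_neutral)
        z = diff / (sd * np.sqrt(1 / cfg.n_upland + 1 / cfg.n_lowland))
        from scipy import stats
        _, p = stats.ttest_ind(z[g["planted_tdsg"].to_numpy()],
                               z[(~g["planted_tdsg"]).to_numpy()])
        assert p > 0.01


class TestPromotersAndMotifs:
    def test_planted_events_toggle_motif(self, small_dataset):
        """Alt allele must create (gain) / destroy (loss) an occurrence
        overlapping the SNP — verified with an independent regex oracle."""
        ds = small_dataset
        assert len(ds.truth.snps) > 0
        for row in ds.truth.snps.itertuples(index=False):
            site = ds.genotypes.sites.iloc[row.site_index]
            seq = ds.promoters.sequences[row.gene_id]
            rel = site["pos"] - ds.promoters.starts[row.gene_id]
            pat = ds.motifs.motifs[row.motif]
            ref_hit = _regex_overlap(seq, pat, rel)
            alt_seq = seq[:rel] + site["alt"] + seq[rel + 1:]
            alt_hit = _regex_overlap(alt_seq, pat, rel)
            if row.planted_motif_gain:
                assert alt_hit and not ref_hit
            else:
                assert ref_hit and not alt_hit

    def test_reference_base_matches_vcf_ref(self, small_dataset):
        ds = small_dataset
        sites = ds.genotypes.sites
        ups = sites[sites["subregion"] == "upstream"].head(50)
        for _, s in ups.iterrows():
            seq = ds.promoters.sequences[s["gene_id"]]
            rel = s["pos"] - ds.promoters.starts[s["gene_id"]]
            assert seq[rel] == s["ref"]

    def test_motif_longer_than_window_rejected(self):
        from ecodiverge.synthetic_data import make_motif_library
        with pytest.raises(ConfigError):
            make_motif_library(_tiny(flank=6),
                               rng=np.random.default_rng(0))


_IUPAC_RE = {
    "A": "A", "C": "C", "G": "G", "T": "T", "R": "[AG]", "Y": "[CT]",
    "S": "[CG]", "W": "[AT]", "K": "[GT]", "M": "[AC]", "B": "[CGT]",
    "D": "[AGT]", "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


def _regex_overlap(seq, pattern, pos):
    """Independent check: does any occurrence of the motif overlap pos?"""
    rx = re.compile("(?=(" + "".join(_IUPAC_RE[c] for c in pattern) + "))")
    L = len(pattern)
    return any(m.start() <= pos < m.start() + L for m in rx.finditer(seq))


class TestTraits:
    def test_row_count_equals_samples(self, small_dataset):
        ds = small_dataset
        assert len(ds.traits) == ds.cfg.n_upland + ds.cfg.n_lowland

    def test_tradeoff_genes_oppositely_correlated(self, small_dataset):
        ds = small_dataset
        g = ds.truth.genes.set_index("gene_id")
        genes = g.index[g["planted_tradeoff"]]
        rwc = ds.traits["RWC_DT"].to_numpy()
        nt = ds.traits["NT_CK"].to_numpy()
        opp = 0
        for gid in genes:
            r1 = np.corrcoef(np.log2(ds.expr_dt.loc[gid] + 1), rwc)[0, 1]
            r2 = np.corrcoef(np.log2(ds.expr_ck.loc[gid] + 1), nt)[0, 1]
            opp += np.sign(r1) == -np.sign(r2)
        assert opp / len(genes) >= 0.9

    def test_null_tradeoff_shows_no_pattern(self):
        cfg = SimConfig(seed=13, n_genes=200, n_modules=2, module_size=30,
                        frac_tdsg=0.35, frac_drg=0.4,
                        tradeoff_strength=0.0, effect_tdsg=0.0,
                        trait_ecotype_offset=0.0)
        ds = generate_dataset(cfg)
        g = ds.truth.genes.set_index("gene_id")
        genes = g.index[g["planted_tradeoff"]]
        rwc = ds.traits["RWC_DT"].to_numpy()
        nt = ds.traits["NT_CK"].to_numpy()
        n = len(ds.traits)
        strong_opp = 0
        for gid in genes:
            r1 = np.corrcoef(np.log2(ds.expr_dt.loc[gid] + 1), rwc)[0, 1]
            r2 = np.corrcoef(np.log2(ds.expr_ck.loc[gid] + 1), nt)[0, 1]
            crit = 2.0 / np.sqrt(n)
            if abs(r1) > crit and abs(r2) > crit and \
                    np.sign(r1) == -np.sign(r2):
                strong_opp += 1
        assert strong_opp / len(genes) < 0.2

    def test_rgy_is_gy_ratio(self, small_dataset):
        t = small_dataset.traits
        assert np.allclose(t["RGY"], t["GY_DT"] / t["GY_CK"])
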