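"""Sequence statistics against brute-force oracles and closed forms."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ecodiverge import popgen as pg


# ---------------------------------------------------------------------------
# brute-force oracles (allele-pair enumeration, independent of the estimators)
# ---------------------------------------------------------------------------

def _alleles(codes):
    """Expand diploid dosages into allele lists per site (missing dropped)."""
    out = []
    for row in np.atleast_2d(codes):
        site = []
        for c in row:
            if c >= 0:
                site.extend([1] * int(c) + [0] * (2 - int(c)))
        out.append(site)
    return out


def pi_bruteforce(codes, length):
    """Mean pairwise allele difference per site, summed over sites / length."""
    total = 0.0
    for site in _alleles(codes):
        n = len(site)
        if n < 2:
            continue
        diffs = sum(a != b for a, b in itertools.combinations(site, 2))
        total += diffs / (n * (n - 1) / 2)
    return total / length


def dxy_bruteforce(a, b, length):
    total = 0.0
    for sa, sb in zip(_alleles(a), _alleles(b)):
        if not sa or not sb:
            continue
        diffs = sum(x != y for x in sa for y in sb)
        total += diffs / (len(sa) * len(sb))
    return total / length


def fst_bruteforce(a, b):
    """Hudson ratio-of-sums from raw pairwise differences."""
    num = den = 0.0
    for sa, sb in zip(_alleles(a), _alleles(b)):
        if len(sa) < 2 or len(sb) < 2:
            continue
        hw1 = sum(x != y for x, y in itertools.combinations(sa, 2)) / \
            (len(sa) * (len(sa) - 1) / 2)
        hw2 = sum(x != y for x, y in itertools.combinations(sb, 2)) / \
            (len(sb) * (len(sb) - 1) / 2)
        hb = sum(x != y for x in sa for y in sb) / (len(sa) * len(sb))
        num += (hw1 + hw2) / 2
        den += hb
    if den <= 0:
        return float("nan")
    return min(max(1 - num / den, 0.0), 1.0)


# ---------------------------------------------------------------------------
# nucleotide diversity
# ---------------------------------------------------------------------------

class TestPi:
    def test_monomorphic_is_zero(self):
        codes = np.zeros((5, 4), dtype=np.int8)
        assert pg.nucleotide_diversity(codes, 100.0) == 0.0

    def test_two_haploids_match_mean_pairwise_difference(self):
        # two haploid samples (one hom-ref, one hom-alt at 1 of 100 sites):
        # represented as one diploid pseudo-sample per haplotype is not
        # possible with dosage coding, so use two homozygous diploids, which
        # carry the same allele frequencies (p = 1/2, n = 4 alleles)
        codes = np.array([[0, 2]], dtype=np.int8)
        got = pg.nucleotide_diversity(codes, 100.0)
        assert got == pytest.approx(pi_bruteforce(codes, 100.0))

    def test_matches_bruteforce_on_random_instances(self, rng):
        for _ in range(100):
            m = rng.integers(1, 6)
            k = rng.integers(2, 5)
            codes = rng.integers(-1, 3, size=(m, k)).astype(np.int8)
            sites_ok = [(row >= 0).sum() >= 1 for row in codes]
            if not all(sites_ok):
                continue
            L = float(rng.integers(5, 50))
            try:
                got = pg.nucleotide_diversity(codes, L)
            except ValueError:
                continue
            assert got == pytest.approx(pi_bruteforce(codes, L), abs=1e-12)

    def test_sample_order_invariance(self, rng):
        codes = rng.integers(0, 3, size=(4, 6)).astype(np.int8)
        perm = rng.permutation(6)
        assert pg.nucleotide_diversity(codes, 10.0) == pytest.approx(
            pg.nucleotide_diversity(codes[:, perm], 10.0))

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError):
            pg.nucleotide_diversity(np.full((3, 2), -1, dtype=np.int8), 10.0)


class TestDxy:
    def test_fixed_difference_closed_form(self):
        a = np.full((1, 3), 0, dtype=np.int8)
        b = np.full((1, 3), 2, dtype=np.int8)
        assert pg.dxy(a, b, 10.0) == pytest.approx(0.1)

    def test_identical_groups_match_bruteforce(self, rng):
        codes = rng.integers(0, 3, size=(5, 4)).astype(np.int8)
        assert pg.dxy(codes, codes, 20.0) == pytest.approx(
            dxy_bruteforce(codes, codes, 20.0))

    def test_group_order_symmetry(self, rng):
        a = rng.integers(0, 3, size=(4, 3)).astype(np.int8)
        b = rng.integers(0, 3, size=(4, 5)).astype(np.int8)
        assert pg.dxy(a, b, 7.0) == pytest.approx(pg.dxy(b, a, 7.0))


class TestFst:
    def test_alternate_fixation_is_one(self):
        a = np.full((2, 3), 0, dtype=np.int8)
        b = np.full((2, 3), 2, dtype=np.int8)
        assert pg.fst_per_gene(a, b) == pytest.approx(1.0)

    def test_equal_frequencies_clamped_to_zero(self):
        a = np.array([[0, 2, 1]], dtype=np.int8)
        b = np.array([[1, 0, 2]], dtype=np.int8)
        assert pg.fst_per_gene(a, b) == 0.0

    def test_three_snp_toy_matches_bruteforce(self):
        a = np.array([[0, 1, 2], [2, 2, 1], [0, 0, 1]], dtype=np.int8)
        b = np.array([[2, 2, 2], [0, 1, 0], [1, 1, 0]], dtype=np.int8)
        assert pg.fst_per_gene(a, b) == pytest.approx(fst_bruteforce(a, b))

    def test_exhaustive_single_snp_small_samples(self):
        """Every 1-SNP instance with 2 diploids per group."""
        for ga in itertools.product(range(3), repeat=2):
            for gb in itertools.product(range(3), repeat=2):
                a = np.array([ga], dtype=np.int8)
                b = np.array([gb], dtype=np.int8)
                want = fst_bruteforce(a, b)
                got = pg.fst_per_gene(a, b)
                if np.isnan(want):
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(want, abs=1e-12)

    def test_monomorphic_region_is_missing(self):
        a = np.zeros((2, 3), dtype=np.int8)
        assert np.isnan(pg.fst_per_gene(a, a))


class TestNeutralFst:
    def _gm(self, codes, gene_ids):
        sites = pd.DataFrame({
            "chrom": "c1", "pos": np.arange(len(codes)),
            "ref": "A", "alt": "T", "gene_id": gene_ids,
            "subregion": ["intergenic" if g == "." else "exon"
                          for g in gene_ids]})
        from ecodiverge.datatypes import GenotypeMatrix
        return GenotypeMatrix(np.asarray(codes, dtype=np.int8), sites,
                              [f"s{i}" for i in range(np.shape(codes)[1])])

    def test_equal_frequencies_mean_zero(self):
        codes = np.tile([0, 1, 2, 0, 1, 2], (10, 1))
        gm = self._gm(codes, ["."] * 10)
        mean, se, n = pg.neutral_fst(gm, [0, 1, 2], [3, 4, 5], seed=0)
        assert mean <= 0.0 + 1e-12
        assert n == 10

    def test_bootstrap_se_close_to_analytic(self, rng):
        m = 10_000
        codes = rng.integers(0, 3, size=(m, 20)).astype(np.int8)
        gm = self._gm(codes, ["."] * m)
        mean, se, n = pg.neutral_fst(gm, list(range(10)), list(range(10, 20)),
                                     seed=1)
        # recompute per-SNP values analytically for the SE of the mean
        hw, hb = pg._site_components(codes[:, :10], codes[:, 10:])
        ok = hb > 0
        per = 1 - hw[ok] / hb[ok]
        analytic = per.std(ddof=1) / np.sqrt(per.size)
        assert se == pytest.approx(analytic, rel=0.10)

    def test_single_snp_se_zero(self):
        codes = np.array([[0, 1, 2, 2, 1, 0]])
        gm = self._gm(codes, ["."])
        _, se, n = pg.neutral_fst(gm, [0, 1, 2], [3, 4, 5], seed=0)
        assert n == 1
        assert se == pytest.approx(0.0, abs=1e-12)


class TestHdgCall:
    def test_at_most_five_percent_flagged(self, rng):
        fst = pd.Series(rng.random(1000))
        flags, thr = pg.call_hdg(fst)
        assert flags.sum() <= 50

    def test_identical_values_flag_none(self):
        flags, _ = pg.call_hdg(pd.Series([0.3] * 100))
        assert flags.sum() == 0


class TestPiDxyScan:
    def _table(self, ratios):
        return pd.DataFrame({
            "gene_id": [f"g{i:03d}" for i in range(len(ratios))],
            "ratio_upland": ratios,
            "ratio_lowland": ratios,
        })

    def test_zero_ratio_always_in_tail(self):
        ratios = [0.0] + [1.0 + i * 0.01 for i in range(99)]
        flags, k = pg.pi_dxy_scan(self._table(ratios), "upland")
        assert k == 5 and flags[0]

    def test_flag_count_is_floor_rule(self, rng):
        for n in (20, 99, 100, 101):
            ratios = rng.random(n)
            flags, k = pg.pi_dxy_scan(self._table(ratios), "upland")
            assert k == int(np.floor(0.05 * n)) == flags.sum()

    def test_ties_broken_by_gene_id(self):
        ratios = [0.5] * 100
        flags, k = pg.pi_dxy_scan(self._table(ratios), "upland")
        assert list(np.flatnonzero(flags)) == list(range(5))

    def test_dxy_zero_excluded(self):
        t = self._table([np.nan] * 50 + [0.1] * 50)
        flags, k = pg.pi_dxy_scan(t, "upland")
        assert k == 2  # floor(0.05 * 50)
        assert not flags[:50].any()


class TestUniformity:
    def test_evenly_spaced_high_p(self):
        pos = (np.arange(100) + 0.5) * 1000
        d, p = pg.density_uniformity_test(pos, 100_000)
        assert d <= 1 / (2 * 100) + 1e-12
        assert p > 0.99

    def test_concentrated_flags_low_p(self):
        pos = np.linspace(0, 1_000, 50)  # all in first window of 100 Mb
        _, p = pg.density_uniformity_test(pos, 100_000_000)
        assert p < 1e-3

    def test_empty_set_is_error(self):
        with pytest.raises(ValueError):
            pg.density_uniformity_test([], 1000)


class TestRegions:
    def test_duplicate_gene_ids_rejected(self):
        ann = pd.DataFrame({"gene_id": ["a", "a"], "chrom": "c1",
                            "start": [10, 100], "end": [20, 200],
                            "strand": "+"})
        with pytest.raises(ValueError):
            pg.build_gene_regions(ann)

    def test_window_clipped_at_chromosome_start(self):
        ann = pd.DataFrame({"gene_id": ["a"], "chrom": ["c1"],
                            "start": [500], "end": [1000], "strand": ["+"]})
        (r,) = pg.build_gene_regions(ann, flank=2000)
        assert r.start == 0 and r.end == 3000

    def test_region_length_arithmetic(self):
        ann = pd.DataFrame({"gene_id": ["a"], "chrom": ["c1"],
                            "start": [5000], "end": [8000], "strand": ["-"]})
        (r,) = pg.build_gene_regions(ann, flank=2000)
        assert r.length == 3000 + 4000
        assert r.tss == 8000  # minus strand: TSS at the right end
        assert r.upstream == (8000, 10000)
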