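"""Shared in-memory containers for the divergence-scan pipeline.

Conventions used throughout the package:

* genomic coordinates are 0-based, half-open internally; VCF/GFF3 readers and
  writers convert from/to the 1-based inclusive conventions of those formats;
* diploid genotypes are coded ``0/1/2`` (alternate-allele dosage), ``-1`` for
  missing;
* expression matrices are genes x samples DataFrames of FPKM values;
* missing values in TSV output are written as ``.``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: columns of the per-site table carried by :class:`GenotypeMatrix`
SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "gene_id", "subregion"]

#: sub-gene compartments a SNP can fall in (``intergenic`` = outside all genes)
SUBREGIONS = ("upstream", "exon", "intron", "downstream", "intergenic")


@dataclass
class GenotypeMatrix:
    """Biallelic SNP genotypes (sites x samples) plus per-site annotation.

    Attributes
    ----------
    codes
        ``int8`` array of shape ``(n_sites, n_samples)`` holding alternate
        allele dosages 0/1/2, with -1 for missing calls.
    sites
        DataFrame with one row per site and columns :data:`SITE_COLUMNS`.
        ``pos`` is 0-based. ``gene_id`` is ``.`` for intergenic sites.
    samples
        Sample names, in column order of ``codes``.
    """

    codes: np.ndarray
    sites: pd.DataFrame
    samples: list[str]

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2:
            raise ValueError("codes must be 2-D (sites x samples)")
        if self.codes.shape[0] != len(self.sites):
            raise ValueError("codes and sites row counts differ")
        if self.codes.shape[1] != len(self.samples):
            raise ValueError("codes column count != number of samples")

    @property
    def n_sites(self) -> int:
        return self.codes.shape[0]

    @property
    def n_samples(self) -> int:
        return self.codes.shape[1]

    def sample_index(self, names) -> np.ndarray:
        idx = {s: i for i, s in enumerate(self.samples)}
        return np.array([idx[n] for n in names], dtype=int)

    def subset_sites(self, mask_or_index) -> "GenotypeMatrix":
        sites = self.sites.loc[mask_or_index] if isinstance(
            mask_or_index, (pd.Series,)
        ) else self.sites.iloc[np.asarray(mask_or_index)]
        codes = self.codes[np.asarray(sites.index)]
        return GenotypeMatrix(codes, sites.reset_index(drop=True), list(self.samples))


@dataclass
class SampleMetadata:
    """Per-sample ecotype / origin / typical-flag table.

    ``table`` has columns ``sample``, ``ecotype`` (``upland`` / ``lowland``),
    ``origin`` (label nested within ecotype) and ``typical`` (bool). All
    grouped statistics in the package are driven by this table.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample", "ecotype", "origin", "typical"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"metadata missing columns: {sorted(missing)}")
        bad = set(self.table["ecotype"]) - {"upland", "lowland"}
        if bad:
            raise ValueError(f"unknown ecotype labels: {sorted(bad)}")

    @property
    def samples(self) -> list[str]:
        return list(self.table["sample"])

    def ecotype_of(self, samples) -> np.ndarray:
        m = dict(zip(self.table["sample"], self.table["ecotype"]))
        return np.array([m[s] for s in samples])

    def origin_of(self, samples) -> np.ndarray:
        m = dict(zip(self.table["sample"], self.table["origin"]))
        return np.array([m[s] for s in samples])

    def typical(self, samples) -> np.ndarray:
        m = dict(zip(self.table["sample"], self.table["typical"]))
        return np.array([bool(m[s]) for s in samples])


@dataclass
class PromoterSet:
    """Upstream regulatory sequences, one per gene.

    Sequences are stored in forward genomic orientation together with their
    genomic start so that VCF (forward-strand) alleles can be substituted
    directly; strand-aware positions relative to the TSS are derived when
    needed.
    """

    sequences: dict  # gene_id -> str (forward strand, length = window)
    starts: dict  # gene_id -> genomic start (0-based) of the stored window
    strands: dict  # gene_id -> '+' or '-'

    def __len__(self) -> int:
        return len(self.sequences)


@dataclass
class MotifLibrary:
    """Named IUPAC motifs (PLACE-style cis-element patterns)."""

    motifs: dict  # name -> IUPAC string

    _VALID = set("ACGTRYSWKMBDHVN")

    def __post_init__(self) -> None:
        for name, pat in self.motifs.items():
            if not pat:
                raise ValueError(f"motif {name!r} is empty")
            bad = set(pat.upper()) - self._VALID
            if bad:
                raise ValueError(f"motif {name!r} has invalid codes {sorted(bad)}")
        self.motifs = {k: v.upper() for k, v in self.motifs.items()}

    def __len__(self) -> int:
        return len(self.motifs)

    def items(self):
        return self.motifs.items()


@dataclass
class GroundTruth:
    """Planted truth emitted by the synthetic-data generator.

    ``genes`` has one row per gene: ``gene_id``, boolean flags
    ``planted_hdg``, ``planted_tdsg``, ``planted_drg``,
    ``planted_sweep_upland``, ``planted_sweep_lowland``, ``planted_motif_gene``,
    ``planted_tradeoff``, and ``planted_module`` (module index, -1 = none).

    ``snps`` has one row per planted cis-element-altering SNP: ``site_index``
    (row in the genotype matrix), ``gene_id``, ``planted_motif_gain``,
    ``planted_motif_loss``, ``motif``.
    """

    genes: pd.DataFrame
    snps: pd.DataFrame = field(default_factory=pd.DataFrame)
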