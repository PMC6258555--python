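"""In-memory containers for genotype and haplotype data.

Coordinates are 0-based half-open internally; VCF export/import shifts to
1-based.  Genotypes are diploid derived/alternate allele dosages coded
0/1/2 with -1 for missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypeTable", "LocusHaplotypes", "HaplotypeSet"]

SAMPLE_COLUMNS = ["id", "population", "ecotype", "habitat"]
SITE_COLUMNS = ["locus", "pos", "ref", "alt"]


@dataclass
class GenotypeTable:
    """Biallelic SNP genotypes (individuals x sites) with metadata.

    genotypes : int8 array, shape (n_individuals, n_sites), values in
        {0, 1, 2, -1}; counts of the alternate allele, -1 = missing.
    samples : DataFrame with columns id, population, ecotype (e.g. "S"/"L"),
        habitat (-1 tidal, +1 seasonal).
    sites : DataFrame with columns locus, pos (0-based), ref, alt, indexed
        like the genotype columns; an optional "id" column names each SNP.
    """

    genotypes: np.ndarray
    samples: pd.DataFrame
    sites: pd.DataFrame

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (individuals x sites)")
        if len(self.samples) != self.genotypes.shape[0]:
            raise ValueError("sample metadata does not match genotype rows")
        if len(self.sites) != self.genotypes.shape[1]:
            raise ValueError("site metadata does not match genotype columns")
        bad = ~np.isin(self.genotypes, (-1, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype codes must be in {0, 1, 2, -1}")
        if "habitat" in self.samples.columns:
            hab = self.samples["habitat"].dropna()
            if not hab.isin([-1, 1]).all():
                raise ValueError("habitat code must be -1 (tidal) or +1 "
                                 "(seasonal)")
        if "id" not in self.sites.columns:
            self.sites = self.sites.copy()
            self.sites["id"] = [
                f"{l}:{p}" for l, p in
                zip(self.sites["locus"], self.sites["pos"])
            ]

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    def subset_sites(self, index) -> "GenotypeTable":
        index = np.asarray(index)
        return GenotypeTable(self.genotypes[:, index],
                             self.samples.reset_index(drop=True),
                             self.sites.iloc[index].reset_index(drop=True))

    def subset_individuals(self, index) -> "GenotypeTable":
        index = np.asarray(index)
        return GenotypeTable(self.genotypes[index],
                             self.samples.iloc[index].reset_index(drop=True),
                             self.sites.reset_index(drop=True))

    def allele_counts(self, individuals=None):
        """Per-site (derived_count, called_haploid_size) over a row subset."""
        g = self.genotypes if individuals is None \
            else self.genotypes[np.asarray(individuals)]
        called = g >= 0
        derived = np.where(called, g, 0).sum(axis=0)
        return derived.astype(np.int64), 2 * called.sum(axis=0)


@dataclass
class LocusHaplotypes:
    """Phased 0/1 haplotypes at one locus.

    haplotypes : uint8 array (n_copies x n_segregating_sites); 0 is the
        ancestral allele when an outgroup is attached.
    deme : int array, deme label (0/1) per haploid copy.
    positions : int array of 0-based site positions within the locus.
    outgroup : optional uint8 array of the outgroup haplotype.
    t_mrca : scaled time of the ingroup MRCA (set by the simulator; used
        to extend the genealogy toward an outgroup).
    """

    locus: str
    haplotypes: np.ndarray
    deme: np.ndarray
    positions: np.ndarray
    length: int
    locus_class: str = "neutral"
    outgroup: np.ndarray | None = None
    t_mrca: float | None = None

    def __post_init__(self):
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        self.deme = np.asarray(self.deme)
        self.positions = np.asarray(self.positions)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be 2-D")
        if self.haplotypes.shape[1] != len(self.positions):
            raise ValueError("positions do not match haplotype columns")
        if self.haplotypes.shape[0] != len(self.deme):
            raise ValueError("deme labels do not match haplotype rows")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("alleles must be 0/1")
        if self.outgroup is not None:
            self.outgroup = np.asarray(self.outgroup, dtype=np.uint8)
            if self.outgroup.shape != (self.haplotypes.shape[1],):
                raise ValueError("outgroup length mismatch")
        self._check_segregating()

    def _check_segregating(self):
        if self.haplotypes.shape[1] == 0:
            return
        rows = self.haplotypes if self.outgroup is None else np.vstack(
            [self.haplotypes, self.outgroup[None, :]])
        if ((rows.min(axis=0) == rows.max(axis=0)).any()):
            raise ValueError("monomorphic column among ingroup+outgroup")


@dataclass
class HaplotypeSet:
    """A collection of per-locus haplotype alignments."""

    loci: list[LocusHaplotypes] = field(default_factory=list)

    def __iter__(self):
        return iter(self.loci)

    def __len__(self):
        return len(self.loci)

    def __getitem__(self, i):
        return self.loci[i]

    def truth_labels(self) -> pd.DataFrame:
        return pd.DataFrame({
            "locus": [l.locus for l in self.loci],
            "locus_class": [l.locus_class for l in self.loci],
        })
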