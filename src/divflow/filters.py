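"""SNP retention filters for RAD-like genotype tables.

Filters are applied in a fixed order -- presence, minor-allele frequency,
neutral-set exclusion, one SNP per locus -- so that the MAF is always
computed on the called alleles of sites that passed the presence cut.
Read-depth and genotype-quality filtering is assumed to have happened
upstream at variant calling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import GenotypeTable

__all__ = ["FilterSpec", "FilterReport", "apply_filters"]


@dataclass
class FilterSpec:
    """Thresholds for :func:`apply_filters`.

    min_maf : strict minor-allele-frequency cut (keep MAF > min_maf),
        computed over called alleles only.
    min_presence : minimum fraction of individuals with a called genotype.
    one_snp_per_locus : keep one uniformly random retained SNP per locus.
    neutral_exclusion_support : drop every SNP on a locus that contains a
        SNP with support above this threshold (requires a support table);
        None disables the filter.
    seed : RNG seed for the random per-locus SNP pick.
    """

    min_maf: float = 0.01
    min_presence: float = 0.80
    one_snp_per_locus: bool = False
    neutral_exclusion_support: float | None = None
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.min_maf <= 1 or not 0 <= self.min_presence <= 1:
            raise ValueError("thresholds must lie in [0, 1]")


@dataclass
class FilterReport:
    n_input: int
    removed_presence: int
    removed_maf: int
    removed_neutral_exclusion: int
    removed_one_per_locus: int
    n_output: int

    def reconciles(self) -> bool:
        removed = (self.removed_presence + self.removed_maf
                   + self.removed_neutral_exclusion
                   + self.removed_one_per_locus)
        return self.n_input - removed == self.n_output


def apply_filters(genotypes: GenotypeTable, spec: FilterSpec,
                  support: pd.DataFrame | None = None
                  ) -> tuple[GenotypeTable, FilterReport]:
    """Apply the retention filters; returns the table and a count report.

    ``support`` is a per-SNP table with columns ``snp_id`` and ``support``
    used by the neutral-set exclusion.
    """
    n_in = genotypes.n_sites
    called = genotypes.genotypes >= 0
    presence = called.mean(axis=0)
    keep = presence >= spec.min_presence
    removed_presence = int(n_in - keep.sum())

    derived, size = genotypes.allele_counts()
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(size > 0, derived / np.maximum(size, 1), 0.0)
    maf = np.minimum(freq, 1 - freq)
    fail_maf = keep & ~(maf > spec.min_maf)
    removed_maf = int(fail_maf.sum())
    keep &= ~fail_maf

    removed_neutral = 0
    if spec.neutral_exclusion_support is not None:
        if support is None:
            raise ValueError("neutral-set exclusion requires a support "
                             "table")
        strong = support.loc[
            support["support"] > spec.neutral_exclusion_support, "snp_id"]
        site_ids = genotypes.sites["id"]
        hit_sites = site_ids.isin(set(strong)).values
        bad_loci = set(genotypes.sites.loc[hit_sites, "locus"])
        fail_neutral = keep & genotypes.sites["locus"].isin(bad_loci).values
        removed_neutral = int(fail_neutral.sum())
        keep &= ~fail_neutral

    removed_thin = 0
    if spec.one_snp_per_locus:
        rng = np.random.default_rng(spec.seed)
        kept_idx = np.flatnonzero(keep)
        loci = genotypes.sites["locus"].values[kept_idx]
        chosen = []
        for locus in pd.unique(loci):
            members = kept_idx[loci == locus]
            chosen.append(rng.choice(members))
        thin = np.zeros_like(keep)
        thin[np.array(chosen, int)] = True
        removed_thin = int(keep.sum() - thin.sum())
        keep = thin

    out = genotypes.subset_sites(np.flatnonzero(keep))
    report = FilterReport(n_in, removed_presence, removed_maf,
                          removed_neutral, removed_thin, out.n_sites)
    if out.n_sites == 0:
        raise ValueError("no SNPs survive the filters")
    return out, report
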