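"""Standing genetic variation at ecotype-associated outlier loci.

Given a set of outlier SNPs (one per locus after top-SNP selection) whose
alleles have been assigned to one ecotype or the other, these routines ask
how much of the alternative ecotype's allelic repertoire is already
carried by individuals of a focal ecotype: per-individual carriage
proportions, resampling accumulation curves over growing samples of N
individuals, and the closed-form hypergeometric expectation of that curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import comb

from .datatypes import GenotypeTable

__all__ = ["select_top_snp_per_locus", "classify_alleles",
           "per_individual_carriage", "accumulation_curve",
           "exact_accumulation_expectation", "AccumulationCurve"]

OUTLIER_COLUMNS = ["snp_id", "locus", "support"]


def select_top_snp_per_locus(outliers: pd.DataFrame) -> pd.DataFrame:
    """Keep the single most strongly supported SNP per locus.

    Ties are broken deterministically by lowest position (when a ``pos``
    column exists) and then lexicographically by SNP id.
    """
    if not {"snp_id", "locus", "support"} <= set(outliers.columns):
        raise ValueError("outlier table needs columns snp_id, locus, "
                         "support")
    tab = outliers.copy()
    tab["_pos"] = tab["pos"] if "pos" in tab.columns else 0
    tab = tab.sort_values(["locus", "support", "_pos", "snp_id"],
                          ascending=[True, False, True, True],
                          kind="stable")
    out = tab.groupby("locus", sort=True).head(1).drop(columns="_pos")
    return out.reset_index(drop=True)


def classify_alleles(genotypes: GenotypeTable, outliers: pd.DataFrame,
                     ecotype_a: str = "S", ecotype_b: str = "L"
                     ) -> pd.DataFrame:
    """Assign each outlier SNP's alleles to an ecotype.

    The allele (REF=0 / ALT=1) with the higher pooled frequency across all
    individuals of ``ecotype_a`` is recorded as a-associated (column
    ``allele_a``); the other allele is b-associated.  SNPs with exactly
    equal pooled frequencies are flagged unassignable and excluded
    downstream.
    """
    eco = genotypes.samples["ecotype"]
    rows_a = np.flatnonzero((eco == ecotype_a).values)
    rows_b = np.flatnonzero((eco == ecotype_b).values)
    if len(rows_a) == 0 or len(rows_b) == 0:
        raise ValueError("both ecotypes must be present")
    site_index = pd.Index(genotypes.sites["id"])
    out = outliers.copy()
    alleles, flags = [], []
    d_a, c_a = genotypes.allele_counts(rows_a)
    for snp in out["snp_id"]:
        s = site_index.get_loc(snp)
        if c_a[s] == 0:
            alleles.append(-1)
            flags.append(False)
            continue
        f_alt = d_a[s] / c_a[s]
        if f_alt == 0.5:
            alleles.append(-1)
            flags.append(False)
        else:
            alleles.append(1 if f_alt > 0.5 else 0)
            flags.append(True)
    out["allele_a"] = alleles
    out["assignable"] = flags
    return out


def _carrier_matrix(genotypes: GenotypeTable, outliers: pd.DataFrame,
                    focal_ecotype: str, ecotype_a: str = "S",
                    alt_allele_col: str = "allele_a"):
    """(individuals x loci) carrier indicator for the alternative allele.

    Rows are individuals of the focal ecotype; entry is 1 when the
    genotype carries >= 1 copy of the allele associated with the *other*
    ecotype, 0 when it does not and -1 when the genotype is missing.
    """
    keep = outliers[outliers["assignable"]] if "assignable" in \
        outliers.columns else outliers
    if len(keep) == 0:
        raise ValueError("no assignable outlier SNPs")
    site_index = pd.Index(genotypes.sites["id"])
    cols = np.array([site_index.get_loc(s) for s in keep["snp_id"]])
    rows = np.flatnonzero(
        (genotypes.samples["ecotype"] == focal_ecotype).values)
    if len(rows) == 0:
        raise ValueError(f"no individuals of ecotype {focal_ecotype!r}")
    g = genotypes.genotypes[np.ix_(rows, cols)]
    allele_a = keep[alt_allele_col].to_numpy()
    # the focal ecotype's "alternative" allele is the one associated with
    # the other ecotype: allele_a when focal != ecotype A else 1-allele_a
    alt = (1 - allele_a) if focal_ecotype == ecotype_a else allele_a
    dosage_alt = np.where(alt[None, :] == 1, g, 2 - g)
    carrier = np.where(g < 0, -1, (dosage_alt >= 1).astype(int))
    ids = genotypes.samples["id"].iloc[rows].to_numpy()
    return carrier, ids, keep["snp_id"].to_numpy()


def per_individual_carriage(genotypes: GenotypeTable,
                            outliers: pd.DataFrame,
                            focal_ecotype: str,
                            ecotype_a: str = "S") -> pd.DataFrame:
    """Fraction of outlier loci at which each focal individual carries
    >= 1 copy of the alternative-ecotype allele.

    Missing genotypes are excluded from that individual's denominator.
    """
    carrier, ids, _ = _carrier_matrix(genotypes, outliers, focal_ecotype,
                                      ecotype_a)
    called = carrier >= 0
    denom = called.sum(axis=1)
    with np.errstate(invalid="ignore"):
        prop = np.where(denom > 0,
                        (carrier == 1).sum(axis=1) / np.maximum(denom, 1),
                        np.nan)
    return pd.DataFrame({"id": ids, "n_loci_called": denom,
                         "carriage": prop})


@dataclass
class AccumulationCurve:
    """Resampling accumulation curve of alternative-allele coverage."""

    focal_ecotype: str
    N: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    reps: int
    seed: int
    replicates: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"N": self.N, "mean": self.mean, "sd": self.sd,
                             "reps": self.reps, "seed": self.seed})


def accumulation_curve(genotypes: GenotypeTable, outliers: pd.DataFrame,
                       focal_ecotype: str, n_grid, reps: int = 100,
                       seed: int = 0, ecotype_a: str = "S",
                       keep_replicates: bool = False) -> AccumulationCurve:
    """Monte-Carlo accumulation curve.

    For each N in ``n_grid``, draw ``reps`` random subsets of N focal
    individuals without replacement; each replicate scores the proportion
    of outlier loci at which any sampled individual carries >= 1 copy of
    the alternative-ecotype allele (missing genotypes count as
    non-carriers).  Deterministic given ``seed``.
    """
    carrier, ids, _ = _carrier_matrix(genotypes, outliers, focal_ecotype,
                                      ecotype_a)
    carrier = (carrier == 1)  # missing -> non-carrier within a replicate
    n_ind, n_loci = carrier.shape
    n_grid = np.asarray(list(n_grid), int)
    if (n_grid < 1).any() or (n_grid > n_ind).any():
        raise ValueError(f"N grid must lie in [1, {n_ind}]")
    rng = np.random.default_rng(seed)
    means = np.empty(len(n_grid))
    sds = np.empty(len(n_grid))
    all_reps = np.empty((len(n_grid), reps)) if keep_replicates else None
    for k, N in enumerate(n_grid):
        vals = np.empty(reps)
        for r in range(reps):
            pick = rng.choice(n_ind, size=N, replace=False)
            vals[r] = carrier[pick].any(axis=0).mean()
        means[k] = vals.mean()
        sds[k] = vals.std(ddof=1) if reps > 1 else 0.0
        if keep_replicates:
            all_reps[k] = vals
    return AccumulationCurve(focal_ecotype, n_grid, means, sds, reps, seed,
                             all_reps)


def exact_accumulation_expectation(genotypes: GenotypeTable,
                                   outliers: pd.DataFrame,
                                   focal_ecotype: str, N: int,
                                   ecotype_a: str = "S") -> float:
    """Closed-form expectation of the accumulation curve at sample size N.

    With n focal individuals and k_l carriers at locus l the probability
    that a random N-subset contains no carrier is C(n-k_l, N)/C(n, N), so
    the expected covered proportion is
    ``sum_l [1 - C(n-k_l, N)/C(n, N)] / L``.
    """
    carrier, ids, _ = _carrier_matrix(genotypes, outliers, focal_ecotype,
                                      ecotype_a)
    carrier = (carrier == 1)
    n, L = carrier.shape
    if not 1 <= N <= n:
        raise ValueError(f"N must lie in [1, {n}]")
    k = carrier.sum(axis=0)
    p_none = comb(n - k, N) / comb(n, N)
    return float((1.0 - p_none).mean())
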