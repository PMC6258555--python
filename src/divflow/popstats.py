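"""Per-locus and per-SNP diversity and divergence statistics.

Haplotype statistics (pi, d_XY, Tajima's D, haplotype F_ST) operate on
0/1 alignment matrices (rows = haploid sequences).  Per-SNP F_ST uses the
Weir-Cockerham (1984) variance-components estimator on diploid genotypes
with ratio-of-averages aggregation across SNPs.  Divergence statistics can
be normalized by the per-locus divergence to an outgroup, which removes
locus-to-locus mutation-rate variation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import GenotypeTable, HaplotypeSet, LocusHaplotypes

__all__ = ["nucleotide_diversity", "dxy", "tajimas_d", "fst_haplotype",
           "fst_snp_wc", "wc_fst_global", "haplotype_stats",
           "split_by_site", "ld_r2", "ld_decay", "mantel",
           "empirical_outlier_scan", "pairwise_fst_matrix"]


def _pair_diffs(seqs: np.ndarray) -> float:
    """Mean number of differences over all within-set pairs."""
    seqs = np.asarray(seqs)
    n = seqs.shape[0]
    if n < 2:
        raise ValueError("need at least two sequences")
    d = seqs.sum(axis=0).astype(float)
    return float((d * (n - d)).sum()) / (n * (n - 1) / 2.0)


def nucleotide_diversity(seqs: np.ndarray, length: int | None = None
                         ) -> float:
    """Nucleotide diversity: mean pairwise difference, per site.

    ``length`` is the alignment length in bp; default = number of columns
    (statistics per segregating site).
    """
    seqs = np.asarray(seqs)
    L = seqs.shape[1] if length is None else length
    if L == 0:
        return 0.0
    return _pair_diffs(seqs) / L


def dxy(group_a: np.ndarray, group_b: np.ndarray,
        length: int | None = None) -> float:
    """Mean per-site pairwise difference between two groups."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.ndim == 1:
        a = a[None, :]
    if b.ndim == 1:
        b = b[None, :]
    if a.shape[1] != b.shape[1]:
        raise ValueError("alignment lengths differ between groups")
    L = a.shape[1] if length is None else length
    if L == 0:
        return 0.0
    da = a.sum(axis=0)
    db = b.sum(axis=0)
    na, nb = a.shape[0], b.shape[0]
    cross = (da * (nb - db) + (na - da) * db).sum()
    return float(cross) / (na * nb) / L


def tajimas_d(seqs: np.ndarray) -> float | None:
    """Tajima's D; returns None (undefined) when no sites segregate.

    Uses the standard constants a1, a2, b1, b2, c1, c2, e1, e2 as
    functions of the sample size n.
    """
    seqs = np.asarray(seqs)
    n = seqs.shape[0]
    if n < 4:
        raise ValueError("Tajima's D requires at least 4 sequences")
    d = seqs.sum(axis=0)
    seg = (d > 0) & (d < n)
    S = int(seg.sum())
    if S == 0:
        return None
    pi = _pair_diffs(seqs)
    i = np.arange(1, n)
    a1 = (1.0 / i).sum()
    a2 = (1.0 / i**2).sum()
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return float((pi - S / a1) / np.sqrt(var))


def fst_haplotype(group_a: np.ndarray, group_b: np.ndarray) -> float | None:
    """Haplotype F_ST = 1 - H_w / H_b.

    ``H_w`` is the mean within-group pairwise difference (the two groups
    weighted equally) and ``H_b`` the mean between-group pairwise
    difference.  Returns None when H_b = 0 (undefined).
    """
    a = np.asarray(group_a)
    b = np.asarray(group_b)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least two sequences per group")
    hw = 0.5 * (_pair_diffs(a) + _pair_diffs(b))
    hb = dxy(a, b, length=1)  # length=1: mean cross-pair difference count
    if hb == 0:
        return None
    return float(1.0 - hw / hb)


def fst_snp_wc(genotypes: GenotypeTable, pops: list[str] | None = None,
               by: str = "population") -> pd.DataFrame:
    """Per-SNP Weir-Cockerham F_ST variance components.

    Returns a DataFrame with the components a (among populations),
    b (among individuals within populations), c (within individuals) and
    ``fst = a / (a + b + c)``.  Negative estimates are reported as-is.
    SNPs where a + b + c = 0 get fst = NaN.
    """
    labels = genotypes.samples[by]
    pops = list(pd.unique(labels)) if pops is None else list(pops)
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    groups = [np.flatnonzero((labels == p).values) for p in pops]
    if any(len(g) < 2 for g in groups):
        raise ValueError("need at least two diploids per population")
    r = len(groups)
    g = genotypes.genotypes
    n_i = np.stack([(g[idx] >= 0).sum(axis=0) for idx in groups])  # (r, S)
    cnt = np.stack([np.where(g[idx] >= 0, g[idx], 0).sum(axis=0)
                    for idx in groups]).astype(float)
    het = np.stack([(g[idx] == 1).sum(axis=0) for idx in groups])
    with np.errstate(divide="ignore", invalid="ignore"):
        p_i = cnt / (2.0 * n_i)
        h_i = het / n_i
        nbar = n_i.sum(axis=0) / r
        nc = (r * nbar - (n_i**2).sum(axis=0) / (r * nbar)) / (r - 1)
        pbar = (n_i * p_i).sum(axis=0) / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar)
                                 - s2 * (r - 1) / r - hbar / 4.0)
                           / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar)
                                   - s2 * (r - 1) / r
                                   - hbar * (2 * nbar - 1) / (4 * nbar))
        c = hbar / 2.0
        fst = a / (a + b + c)
    out = genotypes.sites[["id", "locus", "pos"]].copy()
    out["a"], out["b"], out["c"], out["fst"] = a, b, c, fst
    return out


def wc_fst_global(components: pd.DataFrame) -> float:
    """Multi-locus Weir-Cockerham F_ST: ratio of summed components."""
    ok = components[["a", "b", "c"]].dropna()
    denom = ok.values.sum()
    if denom == 0:
        return float("nan")
    return float(ok["a"].sum() / denom)


def pairwise_fst_matrix(genotypes: GenotypeTable,
                        by: str = "population") -> pd.DataFrame:
    """Matrix of multi-locus WC F_ST for every population pair."""
    pops = list(pd.unique(genotypes.samples[by]))
    mat = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, p in enumerate(pops):
        for q in pops[i + 1:]:
            comp = fst_snp_wc(genotypes, pops=[p, q], by=by)
            val = wc_fst_global(comp)
            mat.loc[p, q] = mat.loc[q, p] = val
    return mat


def split_by_site(loc: LocusHaplotypes, pos: int):
    """Split haplotypes in two groups by the allele carried at ``pos``."""
    col = np.flatnonzero(loc.positions == pos)
    if len(col) != 1:
        raise ValueError(f"position {pos} not found at locus {loc.locus}")
    allele = loc.haplotypes[:, col[0]]
    return allele == 1


@dataclass
class LocusStats:
    """Per-locus summary statistics (see ``haplotype_stats``)."""

    locus: str
    pi_tot: float
    pi_g0: float
    pi_g1: float
    d_xy: float
    d_xy_out: float | None
    norm_dxy: float | None
    norm_pi: float | None
    tajd: float | None
    tajd_g0: float | None
    tajd_g1: float | None
    fst_hap: float | None
    n_sites: int
    n_seqs0: int
    n_seqs1: int


def haplotype_stats(hapset: HaplotypeSet,
                    groups: dict[str, np.ndarray] | None = None
                    ) -> pd.DataFrame:
    """Compute :class:`LocusStats` for every locus.

    ``groups`` optionally maps a locus id to a boolean array putting each
    haploid copy in group 1 (e.g. from :func:`split_by_site` at the top
    outlier SNP); by default the simulator's deme label is used: group 0 =
    deme 0 (short-winged-associated), group 1 = deme 1.  Normalized values
    are only defined when an outgroup sequence is attached and diverged.
    """
    rows = []
    for loc in hapset:
        g1 = (loc.deme == 1) if groups is None else \
            np.asarray(groups[loc.locus], bool)
        a = loc.haplotypes[~g1]
        b = loc.haplotypes[g1]
        L = loc.length
        pi_tot = nucleotide_diversity(loc.haplotypes, L)
        pi0 = nucleotide_diversity(a, L) if a.shape[0] >= 2 else np.nan
        pi1 = nucleotide_diversity(b, L) if b.shape[0] >= 2 else np.nan
        d = dxy(a, b, L) if a.shape[0] and b.shape[0] else np.nan
        if loc.outgroup is not None:
            d_out = dxy(loc.haplotypes, loc.outgroup[None, :], L)
        else:
            d_out = None
        norm_dxy = norm_pi = None
        if d_out is not None and d_out > 0:
            norm_dxy = d / d_out
            norm_pi = pi_tot / d_out
        fh = fst_haplotype(a, b) if a.shape[0] >= 2 and b.shape[0] >= 2 \
            else None
        rows.append(LocusStats(
            locus=loc.locus, pi_tot=pi_tot, pi_g0=pi0, pi_g1=pi1,
            d_xy=d, d_xy_out=d_out, norm_dxy=norm_dxy, norm_pi=norm_pi,
            tajd=tajimas_d(loc.haplotypes)
            if loc.haplotypes.shape[0] >= 4 else None,
            tajd_g0=tajimas_d(a) if a.shape[0] >= 4 else None,
            tajd_g1=tajimas_d(b) if b.shape[0] >= 4 else None,
            fst_hap=fh, n_sites=loc.haplotypes.shape[1],
            n_seqs0=int(a.shape[0]), n_seqs1=int(b.shape[0])).__dict__)
    return pd.DataFrame(rows)


def ld_r2(genotypes: GenotypeTable,
          pairs: list[tuple[int, int]] | None = None,
          min_maf: float = 0.0) -> pd.DataFrame:
    """Squared dosage correlation for pairs of SNP columns.

    Missing genotypes are dropped pairwise.  Monomorphic columns (after
    the optional MAF sub-filter) yield NaN.  When ``pairs`` is None, all
    within-locus pairs are evaluated.
    """
    sites = genotypes.sites
    if pairs is None:
        pairs = []
        for _, idx in sites.groupby("locus", sort=False).indices.items():
            idx = np.sort(idx)
            for i in range(len(idx)):
                for j in range(i + 1, len(idx)):
                    pairs.append((idx[i], idx[j]))
    g = genotypes.genotypes
    rows = []
    for i, j in pairs:
        x, y = g[:, i].astype(float), g[:, j].astype(float)
        ok = (x >= 0) & (y >= 0)
        x, y = x[ok], y[ok]
        r2 = np.nan
        if len(x) >= 2:
            fx, fy = x.mean() / 2.0, y.mean() / 2.0
            maf_x, maf_y = min(fx, 1 - fx), min(fy, 1 - fy)
            if maf_x > 0 and maf_y > 0 and min(maf_x, maf_y) >= min_maf:
                with np.errstate(invalid="ignore"):
                    r = np.corrcoef(x, y)[0, 1]
                r2 = r * r
        dist = abs(int(sites["pos"].iloc[j]) - int(sites["pos"].iloc[i]))
        same = sites["locus"].iloc[i] == sites["locus"].iloc[j]
        rows.append({"i": i, "j": j, "dist": dist if same else np.nan,
                     "r2": r2})
    return pd.DataFrame(rows)


def ld_decay(r2_table: pd.DataFrame, bins: np.ndarray) -> pd.DataFrame:
    """Mean r-squared by distance bin (bins = edge array)."""
    tab = r2_table.dropna(subset=["dist", "r2"]).copy()
    tab["bin"] = pd.cut(tab["dist"], bins=bins)
    out = tab.groupby("bin", observed=False)["r2"].agg(["mean", "count"])
    out.index = [iv.mid for iv in out.index]
    out.index.name = "dist"
    return out.reset_index()


def mantel(mat_a: np.ndarray, mat_b: np.ndarray, n_perm: int = 999,
           seed: int = 0) -> tuple[float, float]:
    """Mantel test: Pearson r over off-diagonal pairs, permutation p.

    Rows and columns of the second matrix are permuted jointly;
    p = (1 + #{permutation r >= observed r}) / (1 + n_perm).
    """
    A = np.asarray(mat_a, float)
    B = np.asarray(mat_b, float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("matrices must be square and of equal size")
    if not (np.allclose(A, A.T) and np.allclose(B, B.T)):
        raise ValueError("matrices must be symmetric")
    iu = np.triu_indices(A.shape[0], k=1)
    va = A[iu]
    r_obs = float(np.corrcoef(va, B[iu])[0, 1])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(A.shape[0])
        r = np.corrcoef(va, B[np.ix_(perm, perm)][iu])[0, 1]
        if r >= r_obs:
            hits += 1
    return r_obs, (1 + hits) / (1 + n_perm)


def empirical_outlier_scan(fst: np.ndarray, q: float = 0.95) -> pd.DataFrame:
    """Empirical upper-tail F_ST scan.

    Flags SNPs with F_ST strictly above the ``q`` quantile and reports a
    support score: -log10 of the empirical upper-tail probability
    (fraction of SNPs with F_ST >= this SNP's value).  A stand-in for
    Bayesian outlier machinery; ties sit below the threshold and are not
    flagged.
    """
    fst = np.asarray(fst, float)
    valid = ~np.isnan(fst)
    if valid.sum() < 100:
        raise ValueError("need >= 100 SNPs for an empirical tail")
    if not 0 <= q <= 1:
        raise ValueError("quantile must be in [0, 1]")
    thr = np.nanquantile(fst, q)
    n = valid.sum()
    order = fst[valid]
    tail = np.array([np.sum(order >= v) for v in fst]) / n
    support = np.where(valid, -np.log10(np.maximum(tail, 1.0 / n)), np.nan)
    return pd.DataFrame({"fst": fst, "outlier": valid & (fst > thr),
                         "support": support})
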