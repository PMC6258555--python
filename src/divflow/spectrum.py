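"""Joint allele frequency spectra: build, project, fold, read, write.

A :class:`Jafs` is a (n1+1) x (n2+1) matrix of site counts indexed by the
number of derived copies in each population.  The fixed corners (0, 0) and
(n1, n2) are uninformative and always masked.  The text format is the
row-major dialect used by diffusion-based SFS software: a header line
``"<n1+1> <n2+1> [folded|unfolded]"``, the entries, then a 0/1 mask line.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom

from .datatypes import GenotypeTable

__all__ = ["Jafs", "default_mask", "build_jafs", "project", "fold",
           "read_sfs", "write_sfs"]


def default_mask(n1: int, n2: int) -> np.ndarray:
    """Boolean mask (True = excluded) with only the fixed corners set."""
    mask = np.zeros((n1 + 1, n2 + 1), bool)
    mask[0, 0] = True
    mask[n1, n2] = True
    return mask


@dataclass
class Jafs:
    """Two-dimensional joint allele frequency spectrum."""

    data: np.ndarray
    mask: np.ndarray | None = None
    folded: bool = False
    total_sites: float | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, float)
        if self.data.ndim != 2:
            raise ValueError("spectrum must be 2-D")
        if (self.data < 0).any():
            raise ValueError("spectrum entries must be nonnegative")
        if self.mask is None:
            self.mask = default_mask(*self.shape_n)
        self.mask = np.asarray(self.mask, bool)
        if self.mask.shape != self.data.shape:
            raise ValueError("mask shape mismatch")
        self.mask[0, 0] = True
        self.mask[self.n1, self.n2] = True

    @property
    def n1(self) -> int:
        return self.data.shape[0] - 1

    @property
    def n2(self) -> int:
        return self.data.shape[1] - 1

    @property
    def shape_n(self) -> tuple[int, int]:
        return self.n1, self.n2

    def sum(self) -> float:
        """Total unmasked mass."""
        return float(self.data[~self.mask].sum())

    def normalized(self) -> np.ndarray:
        """Unmasked entries scaled to sum to one (masked entries zeroed)."""
        out = np.where(self.mask, 0.0, self.data)
        s = out.sum()
        if s == 0:
            raise ValueError("spectrum has zero unmasked mass")
        return out / s

    def copy(self) -> "Jafs":
        return Jafs(self.data.copy(), self.mask.copy(), self.folded,
                    self.total_sites)


def _projection_matrix(n: int, m: int) -> np.ndarray:
    """A[j, i] = P(j derived in a subsample of m | i derived among n)."""
    A = np.zeros((m + 1, n + 1))
    for i in range(n + 1):
        j = np.arange(m + 1)
        A[:, i] = hypergeom.pmf(j, n, i, m)
    return A


def build_jafs(genotypes: GenotypeTable, pop1: str, pop2: str,
               polarization: np.ndarray | None = None,
               size1: int | None = None, size2: int | None = None) -> Jafs:
    """Build the JAFS of two populations from a genotype table.

    Parameters
    ----------
    pop1, pop2 : population labels looked up in ``samples["population"]``.
    polarization : optional per-site array of the ancestral allele coded
        0 (REF) or 1 (ALT), e.g. read off an outgroup.  When None the
        spectrum is folded.
    size1, size2 : target haploid sample sizes.  Sites with missing calls
        are hypergeometrically projected down to these sizes from their
        callable counts; sites callable in fewer copies are dropped.
        Default: the full haploid size of each population.
    """
    rows1 = np.flatnonzero((genotypes.samples["population"] == pop1).values)
    rows2 = np.flatnonzero((genotypes.samples["population"] == pop2).values)
    if len(rows1) == 0 or len(rows2) == 0:
        raise ValueError("empty population selection")
    m1 = 2 * len(rows1) if size1 is None else int(size1)
    m2 = 2 * len(rows2) if size2 is None else int(size2)
    d1, c1 = genotypes.allele_counts(rows1)
    d2, c2 = genotypes.allele_counts(rows2)
    if polarization is not None:
        polarization = np.asarray(polarization)
        if polarization.shape != (genotypes.n_sites,):
            raise ValueError("polarization length mismatch")
        if not np.isin(polarization, (0, 1)).all():
            raise ValueError("polarization must code the ancestral allele "
                             "as 0 (REF) or 1 (ALT)")
        flip = polarization == 1
        d1 = np.where(flip, c1 - d1, d1)
        d2 = np.where(flip, c2 - d2, d2)
    data = np.zeros((m1 + 1, m2 + 1))
    usable = (c1 >= m1) & (c2 >= m2)
    exact = usable & (c1 == m1) & (c2 == m2)
    np.add.at(data, (d1[exact], d2[exact]), 1.0)
    for s in np.flatnonzero(usable & ~exact):
        v1 = hypergeom.pmf(np.arange(m1 + 1), c1[s], d1[s], m1)
        v2 = hypergeom.pmf(np.arange(m2 + 1), c2[s], d2[s], m2)
        data += np.outer(v1, v2)
    jafs = Jafs(data, mask=default_mask(m1, m2), folded=False,
                total_sites=int(usable.sum()))
    if polarization is None:
        jafs = fold(jafs)
    return jafs


def project(jafs: Jafs, m1: int, m2: int) -> Jafs:
    """Hypergeometric down-projection to haploid sizes ``(m1, m2)``."""
    if jafs.folded:
        raise ValueError("project unfolded spectra, then fold")
    n1, n2 = jafs.shape_n
    if m1 > n1 or m2 > n2:
        raise ValueError("projection sizes exceed current sample sizes")
    A1 = _projection_matrix(n1, m1)
    A2 = _projection_matrix(n2, m2)
    data = np.where(jafs.mask, 0.0, jafs.data)
    out = A1 @ data @ A2.T
    return Jafs(out, mask=default_mask(m1, m2), folded=False,
                total_sites=jafs.total_sites)


def fold(jafs: Jafs) -> Jafs:
    """Fold onto minor-allele frequencies.

    Entry (i, j) is combined with its complement (n1-i, n2-j); entries on
    the boundary i + j == (n1+n2)/2 receive half of the combined mass and
    everything above the minor-allele diagonal is zeroed and masked.
    """
    if jafs.folded:
        raise ValueError("spectrum is already folded")
    n1, n2 = jafs.shape_n
    data = np.where(jafs.mask, 0.0, jafs.data)
    total = data + data[::-1, ::-1]
    i = np.arange(n1 + 1)[:, None]
    j = np.arange(n2 + 1)[None, :]
    freq_sum = 2 * (i + j)
    total[freq_sum == n1 + n2] *= 0.5
    keep = freq_sum <= n1 + n2
    folded = np.where(keep, total, 0.0)
    mask = jafs.mask | jafs.mask[::-1, ::-1] | ~keep
    return Jafs(folded, mask=mask, folded=True, total_sites=jafs.total_sites)


def write_sfs(jafs: Jafs, path) -> None:
    with open(path, "w") as fh:
        tag = "folded" if jafs.folded else "unfolded"
        fh.write(f"{jafs.n1 + 1} {jafs.n2 + 1} {tag}\n")
        fh.write(" ".join(repr(float(v)) for v in jafs.data.ravel())
                 + "\n")
        fh.write(" ".join(str(int(v)) for v in jafs.mask.ravel()) + "\n")


def read_sfs(path) -> Jafs:
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if len(lines) < 2:
        raise ValueError(f"truncated SFS file: {path}")
    head = lines[0].split()
    r, c = int(head[0]), int(head[1])
    folded = len(head) > 2 and head[2] == "folded"
    try:
        data = np.array([float(v) for v in lines[1].split()])
    except ValueError as err:
        raise ValueError(f"non-numeric SFS entries in {path}") from err
    if data.size != r * c:
        raise ValueError(f"expected {r * c} entries, found {data.size}")
    data = data.reshape(r, c)
    if len(lines) > 2:
        mask = np.array([int(v) for v in lines[2].split()], bool)
        if mask.size != r * c:
            raise ValueError("mask length mismatch")
        mask = mask.reshape(r, c)
    else:
        mask = default_mask(r - 1, c - 1)
    return Jafs(data, mask=mask, folded=folded)
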