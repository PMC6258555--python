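"""Multi-locus two-deme coalescent data generator.

Generates RAD-like datasets: hundreds of short loci sampled from two demes
(ecotypes), each locus independently drawn from a mixture of heterogeneity
classes -- neutral, "island" (reduced migration, fraction ``P``) and "hrf"
(all effective sizes scaled by ``hrf``, fraction ``Q``) -- plus an optional
outgroup lineage used for polarization and divergence normalization.
Mutation follows the infinite-sites model: each locus receives
Poisson(theta/2 * total branch length) segregating sites at distinct
positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernel
from .datatypes import GenotypeTable, HaplotypeSet, LocusHaplotypes
from .models import (DemographyParams, class_probs, epoch_args,
                     locus_classes, validate)
from .spectrum import Jafs, default_mask

__all__ = ["ScenarioSpec", "simulate_locus", "simulate_dataset",
           "attach_outgroup", "simulate_jafs", "jafs_from_haplotypes"]

_MAX_SEED = 2**31 - 1


@dataclass
class ScenarioSpec:
    """One simulation scenario.

    n1, n2 : haploid sample sizes per deme (even numbers are required when
        diploid genotypes are formed).
    theta_locus : per-locus population mutation rate 4*N_A*mu*locus_length.
    outgroup_time : scaled time (2*N_A generations) of the outgroup split;
        must exceed the split time t_s when given.
    """

    model: str = "SC"
    params: DemographyParams = field(default_factory=DemographyParams)
    n1: int = 8
    n2: int = 8
    n_loci: int = 1000
    locus_length: int = 1200
    theta_locus: float = 2.0
    outgroup_time: float | None = None
    seed: int = 0
    pop_names: tuple[str, str] = ("pop1", "pop2")
    ecotypes: tuple[str, str] = ("S", "L")

    def __post_init__(self):
        validate(self.params, self.model)
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("need at least two haploid copies per deme")
        if self.n1 + self.n2 > 63:
            raise ValueError("at most 63 haploid copies are supported")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.theta_locus <= 0:
            raise ValueError("theta_locus must be > 0")
        if self.outgroup_time is not None \
                and self.outgroup_time <= self.params.t_s:
            raise ValueError("outgroup_time must exceed the split time t_s")


def _mask_to_rows(masks: np.ndarray, n: int) -> np.ndarray:
    """Expand branch bitmasks into a boolean (n_branches x n) matrix."""
    bits = (masks[:, None] >> np.arange(n)[None, :]) & 1
    return bits.astype(np.uint8)


def simulate_locus(spec: ScenarioSpec, locus_class: str,
                   rng: np.random.Generator,
                   locus_id: str = "locus0") -> LocusHaplotypes:
    """Simulate one locus: genealogy plus infinite-sites mutations."""
    if locus_class not in locus_classes(spec.model) + ["neutral"]:
        raise ValueError(f"class {locus_class!r} inconsistent with model "
                         f"{spec.model!r}")
    args = epoch_args(spec.params, spec.model, locus_class)
    _kernel.seed_kernel(int(rng.integers(_MAX_SEED)))
    blen, bd1, bd2, bmask, nb, t_mrca = _kernel.sim_tree(
        spec.n1, spec.n2, *args)
    blen, bmask = blen[:nb], bmask[:nb]
    n = spec.n1 + spec.n2
    nmut = rng.poisson(spec.theta_locus / 2.0 * blen)
    total = int(nmut.sum())
    if total > spec.locus_length:
        raise ValueError("more mutations than sites; raise locus_length or "
                         "lower theta_locus")
    carriers = _mask_to_rows(np.repeat(bmask, nmut), n)  # (S x n)
    haps = carriers.T.copy()  # (n x S)
    positions = np.sort(rng.choice(spec.locus_length, size=total,
                                   replace=False))
    deme = np.concatenate([np.zeros(spec.n1, int), np.ones(spec.n2, int)])
    return LocusHaplotypes(locus=locus_id, haplotypes=haps, deme=deme,
                           positions=positions, length=spec.locus_length,
                           locus_class=locus_class, t_mrca=float(t_mrca))


def attach_outgroup(spec: ScenarioSpec, hapset: HaplotypeSet,
                    rng: np.random.Generator) -> HaplotypeSet:
    """Add one outgroup haplotype per locus.

    The outgroup lineage stays separate until ``outgroup_time`` and then
    coalesces with the ingroup root in the ancestral deme.  Mutations on
    the two extra branches create sites that are monomorphic within the
    ingroup but segregate against the outgroup; allele 0 remains the true
    ancestral state everywhere, so the outgroup allele at any pre-existing
    site is 0.
    """
    if spec.outgroup_time is None:
        raise ValueError("outgroup_time is not set on the scenario")
    out = []
    for loc in hapset:
        if loc.t_mrca is None:
            raise ValueError(f"locus {loc.locus} lacks t_mrca; was it "
                             "simulated by this package?")
        size_anc = epoch_args(spec.params, spec.model, loc.locus_class)[-1]
        t_join = max(loc.t_mrca, spec.outgroup_time)
        t_coal = t_join + rng.exponential(size_anc)
        root_len = t_coal - loc.t_mrca
        out_len = t_coal
        s_root = rng.poisson(spec.theta_locus / 2.0 * root_len)
        s_out = rng.poisson(spec.theta_locus / 2.0 * out_len)
        n, s_old = loc.haplotypes.shape
        extra = s_root + s_out
        if s_old + extra > spec.locus_length:
            raise ValueError("more mutations than sites at locus "
                             f"{loc.locus}")
        free = np.setdiff1d(np.arange(spec.locus_length), loc.positions,
                            assume_unique=True)
        new_pos = rng.choice(free, size=extra, replace=False)
        new_cols = np.zeros((n, extra), np.uint8)
        new_cols[:, :s_root] = 1  # ingroup-root branch: all ingroup derived
        og = np.zeros(s_old + extra, np.uint8)
        og[s_old + s_root:] = 1   # outgroup-private derived sites
        haps = np.hstack([loc.haplotypes, new_cols])
        positions = np.concatenate([loc.positions, new_pos])
        order = np.argsort(positions, kind="stable")
        out.append(LocusHaplotypes(
            locus=loc.locus, haplotypes=haps[:, order], deme=loc.deme,
            positions=positions[order], length=loc.length,
            locus_class=loc.locus_class, outgroup=og[order],
            t_mrca=loc.t_mrca))
    return HaplotypeSet(out)


def _draw_classes(spec: ScenarioSpec, rng: np.random.Generator):
    probs = class_probs(spec.params, spec.model)
    names = list(probs)
    idx = rng.choice(len(names), size=spec.n_loci, p=list(probs.values()))
    return [names[i] for i in idx]


def _pair_diploids(spec: ScenarioSpec, rng: np.random.Generator):
    """Random within-deme pairing of haploid copies into diploids."""
    if spec.n1 % 2 or spec.n2 % 2:
        raise ValueError("diploid genotypes require even n1 and n2")
    p1 = rng.permutation(spec.n1).reshape(-1, 2)
    p2 = (spec.n1 + rng.permutation(spec.n2)).reshape(-1, 2)
    return np.vstack([p1, p2])


def simulate_dataset(spec: ScenarioSpec):
    """Simulate a full dataset.

    Returns ``(HaplotypeSet, GenotypeTable, truth)`` where ``truth`` is a
    per-locus DataFrame of the (hidden) heterogeneity class labels.
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    classes = _draw_classes(spec, rng)
    width = len(str(max(spec.n_loci - 1, 1)))
    loci = [simulate_locus(spec, cls, rng, locus_id=f"L{i:0{width}d}")
            for i, cls in enumerate(classes)]
    hapset = HaplotypeSet(loci)
    if spec.outgroup_time is not None:
        hapset = attach_outgroup(spec, hapset, rng)
    pairs = _pair_diploids(spec, rng)
    genotypes = genotype_table(spec, hapset, pairs)
    return hapset, genotypes, hapset.truth_labels()


def genotype_table(spec: ScenarioSpec, hapset: HaplotypeSet,
                   pairs: np.ndarray) -> GenotypeTable:
    """Collapse haploid copies into diploid genotypes (ALT = derived)."""
    blocks, sites = [], []
    for loc in hapset:
        g = loc.haplotypes[pairs[:, 0]] + loc.haplotypes[pairs[:, 1]]
        blocks.append(g.astype(np.int8))
        sites.append(pd.DataFrame({
            "locus": loc.locus, "pos": loc.positions,
            "ref": "A", "alt": "G",
        }))
    geno = np.hstack(blocks) if blocks else np.zeros((len(pairs), 0),
                                                     np.int8)
    n_ind1 = spec.n1 // 2
    names, pops, ecos, habs = [], [], [], []
    for d, (pop, eco, hab, count) in enumerate(
            [(spec.pop_names[0], spec.ecotypes[0], -1, n_ind1),
             (spec.pop_names[1], spec.ecotypes[1], +1, spec.n2 // 2)]):
        for i in range(count):
            names.append(f"{pop}_{i:03d}")
            pops.append(pop)
            ecos.append(eco)
            habs.append(hab)
    samples = pd.DataFrame({"id": names, "population": pops,
                            "ecotype": ecos, "habitat": habs})
    site_df = pd.concat(sites, ignore_index=True) if sites else \
        pd.DataFrame(columns=["locus", "pos", "ref", "alt"])
    return GenotypeTable(geno, samples, site_df)


def jafs_from_haplotypes(hapset: HaplotypeSet, n1: int, n2: int) -> Jafs:
    """JAFS accumulated directly from simulated haplotypes (truth-polarized).

    Sites where the ingroup is monomorphic (outgroup-only variants) fall in
    the masked corners.
    """
    data = np.zeros((n1 + 1, n2 + 1))
    for loc in hapset:
        in1 = loc.deme == 0
        d1 = loc.haplotypes[in1].sum(axis=0)
        d2 = loc.haplotypes[~in1].sum(axis=0)
        np.add.at(data, (d1, d2), 1)
    return Jafs(data, mask=default_mask(n1, n2), folded=False)


def simulate_jafs(spec: ScenarioSpec, rng: np.random.Generator | None = None
                  ) -> Jafs:
    """Fast path: simulate only the dataset-level JAFS.

    Branch lengths are accumulated per heterogeneity class over the
    expected number of loci in each class and Poisson site counts are
    drawn cell-wise; this is distributionally identical to summing
    per-locus infinite-sites spectra.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    classes = _draw_classes(spec, rng)
    counts = pd.Series(classes).value_counts()
    total_T = np.zeros((spec.n1 + 1, spec.n2 + 1))
    for cls, n_loci in counts.items():
        _kernel.seed_kernel(int(rng.integers(_MAX_SEED)))
        args = epoch_args(spec.params, spec.model, cls)
        total_T += _kernel.accumulate_branch_jafs(
            spec.n1, spec.n2, *args, int(n_loci))
    expected = spec.theta_locus / 2.0 * total_T
    data = rng.poisson(expected).astype(float)
    mask = default_mask(spec.n1, spec.n2)
    data[mask] = 0.0
    return Jafs(data, mask=mask, folded=False)
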