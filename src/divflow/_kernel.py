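"""Backward-in-time structured coalescent kernel for two demes.

Time is measured in units of 2*N_A generations (N_A = ancestral effective
size).  Under this scaling a pair of lineages in a deme of relative size
``nu`` coalesces at rate ``1/nu`` and a lineage in deme i jumps backward
into deme j at rate ``M_ij = 2*N_A*m_ij`` where ``m_ij`` is the per
generation fraction of deme i that are new migrants from deme j.

The scenario seen backward from the present is piecewise constant:

* ``[0, t_mig)``  -- two demes, migration active at rates ``m1`` (lineages
  leaving deme 0) and ``m2`` (lineages leaving deme 1);
* ``[t_mig, t_s)`` -- two demes, no migration;
* ``[t_s, inf)``  -- a single ancestral deme of relative size ``size_anc``.

Strict isolation is ``t_mig = 0``; isolation-with-migration is
``t_mig = t_s``; secondary contact is ``0 < t_mig < t_s``.

All functions are numba-compiled; randomness uses numba's internal
``np.random`` state, seeded once via :func:`seed_kernel`.
"""

import numpy as np
from numba import njit

__all__ = ["seed_kernel", "sim_tree", "accumulate_branch_jafs"]


@njit(cache=True)
def seed_kernel(seed):
    """Seed the numba-internal RNG used by all kernel functions."""
    np.random.seed(seed)


@njit(cache=True)
def sim_tree(n1, n2, nu1, nu2, t_s, t_mig, m1, m2, size_anc):
    """Simulate one genealogy; return its branches.

    Returns
    -------
    blen : float64[2n-2]   branch lengths (lifetime of each coalesced lineage)
    bd1, bd2 : int64[2n-2] number of sample descendants in deme 0 / deme 1
    bmask : int64[2n-2]    bitmask of sample descendants (bit k = sample k;
                           samples 0..n1-1 are deme 0, n1..n1+n2-1 deme 1)
    t_mrca : float64       time of the ingroup most recent common ancestor
    """
    n = n1 + n2
    deme = np.empty(n, np.int64)
    d1 = np.empty(n, np.int64)
    d2 = np.empty(n, np.int64)
    mask = np.empty(n, np.int64)
    birth = np.zeros(n, np.float64)
    for i in range(n1):
        deme[i] = 0
        d1[i] = 1
        d2[i] = 0
        mask[i] = np.int64(1) << i
    for i in range(n1, n):
        deme[i] = 1
        d1[i] = 0
        d2[i] = 1
        mask[i] = np.int64(1) << i

    blen = np.empty(2 * n - 2, np.float64)
    bd1 = np.empty(2 * n - 2, np.int64)
    bd2 = np.empty(2 * n - 2, np.int64)
    bmask = np.empty(2 * n - 2, np.int64)
    nb = 0

    nact = n
    t = 0.0
    while nact > 1:
        if t >= t_s:
            k1 = nact
            k2 = 0
            rc1 = k1 * (k1 - 1) / 2.0 / size_anc
            rc2 = 0.0
            rm1 = 0.0
            rm2 = 0.0
        else:
            k1 = 0
            for i in range(nact):
                if deme[i] == 0:
                    k1 += 1
            k2 = nact - k1
            rc1 = k1 * (k1 - 1) / 2.0 / nu1
            rc2 = k2 * (k2 - 1) / 2.0 / nu2
            if t < t_mig:
                rm1 = k1 * m1
                rm2 = k2 * m2
            else:
                rm1 = 0.0
                rm2 = 0.0
        tot = rc1 + rc2 + rm1 + rm2
        if tot <= 0.0:
            # one lineage stranded per deme with no migration: wait for t_s
            t = t_s
            continue
        dt = np.random.exponential(1.0 / tot)
        tn = t + dt
        if t < t_mig and tn >= t_mig and t_mig < t_s:
            t = t_mig
            continue
        if t < t_s and tn >= t_s:
            t = t_s
            continue
        t = tn
        u = np.random.random() * tot
        if u < rc1 + rc2:
            target = 0 if u < rc1 else 1
            if t >= t_s:
                kk = nact
            else:
                kk = k1 if target == 0 else k2
            # pick an ordered pair (a-th, b-th lineage of the deme), a != b
            a = int(np.random.random() * kk)
            b = int(np.random.random() * (kk - 1))
            if b >= a:
                b += 1
            ia = -1
            ib = -1
            seen = 0
            for i in range(nact):
                if t >= t_s or deme[i] == target:
                    if seen == a:
                        ia = i
                    if seen == b:
                        ib = i
                    seen += 1
            # record the two child branches
            blen[nb] = t - birth[ia]
            bd1[nb] = d1[ia]
            bd2[nb] = d2[ia]
            bmask[nb] = mask[ia]
            nb += 1
            blen[nb] = t - birth[ib]
            bd1[nb] = d1[ib]
            bd2[nb] = d2[ib]
            bmask[nb] = mask[ib]
            nb += 1
            # merge into slot ia, swap-remove ib
            d1[ia] += d1[ib]
            d2[ia] += d2[ib]
            mask[ia] |= mask[ib]
            birth[ia] = t
            nact -= 1
            deme[ib] = deme[nact]
            d1[ib] = d1[nact]
            d2[ib] = d2[nact]
            mask[ib] = mask[nact]
            birth[ib] = birth[nact]
        else:
            # migration event
            if u - rc1 - rc2 < rm1:
                src = 0
                kk = k1
            else:
                src = 1
                kk = k2
            a = int(np.random.random() * kk)
            seen = 0
            for i in range(nact):
                if deme[i] == src:
                    if seen == a:
                        deme[i] = 1 - src
                        break
                    seen += 1
    return blen, bd1, bd2, bmask, nb, t

@njit(cache=True)
def accumulate_branch_jafs(n1, n2, nu1, nu2, t_s, t_mig, m1, m2, size_anc,
                           nreps, base_seed=-1):
    """Accumulate branch lengths by joint descendant-count class.

    ``T[i, j]`` is the summed length, over ``nreps`` independent
    genealogies, of branches subtending ``i`` sample copies in deme 0 and
    ``j`` in deme 1.  The expected number of segregating sites in JAFS
    cell (i, j) is ``theta/2 * T[i, j] / nreps`` per locus.

    When ``base_seed >= 0`` every replicate runs on its own RNG substream
    (``base_seed + r``).  Re-evaluating at nearby parameter values then
    reuses the same randomness per genealogy, which makes the Monte-Carlo
    error a smooth function of the parameters (common random numbers) and
    the likelihood surface navigable by a simplex optimizer.
    """
    T = np.zeros((n1 + 1, n2 + 1), np.float64)
    for r in range(nreps):
        if base_seed >= 0:
            np.random.seed(base_seed + r)
        blen, bd1, bd2, bmask, nb, tm = sim_tree(
            n1, n2, nu1, nu2, t_s, t_mig, m1, m2, size_anc)
        for b in range(nb):
            T[bd1[b], bd2[b]] += blen[b]
    return T
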