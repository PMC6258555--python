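"""Expected-JAFS engine, composite likelihood and replicated model fitting.

The expected spectrum of a heterogeneous model is the mixture

    (1-P)(1-Q) F(M, nu) + P(1-Q) F(M_I, nu)
  + (1-P) Q   F(M, hrf*nu) + P Q F(M_I, hrf*nu)

where each ``F`` is the expected JAFS of the homogeneous model.  ``F`` is
estimated by Monte-Carlo structured coalescent: branch lengths are
accumulated by joint descendant-count class over many genealogies, so the
expected site count in cell (i, j) per unit ``theta`` is
``E[T_ij] / 2``.  A fixed engine seed (common random numbers) makes the
likelihood a deterministic function of the parameters, which keeps the
surface optimizable by a derivative-free simplex.

The fit criterion is the Poisson composite likelihood with the mutation
scaling ``theta`` profiled out analytically:
``theta_hat = sum(O) / sum(F)`` over unmasked cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln

from . import _kernel
from .models import (DemographyParams, MODEL_IDS, class_probs, epoch_args,
                     free_params, validate)
from .spectrum import Jafs, default_mask

__all__ = ["DemographyParams", "FitResult", "EnginePrecisionError",
           "expected_jafs", "loglik", "fit", "compare_models",
           "DEFAULT_BOUNDS"]

#: optimizer box bounds (natural scale); t_sc is optimized as the ratio
#: t_sc / t_s so the constraint t_sc <= t_s is structural.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "nu1": (1e-2, 100.0),
    "nu2": (1e-2, 100.0),
    "t_s": (1e-2, 20.0),
    "t_sc": (1e-2, 1.0),          # as a fraction of t_s
    "M12": (1e-3, 50.0),
    "M21": (1e-3, 50.0),
    "MI12": (1e-4, 50.0),
    "MI21": (1e-4, 50.0),
    "P": (1e-2, 0.99),
    "Q": (1e-2, 0.99),
    "hrf": (5e-2, 1.0),
}


class EnginePrecisionError(RuntimeError):
    """The expected spectrum is zero in a cell with observed sites."""


def expected_jafs(params: DemographyParams, model_id: str, n1: int, n2: int,
                  nreps: int = 5000, engine_seed: int = 17) -> Jafs:
    """Expected JAFS per unit theta under ``model_id``.

    ``nreps`` genealogies are simulated per mixture component
    (precision control); the kernel RNG is reseeded with ``engine_seed``
    before each component so repeated calls with the same seed are
    deterministic.
    """
    validate(params, model_id)
    F = np.zeros((n1 + 1, n2 + 1))
    for cls, w in class_probs(params, model_id).items():
        if w == 0.0:
            continue
        args = epoch_args(params, model_id, cls)
        T = _kernel.accumulate_branch_jafs(n1, n2, *args, nreps,
                                           engine_seed)
        F += w * T / (2.0 * nreps)
    if not np.isfinite(F).all():
        raise ValueError("non-finite expected spectrum entries")
    mask = default_mask(n1, n2)
    F[mask] = 0.0
    if F.sum() == 0:
        raise ValueError("expected spectrum has zero mass")
    return Jafs(F, mask=mask, folded=False)


def loglik(observed: Jafs, model: Jafs) -> tuple[float, float]:
    """Poisson composite log-likelihood with the analytic theta optimum.

    Returns ``(lnL, theta_hat)``.  ``model`` is the expected spectrum per
    unit theta.  Raises :class:`EnginePrecisionError` when a cell with
    observed sites has zero expected mass (raise the engine precision).
    """
    if observed.data.shape != model.data.shape:
        raise ValueError("observed and model spectra differ in shape")
    keep = ~(observed.mask | model.mask)
    O = observed.data[keep]
    F = model.data[keep]
    if observed.folded != model.folded:
        raise ValueError("folded status differs between observed and model")
    bad = (F == 0) & (O > 0)
    if bad.any():
        raise EnginePrecisionError(
            f"{bad.sum()} cells observed but expected mass is zero; "
            "increase engine precision (nreps)")
    theta_hat = float(O.sum() / F.sum())
    mu = theta_hat * F
    pos = O > 0
    lnl = float((O[pos] * np.log(mu[pos])).sum() - mu.sum()
                - gammaln(O + 1).sum())
    return lnl, theta_hat


@dataclass
class FitResult:
    """Best fit of one model plus the replicate-run table."""

    model_id: str
    params: DemographyParams
    lnL: float
    k: int
    theta_hat: float
    replicates: pd.DataFrame
    seed: int
    warnings: list[str] = field(default_factory=list)

    @property
    def AIC(self) -> float:
        return 2.0 * self.k - 2.0 * self.lnL


#: coarse probe grids per parameter (natural scale) for the global stage
PROBE_GRID: dict[str, list[float]] = {
    "nu1": [0.05, 0.2, 1.0, 5.0],
    "nu2": [0.05, 0.2, 1.0, 5.0],
    "t_s": [0.1, 0.3, 1.0, 3.0, 8.0],
    "t_sc": [0.05, 0.3, 0.9],
    "M12": [0.1, 0.5, 2.0, 8.0, 30.0],
    "M21": [0.1, 0.5, 2.0, 8.0, 30.0],
    "MI12": [0.01, 0.1, 1.0],
    "MI21": [0.01, 0.1, 1.0],
    "P": [0.1, 0.3, 0.6],
    "Q": [0.2, 0.5],
    "hrf": [0.1, 0.4, 0.8],
}

#: bounds of the secondary-contact flux coordinate M * t_sc (see below)
FLUX_BOUNDS = (1e-4, 40.0)


def _vector_to_params(x, names, fixed: DemographyParams,
                      flux: bool) -> DemographyParams:
    """Map an optimizer vector (natural scale) to model parameters.

    Internally ``t_sc`` is the ratio t_sc / t_s, so the constraint
    t_sc <= t_s is structural.  In secondary-contact models the migration
    coordinates hold the migration *flux* M * t_sc instead of M itself:
    when contact is recent, only that product is sharply identified, and
    the reparametrization aligns the resulting likelihood ridge with a
    coordinate axis, which derivative-free optimizers handle far better.
    """
    kw = dict(zip(names, x))
    if "t_sc" in kw:
        t_s = kw.get("t_s", fixed.t_s)
        kw["t_sc"] = kw["t_sc"] * t_s
        if flux:
            t_sc = max(kw["t_sc"], 1e-12)
            for m in ("M12", "M21", "MI12", "MI21"):
                if m in kw:
                    kw[m] = kw[m] / t_sc
    return fixed.replace(**kw)


def _expand_symmetric(p: DemographyParams, names) -> DemographyParams:
    if "M12" in names and "M21" not in names:
        p = p.replace(M21=p.M12)
    if "MI12" in names and "MI21" not in names:
        p = p.replace(MI21=p.MI12)
    return p


def fit(observed: Jafs, model_id: str,
        bounds: dict[str, tuple[float, float]] | None = None,
        n_starts: int = 20, engine_reps: int = 3000, engine_seed: int = 17,
        seed: int = 0, fixed: dict[str, float] | None = None,
        symmetric_m: bool = False, maxiter: int = 300,
        probe_budget: int = 2500, fatol: float = 0.05,
        polish: bool = True) -> FitResult:
    """Replicated derivative-free fit of ``model_id`` to an observed JAFS.

    The search runs in stages, all on log10-transformed parameters with a
    fixed engine seed (common random numbers) so the objective is a
    deterministic function of the parameters:

    1. a coarse factorial probe grid (subsampled to ``probe_budget``
       points, scored at a fifth of the engine precision) locates
       candidate basins;
    2. Nelder-Mead runs start from the best probes, then from
       U(1/3, 3)-perturbations of the best point so far, ``n_starts``
       simplex runs in total (the replicate table);
    3. the best point is polished by one more simplex run at five-fold
       engine precision.

    Parameters named in ``fixed`` are pinned and excluded from ``k``.
    Deterministic given ``seed``.
    """
    if observed.folded:
        raise ValueError("fit expects an unfolded observed spectrum")
    n1, n2 = observed.shape_n
    fixed = dict(fixed or {})
    names = [p for p in free_params(model_id, symmetric_m)
             if p not in fixed]
    base = DemographyParams(**{k: v for k, v in fixed.items()})
    use_flux = model_id.startswith("SC") and "t_sc" in names
    bnds = {**DEFAULT_BOUNDS, **(bounds or {})}
    for nm in names:
        if bnds[nm][0] <= 0 or not np.isfinite(bnds[nm]).all():
            raise ValueError(f"bounds for {nm} must be finite and positive")
    mig_names = {"M12", "M21", "MI12", "MI21"}

    def coord_bounds(nm):
        if use_flux and nm in mig_names:
            return FLUX_BOUNDS
        return bnds[nm]

    lo = np.log10([coord_bounds(p)[0] for p in names])
    hi = np.log10([coord_bounds(p)[1] for p in names])
    rng = np.random.default_rng(seed)

    def decode(xlog) -> DemographyParams:
        return _expand_symmetric(
            _vector_to_params(10.0 ** np.asarray(xlog), names, base,
                              use_flux), names)

    def objective(xlog, reps=engine_reps):
        over = np.maximum(xlog - hi, 0) + np.maximum(lo - xlog, 0)
        if over.any():
            return 1e8 * (1.0 + over.sum())
        p = decode(xlog)
        for m in mig_names:
            val = getattr(p, m)
            if val and not bnds[m][0] <= val <= bnds[m][1]:
                return 1e8
        try:
            model = expected_jafs(p, model_id, n1, n2, nreps=reps,
                                  engine_seed=engine_seed)
            lnl, _ = loglik(observed, model)
        except (EnginePrecisionError, ValueError):
            return 1e8
        return -lnl

    if not names:  # all parameters fixed: evaluate the point
        model = expected_jafs(base, model_id, n1, n2, nreps=engine_reps,
                              engine_seed=engine_seed)
        lnl, theta_hat = loglik(observed, model)
        reps = pd.DataFrame({"run": [0], "lnL": [lnl],
                             "AIC": [-2.0 * lnl], "converged": [True],
                             "best5": [True]})
        return FitResult(model_id, base.replace(theta=theta_hat), lnl, 0,
                         theta_hat, reps, seed)

    # stage 1: coarse probes
    grids = []
    for nm in names:
        g = PROBE_GRID.get(nm, [bnds[nm][0], np.sqrt(np.prod(bnds[nm])),
                                bnds[nm][1]])
        if use_flux and nm in mig_names:
            g = [0.01, 0.05, 0.2, 1.0, 5.0]  # flux scale
        grids.append(np.log10(g))
    mesh = np.meshgrid(*grids, indexing="ij")
    probes = np.stack([m.ravel() for m in mesh], axis=1)
    probes = np.clip(probes, lo, hi)
    if len(probes) > probe_budget:
        probes = probes[rng.choice(len(probes), probe_budget,
                                   replace=False)]
    probe_reps = max(engine_reps // 5, 200)
    scores = np.array([objective(x, probe_reps) for x in probes])
    order = np.argsort(scores)

    # stage 2: simplex runs from top probes, then perturbations of best
    nm_opts = {"maxiter": maxiter, "fatol": fatol, "xatol": 1e-3,
               "adaptive": True}
    n_probe_starts = min(4, n_starts)
    best_f, best_x = np.inf, probes[order[0]]
    rows = []
    for run in range(n_starts):
        if run < n_probe_starts:
            x0 = probes[order[run]]
        else:
            x0 = np.clip(best_x + np.log10(rng.uniform(1 / 3, 3,
                                                       len(names))),
                         lo, hi)
        res = minimize(objective, x0, method="Nelder-Mead",
                       options=nm_opts)
        p_run = decode(res.x)
        rows.append({"run": run, "lnL": -res.fun,
                     "converged": bool(res.fun < 1e7),
                     **{nm: getattr(p_run, nm) for nm in names}})
        if res.fun < best_f:
            best_f, best_x = res.fun, res.x

    # stage 3: coordinate line scans from the best point -- cheap escapes
    # from ridge-stuck simplexes (the flux transform makes the weakly
    # identified directions axis-aligned) -- then a simplex from any
    # improvement found
    for _ in range(2):
        moved = False
        for dim in range(len(names)):
            scan = np.linspace(lo[dim], hi[dim], 9)
            trial = np.repeat(best_x[None, :], len(scan), axis=0)
            trial[:, dim] = scan
            vals = [objective(x) for x in trial]
            if np.min(vals) < best_f - 2.0 * fatol:
                best_f, best_x = np.min(vals), trial[int(np.argmin(vals))]
                moved = True
        if moved:
            res = minimize(objective, best_x, method="Nelder-Mead",
                           options=nm_opts)
            if res.fun < best_f:
                best_f, best_x = res.fun, res.x
        else:
            break

    # stage 4 (optional): polish at higher engine precision
    if polish:
        res = minimize(objective, best_x, method="Nelder-Mead",
                       args=(engine_reps * 5,),
                       options={**nm_opts,
                                "maxiter": max(maxiter // 2, 100)})
        if res.fun < best_f:
            best_f, best_x = res.fun, res.x

    k = len(names)
    reps = pd.DataFrame(rows)
    reps["AIC"] = 2.0 * k - 2.0 * reps["lnL"]
    reps = reps.sort_values("AIC", kind="stable").reset_index(drop=True)
    reps["best5"] = np.arange(len(reps)) < 5
    if not reps["converged"].any():
        raise RuntimeError("all optimization runs failed to converge")
    best_p = decode(best_x)
    model = expected_jafs(best_p, model_id, n1, n2,
                          nreps=engine_reps * 5, engine_seed=engine_seed)
    lnl, theta_hat = loglik(observed, model)
    warnings = []
    pinned = [nm for i, nm in enumerate(names)
              if best_x[i] <= lo[i] + 1e-6 or best_x[i] >= hi[i] - 1e-6]
    if pinned:
        warnings.append("optimum pinned at bounds: " + ", ".join(pinned))
    return FitResult(model_id, best_p.replace(theta=theta_hat), lnl, k,
                     theta_hat, reps, seed, warnings)


def compare_models(observed: Jafs, model_ids, **fit_kwargs) -> pd.DataFrame:
    """Fit several models and rank them by AIC (ascending).

    Failed fits are recorded with the error message and excluded from the
    delta-AIC ranking.
    """
    model_ids = list(model_ids)
    if len(model_ids) < 2:
        raise ValueError("need at least two models to compare")
    rows = []
    fits = {}
    for mid in model_ids:
        try:
            res = fit(observed, mid, **fit_kwargs)
            fits[mid] = res
            rows.append({"model": mid, "k": res.k, "lnL": res.lnL,
                         "AIC": res.AIC, "error": ""})
        except Exception as err:  # propagate per-model failures as rows
            rows.append({"model": mid, "k": np.nan, "lnL": np.nan,
                         "AIC": np.nan, "error": str(err)})
    table = pd.DataFrame(rows).sort_values(
        "AIC", kind="stable", na_position="last").reset_index(drop=True)
    table["dAIC"] = table["AIC"] - table["AIC"].min()
    table.attrs["fits"] = fits
    return table
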