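"""Demographic model family for two-deme divergence with gene flow.

The model ids combine a divergence scenario with optional heterogeneity
flags:

* ``SI``  -- strict isolation: split at ``t_s``, no migration;
* ``IM``  -- isolation with migration: continuous migration since the split;
* ``SC``  -- secondary contact: isolation after the split, migration resumes
  at ``t_sc`` (measured backward from the present, ``t_sc <= t_s``);
* suffix ``2M``  -- a fraction ``P`` of loci ("genomic islands") experiences
  reduced island migration rates ``MI12``/``MI21`` instead of ``M12``/``M21``;
* suffix ``_hrf`` -- a fraction ``Q`` of loci has all effective sizes
  multiplied by ``hrf`` in (0, 1], emulating linked selection.

Times are in units of 2*N_A generations, sizes relative to the ancestral
population, and migration rates are population rates ``M = 2*N_A*m``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["DemographyParams", "MODEL_IDS", "free_params", "locus_classes",
           "class_probs", "epoch_args", "validate"]

#: canonical parameter order used by the optimizer
PARAM_ORDER = ("nu1", "nu2", "t_s", "t_sc", "M12", "M21", "MI12", "MI21",
               "P", "Q", "hrf")

BASE_MODELS = ("SI", "IM", "SC")
MODEL_IDS = tuple(
    base + flags
    for base in BASE_MODELS
    for flags in ("", "2M", "_hrf", "2M_hrf")
    if not (base == "SI" and "2M" in flags)  # no migration to heterogenize
)


@dataclass
class DemographyParams:
    """Scaled parameters of the two-deme divergence model.

    nu1, nu2 : deme sizes relative to the ancestral size N_A
    t_s      : split time, units of 2*N_A generations
    t_sc     : secondary-contact time (SC models only), t_sc <= t_s
    M12, M21 : population migration rates 2*N_A*m into pop1 / into pop2
    MI12, MI21 : island-class migration rates (2M models only)
    P        : fraction of loci in the island class
    Q        : fraction of loci with linked-selection size reduction
    hrf      : size-reduction factor for the Q fraction, in (0, 1]
    theta    : dataset mutation-rate scaling, theta_A = 4*N_A*mu*L
    """

    nu1: float = 1.0
    nu2: float = 1.0
    t_s: float = 1.0
    t_sc: float = 0.0
    M12: float = 0.0
    M21: float = 0.0
    MI12: float = 0.0
    MI21: float = 0.0
    P: float = 0.0
    Q: float = 0.0
    hrf: float = 1.0
    theta: float | None = None

    def replace(self, **kw) -> "DemographyParams":
        return replace(self, **kw)

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in PARAM_ORDER}


def free_params(model_id: str, symmetric_m: bool = False) -> list[str]:
    """Names of the free parameters of ``model_id``, in optimizer order.

    With ``symmetric_m`` the two directions share one rate (M21 and MI21
    are tied to M12 and MI12 and do not appear).
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model id: {model_id!r}")
    names = ["nu1", "nu2", "t_s"]
    base = model_id.split("2M")[0].split("_")[0]
    has_mig = base in ("IM", "SC")
    if base == "SC":
        names.append("t_sc")
    if has_mig:
        names.append("M12")
        if not symmetric_m:
            names.append("M21")
    if "2M" in model_id:
        names.append("MI12")
        if not symmetric_m:
            names.append("MI21")
        names.append("P")
    if "hrf" in model_id:
        names += ["Q", "hrf"]
    return names


def locus_classes(model_id: str) -> list[str]:
    classes = ["neutral"]
    if "2M" in model_id:
        classes.append("island")
    if "hrf" in model_id:
        classes.append("hrf")
    if "2M" in model_id and "hrf" in model_id:
        classes.append("island_hrf")
    return classes


def class_probs(params: DemographyParams, model_id: str) -> dict[str, float]:
    """Mixture weights of the locus classes; P and Q act independently."""
    P = params.P if "2M" in model_id else 0.0
    Q = params.Q if "hrf" in model_id else 0.0
    probs = {"neutral": (1 - P) * (1 - Q)}
    if "2M" in model_id:
        probs["island"] = P * (1 - Q)
    if "hrf" in model_id:
        probs["hrf"] = (1 - P) * Q
    if "2M" in model_id and "hrf" in model_id:
        probs["island_hrf"] = P * Q
    return probs


def epoch_args(params: DemographyParams, model_id: str,
               locus_class: str = "neutral") -> tuple:
    """Kernel arguments ``(nu1, nu2, t_s, t_mig, m1, m2, size_anc)``.

    ``t_mig`` is the backward time at which migration switches off: 0 for
    SI, ``t_s`` for IM, ``t_sc`` for SC.  Island-class loci use the island
    migration rates in every migration-active epoch; hrf-class loci have
    all deme sizes (including the ancestral deme) scaled by ``hrf``.
    """
    base = model_id.split("2M")[0].split("_")[0]
    if base == "SI":
        t_mig = 0.0
    elif base == "IM":
        t_mig = params.t_s
    else:
        t_mig = params.t_sc
    island = locus_class in ("island", "island_hrf")
    m1 = params.MI12 if island else params.M12
    m2 = params.MI21 if island else params.M21
    scale = params.hrf if locus_class in ("hrf", "island_hrf") else 1.0
    return (params.nu1 * scale, params.nu2 * scale, params.t_s, t_mig,
            m1, m2, scale)


def validate(params: DemographyParams, model_id: str) -> None:
    p = params
    vals = [p.nu1, p.nu2, p.t_s, p.t_sc, p.M12, p.M21, p.MI12, p.MI21]
    if not all(np.isfinite(v) and v >= 0 for v in vals):
        raise ValueError("demographic parameters must be finite and >= 0")
    if p.nu1 <= 0 or p.nu2 <= 0:
        raise ValueError("deme sizes nu1, nu2 must be > 0")
    if model_id.startswith("SC") and p.t_sc > p.t_s:
        raise ValueError(f"t_sc ({p.t_sc}) must not exceed t_s ({p.t_s})")
    if not (0.0 <= p.P <= 1.0 and 0.0 <= p.Q <= 1.0):
        raise ValueError("P and Q must lie in [0, 1]")
    if not (0.0 < p.hrf <= 1.0):
        raise ValueError("hrf must lie in (0, 1]")
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model id: {model_id!r}")
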