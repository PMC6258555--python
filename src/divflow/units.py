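"""Convert mutation-scaled demographic estimates to biological units.

Calibration follows the outgroup-divergence route: the per-site divergence
``d_out`` to an outgroup that split ``T_div_years`` ago gives the yearly
mutation rate ``mu = (d_out / 2) / T_div_years``; the ancestral effective
size then follows from the fitted mutation scaling ``theta = 4*N_A*mu_gen*L``
and all other scaled quantities convert linearly:

    N_i = nu_i * N_A
    T   = 2 * N_A * t          (generations)
    m_ij = M_ij / (2 * N_A)    (migrant fraction per generation)
    migrants_i = nu_i * M_ij   (gene copies per generation)
"""

from __future__ import annotations

from dataclasses import dataclass

from .models import DemographyParams

__all__ = ["CalibrationInputs", "BiologicalEstimates", "estimate_mu",
           "convert"]


@dataclass
class CalibrationInputs:
    """Inputs needed to put scaled estimates on a biological scale.

    d_out : average per-site nucleotide difference to the outgroup.
    T_div_years : outgroup divergence time in years.
    L : total callable sequence length (bp) behind the fitted spectrum.
    gen_per_year : generations per year (default 1; exposed, not asserted).
    """

    d_out: float
    T_div_years: float
    L: float
    gen_per_year: float = 1.0

    def __post_init__(self):
        for name in ("d_out", "T_div_years", "L", "gen_per_year"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class BiologicalEstimates:
    mu: float                  # mutations / site / year
    N_A: float                 # ancestral effective size, individuals
    N1: float
    N2: float
    T_S: float                 # years
    T_SC: float                # years
    m12: float                 # migrant fraction per generation, into pop1
    m21: float
    mI12: float
    mI21: float
    migrants12: float          # gene copies per generation into pop1
    migrants21: float


def estimate_mu(d_out: float, T_div_years: float) -> float:
    """Yearly mutation rate from outgroup divergence: (d_out/2) / T."""
    if not d_out > 0 or not T_div_years > 0:
        raise ValueError("d_out and T_div_years must be > 0")
    return (d_out / 2.0) / T_div_years


def convert(params: DemographyParams,
            calib: CalibrationInputs) -> BiologicalEstimates:
    """Convert a fitted parameter vector into biological units."""
    if params.theta is None:
        raise ValueError("params.theta must be set (fit the model first)")
    mu = estimate_mu(calib.d_out, calib.T_div_years)
    mu_gen = mu / calib.gen_per_year
    N_A = params.theta / (4.0 * mu_gen * calib.L)
    gens_per_unit = 2.0 * N_A
    years = gens_per_unit / calib.gen_per_year
    return BiologicalEstimates(
        mu=mu,
        N_A=N_A,
        N1=params.nu1 * N_A,
        N2=params.nu2 * N_A,
        T_S=params.t_s * years,
        T_SC=params.t_sc * years,
        m12=params.M12 / (2.0 * N_A),
        m21=params.M21 / (2.0 * N_A),
        mI12=params.MI12 / (2.0 * N_A),
        mI21=params.MI21 / (2.0 * N_A),
        migrants12=params.nu1 * params.M12,
        migrants21=params.nu2 * params.M21,
    )
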