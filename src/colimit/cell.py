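"""Steady-state colimitation model of autotrophic growth.

A single well-mixed cell exchanges CO2 and HCO3- with its environment and
consumes both: CO2 through rubisco carboxylation (most of biomass carbon)
and HCO3- through the anabolic "bicarboxylation" reactions of lipid,
nucleotide and arginine biosynthesis (a small minority, fraction ``f_H``).
Intracellular pools obey a pair of linear ODEs:

    dC/dt = alpha (C_out - C) + (k_d + delta/K_in) H - (k_h + delta) C - gamma C
    dH/dt = chi S_ext + beta (H_out - H) + (k_h + delta) C
            - (k_d + delta/K_in) H - phi H

with
    alpha = P_C * SA/V    passive CO2 membrane exchange (1/s)
    beta  = P_H * SA/V    passive HCO3- membrane exchange (1/s)
    gamma                  rubisco activity, [sites] * kcat/KM (1/s)
    delta                  carbonic anhydrase enhancement of hydration (1/s),
                           applied Haldane-consistently in both directions
    chi                    energized Ci uptake (1/s, first-order in the
                           external substrate S_ext; product is cytosolic
                           HCO3- for both DAB-like and SbtA-like systems)
    phi                    bicarboxylation activity (1/s)
    K_in = [HCO3-]/[CO2] equilibrium ratio at cytosolic pH, k_d = k_h/K_in.

Setting the right-hand sides to zero gives a 2x2 linear solve with a unique
nonnegative solution for all valid parameters.  Growth follows Liebig's law
of the minimum over the two carboxylation fluxes against their
stoichiometric demands.  Enzyme saturation and rubisco oxygenation are
deliberately omitted; the model is linear by construction and meant for
coarse, order-of-magnitude reasoning.

Units: concentrations uM, rate constants 1/s, fluxes uM/s (per cell
volume), growth rates 1/h.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from .chemistry import (
    CarbonateParams,
    Environment,
    dehydration_rate,
    dissolved_co2,
    equilibrium_ratio,
)

__all__ = [
    "CellParams",
    "SteadyState",
    "FluxReport",
    "GrowthPrediction",
    "DegenerateParameterError",
    "DEFAULT_QC_UM",
    "boundary_concentrations",
    "steady_state",
    "fluxes",
    "growth_rate",
    "evaluate",
    "naive_depletion_ratio",
    "max_rubisco_site_concentration",
    "percell_fixation_rate",
]

AVOGADRO = 6.02214076e23

#: Biomass carbon demand expressed as a concentration over the cell volume
#: (uM).  ~1e10 carbon atoms per 1 fL cell = 1.66e7 uM.  Growth rate mu
#: (1/h) then satisfies J_B = mu * q_C / 3600 in uM/s.
DEFAULT_QC_UM = 1.66e7


class DegenerateParameterError(ValueError):
    """The steady-state system is singular (no removal path for a pool)."""


@dataclass(frozen=True)
class CellParams:
    """Cell-level rate constants and geometry of the colimitation model.

    Defaults describe a ~1 fL bacterium with measured-range CO2 membrane
    permeability (P_C = 0.3 cm/s, so alpha ~ 1e4 1/s), HCO3- permeability
    orders of magnitude lower, rubisco at a few percent of soluble protein
    (gamma = 50 1/s; the theoretical ceiling at 20% of soluble protein is
    ~1e3 1/s), and no CA or Ci uptake (delta = chi = 0).
    """

    P_C: float = 0.3            # membrane CO2 permeability, cm/s
    P_H: float = 3e-6           # membrane HCO3- permeability, cm/s
    sa_v: float = 3.3e4         # surface-to-volume ratio, 1/cm
    gamma: float = 50.0         # rubisco consumption rate constant, 1/s
    delta: float = 0.0          # CA catalytic enhancement, 1/s
    chi: float = 0.0            # energized Ci uptake rate constant, 1/s
    phi: float = 1.0            # bicarboxylation rate constant, 1/s
    f_H: float = 0.02           # fraction of biomass carbon from HCO3-
    volume_L: float = 1e-15     # cell volume, L
    uptake_substrate: Literal["co2", "hco3"] = "co2"

    def __post_init__(self) -> None:
        for name in ("P_C", "P_H", "sa_v", "gamma", "delta", "chi", "phi"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative, got {getattr(self, name)}")
        if not 0.0 < self.f_H < 0.5:
            raise ValueError(f"f_H must lie in (0, 0.5), got {self.f_H}")
        if not self.volume_L > 0:
            raise ValueError("volume_L must be positive")
        if self.uptake_substrate not in ("co2", "hco3"):
            raise ValueError(f"unknown uptake_substrate {self.uptake_substrate!r}")

    @property
    def alpha(self) -> float:
        """Effective CO2 exchange rate P_C * SA/V (1/s)."""
        return self.P_C * self.sa_v

    @property
    def beta(self) -> float:
        """Effective HCO3- exchange rate P_H * SA/V (1/s)."""
        return self.P_H * self.sa_v

    def with_rates(self, **kwargs: float) -> "CellParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class SteadyState:
    """Intracellular pools and the boundary concentrations they saw (uM)."""

    C_in: float
    H_in: float
    C_out: float
    H_out: float

    def as_dict(self) -> dict:
        return {
            "C_in_uM": self.C_in,
            "H_in_uM": self.H_in,
            "C_out_uM": self.C_out,
            "H_out_uM": self.H_out,
        }


@dataclass(frozen=True)
class FluxReport:
    """All fluxes of one steady state, in uM/s per cell volume.

    Leakage sign convention: positive = net outflow across the membrane.
    ``leak_ratio`` is J_L,tot / J_B, the futile-cycling measure.
    """

    J_rub: float
    J_bic: float
    J_B: float
    J_L_C: float
    J_L_H: float
    J_L_tot: float
    J_chi: float
    leak_ratio: float

    def as_dict(self) -> dict:
        return {f"{k}_uM_per_s": v for k, v in self.__dict__.items() if k != "leak_ratio"} | {
            "leak_ratio": self.leak_ratio
        }


@dataclass(frozen=True)
class GrowthPrediction:
    """Liebig-colimited growth rate and the regime that set it."""

    growth_rate: float  # 1/h
    limiting_regime: Literal["rubisco_limited", "bicarboxylation_limited"]
    doubling_time: float  # h; inf when growth_rate == 0

    def as_dict(self) -> dict:
        return {
            "growth_rate_per_h": self.growth_rate,
            "limiting_regime": self.limiting_regime,
            "doubling_time_h": self.doubling_time,
        }


def boundary_concentrations(
    env: Environment, chem: CarbonateParams = CarbonateParams()
) -> tuple[float, float]:
    """Extracellular (C_out, H_out) in uM, assuming carbonate equilibrium outside."""
    C_out = dissolved_co2(env, chem)
    H_out = C_out * equilibrium_ratio(env.pH_out, chem)
    return C_out, H_out


def _system(cell: CellParams, env: Environment, chem: CarbonateParams):
    """Matrix form A x = b of the zeroed ODEs, x = (C_in, H_in)."""
    C_out, H_out = boundary_concentrations(env, chem)
    K_in = equilibrium_ratio(env.pH_in, chem)
    k_d = dehydration_rate(env.pH_in, chem)
    kh_eff = chem.k_h + cell.delta
    kd_eff = k_d + cell.delta / K_in
    S_ext = C_out if cell.uptake_substrate == "co2" else H_out
    A = np.array(
        [
            [cell.alpha + kh_eff + cell.gamma, -kd_eff],
            [-kh_eff, cell.beta + kd_eff + cell.phi],
        ]
    )
    b = np.array([cell.alpha * C_out, cell.chi * S_ext + cell.beta * H_out])
    return A, b, C_out, H_out, S_ext


def steady_state(
    cell: CellParams,
    env: Environment,
    chem: CarbonateParams = CarbonateParams(),
) -> SteadyState:
    """Solve the 2x2 linear steady state for the intracellular pools.

    Raises
    ------
    DegenerateParameterError
        If a pool has no removal path while receiving input (singular system),
        e.g. all of beta, phi, delta zero with a vanishing dehydration rate.
    """
    A, b, C_out, H_out, _ = _system(cell, env, chem)
    det = A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]
    scale = math.hypot(A[0, 0], A[0, 1]) * math.hypot(A[1, 0], A[1, 1])
    if not math.isfinite(det) or abs(det) <= 1e-14 * max(scale, 1.0):
        raise DegenerateParameterError(
            "steady-state system is singular for these parameters "
            f"(det={det:.3g}); a pool has no effective removal path"
        )
    C_in, H_in = (float(v) for v in np.linalg.solve(A, b))
    # A is an M-matrix and b >= 0, so the solution is nonnegative up to roundoff.
    floor = -1e-9 * max(C_out, H_out, 1.0)
    if C_in < floor or H_in < floor:
        raise AssertionError(
            f"negative steady state (C_in={C_in}, H_in={H_in}): "
            "internal consistency violation"
        )
    return SteadyState(C_in=max(C_in, 0.0), H_in=max(H_in, 0.0), C_out=C_out, H_out=H_out)


def fluxes(ss: SteadyState, cell: CellParams) -> FluxReport:
    """All fluxes implied by a steady state (uM/s per cell volume).

    Checks the steady-state conservation identity
    J_chi - J_L,tot = J_rub + J_bic to 1e-9 relative tolerance.
    """
    J_rub = cell.gamma * ss.C_in
    J_bic = cell.phi * ss.H_in
    J_B = J_rub + J_bic
    J_L_C = cell.alpha * (ss.C_in - ss.C_out)
    J_L_H = cell.beta * (ss.H_in - ss.H_out)
    J_L_tot = J_L_C + J_L_H
    S_ext = ss.C_out if cell.uptake_substrate == "co2" else ss.H_out
    J_chi = cell.chi * S_ext
    residual = J_chi - J_L_tot - J_B
    # roundoff propagates from the gross exchange terms, so the relative
    # tolerance is anchored to the gross turnover, not the (possibly
    # cancelling) net fluxes
    gross = cell.alpha * max(ss.C_in, ss.C_out) + cell.beta * max(ss.H_in, ss.H_out)
    scale = max(abs(J_chi), abs(J_L_tot), abs(J_B), gross, 1e-300)
    if abs(residual) > 1e-9 * scale:
        raise AssertionError(
            f"flux conservation violated: residual {residual:.3e} at scale {scale:.3e}"
        )
    leak_ratio = J_L_tot / J_B if J_B > 0 else math.nan
    return FluxReport(
        J_rub=J_rub,
        J_bic=J_bic,
        J_B=J_B,
        J_L_C=J_L_C,
        J_L_H=J_L_H,
        J_L_tot=J_L_tot,
        J_chi=J_chi,
        leak_ratio=leak_ratio,
    )


def growth_rate(
    fr: FluxReport,
    cell: CellParams,
    q_C_uM: float = DEFAULT_QC_UM,
    law: Literal["liebig", "harmonic"] = "liebig",
    mu_max: float | None = None,
) -> GrowthPrediction:
    """Colimited growth rate (1/h) from the two carboxylation fluxes.

    Liebig's law of the minimum (default):

        mu = 3600 * min( J_rub / ((1 - f_H) q_C),  J_bic / (f_H q_C) )

    The limiting regime is the argmin; exact ties break to
    ``rubisco_limited``.  ``law="harmonic"`` substitutes the smooth
    harmonic-mean alternative for sensitivity analysis.  ``mu_max``
    optionally caps the rate, emulating saturation of some other resource;
    it is off by default and never used by the package's own analyses.
    """
    if not q_C_uM > 0:
        raise ValueError(f"q_C must be positive, got {q_C_uM}")
    mu_rub = 3600.0 * fr.J_rub / ((1.0 - cell.f_H) * q_C_uM)
    mu_bic = 3600.0 * fr.J_bic / (cell.f_H * q_C_uM)
    if law == "liebig":
        mu = min(mu_rub, mu_bic)
    elif law == "harmonic":
        mu = 0.0 if (mu_rub == 0.0 or mu_bic == 0.0) else 1.0 / (1.0 / mu_rub + 1.0 / mu_bic)
    else:
        raise ValueError(f"unknown colimitation law {law!r}")
    regime = "rubisco_limited" if mu_rub <= mu_bic else "bicarboxylation_limited"
    if mu_max is not None:
        mu = min(mu, mu_max)
    doubling = math.log(2.0) / mu if mu > 0 else math.inf
    return GrowthPrediction(growth_rate=mu, limiting_regime=regime, doubling_time=doubling)


def evaluate(
    cell: CellParams,
    env: Environment,
    chem: CarbonateParams = CarbonateParams(),
    q_C_uM: float = DEFAULT_QC_UM,
    law: Literal["liebig", "harmonic"] = "liebig",
    mu_max: float | None = None,
) -> tuple[SteadyState, FluxReport, GrowthPrediction]:
    """Steady state, fluxes and growth prediction for one cell in one environment."""
    ss = steady_state(cell, env, chem)
    fr = fluxes(ss, cell)
    gp = growth_rate(fr, cell, q_C_uM=q_C_uM, law=law, mu_max=mu_max)
    return ss, fr, gp


def naive_depletion_ratio(alpha: float, gamma: float) -> float:
    """Closed-form C_in/C_out when only passive exchange and rubisco act.

    alpha/(alpha + gamma): with alpha ~ 1e4 1/s and even the ceiling
    gamma = 1e3 1/s this exceeds 0.9, i.e. rubisco cannot draw
    intracellular CO2 beneath 90% of the external level.
    """
    if not alpha > 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    if gamma < 0:
        raise ValueError(f"gamma must be nonnegative, got {gamma}")
    return alpha / (alpha + gamma)


def max_rubisco_site_concentration(
    fraction_of_soluble_protein: float,
    total_soluble_protein_mg_per_ml: float = 300.0,
    mass_per_site_kDa: float = 60.0,
) -> float:
    """Rubisco active-site concentration (mM) from a protein budget.

    (fraction x total mg/ml) / (kDa per site): 20% of 300 mg/ml soluble
    protein at 60 kDa per active site gives the ~1 mM ceiling.
    """
    if fraction_of_soluble_protein < 0:
        raise ValueError("fraction must be nonnegative")
    if not total_soluble_protein_mg_per_ml > 0 or not mass_per_site_kDa > 0:
        raise ValueError("protein concentration and site mass must be positive")
    mass_mg_per_ml = fraction_of_soluble_protein * total_soluble_protein_mg_per_ml
    # mg/ml = g/L; dividing by (kDa * 1000 g/mol) gives mol/L; x1000 -> mM
    return mass_mg_per_ml / mass_per_site_kDa


def percell_fixation_rate(
    cell: CellParams,
    env: Environment,
    chem: CarbonateParams = CarbonateParams(),
    demand_molecules: float = 1e10,
) -> tuple[float, float]:
    """Per-cell rubisco fixation rate (molecules/h) in the naive model.

    Uses the steady state with CA and Ci uptake switched off (delta = chi
    = 0), i.e. passive CO2 entry balancing rubisco consumption, and
    returns ``(rate, implied_doubling_h)`` where the doubling time is the
    per-cell carbon demand divided by the fixation rate.
    """
    if not cell.volume_L > 0:
        raise ValueError("volume must be positive")
    if not demand_molecules > 0:
        raise ValueError("carbon demand must be positive")
    naive = cell.with_rates(delta=0.0, chi=0.0)
    ss = steady_state(naive, env, chem)
    # uM/s -> mol/s over the cell volume -> molecules/h
    rate = cell.gamma * ss.C_in * 1e-6 * cell.volume_L * AVOGADRO * 3600.0
    doubling = demand_molecules / rate if rate > 0 else math.inf
    return rate, doubling
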