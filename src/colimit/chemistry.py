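"""Carbonate-system equilibria and uncatalyzed interconversion kinetics.

Dissolved CO2 and bicarbonate interconvert through the slow spontaneous
hydration/dehydration reactions

    CO2 + H2O  <-- k_h -->  HCO3- + H+        (k_h ~ 0.04 1/s at 25 C)

At fixed pH the pair behaves as a two-pool linear system whose equilibrium
ratio [HCO3-]/[CO2] follows Henderson-Hasselbalch with the effective first
pKa of carbonic acid (~6.35).  These constants supply the boundary
conditions and rate constants used by the cell model: Henry's law sets the
extracellular CO2 concentration from the partial pressure, the equilibrium
ratio sets extracellular HCO3-, and k_h (with its Haldane-consistent
reverse rate) appears inside the cytosolic mass balances.

Carbonate ion (CO3 2-) and carbamates are ignored: both are negligible
below pH ~8 and absent from the model.  Constants are fixed at 25 C; the
model is built for order-of-magnitude comparisons, not marine-CO2-system
accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "CarbonateParams",
    "Environment",
    "dissolved_co2",
    "equilibrium_ratio",
    "dehydration_rate",
    "relaxation_time",
]


@dataclass(frozen=True)
class CarbonateParams:
    """Physicochemical constants of the CO2/HCO3- system.

    Parameters
    ----------
    k_h : float
        Uncatalyzed CO2 hydration rate constant (1/s).
    pK1_eff : float
        Effective first acid dissociation constant of CO2/HCO3- (pH units),
        lumping carbonic acid with dissolved CO2.
    K_H : float
        Henry's-law solubility of CO2 (mol L-1 atm-1).
    temperature_C : float
        Nominal temperature of the constants (degrees C). Informational;
        no temperature correction is applied.
    """

    k_h: float = 0.037
    pK1_eff: float = 6.35
    K_H: float = 0.034
    temperature_C: float = 25.0

    def __post_init__(self) -> None:
        if not self.k_h > 0:
            raise ValueError(f"k_h must be positive, got {self.k_h}")
        if not 5.0 < self.pK1_eff < 8.0:
            raise ValueError(f"pK1_eff must lie in (5, 8), got {self.pK1_eff}")
        if not self.K_H > 0:
            raise ValueError(f"K_H must be positive, got {self.K_H}")


@dataclass(frozen=True)
class Environment:
    """One growth condition: CO2 partial pressure and pH on both membrane sides.

    ``pCO2`` is a fraction of 1 bar (0.0004 = present-day ambient air).
    The five assay conditions modeled throughout the package are ambient
    (0.04%), 0.5%, 1.5%, 5% and 10% CO2.
    """

    pCO2: float
    pH_out: float = 7.0
    pH_in: float = 7.0
    total_pressure_atm: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pCO2 <= 1.0:
            raise ValueError(f"pCO2 must lie in [0, 1], got {self.pCO2}")
        for name in ("pH_out", "pH_in"):
            val = getattr(self, name)
            if not 4.0 <= val <= 10.0:
                raise ValueError(f"{name} must lie in [4, 10], got {val}")
        if not self.total_pressure_atm > 0:
            raise ValueError("total_pressure must be positive")


#: The five experimental CO2 levels (fractions of 1 bar).
ASSAY_PCO2 = (0.0004, 0.005, 0.015, 0.05, 0.10)


def dissolved_co2(env: Environment, params: CarbonateParams = CarbonateParams()) -> float:
    """Equilibrium dissolved CO2 concentration (uM) by Henry's law.

    Strictly linear in ``pCO2``: K_H * pCO2 * P_total, converted to uM.
    At 0.04% CO2 and K_H = 0.034 M/atm this is ~13.6 uM, inside the
    10-20 uM range expected for water equilibrated with the present-day
    atmosphere.
    """
    if env.pCO2 < 0:  # Environment validates, but guard direct misuse
        raise ValueError("pCO2 must be nonnegative")
    return params.K_H * env.pCO2 * env.total_pressure_atm * 1e6


def equilibrium_ratio(pH: float, params: CarbonateParams = CarbonateParams()) -> float:
    """Equilibrium [HCO3-]/[CO2] ratio at the given pH (dimensionless).

    Henderson-Hasselbalch: 10**(pH - pK1_eff).  Monotone increasing in pH;
    equals 1 at pH = pK1_eff and rises tenfold per pH unit.
    """
    if not 4.0 <= pH <= 10.0:
        raise ValueError(f"pH must lie in [4, 10], got {pH}")
    return 10.0 ** (pH - params.pK1_eff)


def dehydration_rate(pH: float, params: CarbonateParams = CarbonateParams()) -> float:
    """Spontaneous HCO3- dehydration rate constant k_d (1/s) at the given pH.

    Fixed by detailed balance: k_d = k_h / K_eq(pH), so that
    k_h * [CO2]_eq = k_d * [HCO3-]_eq holds exactly at equilibrium.
    """
    return params.k_h / equilibrium_ratio(pH, params)


def relaxation_time(pH: float, params: CarbonateParams = CarbonateParams()) -> float:
    """e-folding time (s) of the uncatalyzed CO2 <-> HCO3- system at fixed pH.

    The two-pool linear system relaxes at rate k_h + k_d, so
    tau = 1 / (k_h + k_h / K_eq(pH)).  With default constants at pH 7 this
    is ~22 s, consistent with the ~10 s-scale equilibration that makes a
    carbonic anhydrase worth expressing.
    """
    if not params.k_h > 0:
        raise ValueError("k_h must be positive")
    k_d = dehydration_rate(pH, params)
    return 1.0 / (params.k_h + k_d)
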