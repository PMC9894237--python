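"""Parameter-sweep and scenario engines over the colimitation model.

Each sweep is a pure, deterministic function of its grid and parameters
and returns a :class:`SweepResult`: a tidy table (one row per grid point)
plus scenario-specific extras such as zero-leakage contours, depletion
frontiers or the CO2-pump permeability threshold.

Scenarios implemented:

* :func:`growth_vs_ca` - growth rate versus CA activity across a ladder of
  rubisco activities; exposes the rubisco-limited / bicarboxylation-limited
  regime structure.
* :func:`leakage_heatmap` - futile-cycle ratio J_L,tot/J_B over a (delta,
  chi) grid at fixed rubisco activity, with the J_L,tot = 0 contour.
* :func:`depletion_scan` - C_in/C_out over (gamma, P_C) in the naive model
  and the 50%-depletion frontier.
* :func:`pump_scenario` - C_in/C_out versus CO2-permeability reduction
  under high coexpressed CA and Ci uptake; reports the smallest reduction
  factor at which the cell acts as a CO2 pump (C_in/C_out >= 2).
* :func:`co2_titration` - growth versus pCO2 for a list of genotypes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cell import (
    CellParams,
    DEFAULT_QC_UM,
    evaluate,
    fluxes,
    steady_state,
)
from .chemistry import ASSAY_PCO2, CarbonateParams, Environment

__all__ = [
    "Axis",
    "SweepResult",
    "growth_vs_ca",
    "leakage_heatmap",
    "depletion_scan",
    "pump_scenario",
    "co2_titration",
]


@dataclass(frozen=True)
class Axis:
    """A log-spaced sweep axis."""

    name: str
    lo: float
    hi: float
    n: int = 25

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"axis {self.name!r} needs n >= 2, got {self.n}")
        if not 0 < self.lo < self.hi:
            raise ValueError(
                f"axis {self.name!r} needs 0 < lo < hi, got ({self.lo}, {self.hi})"
            )

    @property
    def values(self) -> np.ndarray:
        return np.geomspace(self.lo, self.hi, self.n)


@dataclass
class SweepResult:
    """Tidy sweep output: one row per grid point, plus scenario extras."""

    table: pd.DataFrame
    meta: dict
    extras: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.9g")

    def to_json(self, path=None) -> str:
        payload = {
            "meta": self.meta,
            "extras": {
                k: (v.to_dict(orient="list") if isinstance(v, pd.DataFrame) else v)
                for k, v in self.extras.items()
            },
            "table": self.table.to_dict(orient="list"),
        }
        text = json.dumps(payload, sort_keys=True, indent=1, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _point_row(cell, env, chem, q_C_uM, **coords) -> dict:
    ss, fr, gp = evaluate(cell, env, chem, q_C_uM=q_C_uM)
    return {
        **coords,
        "C_in_uM": ss.C_in,
        "H_in_uM": ss.H_in,
        "C_out_uM": ss.C_out,
        "H_out_uM": ss.H_out,
        "J_rub": fr.J_rub,
        "J_bic": fr.J_bic,
        "J_B": fr.J_B,
        "J_L_C": fr.J_L_C,
        "J_L_H": fr.J_L_H,
        "J_L_tot": fr.J_L_tot,
        "J_chi": fr.J_chi,
        "leak_ratio": fr.leak_ratio,
        "growth_rate_per_h": gp.growth_rate,
        "limiting_regime": gp.limiting_regime,
    }


def growth_vs_ca(
    gamma_ladder: Sequence[float] = (1.0, 10.0, 100.0, 1000.0),
    delta_axis: Axis = Axis("delta", 1e-2, 1e6, 25),
    cell: CellParams = CellParams(),
    env: Environment = Environment(pCO2=0.0004),
    chem: CarbonateParams = CarbonateParams(),
    q_C_uM: float = DEFAULT_QC_UM,
) -> SweepResult:
    """Growth-rate curves versus CA activity for each rubisco activity.

    At low gamma, growth is rubisco limited and essentially flat in delta
    (spontaneous hydration already meets the small anabolic HCO3- demand);
    at high gamma it is bicarboxylation limited and rises with delta until
    the plateau where pools are fully equilibrated.
    """
    gammas = list(gamma_ladder)
    if len(gammas) < 2:
        raise ValueError("gamma_ladder needs at least 2 values")
    rows = [
        _point_row(
            cell.with_rates(gamma=g, delta=d), env, chem, q_C_uM, gamma=g, delta=d
        )
        for g in gammas
        for d in delta_axis.values
    ]
    meta = {
        "scenario": "growth_vs_ca",
        "gamma_ladder_per_s": gammas,
        "delta_axis": [delta_axis.lo, delta_axis.hi, delta_axis.n],
        "pCO2": env.pCO2,
        "q_C_uM": q_C_uM,
    }
    return SweepResult(table=pd.DataFrame(rows), meta=meta)


def _leak_at(cell, env, chem, chi) -> float:
    c = cell.with_rates(chi=chi)
    return fluxes(steady_state(c, env, chem), c).J_L_tot


def leakage_heatmap(
    delta_axis: Axis = Axis("delta", 1e-2, 1e6, 25),
    chi_axis: Axis = Axis("chi", 1e-2, 1e6, 25),
    cell: CellParams = CellParams(),
    env: Environment = Environment(pCO2=0.0004),
    chem: CarbonateParams = CarbonateParams(),
    q_C_uM: float = DEFAULT_QC_UM,
) -> SweepResult:
    """Futile-cycle ratio J_L,tot/J_B over (delta, chi) at fixed gamma.

    Also locates, for each delta, the Ci-uptake activity at which total
    leakage changes sign (J_L,tot = 0: everything pumped in is fixed).
    J_L,tot is affine in chi, negative at chi = 0 (net passive influx
    balances carboxylation) with positive slope, so the root is unique;
    it is found by bisection to 1e-6 relative tolerance.
    """
    rows = [
        _point_row(
            cell.with_rates(delta=d, chi=x), env, chem, q_C_uM, delta=d, chi=x
        )
        for d in delta_axis.values
        for x in chi_axis.values
    ]
    contour = []
    for d in delta_axis.values:
        base = cell.with_rates(delta=d)
        hi = chi_axis.hi
        while _leak_at(base, env, chem, hi) <= 0 and hi < 1e15:
            hi *= 10.0
        if _leak_at(base, env, chem, hi) <= 0:
            contour.append({"delta": d, "chi_zero_leak": np.nan})
            continue
        root = brentq(
            lambda x: _leak_at(base, env, chem, x), 0.0, hi, rtol=1e-6
        )
        contour.append({"delta": d, "chi_zero_leak": root})
    table = pd.DataFrame(rows)
    meta = {
        "scenario": "leakage_heatmap",
        "gamma_per_s": cell.gamma,
        "delta_axis": [delta_axis.lo, delta_axis.hi, delta_axis.n],
        "chi_axis": [chi_axis.lo, chi_axis.hi, chi_axis.n],
        "pCO2": env.pCO2,
        "max_leak_ratio": float(table["leak_ratio"].max()),
    }
    return SweepResult(
        table=table, meta=meta, extras={"zero_leak_contour": pd.DataFrame(contour)}
    )


def depletion_scan(
    gamma_axis: Axis = Axis("gamma", 1.0, 1e3, 25),
    pc_axis: Axis = Axis("P_C", 1e-4, 1.0, 25),
    cell: CellParams = CellParams(),
    env: Environment = Environment(pCO2=0.0004),
    chem: CarbonateParams = CarbonateParams(),
) -> SweepResult:
    """C_in/C_out over (gamma, P_C) in the naive model.

    "Naive" means passive exchange balancing rubisco consumption only
    (delta = chi = phi = 0).  Reports the frontier where the ratio crosses
    0.5: only very high rubisco activity combined with implausibly low CO2
    permeability can deplete intracellular CO2 below half the external
    level.
    """
    naive = cell.with_rates(delta=0.0, chi=0.0, phi=0.0)
    rows = []
    for g in gamma_axis.values:
        for pc in pc_axis.values:
            c = naive.with_rates(gamma=g, P_C=pc)
            ss = steady_state(c, env, chem)
            rows.append(
                {
                    "gamma": g,
                    "P_C": pc,
                    "alpha": c.alpha,
                    "C_in_uM": ss.C_in,
                    "depletion_ratio": ss.C_in / ss.C_out,
                }
            )

    def ratio(g, pc):
        c = naive.with_rates(gamma=g, P_C=pc)
        ss = steady_state(c, env, chem)
        return ss.C_in / ss.C_out

    frontier = []
    for g in gamma_axis.values:
        lo, hi = ratio(g, pc_axis.lo), ratio(g, pc_axis.hi)
        if (lo - 0.5) * (hi - 0.5) > 0:
            frontier.append({"gamma": g, "P_C_half_depletion": np.nan})
            continue
        root = brentq(
            lambda lpc: ratio(g, 10.0**lpc) - 0.5,
            np.log10(pc_axis.lo),
            np.log10(pc_axis.hi),
            rtol=1e-9,
        )
        frontier.append({"gamma": g, "P_C_half_depletion": 10.0**root})
    meta = {
        "scenario": "depletion_scan",
        "gamma_axis": [gamma_axis.lo, gamma_axis.hi, gamma_axis.n],
        "P_C_axis": [pc_axis.lo, pc_axis.hi, pc_axis.n],
        "pCO2": env.pCO2,
    }
    return SweepResult(
        table=pd.DataFrame(rows),
        meta=meta,
        extras={"half_depletion_frontier": pd.DataFrame(frontier)},
    )


def pump_scenario(
    reduction_axis: Axis = Axis("reduction_factor", 1.0, 1e5, 26),
    chi_high: float = 200.0,
    delta_high: float = 1e4,
    cell: CellParams = CellParams(),
    env: Environment = Environment(pCO2=0.0004),
    chem: CarbonateParams = CarbonateParams(),
) -> SweepResult:
    """Could CA + Ci uptake act as a CO2 pump?  Only at low CO2 permeability.

    Scans C_in/C_out as the CO2 permeability is reduced below its baseline
    (P_C within the measured 0.1-1 cm/s range) while CA is fast enough to
    equilibrate the cytosolic pools (``delta_high``) and Ci uptake runs
    several-fold above the total fixation demand (``chi_high``).  "Acting
    as a pump" is operationalized as C_in/C_out >= 2, the smallest
    unambiguous elevation; the threshold reduction factor is refined by
    bisection and recorded in ``extras``.
    """
    if not 0.1 <= cell.P_C <= 1.0:
        raise ValueError(
            f"baseline P_C must lie in the measured range 0.1-1 cm/s, got {cell.P_C}"
        )
    active = cell.with_rates(chi=chi_high, delta=delta_high)

    def ratio(factor: float) -> float:
        c = active.with_rates(P_C=cell.P_C / factor)
        ss = steady_state(c, env, chem)
        return ss.C_in / ss.C_out

    rows = [
        {"reduction_factor": f, "P_C": cell.P_C / f, "C_in_over_C_out": ratio(f)}
        for f in reduction_axis.values
    ]
    table = pd.DataFrame(rows)
    above = table[table["C_in_over_C_out"] >= 2.0]
    threshold_grid = float(above["reduction_factor"].min()) if len(above) else np.nan
    threshold = np.nan
    if len(above) and ratio(reduction_axis.lo) < 2.0:
        lo = np.log10(reduction_axis.lo)
        hi = np.log10(threshold_grid)
        threshold = 10.0 ** brentq(lambda lf: ratio(10.0**lf) - 2.0, lo, hi, rtol=1e-9)
    elif len(above):
        threshold = float(reduction_axis.lo)
    meta = {
        "scenario": "pump_scenario",
        "criterion": "C_in/C_out >= 2 (smallest unambiguous elevation above C_out)",
        "baseline_P_C_cm_per_s": cell.P_C,
        "chi_high_per_s": chi_high,
        "delta_high_per_s": delta_high,
        "pCO2": env.pCO2,
    }
    return SweepResult(
        table=table,
        meta=meta,
        extras={
            "threshold_factor": threshold,
            "threshold_factor_grid": threshold_grid,
        },
    )


def co2_titration(
    genotype_cells: dict[str, CellParams],
    pco2_levels: Sequence[float] = ASSAY_PCO2,
    env_template: Environment = Environment(pCO2=0.0004),
    chem: CarbonateParams = CarbonateParams(),
    q_C_uM: float = DEFAULT_QC_UM,
) -> SweepResult:
    """Growth rate versus pCO2 for each named genotype (CellParams)."""
    if len(pco2_levels) == 0:
        raise ValueError("pCO2 ladder must be nonempty")
    rows = []
    for name, c in genotype_cells.items():
        for p in pco2_levels:
            env = Environment(
                pCO2=p,
                pH_out=env_template.pH_out,
                pH_in=env_template.pH_in,
                total_pressure_atm=env_template.total_pressure_atm,
            )
            rows.append(_point_row(c, env, chem, q_C_uM, genotype=name, pCO2=p))
    meta = {
        "scenario": "co2_titration",
        "pCO2_levels": list(pco2_levels),
        "genotypes": list(genotype_cells),
        "q_C_uM": q_C_uM,
    }
    return SweepResult(table=pd.DataFrame(rows), meta=meta)
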