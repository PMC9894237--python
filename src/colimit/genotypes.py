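"""CCM-component genotypes and acquisition-trajectory scoring.

A CO2-concentrating mechanism decomposes into three acquirable
functionalities beyond rubisco itself: a carbonic anhydrase (CA), an
energized Ci transporter, and carboxysome encapsulation.  A
:class:`GenotypeConfig` switches the first two on or off in the cell model
(CA sets delta, the transporter sets chi); the carboxysome is an
annotation only - encapsulation acts through compartment geometry the
well-mixed model does not represent, so carboxysome steps cannot be
scored mechanistically here.

:func:`enumerate_trajectories` scores all 3! = 6 orderings in which the
three components could have been acquired as atmospheric CO2 declined.
Each acquisition step is evaluated at the next level of a declining pCO2
schedule (default 5% -> 1.5% -> 0.5% -> ambient).  A trajectory is
certified *fitness positive* when every mechanistically scored step is
non-decreasing in growth rate AND every pre-terminal step is scorable -
i.e. the unscorable carboxysome step comes last.  Exactly two orderings
qualify: CA then transporter, and transporter then CA, each followed by
the carboxysome.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cell import CellParams, DEFAULT_QC_UM, evaluate
from .chemistry import ASSAY_PCO2, CarbonateParams, Environment

__all__ = [
    "GenotypeConfig",
    "TrajectoryStep",
    "TrajectoryScore",
    "COMPONENTS",
    "DECLINING_SCHEDULE",
    "evaluate_genotype",
    "enumerate_trajectories",
]

COMPONENTS = ("ca", "transporter", "carboxysome")

#: Declining-CO2 evaluation schedule (fractions of 1 bar), the assay ladder
#: walked downward: 5% -> 1.5% -> 0.5% -> ambient.
DECLINING_SCHEDULE = (0.05, 0.015, 0.005, 0.0004)

# On-state activities.  chi_on is sized to the anabolic HCO3- demand
# (f_H/(1-f_H) * J_rub is ~1 uM/s per uM of C_out at default gamma);
# delta_on is ~270x the spontaneous hydration rate, modest for a CA.
# Both sit inside the zero-leakage-feasible region (J_L,tot < 0).
DELTA_ON = 10.0
CHI_ON = 0.3


@dataclass(frozen=True)
class GenotypeConfig:
    """On/off configuration of CCM components layered onto a base cell."""

    has_ca: bool = False
    has_transporter: bool = False
    has_carboxysome: bool = False  # annotation only, no mechanistic effect
    rubisco_gamma: float = CellParams().gamma
    delta_on: float = DELTA_ON
    chi_on: float = CHI_ON

    def __post_init__(self) -> None:
        if not self.delta_on > 0 or not self.chi_on > 0:
            raise ValueError("delta_on and chi_on must be positive")
        if self.rubisco_gamma < 0:
            raise ValueError("rubisco_gamma must be nonnegative")

    @property
    def label(self) -> str:
        parts = [
            name
            for flag, name in [
                (self.has_ca, "CA"),
                (self.has_transporter, "transporter"),
                (self.has_carboxysome, "carboxysome"),
            ]
            if flag
        ]
        return "rubisco_alone" if not parts else "rubisco+" + "+".join(parts)

    def to_cell(self, base: CellParams = CellParams()) -> CellParams:
        return base.with_rates(
            gamma=self.rubisco_gamma,
            delta=self.delta_on if self.has_ca else 0.0,
            chi=self.chi_on if self.has_transporter else 0.0,
        )

    def with_component(self, component: str) -> "GenotypeConfig":
        if component not in COMPONENTS:
            raise ValueError(f"unknown component {component!r}")
        flags = {
            "has_ca": self.has_ca or component == "ca",
            "has_transporter": self.has_transporter or component == "transporter",
            "has_carboxysome": self.has_carboxysome or component == "carboxysome",
        }
        return GenotypeConfig(
            rubisco_gamma=self.rubisco_gamma,
            delta_on=self.delta_on,
            chi_on=self.chi_on,
            **flags,
        )


def evaluate_genotype(
    genotype: GenotypeConfig,
    pco2_levels: Sequence[float] = ASSAY_PCO2,
    base_cell: CellParams = CellParams(),
    env_template: Environment = Environment(pCO2=0.0004),
    chem: CarbonateParams = CarbonateParams(),
    q_C_uM: float = DEFAULT_QC_UM,
) -> np.ndarray:
    """Model growth rate (1/h) of one genotype at each pCO2 level."""
    cell = genotype.to_cell(base_cell)
    out = []
    for p in pco2_levels:
        env = Environment(
            pCO2=p,
            pH_out=env_template.pH_out,
            pH_in=env_template.pH_in,
            total_pressure_atm=env_template.total_pressure_atm,
        )
        out.append(evaluate(cell, env, chem, q_C_uM=q_C_uM)[2].growth_rate)
    return np.asarray(out)


@dataclass(frozen=True)
class TrajectoryStep:
    component: str
    pCO2: float
    growth_before: float
    growth_after: float
    scored: bool

    @property
    def non_decreasing(self) -> bool | None:
        return self.growth_after >= self.growth_before if self.scored else None


@dataclass
class TrajectoryScore:
    order: tuple[str, ...]
    steps: list[TrajectoryStep] = field(default_factory=list)
    fitness_positive: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "order": "->".join(self.order),
                    "step": i + 1,
                    "component": s.component,
                    "pCO2": s.pCO2,
                    "growth_before_per_h": s.growth_before,
                    "growth_after_per_h": s.growth_after,
                    "scored": s.scored,
                    "fitness_positive": self.fitness_positive,
                }
                for i, s in enumerate(self.steps)
            ]
        )


def enumerate_trajectories(
    schedule: Sequence[float] = DECLINING_SCHEDULE,
    base_cell: CellParams = CellParams(),
    env_template: Environment = Environment(pCO2=0.0004),
    chem: CarbonateParams = CarbonateParams(),
    delta_on: float = DELTA_ON,
    chi_on: float = CHI_ON,
    rubisco_gamma: float | None = None,
    q_C_uM: float = DEFAULT_QC_UM,
) -> list[TrajectoryScore]:
    """Score all six orderings of CCM-component acquisition.

    ``schedule`` is the declining pCO2 ladder; the ancestor is evaluated
    at ``schedule[0]`` and step *i* (acquiring one component) at
    ``schedule[i + 1]``, the environment into which the lineage descends.
    Requires ``len(schedule) >= len(COMPONENTS) + 1``.
    """
    schedule = list(schedule)
    if len(schedule) < len(COMPONENTS) + 1:
        raise ValueError(
            f"schedule needs at least {len(COMPONENTS) + 1} pCO2 levels, "
            f"got {len(schedule)}"
        )
    gamma = base_cell.gamma if rubisco_gamma is None else rubisco_gamma

    def growth(g: GenotypeConfig, pco2: float) -> float:
        return float(
            evaluate_genotype(
                g, [pco2], base_cell, env_template, chem, q_C_uM=q_C_uM
            )[0]
        )

    results = []
    for order in itertools.permutations(COMPONENTS):
        genotype = GenotypeConfig(
            rubisco_gamma=gamma, delta_on=delta_on, chi_on=chi_on
        )
        steps: list[TrajectoryStep] = []
        for i, component in enumerate(order):
            pco2 = schedule[i + 1]
            before = growth(genotype, pco2)
            genotype = genotype.with_component(component)
            after = growth(genotype, pco2)
            steps.append(
                TrajectoryStep(
                    component=component,
                    pCO2=pco2,
                    growth_before=before,
                    growth_after=after,
                    scored=component != "carboxysome",
                )
            )
        scored_ok = all(s.non_decreasing for s in steps if s.scored)
        # The carboxysome step cannot be scored by this model; a trajectory
        # is only certified when every pre-terminal step is demonstrable.
        carboxysome_last = order[-1] == "carboxysome"
        results.append(
            TrajectoryScore(
                order=order,
                steps=steps,
                fitness_positive=bool(scored_ok and carboxysome_last),
            )
        )
    return results
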