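"""Synthetic data generators: barcode libraries and growth curves.

Everything downstream of the wet lab is testable against data simulated
here with known ground truth.

Barcode libraries (:func:`simulate_library`) emulate a pooled transposon
competition assay: each gene carries 30-50 distinct insertion strains
(mean ~40), strain frequencies evolve deterministically over d ~ 6.5-7.5
doublings of competitive growth as

    f_i(end)  proportional to  f_i(0) * 2**(d * (1 + w_i)),

with w_i the per-gene relative fitness (w = 0 neutral), and reads are
drawn multinomially at fixed depth for the T0 and each endpoint sample.
Specifying a gene's intended log2 effect e sets w = e / d, so that the
expected recovered fitness is ~e (exact up to the compositional
normalization by the library-wide expansion).

Growth curves (:func:`simulate_growth`) are logistic trajectories whose
rates come from the colimitation model per genotype and pCO2, with
additive Gaussian OD noise - the shape of a gas-controlled plate-reader
endpoint experiment.

All randomness flows through one seeded generator; a fixed seed gives
byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cell import CellParams, DEFAULT_QC_UM
from .chemistry import ASSAY_PCO2, CarbonateParams, Environment
from .genotypes import GenotypeConfig, evaluate_genotype

__all__ = [
    "LibrarySpec",
    "SimulatedLibrary",
    "simulate_library",
    "GrowthSimSpec",
    "simulate_growth",
    "endpoint_table",
]


@dataclass(frozen=True)
class LibrarySpec:
    """Design of a synthetic barcoded library experiment.

    ``conditions`` maps condition name -> per-gene intended log2 fitness
    effects (length ``n_genes``); genes not listed are neutral.  Reads per
    sample default to 1e6; doublings are drawn uniformly in [6.5, 7.5] per
    replicate.
    """

    n_genes: int = 200
    insertions_min: int = 30
    insertions_max: int = 50
    conditions: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: {"condition": np.zeros(200)}
    )
    reads_per_sample: int = 1_000_000
    doublings_min: float = 6.5
    doublings_max: float = 7.5
    n_replicates: int = 2
    strain_effect_sd: float = 0.0  # within-gene spread of log2 effects
    f0_lognormal_sigma: float = 0.5  # inoculum frequency dispersion
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not 1 <= self.insertions_min <= self.insertions_max:
            raise ValueError("need 1 <= insertions_min <= insertions_max")
        if self.reads_per_sample <= 0:
            raise ValueError("reads_per_sample must be positive")
        if not 0 < self.doublings_min <= self.doublings_max:
            raise ValueError("need 0 < doublings_min <= doublings_max")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for cond, effects in self.conditions.items():
            if len(effects) != self.n_genes:
                raise ValueError(
                    f"condition {cond!r} has {len(effects)} effects, "
                    f"expected n_genes = {self.n_genes}"
                )


@dataclass
class SimulatedLibrary:
    """Counts plus ground truth and the T0 pairing needed downstream."""

    counts: pd.DataFrame  # barcode, gene, scaffold, pos, sample, count
    truth: pd.DataFrame  # gene, condition, true_log2_effect
    t0_map: dict[str, str]
    doublings: dict[str, float]
    spec: LibrarySpec


def simulate_library(spec: LibrarySpec) -> SimulatedLibrary:
    """Simulate T0 and endpoint barcode counts with known gene effects."""
    rng = np.random.default_rng(spec.seed)
    genes = np.array([f"gene{i:04d}" for i in range(spec.n_genes)])
    n_ins = rng.integers(
        spec.insertions_min, spec.insertions_max + 1, size=spec.n_genes
    )
    gene_of_strain = np.repeat(np.arange(spec.n_genes), n_ins)
    n_strains = int(n_ins.sum())
    barcodes = np.array([f"bc{i:06d}" for i in range(n_strains)])
    positions = rng.integers(1, 3_000_000, size=n_strains)

    # inoculum frequencies: lognormal strain-to-strain dispersion
    f0 = rng.lognormal(mean=0.0, sigma=spec.f0_lognormal_sigma, size=n_strains)
    f0 /= f0.sum()

    frames = []
    t0_map: dict[str, str] = {}
    doublings: dict[str, float] = {}
    truth_rows = []
    for cond, effects in spec.conditions.items():
        for g, e in zip(genes, np.asarray(effects, dtype=float)):
            truth_rows.append(
                {"gene": g, "condition": cond, "true_log2_effect": e}
            )

    strain_cols = {
        "barcode": barcodes,
        "gene": genes[gene_of_strain],
        "scaffold": "synthetic_chromosome",
        "pos": positions,
    }

    for rep in range(1, spec.n_replicates + 1):
        d = rng.uniform(spec.doublings_min, spec.doublings_max)
        t0_name = f"T0_rep{rep}"
        doublings[t0_name] = d
        t0_counts = rng.multinomial(spec.reads_per_sample, f0)
        frames.append(
            pd.DataFrame({**strain_cols, "sample": t0_name, "count": t0_counts})
        )
        for cond, effects in spec.conditions.items():
            e_strain = np.asarray(effects, dtype=float)[gene_of_strain]
            if spec.strain_effect_sd > 0:
                e_strain = e_strain + rng.normal(
                    0.0, spec.strain_effect_sd, size=n_strains
                )
            # w = e/d  =>  2**(d*(1+w)) = 2**d * 2**e; 2**d cancels on
            # normalization, leaving the intended log2 change per strain.
            f_end = f0 * np.exp2(d + e_strain)
            f_end /= f_end.sum()
            name = f"{cond}_rep{rep}"
            end_counts = rng.multinomial(spec.reads_per_sample, f_end)
            frames.append(
                pd.DataFrame({**strain_cols, "sample": name, "count": end_counts})
            )
            t0_map[name] = t0_name

    counts = pd.concat(frames, ignore_index=True)
    return SimulatedLibrary(
        counts=counts,
        truth=pd.DataFrame(truth_rows),
        t0_map=t0_map,
        doublings=doublings,
        spec=spec,
    )


@dataclass(frozen=True)
class GrowthSimSpec:
    """Design of a synthetic growth-curve experiment.

    Defaults mirror a multiday plate-reader run: inoculum 0.005 OD600,
    reads every 30 min for 4 d, additive OD noise sd 0.01.  Use
    ``duration_h=48`` for a chemoautotroph-like endpoint assay.
    """

    pco2_levels: Sequence[float] = ASSAY_PCO2
    duration_h: float = 96.0
    interval_h: float = 0.5
    inoculum_od: float = 0.005
    carrying_capacity_od: float = 1.0
    noise_sd: float = 0.01
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.duration_h > 0 or not self.interval_h > 0:
            raise ValueError("duration and interval must be positive")
        if not 0 < self.inoculum_od < self.carrying_capacity_od:
            raise ValueError("need 0 < inoculum < carrying capacity")


def _logistic(t: np.ndarray, rate: float, od0: float, K: float) -> np.ndarray:
    # exact logistic solution; flat at od0 when rate == 0
    g = np.exp(np.clip(rate * t, None, 700.0))
    return K * od0 * g / (K + od0 * (g - 1.0))


def simulate_growth(
    spec: GrowthSimSpec,
    genotypes: Mapping[str, GenotypeConfig] | None = None,
    base_cell: CellParams = CellParams(),
    chem: CarbonateParams = CarbonateParams(),
    env_template: Environment = Environment(pCO2=0.0004),
    q_C_uM: float = DEFAULT_QC_UM,
    growth_rates: Mapping[str, Sequence[float]] | None = None,
) -> pd.DataFrame:
    """Simulate OD(t) curves for each genotype x pCO2 x replicate.

    Growth rates come from the colimitation model via ``genotypes`` (or
    may be supplied directly through ``growth_rates``, keyed by genotype
    name, one value per pCO2 level).  Returns a tidy table with columns
    ``genotype, pCO2, replicate, time_h, od``.
    """
    if genotypes is None and growth_rates is None:
        genotypes = {
            "rubisco_alone": GenotypeConfig(),
            "rubisco+CA+transporter": GenotypeConfig(has_ca=True, has_transporter=True),
        }
    if growth_rates is None:
        growth_rates = {
            name: evaluate_genotype(
                g, spec.pco2_levels, base_cell, env_template, chem, q_C_uM=q_C_uM
            )
            for name, g in genotypes.items()
        }
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, spec.duration_h + spec.interval_h / 2, spec.interval_h)
    frames = []
    for name, rates in growth_rates.items():
        rates = np.asarray(rates, dtype=float)
        if len(rates) != len(spec.pco2_levels):
            raise ValueError(
                f"genotype {name!r}: {len(rates)} rates for "
                f"{len(spec.pco2_levels)} pCO2 levels"
            )
        for pco2, rate in zip(spec.pco2_levels, rates):
            clean = _logistic(t, rate, spec.inoculum_od, spec.carrying_capacity_od)
            for rep in range(1, spec.n_replicates + 1):
                noise = (
                    rng.normal(0.0, spec.noise_sd, size=t.shape)
                    if spec.noise_sd > 0
                    else 0.0
                )
                frames.append(
                    pd.DataFrame(
                        {
                            "genotype": name,
                            "pCO2": pco2,
                            "replicate": rep,
                            "time_h": t,
                            "od": clean + noise,
                        }
                    )
                )
    return pd.concat(frames, ignore_index=True)


def endpoint_table(curves: pd.DataFrame) -> pd.DataFrame:
    """Endpoint OD per genotype x pCO2 x replicate (last timepoint)."""
    idx = curves.groupby(["genotype", "pCO2", "replicate"])["time_h"].idxmax()
    cols = ["genotype", "pCO2", "replicate", "time_h", "od"]
    return curves.loc[idx, cols].rename(columns={"od": "endpoint_od"}).reset_index(
        drop=True
    )
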