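# Methods

## The colimitation model

`colimit` models the growth of a CO2-fixing bacterium as colimited by two
carboxylation fluxes: rubisco carboxylation of CO2 in the Calvin-Benson-
Bassham cycle, which supplies most biomass carbon, and the anabolic
"bicarboxylation" reactions of lipid, nucleotide and arginine biosynthesis,
which strictly require HCO3- and supply a small minority of biomass carbon
(fraction `f_H`). A cell that fixes CO2 at a prodigious rate but cannot
supply HCO3- to these reactions does not grow — which is why expressing a
carbonic anhydrase (CA) or an energized inorganic-carbon (Ci) transporter
can rescue growth at low CO2 even though neither raises the rubisco
substrate concentration appreciably.

The cell is a single well-mixed compartment with intracellular pools C
(CO2, uM) and H (HCO3-, uM) obeying

    dC/dt = alpha (C_out - C) + (k_d + delta/K_in) H - (k_h + delta) C - gamma C
    dH/dt = chi S_ext + beta (H_out - H) + (k_h + delta) C - (k_d + delta/K_in) H - phi H

All coefficients are first-order rate constants (1/s); the model is linear
by construction and deliberately omits enzyme saturation and rubisco
oxygenation — it is built for coarse, order-of-magnitude comparisons.
Setting the right-hand sides to zero yields a 2x2 linear solve whose matrix
is an M-matrix, so the steady state exists, is unique and nonnegative
whenever each pool retains a removal path (otherwise a
`DegenerateParameterError` is raised).

Key structural choices:

* **CA is equilibrium-respecting.** `delta` enhances hydration and its
  reverse Haldane-consistently (forward `delta`, reverse `delta/K_in`), so
  an arbitrarily active CA at zero consumption leaves the pools exactly at
  the Henderson-Hasselbalch ratio `K_in = 10^(pH_in - pK1_eff)`. This is
  asserted as a property test (CA neutrality).
* **Uptake produces cytosolic HCO3-.** Both transporter families modeled
  (vectorial CO2-hydrating DAB-type and Na+:HCO3- symporting SbtA-type)
  deliver HCO3- to the cytosol; the flag `uptake_substrate` selects whether
  the first-order driving pool `S_ext` is external CO2 (default, DAB-like)
  or external HCO3- (SbtA-like).
* **Growth follows Liebig's law of the minimum**:
  `mu = 3600 * min(J_rub / ((1-f_H) q_C), J_bic / (f_H q_C))` in 1/h, with
  `J_rub = gamma*C`, `J_bic = phi*H`. The minimum reproduces the sharp
  two-regime structure (rubisco-limited vs bicarboxylation-limited) seen in
  the CA-activity sweeps; a smooth harmonic-mean alternative is available
  behind `law="harmonic"` for sensitivity analysis. Exact ties break to
  `rubisco_limited`.
* **Flux accounting.** Leakage is positive outward: `J_L,C = alpha (C -
  C_out)`, `J_L,H = beta (H - H_out)`, `J_L,tot = J_L,C + J_L,H`, and the
  steady state satisfies `J_chi - J_L,tot = J_rub + J_bic` identically
  (checked at 1e-9 relative to the gross membrane turnover on every call).
  The futile-cycle measure is `leak_ratio = J_L,tot / J_B`.

## Parameters, defaults and rationale

| symbol | meaning | default | why |
|---|---|---|---|
| `k_h` | uncatalyzed CO2 hydration | 0.037 1/s | textbook 25 C value; gives ~22 s relaxation at pH 7 |
| `pK1_eff` | effective first pKa of CO2/HCO3- | 6.35 | textbook effective value lumping H2CO3 with CO2(aq) |
| `K_H` | Henry solubility of CO2 | 0.034 M/atm | textbook 25 C value; 13.6 uM at 0.04% CO2 |
| `P_C` | membrane CO2 permeability | 0.3 cm/s | inside the measured 0.1-1 cm/s range |
| `P_H` | membrane HCO3- permeability | 3e-6 cm/s | orders of magnitude below `P_C` near neutral pH |
| `sa_v` | surface/volume | 3.3e4 1/cm | ~1 um bacterium; `alpha = P_C*sa_v ~ 1e4` 1/s |
| `gamma` | rubisco activity | 50 1/s | rubisco at ~1% of soluble protein. The hard ceiling (20% of soluble protein, 1 mM active sites) gives `gamma < 1e3` 1/s; a non-cyanobacterial autotroph sits well below it |
| `phi` | bicarboxylation activity | 1 1/s | sized so that equilibrated pools meet the anabolic demand at moderate growth rates: `phi*K_eq/gamma ~ f_H/(1-f_H)` within an order of magnitude |
| `f_H` | HCO3--derived biomass carbon | 0.02 | "small minority" of biomass carbon; configurable |
| `q_C` | biomass carbon demand | 1.66e7 uM | 1e10 carbon atoms per 1 fL cell |
| `delta_on` | genotype CA on-state | 10 1/s | ~270x spontaneous hydration: a modestly expressed CA |
| `chi_on` | genotype uptake on-state | 0.3 1/s | supplies HCO3- at the order of the anabolic demand (`f_H/(1-f_H) * J_rub ~ 1` uM/s per uM C_out); sits in the zero-leakage-feasible region (leak_ratio < 1) |
| pH_in = pH_out | 7.0 | near-neutral cytosol and buffered media |

Temperature dependence is not modeled; experiments at 30-37 C are treated
as 25 C chemistry. Carbonate ion and carbamates are ignored (negligible
below pH ~8).

### The pump scenario's "high activity" setting

`pump_scenario` asks how far CO2 permeability must fall before coexpressed
CA + Ci uptake could act as a CO2 pump (`C_in/C_out >= 2`, the smallest
unambiguous operationalization of "substantially above", recorded in the
output metadata). "High activity" means CA fast enough to equilibrate the
cytosolic pools (`delta = 1e4` 1/s) and uptake several-fold above the total
fixation demand (`chi = 200` 1/s = 4x `gamma`): pumping harder than demand
buys nothing and is precisely the futile-cycle regime quantified by
`leakage_heatmap`. Under these settings the threshold is a ~110-fold
reduction below the measured permeability — CO2 pumping across an
unmodified membrane is not a plausible explanation for the observed growth
rescues. The threshold scales as `alpha / (chi - 2 gamma - (beta + 2 phi)
K_eq)`, so "faster" uptake assumptions lower it; even an order of magnitude
more uptake than demand leaves a >10-fold permeability gap.

## Numerical choices

* Steady states via `numpy.linalg.solve` on the 2x2 system; singularity
  detected when |det| <= 1e-14 x the product of row norms. Solutions are
  clamped at zero only within -1e-9 x the boundary scale (roundoff);
  anything more negative raises an internal-consistency error.
* The independent oracle for the linear solve is explicit stiff time
  integration (`scipy.integrate.solve_ivp`, Radau, rtol 1e-10) from empty
  pools to 40 slow-eigenvalue e-foldings; agreement is required at 1e-6
  relative over 100 log-uniform random parameter sets (fixed seed).
* Zero-leakage contours: `J_L,tot` is affine in `chi` (negative at
  `chi = 0`, positive slope), so the root is unique; it is bracketed and
  found by `brentq` at 1e-6 relative tolerance. Depletion frontiers and the
  pump threshold are refined the same way on log-scaled coordinates.
* Sweep grids are log-spaced, default 25 points per axis; sweeps are pure
  functions of (grid, parameters) and re-serialize byte-identically.
* Growth-rate monotonicity in CA activity holds up to a ~1e-4 relative
  wrinkle: in the rubisco-limited plateau CA-catalyzed hydration consumes a
  little CO2, so the plateau droops slightly. Property tests assert
  monotonicity up to 1e-3 relative tolerance rather than strictly.

## Genotypes and trajectory certification

A genotype toggles CA (`delta_on`) and Ci transport (`chi_on`); the
carboxysome flag is an annotation with no mechanistic effect, because
encapsulation acts through compartment geometry and local pH that a
well-mixed model cannot represent (that modeling belongs to
reaction-diffusion treatments and is out of scope here).

`enumerate_trajectories` walks all six orderings of {CA, transporter,
carboxysome} down a declining CO2 schedule (5% -> 1.5% -> 0.5% -> ambient),
evaluating each acquisition step at the level the lineage is descending
into. A trajectory is certified **fitness positive** when (i) every
mechanistically scored step is non-decreasing in growth rate and (ii) every
pre-terminal step is scorable — i.e. the carboxysome, which this model
cannot score, is acquired last. Exactly two orderings qualify: CA before
transporter and transporter before CA. Non-decreasing (rather than
strictly increasing) is used because some scored steps are positive but
tiny (e.g. adding a transporter to a CA-expressing, rubisco-limited cell
raises growth by ~1e-5 relative).

Because the model is linear in concentrations at fixed pH, the *fold*
benefit of any genotype is independent of pCO2; the empirical observation
that CCM components become dispensable at 5-10% CO2 reflects enzyme
saturation, which this model deliberately omits. An optional `mu_max` cap
on the growth law lets users emulate saturation; it is off by default and
unused by the package's own analyses.

## Fitness statistic

Strain fitness is the log2 ratio of relative barcode abundance between an
endpoint sample and its T0 preculture, with a pseudocount (default 0.5
reads) added to each count: `log2(((n_end + p)/N_end) / ((n_t0 + p)/N_t0))`.
Gene fitness is the unweighted mean over that gene's insertion strains
after excluding strains with fewer than 3 T0 reads (both thresholds
configurable); an inverse-variance-weighted mean using Poisson counting
noise is available behind `weighted=True`. Genes whose strains all fail
the T0 filter are flagged, never silently dropped. Replicate concordance
is the Pearson correlation over shared gene-level values (>= 3 genes
required). No global re-centering is applied by default; with a mostly
neutral library the compositional bias is ~0.1 log2 units, well inside the
0.3-unit recovery tolerance the test suite enforces.

## Synthetic data: what it emulates, and what it does not

`simulate_library` generates a pooled competition assay: 200 genes by
default, 30-50 insertion strains per gene (mean ~40), lognormal inoculum
dispersion (sigma 0.5), 6.5-7.5 doublings of deterministic exponential
competition with per-gene relative fitness, and multinomial read sampling
at 1e6 reads per sample for T0 and each endpoint. Specifying a gene's
intended log2 effect `e` sets the per-doubling fitness to `e/d`, so the
expected recovered fitness is `e` up to the compositional normalization.
`simulate_growth` produces logistic OD(t) curves (inoculum 0.005 OD,
additive Gaussian noise sd 0.01 OD) whose rates come from the colimitation
model per genotype and pCO2 over a 4-day plate-reader-style run.

Not emulated: sequencing error and barcode chimeras, strain-to-strain
effect heterogeneity within a gene (available via `strain_effect_sd` but
zero by default), PCR amplification bias, lag phases, evaporation, and any
regulatory response of the host. Passing recovery tests therefore show
that the statistics are correct for idealized count noise at the stated
depth and library shape, not that they are robust to those artifacts. All
randomness flows through a single seeded `numpy` generator; a fixed seed
reproduces tables byte-for-byte.

## Problem sizes

Default analyses are desk-scale by design: 25x25 steady-state grids for
heatmaps (each point a 2x2 solve), 26-point permeability scans, a
200-gene/~8000-strain/1e6-read synthetic library for recovery tests, and a
100-parameter-set integration-oracle comparison. The full test suite runs
in about a minute on one CPU.

## Known limitations

* Linearity: no saturation, no oxygenation, no Michaelis-Menten kinetics;
  absolute growth rates at high CO2 are unrealistically large and should
  be read as relative measures only.
* Single compartment: no carboxysome interior, shell permeability or local
  pH; carboxysome contributions are structurally unscorable here.
* Fixed pH chemistry at 25 C; no alkalinity or ionic-strength corrections.
* The energy cost of Ci uptake is proxied by the uptake flux `J_chi`
  itself; no ATP/ion stoichiometry is asserted.
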