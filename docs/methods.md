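# Methods

This note records the models behind each analysis track, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical conventions. Nothing here states a result the test suite
or `scripts/acceptance.py` does not itself compute.

## Equilibrium thermodynamics

Reactions are exact rational stoichiometries over named species; electrons
are an explicit pseudo-species `e-` (charge −1, no elements) so half
reactions pass the same element/charge balance check as full reactions.
Combination under Hess's law adds coefficients and log K values with
rational multipliers, so species cancel exactly rather than to rounding
error.

Constants follow the rounded hand-calculation convention of
low-temperature geochemistry: T = 298 K (not 298.15), ln 10 taken as
2.303 (not 2.302585), F = 96.49 kJ V⁻¹ eq⁻¹. These are the only values
under which the shipped reaction-level sums (ΔrH° = −122.82 kJ mol⁻¹,
ΔrS° = −359.74 J mol⁻¹ K⁻¹ for the superoxide reaction) reproduce the
published intermediate ΔrG° = −15.62 kJ mol⁻¹ at printed precision; all
are configurable through `ThermoConstants`.

Two conventions are recorded explicitly in the database rather than left
implicit:

* The Au⁰/Au³⁺ couple is stored with E° = −1.52 V *for the oxidation as
  written* (`Au(s) = Au3+ + 3 e-`), with ΔG° = −nFE° applied to that
  direction, giving +440 kJ mol⁻¹. The equivalent reduction potential is
  +1.52 V.
* The derived log K of the superoxide/water couple is reported with a
  ±0.1 tolerance in tests: the chain is assembled from intermediates
  rounded to two decimals, and that rounding propagates (full-precision
  recomputation gives 79.85 against the published 79.84).

Species-level formation enthalpies/entropies behind the reaction-level
sums are not distributed here; the database stores the sums themselves
(columns `drH`, `drS` on reaction R3) and leaves the species columns
blank.

## Eh–pH predominance diagrams

Diagrams are built by the two-stage "mosaic" procedure: the ligand
subsystem (carbon: CH₄/C(s)/CO₂(aq)/HCO₃⁻/CO₃²⁻ anchored on bicarbonate;
sulfur: H₂S/HS⁻/S(s)/HSO₄⁻/SO₄²⁻/S₂O₃²⁻ anchored on thiosulfate) is
resolved first at total activity 0.01, then gold speciation is evaluated
with the winning ligand rescaled to the anchor activity.

Stability is compared per mole of the subsystem element under the
equal-activity convention: each dissolved species is assigned the anchor
activity, solids and water unit activity, and the species whose
equilibrium activity (computed from its formation reaction `F:<name>` in
the database) most exceeds its assigned activity predominates. A cell
belongs to Au(s) when no dissolved gold species in equilibrium with the
metal reaches the requested activity level; the 1 ppm/1 ppb/1 ppt contours
default to the decade activities 10⁻⁶/10⁻⁹/10⁻¹², with the exact
molar-mass conversion (10⁻⁵·²⁹ for 1 ppm, via 196.97 g mol⁻¹) available
through `mass_fraction_to_log_activity`.

Consequences of this design worth noting:

* Thiosulfate instability in acid is emergent: S₂O₃²⁻ simply never wins a
  cell because sulfate or sulfide species are always more stable, so no
  hard pH cutoff is coded.
* Ties are broken by species order in the database (first maximum wins),
  making the diagram deterministic for a fixed database and grid.
* Ionic-strength corrections, temperature extrapolation and pressure
  dependence are out of scope; all activities are molal, water and solids
  at unit activity.

The default grid is 0.05 pH × 0.005 V over pH 0–14, Eh −0.8–1.6 V
(281 × 481 cells), which builds in about a second per system. The
formation constants for species without published values in the source
chain (the Au(I) hydrolysis steps, the Au–HS complexes, and the
carbon/sulfur couples, taken from standard-state ΔfG° compilations or
estimated) ship as an *editable* TSV with a note per row; tests pin only
the published constants and the structural properties of the diagram
(metal-field nesting across contours, per-point agreement with a
brute-force oracle, the overlay-line endpoints), not the exact positions
of boundaries that depend on those editable values. Both AuHS(aq) and
Au(HS)₂⁻ are included since the relevant species set is not settled;
either can be removed by editing the database.

## Microcosm kinetics

The analysis is deliberately descriptive — phase-wise ordinary least
squares on replicate means — not mechanistic (no Michaelis–Menten or
autocatalytic model), because the quantity of interest is the linear
oxidation rate within inspected windows. Choices:

* Replicates are summarised as mean ± sd per time point before fitting
  (matching how triplicate microcosm data are reported); raw-replicate
  fitting is available by building the series from the tidy table
  without aggregation.
* Phase windows are user-specified (defaults 0–45 h and 191–453 h). An
  SSE-minimising two-segment breakpoint search is provided as an
  exploratory helper but is never used for headline rates.
* Concentrations inferred below zero from the calibration are clipped at
  0 and counted (`count_clipped`).
* The Au(III)–pH Pearson correlation uses the exact t transform with
  n − 2 degrees of freedom; one-tailed p-values are supported because
  directional hypotheses (oxidation consumes protons) are natural here.

## Community ecology

* Inverse Simpson is 1/Σp²; Berger–Parker is reported as dominance
  n_max/N (the common OTU-pipeline convention), with the reciprocal
  available via a flag since usage varies.
* Chao1 uses f₁²/(2f₂) with the bias-corrected f₁(f₁−1)/(2(f₂+1)) branch
  when no doubletons exist.
* Hotspots: au ≥ 1.5 × median(anomaly au), inclusive at the threshold.
  The rule is scale-equivariant.
* Diversity–gold correlations are Pearson with exact t-transform
  p-values, significance at α = 0.1, and no multiple-testing correction —
  matching how small two-area soil surveys are conventionally screened.
* Networks: counts are aggregated to taxonomic order by default (the
  networks of interest connect orders), converted to relative abundances,
  filtered to taxa present in ≥ 7 sites, and correlated pairwise (Pearson
  default, Spearman optional). The edge threshold defaults to |r| ≥ 0.8:
  random-matrix-theory threshold selection used by some online pipelines
  is intentionally replaced by this fixed, configurable cutoff.
* Module detection is greedy agglomerative modularity maximisation
  (Clauset–Newman–Moore, via networkx) on the unsigned edge set; tests
  verify the returned Q against an exhaustive scan over all partitions on
  small graphs.
* Stress centrality c_S(x) counts, over unordered pairs (s, t) with
  s ≠ x ≠ t, every unweighted shortest path containing x as an interior
  node — "short paths" is read as shortest paths, the standard definition.
  The implementation enumerates all shortest paths, which is exact and
  fast at the network sizes produced here (tens of nodes).

## Synthetic generators

All generators are pure functions of (scenario, seed) via
`numpy.random.default_rng`; identical seeds give byte-identical tables.

**Microcosm**: Au(III) is piecewise linear through ordered phase windows
(default slopes 0.19 then 0.01 µM h⁻¹ over 0–45 h and 191–453 h), with
anchor points for the 13.44 µM peak at 119 h (33.6 % of the 40 µM spike)
and the terminal decline to the 5.68 µM reference plateau; values hold
("plateau") where nothing is specified. Sampling times are 0, 17, 45,
119, 191, 310, 453, 693 h with 3 replicates. Replicate noise is Gaussian
(default sd 1 µM, the order of reported replicate scatter) clipped at 0 —
matching the analysis module's clipping. pH is base 5.0 plus 0.1 pH/µM
times Au(III) inside the 45–191 h window, so the Au(III)–pH coupling
exists only in the rate-change period.

**Two-area survey**: 10 anomaly + 9 reference sites; soil gold is
log-normal with anomaly median 3.54 ng g⁻¹ and log-sd 1.0 (heavy enough
that a few sites exceed 1.5 × the median, forming hotspots, with values
reaching tens of ng g⁻¹) against a reference median of 1.2 ng g⁻¹ and
log-sd 0.5. Per-site target inverse Simpson is log-normal (median 8,
log-sd 0.45) driven by a latent variable that correlates with
standardised log-gold at strength `coupling` — default 0.95 in the
anomaly, 0 in the reference. Compositions follow a geometric
rank-abundance profile solved (by root finding) to hit the target
diversity over a 120-OTU pool, drawn through a Dirichlet (concentration
200 per unit probability) and a multinomial at depth 20 000. Taxonomy
cycles ten common soil-fungal orders (including a high-prevalence
Hypocreales), two phyla.

What the generators do **not** emulate: read-level sequencing artefacts
(chimeras, length variation, OTU clustering error), spatial
autocorrelation of soil geochemistry, compositional interactions between
specific taxa, pH–gold cross-correlation, or mechanistic kinetics of the
Au(III) re-reduction step. Passing recovery tests therefore demonstrates
estimator correctness under the stated statistical structure, not
robustness to every property of real field data.

A note on null behaviour: with coupling 0 the diversity–gold correlation
is a true null, and at n = 10 sites the sampling sd of Pearson r is ≈ 1/3
— so |r| regularly exceeds 0.3 by chance. The null test therefore checks
that r is centred on zero and that the α = 0.1 test fires at roughly its
nominal rate, which is the statistically meaningful property.

## Pipeline and determinism

The driver funnels all randomness through one seed, writes a provenance
header (version, config hash, seed; output paths excluded from the hash)
into every table, and reports machine-readable `results.json` plus a
human-readable summary. Problem sizes in the acceptance script — default
diagram grid, 200-seed recovery loops — were chosen so the whole script
completes in seconds while keeping Monte-Carlo rates stable to a couple
of percentage points.

## Known limitations

* The Eh–pH diagrams depend on the editable formation constants for the
  species whose values are estimates; boundary positions involving those
  species should be treated as indicative until the constants are
  replaced with a vetted compilation.
* The greedy modularity optimiser is a heuristic; on larger graphs the
  returned partition may be below the global optimum (tests bound this
  only on small graphs).
* Phase-rate estimation assumes the user-chosen windows isolate linear
  segments; the breakpoint helper minimises SSE but does not test
  linearity.
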