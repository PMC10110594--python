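# Methods

## Model

Each brain region is modelled as two reciprocally coupled neural masses.
The excitatory population's synaptic gating `S^E` relaxes with the NMDA time
constant (τ_NMDA = 100 ms) and is driven by its own rate through the kinetic
factor γ = 0.641; the inhibitory gating `S^I` relaxes with the GABA-A time
constant (τ_GABA = 10 ms). Rates come from the frequency–current curve
`F(I) = y / (1 − exp(−d·y))`, `y = g_nm·g·(I − I_thr)`, which is strictly
increasing, nonnegative, and takes the value `1/d` at threshold (the
removable singularity is evaluated by its limit, with a first-order series
used within |d·y| < 1e-9). Regions interact only through their excitatory
populations, weighted by the structural connectome and the global coupling
G = 2.4. Neuromodulation multiplies the F–I gain of *both* populations of
region *n* by `g_nm = 1 + s_nm·d_n^rec`, with s_nm = 0.025 per unit receptor
density; the placebo condition is the same model with unit gains, so setting
s_nm = 0 reproduces placebo bit for bit.

Biophysical constants (currents in nA, rates in Hz):
I0 = 0.382, W_E = 1, W_I = 0.7, w+ = 1.4, J_NMDA = 0.15 nA,
I_thr^E = 0.403, I_thr^I = 0.288, g_E = 310 /nC, g_I = 615 /nC,
d_E = 0.16 s, d_I = 0.087 s, σ = 0.01 nA.

### Units and integration

The printed gating equations mix Hz (rates) with ms (time constants). We
integrate in milliseconds: rate terms in the drifts carry a factor 1e-3
(spikes per ms), which is what makes a ~3 Hz fixed point attainable with
these time constants. Euler–Maruyama at dt = 0.1 ms, independent standard
normal increments per gating variable scaled by σ·√dt, gating clipped to
[0, 1] after every step (the gating variables are occupancy fractions; at
σ = 0.01 the clip activates only in rare excursions near the boundaries).
The integrator is a numba kernel; a step-level reference implementation
(`em_step`) is kept in sync by test.

Simulated duration defaults to 120 s with the first 20 s discarded and
instantaneous excitatory rates recorded every 1 ms, i.e. 100 000 samples per
region — comfortably enough for stable gamma fits (the shape/scale MLEs at
this sample size have sub-percent spread). Durations, step and sampling
interval are all configurable.

### Feedback inhibitory control (FIC)

The per-region inhibitory weight `J^FIC` is calibrated so that every
excitatory population's time-averaged rate in the *placebo* condition lies
within ±0.5 Hz of the 3 Hz set-point; the calibrated weights are then held
fixed under receptor activation (the drug perturbs a placebo-calibrated
brain — re-calibrating under drug would cancel the manipulation).

Calibration is iterative, but the error signal lives in current space, not
rate space: after each 10 s calibration window the measured mean rate is
mapped back through the inverse F–I curve and compared with the current that
yields the target rate, and `J` moves by that current error divided by the
inhibitory gating at the set-point. Rate-space updates (`J += η·(rate −
target)`) are poorly conditioned here — the rate error saturates at −3 Hz
for silenced regions while `J` may be off by several nA — and at G = 2.4 the
network can transiently run away during the search, which current-space
Newton steps recover from in one or two iterations. Per-region step sizes
halve whenever the region's deviation changes sign. Convergence is declared
only after a 40 s confirmation window puts every region within half the
tolerance (0.25 Hz at the default ±0.5 Hz), which leaves margin for
run-to-run variability of validation simulations (population-mean drift
between independent 100 s runs is ≈ ±0.1 Hz on a 30-region synthetic
system). If the iteration budget runs out, the best confirmed state is
returned as long as it still honours the full tolerance — surrogate
connectomes with extreme strength outliers occasionally settle between 0.25
and 0.5 Hz. The warm start is the analytic uncoupled
balanced state: the inhibitory self-consistency is solved by root finding at
the excitatory set-point, and the long-range term enters through each
region's strength.

Failure to converge within `max_iter` raises an error carrying the worst
region's deviation.

## Entropy estimation

Stationary firing-rate distributions of this model are well approximated by
gamma distributions. Per region we fit the two-parameter gamma (location
fixed at 0) by maximum likelihood and evaluate the differential entropy in
closed form, `h = k + ln θ + ln Γ(k) + (1 − k) ψ(k)` nats; the closed form
is verified against numerical quadrature of −∫ p ln p to 1e-6 over
k ∈ [0.5, 50], θ ∈ [0.01, 10]. Rates below 1e-6 Hz are floored before
fitting (gamma support is positive; exact zeros are numerical artefacts at
this noise level). Goodness of fit is tracked with the one-sample KS
statistic against the fitted CDF. Fits require ≥ 100 samples and reject
constant series.

Contrasts: `Δh_n = (h_n^5HT2A − h_n^PLA)/h_n^PLA`, aggregated over
repetitions as mean ± 1 SD. The condition contrast uses a two-sided paired
Wilcoxon signed-rank test across regions on repetition-averaged entropies,
and the paired Cohen's d (mean difference / SD of differences across
regions) computed per repetition and summarised as mean ± SD over
repetitions — chosen because the d-dispersion is reported across
simulations while the pairing is region-wise. A zero-variance difference
vector yields an infinite d, which is passed through (flagged by the
caller) rather than capped. Group summaries average hemispheric twins
first, then groups (anatomical lobes or resting-state networks).

## Region partition

Regions split into three groups by what drives their entropy change:
strongly strength-dependent (S1), weakly strength-dependent (S2), and
receptor-density-dependent (R1).

*Seeding.* A prior set of regions (anatomically, the occipital cortex; the
synthetic metadata tags stand-ins) anchors a quadratic OLS fit of Δh against
strength; the remaining regions anchor a linear fit against receptor
density. Each non-prior region joins S1 when its squared residual under the
quadratic strength fit is smaller than under the linear density fit.

*Optimisation.* The non-S1 regions are split into S2/R1 by random search:
each proposal relabels every free region independently (R1 probability
drawn fresh per proposal) and is accepted only on strict improvement of the
grouped-model R²; search stops after `n_iter` proposals or 500 consecutive
non-improvements.

*Refinement.* The grouped model is nearly symmetric under exchanging the
S2/R1 labels — every group carries both a strength and a density term — so
R² alone identifies the split but not which side is which, and random
search alone can stall in mixed local optima. Two additions make the
partition well determined: an EM-style refinement (fit the grouped model,
reassign each free region to the group whose fitted curve predicts it best,
refit; both half-steps reduce squared error, so R² is monotone), run from
multiple starts; and a deterministic canonicalisation that names the
strength-driven side S2 and the receptor-driven side R1 by comparing
within-group correlations. Prior regions never leave S1. The refinement can
be disabled (`refine=False`) to recover the bare random search.

*Model.* The default design has 7 terms: a shared constant plus one
strength and one density term per group, with the strength term entering
quadratically for S1/S2 and linearly for R1. A fuller 12-term interaction
design (per-group intercept, linear and quadratic strength, density) is
available as `design="full"`. Empty groups drop their columns with a
warning; rank deficiency is flagged on the fit. Overall and per-group R²
are reported, per-group values computed from the global predictions
restricted to each group's own observations.

## Connectome null models

* RAND relocates the upper-triangle edges uniformly among all node pairs
  (weights permuted over the new edges): preserves edge count and total
  weight exactly, destroys degree and strength sequences.
* DPR rewires the binary topology by double-edge swaps (10 swaps per edge
  by default) preserving each node's degree exactly, then reassigns the
  original weight multiset at random to the new edges.
* DSPR starts from a DPR rewiring and restores each node's strength by
  symmetric iterative proportional scaling (each weight multiplied by the
  geometric mean of its endpoints' target/current strength ratios) to a
  relative tolerance of 1e-3; non-convergence raises with the worst
  deviation.

Every generated surrogate is audited for its preservation ladder in the
tests. Topology metrics follow the standard weighted-graph definitions
(path-based metrics use edge length 1/weight; eigenvector centrality is the
leading eigenvector of the weight matrix; communicability and sub-graph
centrality come from the matrix exponential; PageRank uses damping 0.85);
they are delegated to networkx/scipy and verified against brute-force
oracles (explicit path enumeration, series-summed matrix exponential, power
iteration) in the tests. On disconnected graphs closeness is computed
within components and the profile flagged.

The surrogate experiment re-calibrates FIC on every surrogate, simulates
both conditions, and correlates the surrogate-ensemble mean Δh with the
original connectome's Δh.

## Synthetic data

The generator emulates the statistical shape of the empirical inputs:

* **Connectomes** — Erdős–Rényi topology at a target edge density with
  log-normal weights (μ = −2, σ = 1, heavy-tailed like proportion-of-fibers
  DTI matrices), edges below 0.1 % of the maximum weight pruned (mirroring
  relative thresholding; an absolute mode is available), connectedness
  enforced by re-drawing, and weights rescaled to a mean node strength of
  0.5. The scale matters dynamically: at mean strength ~1 and G = 2.4 the
  balanced 3 Hz state loses stability to collective noise-driven runaways,
  while at 0.5 (or lower) the model sits in the same balanced regime in
  which the empirical connectome is known to operate — thresholded
  proportion-of-fibers matrices likewise have sub-unit row sums.
* **Receptor maps** — a Gaussian copula mixes normal scores of the strength
  ranks with in-sample-orthogonalised noise at weight ρ (the target
  strength–density correlation), then maps through the normal CDF to a
  configurable range, default [0, 20] so gains reach ≈ 1.5 at the default
  s_nm. At |ρ| = 1 the map is an exact monotone transform of strength.
* **Metadata** — hemispheric twin pairs with lobe and resting-state-network
  tags constant within pairs; a configurable fraction of pairs is tagged as
  the prior (occipital stand-in) group.
* **Planted Δh** — the grouped model's own response (shared constant,
  quadratic strength for S1/S2, linear density for R1) plus Gaussian noise,
  with ground-truth labels returned. The default recovery fixture uses a
  90-region, density-0.3 connectome, S1 = the top-30 %-strength regions
  (hub alignment, as in the empirical partition), S2/R1 assigned at random
  among the rest — random mixing is what keeps the split identifiable,
  since density-sorted groups are fit equally well by either labelling —
  and default coefficients const = 0.02, S1 strength² = 0.15,
  S2 strength² = 0.03, R1 density slope = 0.006.

What the synthetic data does *not* emulate: cortical geometry and
distance-dependent wiring, modular/community structure, subject-level
variability, and any empirical receptor-density topography. Passing tests
on synthetic systems therefore demonstrate the correctness and the
qualitative behaviour of the machinery (calibration contract, directional
entropy increase, strength-over-density explanation, null-model ordering),
not quantitative reproduction of empirical values, which requires the
empirical connectome and receptor files as inputs.

## Problem sizes and repetitions

Library defaults are sized for single-workstation runs: 120 s simulations,
30-region synthetic systems, 20 repetitions for condition contrasts, 5–10
surrogates per null scheme with 2 repetitions each, 2000 partition search
proposals. Production-scale analyses (90 regions, hundreds of repetitions
and surrogates) use the same code paths with larger configuration values.

## Reproducibility

All randomness flows from explicit integer seeds: the integration kernel
seeds its own generator per run, repetition seeds derive deterministically
from the master seed (distinct per condition), surrogate seeds from the
surrogate-spec seed and index, and the pipeline records every derived seed
in its manifest. Identical configuration + seed yields byte-identical
output tables.

## Known limitations

* The calibration set-point contract is ±0.5 Hz per region; tighter
  contracts would need longer confirmation windows as the population-mean
  noise floor is reached.
* The gamma fit is an approximation; strongly bimodal rate distributions
  (outside the calibrated regime) would bias the entropy estimate, which is
  why the KS statistic is retained per fit.
* The partition's S2/R1 identification relies on the two groups spanning
  overlapping covariate ranges; degenerate geometries (e.g. density-sorted
  group membership) are intrinsically ambiguous for any R²-based search.
* Fitting the global coupling and neuromodulatory gain to empirical
  functional data, BOLD forward modelling, and multi-receptor
  neuromodulation are out of scope; G = 2.4 and s_nm = 0.025 are taken as
  given.
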