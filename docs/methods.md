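# Methods

## Steady-state cascade models

A circuit is an ordered cascade: one HSL input block (LuxR constitutively
expressed; output promoter P_lux, inducible, or P_luxRep, repressible), zero
to two repressor NOT gates (tetR → P_LtetO1, lacI → P_LlacO1, both LVA
tagged), an RFP reporter, and optionally a constitutive GFP monitor
cassette. Each regulated promoter is a four-parameter Hill function
`delta + alpha / (1 + (K/I)^(+-eta))`; `eta` is stored positive and an
explicit orientation flag supplies the exponent's sign, with the analytic
limit used at I = 0 (delta for inducible, delta + alpha for repressible).
Intracellular species are assumed at steady state in exponentially growing
cells; growth dilutes proteins (rate mu, fixed externally per circuit and
HSL concentration from the data, never fitted) but does not otherwise enter
transcription or translation. Fixed rate constants: gamma_tet = 0.0173,
gamma_lac = 0.0533, a (RFP maturation) = 0.0167, a_G (GFP maturation)
= 0.0462 min^-1.

The burden model multiplies nothing and adds nothing to the wiring — its
only structural change is the shared capacity denominator
`D̂ = 1 + Sigma_input + sum_k J_k S_max,k` dividing every realised synthesis
rate. The sum runs over the circuit-borne regulated genes (tetR, lacI,
RFP); host genes and the constitutive monitor are folded into the
rescaling, so `D̂` is expressed relative to the host's own load and the
monitor's output `a_G S_m / ((mu + a_G) D̂)` reports free capacity. The
LuxR cassette enters only through the lumped dimensionless term
`Sigma = J · Ŝ` of its promoter class; LuxR protein itself is never
modelled, and neither is any HSL–LuxR binding mechanism.

Units: block inputs and outputs share a common currency of red-fluorescence
arbitrary units (AU_R cell^-1 for protein levels, AU_R cell^-1 min^-1 for
rates; AU_G for the monitor), so that transfer functions measured on
separate circuits compose.

### Sigma-to-block assignment

Three Sigma classes (promoters P_R, P_LlacO1, P_LtetO1 driving luxR) serve
four input blocks, so two blocks share a class. The assignment is not fully
determined by the source material; the packaged registry
(`data/circuits.yaml`) uses X_1 → lambda, X_2 → lac, X_3 → tet,
X_rep → lambda, and treats it as configuration, editable without touching
code. The reporter's usage weight J_RFP is shared by circuits with and
without the monitor cassette.

### Fixed-point solution and ODE oracle

`D̂` is implicit (downstream S_max values depend on protein levels scaled by
`D̂`). It is solved by fixed-point iteration from `D̂ = 1` with a 0.5
damping factor applied to any component whose residual changes sign on
consecutive iterations, relative tolerance 1e-9, iteration cap 10,000, and
(inside the fitters) warm starts from the previous evaluation's solution.
Any converged result satisfies the self-consistency
`|D̂ − (1 + Sigma + sum J S_max)| < tol·D̂` by construction. An independent
oracle integrates the cascade kinetics
`dP_j/dt = S_j(state)/D̂(state) − (mu + gamma_j) P_j` (LSODA, rtol 1e-9) to
quasi-steady state; the test suite checks agreement within 0.1% on 100
randomised topology/parameter/condition draws.

### Logic classification

A circuit's logic is read from its output at zero versus maximal HSL:
OFF-to-ON, ON-to-OFF, or flat when the central values differ by less than a
relative tolerance (default 5%). The expected direction is
`(−1)^(number of repressible elements)`; a mismatch flag marks circuits
whose observed switching contradicts their composed parity — the burden
signature this analysis is about.

## Plate-data reduction

Raw microplate series are blanked per time point (sterile medium for
absorbance; a non-fluorescent culture for red; for green, a
cell-density-dependent autofluorescence `exp(q + m·OD600)` fitted by
ordinary least squares on ln(green) vs blanked OD of condition-matched
no-GFP controls, points ≤ 0 dropped). Growth rate is the ln(OD) slope and
`S_cell = (dF/dt)/OD` the arithmetic per-timepoint mean, both restricted to
the exponential window 0.05 ≤ OD600 ≤ 0.18 — boundary points are included
(closed interval), a documented choice where the window is conventionally
written with strict inequalities. The derivative uses centred differences
on the 5-minute grid, one-sided at the ends. Rates are normalised to the
mean `S_cell` of channel-matched constitutive reference cultures, giving a
relative-promoter-unit-like scale. Growth-rate dependence of
autofluorescence is honoured by requiring condition-matched controls rather
than an explicit covariate.

## Synthetic data

The generator replaces the study's non-deposited measurements. Defaults are
the study conditions: HSL grid {0} ∪ 8 log-spaced points from 0.1 nM to
10 uM; 3 biological replicates; per-condition Gaussian noise with CV 10%
(typical of the reported replicate variability), negatives truncated at
zero; growth rates declining linearly with each strain's burden proxy
(`D̂ − 1` at the packaged burden parameters) from 0.02 to 0.008 min^-1,
spanning the strains' reported 2.5-fold range — a deterministic stand-in,
since the measured per-strain values are figure-only. The monitor-only
culture (`Mon_rg`) is generated alongside the collection; see Fitting for
why it matters.

The plate-kinetics generator emulates the measurement chain one level
deeper: OD grows exponentially from 0.02 after a lag and caps at OD_max
(a logistic law is available, but the exponential-with-cap default keeps
the reduction window exactly exponential, which is all the reduction ever
uses); fluorescence accumulates as dF/dt = s·OD with maturation folded into
the effective rate; the green channel adds `exp(q + m·OD)`; channels add
constant instrument background and small Gaussian read noise; matched
blanks, no-GFP controls and reference wells are emitted. What the generator
does **not** emulate — context-dependent part variability, cell-to-cell
heterogeneity/bimodality, evaporation, gain drift, growth-rate feedback on
resource pools — bounds what green tests mean: they certify the pipeline's
internal consistency under the stated statistical structure, not robustness
to real-data pathologies.

## Fitting

Weighted least squares with per-residual weight `1/sigma_i^2`, where
`sigma_i` is the replicate standard deviation of the residual's condition
(ddof 1). Degenerate zero sigmas take the smallest positive sigma in the
slice for weighting only; simulation uses the raw value (zero noise stays
zero). Parameters are optimised in log10 space (positivity by construction)
with scipy's trust-region-reflective least squares and a seeded multistart
(default 5 starts, ±0.3 decades around data-driven initial values: basal
rate from the low-signal plateau, range from the data span, K from the
geometric mean of the input grid, eta 1.2). Bounds: eta ∈ [0.3, 10]
(identifiability on sparse grids), K within the observed input range
×[1e-2, 1e2] for input blocks, J and Sigma in [1e-8, 10].

Sequential (bottom-up) procedure — no-burden model: four independent
4-parameter fits on the input-block circuits (RFP), then each NOT gate with
upstream parameters fixed. Burden model: the four input blocks fitted
simultaneously (16 Hill parameters + J_RFP + three Sigma + S_m) on RFP and
GFP jointly, then each gate's Hill parameters plus its J. The stage-1
burden fit is exactly scale-degenerate on input-block data alone (rates,
1 + Sigma and S_m can all be multiplied by a common factor); the
monitor-only culture, whose GFP output is the unloaded `a_G S_m/(mu+a_G)`,
anchors the scale and is included in stage 1 whenever present. A
simultaneous variant fits every circuit jointly and feeds the
likelihood-ratio comparison.

### Uncertainty

Two Monte Carlo flavours, used for different questions:

* **Parametric bootstrap** (`monte_carlo_uncertainty`,
  `bootstrap_training_*`): simulate datasets at the point estimates with the
  per-condition replicate noise, truncate negatives, refit each from the
  point estimate; in the two-stage procedure each draw's gate refit fixes
  the upstream parameters to that draw's stage-1 estimates, propagating
  upstream uncertainty downstream. Default 10,000 draws at study scale; the
  desk-scale default is 200 and the test suite uses 25–200. Failed refits
  are dropped and counted (error above a 20% failure rate).
* **Recovery Monte Carlo** (`monte_carlo_recovery`): simulate independent
  datasets at a known generating truth and refit each; the median measures
  the estimator's central recovery. This is the right instrument for
  parameter-recovery claims because single-dataset estimates of weakly
  identified parameters are widely dispersed: the tet gate's switch point
  K_T sits above the smallest repressor input reachable on the grid, so its
  upper plateau is unobserved and (alpha, K, eta) trade off along a ridge —
  a single seeded estimate has ~35% spread while the 200-run median is
  within a few percent.

The 95% percentile intervals of the parametric bootstrap undercover
somewhat (~80–86% measured for the input-block Hill coefficient at 3
replicates): the replicate SD of n = 3 underestimates the noise scale and
percentile intervals centred on heavy-tailed estimates inherit their
outliers. This is a property of the prescribed procedure, not of its
implementation, and is left as is; see the test suite for the measured
operating characteristics.

### Likelihood and model comparison

The log-likelihood is computed as
`LL = −(√(2π) · Σ sigma_i + ½ Σ r_i²)` over RFP residuals, matching the
expression used alongside the source analysis's likelihood-ratio test; a
textbook Gaussian log-likelihood (with `Σ ln sigma_i` and the `n/2·ln 2π`
constant) is available behind a flag. The two differ by residual-independent
terms when both models see the same sigmas, so the LR statistic
`2(LL_alt − LL_null)` is the same either way. The burden model nests the
Hill-only model with 7 extra parameters (three Sigma, three J, S_m);
p-values come from the chi-square reference.

## Prediction and sensitivity

Test-set circuits are never refitted: each parameter vector of the bootstrap
distribution is composed into the cascade and evaluated over the grid with
the dataset's fixed growth rates; bands are pointwise per-HSL percentiles
(2.5/50/97.5 by default), draws with non-converged fixed points dropped and
counted. Univariate sensitivity replaces one Hill parameter class across a
circuit's blocks with independent Gaussians (mean = estimate, CV 25%, so a
parameter's 95% interval is ~0.5p–1.5p); negative draws are rejected and
resampled, which at CV 25% shifts the mean immaterially. Multivariate
sensitivity draws all Hill parameters jointly with the bootstrap correlation
matrix, repaired by eigenvalue clipping if not positive semi-definite.
Prediction performance is the Pearson correlation of observed condition
means against predicted medians, per observable.

## Problem sizes

The analysis drivers use 200 bootstrap draws for the no-burden fit, 60 for
the burden fit, 150 prediction draws and 400 sensitivity draws; the test
suite runs the ODE cross-check at 100 randomised cases, interval-coverage
at 200 repeats × 50 bootstrap draws, and recovery Monte Carlo at 200
datasets — sizes chosen so the full pipeline remains a desk-scale
computation while keeping Monte Carlo error well inside the asserted
tolerances.

## Known limitations

* The Sigma-to-block assignment and the per-strain growth-rate table are
  configuration stand-ins; conclusions that depend on which input block
  carries which LuxR load should be re-checked against the real mapping.
* The weak-RBS tet gate's usage weight (`J_tet_w`) defaults to J_tet/10 on
  the translation-efficiency argument; it was never estimated from data.
* Growth rate is an input, not a prediction: the models take mu as measured
  and say nothing about how load feeds back on growth.
* Percentile-bootstrap undercoverage at n = 3 replicates (above).
* The no-burden model's monotonicity-by-parity guarantee holds at fixed mu;
  condition-dependent growth rates can introduce small non-monotonicities
  near saturation.
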