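# Methods

This note records the models the package implements, the defaults it
ships, the numerical choices behind them, and what the synthetic studies
do and do not demonstrate.

## Input distributions and gates

Single-variant fluorescence is modelled as log-normal with log-location
μ and log-width σ; the linear-scale mean ν = exp(μ + σ²/2) and CV
c = √(exp σ² − 1) are the quantities of scientific interest.  The
log-normal is a deliberate minimal choice: it approximates flow-cytometry
measurements in bacteria and yeast well and makes the binned likelihood
cheap.  No other family is supported.

Gates are contiguous half-open intervals [L_j, U_j), normally log-spaced
with width w = log(u/ℓ)/m.  Semibounded configurations replace the outer
finite edges with the exact sentinels 0 and +∞, so gate probabilities
F(U_j) − F(L_j) form a true partition of the support and censored-
likelihood terms are exact rather than approximated with large cutoffs.
Sampling is by inverse-CDF of uniforms (tested to agree distributionally
with a library log-normal sampler).

`n_cells` in simulations counts cells **drawn**: in bounded
configurations a draw can miss every gate and is lost, exactly as a real
sorter discards out-of-range cells.  This is what produces the boundary
bias of the simple estimators; a "sorted" mode that draws until the
requested number of cells lands in gates is available for the other
reading of a fixed-N experiment.

## Estimators

* **Simple mean/CV**: cells in gate j are imputed φ_j = b√(L_j U_j) with
  b = w/(e^{w/2} − e^{−w/2}), the prefactor that minimises bias for
  log-spaced gates.  The denominator is the number of *sorted* cells —
  out-of-range cells are invisible in real data — which is the mechanism
  behind the large boundary bias these estimators show.
* **Binned MLE**: Nelder–Mead on (μ, log σ); the log-parameterisation
  keeps σ positive without constraints.  Initialisation comes from the
  simple estimators where they are defined, otherwise from the weighted
  moments of log-gate midpoints.  Tolerances 1e−8 on parameters and
  objective, 10⁴ iterations cap.  Zero-count gates contribute 0·log p = 0;
  probabilities are floored at 1e−300 inside the log only.  Data with all
  mass in one gate leave σ unidentified and are flagged `converged=False`.
* **Robust MLE**: the likelihood on fractions with the outlier mixture
  λ_j = (1−γ)p_j + γT_j, γ = 0.05 by default (the value used for the
  32-gate yeast-promoter style reanalysis).  The extreme gates are always
  treated as censoring gates regardless of the recorded boundaries.
* **QC filter** defaults: ≥300 reads; ≤60 % in one gate, ≤90 % in the top
  two gates (top two *by count*, adjacency not required — the rule's
  published wording is ambiguous and this is the stricter reading),
  ≤40 % in either censoring gate; KL(t‖λ) ≤ 0.4 bits.
* **Reference estimator**: mean and divide-by-N variance of log samples —
  the MLE from full-resolution data, used as the efficiency yardstick.
  Benchmarks feed it the *same* raw draws that were binned, making
  efficiency a paired ratio with far less Monte Carlo noise than
  independent simulations would give.

Benchmark gate placement: the published 6-gate, w = 0.8 simulations never
state ℓ and u, so the benchmark helpers take them as configuration; the
package's own studies anchor ℓ = 1 and place the ν grid mid-range
(`centered_benchmark_gates` centres a gate boundary on a requested ν).

## Regrouping, depth, enrichment

Regrouping sums fractions/counts and per-gate totals within consecutive
gate groups.  Raw reads (not depth-corrected cells) are summed, so the
identity partition reproduces original estimates bit-for-bit; depth
factors d_j = h_j/Σ_i r_ij are applied per *original* gate wherever cells
are needed (enrichment Φ, depth-weighted simple mean), which is
equivalent to computing depth before regrouping for those quantities.
Gates with recorded cells but no reads get d_j = 0 with a warning rather
than failing the table.  The depth-weighted simple mean uses the plain
geometric midpoint √(L_j U_j) (no b prefactor), matching how multi-gate
datasets are reduced for fold-change work; fold-change is f = ν/ν_null.

## Dual reporters

Each channel is the product of a shared log-normal factor W (σ_W = 0.40
by default) and a reporter-specific factor; on the log scale widths add
in quadrature and the GFP/RFP ratio cancels W exactly.  The GFP-specific
factor for a variant of mean ν has CV ν^(−1/2) (Poisson-like intrinsic
scaling): σ′ = √log(1+ν⁻¹).  The reference reporter defaults to
σ′_RFP = 0.15, μ_W = μ′_RFP = 0 (pure scale factors, irrelevant to any
result).  The default gate grid uses w = 0.15 over five natural-log units
(>2 decades).

## Sequence-activity models

Additive model G = G₀ + Σ_p H[p, Q_p] in the reference-zero gauge
(H of the reference base is identically 0).  Random models draw the 3P
free entries i.i.d. Normal(−G₀/R, (4G₀/3R)²) with G₀ = 3.0, where the
robustness R is, by construction, the mutation count at which half of
random variants drop below G = 0.  Pairwise terms J are
Normal(0, (S·G₀/R)²) for every position pair and every non-reference base
combination, stored symmetrically; S is the interaction power.  Random
libraries mutate each position independently with probability r_mut/P
(at most one substitution per position); the targeted library is the
reference plus all 3P single mutants.  Activity maps to mean
fluorescence as ν = ν_null/(1+e^G) (two-state repression) or ν = 1+e^G
(expression).

## Least-squares fitting

`lsq_fit_additive` minimises Σ_i (ν̂_i − ν(G(Q⁽ⁱ⁾)))² over (G₀, H) with
an analytic Jacobian (Levenberg–Marquardt), G clipped to ±60 to keep the
exponentials finite.  The default objective weights all variants
equally in fluorescence units.  Sort-seq noise is multiplicative
(standard deviation ∝ ν), so the unweighted objective is statistically
inefficient: a variance calculation for the library-design conditions
shows its single-mutant prediction error exactly matches the targeted
design's (no pooling gain), while the generalized-least-squares optimum
is ~30 % smaller.  `weighting="irls"` therefore runs a few rounds of
iteratively reweighted least squares with weights 1/ν_pred **frozen from
the previous round** — frozen weights keep the estimator unbiased
(weights that move with the current parameters reward inflating
predictions) — and approaches the GLS bound.  The library-design
experiment uses IRLS; the plain objective remains the default for the
basic fitting API.

## Mutual-information fitting

Reads are ranked by model activity G (stable order; exact ties broken by
a fixed seeded jitter of ~1e−9 relative scale, so a constant model
scores ≈0 bits instead of artifact structure).  The ranked gate
indicator table is compressed in blocks of `block` rows (a final partial
block keeps its smaller mass), smoothed along the rank axis by a
Gaussian filter of standard deviation `kernel_frac` × (number of
compressed rows), renormalised to total mass 1, and scored by MI in
bits.  MI is invariant to any strictly monotone transform of G, hence to
the overall scale — and also to the **sign** — of H.

The Monte Carlo fit perturbs one free H entry per step by Normal(0, 1),
renormalises H to unit standard deviation of its free entries (fixing
the scale flat direction), keeps any step that does not decrease MI, and
keeps a decrease δ with probability 2^(−nδ) (n = total reads).  At
realistic n this rule is effectively greedy, and a chain can lock into a
local maximum determined by its random start.  Two mitigations ship:

* **Multi-start** (default 4): short exploration chains from independent
  random inits; the chain with the highest MI is continued for the
  remaining budget.  This plays the role of the temperature-exchange
  step sometimes added to such samplers, at a fraction of the cost.
* **Sign orientation**: `orient="up"/"down"` flips the averaged H so that
  G correlates positively/negatively with gate index, resolving the
  mirror ambiguity from the data.

The fitted model is the ensemble average of H over the continued chain's
second half (configurable via `average_from`), re-gauged to
reference-zero with G₀ = 0 (G₀ is not an MI parameter).

**Block size.** The production default `block=1000` rows per compressed
bin suits datasets of ~10⁶ reads.  At 5·10⁴ reads it leaves only 50 rank
rows, and the MI objective becomes nearly flat across models that agree
only coarsely — fits then plateau at near-maximal MI with poorly
determined H.  The package's desk-scale studies use `block=100` (several
hundred rank rows), where parameter recovery is essentially exact
(r ≈ 0.999 against truth).  Choose the block so the compressed table
keeps a few hundred rows.

## Library-design experiment

Defaults follow the study conditions: P = 50 (all-A reference), G₀ = 3,
24 bounded gates of width 0.3, input CV 0.5, targeted = 151 variants ×
20 cells, random = 3000 variants × 1 cell (budgets matched at ~3000
cells), ν = 1+e^G.  Gate placement is not stated in the source
conditions; the grid is centred on the activity-induced ν range padded
by two input widths.  The figure of merit is the RMS over single mutants
of (estimate − truth)/truth; per-condition values pool squared errors
across repeats (default 20 model draws; the shipped studies use 4–6 to
stay desk-scale).  Random-library variants whose single cell misses all
gates are dropped from the fit.

## Epistasis statistics

IS = f_pred/f_αβ with f_pred = C/(C + AB), C = f_WT⁻¹−1, A = f_α⁻¹−1,
B = f_β⁻¹−1 — exactly 1 when fold-changes follow the additive two-state
model.  K = log(ε_αβ ε_WT/(ε_α ε_β)) uses the natural log (the source
formula leaves the base unstated; it is configurable), and ε is the
enrichment below a user-chosen gate (bottom two gates being the common
default).  No significance thresholds are imposed — none are
established for these scores.

## What the synthetic studies show — and what they do not

The fixture generator draws (ν, σ) per variant, samples multinomial read
fractions from the analytic gate probabilities, and emits the hidden
truth alongside.  It emulates the *statistical* structure of published
gate-fraction exports (32 gates, per-gate totals, per-variant fractions)
but not their failure modes: no mis-sorting beyond the modelled uniform
outlier fraction, no PCR or sequencing-depth artifacts beyond the d_j
factors, no non-log-normal biology, no doublets or spillover.  Passing
tests therefore certify the estimators and fitting machinery under the
stated model, not the model's adequacy for any particular instrument or
organism.

Problem sizes in the shipped tests and in `scripts/acceptance.py` are
the package's own desk-scale choices (e.g. 1000 benchmark repeats at
N = 100 cells; ~5·10⁴ reads and 3·10⁴ Monte Carlo steps for the
model-fitting study; 4–6 design-experiment repeats); all are parameters,
and larger studies only require changing them.
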