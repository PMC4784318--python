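# sortseqkit

Simulation and inference toolkit for **sort-seq** experiment design.

Sort-seq couples fluorescence-activated cell sorting (FACS) of a variant
library with deep sequencing of every sorted bin: for each sequence
variant one observes how its cells distribute across `m` fluorescence
gates — a low-resolution sample of that variant's *input distribution* of
single-cell fluorescence.  The central questions the package addresses,
for experimentalists and modellers planning or re-analysing such assays:

* How precisely can a variant's mean fluorescence ν and cell-to-cell
  variability (CV) be recovered from binned counts, as a function of the
  gate width `w`, the number of gates, and the measurement boundaries?
* When is a single sorting gate (enrichment assay) good enough?
* How should mutant libraries be designed — every variant of interest
  individually, or many random multi-mutants plus a model?

## Model and estimators

Per-cell fluorescence of a variant is log-normal:
`F_{μ,σ}(x) = ½(1 + erf((log x − μ)/(σ√2)))`, with
`ν = exp(μ + σ²/2)` and `c = sqrt(exp(σ²) − 1)` (`c ≈ σ` for small σ).
Gates are log-spaced intervals of width `w = log(u/ℓ)/m`; the outermost
gates may be *semibounded* (censoring) so every cell is captured.

From the per-gate counts `r_j` the package computes:

* **simple mean / CV** — every cell in gate j is imputed
  `φ_j = b·√(L_j U_j)`, `b = w/(e^{w/2} − e^{−w/2})`; the estimates are the
  weighted mean and CV of the `φ_j`;
* **binned MLE** — `(μ̂, σ̂)` maximising
  `Σ_j r_j log(F(U_j) − F(L_j))` (Nelder–Mead), with censored terms for
  semibounded gates;
* **robust MLE** — the same likelihood on read *fractions* `t_j` with an
  outlier mixture `λ_j = (1−γ)p_j + γT_j` (default γ = 5 %), plus a
  three-stage QC filter (read count, concentration rules, KL divergence
  between observed and fitted fractions);
* **reference** — the full-resolution MLE from raw values, the yardstick
  for the *efficiency* `η = MSE(reference)/MSE(binned)`.

On top of estimation: gate **regrouping** (emulate coarser designs from
many-gate data), read-depth normalisation `d_j = h_j/Σ_i r_ij`,
single-gate **enrichment** `ε = 1 − F(τ)`, additive / pairwise-epistatic
**sequence-activity models** `G = G₀ + Σ_p H[p, Q_p] (+ ΣJ)` fit by least
squares or by **mutual-information maximisation** over ranked reads,
per-position **information footprints**, the targeted-vs-random
**library-design** experiment, and the epistasis statistics **IS** and
**K**.

## Worked example

`examples/01_simulate_and_estimate.py` simulates one variant
(ν = 15, CV = 0.9) at 100 cells in 6 semibounded log-spaced gates and
re-estimates its parameters:

```
cells per gate: [3, 11, 28, 35, 19, 4]
truth:          nu =  15.00   cv = 0.900
binned MLE:     nu =  18.69   cv = 1.072
full-res MLE:   nu =  18.07   cv = 1.021
```

The binned MLE lands within a few percent of the full-resolution
estimate computed from the same 100 raw fluorescence values — at this
sample size almost nothing is lost to binning; both differ from the
truth only through the shared sampling noise of a single 100-cell
experiment.

`examples/06_library_design.py` runs the library-design comparison
(robustness R = 10, CV 0.5, 24 gates of width 0.3):

```
targeted design RMS relative error:            0.117
random design, r_mut=   3: RMS rel. error = 0.084 (0.72x targeted)
random design, r_mut=  15: RMS rel. error = 0.185 (1.58x targeted)
```

At 3 mutations per variant the 3000-variant random library estimates
single-mutant means *more* precisely than sorting each single mutant
directly with the same total cell budget; at 15 mutations (above R) most
variants are non-functional and the advantage reverses.

The other scripts in `examples/` cover estimator benchmarking, gate
regrouping and enrichment, dual-reporter noise separation, activity-model
fitting by least squares and mutual information, and epistasis scoring —
each prints a few numbers and a line on what they mean.

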