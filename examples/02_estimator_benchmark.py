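"""Benchmark estimator bias and efficiency over repeated experiments.

Repeats N=100-cell experiments for a mid-range variant at two noise
levels and reports relative bias and efficiency (reference MSE over
sort-seq MSE) of the simple mean and the binned MLE.
"""

import math

import numpy as np

import sortseqkit as sk

rng = np.random.default_rng(1)
bounded = sk.make_log_gates(6, 1.0, math.exp(4.8))
semi = sk.make_log_gates(6, 1.0, math.exp(4.8), semibounded=True)
nu_mid = math.exp(2.4)

for sigma in (0.4, 0.8):
    simple = sk.run_benchmark("simple", bounded, [nu_mid], [sigma], rng, n_repeats=300)
    mle = sk.run_benchmark("mle", semi, [nu_mid], [sigma], rng, n_repeats=300)
    s = simple.cell(nu_mid, sigma, "mean")
    m = mle.cell(nu_mid, sigma, "mean")
    print(
        f"sigma={sigma}: simple-mean bias {100 * s['relative_bias']:+5.2f} % "
        f"(eff {s['efficiency']:.2f}) | MLE bias {100 * m['relative_bias']:+5.2f} % "
        f"(eff {m['efficiency']:.2f})"
    )
print(
    "Both estimators are nearly unbiased mid-range; efficiency near 1 means\n"
    "binning into 6 gates loses little versus measuring every cell exactly."
)
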