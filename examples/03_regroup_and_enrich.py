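"""Regroup a 32-gate dataset into coarser designs and compute enrichment.

A synthetic 32-gate fraction table (in the style of published yeast
promoter exports) is regrouped to 16 gates; the MLE mean barely moves for
broad variants.  The single-gate enrichment (fraction of cells below a
threshold gate) is compared with its analytic expectation.
"""

import math

import numpy as np

import sortseqkit as sk
from sortseqkit.io import generate_fixture_library

rng = np.random.default_rng(2)
gates = sk.make_log_gates(32, math.exp(-2), math.exp(2), semibounded=True)
table, truth = generate_fixture_library(
    5, (math.exp(-0.5), math.exp(0.5)), (0.2, 0.4), gates, 20_000, rng
)

half = sk.regroup_gates(table, sk.uniform_partition(32, 16))
for v in table.variants:
    rec32 = sk.robust_mle_fit(table.fractions.loc[v].to_numpy(), gates, table.T, gamma=0.0)
    rec16 = sk.robust_mle_fit(half.fractions.loc[v].to_numpy(), half.gates, half.T, gamma=0.0)
    change = 100 * (rec16.nu_hat - rec32.nu_hat) / rec32.nu_hat
    eps = sk.enrichment_below(table, v, 16)
    analytic = 1 - sk.expected_enrichment(
        truth.loc[v, "mu"], truth.loc[v, "sigma"], float(gates.lower[16])
    )
    print(
        f"{v}: nu(32 gates) = {rec32.nu_hat:5.3f}, 32->16 change = {change:+6.3f} %, "
        f"enrichment below gate 16 = {eps:.3f} (analytic {analytic:.3f})"
    )
print(
    "Halving the gate count changes broad-variant means by well under a\n"
    "percent, and single-gate enrichment tracks the log-normal tail."
)
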