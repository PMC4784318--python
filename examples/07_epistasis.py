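"""Score a mutation pair for epistasis with IS and the enrichment ratio K.

Fold-changes follow the two-state repression model f = 1/(1+e^G).  For an
additive pair, the predicted double-mutant fold-change matches the
observation (IS = 1); a pairwise interaction term J shifts IS away from 1
and the model-free K away from 0 in a correlated way.
"""

import math

import sortseqkit as sk


def fold(G):
    return 1 / (1 + math.exp(G))


G0, Ha, Hb = -1.0, 1.5, 0.8
f_wt, f_a, f_b = fold(G0), fold(G0 + Ha), fold(G0 + Hb)

for J in (0.0, -1.5):
    f_ab = fold(G0 + Ha + Hb + J)
    pred = sk.predicted_double_fold(f_wt, f_a, f_b)
    IS = sk.interaction_strength(pred, f_ab)
    # enrichment of repressed cells tracks fold-change here: eps ~ 1 - f
    K = sk.enrichment_ratio_K(1 - f_wt, 1 - f_a, 1 - f_b, 1 - f_ab)
    label = "additive pair" if J == 0 else f"interacting pair (J={J})"
    print(f"{label}: f_pred = {pred:.3f}, f_observed = {f_ab:.3f}, IS = {IS:.3f}, K = {K:+.3f}")
print(
    "The additive pair sits at IS = 1 exactly; the interaction shifts both\n"
    "the model-based IS and the model-free K away from that baseline in a\n"
    "correlated direction."
)
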