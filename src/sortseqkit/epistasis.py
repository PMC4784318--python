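"""Pairwise mutation-interaction statistics from sort-seq measurements.

Two probes of epistasis between mutations alpha and beta:

* **Interaction Strength (IS)** — model-based.  Under the additive
  activity model pushed through the two-state repression map, the
  fold-changes of the wild type and the two single mutants predict the
  double mutant's fold-change (f_pred below); IS = f_pred / f_observed,
  so IS = 1 means the pair behaves additively.

* **Enrichment ratio K** — model-free.  With eps the fraction of a
  variant's reads below a sorting threshold (e.g. the bottom two gates),
  K = log(eps_ab * eps_WT / (eps_a * eps_b)) vanishes under a
  multiplicative null and deviates when the pair interacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class EpistasisRecord:
    alpha: str
    beta: str
    f_pred: float | None = None
    IS: float | None = None
    K: float | None = None


def predicted_double_fold(f_WT: float, f_alpha: float, f_beta: float) -> float:
    """Additive-model prediction of the double mutant's fold-change.

    f_pred = C / (C + A*B) with C = 1/f_WT - 1, A = 1/f_alpha - 1,
    B = 1/f_beta - 1.  A neutral mutation (f_alpha = f_WT) cancels out and
    leaves f_pred = f_beta; f_WT = 1 (no repression at all) degenerates to
    f_pred = 0.
    """
    for name, f in (("f_WT", f_WT), ("f_alpha", f_alpha), ("f_beta", f_beta)):
        if not 0 < f <= 1:
            raise ValueError(f"{name} must be in (0, 1], got {f}")
    C = 1.0 / f_WT - 1.0
    A = 1.0 / f_alpha - 1.0
    B = 1.0 / f_beta - 1.0
    denom = C + A * B
    if denom == 0:
        return 0.0
    return C / denom


def interaction_strength(f_pred: float, f_alphabeta: float) -> float:
    """IS = f_pred / f_alphabeta; 1 means additive-model consistency."""
    if f_alphabeta <= 0:
        raise ValueError("f_alphabeta must be positive")
    return f_pred / f_alphabeta


def enrichment_ratio_K(
    eps_WT: float,
    eps_alpha: float,
    eps_beta: float,
    eps_alphabeta: float,
    base: float | None = None,
) -> float:
    """K = log(eps_ab * eps_WT / (eps_a * eps_b)); natural log by default."""
    for name, e in (
        ("eps_WT", eps_WT),
        ("eps_alpha", eps_alpha),
        ("eps_beta", eps_beta),
        ("eps_alphabeta", eps_alphabeta),
    ):
        if e <= 0:
            raise ValueError(f"{name} must be positive, got {e}")
    k = math.log(eps_alphabeta * eps_WT / (eps_alpha * eps_beta))
    if base is not None:
        k /= math.log(base)
    return k


def epistasis_record(
    alpha: str,
    beta: str,
    f_WT: float,
    f_alpha: float,
    f_beta: float,
    f_alphabeta: float,
    eps_WT: float | None = None,
    eps_alpha: float | None = None,
    eps_beta: float | None = None,
    eps_alphabeta: float | None = None,
) -> EpistasisRecord:
    """Bundle IS (always) and K (when enrichments are supplied) for a pair."""
    f_pred = predicted_double_fold(f_WT, f_alpha, f_beta)
    IS = interaction_strength(f_pred, f_alphabeta)
    K = None
    if None not in (eps_WT, eps_alpha, eps_beta, eps_alphabeta):
        K = enrichment_ratio_K(eps_WT, eps_alpha, eps_beta, eps_alphabeta)
    return EpistasisRecord(alpha=alpha, beta=beta, f_pred=f_pred, IS=IS, K=K)
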