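"""Fitting sequence-activity models to sort-seq data.

Two complementary routes:

* **Least squares** — per-variant mean-fluorescence estimates are fit
  through an explicit activity-to-fluorescence map (the two-state
  repression model nu = nu_null/(1+e^G), or the expression map
  nu = 1+e^G), minimising the squared difference between predicted and
  estimated means over (G0, H).

* **Mutual information** — no map and no distributional assumption.  Reads
  are ranked by model activity; the rank-by-gate joint table (compressed
  in blocks and smoothed along the rank axis with a narrow Gaussian
  filter) has high mutual information exactly when the model orders reads
  the way fluorescence did.  A Metropolis-like Monte Carlo perturbs one
  H entry at a time, always keeping changes that do not decrease MI and
  keeping an MI decrease of delta with probability 2^(-n*delta) (n =
  total reads).  Because only the *ranking* of G matters, the overall
  scale of H is a flat direction; H is renormalised to unit standard
  deviation after every step, and the fitted model is reported as an
  ensemble average over the post-convergence iterations.

The per-position information footprint — MI between base identity and
gate index — flags functionally sensitive positions with no model at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.special import ndtr

from .seqmodel import (
    ActivityModel,
    SequenceVariant,
    encode_sequence,
)


@dataclass(frozen=True)
class ReadGateMatrix:
    """Per-read sequences and gate assignments.

    ``seq_matrix`` is an (n, P) uint8 matrix of encoded sequences and
    ``gate`` the 0-based gate index of each read; ``m`` the gate count.
    """

    seq_matrix: np.ndarray
    gate: np.ndarray
    m: int

    def __post_init__(self) -> None:
        seq = np.asarray(self.seq_matrix, dtype=np.uint8)
        gate = np.asarray(self.gate, dtype=np.int64)
        object.__setattr__(self, "seq_matrix", seq)
        object.__setattr__(self, "gate", gate)
        if seq.ndim != 2 or gate.ndim != 1 or seq.shape[0] != gate.size:
            raise ValueError("seq_matrix rows and gate entries must correspond")
        if gate.size and (gate.min() < 0 or gate.max() >= self.m):
            raise ValueError("gate indices out of range")

    @property
    def n(self) -> int:
        return self.gate.size

    @property
    def P(self) -> int:
        return self.seq_matrix.shape[1]

    @classmethod
    def from_reads(cls, sequences, gate_indices, m: int) -> "ReadGateMatrix":
        """Build from per-read sequence strings and 0-based gate indices."""
        mat = np.stack([encode_sequence(s) for s in sequences])
        return cls(seq_matrix=mat, gate=np.asarray(gate_indices), m=m)

    @classmethod
    def from_counts(cls, variants, counts, m: int) -> "ReadGateMatrix":
        """Expand per-variant per-gate counts into one row per read."""
        seqs, gates = [], []
        for variant, row in zip(variants, counts):
            seq = variant.bases if isinstance(variant, SequenceVariant) else variant
            codes = encode_sequence(seq)
            for j, r in enumerate(np.asarray(row, dtype=int)):
                if r > 0:
                    seqs.extend([codes] * r)
                    gates.extend([j] * r)
        return cls(seq_matrix=np.stack(seqs), gate=np.asarray(gates), m=m)


@dataclass(frozen=True)
class LsqFitResult:
    model: ActivityModel
    converged: bool
    cost: float


def _free_indices(reference: str) -> tuple[np.ndarray, np.ndarray]:
    """(position, base) index arrays of the 3P non-reference H entries."""
    ref = encode_sequence(reference)
    P = ref.size
    pos = np.repeat(np.arange(P), 3)
    bases = np.concatenate([[q for q in range(4) if q != r] for r in ref])
    return pos, bases.astype(np.int64)


def _design_matrix(seq_matrix: np.ndarray, reference: str) -> np.ndarray:
    """(n, 3P) indicator matrix of non-reference bases per read/variant."""
    pos, bases = _free_indices(reference)
    return (seq_matrix[:, pos] == bases[None, :]).astype(float)


def lsq_fit_additive(
    nu_hat,
    sequences,
    reference: str,
    nu_null: float | None = None,
    link: str = "repression",
    init: np.ndarray | None = None,
    weighting: str = "none",
    irls_iterations: int = 3,
) -> LsqFitResult:
    """Nonlinear least-squares fit of (G0, H) to per-variant mean estimates.

    ``link`` selects the activity-to-fluorescence map: "repression"
    (nu = nu_null/(1+e^G), requires nu_null) or "expression" (nu = 1+e^G).

    ``weighting="none"`` minimises the plain squared differences in
    fluorescence units.  Sort-seq measurement noise is multiplicative
    (its standard deviation scales with the mean), so the plain objective
    over-weights bright variants; ``weighting="irls"`` runs iteratively
    reweighted least squares with weights 1/nu_predicted frozen from the
    previous round, which is unbiased and close to the generalized
    least-squares optimum under constant-CV noise.
    """
    nu_hat = np.asarray(nu_hat, dtype=float)
    seqs = [
        s.bases if isinstance(s, SequenceVariant) else s for s in sequences
    ]
    if len(seqs) != nu_hat.size:
        raise ValueError("one sequence per estimate required")
    mat = np.stack([encode_sequence(s) for s in seqs])
    X = _design_matrix(mat, reference)
    n_free = X.shape[1]
    if nu_hat.size < n_free + 1:
        import warnings

        warnings.warn(
            f"{nu_hat.size} observations for {n_free + 1} parameters", stacklevel=2
        )
    if link == "repression":
        if nu_null is None or nu_null <= 0:
            raise ValueError("repression link needs nu_null > 0")

        def predict(G):
            return nu_null / (1.0 + np.exp(G))

        def dpredict(G):
            e = np.exp(G)
            return -nu_null * e / (1.0 + e) ** 2

        g0_init = float(np.median(np.log(np.clip(nu_null / np.clip(nu_hat, 1e-12, None) - 1.0, 1e-6, 1e6))))
    elif link == "expression":

        def predict(G):
            return 1.0 + np.exp(G)

        def dpredict(G):
            return np.exp(G)

        g0_init = float(np.median(np.log(np.clip(nu_hat - 1.0, 1e-6, None))))
    else:
        raise ValueError(f"unknown link {link!r}")

    if weighting not in ("none", "irls"):
        raise ValueError(f"unknown weighting {weighting!r}")

    Xa = np.concatenate([np.ones((X.shape[0], 1)), X], axis=1)
    weights = np.ones(X.shape[0])

    def unpack(theta):
        return np.clip(theta[0] + X @ theta[1:], -60.0, 60.0)

    def residuals(theta):
        return (nu_hat - predict(unpack(theta))) / weights

    def jac(theta):
        d = dpredict(unpack(theta)) / weights
        return -d[:, None] * Xa

    theta0 = np.zeros(1 + n_free) if init is None else np.asarray(init, dtype=float)
    if init is None:
        theta0[0] = g0_init
    n_rounds = irls_iterations if weighting == "irls" else 1
    for _ in range(n_rounds):
        res = least_squares(residuals, theta0, jac=jac, method="lm", max_nfev=20000)
        theta0 = res.x
        if weighting == "irls":
            weights = np.clip(np.abs(predict(unpack(res.x))), 1e-3, None)
    pos, bases = _free_indices(reference)
    H = np.zeros((len(reference), 4))
    H[pos, bases] = res.x[1:]
    model = ActivityModel(reference=reference, G0=float(res.x[0]), H=H)
    return LsqFitResult(model=model, converged=bool(res.success), cost=float(res.cost))


def information_footprint(reads: ReadGateMatrix) -> np.ndarray:
    """Per-position MI (bits) between base identity and gate index."""
    n, m = reads.n, reads.m
    if n < 1:
        raise ValueError("no reads")
    out = np.zeros(reads.P)
    gate = reads.gate
    for p in range(reads.P):
        codes = reads.seq_matrix[:, p].astype(np.int64)
        a = np.bincount(codes * m + gate, minlength=4 * m).reshape(4, m)
        A = a / n
        Aq = A.sum(axis=1, keepdims=True)
        Aj = A.sum(axis=0, keepdims=True)
        mask = A > 0
        out[p] = float(
            (A[mask] * np.log2(A[mask] / (Aq @ Aj)[mask])).sum()
        )
    return out


def _rank_mi_machinery(n: int, m: int, block: int, kernel_frac: float):
    """Precompute block edges and the rank-axis smoothing kernel."""
    n_blocks = math.ceil(n / block)
    sigma = kernel_frac * n_blocks
    i = np.arange(n_blocks)
    diff = i[:, None] - i[None, :]
    kernel = ndtr(diff / sigma) - ndtr((diff - 1) / sigma)
    return n_blocks, kernel


def _mi_from_scores(
    scores: np.ndarray,
    tiebreak: np.ndarray,
    gate: np.ndarray,
    m: int,
    block: int,
    n_blocks: int,
    kernel: np.ndarray,
) -> float:
    n = scores.size
    # tiebreak is a fixed tiny jitter: it decides the order of exactly tied
    # scores (identical sequences, or a constant model) without disturbing
    # the ranking of distinct ones
    order = np.argsort(scores + tiebreak)
    rows = np.arange(n) // block
    C = np.bincount(rows * m + gate[order], minlength=n_blocks * m).reshape(
        n_blocks, m
    ) / float(n)
    D = kernel @ C
    D /= D.sum()
    Di = D.sum(axis=1, keepdims=True)
    Dj = D.sum(axis=0, keepdims=True)
    mask = D > 0
    return float((D[mask] * np.log2(D[mask] / (Di @ Dj)[mask])).sum())


def mi_of_model(
    reads: ReadGateMatrix,
    model: ActivityModel,
    block: int = 1000,
    kernel_frac: float = 0.01,
    rng: np.random.Generator | None = None,
) -> float:
    """Mutual information (bits) between model-activity rank and gate.

    Reads are ranked by G (ascending, seeded random tiebreak), compressed
    in blocks of ``block`` rows (a final partial block keeps its smaller
    mass), smoothed along the rank axis with a Gaussian filter whose
    standard deviation is ``kernel_frac`` times the number of compressed
    rows, renormalised to total mass 1, and scored by MI.  Invariant under
    any strictly monotone transform of G, including rescaling H.
    """
    if reads.n < block:
        raise ValueError(f"need at least block={block} reads, got {reads.n}")
    rng = rng or np.random.default_rng(0)
    g = _read_scores(reads, model.H)
    tb = _tiebreak_jitter(g, reads.n, rng)
    n_blocks, kernel = _rank_mi_machinery(reads.n, reads.m, block, kernel_frac)
    return _mi_from_scores(g, tb, reads.gate, reads.m, block, n_blocks, kernel)


def _tiebreak_jitter(scores: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    eps = 1e-9 * (float(np.std(scores)) + 1.0)
    return rng.random(n) * eps


def _read_scores(reads: ReadGateMatrix, H: np.ndarray) -> np.ndarray:
    pos = np.arange(reads.P)
    return H[pos, reads.seq_matrix.astype(np.int64)].sum(axis=1)


@dataclass(frozen=True)
class MIFitResult:
    model: ActivityModel
    mi_trace: np.ndarray
    acceptance_rate: float


def mi_fit_montecarlo(
    reads: ReadGateMatrix,
    reference: str,
    rng: np.random.Generator,
    init: ActivityModel | None = None,
    n_steps: int = 300_000,
    average_from: int | None = None,
    block: int = 1000,
    kernel_frac: float = 0.01,
    orient: str = "none",
    n_starts: int = 4,
) -> MIFitResult:
    """Monte Carlo maximisation of rank/gate mutual information over H.

    One randomly chosen non-reference H[p, q] is perturbed by Normal(0, 1)
    per step; H is renormalised to unit standard deviation of its free
    entries after every step (scale is a flat direction of MI).  Changes
    that do not decrease MI are kept; a decrease of delta is kept with
    probability 2^(-n*delta).  At large n that rule is effectively greedy,
    so a chain can lock into a local maximum set by its random start; as a
    guard, ``n_starts`` short exploration chains are run from independent
    random inits and the one reaching the highest MI is continued for the
    remaining budget (``n_starts=1`` disables this; an explicit ``init``
    also does).  The returned model averages H over the continued chain's
    steps from ``average_from`` (default: its second half) onward, in the
    reference-zero gauge with G0 = 0.

    MI is blind to the sign of H (ranking by G and by -G score the same),
    so the chain converges to one of two mirror solutions.  ``orient``
    resolves the ambiguity from the data: "up" flips H if needed so that
    larger G goes with higher gate index (activity raises fluorescence),
    "down" the opposite (activity represses), "none" leaves the chain's
    sign untouched.
    """
    if reads.n < block:
        raise ValueError(f"need at least block={block} reads, got {reads.n}")
    P = reads.P
    if len(reference) != P:
        raise ValueError("reference length mismatch")
    pos_free, base_free = _free_indices(reference)
    n_free = pos_free.size

    n = reads.n
    m = reads.m
    gate = reads.gate
    tb = _tiebreak_jitter(np.zeros(1), n, rng)
    n_blocks, kernel = _rank_mi_machinery(n, m, block, kernel_frac)
    # per-free-parameter read masks let a single-entry perturbation update
    # all read scores with one indexed add
    masks = [
        np.flatnonzero(reads.seq_matrix[:, p] == q)
        for p, q in zip(pos_free, base_free)
    ]

    def normalized(H):
        s = H[pos_free, base_free].std()
        return H / s if s > 0 else H

    def new_state(H):
        H = normalized(H)
        g = _read_scores(reads, H)
        mi = _mi_from_scores(g, tb, gate, m, block, n_blocks, kernel)
        return [H, g, mi]

    def run_chain(state, k, H_sum=None, trace_out=None):
        accepted = 0
        H, g, mi_cur = state
        for step in range(k):
            idx = int(rng.integers(n_free))
            delta = float(rng.normal())
            H_trial = H.copy()
            H_trial[pos_free[idx], base_free[idx]] += delta
            scale = H_trial[pos_free, base_free].std()
            if scale > 0:
                H_trial /= scale
                g_trial = g.copy()
                g_trial[masks[idx]] += delta
                g_trial /= scale
                mi_trial = _mi_from_scores(
                    g_trial, tb, gate, m, block, n_blocks, kernel
                )
                accept = mi_trial >= mi_cur
                if not accept:
                    accept = rng.random() < 2.0 ** (-n * (mi_cur - mi_trial))
                if accept:
                    H, g, mi_cur = H_trial, g_trial, mi_trial
                    accepted += 1
            if trace_out is not None:
                trace_out.append(mi_cur)
            if H_sum is not None:
                H_sum += H
        state[0], state[1], state[2] = H, g, mi_cur
        return accepted

    trace: list[float] = []
    total_accepted = 0
    if init is not None:
        state = new_state(init.H.copy())
        continue_steps = n_steps
    elif n_starts <= 1:
        H0 = np.zeros((P, 4))
        H0[pos_free, base_free] = rng.normal(0.0, 1.0, size=n_free)
        state = new_state(H0)
        continue_steps = n_steps
    else:
        explore = max(1, n_steps // (2 * n_starts))
        states = []
        for _ in range(n_starts):
            H0 = np.zeros((P, 4))
            H0[pos_free, base_free] = rng.normal(0.0, 1.0, size=n_free)
            st = new_state(H0)
            total_accepted += run_chain(st, explore, trace_out=trace)
            states.append(st)
        state = max(states, key=lambda st: st[2])
        continue_steps = n_steps - n_starts * explore

    if average_from is None:
        average_from = len(trace) + continue_steps // 2
    pre = max(0, min(continue_steps, average_from - len(trace)))
    total_accepted += run_chain(state, pre, trace_out=trace)
    H_sum = np.zeros((P, 4))
    post = continue_steps - pre
    total_accepted += run_chain(state, post, H_sum=H_sum, trace_out=trace)
    H_avg = H_sum / post if post > 0 else state[0]

    H_avg[np.arange(P), encode_sequence(reference)] = 0.0
    if orient != "none":
        if orient not in ("up", "down"):
            raise ValueError(f"unknown orient {orient!r}")
        g_avg = _read_scores(reads, H_avg)
        corr = float(np.corrcoef(g_avg, gate)[0, 1])
        if (orient == "up" and corr < 0) or (orient == "down" and corr > 0):
            H_avg = -H_avg
    model = ActivityModel(reference=reference, G0=0.0, H=H_avg)
    return MIFitResult(
        model=model,
        mi_trace=np.asarray(trace),
        acceptance_rate=total_accepted / max(len(trace), 1),
    )
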