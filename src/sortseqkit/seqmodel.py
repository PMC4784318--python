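"""Sequence-to-activity models and mutant-library construction.

The additive model assigns a variant the activity

    G(Q) = G0 + sum_p H[p, Q_p]

where H[p, q] is the contribution of base q at position p (the reference
base contributes 0 — the gauge convention used throughout).  An optional
pairwise term J[p1, q1, p2, q2] adds epistatic interactions between
non-reference bases.  Random model generators parameterise the effect
sizes by *robustness* R — the number of random mutations after which half
of the variants have G < 0 — and *interaction power* S, the ratio of the
interaction scale to the additive scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}


def encode_sequence(seq: str) -> np.ndarray:
    """Map an ACGT string to a uint8 index vector."""
    try:
        return np.array([_BASE_INDEX[b] for b in seq], dtype=np.uint8)
    except KeyError as exc:
        raise ValueError(f"unknown base {exc.args[0]!r}") from exc


def decode_sequence(codes: np.ndarray) -> str:
    return "".join(ALPHABET[int(c)] for c in codes)


@dataclass(frozen=True)
class SequenceVariant:
    bases: str
    id: str = ""

    def __post_init__(self) -> None:
        if any(b not in _BASE_INDEX for b in self.bases):
            raise ValueError(f"sequence contains non-ACGT characters: {self.bases!r}")

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def codes(self) -> np.ndarray:
        return encode_sequence(self.bases)


@dataclass
class ActivityModel:
    """Additive (optionally pairwise-interacting) sequence-activity model.

    ``H`` has shape (P, 4) with H[p, reference base] == 0.  ``J``, when
    present, has shape (P, 4, P, 4), is symmetric under pair swap, and is
    zero whenever either base is the reference at its position.
    """

    reference: str
    G0: float
    H: np.ndarray
    J: np.ndarray | None = None
    R: float | None = field(default=None)

    def __post_init__(self) -> None:
        self.H = np.asarray(self.H, dtype=float)
        P = len(self.reference)
        if self.H.shape != (P, 4):
            raise ValueError(f"H must have shape ({P}, 4)")
        ref = encode_sequence(self.reference)
        if not np.allclose(self.H[np.arange(P), ref], 0.0):
            raise ValueError("H must be 0 for the reference base at each position")
        if self.J is not None:
            self.J = np.asarray(self.J, dtype=float)
            if self.J.shape != (P, 4, P, 4):
                raise ValueError(f"J must have shape ({P}, 4, {P}, 4)")

    @property
    def P(self) -> int:
        return len(self.reference)

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame | None]:
        """Serialize to (additive table, interaction table or None)."""
        rows = [
            {"position": p + 1, "base": ALPHABET[q], "H": self.H[p, q]}
            for p in range(self.P)
            for q in range(4)
        ]
        h_frame = pd.DataFrame(rows)
        if self.J is None:
            return h_frame, None
        p1, q1, p2, q2 = np.nonzero(self.J)
        keep = (p1 < p2) | ((p1 == p2) & (q1 < q2))
        j_frame = pd.DataFrame(
            {
                "p1": p1[keep] + 1,
                "q1": [ALPHABET[q] for q in q1[keep]],
                "p2": p2[keep] + 1,
                "q2": [ALPHABET[q] for q in q2[keep]],
                "J": self.J[p1[keep], q1[keep], p2[keep], q2[keep]],
            }
        )
        return h_frame, j_frame


def activity(model: ActivityModel, variant: SequenceVariant | str) -> float:
    """Evaluate G (or G_I when interactions are present) for one variant."""
    seq = variant.bases if isinstance(variant, SequenceVariant) else variant
    if len(seq) != model.P:
        raise ValueError(f"variant length {len(seq)} != model length {model.P}")
    codes = encode_sequence(seq)
    pos = np.arange(model.P)
    g = model.G0 + float(model.H[pos, codes].sum())
    if model.J is not None:
        sub = model.J[pos[:, None], codes[:, None], pos[None, :], codes[None, :]]
        g += float(np.triu(sub, k=1).sum())
    return g


def activity_many(model: ActivityModel, seq_matrix: np.ndarray) -> np.ndarray:
    """Vectorized activities for an (n, P) matrix of encoded sequences."""
    seq_matrix = np.asarray(seq_matrix)
    n, P = seq_matrix.shape
    if P != model.P:
        raise ValueError("sequence length mismatch")
    pos = np.arange(P)
    g = model.G0 + model.H[pos, seq_matrix].sum(axis=1)
    if model.J is not None:
        ref = encode_sequence(model.reference)
        for i in range(n):
            codes = seq_matrix[i]
            mut = np.flatnonzero(codes != ref)
            if mut.size >= 2:
                sub = model.J[
                    mut[:, None], codes[mut][:, None], mut[None, :], codes[mut][None, :]
                ]
                g[i] += np.triu(sub, k=1).sum()
    return g


def sample_additive_model(
    P: int,
    R: float,
    rng: np.random.Generator,
    G0: float = 3.0,
    reference: str | None = None,
) -> ActivityModel:
    """Draw a random additive model with robustness R.

    Each non-reference H[p, q] is i.i.d. Normal(-G0/R, (4*G0/(3*R))^2), so
    after R random mutations the expected activity is 0 and about half of
    R-mutation variants are non-functional (G < 0).
    """
    if R <= 0:
        raise ValueError("R must be positive")
    reference = reference or "A" * P
    if len(reference) != P:
        raise ValueError("reference length != P")
    ref = encode_sequence(reference)
    H = rng.normal(-G0 / R, 4.0 * G0 / (3.0 * R), size=(P, 4))
    H[np.arange(P), ref] = 0.0
    return ActivityModel(reference=reference, G0=G0, H=H, R=R)


def sample_interaction_terms(
    model: ActivityModel, S: float, rng: np.random.Generator
) -> ActivityModel:
    """Add pairwise terms J ~ Normal(0, (S*G0/R)^2) to an additive model.

    Terms are drawn for every position pair and every combination of
    non-reference bases, stored symmetrically.  S = 0 gives J identically
    zero (the purely additive model).
    """
    if S < 0:
        raise ValueError("S must be nonnegative")
    if model.R is None:
        raise ValueError("model must record its robustness R")
    P = model.P
    ref = encode_sequence(model.reference)
    J = np.zeros((P, 4, P, 4))
    if S > 0:
        scale = S * model.G0 / model.R
        draw = rng.normal(0.0, scale, size=(P, 4, P, 4))
        nonref = np.ones((P, 4), dtype=bool)
        nonref[np.arange(P), ref] = False
        mask = (
            nonref[:, :, None, None]
            & nonref[None, None, :, :]
            & (np.arange(P)[:, None, None, None] < np.arange(P)[None, None, :, None])
        )
        J[mask] = draw[mask]
        J = J + np.transpose(J, (2, 3, 0, 1))
    return ActivityModel(reference=model.reference, G0=model.G0, H=model.H, J=J, R=model.R)


def activity_to_mean(G, mode: str, nu_null: float | None = None):
    """Map activity to mean fluorescence.

    mode="repression": nu = nu_null / (1 + e^G), the two-state occupancy
    model (higher activity represses more).  mode="expression":
    nu = 1 + e^G (higher activity means brighter cells).
    """
    G = np.asarray(G, dtype=float)
    if mode == "repression":
        if nu_null is None or nu_null <= 0:
            raise ValueError("repression mode needs nu_null > 0")
        out = nu_null / (1.0 + np.exp(G))
    elif mode == "expression":
        out = 1.0 + np.exp(G)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(out) if out.ndim == 0 else out


def make_random_library(
    reference: SequenceVariant | str,
    r_mut: float,
    rng: np.random.Generator,
    n_variants: int = 3000,
) -> list[SequenceVariant]:
    """Random mutant library: each position mutates independently with
    probability r_mut/P, the substitute drawn uniformly from the three
    alternatives, giving a mean of r_mut mutations per variant."""
    seq = reference.bases if isinstance(reference, SequenceVariant) else reference
    ref = encode_sequence(seq)
    P = ref.size
    if not 0 < r_mut < P:
        raise ValueError("need 0 < r_mut < P")
    hits = rng.random((n_variants, P)) < r_mut / P
    # uniform over the 3 non-reference bases via a 1..3 offset mod 4
    offsets = rng.integers(1, 4, size=(n_variants, P), dtype=np.uint8)
    codes = np.where(hits, (ref[None, :] + offsets) % 4, ref[None, :]).astype(np.uint8)
    return [
        SequenceVariant(bases=decode_sequence(codes[i]), id=f"rand_{i}")
        for i in range(n_variants)
    ]


def make_targeted_library(reference: SequenceVariant | str) -> list[SequenceVariant]:
    """The reference plus all 3P single-position mutants."""
    seq = reference.bases if isinstance(reference, SequenceVariant) else reference
    out = [SequenceVariant(bases=seq, id="WT")]
    for p, ref_base in enumerate(seq):
        for q in ALPHABET:
            if q != ref_base:
                mut = seq[:p] + q + seq[p + 1 :]
                out.append(SequenceVariant(bases=mut, id=f"{ref_base}{p + 1}{q}"))
    return out
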