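"""Gate regrouping, read-depth normalization, enrichment and fold-change.

Combining reads from adjacent gates of a many-gate experiment emulates a
coarser sorting design from the same data: the combined gate spans the
outer boundaries of its members, and fractions/counts simply add.  When
per-gate sequencing depth differs from the number of sorted cells, raw
read counts r_ij are converted to estimated cell counts with the per-gate
depth factor d_j = h_j / sum_i r_ij (h_j = sorted cells in gate j), so a
variant's estimated cells in gate j are d_j * r_ij.  Enrichment below a
gate index and fold-change relative to a non-functional reference follow
directly from the depth-corrected cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distributions import GateConfig
from .estimate import GateFractionTable


@dataclass(frozen=True)
class ReadCountTable:
    """Raw per-variant per-gate read counts with per-gate sorted totals.

    ``counts`` is a variants x gates DataFrame; ``h`` the per-gate number
    of sorted cells; ``sequences`` an optional variant -> sequence map.
    """

    counts: pd.DataFrame
    gates: GateConfig
    h: np.ndarray
    sequences: pd.Series | None = None

    def __post_init__(self) -> None:
        h = np.asarray(self.h, dtype=float)
        object.__setattr__(self, "h", h)
        if self.counts.shape[1] != self.gates.m or h.size != self.gates.m:
            raise ValueError("count columns, h and gates disagree on m")
        if (self.counts.to_numpy() < 0).any() or np.any(h < 0):
            raise ValueError("counts and h must be nonnegative")

    @property
    def variants(self) -> list:
        return list(self.counts.index)


def depth_factors(table: ReadCountTable) -> np.ndarray:
    """Per-gate reads-to-cells conversion d_j = h_j / sum_i r_ij.

    Gates with recorded cells but no reads cannot be converted; they get
    d_j = 0 with a warning (their reads contribute nothing anyway).
    """
    totals = table.counts.to_numpy(float).sum(axis=0)
    d = np.zeros(table.gates.m)
    ok = totals > 0
    d[ok] = table.h[ok] / totals[ok]
    orphan = (~ok) & (table.h > 0)
    if orphan.any():
        warnings.warn(
            f"gates {np.flatnonzero(orphan) + 1} report sorted cells but no reads; "
            "dropping them from depth normalization",
            stacklevel=2,
        )
    return d


def cells_matrix(table: ReadCountTable) -> pd.DataFrame:
    """Estimated sorted cells per variant and gate, d_j * r_ij."""
    return table.counts * depth_factors(table)


def _validate_partition(grouping, m: int) -> list[list[int]]:
    groups = [list(g) for g in grouping]
    flat = [j for g in groups for j in g]
    if flat != list(range(m)):
        raise ValueError(
            "grouping must partition gate indices 0..m-1 into consecutive runs"
        )
    return groups


def pair_partition(m: int) -> list[list[int]]:
    """Partition of m gates into consecutive pairs (m must be even)."""
    if m % 2:
        raise ValueError("pairing requires an even number of gates")
    return [[2 * j, 2 * j + 1] for j in range(m // 2)]


def uniform_partition(m: int, k: int) -> list[list[int]]:
    """Partition of m gates into k equal consecutive groups."""
    if m % k:
        raise ValueError(f"{m} gates do not split evenly into {k} groups")
    size = m // k
    return [list(range(j * size, (j + 1) * size)) for j in range(k)]


def _regroup_gates_config(gates: GateConfig, groups: list[list[int]]) -> GateConfig:
    lower = np.array([gates.lower[g[0]] for g in groups])
    upper = np.array([gates.upper[g[-1]] for g in groups])
    return GateConfig(lower, upper)


def regroup_gates(table, grouping):
    """Combine adjacent gates of a fraction or count table.

    ``grouping`` is an ordered partition of the 0-based gate indices into
    consecutive runs, e.g. ``[[0, 1], [2, 3]]``.  Fractions/counts and the
    per-gate totals sum within each group; per-variant normalization is
    preserved.  The identity partition returns an equivalent table.
    """
    if isinstance(table, GateFractionTable):
        m = table.gates.m
        groups = _validate_partition(grouping, m)
        new_gates = _regroup_gates_config(table.gates, groups)
        vals = table.fractions.to_numpy(float)
        new_vals = np.stack([vals[:, g].sum(axis=1) for g in groups], axis=1)
        new_T = np.array([table.T[g].sum() for g in groups])
        frame = pd.DataFrame(
            new_vals,
            index=table.fractions.index,
            columns=[f"t_{j + 1}" for j in range(len(groups))],
        )
        return GateFractionTable(fractions=frame, gates=new_gates, T=new_T)
    if isinstance(table, ReadCountTable):
        m = table.gates.m
        groups = _validate_partition(grouping, m)
        new_gates = _regroup_gates_config(table.gates, groups)
        vals = table.counts.to_numpy(float)
        new_vals = np.stack([vals[:, g].sum(axis=1) for g in groups], axis=1)
        new_h = np.array([table.h[g].sum() for g in groups])
        frame = pd.DataFrame(
            new_vals,
            index=table.counts.index,
            columns=[f"r_{j + 1}" for j in range(len(groups))],
        )
        return ReadCountTable(
            counts=frame, gates=new_gates, h=new_h, sequences=table.sequences
        )
    raise TypeError(f"cannot regroup {type(table).__name__}")


def enrichment_below(table, variant, m_prime: int) -> float:
    """Fraction of a variant's cells in gate ``m_prime`` (1-based) or below.

    Count tables are depth-normalized first (d_j * r_ij); fraction tables
    sum the stored fractions directly.
    """
    if isinstance(table, GateFractionTable):
        m = table.gates.m
        if not 1 <= m_prime <= m:
            raise ValueError(f"m_prime must be in 1..{m}")
        t = table.fractions.loc[variant].to_numpy(float)
        return float(t[:m_prime].sum())
    if isinstance(table, ReadCountTable):
        m = table.gates.m
        if not 1 <= m_prime <= m:
            raise ValueError(f"m_prime must be in 1..{m}")
        cells = cells_matrix(table).loc[variant].to_numpy(float)
        total = cells.sum()
        if total == 0:
            raise ValueError(f"variant {variant!r} has no reads")
        return float(cells[:m_prime].sum() / total)
    raise TypeError(f"cannot compute enrichment for {type(table).__name__}")


def weighted_simple_mean(table: ReadCountTable, variant) -> float:
    """Depth-weighted simple mean sum_j d_j r_ij sqrt(L_j U_j) / sum_j d_j r_ij.

    The per-gate representative here is the plain geometric midpoint
    sqrt(L_j U_j) (no bias-minimising prefactor).
    """
    gates = table.gates
    if gates.semibounded_low or gates.semibounded_high:
        raise ValueError("weighted simple mean needs bounded gates")
    cells = cells_matrix(table).loc[variant].to_numpy(float)
    total = cells.sum()
    if total == 0:
        raise ValueError(f"variant {variant!r} has no reads")
    phi = np.sqrt(gates.lower * gates.upper)
    return float(cells @ phi / total)


def fold_change(nu: float, nu_null: float) -> float:
    """Fold-change f = nu / nu_null relative to a non-functional reference."""
    if nu_null <= 0:
        raise ValueError("nu_null must be positive")
    return nu / nu_null
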