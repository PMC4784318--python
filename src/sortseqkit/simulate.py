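"""Sampling of sort-seq experiments: cell draws, gate binning, dual reporters.

Sampling follows the inverse-CDF recipe: a uniform y in (0, 1) is mapped to
a fluorescence X = F^-1(y) of the variant's log-normal input distribution,
and the cell is assigned to the gate j with L_j <= X < U_j.  In bounded
configurations a draw can miss every gate; by default those cells still
count toward the number drawn (they are real cells the sorter discards),
which is the source of boundary bias in downstream estimates.

The dual-reporter model expresses each fluorescence channel as the product
of a shared (extrinsic) log-normal factor W and a reporter-specific
(intrinsic) factor Z, so channel parameters add in quadrature on the log
scale and the ratio channel GFP/RFP cancels the shared factor entirely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtri

from .distributions import GateConfig, LogNormalInput, make_log_gates

DEFAULT_SIGMA_W = 0.40
DEFAULT_SIGMA_RFP = 0.15
DEFAULT_DUAL_GATE_WIDTH = 0.15


@dataclass(frozen=True)
class OutputCounts:
    """Per-variant output distribution: cells per gate plus the number drawn."""

    counts: np.ndarray
    n_drawn: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if np.any(counts < 0):
            raise ValueError("counts must be nonnegative")
        if counts.sum() > self.n_drawn:
            raise ValueError("more sorted cells than drawn cells")

    @property
    def n_sorted(self) -> int:
        return int(self.counts.sum())

    @property
    def m(self) -> int:
        return self.counts.size


def sample_fluorescence(
    dist: LogNormalInput, n_cells: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw per-cell fluorescence by inverse-CDF sampling of uniforms."""
    y = rng.random(n_cells)
    return np.exp(dist.mu + dist.sigma * ndtri(y))


def bin_cells(x: np.ndarray, gates: GateConfig) -> OutputCounts:
    """Assign fluorescence values to gates (half-open [L_j, U_j) intervals)."""
    edges = gates.edges
    idx = np.searchsorted(edges, x, side="right") - 1
    inside = (idx >= 0) & (idx < gates.m)
    counts = np.bincount(idx[inside], minlength=gates.m)
    return OutputCounts(counts=counts, n_drawn=int(x.size))


def sample_output(
    dist: LogNormalInput,
    gates: GateConfig,
    n_cells: int,
    rng: np.random.Generator,
    count: str = "drawn",
) -> OutputCounts:
    """Simulate the output distribution of one variant.

    Parameters
    ----------
    count : {"drawn", "sorted"}
        With "drawn" (default), ``n_cells`` cells are drawn and any that
        fall outside a bounded configuration are lost.  With "sorted",
        draws continue until ``n_cells`` cells land inside a gate.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be nonnegative")
    if count == "drawn":
        return bin_cells(sample_fluorescence(dist, n_cells, rng), gates)
    if count != "sorted":
        raise ValueError(f"unknown count mode {count!r}")
    counts = np.zeros(gates.m, dtype=np.int64)
    drawn = 0
    remaining = n_cells
    while remaining > 0:
        batch = bin_cells(sample_fluorescence(dist, remaining, rng), gates)
        drawn += batch.n_drawn
        counts += batch.counts
        remaining = n_cells - int(counts.sum())
    return OutputCounts(counts=counts, n_drawn=drawn)


@dataclass(frozen=True)
class DualReporterModel:
    """Shared/specific decomposition of per-channel log-normal parameters.

    ``specific`` maps a reporter name to its intrinsic (mu', sigma').  The
    composite channel for reporter FP has mu = mu' + mu_W and
    sigma = sqrt(sigma'^2 + sigma_W^2); the ratio channel "A/B" has
    mu = mu'_A - mu'_B and sigma = sqrt(sigma'_A^2 + sigma'_B^2) with no
    shared-factor contribution.
    """

    sigma_W: float = DEFAULT_SIGMA_W
    mu_W: float = 0.0
    specific: dict = field(default_factory=dict)


def derive_reporter_channels(
    model: DualReporterModel, reporter: str
) -> tuple[float, float]:
    """Composite (mu, sigma) for a reporter name or a "num/den" ratio."""
    if "/" in reporter:
        num, den = reporter.split("/", 1)
        try:
            mu_n, s_n = model.specific[num]
            mu_d, s_d = model.specific[den]
        except KeyError as exc:
            raise KeyError(f"unknown reporter {exc.args[0]!r}") from exc
        return mu_n - mu_d, math.hypot(s_n, s_d)
    try:
        mu_p, s_p = model.specific[reporter]
    except KeyError as exc:
        raise KeyError(f"unknown reporter {reporter!r}") from exc
    return mu_p + model.mu_W, math.hypot(s_p, model.sigma_W)


def gfp_intrinsic_params(nu: float) -> tuple[float, float]:
    """Intrinsic (mu', sigma') giving the reporter-specific factor mean nu
    and CV nu^(-1/2) (Poisson-like scaling of intrinsic noise)."""
    if nu <= 0:
        raise ValueError("nu must be positive")
    sigma_p = math.sqrt(math.log1p(1.0 / nu))
    mu_p = math.log(nu / math.sqrt(1.0 + 1.0 / nu))
    return mu_p, sigma_p


def simulate_dual_reporter_experiment(
    variant_means,
    cells_per_variant,
    rng: np.random.Generator,
    gates: GateConfig | None = None,
    sigma_W: float = DEFAULT_SIGMA_W,
    sigma_rfp: float = DEFAULT_SIGMA_RFP,
) -> dict[str, list[OutputCounts]]:
    """Simulate single-channel (GFP) and ratio-channel (GFP/RFP) sort-seq.

    Each variant's GFP-specific factor has mean ``nu`` and CV nu^(-1/2);
    the shared factor (sigma_W) and the reference reporter (sigma_rfp) are
    common to all variants.  Both channels are sampled with the same cell
    budget.  The default gate configuration uses width w=0.15 spanning a
    bit over two decades, centred on the variant means.
    """
    variant_means = np.asarray(variant_means, dtype=float)
    cells_per_variant = np.asarray(cells_per_variant, dtype=int)
    if variant_means.shape != cells_per_variant.shape:
        raise ValueError("variant_means and cells_per_variant lengths differ")
    if gates is None:
        center = float(np.median(np.log(variant_means)))
        half = 2.5  # > 2 decades total on the natural-log scale
        m = int(round(2 * half / DEFAULT_DUAL_GATE_WIDTH))
        gates = make_log_gates(m, math.exp(center - half), math.exp(center + half))
    out: dict[str, list[OutputCounts]] = {"single": [], "ratio": []}
    for nu, n in zip(variant_means, cells_per_variant):
        mu_p, s_p = gfp_intrinsic_params(float(nu))
        model = DualReporterModel(
            sigma_W=sigma_W, specific={"GFP": (mu_p, s_p), "RFP": (0.0, sigma_rfp)}
        )
        for mode, channel in (("single", "GFP"), ("ratio", "GFP/RFP")):
            mu, sigma = derive_reporter_channels(model, channel)
            dist = LogNormalInput(mu=mu, sigma=sigma)
            out[mode].append(sample_output(dist, gates, int(n), rng))
    return out
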