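"""Log-normal input distributions and sorting-gate geometry.

A sort-seq experiment observes, for each sequence variant, how its cells
distribute across a set of fluorescence intervals ("gates").  The per-cell
fluorescence of a single variant is modelled as log-normal, parameterised
either on the log scale (location ``mu``, width ``sigma``) or through its
linear-scale mean ``nu`` and coefficient of variation ``c``:

    nu = exp(mu + sigma^2 / 2),    c = sqrt(exp(sigma^2) - 1)

(for small sigma, c ~= sigma).  Gates are contiguous intervals, typically
evenly spaced on a log scale with width ``w = log(u/l)/m`` between the
measurement boundaries ``l`` and ``u``; the outermost gates may instead be
*semibounded* (censoring) gates extending to 0 and +infinity so that every
cell is captured.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr


def moments_to_params(nu: float, c: float) -> tuple[float, float]:
    """Convert a linear-scale mean and CV to log-normal (mu, sigma).

    sigma = sqrt(log(1 + c^2)), mu = log(nu) - sigma^2/2.
    """
    if nu <= 0 or c <= 0:
        raise ValueError(f"nu and c must be positive, got nu={nu}, c={c}")
    sigma = math.sqrt(math.log1p(c * c))
    mu = math.log(nu) - sigma * sigma / 2.0
    return mu, sigma


def params_to_moments(mu: float, sigma: float) -> tuple[float, float]:
    """Convert log-normal (mu, sigma) to the linear-scale mean and CV."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    nu = math.exp(mu + sigma * sigma / 2.0)
    c = math.sqrt(math.expm1(sigma * sigma))
    return nu, c


@dataclass(frozen=True)
class LogNormalInput:
    """Per-variant input distribution of single-cell fluorescence.

    Attributes
    ----------
    mu, sigma : float
        Log-scale location and width (sigma > 0).
    """

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")

    @classmethod
    def from_moments(cls, nu: float, c: float) -> "LogNormalInput":
        return cls(*moments_to_params(nu, c))

    @property
    def nu(self) -> float:
        """Linear-scale mean fluorescence."""
        return math.exp(self.mu + self.sigma**2 / 2.0)

    @property
    def c(self) -> float:
        """Coefficient of variation."""
        return math.sqrt(math.expm1(self.sigma**2))


def lognormal_cdf(x, mu: float, sigma: float):
    """Log-normal CDF F_{mu,sigma}(x) = Phi((log x - mu)/sigma).

    Accepts scalars or arrays; x = 0 maps to 0 and x = inf to 1 exactly
    (the distribution's support is the positive axis).
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    x = np.asarray(x, dtype=float)
    out = np.zeros(x.shape)
    pos = x > 0
    with np.errstate(divide="ignore"):
        out[pos] = ndtr((np.log(x[pos]) - mu) / sigma)
    out[np.isinf(x)] = 1.0
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class GateConfig:
    """Ordered, contiguous fluorescence gates.

    ``lower`` and ``upper`` are equal-length arrays of gate boundaries
    (strictly increasing, lower[j+1] == upper[j]).  Semibounded outer
    gates use the sentinels 0.0 and ``inf``.  A cell with fluorescence X
    belongs to gate j iff lower[j] <= X < upper[j].
    """

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        if lower.shape != upper.shape or lower.ndim != 1 or lower.size < 1:
            raise ValueError("lower/upper must be equal-length 1-d arrays")
        if not np.all(upper > lower):
            raise ValueError("each gate needs upper > lower")
        if not np.allclose(lower[1:], upper[:-1]):
            raise ValueError("gates must be contiguous (lower[j+1] == upper[j])")

    @property
    def m(self) -> int:
        return self.lower.size

    @property
    def semibounded_low(self) -> bool:
        return self.lower[0] == 0.0

    @property
    def semibounded_high(self) -> bool:
        return bool(np.isinf(self.upper[-1]))

    @property
    def semibounded(self) -> bool:
        return self.semibounded_low and self.semibounded_high

    @property
    def finite_lower(self) -> float:
        """The finite measurement boundary l (lowest finite edge)."""
        return float(self.upper[0] if self.semibounded_low else self.lower[0])

    @property
    def finite_upper(self) -> float:
        """The finite measurement boundary u (highest finite edge)."""
        return float(self.lower[-1] if self.semibounded_high else self.upper[-1])

    @property
    def w(self) -> float:
        """Log-width of the interior (finite) gates."""
        lo = np.where(self.lower == 0, np.nan, self.lower)
        hi = np.where(np.isinf(self.upper), np.nan, self.upper)
        widths = np.log(hi) - np.log(lo)
        widths = widths[np.isfinite(widths)]
        if widths.size == 0:
            raise ValueError("no finite gate from which to derive w")
        return float(widths.mean())

    @property
    def edges(self) -> np.ndarray:
        """All m+1 boundaries, [lower[0], ..., upper[-1]]."""
        return np.concatenate([self.lower, self.upper[-1:]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gate": np.arange(1, self.m + 1), "lower": self.lower, "upper": self.upper}
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GateConfig":
        frame = frame.sort_values("gate")
        return cls(frame["lower"].to_numpy(float), frame["upper"].to_numpy(float))


def make_log_gates(
    m: int, lower_bound: float, upper_bound: float, semibounded: bool = False
) -> GateConfig:
    """Build m contiguous log-spaced gates spanning [lower_bound, upper_bound].

    With ``semibounded=True`` the outermost gates are extended to 0 and
    +infinity while the interior boundaries remain log-spaced over the
    stated range, so the gates partition the whole fluorescence axis.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if not (0 < lower_bound < upper_bound):
        raise ValueError("need 0 < lower_bound < upper_bound")
    edges = np.exp(np.linspace(math.log(lower_bound), math.log(upper_bound), m + 1))
    edges[0] = lower_bound
    edges[-1] = upper_bound
    lower, upper = edges[:-1].copy(), edges[1:].copy()
    if semibounded:
        lower[0] = 0.0
        upper[-1] = np.inf
    return GateConfig(lower, upper)


def gate_probabilities(gates: GateConfig, mu: float, sigma: float) -> np.ndarray:
    """P(cell in gate j) = F(U_j) - F(L_j) under the log-normal input.

    Sums to 1 exactly when the configuration is semibounded; otherwise the
    deficit is the probability of falling outside the measurement range.
    """
    cdf_hi = lognormal_cdf(gates.upper, mu, sigma)
    cdf_lo = lognormal_cdf(gates.lower, mu, sigma)
    return np.clip(cdf_hi - cdf_lo, 0.0, 1.0)


def expected_enrichment(mu: float, sigma: float, threshold: float) -> float:
    """Expected single-gate enrichment: P(X > threshold) = 1 - F(threshold)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return 1.0 - float(lognormal_cdf(threshold, mu, sigma))
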