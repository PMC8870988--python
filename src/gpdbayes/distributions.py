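"""Generalized Pareto and stable baseline distributions.

The generalized Pareto distribution (GPD) with shape ``xi`` and scale
``sigma`` models exceedances ``X - u | X > u`` over a high threshold
``u``.  ``xi > 0`` gives a heavy (power-law) tail, ``xi = 0`` an
exponential tail, ``xi < 0`` a bounded tail with right endpoint
``-sigma/xi``.

Baseline observations come from a stable location--scale family
``X = a Z + b`` where ``Z`` is the standard member.  Only the three
analytic stable families are supported: Lévy (alpha=1/2, beta=1),
Cauchy (alpha=1, beta=0) and Normal (alpha=2, beta=0; standardized as
N(0,1)).  Non-Gaussian stable laws obey the tail asymptotics
``P(Z > x) ~ (1+beta) C_alpha x^(-alpha)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "GPDParams",
    "StableSpec",
    "GammaSpec",
    "ExceedanceSample",
    "InvalidParameterError",
    "UnsupportedFamilyError",
    "EmptyTailError",
    "DomainError",
    "gpd_cdf",
    "gpd_logpdf",
    "gpd_quantile",
    "gpd_sample",
    "stable_sample",
    "stable_survival_approx",
    "extract_exceedances",
    "read_series",
]

logger = logging.getLogger(__name__)

#: |xi| below this routes through the exponential (xi = 0) branch to
#: avoid catastrophic cancellation in (1 + xi x / sigma)^(-1/xi).
XI_ZERO_CUTOFF = 1e-8


class InvalidParameterError(ValueError):
    """Raised for parameter values outside the model's domain."""


class UnsupportedFamilyError(ValueError):
    """Raised for a stable (alpha, beta) pair with no analytic density."""


class EmptyTailError(ValueError):
    """Raised when thresholding leaves no exceedances."""


class DomainError(ValueError):
    """Raised for arguments outside a function's domain."""


@dataclass(frozen=True)
class GPDParams:
    """Shape ``xi`` (dimensionless) and scale ``sigma`` (data units) of a GPD."""

    xi: float
    sigma: float

    def __post_init__(self) -> None:
        if not (self.sigma > 0) or not np.isfinite(self.sigma):
            raise InvalidParameterError(f"sigma must be positive, got {self.sigma}")
        if not np.isfinite(self.xi):
            raise InvalidParameterError(f"xi must be finite, got {self.xi}")

    @property
    def upper_endpoint(self) -> float:
        """Right endpoint of the support: ``inf`` if xi >= 0, else -sigma/xi."""
        if self.xi >= 0:
            return math.inf
        return -self.sigma / self.xi

    def mean(self) -> float:
        """Expected value sigma/(1 - xi); infinite for xi >= 1."""
        if self.xi >= 1:
            return math.inf
        return self.sigma / (1.0 - self.xi)


_FAMILIES = {(0.5, 1.0): "levy", (1.0, 0.0): "cauchy", (2.0, 0.0): "normal"}


@dataclass(frozen=True)
class StableSpec:
    """A stable law ``X = a Z + b`` from one of the analytic families.

    ``alpha`` is the index of stability, ``beta`` the skewness; the
    standard member ``Z`` has ``a=1, b=0``.  The Normal family's
    standard member is N(0,1) (not the variance-2 canonical stable),
    so ``a`` coincides with the usual Normal standard deviation.
    """

    alpha: float
    beta: float
    a: float = 1.0
    b: float = 0.0

    def __post_init__(self) -> None:
        if (self.alpha, self.beta) not in _FAMILIES:
            raise UnsupportedFamilyError(
                f"(alpha={self.alpha}, beta={self.beta}) is not one of the "
                "analytic stable families: Lévy (1/2, 1), Cauchy (1, 0), Normal (2, 0)"
            )
        if not (self.a > 0):
            raise InvalidParameterError(f"scale a must be positive, got {self.a}")

    @property
    def family(self) -> str:
        return _FAMILIES[(self.alpha, self.beta)]

    @classmethod
    def from_family(cls, family: str, a: float = 1.0, b: float = 0.0) -> "StableSpec":
        pairs = {v: k for k, v in _FAMILIES.items()}
        if family not in pairs:
            raise UnsupportedFamilyError(f"unknown stable family {family!r}")
        alpha, beta = pairs[family]
        return cls(alpha=alpha, beta=beta, a=a, b=b)


@dataclass(frozen=True)
class GammaSpec:
    """Gamma(shape, rate) baseline, as used for the PM2.5-type application."""

    shape_g: float
    rate_g: float

    def __post_init__(self) -> None:
        if not (self.shape_g > 0 and self.rate_g > 0):
            raise InvalidParameterError(
                f"Gamma shape and rate must be positive, got ({self.shape_g}, {self.rate_g})"
            )


@dataclass(frozen=True)
class ExceedanceSample:
    """Threshold ``u`` at tail level ``p`` and the shifted exceedances x - u."""

    u: float
    p: float
    values: np.ndarray
    n_source: int
    m: int = field(init=False)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "m", vals.size)
        if vals.size and vals.min() <= 0:
            raise InvalidParameterError("exceedances must all be strictly positive")
        if self.m > self.n_source:
            raise InvalidParameterError("more exceedances than source observations")


def _frozen_gpd(params: GPDParams):
    if abs(params.xi) < XI_ZERO_CUTOFF:
        return stats.expon(scale=params.sigma)
    return stats.genpareto(c=params.xi, scale=params.sigma)


def gpd_cdf(x, params: GPDParams):
    """GPD distribution function G(x | xi, sigma).

    Values outside the support are clipped (0 below zero, 1 above the
    upper endpoint) rather than raising: Metropolis--Hastings proposals
    legitimately probe out-of-support regions.
    """
    out = _frozen_gpd(params).cdf(x)
    return np.clip(out, 0.0, 1.0)


def gpd_logpdf(x, params: GPDParams):
    """Log density of the GPD; ``-inf`` outside the support."""
    return _frozen_gpd(params).logpdf(x)


def gpd_quantile(q, params: GPDParams):
    """Inverse of :func:`gpd_cdf` on [0, 1)."""
    q = np.asarray(q, dtype=float)
    if np.any((q < 0) | (q >= 1)):
        raise DomainError("quantile level must lie in [0, 1)")
    out = _frozen_gpd(params).ppf(q)
    return out if out.ndim else float(out)


def gpd_sample(n: int, params: GPDParams, seed: int) -> np.ndarray:
    """Draw ``n`` values by inverse-transform sampling, reproducible by ``seed``."""
    if n < 1:
        raise DomainError("n must be at least 1")
    rng = np.random.default_rng(seed)
    return np.asarray(gpd_quantile(rng.random(n), params))


def stable_sample(n: int, spec: StableSpec, seed: int) -> np.ndarray:
    """Draw ``n`` values ``a Z + b`` using the family's exact closed-form transform.

    Lévy: reciprocal of a squared unit-Normal draw; Cauchy: tangent
    transform of a uniform draw; Normal: unit-Normal draw.
    """
    if n < 1:
        raise DomainError("n must be at least 1")
    rng = np.random.default_rng(seed)
    fam = spec.family
    if fam == "levy":
        z = 1.0 / rng.standard_normal(n) ** 2
    elif fam == "cauchy":
        z = np.tan(np.pi * (rng.random(n) - 0.5))
    else:  # normal
        z = rng.standard_normal(n)
    return spec.a * z + spec.b


def stable_survival_approx(x, spec: StableSpec):
    """Power-law tail approximation (1 + beta) C_alpha x^(-alpha) of the standard member.

    Valid only for alpha < 2 (the Normal tail is not power-law) and x > 0.
    """
    # local import: relations depends on this module, avoid cycle at import time
    from .relations import stable_tail_constant

    if spec.alpha >= 2:
        raise DomainError("the power-law tail approximation requires alpha < 2")
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise DomainError("x must be positive")
    out = (1.0 + spec.beta) * stable_tail_constant(spec.alpha) * x ** (-spec.alpha)
    return out if out.ndim else float(out)


def empirical_threshold(data, p: float) -> float:
    """Order statistic at (1-based) index ceil(p*n) of the sorted sample.

    This convention guarantees the threshold is an observed value and
    leaves roughly (1-p)*n strict exceedances.
    """
    x = np.sort(np.asarray(data, dtype=float))
    n = x.size
    idx = math.ceil(p * n)
    idx = min(max(idx, 1), n)
    return float(x[idx - 1])


def extract_exceedances(data, p: float, u: float | None = None) -> ExceedanceSample:
    """Threshold the series at its empirical p-quantile and shift the tail.

    ``u`` may be supplied explicitly (e.g. the theoretical quantile of a
    known baseline); otherwise the empirical order-statistic convention
    of :func:`empirical_threshold` is used.
    """
    if not (0 < p < 1):
        raise DomainError("p must lie strictly between 0 and 1")
    x = np.asarray(data, dtype=float)
    if u is None:
        u = empirical_threshold(x, p)
    vals = x[x > u] - u
    if vals.size == 0:
        raise EmptyTailError(f"no observations exceed the threshold u={u} (p={p})")
    return ExceedanceSample(u=float(u), p=p, values=vals, n_source=x.size)


_NA_TOKENS = {"", "na", "nan", "null", "none"}


def read_series(path) -> np.ndarray:
    """Read a univariate series: one value per line, or single-column CSV.

    An optional non-numeric header line is skipped; blank lines and
    NaN-like tokens are dropped with a logged count.
    """
    values: list[float] = []
    dropped = 0
    first = True
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            tok = line.strip().split(",")[0].strip()
            if tok.lower() in _NA_TOKENS:
                if tok:  # blank lines and NA tokens both count as dropped
                    dropped += 1
                elif line.strip() == "" and not first:
                    dropped += 1
                first = False
                continue
            try:
                v = float(tok)
            except ValueError:
                if first:
                    first = False
                    continue  # header
                raise DomainError(f"cannot parse {tok!r} as a number in {path}")
            first = False
            if math.isnan(v):
                dropped += 1
                continue
            values.append(v)
    if dropped:
        logger.info("read_series: dropped %d blank/NaN entries from %s", dropped, path)
    return np.asarray(values, dtype=float)
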