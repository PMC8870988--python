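"""Mappings from baseline-distribution parameters to GPD tail parameters.

For a stable baseline ``X = a Z + b`` thresholded at its p-quantile,
the exceedance law is GPD(xi_Z, a * sigma_Z) where (xi_Z, sigma_Z)
depend only on the *standard* member Z and the tail level p:

* non-Gaussian stable (alpha < 2), closed form:
  ``xi_Z = 1/alpha``, ``sigma_Z = (1/alpha) * [C_alpha (1+beta) / (1-p)]^(1/alpha)``
  with the tail constant ``C_alpha = Gamma(alpha) sin(alpha pi / 2) / pi``;
* Normal baseline, simulation-calibrated polynomials valid for
  p in [0.90, 0.995]:
  ``xi_Z = -0.7 + 0.61 p``,
  ``sigma_Z = 0.34 + 3.18 (1-p) - 12.4 (1-p)^2``;
* Gamma(shape, rate) baseline: ``xi = 0``,
  ``sigma = (1 + 0.22 (ln shape)^2) / rate`` — exact for shape = 1,
  where the exponential tail is the baseline itself.

:func:`calibrate_relation` re-derives such curves by simulation for any
standard baseline: repeated exceedance samples are fitted by the tail
Metropolis--Hastings samplers and polynomial curves are fitted to the
per-p posterior means.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from .distributions import (
    DomainError,
    ExceedanceSample,
    GammaSpec,
    GPDParams,
    InvalidParameterError,
    UnsupportedFamilyError,
)

__all__ = [
    "TailRelation",
    "RelationFit",
    "NORMAL_P_WINDOW",
    "stable_tail_constant",
    "prop1_relation",
    "family_relation",
    "map_to_gpd",
    "gamma_relation",
    "calibrate_relation",
]

#: Validity window of the Normal-family calibrated polynomials.
NORMAL_P_WINDOW = (0.90, 0.995)


@dataclass(frozen=True)
class TailRelation:
    """Standard-baseline GPD parameters (xi_Z, sigma_Z) at tail level p."""

    p: float
    xi_Z: float
    sigma_Z: float
    family: str = "custom"

    def __post_init__(self) -> None:
        if not (self.sigma_Z > 0):
            raise InvalidParameterError(f"sigma_Z must be positive, got {self.sigma_Z}")


def stable_tail_constant(alpha: float) -> float:
    """Tail constant C_alpha = Gamma(alpha) sin(alpha pi / 2) / pi."""
    if not (0 < alpha <= 2):
        raise DomainError(f"alpha must lie in (0, 2], got {alpha}")
    if alpha == 2:
        return 0.0  # sin(pi) exactly
    return math.gamma(alpha) * math.sin(alpha * math.pi / 2.0) / math.pi


def prop1_relation(alpha: float, beta: float, p: float) -> TailRelation:
    """Closed-form tail relation for a standard non-Gaussian stable baseline.

    The shape estimator ``1/alpha`` depends only on the index of
    stability, never on p; the scale picks up the tail level through
    ``(1-p)^(-1/alpha)``.
    """
    if not (0 < alpha < 2):
        raise DomainError(f"the closed-form relation requires 0 < alpha < 2, got {alpha}")
    if not (-1 <= beta <= 1):
        raise DomainError(f"beta must lie in [-1, 1], got {beta}")
    if not (0 < p < 1):
        raise DomainError(f"p must lie in (0, 1), got {p}")
    xi_z = 1.0 / alpha
    c = stable_tail_constant(alpha)
    sigma_z = xi_z * (c * (1.0 + beta) / (1.0 - p)) ** xi_z
    family = {(0.5, 1.0): "levy", (1.0, 0.0): "cauchy"}.get((alpha, beta), "custom")
    return TailRelation(p=p, xi_Z=xi_z, sigma_Z=sigma_z, family=family)


def family_relation(family: str, p: float) -> TailRelation:
    """Dispatch to the family's tail relation (closed form or calibrated)."""
    if not (0 < p < 1):
        raise DomainError(f"p must lie in (0, 1), got {p}")
    if family == "levy":
        return TailRelation(p=p, xi_Z=2.0, sigma_Z=(4.0 / math.pi) * (1.0 - p) ** -2, family="levy")
    if family == "cauchy":
        return TailRelation(p=p, xi_Z=1.0, sigma_Z=1.0 / (math.pi * (1.0 - p)), family="cauchy")
    if family == "normal":
        lo, hi = NORMAL_P_WINDOW
        if not (lo <= p <= hi):
            warnings.warn(
                f"Normal-family relation evaluated at p={p}, outside its "
                f"calibrated window [{lo}, {hi}]",
                stacklevel=2,
            )
        q = 1.0 - p
        return TailRelation(
            p=p,
            xi_Z=-0.7 + 0.61 * p,
            sigma_Z=0.34 + 3.18 * q - 12.4 * q * q,
            family="normal",
        )
    raise UnsupportedFamilyError(f"unknown baseline family {family!r}")


def map_to_gpd(rel: TailRelation, a: float) -> GPDParams:
    """Scale the standard-baseline relation to scale parameter ``a``: (xi_Z, a*sigma_Z)."""
    if not (a > 0):
        raise InvalidParameterError(f"scale a must be positive, got {a}")
    return GPDParams(xi=rel.xi_Z, sigma=a * rel.sigma_Z)


def gamma_relation(spec: GammaSpec, reading: str = "ln_sq") -> GPDParams:
    """Calibrated tail relation for a Gamma(shape, rate) baseline.

    The tail is exponential (xi = 0) with scale
    ``(1 + 0.22 (ln shape)^2) / rate``.  For shape = 1 the baseline is
    Exponential(rate) whose tail equals the baseline exactly, forcing
    sigma = 1/rate — which the default reading reproduces.  The
    ``reading="log2"`` variant uses a base-2 logarithm (not squared)
    instead.
    """
    if reading == "ln_sq":
        factor = 1.0 + 0.22 * math.log(spec.shape_g) ** 2
    elif reading == "log2":
        factor = 1.0 + 0.22 * math.log2(spec.shape_g)
    else:
        raise DomainError(f"unknown reading {reading!r}; use 'ln_sq' or 'log2'")
    if factor <= 0:
        raise InvalidParameterError(
            f"relation gives non-positive sigma for shape={spec.shape_g} under reading {reading!r}"
        )
    # xi=0 is below the numerical cutoff, so the exponential branch is used throughout
    return GPDParams(xi=0.0, sigma=factor / spec.rate_g)


_STANDARD_DISTS = {"levy": stats.levy, "cauchy": stats.cauchy, "normal": stats.norm}


class CalibrationError(RuntimeError):
    """Raised when a simulation calibration cannot produce a fit."""


@dataclass
class RelationFit:
    """Simulation-calibrated tail relation curves over a p-grid.

    ``xi_curve`` holds ascending polynomial coefficients in p.
    ``sigma_curve`` holds either ascending polynomial coefficients in
    (1-p) (``sigma_model="poly_1mp"``) or (log-intercept, log-log slope)
    of a power law in (1-p) (``sigma_model="powerlaw"``).
    """

    family: str
    p_grid: list
    xi_curve: list
    sigma_curve: list
    sigma_model: str
    reps: int
    provenance: dict = field(default_factory=dict)

    def xi_at(self, p: float) -> float:
        return float(np.polynomial.polynomial.polyval(p, self.xi_curve))

    def sigma_at(self, p: float) -> float:
        if self.sigma_model == "powerlaw":
            c0, c1 = self.sigma_curve
            return float(math.exp(c0) * (1.0 - p) ** c1)
        return float(np.polynomial.polynomial.polyval(1.0 - p, self.sigma_curve))

    def evaluate(self, p: float) -> TailRelation:
        lo, hi = min(self.p_grid), max(self.p_grid)
        if not (lo <= p <= hi):
            warnings.warn(
                f"RelationFit for {self.family!r} evaluated at p={p}, outside "
                f"its calibrated range [{lo}, {hi}]",
                stacklevel=2,
            )
        return TailRelation(p=p, xi_Z=self.xi_at(p), sigma_Z=self.sigma_at(p), family=self.family)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RelationFit":
        return cls(**json.loads(text))


def calibrate_relation(
    standard_sampler,
    p_grid,
    reps: int = 100,
    mh_settings=None,
    seed: int = 0,
    m: int = 1000,
    tail: str | None = None,
) -> RelationFit:
    """Re-derive a (xi_Z, sigma_Z) curve for a standard baseline by simulation.

    ``standard_sampler`` is either a family name ("levy", "cauchy",
    "normal") or any object with a ``.ppf`` method (e.g. a frozen
    scipy distribution).  For each p in ``p_grid`` and each rep, ``m``
    exceedances of the standard baseline above its theoretical
    p-quantile are drawn by conditional inverse-transform sampling and
    fitted by the appropriate tail MH sampler (heavy-tail for Lévy /
    Cauchy / custom, light-tail for Normal); the per-p averages of the
    posterior means are then fitted by the same curve shapes the
    hard-coded relations use.

    Reps whose chains have a per-component acceptance rate outside
    [0.05, 0.8] are excluded, with a warning, and flagged in the
    returned provenance.
    """
    from . import estimators  # deferred: estimators imports this module
    from .mh import MHConfig

    p_grid = sorted(float(p) for p in p_grid)
    if not p_grid or not all(0 < p < 1 for p in p_grid):
        raise DomainError("p_grid must be non-empty and lie within (0, 1)")
    if reps < 1:
        raise DomainError("reps must be at least 1")

    if isinstance(standard_sampler, str):
        family = standard_sampler
        if family not in _STANDARD_DISTS:
            raise UnsupportedFamilyError(f"unknown standard family {family!r}")
        dist = _STANDARD_DISTS[family]
    else:
        family = "custom"
        dist = standard_sampler
    if tail is None:
        tail = "light" if family == "normal" else "heavy"
    if mh_settings is None:
        mh_settings = MHConfig(n_keep=2000, burn_in=1000, thinning=5)

    xi_means, sigma_means, kept_p, excluded = [], [], [], []
    for ip, p in enumerate(p_grid):
        u = float(dist.ppf(p))
        xi_acc, sig_acc = [], []
        for rep in range(reps):
            child = np.random.SeedSequence([seed, ip, rep])
            rs = child.generate_state(2)
            rng = np.random.default_rng(int(rs[0] % 2**31))
            z = dist.ppf(p + (1.0 - p) * rng.random(m))
            sample = ExceedanceSample(u=u, p=p, values=np.asarray(z) - u, n_source=m)
            cfg = mh_settings.replace(seed=int(rs[1] % 2**31))
            if tail == "heavy":
                res = estimators.fit_mh_heavy(sample, config=cfg)
            else:
                res = estimators.fit_mh_light(sample, config=cfg)
            rates = res.posterior.chain.acceptance_rates
            if np.any(rates < 0.05) or np.any(rates > 0.8):
                excluded.append({"p": p, "rep": rep, "acceptance_rates": list(map(float, rates))})
                warnings.warn(
                    f"calibration rep excluded at p={p} (rep {rep}): acceptance "
                    f"rates {rates} outside [0.05, 0.8]",
                    stacklevel=2,
                )
                continue
            xi_acc.append(res.xi)
            sig_acc.append(res.sigma)
        if xi_acc:
            kept_p.append(p)
            xi_means.append(float(np.mean(xi_acc)))
            sigma_means.append(float(np.mean(sig_acc)))

    xi_deg = 0 if family in ("levy", "cauchy") else 1
    sigma_model = "powerlaw" if tail == "heavy" else "poly_1mp"
    sig_ncoef = 2 if sigma_model == "powerlaw" else 3
    if len(kept_p) < max(xi_deg + 1, sig_ncoef):
        raise CalibrationError(
            f"only {len(kept_p)} usable grid points; need at least "
            f"{max(xi_deg + 1, sig_ncoef)} to fit the curves"
        )
    pk = np.asarray(kept_p)
    xi_curve = np.polynomial.polynomial.polyfit(pk, xi_means, xi_deg)
    if sigma_model == "powerlaw":
        slope, intercept = np.polyfit(np.log(1.0 - pk), np.log(sigma_means), 1)
        sigma_curve = [float(intercept), float(slope)]
    else:
        sigma_curve = list(map(float, np.polynomial.polynomial.polyfit(1.0 - pk, sigma_means, 2)))

    return RelationFit(
        family=family,
        p_grid=list(map(float, kept_p)),
        xi_curve=list(map(float, np.atleast_1d(xi_curve))),
        sigma_curve=sigma_curve,
        sigma_model=sigma_model,
        reps=reps,
        provenance={
            "seed": seed,
            "m": m,
            "tail": tail,
            "mh_settings": mh_settings.to_dict(),
            "per_p_xi_means": xi_means,
            "per_p_sigma_means": sigma_means,
            "excluded": excluded,
        },
    )
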