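"""Componentwise random-walk Metropolis--Hastings engine.

One shared sampler drives every fitter in the package: each parameter
is updated in turn with a Gaussian random-walk proposal, accepted with
probability ``min{1, exp(delta log-posterior)}``.  Support constraints
enter exclusively through ``-inf`` log-posterior values, never through
exceptions, so proposals may probe out-of-support regions freely.

Proposal scales are adapted during burn-in (targeting a 25--40%
acceptance rate) and then frozen, so retained draws come from a
fixed-kernel phase and the stationary distribution is preserved.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MHConfig",
    "Chain",
    "PosteriorResult",
    "InitializationError",
    "run_mh",
    "summarize_chain",
    "chain_to_csv",
    "result_to_json",
]


class InitializationError(RuntimeError):
    """No finite-log-posterior starting point could be found."""


@dataclass(frozen=True)
class MHConfig:
    """Settings for one MH run.

    Defaults follow the reference study protocol (10,000 burn-in
    iterations, thinning 25, 10,000 retained draws); desk-scale work
    should pass reduced values.  ``init="auto"`` triggers a small
    deterministic grid search for a finite starting point.
    """

    n_keep: int = 10_000
    burn_in: int = 10_000
    thinning: int = 25
    proposal_sds: tuple | None = None
    seed: int = 0
    init: tuple | str = "auto"
    adapt: bool = True

    def __post_init__(self) -> None:
        if self.n_keep < 1:
            raise ValueError("n_keep must be at least 1")
        if self.thinning < 1:
            raise ValueError("thinning must be at least 1")
        if self.burn_in < 0:
            raise ValueError("burn_in must be non-negative")
        if self.proposal_sds is not None:
            sds = tuple(float(s) for s in self.proposal_sds)
            if any(s <= 0 for s in sds):
                raise ValueError("proposal_sds must all be positive")
            object.__setattr__(self, "proposal_sds", sds)
        if not isinstance(self.init, str):
            object.__setattr__(self, "init", tuple(float(v) for v in self.init))

    def replace(self, **kw) -> "MHConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["proposal_sds"] = None if self.proposal_sds is None else list(self.proposal_sds)
        d["init"] = self.init if isinstance(self.init, str) else list(self.init)
        return d


@dataclass
class Chain:
    """Retained draws plus per-parameter acceptance bookkeeping."""

    draws: np.ndarray  # (n_keep, n_params)
    acceptance_rates: np.ndarray  # per parameter, sampling phase only
    param_names: tuple
    config: MHConfig
    final_proposal_sds: np.ndarray = field(default=None)

    @property
    def n_params(self) -> int:
        return self.draws.shape[1]


@dataclass
class PosteriorResult:
    """Chain means (the point estimators) and central 95% credible intervals."""

    point_estimate: np.ndarray
    chain: Chain
    credible_intervals: np.ndarray  # (n_params, 2): 2.5% and 97.5% quantiles

    @property
    def param_names(self) -> tuple:
        return self.chain.param_names


_AUTO_GRID = (1.0, 0.5, 2.0, 5.0, 0.1, 10.0, -0.5, -1.0, -2.0, -5.0)
_ADAPT_WINDOW = 50


def _find_start(log_target, n_params: int) -> np.ndarray:
    for cand in itertools.product(_AUTO_GRID, repeat=n_params):
        theta = np.asarray(cand, dtype=float)
        lp = log_target(theta)
        if math.isfinite(lp):
            return theta
    raise InitializationError(
        "no finite-log-posterior starting point on the automatic grid; "
        "supply init explicitly"
    )


def run_mh(log_target, config: MHConfig, param_names=None) -> Chain:
    """Run componentwise random-walk MH on ``log_target``.

    ``log_target`` maps a parameter vector to a log-posterior value;
    ``-inf`` means certain rejection, NaN is a hard error.  Exactly
    ``config.n_keep`` draws are returned after discarding ``burn_in``
    iterations and keeping every ``thinning``-th draw; the run is
    fully reproducible from ``config.seed``.
    """
    if isinstance(config.init, str):
        if config.init != "auto":
            raise ValueError(f"init must be 'auto' or a sequence, got {config.init!r}")
        if param_names is not None:
            n_params = len(param_names)
        elif config.proposal_sds is not None:
            n_params = len(config.proposal_sds)
        else:
            raise InitializationError(
                "init='auto' needs param_names or proposal_sds to fix the dimension"
            )
        theta = _find_start(log_target, n_params)
    else:
        theta = np.asarray(config.init, dtype=float)
        n_params = theta.size
    if param_names is None:
        param_names = tuple(f"p{i}" for i in range(n_params))
    param_names = tuple(param_names)
    if len(param_names) != n_params:
        raise ValueError("param_names length does not match the parameter dimension")

    lp = float(log_target(theta))
    if math.isnan(lp):
        raise ValueError("log_target returned NaN at the starting point")
    if not math.isfinite(lp):
        raise InitializationError("log_target is not finite at the supplied init")

    if config.proposal_sds is not None:
        sds = np.asarray(config.proposal_sds, dtype=float).copy()
    else:
        sds = np.maximum(0.25 * np.abs(theta), 0.1)

    rng = np.random.default_rng(config.seed)
    n_iter = config.burn_in + config.n_keep * config.thinning
    draws = np.empty((config.n_keep, n_params))
    accept_sampling = np.zeros(n_params, dtype=np.int64)
    accept_window = np.zeros(n_params, dtype=np.int64)
    kept = 0

    for it in range(n_iter):
        in_burn = it < config.burn_in
        for j in range(n_params):
            step = rng.normal(0.0, sds[j])
            log_u = math.log(rng.random())
            prop = theta.copy()
            prop[j] += step
            lp_prop = float(log_target(prop))
            if math.isnan(lp_prop):
                raise ValueError(f"log_target returned NaN at {prop}")
            if lp_prop - lp >= 0 or log_u < lp_prop - lp:
                theta = prop
                lp = lp_prop
                if in_burn:
                    accept_window[j] += 1
                else:
                    accept_sampling[j] += 1
        if in_burn:
            if config.adapt and (it + 1) % _ADAPT_WINDOW == 0:
                rates = accept_window / _ADAPT_WINDOW
                sds[rates < 0.25] *= 0.7
                sds[rates > 0.40] *= 1.4
                accept_window[:] = 0
        else:
            post = it - config.burn_in + 1
            if post % config.thinning == 0:
                draws[kept] = theta
                kept += 1

    rates = accept_sampling / (config.n_keep * config.thinning)
    return Chain(
        draws=draws,
        acceptance_rates=rates,
        param_names=param_names,
        config=config,
        final_proposal_sds=sds,
    )


def summarize_chain(chain: Chain) -> PosteriorResult:
    """Per-parameter posterior mean and empirical (2.5%, 97.5%) quantiles."""
    if chain.draws.size == 0:
        raise ValueError("cannot summarize an empty chain")
    means = chain.draws.mean(axis=0)
    ci = np.quantile(chain.draws, [0.025, 0.975], axis=0).T
    return PosteriorResult(point_estimate=means, chain=chain, credible_intervals=ci)


def chain_to_csv(chain: Chain, path) -> None:
    """Write retained draws as CSV, one column per parameter."""
    header = ",".join(chain.param_names)
    np.savetxt(path, chain.draws, delimiter=",", header=header, comments="")


def result_to_json(result: PosteriorResult) -> str:
    """JSON summary: means, intervals, acceptance rates and configuration."""
    chain = result.chain
    doc = {
        "param_names": list(chain.param_names),
        "point_estimate": [float(v) for v in result.point_estimate],
        "credible_intervals": {
            name: [float(lo), float(hi)]
            for name, (lo, hi) in zip(chain.param_names, result.credible_intervals)
        },
        "acceptance_rates": [float(r) for r in chain.acceptance_rates],
        "config": chain.config.to_dict(),
    }
    return json.dumps(doc, indent=2)
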