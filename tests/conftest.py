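"""Shared fixtures and independent oracles for the test suite.

The ``printed_log_r*`` functions transcribe the closed-form
conditional acceptance ratios of the three samplers directly from
their prior-times-likelihood definitions.  They are intentionally
independent of the package's log-posterior builders so that the
ratio-structure tests compare two separately derived expressions.
"""

import numpy as np
import pytest

from gpdbayes import ExceedanceSample, GPDParams, gpd_sample


# ---- light-tail sampler: k | delta and delta | k conditional ratios ----


def printed_log_rk(k_new, k_old, delta, x, a0, b0):
    s = np.log1p(-np.asarray(x) / delta).sum()
    m = len(x)
    return (
        (a0 - m - 1) * (np.log(k_new) - np.log(k_old))
        - b0 * (k_new - k_old)
        + (1.0 / k_new - 1.0 / k_old) * s
    )


def printed_log_rdelta(d_new, d_old, k, x, a1, b1):
    x = np.asarray(x)
    m = len(x)
    s_new = np.log1p(-x / d_new).sum()
    s_old = np.log1p(-x / d_old).sum()
    return (
        (a1 - m - 1) * (np.log(d_new) - np.log(d_old))
        - b1 * (d_new - d_old)
        + (1.0 / k - 1.0) * (s_new - s_old)
    )


# ---- heavy-tail sampler: xi | sigma and sigma | xi conditional ratios ----


def printed_log_rxi(xi_new, xi_old, sigma, x, a0):
    x = np.asarray(x)
    t_old = np.log1p(xi_old * x / sigma).sum()
    t_new = np.log1p(xi_new * x / sigma).sum()
    return (
        (a0 + 1) * (np.log(xi_old) - np.log(xi_new))
        + (1 + 1.0 / xi_old) * t_old
        - (1 + 1.0 / xi_new) * t_new
    )


def printed_log_rsigma(s_new, s_old, xi, x, a1, b1):
    x = np.asarray(x)
    m = len(x)
    t_old = np.log1p(xi * x / s_old).sum()
    t_new = np.log1p(xi * x / s_new).sum()
    return (
        (m + a1 + 1) * (np.log(s_old) - np.log(s_new))
        + b1 * (1.0 / s_old - 1.0 / s_new)
        + (1 + 1.0 / xi) * (t_old - t_new)
    )


# ---- informative-priors sampler conditional ratios ----


def printed_log_rxi_ip(xi_new, xi_old, sigma, x, xi_z, b1):
    x = np.asarray(x)
    t_old = np.log1p(xi_old * x / sigma).sum()
    t_new = np.log1p(xi_new * x / sigma).sum()
    return (
        ((xi_old - xi_z) ** 2 - (xi_new - xi_z) ** 2) / (2 * b1**2)
        + (1 + 1.0 / xi_old) * t_old
        - (1 + 1.0 / xi_new) * t_new
    )


def printed_log_rsigma_ip(s_new, s_old, xi, x, a_sigma_z, b2):
    x = np.asarray(x)
    m = len(x)
    t_old = np.log1p(xi * x / s_old).sum()
    t_new = np.log1p(xi * x / s_new).sum()
    return (
        m * (np.log(s_old) - np.log(s_new))
        + ((s_old - a_sigma_z) ** 2 - (s_new - a_sigma_z) ** 2) / (2 * b2**2)
        + (1 + 1.0 / xi) * (t_old - t_new)
    )


def make_tail(xi, sigma, m, seed, p=0.9):
    """A synthetic exceedance sample drawn exactly from GPD(xi, sigma)."""
    values = gpd_sample(m, GPDParams(xi=xi, sigma=sigma), seed=seed)
    return ExceedanceSample(u=0.0, p=p, values=values, n_source=10 * m)


@pytest.fixture
def heavy_tail_sample():
    return make_tail(1.0, 3.1831, m=1000, seed=42)


@pytest.fixture
def light_tail_sample():
    return make_tail(-0.151, 0.534, m=1000, seed=43)
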