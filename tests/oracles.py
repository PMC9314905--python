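"""Brute-force oracles used by the tests.

These recompute quantities the package estimates by MCMC using direct
numerical integration on tensor Gauss-Legendre grids, staying entirely
independent of the sampler and Chib code paths.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import gammaln, logsumexp

from oneinflate import CountFrequencies, ModelSpec, PriorConfig


def _gl_nodes(a: float, b: float, m: int) -> tuple[np.ndarray, np.ndarray]:
    x, w = leggauss(m)
    return 0.5 * (b - a) * x + 0.5 * (a + b), 0.5 * (b - a) * w


def _base_logpmf_grid(family: str, k: int, lam, p, r):
    """log f(k | theta) broadcast over parameter grids."""
    if family == "poisson":
        return -lam + k * np.log(lam) - gammaln(k + 1)
    if family == "geometric":
        return k * np.log1p(-p) + np.log(p)
    return (
        gammaln(k + r) - gammaln(r) - gammaln(k + 1)
        + r * np.log(p) + k * np.log1p(-p)
    )


def trunc_loglik_grid(
    data: CountFrequencies, spec: ModelSpec, lam=None, p=None, r=None, omega=None
):
    """Zero-truncated log likelihood on a parameter grid (broadcast)."""
    f0 = np.exp(_base_logpmf_grid(spec.family, 0, lam, p, r))
    out = 0.0
    for k, nk in data.freqs.items():
        logfk = _base_logpmf_grid(spec.family, k, lam, p, r)
        if spec.inflated:
            if k == 1:
                fk = (1.0 - omega) * np.exp(logfk) + omega * (1.0 - f0)
                logfk = np.log(fk)
            else:
                logfk = logfk + np.log1p(-omega)
        out = out + nk * (logfk - np.log1p(-f0))
    return out


def quad_logml(
    data: CountFrequencies,
    spec: ModelSpec,
    priors: PriorConfig,
    nodes_theta: int = 160,
    nodes_omega: int = 100,
    lam_hi: float = 30.0,
    r_hi: float = 60.0,
) -> float:
    """log p(y|M) = -log n + log Int L_trunc(theta) p(theta) dtheta.

    Quadrature over the full parameter block, N already integrated out
    analytically under p(N) ~ 1/N.
    """
    from scipy import stats

    axes: list[tuple[str, np.ndarray, np.ndarray, np.ndarray]] = []
    eps = 1e-9
    if spec.family == "poisson":
        x, w = _gl_nodes(eps, lam_hi, nodes_theta)
        lp = stats.gamma.logpdf(x, priors.lambda_shape, scale=1.0 / priors.lambda_rate)
        axes.append(("lam", x, w, lp))
    else:
        if spec.family == "negbin":
            x, w = _gl_nodes(eps, r_hi, nodes_theta)
            if priors.r_prior == "gamma":
                lp = stats.gamma.logpdf(x, priors.r_a, scale=1.0 / priors.r_b)
            else:
                lp = stats.invgamma.logpdf(x, priors.r_a, scale=priors.r_b)
            axes.append(("r", x, w, lp))
        x, w = _gl_nodes(eps, 1.0 - eps, nodes_theta)
        lp = stats.beta.logpdf(x, priors.p_a, priors.p_b)
        axes.append(("p", x, w, lp))
    if spec.inflated:
        x, w = _gl_nodes(eps, 1.0 - eps, nodes_omega)
        lp = stats.beta.logpdf(x, priors.omega_a, priors.omega_b)
        axes.append(("omega", x, w, lp))

    shape = [len(ax[1]) for ax in axes]
    grids = {}
    logw = np.zeros(shape)
    logprior = np.zeros(shape)
    for i, (name, x, w, lp) in enumerate(axes):
        view = [None] * len(axes)
        view[i] = slice(None)
        grids[name] = x[tuple(view)]
        logw = logw + np.log(w)[tuple(view)]
        logprior = logprior + lp[tuple(view)]
    ll = trunc_loglik_grid(
        data, spec,
        lam=grids.get("lam"), p=grids.get("p"), r=grids.get("r"),
        omega=grids.get("omega"),
    )
    return float(logsumexp(ll + logprior + logw)) - math.log(data.n)


def grid_joint_posterior_oip(
    data: CountFrequencies,
    priors: PriorConfig,
    lam_grid: np.ndarray,
    om_grid: np.ndarray,
    n_cap: int,
):
    """Exact joint posterior of (lambda, omega, N) for the one-inflated
    Poisson on a discretized grid, p(N) ~ 1/N, N capped at ``n_cap``.

    Returns the three marginal pmfs (over grid cells for lambda/omega and
    over integers n..n_cap for N), each normalized to 1.
    """
    n = data.n
    Ns = np.arange(n, n_cap + 1)
    L = lam_grid[:, None, None]
    W = om_grid[None, :, None]
    NN = Ns[None, None, :]
    f0 = np.exp(-L)
    loglik = (
        gammaln(NN + 1) - gammaln(NN - n + 1) - np.log(NN)
        + (NN - n) * np.log(f0)
    )
    for k, nk in data.freqs.items():
        base = np.exp(-L + k * np.log(L) - gammaln(k + 1))
        fk = (1 - W) * base + W * (1 - f0) if k == 1 else (1 - W) * base
        loglik = loglik + nk * np.log(fk)
    from scipy import stats

    logprior = (
        stats.gamma.logpdf(L, priors.lambda_shape, scale=1.0 / priors.lambda_rate)
        + stats.beta.logpdf(W, priors.omega_a, priors.omega_b)
    )
    post = np.exp(loglik + logprior - (loglik + logprior).max())
    post /= post.sum()
    return post.sum(axis=(1, 2)), post.sum(axis=(0, 2)), post.sum(axis=(0, 1))
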