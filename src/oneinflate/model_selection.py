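"""Marginal likelihoods, posterior model probabilities, and averaging.

Under the scale-invariant prior p(N) = c/N the population size
integrates out of the marginal likelihood analytically,

    p(y | M) = (c / n) * Integral  prod_i f(y_i | theta) / (1 - f(0 | theta))
               p(theta) d theta,

so model comparison depends solely on how well the zero-truncated
distribution fits the observed captures, and the constant c cancels from
posterior model probabilities.  The remaining integral is estimated with
Chib's method from the Gibbs output: the basic marginal-likelihood
identity is evaluated at the posterior mean theta*, with posterior
ordinates Rao-Blackwellized over the latent draws and, for the
Metropolis-updated NB size r, estimated with the Chib-Jeliazkov ratio.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .base_models import ModelParams, ModelSpec, _f01, oi_logpmf, base_logpmf
from .counts_io import CountFrequencies
from .gibbs import (
    PosteriorDraws,
    PriorConfig,
    SamplerConfig,
    r_log_accept_ratio,
    run_sampler,
)

__all__ = [
    "truncated_loglik",
    "ChibEstimate",
    "log_marginal_likelihood_chib",
    "posterior_model_probs",
    "ModelComparison",
    "compare_models",
    "bayes_factor",
    "model_average_N",
]

_MIN_RETAINED = 1000


def truncated_loglik(
    data: CountFrequencies, spec: ModelSpec, params: ModelParams
) -> float:
    """Zero-truncated log likelihood sum_k n_k [log f(k) - log(1 - f(0))].

    ``f`` is the one-inflated pmf for inflated specs and the base pmf
    otherwise; in both cases f(0) equals the base zero probability.
    Returns -inf when f(0|theta) is numerically 1 (nothing observable).
    """
    params.validate(spec)
    f0, _ = _f01(spec, params)
    if f0 >= 1.0:
        return -np.inf
    ks = np.fromiter(data.freqs.keys(), dtype=np.int64)
    ws = np.fromiter(data.freqs.values(), dtype=np.int64)
    if spec.inflated:
        logf = oi_logpmf(ks, spec, params)
    else:
        logf = base_logpmf(ks, spec, params)
    return float(ws @ (logf - math.log1p(-f0)))


def _logmeanexp(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(logsumexp(x) - math.log(x.shape[0]))


def _params_at(spec: ModelSpec, point: Mapping[str, float]) -> ModelParams:
    return ModelParams(**{k: point.get(k) for k in spec.param_names}).validate(spec)


@dataclass(frozen=True)
class ChibEstimate:
    """Decomposed Chib estimate of log p(y | M) (c = 1 in the c/n factor)."""

    spec: ModelSpec
    logml: float
    loglik: float
    log_prior: float
    log_ordinates: dict[str, float]
    theta_star: dict[str, float]


def _require_jeffreys_n(priors: PriorConfig) -> None:
    if not (priors.n_prior == "power" and priors.n_power == -1.0):
        raise ValueError(
            "marginal likelihoods are computed with N integrated out under "
            "p(N) ~ 1/N; model comparison under other N-priors is not "
            "supported (the improper-constant cancellation argument requires "
            "the same 1/N prior in every model)"
        )


def log_marginal_likelihood_chib(
    data: CountFrequencies,
    spec: ModelSpec,
    priors: PriorConfig | None = None,
    config: SamplerConfig | None = None,
    draws: PosteriorDraws | None = None,
) -> ChibEstimate:
    """Estimate log p(y|M) from a Gibbs run via Chib's identity.

    Evaluated at theta* = posterior means: block 1 is the base-family
    parameter block (lambda; p; or p then r for the NB), block 2 the
    inflation weight omega.  The first-block ordinate is
    Rao-Blackwellized over the main run; later blocks use reduced runs
    with the earlier blocks pinned at their starred values.  The
    Metropolis-updated r block uses the Chib-Jeliazkov two-run ordinate;
    with a Gamma prior and the CRT updater it is Rao-Blackwellized
    instead.

    ``draws`` may supply an existing main run (it must match ``priors``
    and ``config``); otherwise one is run here.
    """
    priors = priors or PriorConfig()
    config = config or SamplerConfig()
    _require_jeffreys_n(priors)
    if draws is None:
        draws = run_sampler(data, spec, priors, config)
    if len(draws) < _MIN_RETAINED:
        raise ValueError(
            f"{len(draws)} retained draws < {_MIN_RETAINED}: posterior "
            "ordinates would be too noisy; lengthen the chain"
        )

    ch = draws.chains
    star = {name: float(ch[name].mean()) for name in spec.param_names}
    params_star = _params_at(spec, star)
    N = ch["N"].astype(float)
    s_star = ch["s_star"].astype(float)
    ords: dict[str, float] = {}

    # ---- block 1 ordinate from the main run --------------------------
    if spec.family == "poisson":
        ords["lambda_"] = _logmeanexp(
            stats.gamma.logpdf(
                star["lambda_"],
                priors.lambda_shape + s_star,
                scale=1.0 / (priors.lambda_rate + N),
            )
        )
        log_prior = stats.gamma.logpdf(
            star["lambda_"], priors.lambda_shape, scale=1.0 / priors.lambda_rate
        )
    elif spec.family == "geometric":
        ords["p"] = _logmeanexp(
            stats.beta.logpdf(star["p"], priors.p_a + N, priors.p_b + s_star)
        )
        log_prior = stats.beta.logpdf(star["p"], priors.p_a, priors.p_b)
    else:
        ords["p"] = _logmeanexp(
            stats.beta.logpdf(
                star["p"], priors.p_a + N * ch["r"], priors.p_b + s_star
            )
        )
        log_prior = stats.beta.logpdf(star["p"], priors.p_a, priors.p_b)
        ords["r"] = _r_ordinate(data, spec, priors, config, star)
        if priors.r_prior == "gamma":
            log_prior += stats.gamma.logpdf(
                star["r"], priors.r_a, scale=1.0 / priors.r_b
            )
        else:
            log_prior += stats.invgamma.logpdf(star["r"], priors.r_a, scale=priors.r_b)

    # ---- omega ordinate from a reduced run with theta* fixed ----------
    if spec.inflated:
        fixed = {k: star[k] for k in spec.param_names if k != "omega"}
        red = run_sampler(
            data, spec, priors, replace(config, seed=config.seed + 202),
            fixed=fixed,
        )
        ords["omega"] = _logmeanexp(
            stats.beta.logpdf(
                star["omega"],
                priors.omega_a + red.chains["nz"].astype(float),
                priors.omega_b + data.tail_count,
            )
        )
        log_prior += stats.beta.logpdf(star["omega"], priors.omega_a, priors.omega_b)

    loglik = truncated_loglik(data, spec, params_star)
    logml = (
        -math.log(data.n) + loglik + float(log_prior) - sum(ords.values())
    )
    return ChibEstimate(
        spec=spec,
        logml=logml,
        loglik=loglik,
        log_prior=float(log_prior),
        log_ordinates=ords,
        theta_star=star,
    )


def _r_ordinate(
    data: CountFrequencies,
    spec: ModelSpec,
    priors: PriorConfig,
    config: SamplerConfig,
    star: Mapping[str, float],
) -> float:
    """Posterior ordinate of the NB size r at r*, given p fixed at p*."""
    r_star, p_star = star["r"], star["p"]
    use_crt = priors.r_prior == "gamma" and config.r_update == "crt"
    red1 = run_sampler(
        data, spec, priors, replace(config, seed=config.seed + 101),
        fixed={"p": p_star},
        retained_hook=None if use_crt else _cj_numerator_hook(
            priors, r_star, _cj_scale(r_star)
        ),
    )
    if use_crt:
        rate = priors.r_b - red1.chains["N"].astype(float) * math.log(p_star)
        return _logmeanexp(
            stats.gamma.logpdf(
                r_star,
                priors.r_a + red1.chains["l_crt"].astype(float),
                scale=1.0 / rate,
            )
        )
    # Chib-Jeliazkov: numerator E_post[alpha(r -> r*) q(r*, r)] over the
    # reduced run, denominator E_q[alpha(r* -> r')] with r held at r*.
    sigma = _cj_scale(r_star)
    log_num = _logmeanexp(red1.chains["hook"])
    prop_rng = np.random.default_rng(config.seed + 303)

    def den_hook(state) -> float:
        r_prop = r_star + sigma * prop_rng.standard_normal()
        if r_prop <= 0:
            return 0.0
        delta = r_log_accept_ratio(
            state.nstar, state.N, state.params.p, r_star, r_prop, priors
        )
        return math.exp(min(delta, 0.0))

    red2 = run_sampler(
        data, spec, priors, replace(config, seed=config.seed + 404),
        fixed={"p": p_star, "r": r_star},
        retained_hook=den_hook,
    )
    den = float(red2.chains["hook"].mean())
    return log_num - math.log(den)


def _cj_scale(r_star: float) -> float:
    return 0.5 + 0.25 * r_star


def _cj_numerator_hook(priors: PriorConfig, r_star: float, sigma: float):
    log_norm = -0.5 * math.log(2.0 * math.pi) - math.log(sigma)

    def hook(state) -> float:
        r = state.params.r
        delta = r_log_accept_ratio(
            state.nstar, state.N, state.params.p, r, r_star, priors
        )
        logq = log_norm - 0.5 * ((r_star - r) / sigma) ** 2
        return min(delta, 0.0) + logq

    return hook


# --------------------------------------------------------------------------
# model probabilities, Bayes factors, averaging
# --------------------------------------------------------------------------

def posterior_model_probs(
    logmls: Sequence[float], prior_probs: Sequence[float] | None = None
) -> np.ndarray:
    """Posterior model probabilities from log marginal likelihoods.

    Softmax with max-subtraction; equal prior probabilities by default.
    Invariant to adding a common constant to every log marginal
    likelihood (which is why the improper-prior constant is harmless).
    """
    logmls = np.asarray(logmls, dtype=float)
    if logmls.shape[0] < 2:
        raise ValueError("need at least two models to compare")
    if np.isnan(logmls).any():
        raise ValueError("NaN log marginal likelihood")
    if prior_probs is None:
        logp = np.zeros_like(logmls)
    else:
        prior_probs = np.asarray(prior_probs, dtype=float)
        if prior_probs.shape != logmls.shape or (prior_probs <= 0).any():
            raise ValueError("prior_probs must be positive and match logmls")
        logp = np.log(prior_probs / prior_probs.sum())
    z = logmls + logp
    z = z - z.max()
    w = np.exp(z)
    return w / w.sum()


def model_average_N(
    N_hats: Sequence[float], probs: Sequence[float], atol: float = 1e-8
) -> float:
    """Model-averaged population size N_bar = sum_i N_hat_i P(M_i | y)."""
    probs = np.asarray(probs, dtype=float)
    if abs(probs.sum() - 1.0) > atol:
        raise ValueError("model probabilities must sum to 1")
    return float(np.asarray(N_hats, dtype=float) @ probs)


@dataclass(frozen=True)
class ModelComparison:
    """Joint comparison of several models on one dataset."""

    models: tuple[str, ...]
    logml: dict[str, float]
    post_prob: dict[str, float]
    N_hat: dict[str, float]  # per-model posterior mean of N
    N_bar: float
    prior_prob: dict[str, float] = field(default_factory=dict)

    def bayes_factor(self, model_i: str, model_j: str) -> dict[str, float]:
        """Bayes factor in favor of model_i over model_j.

        Returned on natural-log, log10, and ratio scales; the
        posterior-odds form folds in non-equal prior probabilities.
        """
        d = self.logml[model_i] - self.logml[model_j]
        prior_odds = (
            self.prior_prob.get(model_i, 1.0) / self.prior_prob.get(model_j, 1.0)
        )
        return {
            "log_bf": d,
            "log10_bf": d / math.log(10.0),
            "bf": math.exp(d) if d < 700 else math.inf,
            "posterior_odds": (math.exp(d) if d < 700 else math.inf) * prior_odds,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(
            {
                "models": list(self.models),
                "log_marginal_likelihood": self.logml,
                "posterior_prob": self.post_prob,
                "N_hat": self.N_hat,
                "N_bar": self.N_bar,
            },
            **kw,
        )

    def to_text(self) -> str:
        lines = [f"{'model':<8}{'log m(y)':>14}{'P(M|y)':>10}{'N_hat':>12}"]
        for m in self.models:
            lines.append(
                f"{m:<8}{self.logml[m]:>14.2f}{self.post_prob[m]:>10.3f}"
                f"{self.N_hat[m]:>12.1f}"
            )
        lines.append(f"model-averaged N_bar = {self.N_bar:.1f}")
        return "\n".join(lines)


def compare_models(
    data: CountFrequencies,
    specs: Sequence[ModelSpec | str],
    priors: PriorConfig | Mapping[str, PriorConfig] | None = None,
    config: SamplerConfig | None = None,
    prior_probs: Sequence[float] | None = None,
) -> ModelComparison:
    """Fit each model, estimate its marginal likelihood, and combine.

    ``priors`` may be a single shared :class:`PriorConfig` or a mapping
    from model label (e.g. ``"oinb"``) to a per-model configuration.
    """
    specs = [ModelSpec.parse(s) if isinstance(s, str) else s for s in specs]
    labels = [s.label for s in specs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate models in comparison")
    if len(specs) < 2:
        raise ValueError("need at least two models to compare")
    config = config or SamplerConfig()

    logmls, N_hats = {}, {}
    for i, spec in enumerate(specs):
        pri = priors
        if isinstance(priors, Mapping):
            pri = priors.get(spec.label.lower(), None)
        pri = pri or PriorConfig()
        cfg = replace(config, seed=config.seed + 1000 * i)
        draws = run_sampler(data, spec, pri, cfg)
        est = log_marginal_likelihood_chib(data, spec, pri, cfg, draws=draws)
        logmls[spec.label] = est.logml
        N_hats[spec.label] = float(draws.chains["N"].mean())

    probs = posterior_model_probs(
        [logmls[m] for m in labels], prior_probs
    )
    post = {m: float(p) for m, p in zip(labels, probs)}
    if prior_probs is None:
        prior = {m: 1.0 / len(labels) for m in labels}
    else:
        tot = float(np.sum(prior_probs))
        prior = {m: float(p) / tot for m, p in zip(labels, prior_probs)}
    return ModelComparison(
        models=tuple(labels),
        logml=logmls,
        post_prob=post,
        N_hat=N_hats,
        N_bar=model_average_N([N_hats[m] for m in labels], probs),
        prior_prob=prior,
    )
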