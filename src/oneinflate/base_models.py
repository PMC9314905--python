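"""Base and one-inflated count distributions.

The one-inflation mechanism: an individual whose latent capture count
``Y* > 1`` is, with probability ``omega``, observed as a singleton
(``Y = 1``) instead; counts of 0 and 1 are unaffected.  The observed
count ``Y`` therefore has pmf

    P(Y = 0) = f(0 | theta)
    P(Y = 1) = (1 - omega) f(1 | theta) + omega (1 - f(0 | theta))
    P(Y = j) = (1 - omega) f(j | theta),   j > 1

where ``f(. | theta)`` is the base pmf: Poisson(lambda), geometric
(``P(Y*=k) = (1-p)^k p``, support k >= 0), or negative binomial in the
(r, p) size/probability parameterization
``Gamma(k+r)/(Gamma(r) k!) p^r (1-p)^k`` (r = 1 recovers the geometric).

All pmfs are evaluated in log space (log-gamma based) and exponentiated
at the boundary, so large counts and small NB sizes do not underflow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

__all__ = [
    "ModelSpec",
    "ModelParams",
    "base_pmf",
    "base_logpmf",
    "base_cdf",
    "oi_pmf",
    "oi_logpmf",
    "ystar_given_one",
    "truncated_ystar_pmf",
    "truncated_ystar_support",
    "sample_truncated_ystar",
    "prob_inflated_given_one",
    "MODEL_ALIASES",
]

FAMILIES = ("poisson", "geometric", "negbin")

#: Short model labels used throughout (CLI, reports): base families and
#: their one-inflated (OI) counterparts.
MODEL_ALIASES = {
    "poi": ("poisson", False),
    "geo": ("geometric", False),
    "nb": ("negbin", False),
    "oip": ("poisson", True),
    "oig": ("geometric", True),
    "oinb": ("negbin", True),
}

_TAIL_TOL = 1e-12  # adaptive truncation tolerance for tail sampling


@dataclass(frozen=True)
class ModelSpec:
    """A model family plus whether the one-inflation layer is present."""

    family: str
    inflated: bool = False

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown family {self.family!r}; expected one of {FAMILIES}"
            )

    @classmethod
    def parse(cls, label: str) -> "ModelSpec":
        """Build from a short label: poi, geo, nb, oip, oig, oinb."""
        key = label.strip().lower()
        if key not in MODEL_ALIASES:
            raise ValueError(
                f"unknown model {label!r}; expected one of {sorted(MODEL_ALIASES)}"
            )
        family, inflated = MODEL_ALIASES[key]
        return cls(family, inflated)

    @property
    def label(self) -> str:
        if self.inflated:
            return {"poisson": "OIP", "geometric": "OIG", "negbin": "OINB"}[self.family]
        return {"poisson": "Poi", "geometric": "Geo", "negbin": "NB"}[self.family]

    @property
    def param_names(self) -> tuple[str, ...]:
        names = {
            "poisson": ("lambda_",),
            "geometric": ("p",),
            "negbin": ("r", "p"),
        }[self.family]
        return names + (("omega",) if self.inflated else ())


@dataclass
class ModelParams:
    """Parameter block for a :class:`ModelSpec`.

    Only the fields the spec requires may be set: ``lambda_`` (Poisson
    rate), ``p`` (geometric / NB success probability), ``r`` (NB size),
    and ``omega`` (inflation weight, inflated models only).  ``omega=0``
    makes the inflated model identical to its base model.
    """

    lambda_: Optional[float] = None
    p: Optional[float] = None
    r: Optional[float] = None
    omega: Optional[float] = None

    def validate(self, spec: ModelSpec) -> "ModelParams":
        need = set(spec.param_names)
        have = {
            name
            for name in ("lambda_", "p", "r", "omega")
            if getattr(self, name) is not None
        }
        if have != need:
            raise ValueError(
                f"{spec.label} requires parameters {sorted(need)}, got {sorted(have)}"
            )
        if "lambda_" in need and not self.lambda_ > 0:
            raise ValueError(f"lambda must be > 0, got {self.lambda_}")
        if "p" in need and not 0 < self.p < 1:
            raise ValueError(f"p must be in (0,1), got {self.p}")
        if "r" in need and not self.r > 0:
            raise ValueError(f"r must be > 0, got {self.r}")
        if "omega" in need and not 0 <= self.omega < 1:
            # omega = 1 would leave no observable counts > 1: non-identifiable.
            raise ValueError(f"omega must be in [0,1), got {self.omega}")
        return self


def _dist(spec: ModelSpec, params: ModelParams):
    if spec.family == "poisson":
        return stats.poisson(params.lambda_)
    if spec.family == "geometric":
        return stats.nbinom(1.0, params.p)
    return stats.nbinom(params.r, params.p)


def base_logpmf(k, spec: ModelSpec, params: ModelParams):
    """log f(k | theta) of the base (non-inflated) family."""
    _validate_base(spec, params)
    return _dist(spec, params).logpmf(k)


def base_pmf(k, spec: ModelSpec, params: ModelParams):
    """f(k | theta) of the base family."""
    _validate_base(spec, params)
    return np.exp(_dist(spec, params).logpmf(k))


def base_cdf(k, spec: ModelSpec, params: ModelParams):
    """F(k | theta) of the base family."""
    _validate_base(spec, params)
    return _dist(spec, params).cdf(k)


def _validate_base(spec: ModelSpec, params: ModelParams) -> None:
    ModelParams(
        lambda_=params.lambda_, p=params.p, r=params.r
    ).validate(ModelSpec(spec.family, False))


def _f01(spec: ModelSpec, params: ModelParams) -> tuple[float, float]:
    """(f(0|theta), f(1|theta)) in closed form."""
    if spec.family == "poisson":
        f0 = np.exp(-params.lambda_)
        return f0, params.lambda_ * f0
    if spec.family == "geometric":
        return params.p, (1.0 - params.p) * params.p
    f0 = params.p ** params.r
    return f0, params.r * f0 * (1.0 - params.p)


def oi_logpmf(j, spec: ModelSpec, params: ModelParams):
    """log pmf of the observed count Y under the one-inflated model."""
    if not spec.inflated:
        raise ValueError("oi_pmf requires an inflated ModelSpec")
    params.validate(spec)
    j = np.asarray(j)
    w = params.omega
    f0, f1 = _f01(spec, params)
    base = base_logpmf(j, ModelSpec(spec.family), params) + np.log1p(-w)
    out = np.where(j == 0, np.log(max(f0, 1e-300)), base)
    with np.errstate(divide="ignore"):
        at_one = np.log((1.0 - w) * f1 + w * (1.0 - f0))
    out = np.where(j == 1, at_one, out)
    return out if out.ndim else float(out)


def oi_pmf(j, spec: ModelSpec, params: ModelParams):
    """pmf of the observed count Y under the one-inflated model."""
    return np.exp(oi_logpmf(j, spec, params))


def prob_inflated_given_one(spec: ModelSpec, params: ModelParams) -> float:
    """P(Z = 1 | Y = 1): probability that an observed singleton is an
    inflated unit (latent count > 1 thinned to 1).

    This is the Binomial success probability used by the Gibbs step that
    reassigns singletons: ``omega (1-F(1)) / (f(1) + omega (1-F(1)))``.
    """
    if not spec.inflated:
        raise ValueError("requires an inflated ModelSpec")
    params.validate(spec)
    f0, f1 = _f01(spec, params)
    tail = max(1.0 - f0 - f1, 0.0)
    denom = f1 + params.omega * tail
    return params.omega * tail / denom if denom > 0 else 0.0


def ystar_given_one(k, spec: ModelSpec, params: ModelParams):
    """P(Y* = k | Y = 1): the latent count of an observed singleton.

    Mass f(1)/(f(1)+omega(1-F(1))) at k=1 (a genuine singleton) and
    omega f(k)/(f(1)+omega(1-F(1))) at each k>1 (an inflated unit);
    zero at k=0.
    """
    if not spec.inflated:
        raise ValueError("requires an inflated ModelSpec")
    params.validate(spec)
    k = np.asarray(k)
    f0, f1 = _f01(spec, params)
    tail = max(1.0 - f0 - f1, 0.0)
    denom = f1 + params.omega * tail
    fk = base_pmf(k, ModelSpec(spec.family), params)
    out = np.where(k == 1, f1 / denom, params.omega * fk / denom)
    out = np.where(k < 1, 0.0, out)
    return out if out.ndim else float(out)


def truncated_ystar_pmf(k, spec: ModelSpec, params: ModelParams):
    """P(Y* = k | Z = 1) = f(k)/(1 - F(1)) for k > 1, else 0.

    The latent-count law of a unit known to be inflated: its true count
    is at least 2, distributed as the base model truncated below 2.
    """
    params = ModelParams(lambda_=params.lambda_, p=params.p, r=params.r)
    params.validate(ModelSpec(spec.family))
    f0, f1 = _f01(spec, params)
    tail = 1.0 - f0 - f1
    if tail <= 0:
        raise ValueError(
            "1 - F(1|theta) is numerically zero: inflation impossible"
        )
    k = np.asarray(k)
    fk = base_pmf(k, ModelSpec(spec.family), params)
    out = np.where(k >= 2, fk / tail, 0.0)
    return out if out.ndim else float(out)


def truncated_ystar_support(
    spec: ModelSpec, params: ModelParams, tol: float = _TAIL_TOL
) -> tuple[np.ndarray, float, float]:
    """Tail probabilities f(k) for k = 2..K plus (f0, f1).

    K is the smallest count with relative upper-tail mass below ``tol``,
    recomputed per theta; the returned array is unnormalized (sums to
    approximately 1 - F(1)).  Used for the exact inverse-CDF /
    multinomial draw of inflated latent counts.
    """
    f0, f1 = _f01(spec, params)
    if 1.0 - f0 - f1 <= 1e-14:
        raise ValueError("1 - F(1|theta) is numerically zero: inflation impossible")
    kcap = 64
    while True:
        ks = np.arange(2, kcap + 1)
        if spec.family == "poisson":
            ratios = params.lambda_ / ks
            probs = f1 * np.cumprod(ratios)
        elif spec.family == "geometric":
            probs = f1 * np.cumprod(np.full(ks.shape, 1.0 - params.p))
        else:
            ratios = (1.0 - params.p) * (ks - 1 + params.r) / ks
            probs = f1 * np.cumprod(ratios)
        # bound the uncaptured tail by a geometric series with the largest
        # possible term-to-term ratio beyond kcap (computing it from the
        # terms avoids the cancellation in 1 - f0 - f1)
        if spec.family == "poisson":
            rmax = params.lambda_ / (kcap + 1)
        elif spec.family == "geometric":
            rmax = 1.0 - params.p
        else:
            rmax = max(
                (1.0 - params.p) * (kcap + params.r) / (kcap + 1),
                1.0 - params.p,
            )
        total = probs.sum()
        if rmax < 1.0:
            est_tail = probs[-1] * rmax / (1.0 - rmax)
            if est_tail <= tol * max(total, 1e-300):
                return probs, f0, f1
        if kcap >= 2**18:
            return probs, f0, f1
        kcap *= 2


def sample_truncated_ystar(
    n_draws: int,
    spec: ModelSpec,
    params: ModelParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Aggregated draw of latent counts from P(Y*=k | Z=1).

    Returns ``nz_k`` frequencies indexed from k=2 (a single multinomial
    over the adaptively truncated tail pmf).
    """
    probs, _, _ = truncated_ystar_support(spec, params)
    if n_draws == 0:
        return np.zeros(0, dtype=np.int64)
    return rng.multinomial(n_draws, probs / probs.sum())
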