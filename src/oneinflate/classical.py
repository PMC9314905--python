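"""Closed-form benchmark estimators of the population size.

Chao's lower bound and Zelterman's truncated-Poisson estimator both rest
on the singleton count n1, so an excess of singletons (one-inflation)
biases them upward.  The modified Chao estimators drop n1 entirely and
rebuild the zero class from doubletons and tripletons, using the moment
identity E[n2]/E[n3] of the assumed base family:

* one-inflated Poisson base: lambda = 3 n3 / n2 and
  n0 = 2 n2 / lambda^2, giving  N = n + 2 n2^3 / (9 n3^2);
* one-inflated geometric base: 1 - p = n3 / n2 and
  n0 = n2 / (1 - p)^2, giving  N = n + n2^3 / n3^2.

Because only frequencies of k >= 2 enter, these are robust to any
inflation mechanism that moves mass onto k = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .counts_io import CountFrequencies

__all__ = ["EstimateRecord", "chao", "zelterman", "modified_chao"]


@dataclass(frozen=True)
class EstimateRecord:
    """A point estimate of N with its building blocks.

    ``interval``, when present, is a rough log-normal approximation and
    is labeled as such: it does not reproduce the interval constructions
    used in the primary literature.
    """

    estimator: str
    N_hat: float
    components: dict[str, float]
    interval: Optional[tuple[float, float]] = None
    interval_kind: Optional[str] = None


def chao(data: CountFrequencies, bias_corrected: bool = False,
         level: float = 0.95) -> EstimateRecord:
    """Chao's lower-bound estimator N = n + n1^2 / (2 n2).

    With ``bias_corrected`` the n0 term becomes n1(n1-1)/(2(n2+1)),
    which stays finite when n2 = 0.  The attached interval is a
    log-normal approximation on n0 (approximate only).
    """
    n1, n2 = data[1], data[2]
    if n2 == 0 and not bias_corrected:
        raise ValueError(
            "n2 = 0: Chao estimator undefined; use bias_corrected=True "
            "for the n1(n1-1)/(2(n2+1)) variant"
        )
    if bias_corrected:
        n0_hat = n1 * (n1 - 1) / (2.0 * (n2 + 1))
    else:
        n0_hat = n1 * n1 / (2.0 * n2)
    interval = None
    if n1 > 0 and n2 > 0 and n0_hat > 0:
        # classical variance of the Chao n0 estimate, then a log-normal CI
        ratio = n1 / n2
        var = n2 * (0.25 * ratio**4 + ratio**3 + 0.5 * ratio**2)
        c = math.exp(
            stats_norm_ppf(0.5 + level / 2.0)
            * math.sqrt(math.log1p(var / n0_hat**2))
        )
        interval = (data.n + n0_hat / c, data.n + n0_hat * c)
    return EstimateRecord(
        estimator="chao" + ("_bc" if bias_corrected else ""),
        N_hat=data.n + n0_hat,
        components={"n": data.n, "n1": n1, "n2": n2, "n0_hat": n0_hat},
        interval=interval,
        interval_kind="log-normal approximation (not the published CI)"
        if interval else None,
    )


def zelterman(data: CountFrequencies) -> EstimateRecord:
    """Zelterman's estimator: lambda = 2 n2 / n1, N = n / (1 - e^-lambda)."""
    n1, n2 = data[1], data[2]
    if n1 == 0 or n2 == 0:
        raise ValueError("Zelterman estimator needs n1 > 0 and n2 > 0")
    lam = 2.0 * n2 / n1
    N_hat = data.n / (1.0 - math.exp(-lam))
    return EstimateRecord(
        estimator="zelterman",
        N_hat=N_hat,
        components={"n": data.n, "n1": n1, "n2": n2, "lambda_hat": lam},
    )


def modified_chao(data: CountFrequencies, family: str = "poisson") -> EstimateRecord:
    """Singleton-free modified Chao estimator under a one-inflated base.

    ``family`` selects the base distribution whose moment identity links
    n2 and n3: "poisson" gives N = n + 2 n2^3 / (9 n3^2), "geometric"
    gives N = n + n2^3 / n3^2.
    """
    if family not in ("poisson", "geometric"):
        raise ValueError("family must be 'poisson' or 'geometric'")
    n2, n3 = data[2], data[3]
    if n3 == 0:
        raise ValueError("n3 = 0: modified Chao estimator undefined")
    if family == "poisson":
        lam = 3.0 * n3 / n2 if n2 > 0 else math.inf
        n0_hat = 2.0 * n2**3 / (9.0 * n3**2)
        comps = {"n": data.n, "n2": n2, "n3": n3, "lambda_hat": lam}
    else:
        one_minus_p = n3 / n2 if n2 > 0 else math.inf
        n0_hat = n2**3 / n3**2
        comps = {"n": data.n, "n2": n2, "n3": n3, "p_hat": 1.0 - one_minus_p}
    return EstimateRecord(
        estimator=f"modified_chao_{'oip' if family == 'poisson' else 'oig'}",
        N_hat=data.n + n0_hat,
        components={**comps, "n0_hat": n0_hat},
    )


def stats_norm_ppf(q: float) -> float:
    from scipy.stats import norm

    return float(norm.ppf(q))
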