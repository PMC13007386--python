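"""JZS (Jeffreys-Zellner-Siow) Bayes-factor t-tests.

BF10 compares H1 — a Cauchy prior with scale ``r`` on the standardised
effect size delta — against the point null delta = 0, for a one-sample (or
paired-difference) t-test.  The marginal likelihood under H1 is the
noncentral-t density integrated over the Cauchy prior, evaluated by
adaptive quadrature; the null likelihood is the central t density.
Evidence categories follow the conventional thresholds: BF10 > 3 supports
the alternative, BF10 < 1/3 the null, anything between is insufficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy.stats import cauchy, nct
from scipy.stats import t as t_dist

DEFAULT_SCALE_R = np.sqrt(2.0) / 2.0

CATEGORY_ALTERNATIVE = "alternative"
CATEGORY_NULL = "null"
CATEGORY_INSUFFICIENT = "insufficient"


@dataclass(frozen=True)
class BayesResult:
    bf10: float
    t_stat: float
    n: int
    scale_r: float
    category: str


def categorize_bf(bf10: float) -> str:
    """Threshold at 3 and 1/3; the boundaries themselves are insufficient."""
    if bf10 <= 0:
        raise ValueError("BF10 must be positive")
    if bf10 > 3.0:
        return CATEGORY_ALTERNATIVE
    if bf10 < 1.0 / 3.0:
        return CATEGORY_NULL
    return CATEGORY_INSUFFICIENT


def jzs_bf_from_t(
    t: float,
    n: int,
    scale_r: float = DEFAULT_SCALE_R,
    sided: str = "two",
    tol: float = 1e-8,
) -> float:
    """BF10 from a one-sample t statistic with n observations.

    ``sided='two'`` integrates over the full Cauchy prior; ``'greater'``
    over the positive half (doubled density), for directional
    above-chance tests.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    nu = n - 1
    sqrt_n = np.sqrt(n)

    def integrand(delta: float) -> float:
        return nct.pdf(t, nu, delta * sqrt_n) * cauchy.pdf(delta, scale=scale_r)

    if sided == "two":
        m1, _ = integrate.quad(integrand, -np.inf, np.inf, epsabs=tol, epsrel=tol, limit=200)
    elif sided == "greater":
        m1, _ = integrate.quad(integrand, 0.0, np.inf, epsabs=tol, epsrel=tol, limit=200)
        m1 *= 2.0
    else:
        raise ValueError("sided must be 'two' or 'greater'")
    m0 = t_dist.pdf(t, nu)
    return float(m1 / m0)


def bf_ttest_onesample(
    x: np.ndarray,
    mu0: float = 0.0,
    scale_r: float = DEFAULT_SCALE_R,
    sided: str = "two",
) -> BayesResult:
    """JZS Bayes factor for H1: mean(x) != mu0 (or > mu0 when one-sided)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("x must be a vector with at least 2 observations")
    if not np.all(np.isfinite(x)):
        raise ValueError("x must be finite")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance: the t statistic is undefined")
    n = x.size
    t = (x.mean() - mu0) / (sd / np.sqrt(n))
    bf10 = jzs_bf_from_t(t, n, scale_r=scale_r, sided=sided)
    return BayesResult(bf10=bf10, t_stat=float(t), n=n, scale_r=scale_r,
                       category=categorize_bf(bf10))


def bf_ttest_paired(
    x: np.ndarray,
    y: np.ndarray,
    scale_r: float = DEFAULT_SCALE_R,
    sided: str = "two",
) -> BayesResult:
    """One-sample JZS test on the paired differences x - y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    return bf_ttest_onesample(x - y, mu0=0.0, scale_r=scale_r, sided=sided)
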