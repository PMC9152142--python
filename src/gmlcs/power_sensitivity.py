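"""Analytic sensitivity analysis for the study design.

Two computations, mirroring what a conventional power tool reports for a
two-group, three-occasion repeated-measures design:

* the minimal detectable within-between (time-by-group) interaction effect
  size, Cohen's f, from inverting noncentral-F power with noncentrality
  lambda = f^2 * N * m * eps / (1 - rho), numerator df (g-1)(m-1)eps and
  denominator df (N-g)(m-1)eps, where rho is the correlation among repeated
  measures and eps the nonsphericity correction;
* the minimal detectable bivariate-normal correlation, either from the
  exact finite-sample distribution of the sample correlation coefficient
  (a Gaussian hypergeometric density, integrated numerically) or from the
  Fisher-z approximation r = tanh((z_{1-a} + z_{power}) / sqrt(N - 3)).

Both are solved by bisection to 1e-6.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize, special, stats


@dataclass
class PowerConfig:
    """Design and error rates for the sensitivity computations.

    ``rep_measures_correlation`` (rho, default 0.5) and ``nonsphericity``
    (eps, default 1) follow the conventional defaults of repeated-measures
    power tools; ``tails`` applies to the correlation test only.
    """

    alpha: float = 0.05
    power: float = 0.95
    n_total: int = 75
    groups: int = 2
    measurements: int = 3
    rep_measures_correlation: float = 0.5
    nonsphericity: float = 1.0
    tails: str = "one"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0 or not 0.0 < self.power < 1.0:
            raise ValueError("alpha and power must lie in (0, 1)")
        if self.power <= self.alpha:
            raise ValueError("power must exceed alpha")
        if self.n_total <= self.groups:
            raise ValueError("n_total must exceed the number of groups")
        if not -1.0 < self.rep_measures_correlation < 1.0:
            raise ValueError("repeated-measures correlation must lie in (-1, 1)")
        if not 0.0 < self.nonsphericity <= 1.0:
            raise ValueError("nonsphericity epsilon must lie in (0, 1]")
        if self.tails not in ("one", "two"):
            raise ValueError("tails must be 'one' or 'two'")


# ----------------------------------------------------------------------
# within-between interaction
# ----------------------------------------------------------------------
def interaction_power(f: float, config: PowerConfig) -> float:
    """Power of the time-by-group interaction F-test at effect size ``f``."""
    n, g, m = config.n_total, config.groups, config.measurements
    eps = config.nonsphericity
    rho = config.rep_measures_correlation
    df1 = (g - 1) * (m - 1) * eps
    df2 = (n - g) * (m - 1) * eps
    lam = f**2 * n * m * eps / (1.0 - rho)
    fcrit = stats.f.isf(config.alpha, df1, df2)
    return float(stats.ncf.sf(fcrit, df1, df2, lam))


def sensitivity_f_interaction(config: PowerConfig) -> float:
    """Minimal Cohen's f at which the interaction test reaches the target
    power; root of power(f) = power by bisection to 1e-6."""
    target = config.power
    lo, hi = 1e-8, 10.0
    if interaction_power(hi, config) < target:
        raise ValueError("no solution: target power unreachable for f in (0, 10)")
    return float(optimize.brentq(lambda f: interaction_power(f, config) - target, lo, hi, xtol=1e-6))


# ----------------------------------------------------------------------
# bivariate correlation
# ----------------------------------------------------------------------
def _corr_pdf(r: np.ndarray, rho: float, n: int) -> np.ndarray:
    """Exact density of the sample correlation of n bivariate-normal pairs
    with population correlation rho (Gaussian-hypergeometric form)."""
    r = np.asarray(r, dtype=float)
    log_c = (
        math.log(n - 2)
        + special.gammaln(n - 1)
        + 0.5 * (n - 1) * math.log1p(-(rho**2))
        - 0.5 * math.log(2.0 * math.pi)
        - special.gammaln(n - 0.5)
    )
    with np.errstate(divide="ignore"):
        log_body = 0.5 * (n - 4) * np.log1p(-(r**2)) - (n - 1.5) * np.log1p(-rho * r)
    hyp = special.hyp2f1(0.5, 0.5, n - 0.5, 0.5 * (1.0 + rho * r))
    return np.exp(log_c + log_body) * hyp


def _critical_r(alpha: float, n: int, tails: str) -> float:
    """Null critical value of the sample correlation via the exact
    t-transform t = r sqrt(n-2) / sqrt(1-r^2)."""
    a = alpha if tails == "one" else alpha / 2.0
    t = stats.t.isf(a, n - 2)
    return float(t / math.sqrt(n - 2 + t**2))


def correlation_power(rho: float, config: PowerConfig, exact: bool = True) -> float:
    """Power to detect a positive correlation ``rho`` at the configured
    alpha/tails (upper-tail rejection region; for two tails the lower region
    is negligible for the positive effect sizes considered here)."""
    n = config.n_total
    rc = _critical_r(config.alpha, n, config.tails)
    if exact:
        # split at the density's mode (near rho): for large n the density is
        # a narrow spike that adaptive quadrature can otherwise step over
        pts = [rho] if rc < rho < 1.0 else None
        val, _ = integrate.quad(_corr_pdf, rc, 1.0, args=(rho, n), limit=200, points=pts)
        return float(val)
    z = math.atanh(rho) * math.sqrt(n - 3)
    za = stats.norm.isf(config.alpha if config.tails == "one" else config.alpha / 2)
    return float(stats.norm.sf(za - z))


def sensitivity_r(config: PowerConfig, exact: bool = True) -> float:
    """Minimal detectable correlation at the configured alpha, power and N;
    bisection to 1e-6 on the exact (default) or Fisher-z power curve."""
    if config.n_total < 4:
        raise ValueError("the correlation test needs n_total >= 4")
    target = config.power
    # upper bracket stops short of rho = 1, where the exact density
    # degenerates to a point mass and quadrature breaks down
    lo, hi = 1e-8, 0.995
    if correlation_power(hi, config, exact=exact) < target:
        raise ValueError("no solution: target power unreachable for r in (0, 1)")
    return float(
        optimize.brentq(
            lambda rho: correlation_power(rho, config, exact=exact) - target,
            lo,
            hi,
            xtol=1e-6,
        )
    )


def fisher_z_r(config: PowerConfig) -> float:
    """Closed-form Fisher-z minimal correlation:
    tanh((z_{1-alpha} + z_{power}) / sqrt(N - 3))."""
    a = config.alpha if config.tails == "one" else config.alpha / 2
    za = stats.norm.isf(a)
    zb = stats.norm.isf(1.0 - config.power)
    return float(math.tanh((za + zb) / math.sqrt(config.n_total - 3)))
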