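"""Power analysis for a two-sided test of a Pearson/Spearman correlation.

Mirrors the classic Fisher-z algorithm with small-sample bias correction:
the critical correlation is derived from the two-sided t criterion on n-2
degrees of freedom, effect and criterion are mapped through the variance
stabilizing z = arctanh transform (with the bias term r / (2(n-1))), and
power is the normal tail mass beyond the criterion at precision sqrt(n-3).
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, stats


def correlation_power(r: float, n: int, alpha: float = 0.05) -> float:
    """Probability of detecting a true correlation ``r`` at level ``alpha``.

    Two-sided test; both rejection tails are counted.  As r -> 0 power
    approaches alpha (the test size).
    """
    if not 0 <= r < 1:
        raise ValueError("r must lie in [0, 1)")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n < 4:
        raise ValueError("need n >= 4")
    t_crit = stats.t.ppf(1 - alpha / 2, df=n - 2)
    r_crit = t_crit / np.sqrt(n - 2 + t_crit**2)
    z = np.arctanh(r) + r / (2 * (n - 1))
    z_crit = np.arctanh(r_crit)
    scale = np.sqrt(n - 3)
    return float(stats.norm.cdf((z - z_crit) * scale) + stats.norm.cdf((-z - z_crit) * scale))


def detectable_r(power: float, n: int, alpha: float = 0.05, tol: float = 1e-6) -> float:
    """Smallest true correlation detected with the requested power.

    Inverts :func:`correlation_power` by bisection on (0, 0.999).
    """
    if not alpha < power < 1:
        raise ValueError("power must lie in (alpha, 1)")
    lo, hi = 1e-12, 0.999
    f = lambda r: correlation_power(r, n, alpha) - power
    if f(hi) < 0:
        raise ValueError("requested power unreachable for r < 0.999 at this n")
    return float(optimize.brentq(f, lo, hi, xtol=tol))


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Per-test level controlling the family-wise error over m tests."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def power_curve(n: int, alpha: float = 0.05, r_max: float = 0.4, num: int = 200) -> dict:
    """Power as a function of true r on [0, r_max] (for plotting)."""
    rs = np.linspace(0, r_max, num)
    return {"r": rs, "power": np.array([correlation_power(r, n, alpha) for r in rs])}
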