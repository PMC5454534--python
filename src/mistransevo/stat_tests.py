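"""Inferential statistics used throughout the analyses.

Student two-sample t-test, one-way ANOVA and the Mann–Whitney U-test, with
two-sided p-values computed from first principles on top of the regularized
incomplete beta function.  The tail areas come straight from the classical
identities

    P(|T_df| >= t)      = I_{df/(df+t^2)}(df/2, 1/2)
    P(F_{d1,d2} >= F)   = I_{d2/(d2+d1*F)}(d2/2, d1/2)

where I_x(a, b) is the regularized incomplete beta function.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import betainc

__all__ = [
    "StatResult",
    "p_from_t",
    "p_from_f",
    "two_sample_t",
    "one_way_anova",
    "mann_whitney_u",
]


@dataclass
class StatResult:
    """A named test statistic with degrees of freedom and two-sided p-value."""

    test_name: str
    statistic: float
    df: tuple[float, ...]
    p_value: float
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")

    def to_dict(self) -> dict:
        return {
            "test": self.test_name,
            "statistic": float(self.statistic),
            "df": list(self.df),
            "p_two_sided": float(self.p_value),
            **self.extras,
        }


def p_from_t(t: float, df: float) -> float:
    """Two-sided tail area of Student's t distribution.

    Parameters
    ----------
    t : observed statistic (any sign).
    df : degrees of freedom, > 0 (non-integer allowed, for Welch tests).
    """
    if df <= 0:
        raise ValueError(f"degrees of freedom must be positive, got {df}")
    t = float(t)
    if not math.isfinite(t):
        raise ValueError("t statistic must be finite")
    return float(betainc(df / 2.0, 0.5, df / (df + t * t)))


def p_from_f(f: float, df1: int, df2: int) -> float:
    """Upper-tail probability of the F distribution, P(F_{df1,df2} >= f)."""
    if f < 0:
        raise ValueError(f"F statistic must be non-negative, got {f}")
    if df1 <= 0 or df2 <= 0:
        raise ValueError("degrees of freedom must be positive")
    return float(betainc(df2 / 2.0, df1 / 2.0, df2 / (df2 + df1 * f)))


def two_sample_t(
    x: Sequence[float], y: Sequence[float], equal_var: bool = True
) -> StatResult:
    """Two-sample t-test, pooled-variance by default (Welch via equal_var=False).

    The pooled form with df = n_x + n_y - 2 is the default because the
    experimental comparisons of interest are balanced few-replicate designs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError("each sample needs at least two observations")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    diff = x.mean() - y.mean()
    if equal_var:
        df = nx + ny - 2
        pooled = ((nx - 1) * vx + (ny - 1) * vy) / df
        if pooled == 0:
            raise ValueError("zero pooled variance: t statistic undefined")
        t = diff / math.sqrt(pooled * (1.0 / nx + 1.0 / ny))
        dof: float = float(df)
    else:
        se2 = vx / nx + vy / ny
        if se2 == 0:
            raise ValueError("zero variance in both samples")
        t = diff / math.sqrt(se2)
        dof = se2 * se2 / (
            (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
        )
    return StatResult(
        "two_sample_t" if equal_var else "welch_t",
        float(t),
        (dof,),
        p_from_t(t, dof),
        extras={"n_x": int(nx), "n_y": int(ny)},
    )


def one_way_anova(groups: Sequence[Sequence[float]]) -> StatResult:
    """One-way fixed-effects analysis of variance.

    For two groups the F statistic equals the square of the pooled-variance
    t statistic on the same data.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrays)
    if k < 2:
        raise ValueError("need at least two groups")
    n = sum(a.size for a in arrays)
    if n <= k:
        raise ValueError("total sample size must exceed the number of groups")
    grand = np.concatenate(arrays).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df1, df2 = k - 1, n - k
    if ss_within == 0:
        raise ValueError("zero within-group variance everywhere: F undefined")
    f = (ss_between / df1) / (ss_within / df2)
    return StatResult(
        "one_way_anova",
        float(f),
        (float(df1), float(df2)),
        p_from_f(f, df1, df2),
        extras={"n": int(n), "k": int(k)},
    )


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U of x: number of (x_i, y_j) pairs with x_i > y_j, ties counting 1/2."""
    wins = (x[:, None] > y[None, :]).sum()
    ties = (x[:, None] == y[None, :]).sum()
    return float(wins) + 0.5 * float(ties)


def _exact_mwu_tails(pooled: np.ndarray, nx: int, u_obs: float) -> tuple[float, float]:
    """Exact lower/upper tail probabilities of U over all C(n, nx) splits."""
    n = pooled.size
    us = []
    idx = np.arange(n)
    for combo in itertools.combinations(idx, nx):
        mask = np.zeros(n, dtype=bool)
        mask[list(combo)] = True
        us.append(_u_statistic(pooled[mask], pooled[~mask]))
    arr = np.asarray(us)
    lo = float(np.mean(arr <= u_obs + 1e-9))
    hi = float(np.mean(arr >= u_obs - 1e-9))
    return lo, hi


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], two_sided: bool = True,
    method: str = "auto",
) -> StatResult:
    """Mann–Whitney U-test; U is the number of wins of x over y (ties = 1/2).

    Exact enumeration of all C(n_x+n_y, n_x) splits for n_x*n_y <= 200;
    otherwise a normal approximation with midrank tie correction and a
    continuity correction of 1/2.  method forces a branch ("exact" /
    "normal") mainly so the two can be compared.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 1 or ny < 1:
        raise ValueError("both samples must be non-empty")
    if method not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown method {method!r}")
    u = _u_statistic(x, y)
    use_exact = nx * ny <= 200 if method == "auto" else method == "exact"
    if use_exact:
        lo, hi = _exact_mwu_tails(np.concatenate([x, y]), nx, u)
        p = min(1.0, 2.0 * min(lo, hi)) if two_sided else hi
        method = "exact"
    else:
        mu = nx * ny / 2.0
        pooled = np.concatenate([x, y])
        _, counts = np.unique(pooled, return_counts=True)
        n = nx + ny
        tie_term = ((counts**3 - counts).sum()) / (n * (n - 1))
        sigma2 = nx * ny / 12.0 * (n + 1 - tie_term)
        if sigma2 <= 0:
            p = 1.0
        else:
            sigma = math.sqrt(sigma2)
            # Edgeworth correction: U is symmetric (skew 0) with excess
            # kurtosis gamma2 = -(6/5)(nx^2+ny^2+nx*ny+nx+ny)/(nx*ny*(n+1))
            gamma2 = (
                -1.2 * (nx * nx + ny * ny + nx * ny + nx + ny)
                / (nx * ny * (n + 1))
            )

            def _cdf(z: float) -> float:
                phi = math.exp(-z * z / 2.0) / math.sqrt(2.0 * math.pi)
                base = 0.5 * math.erfc(-z / math.sqrt(2.0))
                return base - phi * (z**3 - 3.0 * z) * gamma2 / 24.0

            lower = _cdf((u - mu + 0.5) / sigma)
            upper = 1.0 - _cdf((u - mu - 0.5) / sigma)
            if two_sided:
                p = min(1.0, max(0.0, 2.0 * min(lower, upper)))
            else:
                p = min(1.0, max(0.0, upper))
        method = "normal_approx"
    return StatResult(
        "mann_whitney_u",
        u,
        (float(nx), float(ny)),
        p,
        extras={"method": method},
    )
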