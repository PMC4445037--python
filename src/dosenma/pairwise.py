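"""Classical pairwise meta-analysis: DerSimonian–Laird pooling and Begg's test.

Random-effects pooling uses the DerSimonian–Laird moment estimator of the
between-trial variance tau^2, Wald 95% confidence intervals, Cochran's Q and
the I^2 heterogeneity percentage.  Publication bias is screened with the
Begg–Mazumdar rank correlation between standardized effects and their
variances (Kendall's tau-b, normal approximation with continuity
correction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .effect_sizes import ContrastEstimate


@dataclass(frozen=True)
class PairwiseResult:
    comparison: tuple[str, str]
    scale: str
    k: int
    pooled_effect: float  # on the analysis scale (SMD or log-OR)
    ci95: tuple[float, float]
    tau2: float
    Q: float
    df: int
    p_Q: float
    I2: float  # percent

    @property
    def variance(self) -> float:
        """Variance of the pooled estimate, 1 / sum of RE weights."""
        return ((self.ci95[1] - self.ci95[0]) / (2 * 1.96)) ** 2

    @property
    def pooled_ratio(self) -> float:
        """Pooled odds ratio (exp of the pooled log-OR)."""
        if self.scale != "log_or":
            raise ValueError("ratio scale only defined for log-OR results")
        return math.exp(self.pooled_effect)

    @property
    def ci95_ratio(self) -> tuple[float, float]:
        if self.scale != "log_or":
            raise ValueError("ratio scale only defined for log-OR results")
        return (math.exp(self.ci95[0]), math.exp(self.ci95[1]))


@dataclass(frozen=True)
class BeggResult:
    kendall_tau: float
    z: float
    p: float
    k: int
    insufficient: bool = False  # k < 3: test not applicable, p fixed at 1


def _check_homogeneous(estimates: Sequence[ContrastEstimate]) -> None:
    comps = {e.comparison for e in estimates}
    scales = {e.scale for e in estimates}
    if len(comps) > 1:
        raise ValueError(f"mixed comparisons: {sorted(comps)}")
    if len(scales) > 1:
        raise ValueError(f"mixed scales: {sorted(scales)}")


def dl_pool(estimates: Sequence[ContrastEstimate]) -> PairwiseResult:
    """DerSimonian–Laird random-effects pool of one comparison.

    Fixed-effect weights w_i = 1/v_i give Q = sum w_i (y_i - ybar_FE)^2 and
    tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)); random-effects
    weights 1/(v_i + tau^2) give the pooled estimate and its Wald 95% CI.
    I^2 = max(0, 100 (Q - df)/Q), zero when Q = 0.
    """
    if not estimates:
        raise ValueError("no estimates to pool")
    _check_homogeneous(estimates)
    y = np.array([e.effect for e in estimates], dtype=float)
    v = np.array([e.variance for e in estimates], dtype=float)
    k = len(y)
    comparison = estimates[0].comparison
    scale = estimates[0].scale

    w = 1.0 / v
    y_fe = float(np.sum(w * y) / np.sum(w))
    q = float(np.sum(w * (y - y_fe) ** 2))
    df = k - 1
    if k == 1:
        tau2 = 0.0
        p_q = 1.0
        i2 = 0.0
    else:
        denom = float(np.sum(w) - np.sum(w ** 2) / np.sum(w))
        tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0
        p_q = float(stats.chi2.sf(q, df))
        i2 = max(0.0, 100.0 * (q - df) / q) if q > 0 else 0.0
    w_star = 1.0 / (v + tau2)
    pooled = float(np.sum(w_star * y) / np.sum(w_star))
    se = 1.0 / math.sqrt(float(np.sum(w_star)))
    return PairwiseResult(
        comparison=comparison,
        scale=scale,
        k=k,
        pooled_effect=pooled,
        ci95=(pooled - 1.96 * se, pooled + 1.96 * se),
        tau2=tau2,
        Q=q,
        df=df,
        p_Q=p_q,
        I2=i2,
    )


def beggs_test(estimates: Sequence[ContrastEstimate]) -> BeggResult:
    """Begg–Mazumdar rank-correlation test for small-study effects.

    Correlates the standardized fixed-effect deviates
    u_i = (y_i - ybar_FE)/sqrt(v_i - 1/sum w) with the variances v_i using
    Kendall's tau-b; the two-sided p comes from the normal approximation of
    Kendall's S with continuity correction (and tie correction in Var(S)).
    With fewer than three studies the test is undefined and p = 1 is
    returned with an ``insufficient`` flag.
    """
    k = len(estimates)
    if k < 3:
        return BeggResult(kendall_tau=float("nan"), z=0.0, p=1.0, k=k,
                          insufficient=True)
    _check_homogeneous(estimates)
    y = np.array([e.effect for e in estimates], dtype=float)
    v = np.array([e.variance for e in estimates], dtype=float)
    w = 1.0 / v
    y_fe = float(np.sum(w * y) / np.sum(w))
    # variance of (y_i - ybar_FE); clip guards rounding when one study dominates
    dev_var = np.maximum(v - 1.0 / float(np.sum(w)), 1e-12)
    u = (y - y_fe) / np.sqrt(dev_var)

    tau_b = float(stats.kendalltau(u, v).statistic)

    # Kendall's S with tie-corrected variance and continuity correction
    s = 0.0
    for i in range(k):
        s += float(np.sum(np.sign((u[i + 1:] - u[i]) * (v[i + 1:] - v[i]))))

    def _tie_term(x: np.ndarray) -> float:
        _, counts = np.unique(x, return_counts=True)
        return float(np.sum(counts * (counts - 1) * (2 * counts + 5)))

    var_s = (k * (k - 1) * (2 * k + 5) - _tie_term(u) - _tie_term(v)) / 18.0
    if var_s <= 0:
        return BeggResult(kendall_tau=tau_b, z=0.0, p=1.0, k=k)
    z = max(abs(s) - 1.0, 0.0) / math.sqrt(var_s)
    p = float(2.0 * stats.norm.sf(z))
    return BeggResult(kendall_tau=tau_b, z=z, p=p, k=k)
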