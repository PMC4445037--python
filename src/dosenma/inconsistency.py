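"""Direct-vs-indirect agreement in a closed loop (Bucher method).

In a three-treatment loop the comparison A vs B is estimated directly from
head-to-head trials and indirectly through the common comparator C:
indirect = (A vs C) - (B vs C), with the variances adding.  The discrepancy
between the two routes, exponentiated on the OR scale, is the ratio of odds
ratios (RoR); a 95% CI of the absolute-oriented RoR lying entirely above 1
(equivalently |z| > 1.96) flags statistically significant inconsistency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .effect_sizes import ContrastEstimate


@dataclass(frozen=True)
class LoopInconsistency:
    loop: tuple[str, str, str]
    direct_effect: float
    direct_variance: float
    indirect_effect: float
    indirect_variance: float
    discrepancy: float  # |direct - indirect| on the additive scale
    ci95: tuple[float, float]  # CI of the absolute-oriented discrepancy
    z: float
    p: float
    significant: bool
    scale: str

    @property
    def ror(self) -> float:
        """Ratio of odds ratios (>= 1 by the absolute-value orientation)."""
        if self.scale != "log_or":
            raise ValueError("RoR defined on the log-OR scale only")
        return math.exp(self.discrepancy)

    @property
    def ror_ci95(self) -> tuple[float, float]:
        if self.scale != "log_or":
            raise ValueError("RoR defined on the log-OR scale only")
        return (math.exp(self.ci95[0]), math.exp(self.ci95[1]))


def bucher_indirect(ac: ContrastEstimate, bc: ContrastEstimate) -> ContrastEstimate:
    """Indirect A-vs-B estimate through the common comparator C.

    effect = effect_AC - effect_BC; variance = var_AC + var_BC.
    """
    if ac.scale != bc.scale:
        raise ValueError("estimates must share a scale")
    if ac.comparison[1] != bc.comparison[1]:
        raise ValueError(
            f"common comparator mismatch: {ac.comparison[1]} vs {bc.comparison[1]}"
        )
    return ContrastEstimate(
        study_id=f"indirect({ac.study_id},{bc.study_id})",
        comparison=(ac.comparison[0], bc.comparison[0]),
        effect=ac.effect - bc.effect,
        variance=ac.variance + bc.variance,
        scale=ac.scale,
    )


def loop_ror(direct: ContrastEstimate, indirect: ContrastEstimate) -> LoopInconsistency:
    """Compare direct and indirect estimates of the same edge.

    The discrepancy is reported in absolute orientation, so the RoR is
    always >= 1; inconsistency is significant when the CI of the oriented
    discrepancy excludes 0 (RoR CI entirely above 1), i.e. |z| > 1.96.
    """
    if direct.scale != indirect.scale:
        raise ValueError("direct and indirect estimates must share a scale")
    if set(direct.comparison) != set(indirect.comparison):
        raise ValueError("direct and indirect estimates must address the same edge")
    diff = direct.effect - indirect.effect
    se = math.sqrt(direct.variance + indirect.variance)
    z = diff / se if se > 0 else 0.0
    adiff = abs(diff)
    ci = (adiff - 1.96 * se, adiff + 1.96 * se)
    p = float(2.0 * stats.norm.sf(abs(z)))
    loop = tuple(dict.fromkeys(direct.comparison + indirect.comparison))
    if len(loop) == 2:  # same edge both ways; name the loop by its edge
        loop = loop + ("?",)
    return LoopInconsistency(
        loop=loop[:3],
        direct_effect=direct.effect,
        direct_variance=direct.variance,
        indirect_effect=indirect.effect,
        indirect_variance=indirect.variance,
        discrepancy=adiff,
        ci95=ci,
        z=z,
        p=p,
        significant=abs(z) > 1.96,
        scale=direct.scale,
    )
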