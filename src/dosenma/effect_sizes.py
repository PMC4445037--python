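"""Trial-level effect sizes: Hedges' g and log odds ratios with variances.

Continuous outcomes (pain/function severity scores) are contrasted as
standardized mean differences with the small-sample bias correction
(Hedges' g); a negative value favors the first arm.  Binary adverse-event
outcomes are contrasted as log odds ratios from the 2x2 table, with the
Haldane–Anscombe 0.5 continuity correction when any cell is zero.

Also implements the outcome-scale hierarchy rule: when a study reports
several pain or function scales, the highest-ranked scale is the one
analyzed.
"""

from __future__ import annotations

import json
import importlib.resources
import math
from dataclasses import dataclass
from typing import Sequence

from .data_model import ArmRecord, BinaryOutcome, ContinuousOutcome


class DegenerateDataError(ValueError):
    """Raised when the data admit no finite effect size (e.g. pooled SD 0)."""


@dataclass(frozen=True)
class ContrastEstimate:
    """An effect for 'X vs Y' in one study with its sampling variance."""

    study_id: str
    comparison: tuple[str, str]  # (X, Y)
    effect: float
    variance: float
    scale: str  # "smd" | "log_or"
    double_zero: bool = False  # both arms 0 or both all-events (binary only)

    def __post_init__(self) -> None:
        if self.comparison[0] == self.comparison[1]:
            raise ValueError("comparison treatments must be distinct")
        if not self.variance > 0:
            raise ValueError(f"variance must be positive, got {self.variance}")


def hedges_g(arm_x: ArmRecord, arm_y: ArmRecord) -> ContrastEstimate:
    """Bias-corrected standardized mean difference of arm X vs arm Y.

    Pooled SD s_p = sqrt(((n_x-1)s_x^2 + (n_y-1)s_y^2)/(n_x+n_y-2)),
    d = (mean_x - mean_y)/s_p, J = 1 - 3/(4(n_x+n_y-2) - 1), g = J*d,
    Var(g) = (n_x+n_y)/(n_x*n_y) + g^2/(2(n_x+n_y)).

    Outcomes are severity scores, so negative g favors arm X.
    """
    if arm_x.study_id != arm_y.study_id:
        raise ValueError("arms must come from the same study")
    if not (isinstance(arm_x.outcome, ContinuousOutcome)
            and isinstance(arm_y.outcome, ContinuousOutcome)):
        raise TypeError("hedges_g requires continuous outcomes")
    nx, ny = arm_x.n, arm_y.n
    if nx + ny < 3:
        raise ValueError("need n_x + n_y >= 3")
    sx, sy = arm_x.outcome.sd, arm_y.outcome.sd
    df = nx + ny - 2
    sp2 = ((nx - 1) * sx * sx + (ny - 1) * sy * sy) / df
    if sp2 <= 0:
        raise DegenerateDataError(
            f"pooled SD is zero in study {arm_x.study_id}"
        )
    d = (arm_x.outcome.mean - arm_y.outcome.mean) / math.sqrt(sp2)
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    g = j * d
    var = (nx + ny) / (nx * ny) + g * g / (2.0 * (nx + ny))
    return ContrastEstimate(
        study_id=arm_x.study_id,
        comparison=(arm_x.treatment, arm_y.treatment),
        effect=g,
        variance=var,
        scale="smd",
    )


def log_odds_ratio(
    arm_x: ArmRecord, arm_y: ArmRecord, zero_cell_rule: str = "haldane"
) -> ContrastEstimate:
    """Log odds ratio of arm X vs arm Y from the 2x2 table.

    With cells a = events_x, b = n_x - events_x, c = events_y,
    d = n_y - events_y: effect = ln(ad/(bc)), Var = 1/a + 1/b + 1/c + 1/d.
    ``zero_cell_rule="haldane"`` adds 0.5 to all four cells when any is zero.
    Trials with zero (or all) events in both arms stay finite after the
    correction but are flagged ``double_zero`` so classical pooling can drop
    them.
    """
    if arm_x.study_id != arm_y.study_id:
        raise ValueError("arms must come from the same study")
    if not (isinstance(arm_x.outcome, BinaryOutcome)
            and isinstance(arm_y.outcome, BinaryOutcome)):
        raise TypeError("log_odds_ratio requires binary outcomes")
    a = float(arm_x.outcome.events)
    b = float(arm_x.n - arm_x.outcome.events)
    c = float(arm_y.outcome.events)
    d = float(arm_y.n - arm_y.outcome.events)
    double_zero = (a == 0 and c == 0) or (b == 0 and d == 0)
    if min(a, b, c, d) == 0:
        if zero_cell_rule == "haldane":
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        elif zero_cell_rule == "none":
            raise DegenerateDataError(
                f"zero cell in study {arm_x.study_id} with zero_cell_rule='none'"
            )
        else:
            raise ValueError(f"unknown zero_cell_rule {zero_cell_rule!r}")
    effect = math.log(a * d / (b * c))
    var = 1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d
    return ContrastEstimate(
        study_id=arm_x.study_id,
        comparison=(arm_x.treatment, arm_y.treatment),
        effect=effect,
        variance=var,
        scale="log_or",
        double_zero=double_zero,
    )


# ---------------------------------------------------------------------------
# Outcome-scale hierarchy


@dataclass(frozen=True)
class OutcomeHierarchy:
    """Ordered outcome-scale names, highest priority first."""

    scales: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.scales:
            raise ValueError("hierarchy must be non-empty")
        if len(set(self.scales)) != len(self.scales):
            raise ValueError("hierarchy contains duplicate scales")

    def rank(self, scale: str) -> int:
        return self.scales.index(scale)


def default_hierarchy(kind: str) -> OutcomeHierarchy:
    """Shipped pain/function scale hierarchies (editable JSON config)."""
    cfg = json.loads(
        (importlib.resources.files("dosenma") / "data" / "hierarchies.json")
        .read_text()
    )
    if kind not in cfg:
        raise KeyError(f"no default hierarchy for {kind!r}")
    return OutcomeHierarchy(tuple(cfg[kind]))


def select_outcome(candidates: Sequence[tuple[str, object]],
                   hierarchy: OutcomeHierarchy):
    """Pick the candidate whose scale ranks highest in the hierarchy.

    ``candidates`` is a list of (scale name, summary); returns the chosen
    summary.  Deterministic: on equal rank, the first listed wins.
    """
    if not candidates:
        raise ValueError("no candidates supplied")
    ranked = [
        (hierarchy.rank(scale), i)
        for i, (scale, _) in enumerate(candidates)
        if scale in hierarchy.scales
    ]
    if not ranked:
        names = [scale for scale, _ in candidates]
        raise ValueError(
            f"no candidate scale {names} appears in the hierarchy"
        )
    _, best = min(ranked)
    return candidates[best][1]
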