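"""Synthetic three-node trial networks with known truth.

The generator embodies exactly the statistical structure the NMA assumes:
trial-specific effects delta are drawn around the consistency means
d_t - d_baseline with common between-trial SD tau (jointly normal with
covariance tau^2/2 within a three-arm trial), then arm-level summaries are
sampled from the implied sampling distributions — observed means from
Normal(mu_arm, sd^2/n) and observed SDs from the scaled chi-square law for
continuous outcomes; event counts from Binomial(n, inverse-logit(baseline
logit + delta)) with trial-varying baseline logits for adverse events.

The default configuration mirrors the published 24-trial celecoxib network:
two three-arm trials (100 mg BID / 200 mg QD / placebo), five BID-placebo
and seventeen QD-placebo two-arm trials, arm sizes 117-481, with true
vs-placebo effects taken from the published posterior medians
(SMD -0.38 for 200 mg QD, -0.42 for 100 mg BID; GI-AE odds ratios 1.19 and
1.28) and moderate heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit, logit

from .data_model import ArmRecord, BinaryOutcome, ContinuousOutcome

_PAIR_CHOL = np.linalg.cholesky(np.array([[1.0, 0.5], [0.5, 1.0]]))


@dataclass(frozen=True)
class SimConfig:
    """Generative truth for a simulated trial network.

    ``d`` maps treatment id to its true basic parameter (SMD or log-OR
    scale); the reference is implicitly 0.  ``designs`` lists (treatment
    tuple, number of trials); together they must form a connected network.
    """

    d: dict[str, float]
    tau: float
    designs: tuple[tuple[tuple[str, ...], int], ...]
    arm_size_range: tuple[int, int] = (117, 481)
    baseline_mean: float = 60.0  # e.g. 0-100 pain score at follow-up
    baseline_sd: float = 20.0  # common population SD (SMD denominator)
    baseline_event_p: float = 0.25  # mean control-arm AE probability
    baseline_logit_sd: float = 0.3  # between-trial spread of control logits
    reference: str = "PBO"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError("tau must be non-negative")
        if not 0 < self.baseline_event_p < 1:
            raise ValueError("baseline event probability must lie in (0,1)")
        if self.arm_size_range[0] < 2 or self.arm_size_range[0] > self.arm_size_range[1]:
            raise ValueError("invalid arm-size range")
        # connectivity of the design network
        nodes = {self.reference} | set(self.d)
        reached = {self.reference}
        designs = [set(ts) for ts, k in self.designs if k > 0]
        grew = True
        while grew:
            grew = False
            for ts in designs:
                if ts & reached and not ts <= reached:
                    reached |= ts
                    grew = True
        if not nodes <= reached:
            raise ValueError(
                f"designs do not connect treatments {sorted(nodes - reached)}"
            )

    @property
    def n_trials(self) -> int:
        return sum(k for _, k in self.designs)

    @property
    def n_arms(self) -> int:
        return sum(len(ts) * k for ts, k in self.designs)

    def effect(self, treatment: str) -> float:
        if treatment == self.reference:
            return 0.0
        return self.d[treatment]


@dataclass(frozen=True)
class TruthBundle:
    config: SimConfig
    outcome_kind: str
    deltas: dict[str, tuple[float, ...]]  # study -> realized non-baseline deltas
    arms: tuple[ArmRecord, ...]


def default_published_config(outcome_kind: str = "continuous",
                              seed: int = 0) -> SimConfig:
    """24-trial network with the published geometry and effect sizes."""
    designs = (
        (("C100BID", "C200QD", "PBO"), 2),
        (("C100BID", "PBO"), 5),
        (("C200QD", "PBO"), 17),
    )
    if outcome_kind == "continuous":
        d = {"C200QD": -0.38, "C100BID": -0.42}
        tau = 0.15
    elif outcome_kind == "binary":
        d = {"C200QD": float(np.log(1.19)), "C100BID": float(np.log(1.28))}
        tau = 0.1
    else:
        raise ValueError(f"unknown outcome_kind {outcome_kind!r}")
    return SimConfig(d=d, tau=tau, designs=designs, seed=seed)


def _draw_deltas(cfg: SimConfig, treatments: tuple[str, ...],
                 baseline: str, rng: np.random.Generator) -> np.ndarray:
    """Realized trial effects for the non-baseline arms (joint normal)."""
    others = [t for t in treatments if t != baseline]
    mean = np.array([cfg.effect(t) - cfg.effect(baseline) for t in others])
    if cfg.tau == 0:
        return mean
    z = rng.standard_normal(len(others))
    if len(others) == 1:
        return mean + cfg.tau * z
    return mean + cfg.tau * (_PAIR_CHOL @ z)


def simulate_network(cfg: SimConfig, outcome_kind: str) -> TruthBundle:
    """Generate a trial network; bit-identical under the same seed."""
    if outcome_kind not in ("continuous", "binary"):
        raise ValueError(f"unknown outcome_kind {outcome_kind!r}")
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.arm_size_range
    arms: list[ArmRecord] = []
    deltas: dict[str, tuple[float, ...]] = {}
    idx = 0
    for treatments, k in cfg.designs:
        baseline = cfg.reference if cfg.reference in treatments else treatments[0]
        ordered = [baseline] + [t for t in treatments if t != baseline]
        for _ in range(k):
            idx += 1
            study = f"SIM{idx:03d}"
            delta = _draw_deltas(cfg, tuple(ordered), baseline, rng)
            deltas[study] = tuple(float(x) for x in delta)
            ns = rng.integers(lo, hi + 1, size=len(ordered))
            if outcome_kind == "continuous":
                mu_arm = cfg.baseline_mean + np.concatenate(
                    [[0.0], delta]) * cfg.baseline_sd
                for t, n, m in zip(ordered, ns, mu_arm):
                    n = int(n)
                    mean_hat = m + cfg.baseline_sd / np.sqrt(n) * rng.standard_normal()
                    sd_hat = cfg.baseline_sd * np.sqrt(
                        rng.chisquare(n - 1) / (n - 1))
                    arms.append(ArmRecord(
                        study_id=study, treatment=t, n=n,
                        outcome=ContinuousOutcome(mean=float(mean_hat),
                                                  sd=float(sd_hat)),
                    ))
            else:
                base_logit = (logit(cfg.baseline_event_p)
                              + cfg.baseline_logit_sd * rng.standard_normal())
                etas = base_logit + np.concatenate([[0.0], delta])
                for t, n, eta in zip(ordered, ns, etas):
                    n = int(n)
                    events = int(rng.binomial(n, float(expit(eta))))
                    arms.append(ArmRecord(
                        study_id=study, treatment=t, n=n,
                        outcome=BinaryOutcome(events=events),
                    ))
    return TruthBundle(config=cfg, outcome_kind=outcome_kind,
                       deltas=deltas, arms=tuple(arms))


def with_seed(cfg: SimConfig, seed: int) -> SimConfig:
    """Copy of a config with a different seed."""
    return replace(cfg, seed=seed)
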