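"""Bayesian random-effects network meta-analysis with a built-in MCMC sampler.

Model
-----
Treatments enter through basic parameters d_k — the effect of treatment k
relative to the reference (placebo) on the linear-predictor scale — with the
reference fixed at 0.  Every other contrast follows from the consistency
relation d_X - d_Y.  Trial-specific effects delta_ik are exchangeable around
the consistency means with a common (homogeneous) between-trial SD tau; for
a three-arm trial the two deltas are jointly normal with covariance tau^2/2
(equivalently the sequential conditional construction whose k-th arm has
conditional variance tau^2 * k / (2(k-1))).

Binary outcomes use an arm-level binomial likelihood,
events_ik ~ Binomial(n_ik, p_ik) with logit(p_ik) = mu_i + delta_ik and
delta = 0 on the trial's baseline arm.  Continuous outcomes use trial-level
standardized mean differences (Hedges' g) of each arm against the trial
baseline, y_ik ~ N(delta_ik, v_ik), with covariance 1/n_baseline between two
contrasts sharing a baseline arm; d and tau are sampled with the deltas
marginalized out analytically.

Location parameters (d, mu) carry vague Normal(0, 10000) priors; tau is
uniform on (0, upper) with a wide upper bound per outcome scale.  Sampling
is component/block random-walk Metropolis within Gibbs with proposal scales
adapted only during burn-in (frozen afterwards, preserving detailed
balance), three dispersed chains by default, and fully seeded determinism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import (
    ArmRecord,
    BinaryOutcome,
    ContinuousOutcome,
    build_network,
)
from .effect_sizes import hedges_g

_LOG2PI = math.log(2.0 * math.pi)

DEFAULT_TAU_UPPER = {"continuous": 2.0, "binary": 5.0}


@dataclass(frozen=True)
class MCMCConfig:
    """MCMC settings; defaults follow the common three-chain convention."""

    n_chains: int = 3
    n_iter: int = 50_000
    n_burnin: int = 10_000
    base_seed: int = 20150
    adapt_fraction: float = 1.0  # fraction of burn-in during which to adapt

    def __post_init__(self) -> None:
        if self.n_burnin >= self.n_iter:
            raise ValueError("n_burnin must be smaller than n_iter")
        if self.n_chains < 2:
            raise ValueError("need at least two chains")
        if not 0.0 <= self.adapt_fraction <= 1.0:
            raise ValueError("adapt_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class ContinuousBlock:
    study_id: str
    base_idx: int  # treatment index of the baseline arm
    treat_idx: tuple[int, ...]  # non-baseline treatment indices
    y: tuple[float, ...]  # Hedges' g of each non-baseline arm vs baseline
    v: tuple[float, ...]  # sampling variances
    cov: float  # covariance between contrasts sharing the baseline arm


@dataclass(frozen=True)
class BinaryBlock:
    study_id: str
    treat_idx: tuple[int, ...]  # baseline first
    r: tuple[int, ...]
    n: tuple[int, ...]


@dataclass(frozen=True)
class NMAModelSpec:
    outcome_kind: str  # "continuous" | "binary"
    treatments: tuple[str, ...]  # reference first
    reference: str
    blocks: tuple
    prior_variance: float = 1e4
    tau_upper: float = 2.0
    tau_fixed: float | None = None  # pin tau (e.g. 0) for analytic checks

    @property
    def scale(self) -> str:
        return "smd" if self.outcome_kind == "continuous" else "log_or"

    @property
    def n_trials(self) -> int:
        return len(self.blocks)

    @property
    def n_basic_parameters(self) -> int:
        return len(self.treatments) - 1

    @property
    def n_baselines(self) -> int:
        return len(self.blocks) if self.outcome_kind == "binary" else 0

    @property
    def n_datapoints(self) -> int:
        """Likelihood data points: arms for binary, contrasts for continuous."""
        if self.outcome_kind == "binary":
            return sum(len(b.r) for b in self.blocks)
        return sum(len(b.y) for b in self.blocks)


def build_model(
    arms: Sequence[ArmRecord],
    outcome_kind: str,
    reference: str = "PBO",
    tau_upper: float | None = None,
    tau_fixed: float | None = None,
) -> NMAModelSpec:
    """Assemble the NMA model from arm records.

    The trial baseline arm is the reference arm when the trial has one,
    otherwise its first-listed arm.  The network must be connected and
    contain the reference treatment.
    """
    network = build_network(arms, reference=reference)
    if reference not in network.treatments:
        raise ValueError(f"reference treatment {reference!r} absent from network")
    treatments = (reference,) + tuple(
        t for t in network.treatments if t != reference
    )
    t_index = {t: i for i, t in enumerate(treatments)}

    by_study: dict[str, list[ArmRecord]] = {}
    for a in arms:
        by_study.setdefault(a.study_id, []).append(a)

    blocks: list = []
    for study, recs in by_study.items():
        if len(recs) > 3:
            raise ValueError(f"trial {study} has more than three arms")
        base = next((a for a in recs if a.treatment == reference), recs[0])
        others = [a for a in recs if a is not base]
        if outcome_kind == "binary":
            for a in recs:
                if not isinstance(a.outcome, BinaryOutcome):
                    raise TypeError(f"trial {study}: expected binary outcomes")
            ordered = [base] + others
            blocks.append(
                BinaryBlock(
                    study_id=study,
                    treat_idx=tuple(t_index[a.treatment] for a in ordered),
                    r=tuple(a.outcome.events for a in ordered),
                    n=tuple(a.n for a in ordered),
                )
            )
        elif outcome_kind == "continuous":
            for a in recs:
                if not isinstance(a.outcome, ContinuousOutcome):
                    raise TypeError(f"trial {study}: expected continuous outcomes")
            contrasts = [hedges_g(a, base) for a in others]
            blocks.append(
                ContinuousBlock(
                    study_id=study,
                    base_idx=t_index[base.treatment],
                    treat_idx=tuple(t_index[a.treatment] for a in others),
                    y=tuple(c.effect for c in contrasts),
                    v=tuple(c.variance for c in contrasts),
                    cov=1.0 / base.n,
                )
            )
        else:
            raise ValueError(f"unknown outcome_kind {outcome_kind!r}")

    upper = tau_upper if tau_upper is not None else DEFAULT_TAU_UPPER[outcome_kind]
    return NMAModelSpec(
        outcome_kind=outcome_kind,
        treatments=treatments,
        reference=reference,
        blocks=tuple(blocks),
        tau_upper=upper,
        tau_fixed=tau_fixed,
    )


# ---------------------------------------------------------------------------
# Posterior container


@dataclass
class NMAPosterior:
    """MCMC draws with chain structure.

    ``d`` holds basic parameters for ``treatments[1:]`` (the reference is
    identically zero), shape (chains, draws, T-1).  ``mu``/``delta`` are only
    present for the arm-level binomial model.
    """

    treatments: tuple[str, ...]
    reference: str
    scale: str  # "smd" | "log_or"
    d: np.ndarray
    tau: np.ndarray
    trial_ids: tuple[str, ...]
    mu: np.ndarray | None = None
    delta: np.ndarray | None = None
    accept_rates: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.d.shape[0]

    @property
    def n_draws(self) -> int:
        return self.d.shape[1]

    def basic_draws(self) -> np.ndarray:
        """Flattened draws of all basic parameters, reference column included.

        Shape (chains * draws, T); column order matches ``treatments``.
        """
        flat = self.d.reshape(-1, self.d.shape[2])
        zeros = np.zeros((flat.shape[0], 1))
        return np.hstack([zeros, flat])

    def contrast_draws(self, x: str, y: str) -> np.ndarray:
        """Draw-wise effect of X vs Y (d_X - d_Y) on the analysis scale."""
        basics = self.basic_draws()
        ix = self.treatments.index(x)
        iy = self.treatments.index(y)
        return basics[:, ix] - basics[:, iy]

    def contrast_summary(self, x: str, y: str) -> tuple[float, float, float]:
        """(median, 2.5th, 97.5th percentile) of the X-vs-Y contrast."""
        draws = self.contrast_draws(x, y)
        lo, med, hi = np.percentile(draws, [2.5, 50.0, 97.5])
        return float(med), float(lo), float(hi)


def summarize(post: NMAPosterior) -> pd.DataFrame:
    """League table of all ordered pairwise contrasts.

    Columns give the posterior median and 95% credible interval (2.5th and
    97.5th percentiles).  For the log-OR scale the exponentiated columns
    ``or_*`` are added and significance means the CrI excludes 1; on the SMD
    scale it means the CrI excludes 0.
    """
    rows = []
    for x in post.treatments:
        for y in post.treatments:
            if x == y:
                continue
            med, lo, hi = post.contrast_summary(x, y)
            row = {
                "x": x,
                "y": y,
                "median": med,
                "lower": lo,
                "upper": hi,
                "significant": bool(lo > 0 or hi < 0),
            }
            if post.scale == "log_or":
                row.update(
                    or_median=math.exp(med),
                    or_lower=math.exp(lo),
                    or_upper=math.exp(hi),
                )
            rows.append(row)
    return pd.DataFrame(rows)


def consistency_contrast(dx: float, dy: float, scale: str = "smd") -> float:
    """Contrast of X vs Y from the two vs-reference effects.

    On an additive scale (SMD or log-OR) this is dx - dy; on the OR scale it
    is the ratio dx / dy.
    """
    if scale in ("smd", "log_or"):
        return dx - dy
    if scale == "or":
        if dx <= 0 or dy <= 0:
            raise ValueError("odds ratios must be positive")
        return dx / dy
    raise ValueError(f"unknown scale {scale!r}")


def export_draws(post: NMAPosterior) -> pd.DataFrame:
    """Long-format posterior draws: (chain, iter, parameter, value)."""
    frames = []
    names = [f"d_{t}" for t in post.treatments[1:]]
    for c in range(post.n_chains):
        for j, name in enumerate(names):
            frames.append(pd.DataFrame({
                "chain": c,
                "iter": np.arange(post.n_draws),
                "parameter": name,
                "value": post.d[c, :, j],
            }))
        frames.append(pd.DataFrame({
            "chain": c,
            "iter": np.arange(post.n_draws),
            "parameter": "tau",
            "value": post.tau[c],
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Convergence


def gelman_rubin(post: NMAPosterior) -> dict[str, float]:
    """Split-chain potential scale reduction factor per monitored parameter."""
    import arviz as az

    if post.n_chains < 2:
        raise ValueError("R-hat requires at least two chains")
    data = {f"d_{t}": post.d[:, :, j]
            for j, t in enumerate(post.treatments[1:])}
    if np.ptp(post.tau) > 0:  # tau may be pinned (zero variance breaks R-hat)
        data["tau"] = post.tau
    if post.mu is not None:
        for i, sid in enumerate(post.trial_ids):
            data[f"mu_{sid}"] = post.mu[:, :, i]
    ds = az.rhat(az.convert_to_dataset(data))
    return {k: float(ds[k].values) for k in data}


def convergence_warnings(rhat: dict[str, float],
                         threshold: float = 1.05) -> list[str]:
    return [f"{k}: R-hat {v:.3f} > {threshold}"
            for k, v in rhat.items() if v > threshold]


# ---------------------------------------------------------------------------
# Residual deviance


@dataclass(frozen=True)
class DevianceReport:
    D_res: float
    n_datapoints: int
    contributions: dict[str, float]

    @property
    def ratio(self) -> float:
        return self.D_res / self.n_datapoints


def binomial_deviance_points(r: np.ndarray, n: np.ndarray,
                             p_draws: np.ndarray) -> np.ndarray:
    """Posterior-mean binomial deviance contribution per data point.

    dev = 2 [ r ln(r / rhat) + (n - r) ln((n - r)/(n - rhat)) ] with
    rhat = n * p and the convention 0 ln 0 = 0, averaged over draws.
    ``p_draws`` has shape (draws, points).
    """
    r = np.asarray(r, dtype=float)
    n = np.asarray(n, dtype=float)
    rhat = n * p_draws
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(r > 0, r * np.log(r / rhat), 0.0)
        t2 = np.where(n - r > 0, (n - r) * np.log((n - r) / (n - rhat)), 0.0)
    return np.mean(2.0 * (t1 + t2), axis=0)


def normal_deviance_points(y: np.ndarray, v: np.ndarray,
                           theta_draws: np.ndarray) -> np.ndarray:
    """Posterior-mean normal deviance (y - theta)^2 / v per data point."""
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    return np.mean((y - theta_draws) ** 2 / v, axis=0)


def residual_deviance(post: NMAPosterior, spec: NMAModelSpec) -> DevianceReport:
    """Posterior mean residual deviance; close to n_datapoints = adequate fit.

    Binary models contribute one point per arm, evaluated at each draw's
    fitted probabilities.  Continuous (contrast-level) models contribute per
    trial the quadratic form (y - delta)' V^{-1} (y - delta); the deltas are
    integrated out analytically given each (d, tau) draw (Rao-Blackwellized
    over the exact conditional), so the expected contribution of a
    well-fitted trial equals its number of contrasts.
    """
    if spec.outcome_kind == "binary":
        return _residual_deviance_binary(post, spec)
    return _residual_deviance_continuous(post, spec)


def _residual_deviance_binary(post, spec):
    from scipy.special import expit

    assert post.mu is not None and post.delta is not None
    mu = post.mu.reshape(-1, post.mu.shape[2])
    delta = post.delta.reshape(-1, post.delta.shape[2]) if post.delta.size else \
        np.zeros((mu.shape[0], 0))
    labels, r_all, n_all, p_cols = [], [], [], []
    nb_pos = 0
    for i, b in enumerate(spec.blocks):
        for k in range(len(b.r)):
            labels.append(f"{b.study_id}:{spec.treatments[b.treat_idx[k]]}")
            r_all.append(b.r[k])
            n_all.append(b.n[k])
            if k == 0:
                p_cols.append(expit(mu[:, i]))
            else:
                p_cols.append(expit(mu[:, i] + delta[:, nb_pos]))
                nb_pos += 1
    p_draws = np.column_stack(p_cols)
    contrib = binomial_deviance_points(np.array(r_all), np.array(n_all), p_draws)
    return DevianceReport(
        D_res=float(np.sum(contrib)),
        n_datapoints=spec.n_datapoints,
        contributions=dict(zip(labels, contrib.astype(float))),
    )


def _residual_deviance_continuous(post, spec):
    d_flat = post.basic_draws()
    tau = post.tau.reshape(-1)
    tau2 = tau ** 2
    contributions: dict[str, float] = {}
    for b in spec.blocks:
        m = len(b.y)
        delta_mean = np.column_stack(
            [d_flat[:, t] - d_flat[:, b.base_idx] for t in b.treat_idx]
        )  # (N, m)
        y = np.array(b.y)
        if m == 1:
            v = b.v[0]
            with np.errstate(divide="ignore"):
                c_cond = np.where(tau2 > 0, tau2 * v / (tau2 + v), 0.0)
                m_cond = np.where(
                    tau2 > 0,
                    c_cond * (delta_mean[:, 0] / np.where(tau2 > 0, tau2, 1.0)
                              + y[0] / v),
                    delta_mean[:, 0],
                )
            dev = ((y[0] - m_cond) ** 2 + c_cond) / v
            contributions[b.study_id] = float(np.mean(dev))
        else:
            V = np.array([[b.v[0], b.cov], [b.cov, b.v[1]]])
            Vinv = np.linalg.inv(V)
            # prior precision of (delta_1, delta_2): inv(tau2 * [[1,.5],[.5,1]])
            P_inv = (4.0 / 3.0) * np.array([[1.0, -0.5], [-0.5, 1.0]])
            N = d_flat.shape[0]
            dev = np.empty(N)
            resid_fixed = y[None, :] - delta_mean  # used when tau == 0
            nz = tau2 > 0
            if np.any(nz):
                prec = (P_inv[None, :, :] / tau2[nz, None, None]
                        + Vinv[None, :, :])
                cov_cond = np.linalg.inv(prec)
                rhs = (np.einsum("nij,nj->ni",
                                 P_inv[None, :, :] / tau2[nz, None, None],
                                 delta_mean[nz])
                       + (Vinv @ y)[None, :])
                m_cond = np.einsum("nij,nj->ni", cov_cond, rhs)
                resid = y[None, :] - m_cond
                quad = np.einsum("ni,ij,nj->n", resid, Vinv, resid)
                trace = np.einsum("ij,nji->n", Vinv, cov_cond)
                dev[nz] = quad + trace
            if np.any(~nz):
                r0 = resid_fixed[~nz]
                dev[~nz] = np.einsum("ni,ij,nj->n", r0, Vinv, r0)
            contributions[b.study_id] = float(np.mean(dev))
    total = float(sum(contributions.values()))
    return DevianceReport(
        D_res=total,
        n_datapoints=spec.n_datapoints,
        contributions=contributions,
    )


# ---------------------------------------------------------------------------
# Samplers


class _AdaptiveScales:
    """Batch proposal-scale adaptation toward a target acceptance rate."""

    def __init__(self, size, init=0.5, target=0.35, batch=50):
        self.log_s = np.full(size, math.log(init))
        self.target = target
        self.batch = batch
        self.acc = np.zeros(size)
        self.tot = 0

    @property
    def scales(self) -> np.ndarray:
        return np.exp(self.log_s)

    def update(self, accepted: np.ndarray, adapting: bool) -> None:
        self.acc += accepted
        self.tot += 1
        if self.tot >= self.batch:
            if adapting:
                rate = self.acc / self.tot
                self.log_s += np.clip(rate - self.target, -0.5, 0.5)
                self.log_s = np.clip(self.log_s, math.log(1e-4), math.log(50.0))
            self.acc[:] = 0.0
            self.tot = 0


def fit(spec: NMAModelSpec, cfg: MCMCConfig | None = None) -> NMAPosterior:
    """Run the Metropolis-within-Gibbs sampler; deterministic given (spec, cfg)."""
    cfg = cfg or MCMCConfig()
    if spec.outcome_kind == "continuous":
        return _fit_continuous(spec, cfg)
    return _fit_binary(spec, cfg)


_TAU_INITS = (0.05, 0.2, 0.5)


def _fit_continuous(spec: NMAModelSpec, cfg: MCMCConfig) -> NMAPosterior:
    T = len(spec.treatments)
    two = [b for b in spec.blocks if len(b.y) == 1]
    three = [b for b in spec.blocks if len(b.y) == 2]
    y2 = np.array([b.y[0] for b in two])
    v2 = np.array([b.v[0] for b in two])
    t2 = np.array([b.treat_idx[0] for b in two], dtype=int)
    b2 = np.array([b.base_idx for b in two], dtype=int)
    if three:
        y3 = np.array([b.y for b in three])
        v3a = np.array([b.v[0] for b in three])
        v3b = np.array([b.v[1] for b in three])
        c3 = np.array([b.cov for b in three])
        t3 = np.array([b.treat_idx for b in three], dtype=int)
        b3 = np.array([b.base_idx for b in three], dtype=int)

    prior_var = spec.prior_variance
    tau_fixed = spec.tau_fixed

    def loglik(dfull: np.ndarray, tau: float) -> float:
        tau2 = tau * tau
        ll = 0.0
        if y2.size:
            mvar = v2 + tau2
            resid = y2 - (dfull[t2] - dfull[b2])
            ll += float(-0.5 * np.sum(np.log(2 * np.pi * mvar)
                                      + resid * resid / mvar))
        if three:
            m00 = v3a + tau2
            m11 = v3b + tau2
            m01 = c3 + 0.5 * tau2
            det = m00 * m11 - m01 * m01
            r0 = y3[:, 0] - (dfull[t3[:, 0]] - dfull[b3])
            r1 = y3[:, 1] - (dfull[t3[:, 1]] - dfull[b3])
            quad = (m11 * r0 * r0 - 2 * m01 * r0 * r1 + m00 * r1 * r1) / det
            ll += float(np.sum(-_LOG2PI - 0.5 * np.log(det) - 0.5 * quad))
        return ll

    n_keep = cfg.n_iter - cfg.n_burnin
    d_out = np.empty((cfg.n_chains, n_keep, T - 1))
    tau_out = np.empty((cfg.n_chains, n_keep))
    acc_rates = {}

    adapt_until = int(cfg.n_burnin * cfg.adapt_fraction)
    for c in range(cfg.n_chains):
        rng = np.random.default_rng(cfg.base_seed + c)
        d = np.zeros(T)
        d[1:] = ((c % 3) - 1) * 0.5
        tau = tau_fixed if tau_fixed is not None else _TAU_INITS[c % 3]
        lam = math.log(tau) if tau > 0 else 0.0
        cur_ll = loglik(d, tau)
        if not np.isfinite(cur_ll):
            raise RuntimeError("non-finite likelihood at initialization")
        sc_d = _AdaptiveScales(T - 1, init=0.3)
        sc_t = _AdaptiveScales(1, init=0.5)
        n_acc = np.zeros(T - 1)
        n_acc_t = 0
        for it in range(cfg.n_iter):
            adapting = it < adapt_until
            acc_d = np.zeros(T - 1)
            scales = sc_d.scales
            for k in range(1, T):
                old = d[k]
                d[k] = old + scales[k - 1] * rng.normal()
                new_ll = loglik(d, tau)
                dlp = (new_ll - cur_ll
                       - 0.5 * (d[k] ** 2 - old ** 2) / prior_var)
                if math.log(rng.random()) < dlp:
                    cur_ll = new_ll
                    acc_d[k - 1] = 1.0
                else:
                    d[k] = old
            sc_d.update(acc_d, adapting)
            if tau_fixed is None:
                lam_new = lam + sc_t.scales[0] * rng.normal()
                tau_new = math.exp(lam_new)
                u = rng.random()
                acc_t = 0.0
                if tau_new < spec.tau_upper:
                    new_ll = loglik(d, tau_new)
                    # uniform prior on tau + log-scale proposal Jacobian
                    dlp = new_ll - cur_ll + (lam_new - lam)
                    if math.log(u) < dlp:
                        cur_ll = new_ll
                        tau, lam = tau_new, lam_new
                        acc_t = 1.0
                sc_t.update(np.array([acc_t]), adapting)
            if it >= cfg.n_burnin:
                j = it - cfg.n_burnin
                d_out[c, j] = d[1:]
                tau_out[c, j] = tau
                n_acc += acc_d
                n_acc_t += 0  # bookkeeping only during burn-in batches
        acc_rates[f"chain{c}_d"] = list(np.round(n_acc / n_keep, 3))

    return NMAPosterior(
        treatments=spec.treatments,
        reference=spec.reference,
        scale="smd",
        d=d_out,
        tau=tau_out,
        trial_ids=tuple(b.study_id for b in spec.blocks),
        accept_rates=acc_rates,
    )


def _fit_binary(spec: NMAModelSpec, cfg: MCMCConfig) -> NMAPosterior:
    T = len(spec.treatments)
    n_trials = len(spec.blocks)
    b_r = np.array([b.r[0] for b in spec.blocks], dtype=float)
    b_n = np.array([b.n[0] for b in spec.blocks], dtype=float)

    nb_trial, nb_t, nb_r, nb_n = [], [], [], []
    base_t = np.array([b.treat_idx[0] for b in spec.blocks], dtype=int)
    for i, b in enumerate(spec.blocks):
        for k in range(1, len(b.r)):
            nb_trial.append(i)
            nb_t.append(b.treat_idx[k])
            nb_r.append(float(b.r[k]))
            nb_n.append(float(b.n[k]))
    nb_trial = np.array(nb_trial, dtype=int)
    nb_t = np.array(nb_t, dtype=int)
    nb_r = np.array(nb_r)
    nb_n = np.array(nb_n)
    n_nb = nb_trial.size

    # positions of single-delta trials and (paired) three-arm trials
    m_per_trial = np.bincount(nb_trial, minlength=n_trials)
    single_pos = np.array(
        [j for j in range(n_nb) if m_per_trial[nb_trial[j]] == 1], dtype=int)
    pair_trials = np.array(
        [i for i in range(n_trials) if m_per_trial[i] == 2], dtype=int)
    pair_pos = np.array(
        [[j for j in range(n_nb) if nb_trial[j] == i] for i in pair_trials],
        dtype=int).reshape(-1, 2)
    single_trials = nb_trial[single_pos]

    prior_var = spec.prior_variance
    tau_fixed = spec.tau_fixed

    def arm_ll(eta: np.ndarray, r: np.ndarray, n: np.ndarray) -> np.ndarray:
        return r * eta - n * np.logaddexp(0.0, eta)

    def delta_prior_by_trial(delta, dfull, tau):
        """Log prior density of each trial's delta block, as (n_trials,) array."""
        tau2 = tau * tau
        out = np.zeros(n_trials)
        mean = dfull[nb_t] - dfull[base_t[nb_trial]]
        resid = delta - mean
        if single_pos.size:
            rs = resid[single_pos]
            out[single_trials] = -0.5 * (math.log(2 * math.pi * tau2)
                                         + rs * rs / tau2)
        if pair_pos.size:
            r0 = resid[pair_pos[:, 0]]
            r1 = resid[pair_pos[:, 1]]
            quad = (4.0 / (3.0 * tau2)) * (r0 * r0 - r0 * r1 + r1 * r1)
            logdet = math.log(0.75) + 4.0 * math.log(tau)
            out[pair_trials] = -_LOG2PI - 0.5 * logdet - 0.5 * quad
        return out

    n_keep = cfg.n_iter - cfg.n_burnin
    d_out = np.empty((cfg.n_chains, n_keep, T - 1))
    tau_out = np.empty((cfg.n_chains, n_keep))
    mu_out = np.empty((cfg.n_chains, n_keep, n_trials))
    delta_out = np.empty((cfg.n_chains, n_keep, n_nb))
    adapt_until = int(cfg.n_burnin * cfg.adapt_fraction)

    emp_mu = np.log((b_r + 0.5) / (b_n - b_r + 0.5))
    emp_delta = (np.log((nb_r + 0.5) / (nb_n - nb_r + 0.5))
                 - emp_mu[nb_trial])

    for c in range(cfg.n_chains):
        rng = np.random.default_rng(cfg.base_seed + c)
        mu = emp_mu.copy()
        delta = emp_delta.copy()
        d = np.zeros(T)
        d[1:] = ((c % 3) - 1) * 0.5
        tau = tau_fixed if tau_fixed is not None else _TAU_INITS[c % 3]
        lam = math.log(tau) if tau > 0 else 0.0

        ll_base = arm_ll(mu, b_r, b_n)
        ll_nb = arm_ll(mu[nb_trial] + delta, nb_r, nb_n)
        lp_delta = delta_prior_by_trial(delta, d, tau)
        if not (np.all(np.isfinite(ll_base)) and np.all(np.isfinite(ll_nb))
                and np.all(np.isfinite(lp_delta))):
            raise RuntimeError("non-finite likelihood at initialization")

        sc_mu = _AdaptiveScales(n_trials, init=0.3)
        sc_de = _AdaptiveScales(n_trials, init=0.3)
        sc_d = _AdaptiveScales(T - 1, init=0.2)
        sc_t = _AdaptiveScales(1, init=0.5)

        for it in range(cfg.n_iter):
            adapting = it < adapt_until

            # -- baselines mu (conditionally independent across trials)
            prop = mu + sc_mu.scales * rng.normal(size=n_trials)
            d_ll = arm_ll(prop, b_r, b_n) - ll_base
            nb_new = arm_ll(prop[nb_trial] + delta, nb_r, nb_n)
            d_ll += np.bincount(nb_trial, weights=nb_new - ll_nb,
                                minlength=n_trials)
            d_ll += -0.5 * (prop ** 2 - mu ** 2) / prior_var
            acc = np.log(rng.random(n_trials)) < d_ll
            mu = np.where(acc, prop, mu)
            ll_base = arm_ll(mu, b_r, b_n)
            ll_nb = np.where(acc[nb_trial], nb_new, ll_nb)
            sc_mu.update(acc.astype(float), adapting)

            # -- trial effects delta (block per trial)
            if n_nb:
                prop_de = delta + sc_de.scales[nb_trial] * rng.normal(size=n_nb)
                nb_new = arm_ll(mu[nb_trial] + prop_de, nb_r, nb_n)
                d_ll = np.bincount(nb_trial, weights=nb_new - ll_nb,
                                   minlength=n_trials)
                lp_new = delta_prior_by_trial(prop_de, d, tau)
                d_ll += lp_new - lp_delta
                acc = np.log(rng.random(n_trials)) < d_ll
                delta = np.where(acc[nb_trial], prop_de, delta)
                ll_nb = np.where(acc[nb_trial], nb_new, ll_nb)
                lp_delta = np.where(acc, lp_new, lp_delta)
                sc_de.update(acc.astype(float), adapting)

            # -- basic parameters d
            acc_d = np.zeros(T - 1)
            scales = sc_d.scales
            for k in range(1, T):
                old = d[k]
                d[k] = old + scales[k - 1] * rng.normal()
                lp_new = delta_prior_by_trial(delta, d, tau)
                dlp = (float(np.sum(lp_new - lp_delta))
                       - 0.5 * (d[k] ** 2 - old ** 2) / prior_var)
                if math.log(rng.random()) < dlp:
                    lp_delta = lp_new
                    acc_d[k - 1] = 1.0
                else:
                    d[k] = old
            sc_d.update(acc_d, adapting)

            # -- heterogeneity tau (log-scale walk, uniform prior)
            if tau_fixed is None:
                lam_new = lam + sc_t.scales[0] * rng.normal()
                tau_new = math.exp(lam_new)
                u = rng.random()
                acc_t = 0.0
                if tau_new < spec.tau_upper:
                    lp_new = delta_prior_by_trial(delta, d, tau_new)
                    dlp = float(np.sum(lp_new - lp_delta)) + (lam_new - lam)
                    if math.log(u) < dlp:
                        lp_delta = lp_new
                        tau, lam = tau_new, lam_new
                        acc_t = 1.0
                sc_t.update(np.array([acc_t]), adapting)

            if it >= cfg.n_burnin:
                j = it - cfg.n_burnin
                d_out[c, j] = d[1:]
                tau_out[c, j] = tau
                mu_out[c, j] = mu
                delta_out[c, j] = delta

    return NMAPosterior(
        treatments=spec.treatments,
        reference=spec.reference,
        scale="log_or",
        d=d_out,
        tau=tau_out,
        trial_ids=tuple(b.study_id for b in spec.blocks),
        mu=mu_out,
        delta=delta_out,
    )
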