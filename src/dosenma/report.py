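"""Publication-style combined reports: one row per outcome.

For each outcome dataset the report runs the Bayesian NMA (league-table
medians and credible intervals), classical DerSimonian–Laird pairwise
meta-analysis with I^2 and Begg's test per direct comparison, the Bucher
direct-vs-indirect loop check, SUCRA/P(best) rankings, and the residual
deviance fit diagnostic — the layout of a combined NMA/pairwise results
table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .data_model import ArmRecord, BinaryOutcome, ContinuousOutcome
from .effect_sizes import ContrastEstimate, hedges_g, log_odds_ratio
from .inconsistency import bucher_indirect, loop_ror
from .nma import (
    MCMCConfig,
    build_model,
    fit,
    gelman_rubin,
    residual_deviance,
    summarize,
)
from .pairwise import beggs_test, dl_pool
from .ranking import rank_probabilities


@dataclass(frozen=True)
class OutcomeDataset:
    """One analyzable outcome: arm records plus analysis direction."""

    name: str
    arms: tuple[ArmRecord, ...]
    outcome_kind: str  # "continuous" | "binary"
    direction: str = "lower_is_better"


def edge_contrasts(
    arms: Sequence[ArmRecord], x: str, y: str, drop_double_zero: bool = True
) -> list[ContrastEstimate]:
    """Per-study X-vs-Y contrasts for every trial containing both arms.

    Double-zero binary trials are dropped from classical pooling by
    default (they carry no information about the odds ratio).
    """
    by_study: dict[str, dict[str, ArmRecord]] = {}
    for a in arms:
        by_study.setdefault(a.study_id, {})[a.treatment] = a
    out: list[ContrastEstimate] = []
    for study in by_study:
        arms_here = by_study[study]
        if x in arms_here and y in arms_here:
            ax, ay = arms_here[x], arms_here[y]
            if isinstance(ax.outcome, ContinuousOutcome):
                out.append(hedges_g(ax, ay))
            elif isinstance(ax.outcome, BinaryOutcome):
                est = log_odds_ratio(ax, ay)
                if est.double_zero and drop_double_zero:
                    continue
                out.append(est)
    return out


def analyze_outcome(
    ds: OutcomeDataset,
    cfg: MCMCConfig | None = None,
    reference: str = "PBO",
    rank_tie_seed: int = 0,
) -> dict:
    """Full analysis of one outcome; returns a nested result dictionary."""
    cfg = cfg or MCMCConfig()
    spec = build_model(ds.arms, ds.outcome_kind, reference=reference)
    post = fit(spec, cfg)
    league = summarize(post)
    rhat = gelman_rubin(post)
    dev = residual_deviance(post, spec)
    ranks = rank_probabilities(post, direction=ds.direction,
                               tie_seed=rank_tie_seed)

    comparisons = []
    non_ref = [t for t in spec.treatments if t != reference]
    for t in non_ref:
        comparisons.append((t, reference))
    for i in range(len(non_ref)):
        for j in range(i + 1, len(non_ref)):
            comparisons.append((non_ref[i], non_ref[j]))

    per_comparison = {}
    for x, y in comparisons:
        med, lo, hi = post.contrast_summary(x, y)
        entry = {"nma_median": med, "nma_lower": lo, "nma_upper": hi}
        direct = edge_contrasts(ds.arms, x, y)
        if direct:
            pooled = dl_pool(direct)
            begg = beggs_test(direct)
            entry.update(
                k_direct=pooled.k,
                pm_pooled=pooled.pooled_effect,
                pm_lower=pooled.ci95[0],
                pm_upper=pooled.ci95[1],
                I2=pooled.I2,
                p_Q=pooled.p_Q,
                begg_p=begg.p,
            )
        else:
            entry.update(k_direct=0)
        per_comparison[f"{x} vs {y}"] = entry

    # Bucher loop check on the (x, y, reference) triangle(s)
    loops = {}
    for i in range(len(non_ref)):
        for j in range(i + 1, len(non_ref)):
            res = loop_check(ds.arms, non_ref[i], non_ref[j], reference)
            if res is not None:
                loops[f"{non_ref[i]}-{non_ref[j]}-{reference}"] = res

    return {
        "outcome": ds.name,
        "outcome_kind": ds.outcome_kind,
        "scale": spec.scale,
        "comparisons": per_comparison,
        "loops": {
            name: {
                "discrepancy": L.discrepancy,
                "ror": L.ror if L.scale == "log_or" else float("nan"),
                "z": L.z,
                "p": L.p,
                "significant": L.significant,
            }
            for name, L in loops.items()
        },
        "ranking": ranks.as_dict(),
        "D_res": dev.D_res,
        "n_datapoints": dev.n_datapoints,
        "deviance_ratio": dev.ratio,
        "max_rhat": max(rhat.values()),
        "league": league,
        "posterior": post,
        "spec": spec,
    }


def loop_check(arms: Sequence[ArmRecord], x: str, y: str, ref: str):
    """Bucher loop inconsistency for the (x, y, ref) triangle, if closed."""
    direct = edge_contrasts(arms, x, y)
    ax = edge_contrasts(arms, x, ref)
    ay = edge_contrasts(arms, y, ref)
    if not (direct and ax and ay):
        return None
    pooled_direct = dl_pool(direct)
    pooled_ax = dl_pool(ax)
    pooled_ay = dl_pool(ay)
    scale = pooled_direct.scale

    def _as_contrast(pooled, comparison):
        return ContrastEstimate(
            study_id="pooled", comparison=comparison,
            effect=pooled.pooled_effect, variance=pooled.variance, scale=scale,
        )

    indirect = bucher_indirect(_as_contrast(pooled_ax, (x, ref)),
                               _as_contrast(pooled_ay, (y, ref)))
    return loop_ror(_as_contrast(pooled_direct, (x, y)), indirect)


def report_table(results: Sequence[dict]) -> pd.DataFrame:
    """Flatten analyze_outcome results into a one-row-per-outcome table."""
    rows = []
    for res in results:
        row: dict = {"outcome": res["outcome"], "scale": res["scale"]}
        ratio = res["scale"] == "log_or"
        for comp, entry in res["comparisons"].items():
            tag = comp.replace(" ", "")
            med, lo, hi = (entry["nma_median"], entry["nma_lower"],
                           entry["nma_upper"])
            if ratio:
                med, lo, hi = math.exp(med), math.exp(lo), math.exp(hi)
            row[f"NM {tag}"] = f"{med:.2f} ({lo:.2f}, {hi:.2f})"
            if entry.get("k_direct", 0) > 0:
                pm, plo, phi = (entry["pm_pooled"], entry["pm_lower"],
                                entry["pm_upper"])
                if ratio:
                    pm, plo, phi = math.exp(pm), math.exp(plo), math.exp(phi)
                row[f"PM {tag}"] = f"{pm:.2f} ({plo:.2f}, {phi:.2f})"
                row[f"I2 {tag}"] = f"{entry['I2']:.0f}%"
                row[f"PB {tag}"] = f"{entry['begg_p']:.2f}"
            else:
                row[f"PM {tag}"] = "-"
                row[f"I2 {tag}"] = "-"
                row[f"PB {tag}"] = "-"
        for name, L in res["loops"].items():
            row[f"loop {name} p"] = f"{L['p']:.2f}"
        row["D_res/n"] = f"{res['D_res']:.1f}/{res['n_datapoints']}"
        row["max R-hat"] = f"{res['max_rhat']:.3f}"
        for t, r in res["ranking"].items():
            row[f"SUCRA {t}"] = f"{r['sucra']:.0f}%"
            row[f"P(best) {t}"] = f"{r['p_best']:.2f}"
        rows.append(row)
    return pd.DataFrame(rows)
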