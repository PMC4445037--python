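"""Fit the Bayesian random-effects NMA to the simulated pain and GI-AE
networks: league tables, SUCRA rankings, convergence and fit diagnostics.

Run analysis/02_simulate_trials.py first.  Uses 3 chains x 20000 draws
(4000 burn-in) per outcome; writes league tables and a summary JSON to
results/.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from dosenma.data_model import read_arm_data
from dosenma.nma import (
    MCMCConfig,
    build_model,
    convergence_warnings,
    fit,
    gelman_rubin,
    residual_deviance,
    summarize,
)
from dosenma.ranking import rank_probabilities

OUT = Path(__file__).resolve().parents[1] / "results"

OUTCOMES = (
    ("pain", "continuous", "lower_is_better"),
    ("gi_ae", "binary", "lower_is_better"),
)


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=20150)
    parser.add_argument("--iters", type=int, default=20000)
    parser.add_argument("--burnin", type=int, default=4000)
    args = parser.parse_args()
    cfg = MCMCConfig(n_chains=3, n_iter=args.iters, n_burnin=args.burnin,
                     base_seed=args.seed)

    summary = {}
    for label, kind, direction in OUTCOMES:
        arms = read_arm_data(OUT / f"sim_{label}_arms.csv", kind)
        spec = build_model(arms, kind)
        post = fit(spec, cfg)
        league = summarize(post)
        league.to_csv(OUT / f"nma_league_{label}.csv", index=False)
        rhat = gelman_rubin(post)
        dev = residual_deviance(post, spec)
        ranks = rank_probabilities(post, direction)

        print(f"== {label} ({kind}) ==")
        vs_ref = league[(league.y == "PBO")]
        for _, row in vs_ref.iterrows():
            if post.scale == "log_or":
                print(f"  {row.x} vs PBO: OR {row.or_median:.2f} "
                      f"({row.or_lower:.2f}, {row.or_upper:.2f})")
            else:
                print(f"  {row.x} vs PBO: SMD {row['median']:.2f} "
                      f"({row.lower:.2f}, {row.upper:.2f})")
        for i, t in enumerate(ranks.treatments):
            print(f"  SUCRA {t}: {ranks.sucra[i]:.0f}%  "
                  f"P(best) {ranks.p_best[i]:.2f}")
        print(f"  residual deviance {dev.D_res:.1f} on {dev.n_datapoints} points"
              f"; tau median {float(np.median(post.tau)):.3f}"
              f"; max R-hat {max(rhat.values()):.3f}")
        warnings = convergence_warnings(rhat)
        for w in warnings:
            print(f"  warning: {w}")

        summary[label] = {
            "tau_median": float(np.median(post.tau)),
            "D_res": dev.D_res,
            "n_datapoints": dev.n_datapoints,
            "max_rhat": max(rhat.values()),
            "rhat_warnings": warnings,
            "sucra": ranks.as_dict(),
        }
    (OUT / "nma_summary.json").write_text(json.dumps(summary, indent=2))
    print(f"wrote {OUT / 'nma_summary.json'}")


if __name__ == "__main__":
    main()
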