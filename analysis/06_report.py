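"""Combined publication-style table: NMA and pairwise estimates, I^2,
Begg's p, loop consistency, rankings and fit diagnostics — one row per
outcome.

Run analysis/02_simulate_trials.py first.  Writes results/combined_report.csv.
"""

import argparse
from pathlib import Path

from dosenma.data_model import read_arm_data
from dosenma.nma import MCMCConfig
from dosenma.report import OutcomeDataset, analyze_outcome, report_table

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=20150)
    parser.add_argument("--iters", type=int, default=20000)
    parser.add_argument("--burnin", type=int, default=4000)
    args = parser.parse_args()
    cfg = MCMCConfig(n_chains=3, n_iter=args.iters, n_burnin=args.burnin,
                     base_seed=args.seed)

    results = []
    for label, kind in (("pain", "continuous"), ("gi_ae", "binary")):
        arms = tuple(read_arm_data(OUT / f"sim_{label}_arms.csv", kind))
        ds = OutcomeDataset(name=label, arms=arms, outcome_kind=kind,
                            direction="lower_is_better")
        results.append(analyze_outcome(ds, cfg))
    table = report_table(results)
    table.to_csv(OUT / "combined_report.csv", index=False)
    with_cols = table[[c for c in table.columns
                       if c.startswith(("outcome", "NM", "D_res", "SUCRA"))]]
    print(with_cols.to_string(index=False))
    print(f"wrote {OUT / 'combined_report.csv'}")


if __name__ == "__main__":
    main()
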