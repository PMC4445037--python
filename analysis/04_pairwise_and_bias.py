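"""Classical pairwise meta-analysis of every direct comparison in the
simulated networks: DerSimonian-Laird pooling, Q / I^2 heterogeneity, and
Begg's publication-bias test.

Run analysis/02_simulate_trials.py first.  Writes results/pairwise.csv.
"""

import math
from itertools import combinations
from pathlib import Path

import pandas as pd

from dosenma.data_model import read_arm_data
from dosenma.pairwise import beggs_test, dl_pool
from dosenma.report import edge_contrasts

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    rows = []
    for label, kind in (("pain", "continuous"), ("gi_ae", "binary")):
        arms = read_arm_data(OUT / f"sim_{label}_arms.csv", kind)
        treatments = sorted({a.treatment for a in arms})
        for x, y in combinations(treatments, 2):
            ests = edge_contrasts(arms, x, y)
            if not ests:
                continue
            pooled = dl_pool(ests)
            begg = beggs_test(ests)
            disp = (math.exp(pooled.pooled_effect) if kind == "binary"
                    else pooled.pooled_effect)
            rows.append({
                "outcome": label, "comparison": f"{x} vs {y}",
                "k": pooled.k, "pooled": round(disp, 3),
                "tau2": round(pooled.tau2, 4),
                "Q": round(pooled.Q, 2), "p_Q": round(pooled.p_Q, 3),
                "I2_pct": round(pooled.I2, 1),
                "begg_p": round(begg.p, 3),
                "begg_applicable": not begg.insufficient,
            })
            print(f"{label} {x} vs {y}: k={pooled.k} pooled={disp:.3f} "
                  f"I2={pooled.I2:.0f}% Begg p={begg.p:.2f}")
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "pairwise.csv", index=False)
    print(f"wrote {OUT / 'pairwise.csv'}")


if __name__ == "__main__":
    main()
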