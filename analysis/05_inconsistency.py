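"""Direct-vs-indirect (Bucher) consistency check of the closed
QD-BID-placebo loop in each simulated network.

Run analysis/02_simulate_trials.py first.  Writes results/inconsistency.csv.
"""

from pathlib import Path

import pandas as pd

from dosenma.data_model import read_arm_data
from dosenma.report import loop_check

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    rows = []
    for label, kind in (("pain", "continuous"), ("gi_ae", "binary")):
        arms = read_arm_data(OUT / f"sim_{label}_arms.csv", kind)
        res = loop_check(arms, "C200QD", "C100BID", "PBO")
        if res is None:
            print(f"{label}: no closed loop")
            continue
        row = {"outcome": label,
               "loop": "C200QD-C100BID-PBO",
               "direct": round(res.direct_effect, 4),
               "indirect": round(res.indirect_effect, 4),
               "discrepancy": round(res.discrepancy, 4),
               "z": round(res.z, 3), "p": round(res.p, 3),
               "significant": res.significant}
        if res.scale == "log_or":
            row["RoR"] = round(res.ror, 3)
            lo, hi = res.ror_ci95
            row["RoR_ci95"] = f"({lo:.3f}, {hi:.3f})"
            print(f"{label}: RoR {res.ror:.3f} ({lo:.3f}, {hi:.3f}), "
                  f"p={res.p:.2f}, significant={res.significant}")
        else:
            print(f"{label}: |direct-indirect| {res.discrepancy:.3f}, "
                  f"p={res.p:.2f}, significant={res.significant}")
        rows.append(row)
    pd.DataFrame(rows).to_csv(OUT / "inconsistency.csv", index=False)
    print(f"wrote {OUT / 'inconsistency.csv'}")


if __name__ == "__main__":
    main()
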