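"""Describe the 24-RCT celecoxib network: counts, patients, edge structure.

Reads the packaged trial-characteristics table and writes descriptive
totals and the treatment-network geometry to results/.
"""

import json
from pathlib import Path

from dosenma.data_model import fixture_counts, load_table1, table1_network

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    trials = load_table1()
    summary = fixture_counts(trials)
    net = table1_network(trials)

    print(f"{summary.n_trials} RCTs, {summary.n_arms} arms, "
          f"{summary.total_patients} patients")
    for t, n in sorted(summary.patients_by_treatment.items()):
        print(f"  {t}: {n} patients")
    for loc, n in sorted(summary.trials_by_location.items()):
        print(f"  {loc}: {n} trials")
    print("direct-comparison edges (trials):")
    for (a, b), k in net.edges:
        print(f"  {a} - {b}: {k}")

    OUT.mkdir(exist_ok=True)
    payload = {
        "n_trials": summary.n_trials,
        "n_arms": summary.n_arms,
        "patients_by_treatment": summary.patients_by_treatment,
        "total_patients": summary.total_patients,
        "trials_by_location": summary.trials_by_location,
        "edges": {f"{a}-{b}": k for (a, b), k in net.edges},
    }
    (OUT / "network_overview.json").write_text(json.dumps(payload, indent=2))
    print(f"wrote {OUT / 'network_overview.json'}")


if __name__ == "__main__":
    main()
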