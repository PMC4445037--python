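"""Domain types and arm-level I/O for a three-node osteoarthritis trial network.

The package models randomized trials comparing up to three treatments —
placebo (``PBO``), celecoxib 200 mg once daily (``C200QD``) and celecoxib
100 mg twice daily (``C100BID``) — with arm-level summaries: sample size plus
either a continuous outcome (mean, SD of a pain/function score) or a binary
adverse-event count.  Trials are held in long format, one row per arm; a
three-arm trial is three rows sharing a ``study_id``.

A packaged fixture digitizes the published characteristics table of the 24
celecoxib RCTs (per-arm sample sizes, OA location, follow-up schedule,
methodological quality on the 0–7 modified Oxford scale).  One printed row
("Lisse 2001") is a pooled report of three RCTs; the fixture stores it exactly
as printed with a ``combined_from`` multiplicity flag, and counting operations
expand that flag.
"""

from __future__ import annotations

import importlib.resources
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import pandas as pd

REFERENCE_ID = "PBO"


class DataValidationError(ValueError):
    """Raised when arm-level input data violate a structural constraint."""


class DisconnectedNetworkError(ValueError):
    """Raised when the trial network does not connect to the reference."""


@dataclass(frozen=True)
class Treatment:
    id: str
    label: str


DEFAULT_TREATMENTS = (
    Treatment("PBO", "placebo"),
    Treatment("C200QD", "celecoxib 200 mg once daily"),
    Treatment("C100BID", "celecoxib 100 mg twice daily"),
)


@dataclass(frozen=True)
class ContinuousOutcome:
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise DataValidationError(f"sd must be positive, got {self.sd}")


@dataclass(frozen=True)
class BinaryOutcome:
    events: int


Outcome = Union[ContinuousOutcome, BinaryOutcome]


@dataclass(frozen=True)
class ArmRecord:
    """One treatment arm of one trial."""

    study_id: str
    treatment: str
    n: int
    outcome: Outcome

    def __post_init__(self) -> None:
        if self.n < 1:
            raise DataValidationError(
                f"n must be >= 1 in study {self.study_id}, got {self.n}"
            )
        if isinstance(self.outcome, BinaryOutcome):
            ev = self.outcome.events
            if not 0 <= ev <= self.n:
                raise DataValidationError(
                    f"events must lie in [0, n] in study {self.study_id}: "
                    f"events={ev}, n={self.n}"
                )


@dataclass(frozen=True)
class TrialMeta:
    """Descriptive row of the packaged trial-characteristics fixture."""

    study_id: str
    label: str
    location: str  # knee | hip | knee_or_hip
    treatments: tuple[str, ...]
    arm_sizes: tuple[int, ...]
    female_pct: tuple[float, ...]
    mean_ages: tuple[float, ...]
    duration_weeks: float
    followup_weeks: tuple[float, ...]
    quality_score: int
    combined_from: int = 1  # >1 when the printed row pools several RCTs

    def __post_init__(self) -> None:
        if len(self.treatments) not in (2, 3):
            raise DataValidationError(
                f"{self.study_id}: arm count must be 2 or 3"
            )
        if not 0 <= self.quality_score <= 7:
            raise DataValidationError(
                f"{self.study_id}: quality score outside 0-7"
            )
        if len(self.arm_sizes) != len(self.treatments):
            raise DataValidationError(
                f"{self.study_id}: arm_sizes/treatments length mismatch"
            )


@dataclass(frozen=True)
class Network:
    """Treatment network: nodes, per-trial arm sets, edges with trial counts."""

    treatments: tuple[str, ...]
    trials: tuple[tuple[str, tuple[str, ...]], ...]  # (study_id, arm treatments)
    edges: tuple[tuple[tuple[str, str], int], ...]  # ((a, b) sorted, n_trials)
    reference: str

    def edge_counts(self) -> dict[frozenset, int]:
        return {frozenset(pair): k for pair, k in self.edges}


@dataclass(frozen=True)
class FixtureSummary:
    n_trials: int
    n_arms: int
    patients_by_treatment: dict[str, int]
    total_patients: int
    trials_by_location: dict[str, int]


# ---------------------------------------------------------------------------
# Arm-level CSV I/O

_CONT_COLS = ["study", "treatment", "n", "mean", "sd"]
_BIN_COLS = ["study", "treatment", "n", "events"]


def read_arm_data(path, outcome_kind: str) -> list[ArmRecord]:
    """Read arm-level records from CSV (one row per arm, header mandatory).

    Continuous columns: study,treatment,n,mean,sd.
    Binary columns: study,treatment,n,events.
    Row order is preserved; validation errors name the offending 1-based
    data row.
    """
    if outcome_kind not in ("continuous", "binary"):
        raise ValueError(f"unknown outcome_kind {outcome_kind!r}")
    cols = _CONT_COLS if outcome_kind == "continuous" else _BIN_COLS
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DataValidationError(f"missing column(s): {', '.join(missing)}")

    records: list[ArmRecord] = []
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            n = int(getattr(row, "n"))
            if outcome_kind == "continuous":
                outcome: Outcome = ContinuousOutcome(
                    mean=float(getattr(row, "mean")), sd=float(getattr(row, "sd"))
                )
            else:
                outcome = BinaryOutcome(events=int(getattr(row, "events")))
            rec = ArmRecord(
                study_id=str(getattr(row, "study")),
                treatment=str(getattr(row, "treatment")),
                n=n,
                outcome=outcome,
            )
        except DataValidationError as exc:
            if isinstance(getattr(row, "events", None), (int, float)) and \
                    outcome_kind == "binary" and \
                    float(getattr(row, "events")) > float(getattr(row, "n")):
                raise DataValidationError(f"events exceed n at row {i}") from exc
            raise DataValidationError(f"{exc} at row {i}") from exc
        except (TypeError, ValueError) as exc:
            raise DataValidationError(f"non-numeric cell at row {i}: {exc}") from exc
        key = (rec.study_id, rec.treatment)
        if key in seen:
            raise DataValidationError(
                f"duplicate (study, treatment) pair {key} at row {i}"
            )
        seen.add(key)
        records.append(rec)
    return records


def write_arm_data(arms: Sequence[ArmRecord], path) -> None:
    """Write arm records to CSV; inverse of :func:`read_arm_data`."""
    if not arms:
        raise ValueError("no arm records to write")
    continuous = isinstance(arms[0].outcome, ContinuousOutcome)
    rows = []
    for a in arms:
        base = {"study": a.study_id, "treatment": a.treatment, "n": a.n}
        if continuous:
            if not isinstance(a.outcome, ContinuousOutcome):
                raise ValueError("mixed outcome kinds in one dataset")
            base.update(mean=repr(a.outcome.mean), sd=repr(a.outcome.sd))
        else:
            if not isinstance(a.outcome, BinaryOutcome):
                raise ValueError("mixed outcome kinds in one dataset")
            base.update(events=a.outcome.events)
        rows.append(base)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Network construction


def build_network(
    arms: Iterable, reference: str = REFERENCE_ID
) -> Network:
    """Build the treatment network from arm records (or (study, treatment) pairs).

    Edges carry the number of trials providing that direct comparison; a
    three-arm trial contributes to all three of its edges.  The graph must be
    connected when viewed from the reference treatment.
    """
    trial_arms: dict[str, list[str]] = {}
    for a in arms:
        if isinstance(a, tuple):
            study, treat = a
        else:
            study, treat = a.study_id, a.treatment
        trial_arms.setdefault(str(study), []).append(str(treat))
    if not trial_arms:
        raise ValueError("no trials supplied")

    edge_counter: Counter = Counter()
    treatments: list[str] = []
    for study, ts in trial_arms.items():
        if len(set(ts)) != len(ts):
            raise DataValidationError(f"duplicate treatment within trial {study}")
        for t in ts:
            if t not in treatments:
                treatments.append(t)
        for i in range(len(ts)):
            for j in range(i + 1, len(ts)):
                edge_counter[tuple(sorted((ts[i], ts[j])))] += 1

    # connectivity from the reference via breadth-first search
    start = reference if reference in treatments else treatments[0]
    reached = {start}
    frontier = [start]
    while frontier:
        node = frontier.pop()
        for (a, b) in edge_counter:
            for u, v in ((a, b), (b, a)):
                if u == node and v not in reached:
                    reached.add(v)
                    frontier.append(v)
    unreachable = [t for t in treatments if t not in reached]
    if unreachable:
        raise DisconnectedNetworkError(
            "network is disconnected; unreachable treatment(s): "
            + ", ".join(sorted(unreachable))
        )

    return Network(
        treatments=tuple(treatments),
        trials=tuple((s, tuple(ts)) for s, ts in trial_arms.items()),
        edges=tuple(sorted(edge_counter.items())),
        reference=start,
    )


# ---------------------------------------------------------------------------
# Packaged fixture


def _fixture_path():
    return importlib.resources.files("dosenma") / "data" / "table1.csv"


def load_table1(path=None) -> list[TrialMeta]:
    """Load the packaged trial-characteristics fixture (one row as printed)."""
    df = pd.read_csv(path if path is not None else _fixture_path())
    out = []
    for row in df.itertuples(index=False):
        out.append(
            TrialMeta(
                study_id=row.study_id,
                label=row.label,
                location=row.location,
                treatments=tuple(row.treatments.split(";")),
                arm_sizes=tuple(int(x) for x in str(row.sample_sizes).split(";")),
                female_pct=tuple(float(x) for x in str(row.female_pct).split(";")),
                mean_ages=tuple(float(x) for x in str(row.mean_ages).split(";")),
                duration_weeks=float(row.duration_weeks),
                followup_weeks=tuple(float(x) for x in str(row.followup_weeks).split(";")),
                quality_score=int(row.quality_score),
                combined_from=int(row.combined_from),
            )
        )
    return out


def expand_trials(trials: Sequence[TrialMeta]) -> list[tuple[str, tuple[str, ...]]]:
    """Expand pooled rows into their constituent RCTs for counting/geometry.

    A row with ``combined_from == m`` becomes m trials with suffixed ids; arm
    sizes of the pooled row are totals and are not divided (they are not used
    at trial level).
    """
    out = []
    for t in trials:
        if t.combined_from == 1:
            out.append((t.study_id, t.treatments))
        else:
            for j in range(t.combined_from):
                out.append((f"{t.study_id}_{j + 1}", t.treatments))
    return out


def table1_network(trials: Sequence[TrialMeta] | None = None) -> Network:
    """Network geometry of the packaged fixture with pooled rows expanded."""
    if trials is None:
        trials = load_table1()
    pairs = [
        (study, treat)
        for study, ts in expand_trials(trials)
        for treat in ts
    ]
    return build_network(pairs)


def fixture_counts(trials: Sequence[TrialMeta]) -> FixtureSummary:
    """Descriptive totals of the fixture: trial/arm counts, patients per group.

    Counts are pure summation/filtering; pooled rows count as their
    ``combined_from`` constituent trials while their (already pooled) patient
    totals are summed once.
    """
    n_trials = sum(t.combined_from for t in trials)
    n_arms = sum(len(t.treatments) * t.combined_from for t in trials)
    patients: Counter = Counter()
    for t in trials:
        for treat, size in zip(t.treatments, t.arm_sizes):
            patients[treat] += size
    by_location: Counter = Counter()
    for t in trials:
        by_location[t.location] += t.combined_from
    return FixtureSummary(
        n_trials=n_trials,
        n_arms=n_arms,
        patients_by_treatment=dict(patients),
        total_patients=sum(patients.values()),
        trials_by_location=dict(by_location),
    )
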