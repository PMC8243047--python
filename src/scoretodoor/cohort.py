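"""Sustained-derangement cohort derivation and the Score-to-Door exposure.

The analysis population is the set of unplanned admissions to critical
care from a general (level-1) ward in which the patient showed *new and
sustained* physiological derangement beforehand: a first NEWS >= 7 that
never subsequently fell below 5 before critical-care admission.  The
exposure of interest — the Score-to-Door (STD) time — is the interval in
hours from that triggering observation to critical-care admission, the
latter timed by the first heart rate recorded on the unit (administrative
admission timestamps are unreliable).

Derivation applies four steps in a fixed order, and every patient is
accounted for exactly once in an exclusion ledger:

1. ward pathway — exclude admissions direct from the emergency
   department or with an intervening operating-theatre visit;
2. sustained trigger — exclude patients whose scores never satisfy the
   trigger-and-floor condition before admission;
3. exposure cap — exclude STD times above 7 days (168 h);
4. complete case — exclude patients with missing analysis variables
   (optional, so the median-imputation sensitivity path can retain them).
"""

from __future__ import annotations

import dataclasses
from datetime import datetime
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DataError",
    "AdmissionEvent",
    "PatientTimeline",
    "CohortEntry",
    "ExclusionLedger",
    "DerivationConfig",
    "detect_sustained_trigger",
    "compute_score_to_door",
    "is_out_of_hours",
    "derive_cohort",
    "cohort_frame",
]

EVENT_TYPES = (
    "hospital_admission",
    "ed_stay",
    "ward_stay",
    "theatre_visit",
    "critical_care_admission",
    "discharge",
    "death",
)

#: covariate/outcome columns required of the analysis table
ANALYSIS_COLUMNS = (
    "age",
    "male",
    "charlson",
    "frailty",
    "sofa_day1",
    "niv_or_imv",
    "sepsis",
    "elective_admission",
    "peri_arrest_call",
    "cc_death",
    "hospital_death",
    "cc_los_days",
    "hospital_los_days",
)


class DataError(ValueError):
    """Malformed input data (unsorted observations, duplicate ids, ...)."""


@dataclasses.dataclass(frozen=True)
class AdmissionEvent:
    patient_id: str
    event_type: str
    start: pd.Timestamp
    end: pd.Timestamp | None = None
    unit_level: int | None = None
    first_heart_rate_time: pd.Timestamp | None = None

    def __post_init__(self):
        if self.event_type not in EVENT_TYPES:
            raise DataError(f"unknown event type {self.event_type!r}")
        if self.end is not None and self.start > self.end:
            raise DataError(f"event for {self.patient_id}: start after end")


@dataclasses.dataclass
class PatientTimeline:
    """Scored observations plus admission events for one hospital stay."""

    patient_id: str
    obs_times: np.ndarray  # datetime64, strictly increasing
    obs_scores: np.ndarray  # int NEWS totals, aligned
    events: Sequence[AdmissionEvent]
    hospital_admission_time: pd.Timestamp

    def __post_init__(self):
        self.obs_times = np.asarray(self.obs_times, dtype="datetime64[s]")
        self.obs_scores = np.asarray(self.obs_scores, dtype=np.int64)
        if len(self.obs_times) != len(self.obs_scores):
            raise DataError(f"{self.patient_id}: observation times/scores length mismatch")
        if len(self.obs_times) > 1 and not (np.diff(self.obs_times) > np.timedelta64(0, "s")).all():
            raise DataError(
                f"{self.patient_id}: observations must be strictly increasing in time "
                "(duplicate timestamps are rejected at load)"
            )


@dataclasses.dataclass
class CohortEntry:
    """One included patient: exposure, covariates and outcomes."""

    patient_id: str
    trigger_time: pd.Timestamp
    trigger_news: int
    door_time: pd.Timestamp
    std_hours: float
    time_to_trigger_days: float
    out_of_hours: bool
    age: float
    male: bool
    charlson: float
    frailty: float
    sofa_day1: float
    niv_or_imv: bool
    sepsis: bool
    elective_admission: bool
    peri_arrest_call: bool
    cc_death: bool
    hospital_death: bool
    cc_los_days: float
    hospital_los_days: float


@dataclasses.dataclass
class ExclusionLedger:
    """Step-ordered accounting of exclusions; always sums to the input count.

    ``excluded_direct_ed`` counts every step-1 (pathway) exclusion: direct
    admission from the emergency department, an intervening theatre visit,
    or no identifiable ward stay before critical care.
    """

    total: int = 0
    excluded_direct_ed: int = 0
    excluded_not_sustained: int = 0
    excluded_over_cap: int = 0
    excluded_missing_data: int = 0
    included: int = 0

    def as_dict(self) -> dict[str, int]:
        return dataclasses.asdict(self)

    def check(self) -> None:
        lost = (
            self.excluded_direct_ed
            + self.excluded_not_sustained
            + self.excluded_over_cap
            + self.excluded_missing_data
        )
        if self.total != lost + self.included:
            raise AssertionError(f"ledger does not conserve patients: {self.as_dict()}")


@dataclasses.dataclass(frozen=True)
class DerivationConfig:
    high_threshold: int = 7
    floor: int = 5
    cap_hours: float = 168.0
    complete_case: bool = True

    def __post_init__(self):
        if not (self.high_threshold > self.floor > 0):
            raise ValueError("thresholds must satisfy high > floor > 0")


def detect_sustained_trigger(
    obs_times: np.ndarray,
    obs_scores: np.ndarray,
    admission_time,
    high_threshold: int = 7,
    floor: int = 5,
) -> tuple[pd.Timestamp, int] | None:
    """Earliest observation scoring >= ``high_threshold`` after which every
    later pre-admission observation scores >= ``floor``.

    Only observations strictly before ``admission_time`` are considered
    (the pre-admission interval is half-open at the door).  Returns
    ``(trigger_time, trigger_score)`` or ``None`` when no observation
    qualifies.  A single qualifying high score satisfies the sustained
    condition vacuously.
    """
    times = np.asarray(obs_times, dtype="datetime64[s]")
    scores = np.asarray(obs_scores, dtype=np.int64)
    if len(times) > 1 and not (np.diff(times) > np.timedelta64(0, "s")).all():
        raise DataError("observations must be strictly increasing in time")
    admission = np.datetime64(pd.Timestamp(admission_time), "s")
    mask = times < admission
    times, scores = times[mask], scores[mask]
    if len(scores) == 0:
        return None
    # suffix minimum: sustained_from[i] == min(scores[i:])
    sustained_from = np.minimum.accumulate(scores[::-1])[::-1]
    ok = (scores >= high_threshold) & (sustained_from >= floor)
    if not ok.any():
        return None
    i = int(np.argmax(ok))
    return pd.Timestamp(times[i]), int(scores[i])


def compute_score_to_door(trigger_time, critical_care_episode: AdmissionEvent) -> float:
    """Hours from the triggering observation to critical-care admission,
    the latter timed by the episode's first recorded heart rate."""
    door = critical_care_episode.first_heart_rate_time
    if door is None:
        raise DataError(
            f"critical-care episode for {critical_care_episode.patient_id} "
            "lacks a first-recorded-heart-rate time"
        )
    delta_h = (pd.Timestamp(door) - pd.Timestamp(trigger_time)).total_seconds() / 3600.0
    if delta_h < 0:
        raise DataError("critical-care admission precedes the triggering observation")
    return delta_h


def is_out_of_hours(t) -> bool:
    """Out-of-hours indicator: the weekend block [Sat 00:00, Mon 00:00)
    plus weekday nights [20:00, 24:00) and [00:00, 08:00).

    The windows are half-open, so exactly 108 of the week's 168 hours are
    out of hours (48 weekend + 5 x 12 weekday-night).
    """
    t = pd.Timestamp(t)
    if t.weekday() >= 5:  # Saturday, Sunday
        return True
    return t.hour >= 20 or t.hour < 8


def _index_episode(timeline: PatientTimeline) -> tuple[AdmissionEvent | None, bool]:
    """First critical-care admission reached from a level-1 ward.

    Returns ``(episode, pathway_ok)``: the first critical-care event whose
    immediately preceding location is a ward stay (not the ED, not
    theatre).  ``pathway_ok`` is False when the patient has critical-care
    admissions but none qualifies at step 1.
    """
    cc_events = sorted(
        (e for e in timeline.events if e.event_type == "critical_care_admission"),
        key=lambda e: e.start,
    )
    for cc in cc_events:
        preceding = [
            e
            for e in timeline.events
            if e.event_type in ("ed_stay", "ward_stay", "theatre_visit") and e.start < cc.start
        ]
        if not preceding:
            continue
        last = max(preceding, key=lambda e: e.start)
        if last.event_type == "ward_stay" and (last.unit_level is None or last.unit_level == 1):
            return cc, True
    return None, False


def derive_cohort(
    timelines: Iterable[PatientTimeline],
    analysis_table: pd.DataFrame,
    config: DerivationConfig | None = None,
) -> tuple[list[CohortEntry], ExclusionLedger]:
    """Apply the inclusion algorithm to scored timelines.

    ``analysis_table`` holds one row per patient (indexed or keyed by
    ``patient_id``) with the covariate and outcome columns of
    :data:`ANALYSIS_COLUMNS`.  Each patient is counted once in the ledger,
    at the first step that excludes them; included patients contribute one
    :class:`CohortEntry` for the first qualifying critical-care admission.
    """
    cfg = config or DerivationConfig()
    table = analysis_table
    if "patient_id" in table.columns:
        table = table.set_index("patient_id")
    if table.index.has_duplicates:
        dup = table.index[table.index.duplicated()][0]
        raise DataError(f"duplicate patient_id in analysis table: {dup!r}")

    ledger = ExclusionLedger()
    entries: list[CohortEntry] = []
    seen: set[str] = set()
    for tl in timelines:
        if tl.patient_id in seen:
            raise DataError(f"duplicate patient_id in timelines: {tl.patient_id!r}")
        seen.add(tl.patient_id)
        ledger.total += 1

        episode, ok = _index_episode(tl)
        if not ok:
            ledger.excluded_direct_ed += 1
            continue
        door = episode.first_heart_rate_time
        if door is None:
            raise DataError(f"{tl.patient_id}: critical-care episode lacks first_heart_rate_time")

        trig = detect_sustained_trigger(
            tl.obs_times, tl.obs_scores, door, cfg.high_threshold, cfg.floor
        )
        if trig is None:
            ledger.excluded_not_sustained += 1
            continue
        trigger_time, trigger_news = trig

        std_hours = compute_score_to_door(trigger_time, episode)
        if std_hours <= 0:
            raise DataError(f"{tl.patient_id}: non-positive Score-to-Door exposure")
        if std_hours > cfg.cap_hours:
            ledger.excluded_over_cap += 1
            continue

        if tl.patient_id not in table.index:
            ledger.excluded_missing_data += 1
            continue
        row = table.loc[tl.patient_id]
        if cfg.complete_case and row[list(ANALYSIS_COLUMNS)].isna().any():
            ledger.excluded_missing_data += 1
            continue

        ledger.included += 1
        entries.append(
            CohortEntry(
                patient_id=tl.patient_id,
                trigger_time=trigger_time,
                trigger_news=trigger_news,
                door_time=pd.Timestamp(door),
                std_hours=std_hours,
                time_to_trigger_days=(
                    (trigger_time - pd.Timestamp(tl.hospital_admission_time)).total_seconds()
                    / 86400.0
                ),
                out_of_hours=is_out_of_hours(trigger_time),
                **{c: row[c] for c in ANALYSIS_COLUMNS},
            )
        )
    ledger.check()
    return entries, ledger


def cohort_frame(entries: Sequence[CohortEntry]) -> pd.DataFrame:
    """Tabular view of the cohort, one row per included patient."""
    cols = [f.name for f in dataclasses.fields(CohortEntry)]
    df = pd.DataFrame([dataclasses.asdict(e) for e in entries], columns=cols)
    return df
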