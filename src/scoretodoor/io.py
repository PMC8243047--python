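"""CSV ingestion and the frame-level derivation pipeline.

All tabular interchange is plain CSV.  Input columns can be renamed via
a column-mapping block in the run configuration (standard name -> column
name in the file); the standard schemas are:

observations
    patient_id, timestamp, respiratory_rate, spo2, on_oxygen,
    systolic_bp, heart_rate, consciousness, temperature
events
    patient_id, event_type, start, end, unit_level, first_heart_rate_time
covariates / outcomes
    patient_id plus the analysis columns of
    :data:`scoretodoor.cohort.ANALYSIS_COLUMNS`
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import (
    AdmissionEvent,
    DataError,
    DerivationConfig,
    ExclusionLedger,
    PatientTimeline,
    cohort_frame,
    derive_cohort,
)
from .news import NEWSBandTable, load_band_table, score_frame

OBSERVATION_COLUMNS = (
    "patient_id",
    "timestamp",
    "respiratory_rate",
    "spo2",
    "on_oxygen",
    "systolic_bp",
    "heart_rate",
    "consciousness",
    "temperature",
)
EVENT_COLUMNS = ("patient_id", "event_type", "start", "end", "unit_level", "first_heart_rate_time")


def _apply_mapping(df: pd.DataFrame, mapping: Mapping[str, str] | None, required) -> pd.DataFrame:
    if mapping:
        df = df.rename(columns={v: k for k, v in mapping.items()})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"missing required columns: {missing}")
    return df


def read_observations(path, mapping: Mapping[str, str] | None = None) -> pd.DataFrame:
    df = _apply_mapping(pd.read_csv(path), mapping, OBSERVATION_COLUMNS)
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df["on_oxygen"] = df["on_oxygen"].astype(bool)
    return df


def read_events(path, mapping: Mapping[str, str] | None = None) -> pd.DataFrame:
    df = _apply_mapping(pd.read_csv(path), mapping, EVENT_COLUMNS)
    for c in ("start", "end", "first_heart_rate_time"):
        df[c] = pd.to_datetime(df[c])
    return df


def read_patient_table(path, mapping: Mapping[str, str] | None = None) -> pd.DataFrame:
    return _apply_mapping(pd.read_csv(path), mapping, ("patient_id",))


def build_timelines(
    observations: pd.DataFrame,
    events: pd.DataFrame,
    bands: NEWSBandTable | None = None,
) -> list[PatientTimeline]:
    """Score all observations and assemble per-patient timelines.

    Hospital admission time is taken from the patient's
    ``hospital_admission`` event, falling back to the earliest recorded
    event or observation.
    """
    bands = bands if bands is not None else load_band_table()
    obs = observations.sort_values(["patient_id", "timestamp"], kind="stable")
    obs = obs.assign(news=score_frame(obs, bands))

    events_by_pid: dict = {}
    for row in events.itertuples(index=False):
        ev = AdmissionEvent(
            patient_id=row.patient_id,
            event_type=row.event_type,
            start=pd.Timestamp(row.start),
            end=None if pd.isna(row.end) else pd.Timestamp(row.end),
            unit_level=None if pd.isna(row.unit_level) else int(row.unit_level),
            first_heart_rate_time=(
                None if pd.isna(row.first_heart_rate_time) else pd.Timestamp(row.first_heart_rate_time)
            ),
        )
        events_by_pid.setdefault(row.patient_id, []).append(ev)

    timelines = []
    for pid, g in obs.groupby("patient_id", sort=True):
        evs = events_by_pid.get(pid, [])
        adm = [e.start for e in evs if e.event_type == "hospital_admission"]
        t_adm = min(adm) if adm else min(
            [e.start for e in evs] + [pd.Timestamp(g["timestamp"].iloc[0])]
        )
        timelines.append(
            PatientTimeline(
                patient_id=pid,
                obs_times=g["timestamp"].to_numpy(dtype="datetime64[s]"),
                obs_scores=g["news"].to_numpy(dtype=np.int64),
                events=evs,
                hospital_admission_time=t_adm,
            )
        )
    # patients with events but no observations still enter the ledger
    for pid in sorted(set(events_by_pid) - set(obs["patient_id"])):
        evs = events_by_pid[pid]
        timelines.append(
            PatientTimeline(
                patient_id=pid,
                obs_times=np.array([], dtype="datetime64[s]"),
                obs_scores=np.array([], dtype=np.int64),
                events=evs,
                hospital_admission_time=min(e.start for e in evs),
            )
        )
    return timelines


def derive_from_frames(
    observations: pd.DataFrame,
    events: pd.DataFrame,
    analysis_table: pd.DataFrame,
    config: DerivationConfig | None = None,
    bands: NEWSBandTable | None = None,
) -> tuple[pd.DataFrame, ExclusionLedger]:
    """End-to-end: score, assemble timelines, derive the cohort frame."""
    timelines = build_timelines(observations, events, bands)
    entries, ledger = derive_cohort(timelines, analysis_table, config)
    return cohort_frame(entries), ledger


def write_ledger(ledger: ExclusionLedger, path) -> None:
    Path(path).write_text(json.dumps(ledger.as_dict(), indent=2) + "\n")


def ledger_flowchart(ledger: ExclusionLedger) -> str:
    """Human-readable inclusion flowchart."""
    d = ledger.as_dict()
    return (
        f"unplanned critical-care admissions assessed   {d['total']:>7}\n"
        f"  - excluded: direct from ED / theatre path   {d['excluded_direct_ed']:>7}\n"
        f"  - excluded: no sustained high NEWS          {d['excluded_not_sustained']:>7}\n"
        f"  - excluded: Score-to-Door > 7 days          {d['excluded_over_cap']:>7}\n"
        f"  - excluded: missing data                    {d['excluded_missing_data']:>7}\n"
        f"included in analysis                          {d['included']:>7}\n"
    )
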