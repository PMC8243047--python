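"""National Early Warning Score (NEWS / NEWS2) computation.

NEWS aggregates six routinely observed physiological parameters —
respiratory rate, peripheral oxygen saturation, systolic blood pressure,
heart rate, level of consciousness and temperature — into an ordinal
severity score from 0 to 20, with an additional weighting of 2 points
when the patient is receiving supplemental oxygen.

Band tables are declarative: each parameter maps an ordered list of
half-open numeric intervals ``[lower, upper)`` to a component score in
{0, 1, 2, 3}.  Two versioned tables ship with the package
(``news_2012`` and ``news2_scale1``, the default); user-supplied tables
can be loaded from YAML by path.  The SpO2 scale for hypercapnic
respiratory failure (NEWS2 "Scale 2") is deliberately not provided.
"""

from __future__ import annotations

import dataclasses
import math
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CONSCIOUSNESS_LEVELS",
    "Observation",
    "NEWSBand",
    "NEWSBandTable",
    "NEWSResult",
    "BandValidationIssue",
    "BandValidationReport",
    "ScoringError",
    "ObservationValidationError",
    "load_band_table",
    "score_observation",
    "score_frame",
    "validate_band_table",
    "max_attainable_score",
]

CONSCIOUSNESS_LEVELS = ("alert", "new_confusion", "voice", "pain", "unresponsive")

#: the six banded numeric parameters, in chart order
BANDED_PARAMETERS = (
    "respiratory_rate",
    "spo2",
    "systolic_bp",
    "heart_rate",
    "temperature",
)

# hard physiological validation limits (values outside are rejected, not clamped)
_VALUE_LIMITS = {
    "respiratory_rate": (0, 150),
    "spo2": (0, 100),
    "systolic_bp": (0, 400),
    "heart_rate": (0, 400),
    "temperature": (20.0, 45.0),
}


class ScoringError(ValueError):
    """An observation cannot be scored (e.g. a parameter is missing)."""


class ObservationValidationError(ValueError):
    """An observation carries a physiologically impossible value."""


@dataclasses.dataclass(frozen=True)
class Observation:
    """One timestamped set of ward vital signs for one patient."""

    patient_id: str
    timestamp: pd.Timestamp
    respiratory_rate: int
    spo2: int
    on_oxygen: bool
    systolic_bp: int
    heart_rate: int
    consciousness: str
    temperature: float


@dataclasses.dataclass(frozen=True)
class NEWSBand:
    lower: float
    upper: float  # half-open: value scores this band iff lower <= value < upper
    score: int


@dataclasses.dataclass(frozen=True)
class NEWSResult:
    total: int
    components: Mapping[str, int]
    band_version: str


@dataclasses.dataclass(frozen=True)
class BandValidationIssue:
    parameter: str
    kind: str  # gap | overlap | score_range | order | max_total | consciousness
    detail: str


@dataclasses.dataclass(frozen=True)
class BandValidationReport:
    valid: bool
    max_total: int
    issues: tuple[BandValidationIssue, ...]


class NEWSBandTable:
    """Versioned band table mapping raw vitals to NEWS component scores."""

    def __init__(
        self,
        version: str,
        parameters: Mapping[str, Sequence[NEWSBand]],
        consciousness: Mapping[str, int],
        oxygen_weight: int,
    ):
        self.version = version
        self.parameters = {p: tuple(bands) for p, bands in parameters.items()}
        self.consciousness = dict(consciousness)
        self.oxygen_weight = int(oxygen_weight)
        # precomputed searchsorted edges for vectorised lookup
        self._edges = {
            p: np.array([b.upper for b in bands[:-1]], dtype=float)
            for p, bands in self.parameters.items()
        }
        self._scores = {
            p: np.array([b.score for b in bands], dtype=np.int64)
            for p, bands in self.parameters.items()
        }

    @classmethod
    def from_dict(cls, spec: Mapping) -> "NEWSBandTable":
        params = {
            name: [NEWSBand(float(b["lower"]), float(b["upper"]), int(b["score"])) for b in bands]
            for name, bands in spec["parameters"].items()
        }
        return cls(
            version=str(spec["version"]),
            parameters=params,
            consciousness={k: int(v) for k, v in spec["consciousness"].items()},
            oxygen_weight=int(spec["oxygen_weight"]),
        )

    @classmethod
    def from_yaml(cls, path) -> "NEWSBandTable":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def component(self, parameter: str, value: float) -> int:
        """Band lookup for a single parameter value."""
        if parameter == "temperature":
            value = round(float(value), 1)
        idx = int(np.searchsorted(self._edges[parameter], value, side="right"))
        return int(self._scores[parameter][idx])


def load_band_table(version_or_path: str = "news2_scale1") -> NEWSBandTable:
    """Load a built-in band table by version label, or any table by file path."""
    builtin = {"news2_scale1", "news_2012"}
    if version_or_path in builtin:
        ref = resources.files("scoretodoor.data") / f"{version_or_path}.yaml"
        return NEWSBandTable.from_dict(yaml.safe_load(ref.read_text()))
    return NEWSBandTable.from_yaml(version_or_path)


def _check_value(parameter: str, value) -> float:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        raise ScoringError(f"missing value for parameter '{parameter}'")
    value = float(value)
    lo, hi = _VALUE_LIMITS[parameter]
    if not (lo <= value <= hi):
        raise ObservationValidationError(
            f"{parameter}={value} outside plausible range [{lo}, {hi}]"
        )
    return value


def score_observation(obs: Observation, bands: NEWSBandTable | None = None) -> NEWSResult:
    """Score one observation set against a band table.

    Raises :class:`ScoringError` if any of the seven inputs is missing and
    :class:`ObservationValidationError` for physiologically impossible
    values (these are rejected, never clamped: a transcription error such
    as SpO2 = 110 must not silently enter cohort derivation).
    """
    bands = bands if bands is not None else load_band_table()
    components: dict[str, int] = {}
    for p in BANDED_PARAMETERS:
        components[p] = bands.component(p, _check_value(p, getattr(obs, p)))
    if obs.consciousness is None or (
        isinstance(obs.consciousness, float) and math.isnan(obs.consciousness)
    ):
        raise ScoringError("missing value for parameter 'consciousness'")
    try:
        components["consciousness"] = bands.consciousness[obs.consciousness]
    except KeyError:
        raise ObservationValidationError(
            f"unknown consciousness level {obs.consciousness!r}; "
            f"expected one of {CONSCIOUSNESS_LEVELS}"
        ) from None
    if obs.on_oxygen is None:
        raise ScoringError("missing value for parameter 'on_oxygen'")
    components["supplemental_oxygen"] = bands.oxygen_weight if obs.on_oxygen else 0
    return NEWSResult(
        total=sum(components.values()),
        components=components,
        band_version=bands.version,
    )


def score_frame(df: pd.DataFrame, bands: NEWSBandTable | None = None) -> pd.Series:
    """Vectorised NEWS totals for a frame of observations.

    The frame must carry the seven input columns with package-standard
    names.  Missing values raise; out-of-range values raise.  Returns an
    integer Series aligned with ``df``.
    """
    bands = bands if bands is not None else load_band_table()
    total = np.zeros(len(df), dtype=np.int64)
    for p in BANDED_PARAMETERS:
        col = df[p]
        if col.isna().any():
            i = int(col.isna().idxmax())
            raise ScoringError(f"missing value for parameter '{p}' (row {i})")
        values = col.to_numpy(dtype=float)
        if p == "temperature":
            values = np.round(values, 1)
        lo, hi = _VALUE_LIMITS[p]
        bad = (values < lo) | (values > hi)
        if bad.any():
            raise ObservationValidationError(
                f"{p} outside plausible range [{lo}, {hi}] in {int(bad.sum())} rows"
            )
        idx = np.searchsorted(bands._edges[p], values, side="right")
        total += bands._scores[p][idx]
    unknown = ~df["consciousness"].isin(bands.consciousness)
    if unknown.any():
        raise ObservationValidationError(
            f"unknown consciousness levels: {sorted(df.loc[unknown, 'consciousness'].unique())}"
        )
    total += df["consciousness"].map(bands.consciousness).to_numpy(dtype=np.int64)
    total += np.where(df["on_oxygen"].to_numpy(dtype=bool), bands.oxygen_weight, 0)
    return pd.Series(total, index=df.index, name="news")


def validate_band_table(bands: NEWSBandTable) -> BandValidationReport:
    """Check the structural invariants of a band table.

    Bands for each parameter must partition the parameter's range without
    gaps or overlaps, in ascending order; every component score must lie
    in {0,1,2,3}; the consciousness map must cover all levels with scores
    in {0,3}; and the maximum attainable total must be 20, the top of the
    NEWS ordinal scale.
    """
    issues: list[BandValidationIssue] = []
    for p, seq in bands.parameters.items():
        for a, b in zip(seq, seq[1:]):
            if b.lower > a.upper:
                issues.append(
                    BandValidationIssue(p, "gap", f"gap at {a.upper} (bands end {a.upper}, restart {b.lower})")
                )
            elif b.lower < a.upper:
                issues.append(
                    BandValidationIssue(p, "overlap", f"overlap on [{b.lower}, {a.upper})")
                )
        for band in seq:
            if band.upper <= band.lower:
                issues.append(BandValidationIssue(p, "order", f"empty band [{band.lower}, {band.upper})"))
            if band.score not in (0, 1, 2, 3):
                issues.append(
                    BandValidationIssue(p, "score_range", f"component score {band.score} outside {{0,1,2,3}}")
                )
    for level in CONSCIOUSNESS_LEVELS:
        if level not in bands.consciousness:
            issues.append(BandValidationIssue("consciousness", "consciousness", f"level '{level}' unmapped"))
    for level, s in bands.consciousness.items():
        if s not in (0, 3):
            issues.append(
                BandValidationIssue("consciousness", "score_range", f"level '{level}' scores {s}, expected 0 or 3")
            )
    max_total = _max_attainable(bands)
    if not issues and max_total != 20:
        issues.append(
            BandValidationIssue("(table)", "max_total", f"maximum attainable total is {max_total}, expected 20")
        )
    return BandValidationReport(valid=not issues, max_total=max_total, issues=tuple(issues))


def _max_attainable(bands: NEWSBandTable) -> int:
    per_param = sum(max(b.score for b in seq) for seq in bands.parameters.values())
    return per_param + max(bands.consciousness.values(), default=0) + bands.oxygen_weight


def max_attainable_score(bands: NEWSBandTable) -> int:
    """Maximum total the table can assign: the sum over parameters of the
    maximal component score, plus the worst consciousness score, plus the
    supplemental-oxygen weight.  Raises on a structurally invalid table."""
    report = validate_band_table(bands)
    structural = [i for i in report.issues if i.kind != "max_total"]
    if structural:
        raise ValueError(f"invalid band table: {structural[0].detail}")
    return report.max_total
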