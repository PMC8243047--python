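"""Synthetic ward-EHR generator.

Emits the raw tables the derivation pipeline consumes — timestamped
vital-sign observations, admission/transfer events, per-patient
covariates and outcomes — for a configurable mix of patient archetypes:

* ``included`` — deteriorates on the ward, crosses NEWS >= 7, stays at
  or above 5 until critical-care admission after a lognormal latency
  targeting a median of 6.3 h (IQR 3.8-10.2 h);
* ``ed_direct`` — admitted to critical care straight from the emergency
  department (no intervening ward stay);
* ``never_sustained`` — either never reaches NEWS 7, or reaches it but
  dips below 5 before admission;
* ``over_cap`` — sustained derangement but latency beyond 7 days.

Observations are constructed score-first: a target NEWS total is drawn,
decomposed into per-parameter component scores, and each component is
realised by sampling a vital value uniformly inside a band carrying that
score.  This makes the generated score exact by construction, so the
generator can guarantee that every ``included`` patient is detected by
the sustained-trigger rule and that every violator fails at the intended
step — properties the test suite verifies by round trip.

Outcomes follow the generating models: death in critical care is
Bernoulli on a logistic linear predictor with a per-hour exposure
log-odds of ln(1.02) by default; length of stay is log-linear in the
exposure (0.012 per hour by default) with lognormal noise.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .news import NEWSBandTable, load_band_table

__all__ = ["GeneratorConfig", "StudyTables", "simulate_trajectories", "assign_outcomes", "simulate_study"]


class GenerationError(ValueError):
    """The generator configuration is infeasible."""


@dataclasses.dataclass
class GeneratorConfig:
    """Knobs of the synthetic study; defaults emulate the source cohort.

    Latency (Score-to-Door) is lognormal with median 6.3 h and sigma
    chosen so the IQR is 3.8-10.2 h; onset of deterioration follows a
    lognormal targeting 3.3 days from hospital admission; trigger-score
    probabilities give median 8 [7-9]; archetype fractions mirror the
    exclusion flowchart (~50% ED-direct, ~39% never-sustained, ~1.3%
    patient-level missing data).  Outcome coefficients are per-unit on
    the log-odds / log-days scale.
    """

    n_patients: int = 500
    seed: int = 0

    # archetype mix
    frac_ed_direct: float = 0.4995
    frac_never_sustained: float = 0.3913
    frac_over_cap: float = 0.01

    # timing
    window_start: str = "2017-01-01"
    window_days: int = 1460
    onset_median_days: float = 3.3
    onset_sigma: float = 1.66
    latency_median_h: float = 6.3
    latency_sigma: float = 0.732
    latency_dist: str = "lognormal"  # lognormal | gamma
    obs_interval_pre_h: float = 6.0
    obs_interval_post_h: float = 1.0
    max_pre_obs: int = 40

    # trigger-score distribution (NEWS at the triggering observation)
    trigger_score_probs: Mapping[int, float] = dataclasses.field(
        default_factory=lambda: {7: 0.40, 8: 0.25, 9: 0.20, 10: 0.08, 11: 0.05, 12: 0.02}
    )

    # covariates
    age_mean: float = 65.0
    age_sd: float = 16.0
    p_male: float = 0.608
    charlson_median: float = 10.0
    charlson_sigma: float = 0.77
    frailty_p_zero: float = 0.5
    frailty_median_pos: float = 2.8
    frailty_sigma: float = 0.8
    sofa_median: float = 5.0
    sofa_sigma: float = 0.727
    p_niv_or_imv: float = 0.427
    p_sepsis: float = 0.356
    p_elective: float = 0.229
    p_peri_arrest: float = 0.109
    missingness_rate: float = 0.0

    # critical-care mortality: logit P = beta0 + beta_std*std_h
    #   + beta_age*(age-65) + beta_sofa*(sofa-5) + beta_niv*niv
    beta0: float = -2.0
    beta_std: float = float(np.log(1.02))
    beta_age: float = float(np.log(1.02))
    beta_sofa: float = float(np.log(1.2))
    beta_niv: float = float(np.log(1.73))
    p_post_cc_death: float = 0.132  # extra hospital-death hazard for cc survivors

    # length of stay: log cc_los_days = gamma0 + gamma_std*std_h
    #   + gamma_sepsis*sepsis + gamma_niv*niv + N(0, sigma_los)
    gamma0: float = 0.718
    gamma_std: float = 0.012
    gamma_sepsis: float = 0.32
    gamma_niv: float = 0.67
    sigma_los: float = 0.8

    band_version: str = "news2_scale1"

    def validate(self) -> None:
        fr = self.frac_ed_direct + self.frac_never_sustained + self.frac_over_cap
        if fr > 1.0 + 1e-9:
            raise GenerationError(f"archetype fractions sum to {fr:.3f} > 1")
        for name in ("frac_ed_direct", "frac_never_sustained", "frac_over_cap", "missingness_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise GenerationError(f"{name}={v} outside [0, 1]")
        if self.latency_median_h <= 0:
            raise GenerationError("latency distribution must be strictly positive")
        if self.latency_dist not in ("lognormal", "gamma"):
            raise GenerationError(f"unknown latency_dist {self.latency_dist!r}")
        p = np.array(list(self.trigger_score_probs.values()), dtype=float)
        if abs(p.sum() - 1) > 1e-6 or (p < 0).any():
            raise GenerationError("trigger_score_probs must be a probability distribution")
        if any(k < 7 for k in self.trigger_score_probs):
            raise GenerationError("trigger scores must be >= 7")


@dataclasses.dataclass
class StudyTables:
    observations: pd.DataFrame
    events: pd.DataFrame
    covariates: pd.DataFrame
    outcomes: pd.DataFrame
    truth: pd.DataFrame


# ---------------------------------------------------------------------------
# score-first observation construction

# realistic sampling ranges; bands are intersected with these before drawing
_REALISTIC = {
    "respiratory_rate": (4, 40),
    "spo2": (80, 100),
    "systolic_bp": (65, 250),
    "heart_rate": (28, 170),
    "temperature": (33.0, 40.8),
}

# when a component score is attainable via more than one band (e.g. systolic
# BP scores 3 both below 91 and at/above 220), weight toward the direction a
# deteriorating ward patient typically takes
_BAND_DIRECTION_P_LOW = {
    "respiratory_rate": 0.15,  # low RR vs high RR
    "systolic_bp": 0.90,  # hypotension vs hypertensive crisis
    "heart_rate": 0.15,  # bradycardia vs tachycardia
    "temperature": 0.35,  # hypothermia vs fever
    "spo2": 1.0,
}

_BANDED = ("respiratory_rate", "spo2", "systolic_bp", "heart_rate", "temperature")
_NONALERT = ("new_confusion", "voice", "pain", "unresponsive")
_NONALERT_P = (0.5, 0.25, 0.15, 0.1)


def _sample_components(total: int, rng: np.random.Generator) -> dict[str, int]:
    """Random decomposition of a target NEWS total into component scores."""
    if not 0 <= total <= 20:
        raise GenerationError(f"target NEWS {total} outside [0, 20]")
    # consciousness contributes 0 or 3; oxygen 0 or 2; banded parameters 0-3
    choices = []
    for consc in (0, 3):
        for oxy in (0, 2):
            r = total - consc - oxy
            if 0 <= r <= 15:
                choices.append((consc, oxy))
    if not choices:
        raise GenerationError(f"target NEWS {total} not decomposable")
    # prefer alert (deterioration is usually cardiorespiratory first) and
    # supplemental oxygen when the score is high
    weights = []
    for consc, oxy in choices:
        w = 0.25 if consc else 1.0
        w *= (0.75 if total >= 5 else 0.15) if oxy else (0.25 if total >= 5 else 0.85)
        weights.append(w)
    weights = np.array(weights) / np.sum(weights)
    consc, oxy = choices[rng.choice(len(choices), p=weights)]
    comp = {"consciousness": consc, "supplemental_oxygen": oxy}
    r = total - consc - oxy
    order = list(_BANDED)
    rng.shuffle(order)
    rest = 3 * len(order)
    for p in order:
        rest -= 3
        lo = max(0, r - rest)
        hi = min(3, r)
        comp[p] = int(rng.integers(lo, hi + 1))
        r -= comp[p]
    assert r == 0
    return comp


def _vital_for_component(param: str, score: int, bands: NEWSBandTable, rng: np.random.Generator):
    """A vital value drawn uniformly inside a band carrying ``score``."""
    cands = [b for b in bands.parameters[param] if b.score == score]
    if not cands:
        raise GenerationError(f"{param}: no band with score {score}")
    if len(cands) > 1:
        b = cands[0] if rng.random() < _BAND_DIRECTION_P_LOW[param] else cands[-1]
    else:
        b = cands[0]
    lo, hi = _REALISTIC[param]
    lo, hi = max(b.lower, lo), min(b.upper, hi + (1 if param != "temperature" else 0.1))
    if param == "temperature":
        grid = np.round(np.arange(round(lo, 1), round(hi, 1) - 1e-9, 0.1), 1)
        grid = grid[(grid >= b.lower) & (grid < b.upper)]
        return float(rng.choice(grid))
    return int(rng.integers(int(np.ceil(lo)), int(np.ceil(hi))))


def _observation_row(pid: str, when: pd.Timestamp, total: int, bands, rng) -> dict:
    comp = _sample_components(total, rng)
    row = {"patient_id": pid, "timestamp": when}
    for p in _BANDED:
        row[p] = _vital_for_component(p, comp[p], bands, rng)
    row["on_oxygen"] = comp["supplemental_oxygen"] > 0
    row["consciousness"] = (
        "alert" if comp["consciousness"] == 0 else str(rng.choice(_NONALERT, p=_NONALERT_P))
    )
    return row


# ---------------------------------------------------------------------------
# trajectories


def _draw_latency_h(cfg: GeneratorConfig, rng: np.random.Generator) -> float:
    med, sig = cfg.latency_median_h, cfg.latency_sigma
    if cfg.latency_dist == "lognormal":
        return float(np.exp(rng.normal(np.log(med), sig)))
    # gamma with the same median and a similar right skew
    shape = 1.8
    scale = med / (shape * (1 - 2 / (9 * shape)) ** 3)
    return float(rng.gamma(shape, scale))


def _minute(ts: pd.Timestamp) -> pd.Timestamp:
    return pd.Timestamp(ts).floor("min")


def simulate_trajectories(cfg: GeneratorConfig):
    """Generate the observations and events tables plus a truth table.

    Returns ``(observations, events, truth)``: truth carries each
    patient's archetype, trigger time/score and generating exposure, and
    is what :func:`assign_outcomes` consumes (after joining covariates).
    """
    cfg.validate()
    bands = load_band_table(cfg.band_version)
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 1]))
    n = int(cfg.n_patients)
    p = np.array(
        [
            cfg.frac_ed_direct,
            cfg.frac_never_sustained,
            cfg.frac_over_cap,
            max(0.0, 1 - cfg.frac_ed_direct - cfg.frac_never_sustained - cfg.frac_over_cap),
        ]
    )
    groups = rng.choice(
        ["ed_direct", "never_sustained", "over_cap", "included"], size=n, p=p / p.sum()
    )
    t_start = pd.Timestamp(cfg.window_start)
    trig_scores = np.array(list(cfg.trigger_score_probs), dtype=int)
    trig_p = np.array([cfg.trigger_score_probs[k] for k in trig_scores], dtype=float)

    obs_rows: list[dict] = []
    ev_rows: list[dict] = []
    truth_rows: list[dict] = []

    for i in range(n):
        pid = f"P{i:06d}"
        group = groups[i]
        t0 = _minute(t_start + pd.Timedelta(days=float(rng.uniform(0, cfg.window_days))))
        if group == "ed_direct":
            onset_h = float(rng.uniform(1, 12))
        else:
            onset_h = 24 * float(
                np.clip(np.exp(rng.normal(np.log(cfg.onset_median_days), cfg.onset_sigma)), 0.05, 60)
            )
        t_onset = _minute(t0 + pd.Timedelta(hours=onset_h))

        latency_h = _draw_latency_h(cfg, rng)
        if group == "over_cap":
            latency_h = 168.0 + float(np.exp(rng.normal(np.log(30.0), 0.7)))
        else:
            latency_h = float(np.clip(latency_h, 0.25, 167.5))
        door = _minute(t_onset + pd.Timedelta(hours=latency_h))
        if door <= t_onset:
            door = t_onset + pd.Timedelta(minutes=15)
        latency_h = (door - t_onset).total_seconds() / 3600.0

        trig_news = int(rng.choice(trig_scores, p=trig_p))

        # pre-onset observations, scoring 0-4
        n_pre = min(int(onset_h // cfg.obs_interval_pre_h), cfg.max_pre_obs)
        pre_times = [
            t0 + pd.Timedelta(hours=cfg.obs_interval_pre_h * j, minutes=int(rng.integers(0, 11)))
            for j in range(n_pre)
        ]
        pre_times = [_minute(t) for t in pre_times if t < t_onset - pd.Timedelta(minutes=2)]
        for t in pre_times:
            obs_rows.append(
                _observation_row(pid, t, int(rng.choice([0, 1, 2, 3, 4], p=[0.4, 0.25, 0.15, 0.12, 0.08])), bands, rng)
            )

        # post-onset observations up to (but excluding) the door
        post_int = cfg.obs_interval_post_h if group != "over_cap" else 6.0
        post_times = []
        j = 0
        while True:
            t = _minute(t_onset + pd.Timedelta(hours=post_int * j, minutes=int(rng.integers(0, 6)) if j else 0))
            if t >= door - pd.Timedelta(minutes=1) or len(post_times) >= 250:
                break
            post_times.append(t)
            j += 1
        if not post_times:
            post_times = [t_onset]

        if group == "never_sustained":
            flavour_dip = rng.random() < 0.4 and len(post_times) >= 2
            if flavour_dip:
                dip_at = int(rng.integers(1, len(post_times)))
                scores = []
                for j2 in range(len(post_times)):
                    if j2 < dip_at:
                        scores.append(trig_news if j2 == 0 else int(rng.integers(5, 10)))
                    elif j2 == dip_at:
                        scores.append(int(rng.integers(2, 5)))  # the disqualifying dip
                    else:
                        scores.append(int(rng.integers(3, 7)))  # never re-triggers
            else:
                scores = [int(rng.integers(3, 7)) for _ in post_times]  # never reaches 7
        else:
            scores = [trig_news] + [
                int(np.clip(trig_news + rng.choice([-2, -1, 0, 1], p=[0.3, 0.3, 0.3, 0.1]), 5, 20))
                for _ in post_times[1:]
            ]
        for t, s in zip(post_times, scores):
            obs_rows.append(_observation_row(pid, t, s, bands, rng))

        # events
        cc_level = int(rng.choice([2, 3], p=[0.4, 0.6]))
        ev_rows.append({"patient_id": pid, "event_type": "hospital_admission", "start": t0, "end": None, "unit_level": None, "first_heart_rate_time": None})
        if group == "ed_direct":
            ev_rows.append({"patient_id": pid, "event_type": "ed_stay", "start": t0, "end": door, "unit_level": None, "first_heart_rate_time": None})
        else:
            ev_rows.append({"patient_id": pid, "event_type": "ed_stay", "start": t0 - pd.Timedelta(hours=4), "end": t0, "unit_level": None, "first_heart_rate_time": None})
            ev_rows.append({"patient_id": pid, "event_type": "ward_stay", "start": t0, "end": door, "unit_level": 1, "first_heart_rate_time": None})
        ev_rows.append(
            {
                "patient_id": pid,
                "event_type": "critical_care_admission",
                "start": door,
                "end": None,
                "unit_level": cc_level,
                "first_heart_rate_time": door,
            }
        )

        sustained = group in ("included", "over_cap", "ed_direct")
        truth_rows.append(
            {
                "patient_id": pid,
                "group": group,
                "hospital_admission_time": t0,
                "trigger_time": post_times[0] if sustained else pd.NaT,
                "trigger_news": trig_news if sustained else np.nan,
                "door_time": door,
                "std_hours": (door - post_times[0]).total_seconds() / 3600.0,
                "time_to_trigger_days": (post_times[0] - t0).total_seconds() / 86400.0,
            }
        )

    observations = pd.DataFrame(
        obs_rows,
        columns=["patient_id", "timestamp", "respiratory_rate", "spo2", "on_oxygen", "systolic_bp", "heart_rate", "consciousness", "temperature"],
    ).sort_values(["patient_id", "timestamp"], kind="stable").reset_index(drop=True)
    events = pd.DataFrame(
        ev_rows,
        columns=["patient_id", "event_type", "start", "end", "unit_level", "first_heart_rate_time"],
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "patient_id",
            "group",
            "hospital_admission_time",
            "trigger_time",
            "trigger_news",
            "door_time",
            "std_hours",
            "time_to_trigger_days",
        ],
    )
    return observations, events, truth


# ---------------------------------------------------------------------------
# covariates and outcomes


def _generate_covariates(cfg: GeneratorConfig, patient_ids, rng: np.random.Generator) -> pd.DataFrame:
    n = len(patient_ids)
    cov = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "age": np.clip(rng.normal(cfg.age_mean, cfg.age_sd, n), 18, 100).round(0),
            "male": rng.random(n) < cfg.p_male,
            "charlson": np.clip(np.round(np.exp(rng.normal(np.log(cfg.charlson_median), cfg.charlson_sigma, n))), 0, 40),
            "frailty": np.where(
                rng.random(n) < cfg.frailty_p_zero,
                0.0,
                np.clip(np.round(np.exp(rng.normal(np.log(cfg.frailty_median_pos), cfg.frailty_sigma, n)), 1), 0, 20),
            ),
            "sofa_day1": np.clip(np.round(np.exp(rng.normal(np.log(cfg.sofa_median), cfg.sofa_sigma, n))), 0, 24),
            "niv_or_imv": rng.random(n) < cfg.p_niv_or_imv,
            "sepsis": rng.random(n) < cfg.p_sepsis,
            "elective_admission": rng.random(n) < cfg.p_elective,
            "peri_arrest_call": rng.random(n) < cfg.p_peri_arrest,
        }
    )
    if cfg.missingness_rate > 0:
        for col in ("charlson", "frailty", "sofa_day1"):
            mask = rng.random(n) < cfg.missingness_rate
            cov.loc[mask, col] = np.nan
    return cov


def assign_outcomes(truth_cov: pd.DataFrame, cfg: GeneratorConfig, rng=None) -> pd.DataFrame:
    """Draw outcomes from the generating models.

    ``truth_cov`` needs ``std_hours``, ``age``, ``sofa_day1``,
    ``niv_or_imv`` and ``sepsis`` per patient.  Critical-care death is
    Bernoulli on the logistic linear predictor; hospital death adds an
    independent post-critical-care hazard; lengths of stay are lognormal
    around the log-linear predictor.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed if rng is None else rng), 3]))
    df = truth_cov
    # median-impute generator-side so injected missingness cannot leak into outcomes
    sofa = df["sofa_day1"].fillna(df["sofa_day1"].median()).to_numpy(dtype=float)
    lp = (
        cfg.beta0
        + cfg.beta_std * df["std_hours"].to_numpy(dtype=float)
        + cfg.beta_age * (df["age"].to_numpy(dtype=float) - 65.0)
        + cfg.beta_sofa * (sofa - 5.0)
        + cfg.beta_niv * df["niv_or_imv"].to_numpy(dtype=float)
    )
    if not np.isfinite(lp).all():
        raise GenerationError("non-finite linear predictor for mortality")
    cc_death = rng.random(len(df)) < expit(lp)
    hospital_death = cc_death | (rng.random(len(df)) < cfg.p_post_cc_death)
    log_los = (
        cfg.gamma0
        + cfg.gamma_std * df["std_hours"].to_numpy(dtype=float)
        + cfg.gamma_sepsis * df["sepsis"].to_numpy(dtype=float)
        + cfg.gamma_niv * df["niv_or_imv"].to_numpy(dtype=float)
        + rng.normal(0.0, cfg.sigma_los, len(df))
    )
    cc_los = np.exp(log_los)
    hospital_los = cc_los + np.exp(rng.normal(np.log(12.0), 0.9, len(df)))
    return pd.DataFrame(
        {
            "patient_id": df["patient_id"].to_numpy(),
            "cc_death": cc_death,
            "hospital_death": hospital_death,
            "cc_los_days": np.round(cc_los, 3),
            "hospital_los_days": np.round(hospital_los, 3),
        }
    )


def simulate_study(cfg: GeneratorConfig) -> StudyTables:
    """Full synthetic study: trajectories, covariates and outcomes."""
    observations, events, truth = simulate_trajectories(cfg)
    rng_cov = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 2]))
    covariates = _generate_covariates(cfg, truth["patient_id"].to_numpy(), rng_cov)
    outcomes = assign_outcomes(truth.merge(covariates, on="patient_id"), cfg)
    return StudyTables(observations, events, covariates, outcomes, truth)
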