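"""Descriptive and regression analyses of the Score-to-Door cohort.

The analysis pipeline is:

* group-wise descriptives — median [IQR] with Mann-Whitney U for
  continuous variables, count (%) with Fisher's exact test for binary
  ones;
* stepwise logistic models for critical-care and hospital mortality:
  a univariable screen at p < 0.2 selects candidate covariates, which
  then enter a multivariable model that always contains the
  Score-to-Door exposure;
* log-linear (OLS on the natural log of a strictly positive outcome)
  models for critical-care length of stay (survivors only) and for the
  determinants of the Score-to-Door time itself;
* bias-corrected accelerated (BCa) bootstrap confidence intervals for
  all multivariable models, resampling patients with replacement;
* a sensitivity analysis refitting the final models after median
  imputation of missing values.

Model fitting is delegated to statsmodels; the BCa construction (bias
correction from the bootstrap distribution, acceleration from empirical
influence values) is implemented here.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

__all__ = [
    "ModelSpec",
    "FittedModel",
    "ScreenResult",
    "describe_cohort",
    "univariable_screen",
    "fit_multivariable",
    "run_stepwise",
    "percent_effect",
    "bca_interval",
    "impute_median",
    "block_summary",
    "compare_significance",
    "spec_cc_mortality",
    "spec_hospital_mortality",
    "spec_cc_los",
    "spec_std_determinants",
]

#: Table-1-style candidate covariates for the stepwise mortality models
MORTALITY_CANDIDATES = (
    "age",
    "male",
    "charlson",
    "frailty",
    "elective_admission",
    "sepsis",
    "time_to_trigger_days",
    "trigger_news",
    "out_of_hours",
    "peri_arrest_call",
    "sofa_day1",
    "niv_or_imv",
)


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """What to fit: outcome, candidate and forced predictors, family.

    ``candidates`` enter only if they survive the univariable screen at
    ``screen_alpha``; ``forced`` predictors are always in the final model.
    A spec with no candidates is fitted directly (no screening), which is
    how the two log-linear models with hand-chosen variables are run.
    """

    outcome: str
    candidates: tuple[str, ...] = ()
    forced: tuple[str, ...] = ()
    screen_alpha: float = 0.2
    final_alpha: float = 0.05
    family: str = "logistic"  # logistic | log_linear
    subset: str | None = None  # pandas query applied before fitting

    def __post_init__(self):
        if self.family not in ("logistic", "log_linear"):
            raise ValueError(f"unknown family {self.family!r}")
        if not self.screen_alpha > self.final_alpha:
            raise ValueError("screen_alpha must exceed final_alpha")


@dataclasses.dataclass
class FittedModel:
    """Coefficient table plus fit metadata for one regression.

    ``terms`` columns: term, beta (log-odds or log-outcome per unit),
    effect (odds ratio, or percent change per unit for log-linear
    models), ci_low/ci_high on the effect scale, beta_ci_low/beta_ci_high
    on the coefficient scale, p (Wald).
    """

    spec: ModelSpec
    terms: pd.DataFrame
    n: int
    converged: bool
    ci_method: str  # bca | wald
    bootstrap_B: int
    seed: int | None


@dataclasses.dataclass
class ScreenResult:
    retained: list[str]
    dropped: pd.DataFrame  # term, reason
    table: pd.DataFrame  # term, beta, p, retained


class FitError(RuntimeError):
    """A regression failed to converge or its inputs are invalid."""


# ---------------------------------------------------------------------------
# descriptives


def _is_binary(s: pd.Series) -> bool:
    if s.dtype == bool:
        return True
    vals = pd.unique(s.dropna())
    return len(vals) <= 2 and set(np.asarray(vals, dtype=float)) <= {0.0, 1.0}


def describe_cohort(
    cohort: pd.DataFrame,
    group_by: str,
    variables: Sequence[str] | None = None,
) -> pd.DataFrame:
    """One row per variable: per-group summary and two-sided p-value.

    Continuous variables are summarised as median [IQR] and compared with
    the Mann-Whitney U test (exact for groups of at most 8 without ties,
    normal approximation with tie correction otherwise); binary variables
    as count (%) against the group denominator, compared with Fisher's
    exact test.
    """
    if cohort.empty:
        raise ValueError("cohort is empty")
    g = cohort[group_by].astype(bool)
    if g.all() or (~g).all():
        raise ValueError(f"grouping flag {group_by!r} has an empty group")
    if variables is None:
        variables = [
            c
            for c in cohort.columns
            if c not in (group_by, "patient_id", "trigger_time", "door_time")
            and pd.api.types.is_numeric_dtype(cohort[c])
        ]
    rows = []
    for var in variables:
        x0 = cohort.loc[~g, var].dropna()
        x1 = cohort.loc[g, var].dropna()
        note = ""
        if _is_binary(cohort[var]):
            test = "fisher_exact"
            k0, k1 = int(x0.sum()), int(x1.sum())
            n0, n1 = len(x0), len(x1)
            summ0 = f"{k0} ({100 * k0 / n0:.1f}%)"
            summ1 = f"{k1} ({100 * k1 / n1:.1f}%)"
            if cohort[var].nunique(dropna=True) < 2:
                p, note = 1.0, "constant variable"
            else:
                _, p = st.fisher_exact([[k0, n0 - k0], [k1, n1 - k1]], alternative="two-sided")
        else:
            test = "mann_whitney"

            def _fmt(x):
                q1, q2, q3 = np.percentile(x, [25, 50, 75])
                return f"{q2:.1f} [{q1:.1f}-{q3:.1f}]"

            summ0, summ1 = _fmt(x0), _fmt(x1)
            if cohort[var].nunique(dropna=True) < 2:
                p, note = 1.0, "constant variable"
            else:
                pooled = np.concatenate([x0, x1])
                method = (
                    "exact"
                    if len(x0) <= 8 and len(x1) <= 8 and len(np.unique(pooled)) == len(pooled)
                    else "asymptotic"
                )
                _, p = st.mannwhitneyu(x0, x1, alternative="two-sided", method=method)
        rows.append(
            {
                "variable": var,
                "test": test,
                "summary_g0": summ0,
                "summary_g1": summ1,
                "n_g0": len(x0),
                "n_g1": len(x1),
                "p": float(p),
                "note": note,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# regression machinery


def _design(cohort: pd.DataFrame, outcome: str, terms: Sequence[str], family: str):
    cols = [outcome, *terms]
    df = cohort[cols].dropna()
    y = df[outcome].to_numpy(dtype=float)
    X = sm.add_constant(df[list(terms)].astype(float), has_constant="add")
    if family == "log_linear":
        if (y <= 0).any():
            raise FitError(f"log-linear outcome {outcome!r} must be strictly positive")
        y = np.log(y)
    return y, X


def _fit(y: np.ndarray, X: pd.DataFrame, family: str, start=None):
    if family == "logistic":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200, start_params=start)
        if not res.mle_retvals.get("converged", False) or not np.isfinite(res.params).all():
            raise FitError("logistic fit did not converge")
        if np.abs(res.params).max() > 50:
            raise FitError("logistic fit diverged (quasi-separation)")
        return res
    return sm.OLS(y, X).fit()


def _influence(res, family: str) -> np.ndarray:
    """Per-observation empirical influence values of the coefficients.

    For M-estimators the influence of row i is H^{-1} s_i with H the
    observed information and s_i the per-row score; these drive the BCa
    acceleration without n leave-one-out refits.
    """
    X = np.asarray(res.model.exog, dtype=float)
    if family == "logistic":
        p = np.asarray(res.predict(), dtype=float)
        resid = np.asarray(res.model.endog, dtype=float) - p
        H = X.T @ (X * (p * (1 - p))[:, None])
    else:
        resid = np.asarray(res.resid, dtype=float)
        H = X.T @ X
    return np.linalg.solve(H, (X * resid[:, None]).T).T  # (n, k)


def percent_effect(beta: float) -> float:
    """Percent change in the outcome per unit of a log-linear predictor:
    100 * (e**beta - 1)."""
    return float(100.0 * np.expm1(beta))


def bca_interval(
    theta_hat: float,
    boot: np.ndarray,
    influence: np.ndarray,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Bias-corrected accelerated bootstrap interval for one statistic.

    ``boot`` is the bootstrap distribution of the statistic, ``influence``
    the per-observation empirical influence values used for the
    acceleration constant.  Degenerate bootstrap distributions collapse to
    a point interval.
    """
    boot = np.asarray(boot, dtype=float)
    if boot.size == 0 or np.allclose(boot, boot[0]):
        return float(theta_hat), float(theta_hat)
    prop = np.mean(boot < theta_hat) + 0.5 * np.mean(boot == theta_hat)
    prop = np.clip(prop, 1.0 / (len(boot) + 1), 1 - 1.0 / (len(boot) + 1))
    z0 = st.norm.ppf(prop)
    u = np.asarray(influence, dtype=float)
    denom = np.sum(u**2) ** 1.5
    a = np.sum(u**3) / (6.0 * denom) if denom > 0 else 0.0
    zlo, zhi = st.norm.ppf([alpha / 2, 1 - alpha / 2])
    alphas = st.norm.cdf([z0 + (z0 + zlo) / (1 - a * (z0 + zlo)), z0 + (z0 + zhi) / (1 - a * (z0 + zhi))])
    lo, hi = np.quantile(boot, alphas)
    return float(lo), float(hi)


def univariable_screen(cohort: pd.DataFrame, spec: ModelSpec) -> ScreenResult:
    """Single-predictor fits for every candidate; retain p < screen_alpha.

    Candidates whose single-predictor model fails (perfect separation,
    non-convergence, constant predictor) are dropped with a warning and
    the run continues.  Forced predictors never pass through the screen.
    """
    data = cohort.query(spec.subset) if spec.subset else cohort
    rows, dropped = [], []
    for term in spec.candidates:
        if data[term].nunique(dropna=True) < 2:
            dropped.append({"term": term, "reason": "constant predictor"})
            warnings.warn(f"screen: dropping constant predictor {term!r}")
            continue
        try:
            y, X = _design(data, spec.outcome, [term], spec.family)
            res = _fit(y, X, spec.family)
            p = float(res.pvalues[term])
        except (FitError, np.linalg.LinAlgError) as exc:
            dropped.append({"term": term, "reason": str(exc)})
            warnings.warn(f"screen: dropping {term!r} ({exc})")
            continue
        rows.append(
            {"term": term, "beta": float(res.params[term]), "p": p, "retained": p < spec.screen_alpha}
        )
    table = pd.DataFrame(rows, columns=["term", "beta", "p", "retained"])
    retained = [r["term"] for r in rows if r["retained"]]
    return ScreenResult(
        retained=retained,
        dropped=pd.DataFrame(dropped, columns=["term", "reason"]),
        table=table,
    )


def fit_multivariable(
    cohort: pd.DataFrame,
    spec: ModelSpec,
    retained: Sequence[str] | None = None,
    bootstrap_B: int = 2000,
    seed: int | None = None,
) -> FittedModel:
    """Fit the final multivariable model with per-term BCa intervals.

    Patients (rows) are resampled with replacement ``bootstrap_B`` times;
    with ``bootstrap_B = 0`` analytic Wald intervals are reported instead
    and the model's ``ci_method`` says so.  Non-convergence raises
    :class:`FitError` — silent coefficients are never returned.
    """
    data = cohort.query(spec.subset) if spec.subset else cohort
    terms = list(dict.fromkeys([*spec.forced, *(retained or [])]))
    if not terms:
        raise ValueError("no predictors: pass retained terms or a spec with forced predictors")
    y, X = _design(data, spec.outcome, terms, spec.family)
    res = _fit(y, X, spec.family)
    n = len(y)
    names = list(X.columns)
    betas = np.asarray(res.params, dtype=float)
    pvals = np.asarray(res.pvalues, dtype=float)

    if bootstrap_B > 0:
        rng = np.random.default_rng(seed)
        Xv = X.to_numpy(dtype=float)
        boot = np.empty((bootstrap_B, len(names)))
        failures = 0
        b = 0
        while b < bootstrap_B:
            idx = rng.integers(0, n, size=n)
            try:
                Xb = pd.DataFrame(Xv[idx], columns=names)
                boot[b] = _fit(y[idx], Xb, spec.family, start=betas).params
            except (FitError, np.linalg.LinAlgError):
                failures += 1
                if failures > bootstrap_B // 4 + 20:
                    raise FitError("bootstrap refits failing repeatedly; model unstable")
                continue
            b += 1
        infl = _influence(res, spec.family)
        ci_beta = np.array(
            [bca_interval(betas[j], boot[:, j], infl[:, j]) for j in range(len(names))]
        )
        ci_method = "bca"
    else:
        ci = res.conf_int(alpha=0.05)
        ci_beta = np.asarray(ci, dtype=float)
        ci_method = "wald"

    if spec.family == "logistic":
        effect = np.exp(betas)
        eff_lo, eff_hi = np.exp(ci_beta[:, 0]), np.exp(ci_beta[:, 1])
    else:
        effect = np.array([percent_effect(b_) for b_ in betas])
        eff_lo = np.array([percent_effect(b_) for b_ in ci_beta[:, 0]])
        eff_hi = np.array([percent_effect(b_) for b_ in ci_beta[:, 1]])

    terms_df = pd.DataFrame(
        {
            "term": names,
            "beta": betas,
            "effect": effect,
            "ci_low": eff_lo,
            "ci_high": eff_hi,
            "beta_ci_low": ci_beta[:, 0],
            "beta_ci_high": ci_beta[:, 1],
            "p": pvals,
        }
    )
    return FittedModel(
        spec=spec,
        terms=terms_df,
        n=n,
        converged=True,
        ci_method=ci_method,
        bootstrap_B=bootstrap_B,
        seed=seed,
    )


def run_stepwise(
    cohort: pd.DataFrame,
    spec: ModelSpec,
    bootstrap_B: int = 2000,
    seed: int | None = None,
) -> tuple[FittedModel, ScreenResult | None]:
    """Univariable screen (if the spec has candidates) followed by the
    multivariable fit with forced predictors always included."""
    screen = univariable_screen(cohort, spec) if spec.candidates else None
    retained = screen.retained if screen else []
    model = fit_multivariable(cohort, spec, retained=retained, bootstrap_B=bootstrap_B, seed=seed)
    return model, screen


# ---------------------------------------------------------------------------
# imputation, blocks, sensitivity


def impute_median(cohort: pd.DataFrame, columns: Sequence[str] | None = None) -> pd.DataFrame:
    """Replace every missing value by the median of its variable's
    available values; non-missing cells are untouched."""
    out = cohort.copy()
    cols = columns if columns is not None else [
        c for c in out.columns if pd.api.types.is_numeric_dtype(out[c])
    ]
    for c in cols:
        if out[c].isna().all():
            raise ValueError(f"variable {c!r} is entirely missing; cannot impute")
        if out[c].isna().any():
            out[c] = out[c].fillna(out[c].median())
    return out


def block_summary(
    cohort: pd.DataFrame,
    value_cols: Sequence[str] = ("cc_death", "sofa_day1"),
    time_col: str = "std_hours",
    block_hours: float = 2.0,
    max_hours: float = 48.0,
) -> pd.DataFrame:
    """Mean and 95% CI of each value column within half-open 2-hour blocks
    of the exposure, with times at or beyond ``max_hours`` clipped into the
    final block.  Blocks with a single member are reported without a CI."""
    if cohort.empty:
        raise ValueError("cohort is empty")
    t = cohort[time_col].to_numpy(dtype=float)
    last_start = max_hours - block_hours
    start = np.minimum(np.floor(t / block_hours) * block_hours, last_start)
    rows = []
    for s in np.unique(start):
        m = start == s
        for col in value_cols:
            x = cohort.loc[m, col].astype(float)
            n = len(x)
            mean = float(x.mean())
            if n > 1 and x.std(ddof=1) > 0:
                half = 1.959963984540054 * float(x.std(ddof=1)) / np.sqrt(n)
                lo, hi = mean - half, mean + half
            else:
                lo = hi = np.nan
            rows.append(
                {
                    "variable": col,
                    "block_start": float(s),
                    "block_end": float(s + block_hours),
                    "n": n,
                    "mean": mean,
                    "ci_low": lo,
                    "ci_high": hi,
                }
            )
    return pd.DataFrame(rows).sort_values(["variable", "block_start"]).reset_index(drop=True)


def compare_significance(
    complete_case: FittedModel, imputed: FittedModel, alpha: float = 0.05
) -> pd.DataFrame:
    """Sensitivity check: do the final models' significance calls agree
    between the complete-case and median-imputed fits?"""
    a = complete_case.terms.set_index("term")["p"]
    b = imputed.terms.set_index("term")["p"]
    terms = a.index.union(b.index)
    df = pd.DataFrame(
        {
            "p_complete_case": a.reindex(terms),
            "p_imputed": b.reindex(terms),
        },
        index=terms,
    )
    df["significant_complete_case"] = df["p_complete_case"] < alpha
    df["significant_imputed"] = df["p_imputed"] < alpha
    df["unchanged"] = df["significant_complete_case"] == df["significant_imputed"]
    return df.reset_index(names="term")


# ---------------------------------------------------------------------------
# canonical model specifications


def spec_cc_mortality() -> ModelSpec:
    """Stepwise logistic model for death during the index critical-care
    admission, Score-to-Door time always included."""
    return ModelSpec(
        outcome="cc_death",
        candidates=MORTALITY_CANDIDATES,
        forced=("std_hours",),
        family="logistic",
    )


def spec_hospital_mortality() -> ModelSpec:
    """Stepwise logistic model for hospital mortality (re-screened)."""
    return ModelSpec(
        outcome="hospital_death",
        candidates=MORTALITY_CANDIDATES,
        forced=("std_hours",),
        family="logistic",
    )


def spec_cc_los() -> ModelSpec:
    """Log-linear model for critical-care length of stay among patients
    who survived critical care; variables chosen a priori, no screening."""
    return ModelSpec(
        outcome="cc_los_days",
        forced=("std_hours", "age", "frailty", "charlson", "sofa_day1", "sepsis", "niv_or_imv"),
        family="log_linear",
        subset="cc_death == 0",
    )


def spec_std_determinants() -> ModelSpec:
    """Log-linear model for the Score-to-Door time itself."""
    return ModelSpec(
        outcome="std_hours",
        forced=(
            "age",
            "frailty",
            "charlson",
            "trigger_news",
            "time_to_trigger_days",
            "out_of_hours",
            "peri_arrest_call",
        ),
        family="log_linear",
    )
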