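"""Left-truncated, right-censored survival analysis of predicted age gaps.

Age is the time scale: a subject enters the risk set at the imaging age
(delayed entry) and exits at the earliest of target-outcome diagnosis,
death from another cause (censored), or administrative data retrieval.
Subjects diagnosed before imaging (prevalent cases) are excluded, since the
question is prognosis, not retrospective detection.

Kaplan-Meier curves and Cox proportional-hazards fits (Efron tie handling,
delayed entry) are computed with lifelines; hand-enumerated product-limit
and closed-form partial-likelihood oracles cross-check them in the test
suite.  Aging groups enter the Cox model as a single ordinal covariate
coded 0 (decelerated) / 1 (typical) / 2 (accelerated), so the reported
hazard ratio is per one-step increase across groups; continuous PAGs give
the risk per one-year increase in the predicted age gap.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats

from .config import ConfigurationError, DataError

RECORD_COLUMNS = ("subject_id", "entry_age", "exit_age", "event")


@dataclass
class CoxFit:
    """One fitted Cox proportional-hazards model."""

    beta: dict[str, float]
    hr: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    se: dict[str, float]
    p: dict[str, float]
    loglik: float
    n: int
    n_events: int
    covariates: tuple[str, ...]
    converged: bool = True

    def summary(self) -> str:
        lines = [f"Cox PH (delayed entry, Efron ties): n={self.n}, "
                 f"events={self.n_events}, loglik={self.loglik:.3f}"]
        for c in self.covariates:
            lo, hi = self.ci95[c]
            lines.append(f"  {c:<12} HR {self.hr[c]:6.3f} "
                         f"(95% CI {lo:.3f}-{hi:.3f})  p={self.p[c]:.3g}")
        return "\n".join(lines)

    def to_json(self, path) -> None:
        doc = {"beta": self.beta, "hr": self.hr,
               "ci95": {k: list(v) for k, v in self.ci95.items()},
               "se": self.se, "p": self.p, "loglik": self.loglik,
               "n": self.n, "n_events": self.n_events,
               "covariates": list(self.covariates),
               "converged": self.converged}
        Path(path).write_text(json.dumps(doc, indent=1))


def build_records(cohort: pd.DataFrame, outcome: str,
                  pag_table: pd.DataFrame | None = None,
                  organ: str | None = None) -> pd.DataFrame:
    """Build left-truncated survival records for one outcome.

    Prevalent cases (diagnosis before imaging) are dropped; entry is the
    imaging age; exit is the earliest of diagnosis, death from another
    cause (censored) or retrieval.  For ``outcome="death"`` all observed
    deaths are events.  If `pag_table` and `organ` are given, that organ's
    corrected PAG and aging-group code are merged in as covariates.
    """
    if outcome != "death" and f"age_{outcome}" not in cohort.columns:
        raise ConfigurationError(f"outcome {outcome!r} not defined in cohort")
    df = cohort.copy()
    entry = df["ca_at_imaging"].to_numpy(dtype=np.float64)
    retrieval = df["retrieval_age"].to_numpy(dtype=np.float64)
    death = df.get("death_age", pd.Series(np.nan, index=df.index)).to_numpy(dtype=np.float64)

    if outcome == "death":
        diag = death
    else:
        diag = df[f"age_{outcome}"].to_numpy(dtype=np.float64)

    exit_age = np.fmin(np.fmin(diag, retrieval), death)
    event = np.isfinite(diag) & (diag <= exit_age)
    keep = ~(np.isfinite(diag) & (diag <= entry))  # drop prevalent cases
    keep &= exit_age > entry

    out = pd.DataFrame({
        "subject_id": df["subject_id"].to_numpy()[keep],
        "entry_age": entry[keep],
        "exit_age": exit_age[keep],
        "event": event[keep].astype(int),
        "ca": entry[keep],
        "sex": (df["sex"].to_numpy()[keep] == "male").astype(int),
        "bmi": df["bmi"].to_numpy()[keep],
    })
    if pag_table is not None:
        if organ is None:
            raise ConfigurationError("organ required to merge PAG covariates")
        sub = pag_table.loc[pag_table["organ"] == organ,
                            ["subject_id", "pag_corrected", "group"]]
        out = out.merge(sub.rename(columns={"pag_corrected": "pag"}),
                        on="subject_id", how="inner")
    return out


def km_estimate(records: pd.DataFrame, label: str = "") -> pd.DataFrame:
    """Product-limit estimate of event-free probability over age.

    Handles delayed entry: the risk set at age t contains subjects with
    ``entry_age < t <= exit_age``.  Returns a step function as a DataFrame
    with columns ``age`` and ``survival`` (starts at 1, nonincreasing).
    """
    if len(records) == 0:
        raise DataError("need at least one record")
    kmf = KaplanMeierFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kmf.fit(records["exit_age"], event_observed=records["event"],
                entry=records["entry_age"], label=label or "km")
    sf = kmf.survival_function_
    return pd.DataFrame({"age": sf.index.to_numpy(dtype=np.float64),
                         "survival": sf.iloc[:, 0].to_numpy(dtype=np.float64)})


def cox_fit(records: pd.DataFrame, covariate_names) -> CoxFit:
    """Cox PH with delayed entry and Efron tie handling.

    Supports the ordinal aging-group code (0/1/2), continuous PAG per year,
    and multivariable adjustment (chronological age, sex, BMI).  Wald 95%
    CIs; monotone-likelihood/separation problems are surfaced as a
    non-converged fit.
    """
    covariate_names = tuple(covariate_names)
    if len(records) == 0:
        raise DataError("no records to fit")
    if int(records["event"].sum()) < 2:
        raise DataError("need at least 2 events for a Cox fit")
    for c in covariate_names:
        if c not in records.columns:
            raise ConfigurationError(f"covariate {c!r} missing from records")
        if np.ptp(records[c].to_numpy(dtype=np.float64)) == 0:
            raise DataError(f"covariate {c!r} is constant")
    df = records[["entry_age", "exit_age", "event", *covariate_names]].copy()
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="exit_age", event_col="event",
                    entry_col="entry_age")
    except ConvergenceError as exc:
        raise DataError(f"Cox fit did not converge (possible complete "
                        f"separation / monotone likelihood): {exc}") from exc
    summ = cph.summary
    beta = {c: float(summ.loc[c, "coef"]) for c in covariate_names}
    se = {c: float(summ.loc[c, "se(coef)"]) for c in covariate_names}
    return CoxFit(
        beta=beta,
        hr={c: float(np.exp(beta[c])) for c in covariate_names},
        ci95={c: (float(np.exp(beta[c] - 1.959963984540054 * se[c])),
                  float(np.exp(beta[c] + 1.959963984540054 * se[c])))
              for c in covariate_names},
        se=se,
        p={c: float(summ.loc[c, "p"]) for c in covariate_names},
        loglik=float(cph.log_likelihood_),
        n=len(df), n_events=int(df["event"].sum()),
        covariates=covariate_names)


def lr_test(full: CoxFit, reduced: CoxFit) -> dict[str, float]:
    """Likelihood-ratio test of nested Cox models on the same records."""
    if not set(reduced.covariates) <= set(full.covariates):
        raise ConfigurationError("models are not nested: reduced covariates "
                                 "must be a subset of the full model's")
    if (full.n, full.n_events) != (reduced.n, reduced.n_events):
        raise ConfigurationError("models were fitted on different records")
    df = len(full.covariates) - len(reduced.covariates)
    chi2 = max(2.0 * (full.loglik - reduced.loglik), 0.0)
    if df == 0:
        p = 1.0 if chi2 == 0.0 else 0.0
    else:
        p = float(stats.chi2.sf(chi2, df))
    return {"chi2": float(chi2), "df": float(df), "p": p}


def hr_per_year(fit: CoxFit, covariate: str) -> float:
    """Percent change in hazard per one-year increase: 100 * (HR - 1)."""
    if covariate not in fit.hr:
        raise ConfigurationError(f"covariate {covariate!r} not in fit")
    return 100.0 * (fit.hr[covariate] - 1.0)
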