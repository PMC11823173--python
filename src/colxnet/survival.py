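"""Cox proportional-hazards models and Kaplan-Meier stratified comparison.

Multivariate Cox models condition an outcome (overall survival or
disease-free interval) on age, gender, binarized tumor stage (1-2 vs 3-4)
and one signal variable (anchor-gene expression, module eigengene, or
%G.A.M.E.), the signal standardized so 1 SD = 1 unit. Fitting uses partial
likelihood with Efron tie handling; hazards are reported as
``hazard_pct = (e^beta - 1) * 100``, the percent change in hazard per unit.
The proportional-hazards assumption is checked by correlating scaled
Schoenfeld residuals with event-time rank. Kaplan-Meier comparison uses the
product-limit estimator per stratum with a two-sided log-rank test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test, proportional_hazard_test

from .io import ClinicalTable

logger = logging.getLogger("colxnet")

__all__ = ["CoxFit", "KMResult", "fit_coxph", "schoenfeld_ph_test",
           "km_estimate", "hazard_pct"]

DEFAULT_COVARIATES = ("age", "gender", "stage_binary")


def hazard_pct(beta: float) -> float:
    """Percent change in hazard per unit of the covariate: (e^beta - 1)*100."""
    return (math.exp(beta) - 1.0) * 100.0


@dataclass
class CoxFit:
    summary: pd.DataFrame        # per covariate: beta, se, z, p, hazard_pct
    log_likelihood: float
    n: int
    n_events: int
    outcome: str
    signal_name: str
    dropped_covariates: list[str] = field(default_factory=list)
    ph_test: pd.DataFrame | None = None
    _fitter: CoxPHFitter | None = None
    _frame: pd.DataFrame | None = None

    def beta(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "beta"])

    def p(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "p"])


def _design_frame(clinical: ClinicalTable, signal: pd.Series, outcome: str,
                  covariates=DEFAULT_COVARIATES) -> tuple[pd.DataFrame, list[str], list[str]]:
    df = clinical.complete_cases(outcome, list(covariates))
    df = df[df["sample_id"].isin(signal.index)].copy()
    df["signal"] = signal.loc[df["sample_id"]].to_numpy(dtype=float)
    df = df.dropna(subset=["signal"])
    cols, dropped = [], []
    if "age" in covariates and "age" in df.columns:
        cols.append("age")
    if "gender" in covariates and "gender" in df.columns:
        vals = df["gender"].unique()
        if len(vals) > 1:
            df["gender_male"] = (df["gender"] == "male").astype(float)
            cols.append("gender_male")
        else:
            dropped.append("gender")
            logger.info("gender has a single level; dropped from the model")
    if "stage_binary" in covariates and "stage_binary" in df.columns:
        vals = df["stage_binary"].unique()
        if len(vals) > 1:
            df["stage_34"] = (df["stage_binary"] == "3-4").astype(float)
            cols.append("stage_34")
        else:
            dropped.append("stage_binary")
            logger.info("all samples in one stage group; stage dropped from the model")
    sd = df["signal"].std(ddof=1)
    if sd == 0:
        raise ValueError("signal variable is constant")
    df["signal"] = (df["signal"] - df["signal"].mean()) / sd
    cols.append("signal")
    tcol, ecol = f"{outcome}_time", f"{outcome}_event"
    frame = df[[tcol, ecol] + cols].rename(columns={tcol: "time", ecol: "event"})
    return frame, cols, dropped


def fit_coxph(clinical: ClinicalTable, signal: pd.Series, outcome: str = "os",
              covariates=DEFAULT_COVARIATES, signal_name: str = "signal",
              run_ph_test: bool = True, min_events: int = 10) -> CoxFit:
    """Fit a multivariate Cox model with one standardized signal variable.

    ``signal`` is indexed by sample id. Complete-case per outcome; requires
    >= 10 events. Degenerate covariates (single level) are dropped with a
    logged note.
    """
    frame, cols, dropped = _design_frame(clinical, signal, outcome, covariates)
    n_events = int(frame["event"].sum())
    if n_events < min_events:
        raise ValueError(f"only {n_events} events; need >= {min_events}")
    cph = CoxPHFitter()
    try:
        cph.fit(frame, duration_col="time", event_col="event")
    except Exception as exc:  # lifelines raises ConvergenceError subclasses
        raise RuntimeError(f"Cox model failed to converge: {exc}") from exc
    s = cph.summary
    summary = pd.DataFrame({
        "beta": s["coef"],
        "se": s["se(coef)"],
        "z": s["z"],
        "p": s["p"],
        "hazard_pct": (np.exp(s["coef"]) - 1.0) * 100.0,
    })
    summary.index.name = "covariate"
    fit = CoxFit(summary=summary, log_likelihood=float(cph.log_likelihood_),
                 n=int(frame.shape[0]), n_events=n_events, outcome=outcome,
                 signal_name=signal_name, dropped_covariates=dropped,
                 _fitter=cph, _frame=frame)
    if run_ph_test:
        fit.ph_test = schoenfeld_ph_test(fit)
    return fit


def schoenfeld_ph_test(fit: CoxFit, clinical: ClinicalTable | None = None
                       ) -> pd.DataFrame:
    """Scaled-Schoenfeld-residual test of proportional hazards per covariate.

    Correlates scaled Schoenfeld residuals with event-time rank; small p
    indicates a time-varying effect (PH violation).
    """
    if fit._fitter is None or fit._frame is None:
        raise ValueError("fit does not carry its fitter; refit with fit_coxph")
    if int(fit._frame["event"].sum()) < 2:
        raise ValueError("PH test needs >= 2 events")
    res = proportional_hazard_test(fit._fitter, fit._frame, time_transform="rank")
    out = res.summary[["test_statistic", "p"]].copy()
    out.index = [i[0] if isinstance(i, tuple) else i for i in out.index]
    out.index.name = "covariate"
    return out


@dataclass
class KMResult:
    curves: dict[str, pd.DataFrame]      # group -> columns time, survival
    medians: dict[str, float]            # NaN when S never reaches 0.5
    logrank_statistic: float
    logrank_p: float
    group_sizes: dict[str, int]


def km_estimate(time, event, km_labels) -> KMResult:
    """Product-limit curves per group and the two-group log-rank test."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    labels = np.asarray(km_labels)
    groups = sorted(set(labels.tolist()))
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 non-empty groups, got {groups}")
    curves, medians, sizes = {}, {}, {}
    for g in groups:
        mask = labels == g
        if event[mask].sum() < 1:
            raise ValueError(f"group {g!r} has no events; log-rank undefined")
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask], label=str(g))
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        curves[g] = sf
        med = kmf.median_survival_time_
        medians[g] = float(med) if np.isfinite(med) else float("nan")
        sizes[g] = int(mask.sum())
    m0, m1 = labels == groups[0], labels == groups[1]
    lr = logrank_test(time[m0], time[m1], event_observed_A=event[m0],
                      event_observed_B=event[m1])
    return KMResult(curves=curves, medians=medians,
                    logrank_statistic=float(lr.test_statistic),
                    logrank_p=float(lr.p_value), group_sizes=sizes)
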