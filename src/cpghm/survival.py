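"""TMB/CpG-stratified survival analysis for ICI-treated cohorts.

Patients are stratified with :func:`cpghm.classify.ici_classify` into
TMB-Lo (< 10 coding mut/Mb), TMB-Hi_CpG-Lo and TMB-Hi_CpG-Hi (coding TMB
>= 10 and CpG>TpG proportion > 0.6; a cohort-median CpG split is
available via ``cpg_cut="median"``).  Kaplan-Meier estimation, log-rank
tests and Cox proportional-hazards regression (Efron tie handling) are
delegated to lifelines; both unadjusted and continuous-TMB-adjusted Cox
models are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .classify import ici_classify

log = logging.getLogger(__name__)

STRATA = ("TMB-Lo", "TMB-Hi_CpG-Lo", "TMB-Hi_CpG-Hi")


def km_estimate(times, events) -> pd.DataFrame:
    """Product-limit (Kaplan-Meier) survival estimate with right censoring.

    Returns a step function as a DataFrame (time, survival, at_risk),
    starting at S(0) = 1 and non-increasing.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("km_estimate requires at least one record")
    if (times <= 0).any():
        raise ValueError("survival times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    at_risk = kmf.event_table["at_risk"].reindex(sf.index)
    return pd.DataFrame(
        {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy(),
         "at_risk": at_risk.to_numpy()}
    )


def logrank(groups: dict) -> tuple[float, float]:
    """Log-rank test across two or more groups.

    ``groups`` maps group label -> (times, events).  Returns the chi-square
    statistic and its p-value on len(groups) - 1 degrees of freedom.
    """
    if len(groups) < 2:
        raise ValueError("log-rank test requires at least two groups")
    times, events, labels = [], [], []
    for name, (t, e) in groups.items():
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=bool)
        times.append(t)
        events.append(e)
        labels.append(np.full(len(t), str(name)))
    res = multivariate_logrank_test(
        np.concatenate(times), np.concatenate(labels), np.concatenate(events)
    )
    return float(res.test_statistic), float(res.p_value)


def cox_hr(records: pd.DataFrame, stratum_col: str = "stratum",
           reference: str = "TMB-Lo", adjust_tmb: bool = False) -> pd.DataFrame:
    """Cox proportional-hazards HR per non-reference stratum.

    Efron handling of tied event times; Wald confidence intervals and
    p-values.  Strata with no events make the partial likelihood
    unbounded; they are reported with an infinite/NaN HR and a warning.
    With ``adjust_tmb`` the continuous TMB column enters as a covariate.
    """
    df = records.copy()
    if not (df["event"].astype(bool)).any():
        raise ValueError("no events observed: Cox model not estimable")
    levels = [reference] + [s for s in pd.unique(df[stratum_col]) if s != reference]
    bad = [
        s for s in levels
        if not df.loc[df[stratum_col] == s, "event"].astype(bool).any()
    ]
    if bad:
        log.warning("strata without events (HR not identifiable): %s", bad)
    dummies = pd.get_dummies(df[stratum_col].astype(pd.CategoricalDtype(levels)),
                             drop_first=True, dtype=float)
    dummies.columns = [str(c) for c in dummies.columns]
    model_df = pd.concat(
        [df[["time", "event"]].astype(float), dummies], axis=1
    )
    if adjust_tmb:
        model_df["tmb"] = df["tmb"].astype(float)
    cph = CoxPHFitter()
    cph.fit(model_df, duration_col="time", event_col="event")
    out = pd.DataFrame(
        {
            "hr": np.exp(cph.params_),
            "ci_low": np.exp(cph.confidence_intervals_.iloc[:, 0]),
            "ci_high": np.exp(cph.confidence_intervals_.iloc[:, 1]),
            "p_value": cph.summary["p"],
        }
    )
    for s in bad:
        if s in out.index:
            out.loc[s, ["hr", "ci_low", "ci_high", "p_value"]] = [np.inf, np.nan, np.nan, np.nan]
    out.index.name = "covariate"
    return out


@dataclass
class IciSurvivalResults:
    """Stratified survival analysis output."""

    records: pd.DataFrame
    km_curves: dict[str, pd.DataFrame]
    logrank_stat: float
    logrank_p: float
    cox_unadjusted: pd.DataFrame
    cox_adjusted: pd.DataFrame
    cpg_cut: float

    def summary(self) -> str:
        counts = self.records["stratum"].value_counts()
        lines = [
            "ICI survival stratification",
            "=" * 47,
            "stratum sizes: "
            + ", ".join(f"{s}={int(counts.get(s, 0))}" for s in STRATA),
            f"CpG>TpG cut-off: {self.cpg_cut:.3g}",
            f"log-rank chi2 = {self.logrank_stat:.2f}, p = {self.logrank_p:.3g}",
            "",
            "Cox PH (reference TMB-Lo), unadjusted:",
            self.cox_unadjusted.to_string(float_format=lambda v: f"{v:.3g}"),
            "",
            "Cox PH adjusted for continuous TMB:",
            self.cox_adjusted.to_string(float_format=lambda v: f"{v:.3g}"),
        ]
        return "\n".join(lines)


class IciSurvivalModel:
    """Stratify an ICI-treated clinical cohort and compare survival.

    ``clinical`` needs columns: sample_id, time (months), event (0/1),
    tmb (coding mut/Mb) and cpg_proportion.  ``cpg_cut`` is the fixed 0.6
    CpG>TpG threshold by default; pass ``"median"`` to split TMB-Hi cases
    on their median proportion instead.
    """

    def __init__(self, clinical: pd.DataFrame, tmb_cut: float = 10.0, cpg_cut=0.6):
        required = {"time", "event", "tmb", "cpg_proportion"}
        missing = required - set(clinical.columns)
        if missing:
            raise ValueError(f"clinical table missing columns: {sorted(missing)}")
        if (clinical["time"] <= 0).any():
            raise ValueError("survival times must be positive")
        self.clinical = clinical.copy()
        self.tmb_cut = tmb_cut
        self.cpg_cut = cpg_cut

    def fit(self) -> IciSurvivalResults:
        df = self.clinical
        cut = self.cpg_cut
        if cut == "median":
            hi = df["tmb"] >= self.tmb_cut
            cut = float(df.loc[hi, "cpg_proportion"].median())
        df = df.assign(
            stratum=ici_classify(df["tmb"], df["cpg_proportion"],
                                 tmb_cut=self.tmb_cut, cpg_cut=cut)
        )
        km = {
            s: km_estimate(g["time"], g["event"].astype(bool))
            for s, g in df.groupby("stratum")
        }
        stat, p = logrank(
            {s: (g["time"].to_numpy(), g["event"].to_numpy(dtype=bool))
             for s, g in df.groupby("stratum")}
        )
        cox_u = cox_hr(df, "stratum", reference="TMB-Lo", adjust_tmb=False)
        cox_a = cox_hr(df, "stratum", reference="TMB-Lo", adjust_tmb=True)
        return IciSurvivalResults(
            records=df, km_curves=km, logrank_stat=stat, logrank_p=p,
            cox_unadjusted=cox_u, cox_adjusted=cox_a, cpg_cut=float(cut),
        )
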