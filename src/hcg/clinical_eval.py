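"""Clinical stratification of a subtype assignment.

Kaplan-Meier curves with the log-rank test for univariate comparison, and
a multivariate Cox proportional-hazards model with subtype, age group
(>= 65 vs < 65) and sex, reporting per-term hazard ratios with 95% CIs and
an overall likelihood-ratio p-value.  The reference stratum is
subtype = CIN, age < 65, sex = female.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from statsmodels.stats.multitest import multipletests

from .omics_io import SUBTYPES

logger = logging.getLogger(__name__)


class SurvivalError(ValueError):
    pass


@dataclass
class SurvivalReport:
    """Hazard ratios, CIs and p-values from the multivariate Cox model."""

    terms: pd.DataFrame       # index: term; columns: hr, ci_low, ci_high, p, count, pct
    overall_p: float          # likelihood-ratio test of the full model vs null
    reference: dict           # {"subtype": ..., "age": ..., "sex": ...}
    classifier: str = ""

    def to_json(self, path=None) -> str:
        payload = {
            "classifier": self.classifier,
            "reference": self.reference,
            "overall_p": self.overall_p,
            "terms": {t: {k: (None if pd.isna(v) else float(v))
                          for k, v in row.items()}
                      for t, row in self.terms.iterrows()},
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_tsv(self, path=None) -> pd.DataFrame:
        df = self.terms.reset_index(names="term")
        df["overall_p"] = self.overall_p
        if path is not None:
            df.to_csv(path, sep="\t", index=False)
        return df


def km_logrank(groups: Sequence[str], time: Sequence[float],
               event: Sequence[int]) -> tuple[dict, float, float]:
    """Per-group Kaplan-Meier curves and the multi-group log-rank test.

    Returns (curves, chi2, p); each curve is a DataFrame of (time, survival).
    Empty groups are dropped with a warning.
    """
    df = pd.DataFrame({"group": list(groups), "time": list(time),
                       "event": list(event)})
    counts = df["group"].value_counts()
    df = df[df["group"].isin(counts[counts > 0].index)]
    if df["group"].nunique() < 2:
        raise SurvivalError("need >= 2 non-empty groups for the log-rank test")
    if df["event"].sum() == 0:
        raise SurvivalError("need >= 1 event")
    curves = {}
    for name, sub in df.groupby("group"):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"])
        sf = kmf.survival_function_
        curves[name] = pd.DataFrame({"time": sf.index.to_numpy(),
                                     "survival": sf.iloc[:, 0].to_numpy()})
    res = multivariate_logrank_test(df["time"], df["group"], df["event"])
    return curves, float(res.test_statistic), float(res.p_value)


def fit_multivariate_cox(labels: Sequence[str], age: Sequence[float],
                         sex: Sequence[str], time: Sequence[float],
                         event: Sequence[int], reference_sex: str = "female",
                         age_cut: float = 65.0,
                         classifier: str = "") -> SurvivalReport:
    """Cox PH fit on subtype (vs CIN), age >= cut (vs <), and sex indicators."""
    labels = pd.Series(list(labels))
    df = pd.DataFrame({"time": list(time), "event": list(event)})
    if (df["time"] <= 0).any():
        raise SurvivalError("survival times must be > 0")
    if df["event"].sum() == 0:
        raise SurvivalError("need >= 1 event")
    other_sex = "male" if reference_sex == "female" else "female"
    for subtype in [s for s in SUBTYPES if s != "CIN"]:
        df[f"subtype_{subtype}"] = (labels == subtype).astype(float).to_numpy()
    df[f"age_ge{age_cut:.0f}"] = (np.asarray(age, dtype=float) >= age_cut).astype(float)
    df[f"sex_{other_sex}"] = (np.asarray(list(sex)) == other_sex).astype(float)

    covariates = [c for c in df.columns if c not in ("time", "event")]
    estimable = []
    inestimable = []
    for c in covariates:
        level_events = df.loc[df[c] == 1, "event"].sum()
        if df[c].nunique() < 2 or level_events == 0:
            inestimable.append(c)
        else:
            estimable.append(c)
    if inestimable:
        logger.warning("inestimable terms (no events or no variation): %s",
                       inestimable)
    cph = CoxPHFitter()
    cph.fit(df[["time", "event"] + estimable], duration_col="time",
            event_col="event")
    summary = cph.summary

    rows = {}
    n = len(df)
    counts = labels.value_counts()
    rows["CIN (reference)"] = {"hr": 1.0, "ci_low": np.nan, "ci_high": np.nan,
                               "p": np.nan, "count": int(counts.get("CIN", 0)),
                               "pct": 100.0 * counts.get("CIN", 0) / n}
    for c in covariates:
        term = c
        entry = {"count": int(df[c].sum()), "pct": 100.0 * df[c].mean()}
        if c in estimable:
            row = summary.loc[c]
            entry.update(hr=float(np.exp(row["coef"])),
                         ci_low=float(np.exp(row["coef lower 95%"])),
                         ci_high=float(np.exp(row["coef upper 95%"])),
                         p=float(row["p"]))
        else:
            entry.update(hr=np.nan, ci_low=np.nan, ci_high=np.nan, p=np.nan)
        rows[term] = entry
    terms = pd.DataFrame.from_dict(rows, orient="index")

    # overall p: likelihood-ratio test of the full model against the null
    lrt = cph.log_likelihood_ratio_test()
    overall_p = float(lrt.p_value)
    return SurvivalReport(terms=terms, overall_p=overall_p,
                          reference={"subtype": "CIN",
                                     "age": f"<{age_cut:.0f}",
                                     "sex": reference_sex},
                          classifier=classifier)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(list(pvalues), dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def rank_strategies(survival_reports: dict, metrics_reports: dict,
                    auroc_tolerance: float = 0.02) -> pd.DataFrame:
    """Compare classifiers on overall metrics plus stratification p.

    The selected classifier has the best (smallest) overall stratification
    p-value among classifiers whose overall auROC is within
    ``auroc_tolerance`` of the best performer.  The returned table is sorted
    by classifier name; selection is order-invariant.
    """
    if not metrics_reports:
        raise SurvivalError("no classifiers to rank")
    rows = []
    for name in sorted(metrics_reports):
        m = metrics_reports[name]
        s = survival_reports.get(name)
        rows.append({
            "classifier": name,
            "auROC": float(m.overall["auROC"]),
            "accuracy": float(m.overall["accuracy"]),
            "F1": float(m.overall["F1"]),
            "auPRC": float(m.overall["auPRC"]),
            "stratification_p": np.nan if s is None else s.overall_p,
        })
    table = pd.DataFrame(rows).set_index("classifier")
    best_auroc = table["auROC"].max()
    eligible = table[table["auROC"] >= best_auroc - auroc_tolerance]
    with_p = eligible.dropna(subset=["stratification_p"])
    pool = with_p if len(with_p) else eligible
    selected = (pool["stratification_p"].idxmin()
                if len(with_p) else pool["auROC"].idxmax())
    table["selected"] = table.index == selected
    return table
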