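"""Progression-free survival to pulmonary valve replacement (PVR).

Kaplan-Meier estimates with right censoring, pairwise log-rank tests between
contraction-pattern clusters, and a multivariable Cox proportional-hazards
model (Breslow tie handling) quantifying the phenotype effect while
controlling for LV volume and function.  Estimation is delegated to
lifelines; this module fixes the data contract, covariate scaling, and the
reporting shapes.

Covariate scaling: hazard ratios for continuous covariates are reported per
standard deviation by default (``scale="per_sd"``), because per-unit ratios
on volumes in mL/m^2 are visually indistinguishable from 1; ``per_unit`` is
available when raw-unit interpretation is wanted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceWarning
from lifelines.statistics import logrank_test

__all__ = ["CoxFit", "km_estimate", "logrank_pairwise", "cox_fit",
           "forest_table"]


def _check_records(records: pd.DataFrame, duration_col: str, event_col: str) -> None:
    if (records[duration_col] <= 0).any():
        raise ValueError(f"{duration_col} must be strictly positive")
    ev = set(records[event_col].unique())
    if not ev <= {0, 1}:
        raise ValueError(f"{event_col} must be 0/1, found {sorted(ev)}")


def km_estimate(records: pd.DataFrame, duration_col: str = "time_months",
                event_col: str = "event",
                group_col: str | None = None) -> pd.DataFrame:
    """Product-limit survival estimate S(t) with the at-risk table.

    Returns a tidy frame (group, time, survival, at_risk, events) with one
    row per distinct observed time per group; S(0) = 1 and S is
    non-increasing, dropping only at event times.
    """
    _check_records(records, duration_col, event_col)
    groups = [(None, records)] if group_col is None else list(records.groupby(group_col))
    out = []
    for gname, sub in groups:
        kmf = KaplanMeierFitter()
        kmf.fit(sub[duration_col], sub[event_col])
        et = kmf.event_table
        surv = kmf.survival_function_["KM_estimate"]
        for t in et.index:
            out.append({
                "group": gname, "time": float(t),
                "survival": float(surv.loc[t]),
                "at_risk": int(et.loc[t, "at_risk"]),
                "events": int(et.loc[t, "observed"]),
            })
    df = pd.DataFrame(out)
    if group_col is None:
        df = df.drop(columns=["group"])
    return df


def logrank_pairwise(records: pd.DataFrame, label_col: str = "cluster",
                     duration_col: str = "time_months",
                     event_col: str = "event") -> pd.DataFrame:
    """Two-group log-rank chi-square p-values for every cluster pair.

    Returns a symmetric matrix (NaN diagonal) indexed by cluster label.
    """
    _check_records(records, duration_col, event_col)
    labels = np.sort(records[label_col].unique())
    mat = pd.DataFrame(np.nan, index=labels, columns=labels)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            ga = records[records[label_col] == a]
            gb = records[records[label_col] == b]
            res = logrank_test(ga[duration_col], gb[duration_col],
                               ga[event_col], gb[event_col])
            mat.loc[a, b] = mat.loc[b, a] = float(res.p_value)
    return mat


@dataclass
class CoxFit:
    """Cox proportional-hazards fit: per-covariate effects and fit metadata."""

    summary: pd.DataFrame        # coef, se, hazard_ratio, ci_lower, ci_upper, p
    log_likelihood: float
    n: int
    n_events: int
    scaling: dict[str, float]    # divisor applied to each covariate (1.0 = raw units)
    warnings: list[str]

    def hazard_ratio(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hazard_ratio"])

    def ci(self, covariate: str) -> tuple[float, float]:
        row = self.summary.loc[covariate]
        return float(row["ci_lower"]), float(row["ci_upper"])


def cox_fit(records: pd.DataFrame, covariates: list[str],
            duration_col: str = "time_months", event_col: str = "event",
            scale: str = "per_sd") -> CoxFit:
    """Multivariable Cox model, Breslow tie handling, 95 % Wald intervals.

    Continuous covariates are divided by their sample SD when
    ``scale="per_sd"`` (binary 0/1 covariates are never rescaled);
    ``scale="per_unit"`` keeps raw units.  Collinear covariates raise;
    non-convergence / separation is flagged in ``warnings`` rather than
    raised, with the coefficients still reported.
    """
    if scale not in ("per_sd", "per_unit"):
        raise ValueError(f"unknown covariate scale {scale!r}")
    _check_records(records, duration_col, event_col)
    if records[event_col].sum() < 1:
        raise ValueError("Cox fit needs at least one event")
    X = records[covariates].astype(float)
    # collinearity check on centered covariates
    xc = X - X.mean()
    sv = np.linalg.svd(xc.to_numpy(), compute_uv=False)
    if sv[0] > 0 and sv[-1] / sv[0] < 1e-10:
        raise ValueError("covariates are collinear (singular design)")

    scaling = {}
    Xs = X.copy()
    for c in covariates:
        vals = X[c]
        is_binary = set(np.unique(vals)) <= {0.0, 1.0}
        if scale == "per_sd" and not is_binary:
            s = float(vals.std(ddof=1))
            scaling[c] = s
            Xs[c] = vals / s
        else:
            scaling[c] = 1.0

    df = pd.concat([Xs, records[[duration_col, event_col]]], axis=1)
    fitter = CoxPHFitter()
    warns: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        fitter.fit(df, duration_col=duration_col, event_col=event_col)
        warns = [str(w.message) for w in caught
                 if issubclass(w.category, ConvergenceWarning)]

    s = fitter.summary
    summary = pd.DataFrame({
        "coef": s["coef"],
        "se": s["se(coef)"],
        "hazard_ratio": np.exp(s["coef"]),
        "ci_lower": np.exp(s["coef"] - 1.96 * s["se(coef)"]),
        "ci_upper": np.exp(s["coef"] + 1.96 * s["se(coef)"]),
        "p": s["p"],
    })
    summary.index.name = "covariate"
    return CoxFit(summary=summary, log_likelihood=float(fitter.log_likelihood_),
                  n=len(df), n_events=int(records[event_col].sum()),
                  scaling=scaling, warnings=warns)


def forest_table(fit: CoxFit) -> pd.DataFrame:
    """Hazard-ratio table ordered by descending HR (forest-plot layout)."""
    tab = fit.summary.sort_values("hazard_ratio", ascending=False).reset_index()
    return tab[["covariate", "hazard_ratio", "ci_lower", "ci_upper", "coef", "se", "p"]]
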