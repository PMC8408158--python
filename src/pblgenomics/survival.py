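"""Survival endpoints and inference for the lymphoma cohort.

Two endpoints are analyzed: overall survival (OS, time from diagnosis to
death from any cause) and lymphoma-specific survival (LSS, time from
diagnosis to death due to lymphoma; patients alive or dead from other
causes are censored at their last follow-up / death time). Times are in
months. Estimation and testing delegate to ``lifelines``:

* Kaplan-Meier product-limit curves, read right-continuously (the 2-year
  rate is S(24) evaluated on the step function);
* two-sided log-rank tests between patient subgroups;
* univariate Cox proportional-hazards regression with Efron tie handling
  (month-granularity follow-up produces heavy ties, for which Efron's
  correction is the accurate default).

Survival screens run each biologically preselected condition through a
log-rank (or Cox) test, restricted to CHOP-like-treated patients when
configured, with Benjamini-Hochberg FDR over the condition family and
significance at q < 0.1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test

from .association import SIGNIFICANCE_Q, bh_fdr


class KaplanMeierEstimate:
    """Product-limit survival curve with right-continuous lookup."""

    def __init__(self, times: Sequence[float], events: Sequence[int]):
        t = np.asarray(times, dtype=float)
        e = np.asarray(events, dtype=int)
        if t.size == 0:
            raise ValueError("need at least one subject")
        if np.any(t < 0):
            raise ValueError("negative survival time")
        kmf = KaplanMeierFitter()
        kmf.fit(t, e)
        sf = kmf.survival_function_
        self._fitter = kmf
        self.times = sf.index.to_numpy(dtype=float)
        self.survival = sf.iloc[:, 0].to_numpy(dtype=float)

    def survival_at(self, t: float) -> float:
        """S(t), right-continuous: the value at the last step time <= t."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        if idx < 0:
            return 1.0
        return float(self.survival[idx])

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "survival": self.survival})


def km_estimate(times, events) -> KaplanMeierEstimate:
    """Kaplan-Meier estimate; ties at a time process deaths before censorings."""
    return KaplanMeierEstimate(times, events)


def logrank_test(groups: Sequence[tuple[Sequence[float], Sequence[int]]]):
    """Two-sided log-rank test across k >= 2 groups.

    ``groups`` is a sequence of ``(times, events)`` pairs. Returns
    ``(chi2_statistic, p_value)`` with k-1 degrees of freedom.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    times, events, labels = [], [], []
    for g, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=int)
        if t.size == 0:
            raise ValueError("log-rank group with zero subjects")
        times.append(t)
        events.append(e)
        labels.append(np.full(t.size, g))
    res = multivariate_logrank_test(
        np.concatenate(times), np.concatenate(labels), np.concatenate(events)
    )
    return float(res.test_statistic), float(res.p_value)


@dataclass(frozen=True)
class CoxResult:
    """Univariate Cox fit: HR = exp(coef), Wald p."""

    condition: str
    hazard_ratio: float
    coef: float
    se: float
    p_cox: float
    n: int
    n_affected: int
    unbounded: bool = False  # monotone likelihood / complete separation


def cox_univariate(times, events, covariate, name: str = "x") -> CoxResult:
    """Univariate Cox proportional-hazards regression (Efron ties).

    Raises on a constant covariate. Complete separation (monotone partial
    likelihood) is flagged via ``unbounded=True`` with the diverged HR as
    fitted under lifelines' step-size control.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    x = np.asarray(covariate, dtype=float)
    if np.all(x == x[0]):
        raise ValueError("covariate is constant; Cox model is unidentifiable")
    df = pd.DataFrame({"time": t, "event": e, name: x})
    cph = CoxPHFitter()
    unbounded = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(df, duration_col="time", event_col="event")
        except ConvergenceError:
            unbounded = True
            cph = CoxPHFitter(penalizer=1e-6)
            cph.fit(df, duration_col="time", event_col="event")
    coef = float(cph.params_[name])
    se = float(cph.standard_errors_[name])
    if abs(coef) > 15:  # HR beyond ~3e6: monotone likelihood in practice
        unbounded = True
    return CoxResult(
        condition=name,
        hazard_ratio=float(np.exp(coef)),
        coef=coef,
        se=se,
        p_cox=float(cph.summary.loc[name, "p"]),
        n=len(df),
        n_affected=int((x != 0).sum()),
        unbounded=unbounded,
    )


def _endpoint_columns(endpoint: str) -> tuple[str, str]:
    endpoint = endpoint.lower()
    if endpoint == "os":
        return "os_months", "os_event"
    if endpoint == "lss":
        return "lss_months", "lss_event"
    raise ValueError("endpoint must be 'OS' or 'LSS'")


def run_survival_screen(
    records: pd.DataFrame,
    conditions: Sequence[str],
    endpoint: str = "lss",
    treatment_filter: str | None = "chop_like",
    method: str = "logrank",
) -> pd.DataFrame:
    """Screen preselected binary conditions against a survival endpoint.

    Parameters
    ----------
    records : DataFrame
        One row per patient with ``os_months/os_event/lss_months/lss_event``
        plus the condition columns (binary, NA allowed) and optionally a
        treatment flag column.
    conditions :
        Names of the binary condition columns; declared a priori — the BH
        family is exactly this list (rows for degenerate conditions keep
        their slot with p = NA).
    treatment_filter :
        Name of a binary column restricting the analysis (e.g. CHOP-like
        chemotherapy); None disables the restriction.
    method :
        'logrank' (two-sided, condition present vs absent) or 'cox'
        (univariate, Wald p) — the latter reproduces the exploratory
        hazard-ratio screen.

    Returns
    -------
    DataFrame with one row per condition: n, events, p, BH q, significance
    at q < 0.1 (plus hazard ratios when ``method='cox'``).
    """
    df = records
    if treatment_filter is not None:
        df = df[df[treatment_filter].fillna(0).astype(float) == 1]
    tcol, ecol = _endpoint_columns(endpoint)
    rows = []
    for cond in conditions:
        sub = df[df[cond].notna() & df[tcol].notna()]
        x = sub[cond].astype(float)
        row = {
            "condition": cond,
            "endpoint": endpoint.upper(),
            "n": len(sub),
            "n_affected": int((x == 1).sum()),
            "n_events": int(sub[ecol].sum()),
            "p": np.nan,
            "hazard_ratio": np.nan,
        }
        if 0 < row["n_affected"] < row["n"]:
            if method == "logrank":
                _, p = logrank_test(
                    [
                        (sub.loc[x == 1, tcol], sub.loc[x == 1, ecol]),
                        (sub.loc[x == 0, tcol], sub.loc[x == 0, ecol]),
                    ]
                )
                row["p"] = p
            elif method == "cox":
                res = cox_univariate(sub[tcol], sub[ecol], x, name=cond)
                row["p"] = res.p_cox
                row["hazard_ratio"] = res.hazard_ratio
            else:
                raise ValueError("method must be 'logrank' or 'cox'")
        rows.append(row)
    out = pd.DataFrame(
        rows,
        columns=[
            "condition", "endpoint", "n", "n_affected", "n_events", "p", "hazard_ratio",
        ],
    )
    tested = out["p"].notna()
    out["q_bh"] = np.nan
    if tested.any():
        out.loc[tested, "q_bh"] = bh_fdr(out.loc[tested, "p"].to_numpy())
    out["significant"] = out["q_bh"] < SIGNIFICANCE_Q
    return out
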