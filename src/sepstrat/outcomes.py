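"""Survival statistics for subgroup treatment-effect analysis.

Kaplan-Meier product-limit estimation, the two-group log-rank test
(aggregate hypergeometric variance at tied event times), a closed-form
O/E (Pike) hazard-ratio estimate with Wald confidence interval, and the
stratified tables used to read heterogeneous treatment effects off risk
levels or subphenotypes.  All analyses assume administrative censoring
at a fixed horizon (28 days throughout the package).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SurvivalCurve",
    "LogRankResult",
    "HazardRatioResult",
    "km_estimate",
    "logrank_test",
    "hazard_ratio",
    "stratified_hte_table",
    "risk_level_mortality",
]


@dataclass
class SurvivalCurve:
    times: np.ndarray      # distinct event/censoring times, ascending
    at_risk: np.ndarray    # risk-set size just before each time
    events: np.ndarray     # deaths at each time
    censored: np.ndarray   # censorings at each time
    survival: np.ndarray   # S(t) just after each time

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.times, "at_risk": self.at_risk,
            "events": self.events, "censored": self.censored,
            "survival": self.survival,
        })


@dataclass
class LogRankResult:
    observed_a: float
    expected_a: float
    observed_b: float
    expected_b: float
    statistic: float
    p_value: float
    degenerate: bool = False


@dataclass
class HazardRatioResult:
    hr: float
    ci_low: float
    ci_high: float
    p_value: float
    method: str = "oe"
    degenerate: bool = False


def _check_surv(times, events):
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("empty survival input")
    if (t < 0).any():
        raise ValueError("times must be >= 0")
    if set(np.unique(e)) - {0, 1}:
        raise ValueError("events must be binary 0/1")
    return t, e


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator.

    Censored subjects leave the risk set after their time; with no
    censoring the curve equals 1 - ECDF of the times.
    """
    t, e = _check_surv(times, events)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    uniq, first = np.unique(t, return_index=True)
    n = t.size
    d = np.array([e[t == u].sum() for u in uniq], dtype=float)
    c = np.array([(1 - e[t == u]).sum() for u in uniq], dtype=float)
    at_risk = n - np.concatenate([[0], np.cumsum(d + c)[:-1]])
    surv = np.cumprod(1.0 - d / at_risk)
    return SurvivalCurve(uniq, at_risk, d, c, surv)


def _logrank_components(times_a, events_a, times_b, events_b):
    ta, ea = _check_surv(times_a, events_a)
    tb, eb = _check_surv(times_b, events_b)
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    g = np.concatenate([np.zeros(ta.size, int), np.ones(tb.size, int)])
    event_times = np.unique(t[e == 1])
    O_a = E_a = V = 0.0
    for u in event_times:
        at = t >= u
        Y = at.sum()
        Ya = (at & (g == 0)).sum()
        d = ((t == u) & (e == 1)).sum()
        da = ((t == u) & (e == 1) & (g == 0)).sum()
        O_a += da
        E_a += Ya * d / Y
        if Y > 1:
            V += d * (Ya / Y) * (1 - Ya / Y) * (Y - d) / (Y - 1)
    O = float((e == 1).sum())
    return float(O_a), float(E_a), O - float(O_a), O - float(E_a), float(V)


def logrank_test(times_a, events_a, times_b, events_b) -> LogRankResult:
    """Standard two-group log-rank test (chi-square, df = 1)."""
    O_a, E_a, O_b, E_b, V = _logrank_components(times_a, events_a, times_b, events_b)
    if O_a + O_b == 0 or V <= 0:
        return LogRankResult(O_a, E_a, O_b, E_b, 0.0, 1.0, degenerate=True)
    stat = (O_a - E_a) ** 2 / V
    return LogRankResult(O_a, E_a, O_b, E_b, float(stat),
                         float(stats.chi2.sf(stat, df=1)))


def hazard_ratio(times_a, events_a, times_b, events_b) -> HazardRatioResult:
    """Two-group hazard ratio via the log-rank O/E (Pike) estimator.

    HR = (O_a/E_a)/(O_b/E_b), log-HR variance 1/E_a + 1/E_b, Wald 95%
    CI and two-sided p.  HR < 1 means lower hazard in group a.
    """
    O_a, E_a, O_b, E_b, _ = _logrank_components(times_a, events_a, times_b, events_b)
    if E_a <= 0 or E_b <= 0:
        return HazardRatioResult(np.nan, np.nan, np.nan, np.nan, degenerate=True)
    if O_a == 0 or O_b == 0:
        hr = (O_a / E_a) / (O_b / E_b) if O_b > 0 else np.inf
        return HazardRatioResult(float(hr), np.nan, np.nan, np.nan, degenerate=True)
    hr = (O_a / E_a) / (O_b / E_b)
    se = np.sqrt(1.0 / E_a + 1.0 / E_b)
    z = np.log(hr) / se
    return HazardRatioResult(
        hr=float(hr),
        ci_low=float(np.exp(np.log(hr) - 1.959963984540054 * se)),
        ci_high=float(np.exp(np.log(hr) + 1.959963984540054 * se)),
        p_value=float(2 * stats.norm.sf(abs(z))),
    )


def stratified_hte_table(cohort: pd.DataFrame, strata) -> pd.DataFrame:
    """Treated-vs-control contrasts within each stratum.

    ``strata`` is a row-aligned label sequence (risk levels or
    subphenotype labels).  Each row reports group sizes, 28-day
    mortality, the O/E hazard ratio with 95% CI and Wald p, and the
    log-rank p; strata lacking treated or control patients (or any
    events) are flagged with statistics omitted.
    """
    strata = np.asarray(strata)
    if strata.shape[0] != len(cohort):
        raise ValueError("strata must be row-aligned with the cohort")
    rows = []
    for s in pd.unique(strata):
        sub = cohort.loc[strata == s]
        tr = sub["treated"].to_numpy(dtype=int) == 1
        row: dict = {
            "stratum": s,
            "n_treated": int(tr.sum()),
            "n_control": int((~tr).sum()),
            "flagged": False,
        }
        if tr.sum() == 0 or (~tr).sum() == 0:
            row["flagged"] = True
            rows.append(row)
            continue
        row["mortality_treated"] = float(sub.loc[tr, "died_28d"].mean())
        row["mortality_control"] = float(sub.loc[~tr, "died_28d"].mean())
        hr = hazard_ratio(
            sub.loc[tr, "survival_days"], sub.loc[tr, "event"],
            sub.loc[~tr, "survival_days"], sub.loc[~tr, "event"],
        )
        lr = logrank_test(
            sub.loc[tr, "survival_days"], sub.loc[tr, "event"],
            sub.loc[~tr, "survival_days"], sub.loc[~tr, "event"],
        )
        row.update(
            hr=hr.hr, ci_low=hr.ci_low, ci_high=hr.ci_high, p=hr.p_value,
            logrank_p=lr.p_value, flagged=hr.degenerate,
        )
        rows.append(row)
    return pd.DataFrame(rows).set_index("stratum")


def risk_level_mortality(cohort: pd.DataFrame, scores: pd.DataFrame) -> pd.DataFrame:
    """Mortality by scorecard risk level, with a chi-square test across
    levels and a monotonicity flag (non-decreasing mortality from mild
    to dangerous), mirroring a risk-gradient table."""
    from sepstrat.scorecard import RISK_LEVELS

    if len(scores) != len(cohort):
        raise ValueError("scores must be row-aligned with the cohort")
    levels = scores["risk_level"].to_numpy()
    died = cohort["died_28d"].to_numpy(dtype=int)
    rows = []
    for lvl in RISK_LEVELS:
        mask = levels == lvl
        rows.append({
            "risk_level": lvl,
            "n": int(mask.sum()),
            "proportion": float(mask.mean()),
            "mortality": float(died[mask].mean()) if mask.any() else np.nan,
        })
    table = pd.DataFrame(rows).set_index("risk_level")
    present = table["n"] > 0
    mort = table.loc[present, "mortality"].to_numpy()
    table.attrs["monotone"] = bool(np.all(np.diff(mort) >= 0))
    observed = np.array([
        [((levels == lvl) & (died == 1)).sum(), ((levels == lvl) & (died == 0)).sum()]
        for lvl in RISK_LEVELS if (levels == lvl).any()
    ])
    if observed.shape[0] >= 2 and observed.sum(axis=0).min() > 0:
        chi2, p, _, _ = stats.chi2_contingency(observed)
        table.attrs["chi2"] = float(chi2)
        table.attrs["chi2_p"] = float(p)
    else:
        table.attrs["chi2"] = np.nan
        table.attrs["chi2_p"] = np.nan
    return table
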