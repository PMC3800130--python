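"""Kaplan–Meier curves, log-rank tests, Cox hazard ratios and a genome-wide
per-probe survival screen.

Expression-stratified groups come either from the bimodal mixture fit
(posterior-0.5 threshold) or from per-cohort median splits. The screen
median-splits every probe within each cohort, pools the cohorts, and ranks
probes by pooled two-group log-rank p. The log-rank statistic is computed
directly from the O−E / hypergeometric-variance sums — vectorized across
probes so a multi-thousand-probe screen is a single pass — while KM and Cox
estimation are delegated to lifelines (Efron tie handling, Greenwood
log–log confidence bands).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.utils import median_survival_times
from scipy import stats

from .bimodal import BimodalFit, classify_samples
from .io import ClinicalTable, ExpressionCohort, intersect_probes


class ConvergenceError(RuntimeError):
    pass


@dataclass
class KMCurve:
    time: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median: float                  # NaN when S never reaches 0.5
    median_ci: tuple[float, float]
    n: int
    n_events: int


@dataclass
class SurvivalComparison:
    labels: np.ndarray
    curves: dict[str, KMCurve]
    hazard_ratio: float
    hr_ci: tuple[float, float]
    hr_p: float
    logrank_chi2: float
    logrank_p: float
    n_per_group: dict[str, int]


def km_estimate(times, events) -> KMCurve:
    """Product-limit estimator with Greenwood log–log 95% CI on the median.

    The median is the earliest time with S(t) <= 0.5 and is NaN (flagged,
    not an error) when the curve never reaches 0.5.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    if (times < 0).any():
        raise ValueError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    surv = kmf.survival_function_.iloc[:, 0]
    med = kmf.median_survival_time_
    ci = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    at_risk = kmf.event_table["at_risk"].reindex(surv.index).to_numpy(float)
    return KMCurve(time=surv.index.to_numpy(dtype=float),
                   survival=surv.to_numpy(dtype=float),
                   at_risk=at_risk,
                   median=float(med) if np.isfinite(med) else np.nan,
                   median_ci=(lo, hi), n=int(times.size),
                   n_events=int(events.sum()))


def logrank_test(groups: list[tuple[np.ndarray, np.ndarray]]
                 ) -> tuple[float, float]:
    """k-sample log-rank: O−E sums with hypergeometric variance, chi2(k−1).

    ``groups`` is a list of (times, events) arrays, one per group.
    """
    k = len(groups)
    if k < 2:
        raise ValueError("need >= 2 groups")
    for g, (t, e) in enumerate(groups):
        if np.asarray(t).size == 0:
            raise ValueError(f"group {g} has no subjects")
    times = np.concatenate([np.asarray(t, dtype=float) for t, _ in groups])
    events = np.concatenate([np.asarray(e, dtype=int) for _, e in groups])
    member = np.concatenate([np.full(np.asarray(t).size, g)
                             for g, (t, _) in enumerate(groups)])
    order = np.argsort(times, kind="stable")
    times, events, member = times[order], events[order], member[order]
    event_times = np.unique(times[events == 1])
    o_minus_e = np.zeros(k)
    cov = np.zeros((k, k))
    for t in event_times:
        at_risk = times >= t
        n = at_risk.sum()
        dying = at_risk & (times == t) & (events == 1)
        d = dying.sum()
        n_g = np.array([(at_risk & (member == g)).sum() for g in range(k)])
        d_g = np.array([(dying & (member == g)).sum() for g in range(k)])
        e_g = d * n_g / n
        o_minus_e += d_g - e_g
        if n > 1:
            factor = d * (n - d) / (n - 1)
            for a in range(k):
                for b in range(k):
                    delta = 1.0 if a == b else 0.0
                    cov[a, b] += factor * n_g[a] * (delta * n - n_g[b]) / n ** 2
    # drop one group (singular covariance)
    v = cov[: k - 1, : k - 1]
    u = o_minus_e[: k - 1]
    chi2 = float(u @ np.linalg.pinv(v) @ u)
    p = float(stats.chi2.sf(chi2, df=k - 1))
    return chi2, p


def cox_hazard_ratio(times, events, group_indicator
                     ) -> tuple[float, tuple[float, float], float]:
    """HR (high vs low) from a single-covariate Cox fit, Efron ties.

    Returns (HR, Wald 95% CI, p). ``group_indicator`` is 1/True for the
    high-hazard candidate group.
    """
    df = pd.DataFrame({
        "time": np.asarray(times, dtype=float),
        "event": np.asarray(events, dtype=int),
        "high": np.asarray(group_indicator, dtype=float),
    })
    if df["high"].nunique() < 2:
        raise ValueError("both groups must be non-empty")
    if df["event"].sum() < 1:
        raise ValueError("need at least one observed event")
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # lifelines ConvergenceError and friends
        raise ConvergenceError(f"Cox fit failed: {exc}") from exc
    coef = float(cph.params_["high"])
    if coef == 0.0 and float(cph.standard_errors_["high"]) == 0.0:
        raise ConvergenceError("Cox fit degenerate (zero information)")
    hr = float(np.exp(coef))
    ci = cph.confidence_intervals_.loc["high"]
    return hr, (float(np.exp(ci.iloc[0])), float(np.exp(ci.iloc[1]))), \
        float(cph.summary.loc["high", "p"])


def stratify_by_expression(values, method: str = "median",
                           fit: BimodalFit | None = None,
                           cohort_ids=None) -> np.ndarray:
    """'high'/'low' labels from a mixture fit or a median split.

    Median split: value > median -> high, <= median -> low; when
    ``cohort_ids`` is given the median is taken within each cohort. The
    mixture route delegates to :func:`gliomix.bimodal.classify_samples`.
    """
    values = np.asarray(values, dtype=float)
    if method == "bimodal_fit":
        if fit is None:
            raise ValueError("bimodal_fit stratification needs a fitted model")
        return classify_samples(fit, values)
    if method != "median":
        raise ValueError(f"unknown stratification method {method!r}")
    if values.size < 2:
        raise ValueError("median split needs >= 2 samples")
    labels = np.empty(values.size, dtype=object)
    if cohort_ids is None:
        labels[:] = np.where(values > np.median(values), "high", "low")
    else:
        cohort_ids = np.asarray(cohort_ids)
        for cid in pd.unique(cohort_ids):
            mask = cohort_ids == cid
            med = np.median(values[mask])
            labels[mask] = np.where(values[mask] > med, "high", "low")
    return labels.astype(str)


def compare_survival(times, events, labels) -> SurvivalComparison:
    """Full high-vs-low comparison: KM per group, log-rank, Cox HR."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    labels = np.asarray(labels, dtype=str)
    curves = {}
    for grp in ("high", "low"):
        mask = labels == grp
        if mask.sum():
            curves[grp] = km_estimate(times[mask], events[mask])
    if len(curves) < 2:
        raise ValueError("both 'high' and 'low' groups must be non-empty")
    chi2, p = logrank_test([(times[labels == g], events[labels == g])
                            for g in ("high", "low")])
    hr, ci, hr_p = cox_hazard_ratio(times, events, labels == "high")
    return SurvivalComparison(
        labels=labels, curves=curves, hazard_ratio=hr, hr_ci=ci, hr_p=hr_p,
        logrank_chi2=chi2, logrank_p=p,
        n_per_group={g: int((labels == g).sum()) for g in ("high", "low")})


# ---------------------------------------------------------------------------
# genome-wide screen


def _logrank_two_group_vectorized(times, events, group1
                                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two-group log-rank for many label vectors at once.

    ``group1`` is (n_probes, n_samples) boolean. Returns (chi2, p,
    hr_approx) per probe, where hr_approx = exp((O−E)/V) is the standard
    score-based hazard-ratio approximation.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    order = np.argsort(times, kind="stable")
    t_s, e_s = times[order], events[order]
    z = np.ascontiguousarray(group1[:, order]).astype(np.float64)
    n = t_s.size
    starts = np.flatnonzero(np.r_[True, t_s[1:] != t_s[:-1]])
    n_at_risk = n - starts                                   # (m,)
    d = np.add.reduceat(e_s.astype(np.float64), starts)      # deaths per time
    # group-1 at risk: suffix sums evaluated at tie-group starts
    suffix = np.cumsum(z[:, ::-1], axis=1)[:, ::-1]
    n1 = suffix[:, starts]                                   # (probes, m)
    d1 = np.add.reduceat(z * e_s, starts, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = n1 / n_at_risk
        e1 = d * frac
        var_factor = np.where(n_at_risk > 1,
                              d * (n_at_risk - d) / np.maximum(n_at_risk - 1, 1),
                              0.0)
        v = var_factor * frac * (1.0 - frac)
    keep = d > 0
    o_minus_e = (d1[:, keep] - e1[:, keep]).sum(axis=1)
    v_sum = v[:, keep].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(v_sum > 0, o_minus_e ** 2 / v_sum, 0.0)
        hr = np.where(v_sum > 0, np.exp(o_minus_e / v_sum), 1.0)
    p = stats.chi2.sf(chi2, df=1)
    return chi2, p, hr


@dataclass
class ScreenResult:
    """Ranked per-probe survival screen."""

    table: pd.DataFrame  # probe_id, chi2, p, hr_approx, rank

    def rank_of(self, probe_id: str) -> int:
        row = self.table.loc[self.table["probe_id"] == probe_id, "rank"]
        if row.empty:
            raise KeyError(f"probe {probe_id!r} not in screen")
        return int(row.iloc[0])

    def percentile_of(self, probe_id: str) -> float:
        return 100.0 * self.rank_of(probe_id) / len(self.table)


def genome_wide_screen(cohorts: list[tuple[ExpressionCohort, ClinicalTable]],
                       probes: list[str] | None = None,
                       chunk_size: int = 2000) -> ScreenResult:
    """Per-probe pooled survival screen across cohorts.

    Every probe is median-split within each cohort; the resulting high/low
    labels are pooled over cohorts and tested with an (unstratified)
    two-group log-rank. Probes are ranked by p ascending, ties broken by
    |approximate HR − 1| descending, then probe_id. Samples without
    survival data are dropped with their cohort.
    """
    if probes is None:
        probes = intersect_probes([c for c, _ in cohorts])
    if not probes:
        raise ValueError("empty probe intersection")
    label_parts, time_parts, event_parts = [], [], []
    for expr, clin in cohorts:
        meta = clin.for_samples(expr.sample_ids)
        keep = meta["os_months"].notna() & meta["event"].notna()
        if keep.sum() == 0:
            continue
        m = expr.matrix.loc[probes].to_numpy(dtype=float)[:, keep.to_numpy()]
        med = np.median(m, axis=1, keepdims=True)
        label_parts.append(m > med)
        time_parts.append(meta.loc[keep, "os_months"].to_numpy(dtype=float))
        event_parts.append(meta.loc[keep, "event"].to_numpy(dtype=int))
    if not time_parts:
        raise ValueError("no samples with survival data")
    times = np.concatenate(time_parts)
    events = np.concatenate(event_parts)
    group1 = np.concatenate(label_parts, axis=1)

    chi2 = np.empty(len(probes))
    p = np.empty(len(probes))
    hr = np.empty(len(probes))
    for lo in range(0, len(probes), chunk_size):
        hi = min(lo + chunk_size, len(probes))
        chi2[lo:hi], p[lo:hi], hr[lo:hi] = _logrank_two_group_vectorized(
            times, events, group1[lo:hi])
    table = pd.DataFrame({"probe_id": probes, "chi2": chi2, "p": p,
                          "hr_approx": hr})
    table = table.sort_values(
        by=["p", "hr_approx", "probe_id"],
        key=lambda col: -np.abs(col - 1.0) if col.name == "hr_approx" else col,
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return ScreenResult(table=table)
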