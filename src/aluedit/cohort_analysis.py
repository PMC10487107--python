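"""Patient-level statistics: AEI/survival correlation, dichotomized
Kaplan-Meier with log-rank and median survival, phase t-tests, and the
covariate correlation/group-difference panel.

Conventions (recorded because the source analysis leaves them open):

* Spearman p-values use the large-sample Gaussian approximation
  z = r * sqrt(n - 1), two-sided; a t-approximation is available via
  ``approximation="t"``.
* Records with AEI exactly at the cutoff go to the high group by default.
* Unpaired comparisons use the Welch (unequal-variance) t-test.
* Zero-variance t-tests: p = 1 when the mean difference is 0, else p = 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class CohortRecord:
    """One patient-phase row of the cohort table."""

    patient_id: str
    phase: str  # "pre" or "on"
    survival_weeks: float
    event: int  # 1 = death observed, 0 = censored
    aei: float | None = None
    adar_expr: float | None = None
    gzma_expr: float | None = None
    prf1_expr: float | None = None
    mutation_load: float | None = None
    neoantigen_load: float | None = None
    neopeptide_load: float | None = None

    def __post_init__(self) -> None:
        if self.survival_weeks < 0:
            raise ValidationError("survival_weeks must be nonnegative")
        if self.event not in (0, 1):
            raise ValidationError("event must be 0 or 1")

    @property
    def cytolytic_score(self) -> float | None:
        if self.gzma_expr is None or self.prf1_expr is None:
            return None
        from .editing_index import cytolytic_score
        return cytolytic_score(self.gzma_expr, self.prf1_expr)


@dataclass(frozen=True)
class AnalysisParams:
    aei_cutoff: float = 50.0
    alpha: float = 0.05
    equal_to_cutoff_goes: str = "high"

    def __post_init__(self) -> None:
        if self.aei_cutoff <= 0:
            raise ValidationError("aei_cutoff must be positive")
        if self.equal_to_cutoff_goes not in ("high", "low"):
            raise ValidationError("equal_to_cutoff_goes must be high/low")


@dataclass
class KMCurve:
    """Product-limit survival estimate.

    ``times`` are the distinct event times (steps); ``survival[i]`` is
    S(t) just after ``times[i]``.  ``at_risk`` and ``events`` give the
    risk-set size and event count at each step.
    """

    times: list[float] = field(default_factory=list)
    survival: list[float] = field(default_factory=list)
    at_risk: list[int] = field(default_factory=list)
    events: list[int] = field(default_factory=list)

    def survival_at(self, t: float) -> float:
        s = 1.0
        for time, surv in zip(self.times, self.survival):
            if time <= t:
                s = surv
            else:
                break
        return s


# ---------------------------------------------------------------------------
# Correlation


def spearman_gaussian(
    x_values: Sequence[float],
    y_values: Sequence[float],
    approximation: str = "gaussian",
) -> tuple[float, float]:
    """Spearman r with a Gaussian-approximation two-sided p-value.

    r is the Pearson correlation of average ranks (ties allowed);
    p = 2 * (1 - Phi(|r| * sqrt(n - 1))).
    """
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y must be paired")
    n = len(x)
    if n < 4:
        raise ValidationError("need at least 4 paired observations")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValidationError("correlation undefined for a constant vector")
    r = float(np.corrcoef(rx, ry)[0, 1])
    if approximation == "gaussian":
        z = abs(r) * math.sqrt(n - 1)
        p = 2.0 * stats.norm.sf(z)
    elif approximation == "t":
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t = abs(r) * math.sqrt((n - 2) / (1.0 - r * r))
            p = 2.0 * stats.t.sf(t, df=n - 2)
    else:
        raise ValidationError(f"unknown approximation {approximation!r}")
    return r, float(min(p, 1.0))


# ---------------------------------------------------------------------------
# Survival


def dichotomize_aei(
    records: Sequence[CohortRecord], params: AnalysisParams = AnalysisParams()
) -> tuple[list[CohortRecord], list[CohortRecord]]:
    """Partition records into (low_group, high_group) by the AEI cutoff."""
    if not records:
        raise ValidationError("cannot dichotomize an empty cohort")
    low, high = [], []
    for rec in records:
        if rec.aei is None:
            raise ValidationError(f"record {rec.patient_id} has no AEI")
        if rec.aei > params.aei_cutoff:
            high.append(rec)
        elif rec.aei < params.aei_cutoff:
            low.append(rec)
        elif params.equal_to_cutoff_goes == "high":
            high.append(rec)
        else:
            low.append(rec)
    if not low or not high:
        logger.warning("dichotomize_aei: one group is empty (low=%d, high=%d)",
                       len(low), len(high))
    logger.info("dichotomize_aei: cutoff %g -> low %d, high %d",
                params.aei_cutoff, len(low), len(high))
    return low, high


def kaplan_meier(
    times: Sequence[float], events: Sequence[int]
) -> KMCurve:
    """Product-limit estimator; censoring shrinks the risk set stepless."""
    times = [float(t) for t in times]
    events = [int(e) for e in events]
    if len(times) != len(events):
        raise ValidationError("times and events must be paired")
    if any(t < 0 for t in times):
        raise ValidationError("times must be nonnegative")
    if any(e not in (0, 1) for e in events):
        raise ValidationError("events must be 0/1")
    order = sorted(range(len(times)), key=lambda i: (times[i], -events[i]))
    curve = KMCurve()
    n_at_risk = len(times)
    s = 1.0
    i = 0
    while i < len(order):
        t = times[order[i]]
        d = 0
        c = 0
        while i < len(order) and times[order[i]] == t:
            if events[order[i]] == 1:
                d += 1
            else:
                c += 1
            i += 1
        if d > 0:
            s *= 1.0 - d / n_at_risk
            curve.times.append(t)
            curve.survival.append(s)
            curve.at_risk.append(n_at_risk)
            curve.events.append(d)
        n_at_risk -= d + c
    return curve


def logrank_test(
    group_a: tuple[Sequence[float], Sequence[int]],
    group_b: tuple[Sequence[float], Sequence[int]],
) -> tuple[float, float, int]:
    """Mantel-Cox test: chi-square, p, and df (always 1).

    Accumulates observed-vs-expected events for group A with the
    hypergeometric variance over the pooled distinct event times.
    """
    ta, ea = [list(map(float, group_a[0])), list(map(int, group_a[1]))]
    tb, eb = [list(map(float, group_b[0])), list(map(int, group_b[1]))]
    if not ta or not tb:
        raise ValidationError("both groups need at least one observation")
    if sum(ea) + sum(eb) == 0:
        raise ValidationError("log-rank needs at least one event")
    event_times = sorted({t for t, e in zip(ta + tb, ea + eb) if e == 1})
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        n_a = sum(1 for x in ta if x >= t)
        n_b = sum(1 for x in tb if x >= t)
        n = n_a + n_b
        d_a = sum(1 for x, e in zip(ta, ea) if x == t and e == 1)
        d_b = sum(1 for x, e in zip(tb, eb) if x == t and e == 1)
        d = d_a + d_b
        if n == 0 or d == 0:
            continue
        expected_a = d * n_a / n
        o_minus_e += d_a - expected_a
        if n > 1:
            var += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
    if var == 0.0:
        return 0.0, 1.0, 1
    chi2 = o_minus_e * o_minus_e / var
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p, 1


def median_survival(curve: KMCurve) -> float | None:
    """Smallest time with S(t) <= 0.5, or None when never reached."""
    for t, s in zip(curve.times, curve.survival):
        if s <= 0.5:
            return t
    return None


# ---------------------------------------------------------------------------
# t-tests


def _guarded_p(t_stat: float, p: float, mean_diff: float) -> float:
    if math.isnan(p):  # zero-variance degenerate case
        return 1.0 if mean_diff == 0 else 0.0
    return p


def phase_comparison(
    pre_records: Sequence[CohortRecord],
    on_records: Sequence[CohortRecord],
) -> dict:
    """Pre- vs on-therapy AEI comparison: Welch unpaired and paired t-tests.

    The paired test matches records by patient_id and needs >= 2 complete
    pairs.  Sample SDs use ddof=1.
    """
    pre_aei = np.array([r.aei for r in pre_records], dtype=float)
    on_aei = np.array([r.aei for r in on_records], dtype=float)
    if np.isnan(pre_aei).any() or np.isnan(on_aei).any():
        raise ValidationError("all records need an AEI")
    with np.errstate(invalid="ignore", divide="ignore"):
        t_u, p_u = stats.ttest_ind(pre_aei, on_aei, equal_var=False)
    p_u = _guarded_p(t_u, float(p_u), float(pre_aei.mean() - on_aei.mean()))

    on_by_id = {r.patient_id: r for r in on_records}
    pairs = [(r.aei, on_by_id[r.patient_id].aei)
             for r in pre_records if r.patient_id in on_by_id]
    if len(pairs) < 2:
        raise ValidationError("paired test needs >= 2 complete pairs")
    diffs = np.array([a - b for a, b in pairs], dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_p, p_p = stats.ttest_rel([a for a, _ in pairs], [b for _, b in pairs])
    p_p = _guarded_p(t_p, float(p_p), float(diffs.mean()))

    return {
        "unpaired_p": p_u,
        "paired_p": p_p,
        "n_pairs": len(pairs),
        "pre_mean": float(pre_aei.mean()),
        "pre_sd": float(pre_aei.std(ddof=1)) if len(pre_aei) > 1 else float("nan"),
        "on_mean": float(on_aei.mean()),
        "on_sd": float(on_aei.std(ddof=1)) if len(on_aei) > 1 else float("nan"),
    }


# ---------------------------------------------------------------------------
# Covariate panel

COVARIATES = ["mutation_load", "neoantigen_load", "neopeptide_load",
              "cytolytic_score"]


def _covariate_value(rec: CohortRecord, name: str) -> float | None:
    if name == "cytolytic_score":
        return rec.cytolytic_score
    return getattr(rec, name)


def covariate_panel(
    records: Sequence[CohortRecord],
    params: AnalysisParams = AnalysisParams(),
    covariates: Sequence[str] = tuple(COVARIATES),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Covariate-vs-AEI panel, pairwise-complete.

    Panel A: Spearman r (Gaussian-approximation p) of each covariate
    against the AEI.  Panel B: low- vs high-AEI group mean +/- SD with a
    Welch t-test p.  Rows with < 4 complete pairs (A) or < 2 per group (B)
    are flagged insufficient-data.
    """
    rows_a, rows_b = [], []
    low, high = dichotomize_aei(records, params)
    for name in covariates:
        pairs = [(rec.aei, _covariate_value(rec, name)) for rec in records
                 if rec.aei is not None and _covariate_value(rec, name) is not None]
        row_a = {"covariate": name, "n": len(pairs), "spearman_r": float("nan"),
                 "p": float("nan"), "significant": "", "note": ""}
        if len(pairs) < 4:
            row_a["note"] = "insufficient-data"
        else:
            x, y = zip(*pairs)
            try:
                r, p = spearman_gaussian(x, y)
                row_a.update(spearman_r=r, p=p,
                             significant="*" if p < params.alpha else "ns")
            except ValidationError:
                row_a["note"] = "constant-covariate"
        rows_a.append(row_a)

        lo_vals = [v for rec in low if (v := _covariate_value(rec, name)) is not None]
        hi_vals = [v for rec in high if (v := _covariate_value(rec, name)) is not None]
        row_b = {"covariate": name,
                 "low_n": len(lo_vals), "high_n": len(hi_vals),
                 "low_mean": float(np.mean(lo_vals)) if lo_vals else float("nan"),
                 "low_sd": float(np.std(lo_vals, ddof=1)) if len(lo_vals) > 1 else float("nan"),
                 "high_mean": float(np.mean(hi_vals)) if hi_vals else float("nan"),
                 "high_sd": float(np.std(hi_vals, ddof=1)) if len(hi_vals) > 1 else float("nan"),
                 "p": float("nan"), "significant": "", "note": ""}
        if len(lo_vals) < 2 or len(hi_vals) < 2:
            row_b["note"] = "insufficient-data"
        else:
            import warnings
            with np.errstate(invalid="ignore", divide="ignore"), \
                    warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                t_stat, p = stats.ttest_ind(lo_vals, hi_vals, equal_var=False)
            p = _guarded_p(t_stat, float(p),
                           float(np.mean(lo_vals) - np.mean(hi_vals)))
            row_b.update(p=p, significant="*" if p < params.alpha else "ns")
        rows_b.append(row_b)
    return pd.DataFrame(rows_a), pd.DataFrame(rows_b)


# ---------------------------------------------------------------------------
# Full report


def analyze_cohort(
    records: Sequence[CohortRecord],
    params: AnalysisParams = AnalysisParams(),
) -> dict:
    """Run the full cohort panel on pre/on records and return a report dict."""
    pre = [r for r in records if r.phase == "pre"]
    on = [r for r in records if r.phase == "on"]
    if not pre:
        raise ValidationError("cohort has no pre-therapy records")
    report: dict = {"params": {
        "aei_cutoff": params.aei_cutoff, "alpha": params.alpha,
        "equal_to_cutoff_goes": params.equal_to_cutoff_goes,
    }}

    r, p = spearman_gaussian([x.aei for x in pre], [x.survival_weeks for x in pre])
    report["aei_vs_survival_pre"] = {"spearman_r": r, "p": p, "n": len(pre)}
    if len(on) >= 4:
        r, p = spearman_gaussian([x.aei for x in on], [x.survival_weeks for x in on])
        report["aei_vs_survival_on"] = {"spearman_r": r, "p": p, "n": len(on)}

    adar = [(x.aei, x.adar_expr, x.survival_weeks) for x in pre if x.adar_expr is not None]
    if len(adar) >= 4:
        r, p = spearman_gaussian([a for a, _, _ in adar], [e for _, e, _ in adar])
        report["adar_vs_aei_pre"] = {"spearman_r": r, "p": p, "n": len(adar)}
        r, p = spearman_gaussian([e for _, e, _ in adar], [s for _, _, s in adar])
        report["adar_vs_survival_pre"] = {"spearman_r": r, "p": p, "n": len(adar)}

    low, high = dichotomize_aei(pre, params)
    report["groups"] = {"low_n": len(low), "high_n": len(high)}
    km_low = kaplan_meier([r_.survival_weeks for r_ in low], [r_.event for r_ in low]) if low else KMCurve()
    km_high = kaplan_meier([r_.survival_weeks for r_ in high], [r_.event for r_ in high]) if high else KMCurve()
    report["km_low"] = km_low
    report["km_high"] = km_high
    report["median_survival_low"] = median_survival(km_low) if low else None
    report["median_survival_high"] = median_survival(km_high) if high else None
    if low and high and (sum(r_.event for r_ in low) + sum(r_.event for r_ in high)) > 0:
        chi2, p, df = logrank_test(
            ([r_.survival_weeks for r_ in low], [r_.event for r_ in low]),
            ([r_.survival_weeks for r_ in high], [r_.event for r_ in high]),
        )
        report["logrank"] = {"chi_square": chi2, "p": p, "df": df}

    if pre and on:
        try:
            report["phase_comparison"] = phase_comparison(pre, on)
        except ValidationError as exc:
            report["phase_comparison"] = {"error": str(exc)}

    panel_a, panel_b = covariate_panel(pre, params)
    report["covariate_panel_a"] = panel_a
    report["covariate_panel_b"] = panel_b
    return report
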