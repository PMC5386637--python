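"""Core survival statistics: Kaplan-Meier curves, log-rank tests, median
dichotomization and Cox proportional-hazards fits.

These are the primitives of the biomarker screen: every feature is
dichotomized at its median and the two groups compared by the Mantel-Haenszel
log-rank test.  The log-rank statistic is implemented here in vectorised form
(:func:`logrank_many`) because a screening run evaluates it tens of thousands
of times; the scalar wrapper :func:`logrank_test` and :func:`km_estimate` are
cross-checked against lifelines in the test suite.

Conventions
-----------
* Median for even n is the mean of the two central order statistics; ties at
  the median are assigned to the "low" group.
* Censored observations tied with a death time remain at risk through that
  death time (the standard product-limit convention).
* Cox fits delegate to :class:`lifelines.CoxPHFitter` (Efron ties, Breslow
  baseline hazard); Wald confidence intervals and p-values are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import ConvergenceError, ValidationError

__all__ = [
    "KMCurve",
    "LogRankResult",
    "CoxFit",
    "dichotomize_by_median",
    "km_estimate",
    "logrank_test",
    "logrank_many",
    "cox_fit",
    "encode_clinical",
]


def _as_time_event(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if time.ndim != 1 or event.shape != time.shape:
        raise ValidationError("time and event must be 1-d arrays of equal length")
    if time.size == 0:
        raise ValidationError("need at least one survival record")
    if np.any(time <= 0):
        raise ValidationError("survival times must be positive")
    if not np.isin(event, (0, 1)).all():
        raise ValidationError("event indicators must be 0 (censored) or 1 (death)")
    return time, event.astype(np.int64)


def dichotomize_by_median(values) -> tuple[np.ndarray, bool]:
    """Split samples at the median of ``values``.

    Returns ``(high, degenerate)`` where ``high`` is a boolean array, True for
    samples strictly above the median (ties at the median go to "low"), and
    ``degenerate`` is True when one group is empty (e.g. all values equal).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise ValidationError("need at least two values to dichotomize")
    high = values > np.median(values)
    degenerate = bool(high.all() or not high.any())
    return high, degenerate


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate evaluated at the distinct death times."""

    event_times: np.ndarray  # increasing times with >= 1 death
    survival: np.ndarray     # S(t) just after each event time
    at_risk: np.ndarray      # number at risk at each event time
    n_deaths: np.ndarray     # deaths at each event time

    def survival_at(self, times, side: str = "right") -> np.ndarray:
        """Evaluate the step function S(t).

        ``side="right"`` gives S(t) (value after any deaths at exactly t);
        ``side="left"`` gives the left limit S(t-).
        """
        times = np.atleast_1d(np.asarray(times, dtype=float))
        idx = np.searchsorted(self.event_times, times, side=("right" if side == "right" else "left"))
        out = np.ones_like(times, dtype=float)
        nz = idx > 0
        out[nz] = self.survival[idx[nz] - 1]
        return out


def km_estimate(time, event) -> KMCurve:
    """Kaplan-Meier product-limit estimator of the survival function."""
    time, event = _as_time_event(time, event)
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    n = t.size
    starts = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])
    deaths = np.add.reduceat(e, starts)
    at_risk = n - starts
    keep = deaths > 0
    d, r = deaths[keep], at_risk[keep]
    surv = np.cumprod(1.0 - d / r)
    return KMCurve(event_times=t[starts][keep], survival=surv, at_risk=r, n_deaths=d)


@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    p_value: float
    observed: tuple[float, float]   # observed deaths in (group a, group b)
    expected: tuple[float, float]   # expected deaths under H0


def logrank_many(high: np.ndarray, time, event):
    """Mantel-Haenszel log-rank test for many median splits of one cohort.

    Parameters
    ----------
    high
        Boolean matrix, shape ``(n_features, n_samples)``; ``high[f, i]`` says
        sample *i* falls in the "high" group for feature *f*.
    time, event
        Shared survival outcome for the ``n_samples`` columns.

    Returns
    -------
    statistic, p_value, degenerate
        Arrays of length ``n_features``.  ``degenerate`` marks features whose
        split left a group empty (statistic 0, p 1) or with zero variance.
    """
    time, event = _as_time_event(time, event)
    high = np.asarray(high, dtype=bool)
    if high.ndim == 1:
        high = high[None, :]
    if high.shape[1] != time.size:
        raise ValidationError("group matrix and survival arrays disagree on sample count")

    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    h = high[:, order]
    n = t.size

    starts = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])
    deaths = np.add.reduceat(e, starts)             # total deaths per distinct time
    at_risk = (n - starts).astype(float)

    # at-risk count in the high group at each distinct time = suffix sum
    suffix = np.cumsum(h[:, ::-1], axis=1)[:, ::-1].astype(float)
    n1 = suffix[:, starts]
    d1 = np.add.reduceat(h & e.astype(bool), starts, axis=1).astype(float)

    ev = deaths > 0
    d = deaths[ev].astype(float)
    r = at_risk[ev]
    n1, d1 = n1[:, ev], d1[:, ev]

    frac = n1 / r
    expected = (d * frac).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        var_t = d * frac * (1.0 - frac) * (r - d) / (r - 1.0)
    var_t[:, r <= 1.0] = 0.0
    variance = var_t.sum(axis=1)
    observed = d1.sum(axis=1)

    degenerate = high.all(axis=1) | ~high.any(axis=1)
    ok = (variance > 0) & ~degenerate
    statistic = np.zeros(high.shape[0])
    statistic[ok] = (observed[ok] - expected[ok]) ** 2 / variance[ok]
    p_value = np.where(ok, stats.chi2.sf(statistic, 1), 1.0)
    degenerate |= variance <= 0
    return statistic, p_value, degenerate


def logrank_test(time_a, event_a, time_b, event_b) -> LogRankResult:
    """Two-sample log-rank test (1-df chi-square)."""
    time_a, event_a = _as_time_event(time_a, event_a)
    time_b, event_b = _as_time_event(time_b, event_b)
    time = np.r_[time_a, time_b]
    event = np.r_[event_a, event_b]
    in_a = np.r_[np.ones_like(time_a, bool), np.zeros_like(time_b, bool)]
    stat, p, degen = logrank_many(in_a[None, :], time, event)

    # per-group observed/expected bookkeeping (for reporting only)
    order = np.argsort(time, kind="stable")
    t, e, a = time[order], event[order], in_a[order]
    starts = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])
    deaths = np.add.reduceat(e, starts).astype(float)
    at_risk = (t.size - starts).astype(float)
    na = np.cumsum(a[::-1])[::-1][starts].astype(float)
    da = np.add.reduceat(a & e.astype(bool), starts).astype(float)
    ea = (deaths * na / at_risk).sum()
    total = deaths.sum()
    if total == 0:
        return LogRankResult(0.0, 1.0, (0.0, 0.0), (0.0, 0.0))
    return LogRankResult(
        statistic=float(stat[0]),
        p_value=float(p[0]),
        observed=(float(da.sum()), float(total - da.sum())),
        expected=(float(ea), float(total - ea)),
    )


@dataclass
class CoxFit:
    """Result of a Cox proportional-hazards fit.

    ``summary`` has one row per covariate with columns ``hazard_ratio``,
    ``ci95_low``, ``ci95_high``, ``coef``, ``se`` and ``p_value`` (Wald).
    """

    summary: pd.DataFrame
    log_likelihood: float
    log_likelihood_null: float
    model: object = field(repr=False)

    def predict_risk(self, design: pd.DataFrame, horizon: float) -> np.ndarray:
        """Probability of death by ``horizon`` per sample, via the Breslow
        baseline cumulative hazard."""
        surv = self.model.predict_survival_function(design, times=[horizon])
        return 1.0 - surv.iloc[0].to_numpy()


def cox_fit(design: pd.DataFrame, time, event) -> CoxFit:
    """Maximize the Cox partial likelihood for the covariates in ``design``.

    Raises :class:`ConvergenceError` on non-convergence or separation instead
    of returning a silently unreliable fit.
    """
    time, event = _as_time_event(time, event)
    if not isinstance(design, pd.DataFrame):
        design = pd.DataFrame(np.asarray(design))
    if design.shape[0] != time.size:
        raise ValidationError("design and survival arrays disagree on sample count")
    if design.shape[1] == 0:
        raise ValidationError("design matrix has no covariates")
    values = design.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValidationError("covariates must be numeric after coding")
    if np.any(values.std(axis=0) == 0):
        raise ValidationError("design contains a constant column")

    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError as LLConvergenceError
    from lifelines.exceptions import ConvergenceWarning

    df = design.copy()
    df["__time"] = time
    df["__event"] = event
    cph = CoxPHFitter(baseline_estimation_method="breslow")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            cph.fit(df, duration_col="__time", event_col="__event")
    except (LLConvergenceError, ConvergenceWarning, np.linalg.LinAlgError) as exc:
        raise ConvergenceError(f"Cox fit failed: {exc}") from exc

    s = cph.summary
    summary = pd.DataFrame(
        {
            "coef": s["coef"],
            "se": s["se(coef)"],
            "hazard_ratio": s["exp(coef)"],
            "ci95_low": s["exp(coef) lower 95%"],
            "ci95_high": s["exp(coef) upper 95%"],
            "p_value": s["p"],
        }
    )
    return CoxFit(
        summary=summary,
        log_likelihood=float(cph.log_likelihood_),
        log_likelihood_null=float(cph._ll_null_),
        model=cph,
    )


STAGES = ("I", "II", "III", "IV")
GRADES = (1, 2, 3, 4)


def encode_clinical(clinical: pd.DataFrame, marker_high=None) -> pd.DataFrame:
    """Code a clinical table for Cox regression.

    Stage indicators contrast II/III/IV against stage I; grade indicators
    contrast 3 and 4 against the pooled 1&2 reference; age enters per year;
    sex is a male indicator.  ``marker_high`` (optional boolean per sample)
    adds a binary marker covariate.
    """
    required = {"stage", "grade", "age", "sex"}
    missing = required - set(clinical.columns)
    if missing:
        raise ValidationError(f"clinical table missing columns: {sorted(missing)}")
    stage = clinical["stage"].astype(str)
    if not stage.isin(STAGES).all():
        raise ValidationError("stage must be one of I, II, III, IV")
    grade = clinical["grade"].astype(int)
    if not grade.isin(GRADES).all():
        raise ValidationError("grade must be in 1..4")
    design = pd.DataFrame(index=clinical.index)
    design["stage_II"] = (stage == "II").astype(float)
    design["stage_III"] = (stage == "III").astype(float)
    design["stage_IV"] = (stage == "IV").astype(float)
    design["grade_3"] = (grade == 3).astype(float)
    design["grade_4"] = (grade == 4).astype(float)
    design["age"] = clinical["age"].astype(float)
    design["sex_male"] = (clinical["sex"].astype(str) == "M").astype(float)
    if marker_high is not None:
        design["marker_high"] = np.asarray(marker_high, dtype=float)
    return design
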