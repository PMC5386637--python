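"""Clinical-utility evaluation of a candidate prognostic marker: does it add
predictive value beyond tumor stage and grade?

Three complementary views:

* :func:`survival_roc` — cumulative/dynamic time-dependent ROC at a horizon,
  with inverse-probability-of-censoring weights (IPCW) from a Kaplan-Meier
  estimate of the censoring distribution; with no censoring it reduces
  exactly to the plain binary AUC of (event by horizon) against the score.
* :func:`decision_curve` — net benefit of treating patients whose predicted
  horizon risk exceeds a threshold probability, against treat-all and
  treat-none references; event rates within the treated subset come from a
  Kaplan-Meier estimate so censored follow-up is handled.
* :func:`chaid_tree` — CHAID recursive partitioning (Kass 1980): per node,
  each predictor's categories are pairwise-merged until all remaining pairs
  differ significantly, the predictor with the smallest Bonferroni-adjusted
  chi-square p is chosen, and the node splits if that p clears the split
  threshold and children meet the size floor.

:func:`compare_models` composes Cox fits (risk at horizon via the Breslow
baseline hazard) with the ROC and decision-curve evaluations for a set of
nested covariate specifications.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import DegenerateError, ValidationError
from .survival import cox_fit, encode_clinical, km_estimate

__all__ = [
    "RocResult",
    "DecisionCurve",
    "ChaidNode",
    "survival_roc",
    "decision_curve",
    "chaid_tree",
    "compare_models",
    "DEFAULT_HORIZON_DAYS",
]

#: default risk-evaluation horizon: 5 years of overall survival
DEFAULT_HORIZON_DAYS = 5 * 365.25


@dataclass(frozen=True)
class RocResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray  # score cutoffs, descending; positive = score >= cutoff


@dataclass(frozen=True)
class DecisionCurve:
    thresholds: np.ndarray
    net_benefit: np.ndarray
    treat_all: np.ndarray
    treat_none: np.ndarray  # identically zero, kept for plotting symmetry


def _ipcw_weights(time, event, horizon):
    """Case/control IPCW weights for the cumulative/dynamic ROC."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    is_case = (event == 1) & (time <= horizon)
    is_control = time > horizon
    if event.all():
        g_case = np.ones(is_case.sum())
        g_ctrl = 1.0
    else:
        cens_km = km_estimate(time, 1 - event)
        g_case = cens_km.survival_at(time[is_case], side="left")
        g_ctrl = float(cens_km.survival_at([horizon], side="right")[0])
    if np.any(g_case <= 0) or g_ctrl <= 0:
        raise DegenerateError("censoring survival reaches zero before the horizon")
    w = np.zeros(time.size)
    w[is_case] = 1.0 / g_case
    w[is_control] = 1.0 / g_ctrl
    return w, is_case, is_control


def survival_roc(scores, time, event, horizon: float) -> RocResult:
    """Time-dependent ROC: cases are deaths by ``horizon``, controls are
    samples event-free at ``horizon``; censored-before-horizon samples drop
    out via zero IPCW weight.  AUC by the trapezoid rule."""
    scores = np.asarray(scores, dtype=float)
    time = np.asarray(time, dtype=float)
    if scores.shape != time.shape:
        raise ValidationError("scores and survival arrays disagree on sample count")
    w, is_case, is_control = _ipcw_weights(time, event, horizon)
    if not is_case.any() or not is_control.any():
        raise DegenerateError("need at least one case and one control at the horizon")

    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    case_w = np.where(is_case, w, 0.0)[order]
    ctrl_w = np.where(is_control, w, 0.0)[order]
    # group tied scores so ties contribute diagonal ROC segments
    boundaries = np.flatnonzero(np.r_[True, s[1:] != s[:-1]])
    cw = np.add.reduceat(case_w, boundaries)
    xw = np.add.reduceat(ctrl_w, boundaries)
    tpr = np.r_[0.0, np.cumsum(cw)] / case_w.sum()
    fpr = np.r_[0.0, np.cumsum(xw)] / ctrl_w.sum()
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(auc=auc, fpr=fpr, tpr=tpr, thresholds=s[boundaries])


def decision_curve(risks, time, event, horizon: float, thresholds) -> DecisionCurve:
    """Net benefit of acting on ``risk >= p_t`` across threshold
    probabilities ``p_t``:

    ``NB(p_t) = P(pos) * (1 - S_pos(h)) - P(pos) * S_pos(h) * p_t / (1 - p_t)``

    where ``S_pos(h)`` is the Kaplan-Meier survival at the horizon within
    the treated (positive) subset."""
    risks = np.asarray(risks, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any((risks < 0) | (risks > 1)):
        raise ValidationError("risks must lie in [0, 1]")
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValidationError("thresholds must lie strictly inside (0, 1)")

    def subset_nb(mask, p_t):
        n_pos = mask.sum()
        if n_pos == 0:
            return 0.0
        p_pos = n_pos / mask.size
        s_pos = float(km_estimate(time[mask], event[mask]).survival_at([horizon])[0])
        event_rate = 1.0 - s_pos
        return p_pos * event_rate - p_pos * (1.0 - event_rate) * p_t / (1.0 - p_t)

    all_mask = np.ones(time.size, dtype=bool)
    nb = np.array([subset_nb(risks >= p_t, p_t) for p_t in thresholds])
    ta = np.array([subset_nb(all_mask, p_t) for p_t in thresholds])
    return DecisionCurve(
        thresholds=thresholds, net_benefit=nb, treat_all=ta,
        treat_none=np.zeros_like(thresholds),
    )


# ---------------------------------------------------------------------------
# CHAID


@dataclass
class ChaidNode:
    """One node of a CHAID tree.  Leaves have ``split_variable is None``."""

    n: int
    n_deaths: int
    split_variable: str | None = None
    groups: list = field(default_factory=list)      # per child: tuple of merged categories
    p_adjusted: float | None = None
    children: list = field(default_factory=list)
    label: tuple = ()                                # categories leading here from the parent

    @property
    def death_rate(self) -> float:
        return self.n_deaths / self.n

    @property
    def is_leaf(self) -> bool:
        return self.split_variable is None

    def render(self, indent: int = 0) -> str:
        pad = "  " * indent
        head = f"{pad}[n={self.n}, deaths={self.n_deaths} ({100 * self.death_rate:.0f}%)]"
        if self.label:
            head += f" <- {'/'.join(map(str, self.label))}"
        lines = [head]
        if not self.is_leaf:
            lines.append(f"{pad}split on {self.split_variable} (adj p={self.p_adjusted:.3g})")
            for child in self.children:
                lines.append(child.render(indent + 1))
        return "\n".join(lines)


def _chi2_p(table: np.ndarray) -> float:
    """Pearson chi-square p, without continuity correction; degenerate
    tables (an empty row/column) give p = 1."""
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        return 1.0
    return float(stats.chi2_contingency(table, correction=False)[1])


def _bonferroni_multiplier(c: int, g: int) -> float:
    """Number of ways to partition c nominal categories into g groups
    (Kass 1980): sum_{i=0}^{g-1} (-1)^i (g-i)^c / (i! (g-i)!)."""
    return float(
        sum((-1) ** i * (g - i) ** c / (math.factorial(i) * math.factorial(g - i)) for i in range(g))
    )


def _merge_categories(values: np.ndarray, outcome: np.ndarray, alpha_merge: float):
    """CHAID category merging for one predictor at one node.

    Returns ``(groups, p_adjusted)``: the merged category groups and the
    Bonferroni-adjusted p of the groups x outcome chi-square.
    """
    cats = sorted(pd.unique(values).tolist())
    if len(cats) < 2:
        return [tuple(cats)], 1.0
    groups = [[c] for c in cats]

    def table_for(group):
        mask = np.isin(values, group)
        d = int(outcome[mask].sum())
        return [d, int(mask.sum()) - d]

    while len(groups) > 2:
        best_p, best_pair = -1.0, None
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                p = _chi2_p(np.array([table_for(groups[i]), table_for(groups[j])]))
                if p > best_p:
                    best_p, best_pair = p, (i, j)
        if best_p <= alpha_merge:
            break
        i, j = best_pair
        groups[i] = groups[i] + groups[j]
        del groups[j]

    table = np.array([table_for(g) for g in groups])
    p_raw = _chi2_p(table)
    p_adj = min(1.0, p_raw * _bonferroni_multiplier(len(cats), len(groups)))
    return [tuple(g) for g in groups], p_adj


def chaid_tree(
    covariates: pd.DataFrame,
    outcome,
    alpha_merge: float = 0.05,
    alpha_split: float = 0.05,
    min_node: int = 30,
    max_depth: int = 3,
) -> ChaidNode:
    """Grow a CHAID tree on categorical predictors and a binary outcome.

    Every column of ``covariates`` must be categorical (strings or small
    discrete codes); ``outcome`` is 0/1 (death during follow-up).
    """
    outcome = np.asarray(outcome, dtype=int)
    if covariates.shape[0] != outcome.size:
        raise ValidationError("covariates and outcome disagree on sample count")
    if not np.isin(outcome, (0, 1)).all():
        raise ValidationError("outcome must be binary 0/1")
    for col in covariates.columns:
        if pd.api.types.is_float_dtype(covariates[col]):
            raise ValidationError(f"covariate {col!r} is continuous; CHAID needs categories")
    cov = covariates.astype(str)

    def grow(idx: np.ndarray, depth: int, label: tuple) -> ChaidNode:
        node = ChaidNode(n=int(idx.size), n_deaths=int(outcome[idx].sum()), label=label)
        if depth >= max_depth or idx.size < 2 * min_node or node.n_deaths in (0, idx.size):
            return node
        candidates = []
        for col in cov.columns:
            groups, p_adj = _merge_categories(cov[col].to_numpy()[idx], outcome[idx], alpha_merge)
            if len(groups) > 1:
                candidates.append((p_adj, col, groups))
        for p_adj, col, groups in sorted(candidates, key=lambda t: (t[0], t[1])):
            if p_adj > alpha_split:
                break
            masks = [np.isin(cov[col].to_numpy()[idx], g) for g in groups]
            if all(m.sum() >= min_node for m in masks):
                node.split_variable = col
                node.groups = groups
                node.p_adjusted = p_adj
                node.children = [
                    grow(idx[m], depth + 1, tuple(g)) for m, g in zip(masks, groups)
                ]
                break
        return node

    return grow(np.arange(outcome.size), 0, ())


# ---------------------------------------------------------------------------
# Model comparison

_SPEC_COLUMNS = {
    "stage": ["stage_II", "stage_III", "stage_IV"],
    "grade": ["grade_3", "grade_4"],
    "age": ["age"],
    "sex": ["sex_male"],
    "marker": ["marker_high"],
}


def compare_models(
    clinical: pd.DataFrame,
    marker_high,
    specs: list[list[str]],
    horizon: float = DEFAULT_HORIZON_DAYS,
    thresholds=None,
):
    """Fit a Cox model per covariate specification, derive each sample's
    horizon risk, and evaluate survival ROC and decision curves.

    ``specs`` are lists drawn from {stage, grade, age, sex, marker}.
    Returns ``(summary, curves, risks)``: a DataFrame (one row per spec,
    with its AUC), a dict spec-label -> :class:`DecisionCurve`, and a dict
    spec-label -> per-sample risk array.
    """
    if thresholds is None:
        thresholds = np.arange(0.01, 1.0, 0.01)
    design_full = encode_clinical(clinical, marker_high=marker_high)
    time = clinical["time_days"].to_numpy(dtype=float)
    event = clinical["event"].to_numpy(dtype=int)

    rows, curves, risks = [], {}, {}
    for spec in specs:
        unknown = set(spec) - set(_SPEC_COLUMNS)
        if unknown:
            raise ValidationError(f"unknown covariates in spec: {sorted(unknown)}")
        if not spec:
            raise ValidationError("model specification must name at least one covariate")
        label = "+".join(spec)
        cols = [c for name in spec for c in _SPEC_COLUMNS[name]]
        fit = cox_fit(design_full[cols], time, event)
        risk = fit.predict_risk(design_full[cols], horizon)
        roc = survival_roc(risk, time, event, horizon)
        curves[label] = decision_curve(risk, time, event, horizon, thresholds)
        risks[label] = risk
        rows.append({"model": label, "auc": roc.auc})
    summary = pd.DataFrame(rows).set_index("model")
    return summary, curves, risks
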