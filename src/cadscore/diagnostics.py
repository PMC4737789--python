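"""Diagnostic-accuracy statistics.

AUC is the tie-corrected Mann-Whitney statistic with a DeLong variance for
confidence intervals and paired comparisons; the optimal cut-point follows
Liu's criterion (maximum sensitivity x specificity); reclassification is
summarised by categorical and continuous net-reclassification indices and
the integrated discrimination improvement, with asymptotic normal CIs.

Threshold semantics everywhere: "positive" means score strictly greater
than the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm, rankdata

from .config import DEFAULT_CONFIG, AlgorithmConfig
from .errors import ParameterError


# --------------------------------------------------------------------------
# ROC / AUC (Mann-Whitney + DeLong)
# --------------------------------------------------------------------------

@dataclass
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int


def _check_two_classes(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise ParameterError("both classes must be present")


def _midrank(x: np.ndarray) -> np.ndarray:
    return rankdata(x, method="average")


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """DeLong structural components V10 (events) and V01 (non-events)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    tx = _midrank(pos)
    ty = _midrank(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    return auc, v10, v01


def roc_auc(
    scores: Sequence[float], labels: Sequence[int], alpha: float = 0.05
) -> ROCResult:
    """Tie-corrected Mann-Whitney AUC with a DeLong Wald CI."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ParameterError("scores and labels length mismatch")
    _check_two_classes(labels)
    auc, v10, v01 = _delong_components(scores, labels)
    var = (np.var(v10, ddof=1) / v10.size if v10.size > 1 else 0.0) + (
        np.var(v01, ddof=1) / v01.size if v01.size > 1 else 0.0
    )
    z = norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(max(var, 0.0))
    return ROCResult(
        auc=float(auc),
        ci_low=float(max(0.0, auc - half)),
        ci_high=float(min(1.0, auc + half)),
        n_pos=int((labels == 1).sum()),
        n_neg=int((labels == 0).sum()),
    )


def compare_auc_paired(
    scores_a: Sequence[float], scores_b: Sequence[float], labels: Sequence[int]
) -> float:
    """Two-sided DeLong test for paired AUCs; returns the p-value.

    Identical score vectors give p = 1 by convention (zero variance of the
    difference).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if a.shape != b.shape or a.shape != labels.shape:
        raise ParameterError("paired comparison requires equal-length inputs")
    _check_two_classes(labels)
    auc_a, v10a, v01a = _delong_components(a, labels)
    auc_b, v10b, v01b = _delong_components(b, labels)
    m, n = v10a.size, v01a.size
    s10 = np.cov(np.stack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 1e-16:
        return 1.0
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    return float(2.0 * norm.sf(abs(z)))


# --------------------------------------------------------------------------
# Cut-point selection
# --------------------------------------------------------------------------

def liu_cutpoint(
    scores: Sequence[float],
    labels: Sequence[int],
    method: Optional[str] = None,
    config: AlgorithmConfig = DEFAULT_CONFIG,
) -> float:
    """Optimal threshold by Liu's criterion (max sensitivity x specificity).

    Candidates are midpoints between adjacent distinct scores; ties are
    broken toward the lower threshold.  ``method='youden'`` maximises
    sensitivity + specificity - 1 instead.
    """
    method = method or config.cutpoint_method
    if method not in ("liu", "youden"):
        raise ParameterError(f"unknown cut-point method {method!r}")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    uniq = np.unique(scores)
    if uniq.size < 2:
        return float(uniq[0])
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    n_pos = (labels == 1).sum()
    n_neg = (labels == 0).sum()
    best_thr, best_obj = None, -np.inf
    for thr in candidates:  # ascending, so strict > keeps the lower tie
        positive = scores > thr
        sens = (positive & (labels == 1)).sum() / n_pos
        spec = (~positive & (labels == 0)).sum() / n_neg
        obj = sens * spec if method == "liu" else sens + spec - 1.0
        if obj > best_obj + 1e-12:
            best_obj, best_thr = obj, thr
    return float(best_thr)


# --------------------------------------------------------------------------
# Binary metrics
# --------------------------------------------------------------------------

@dataclass
class BinaryMetrics:
    """Confusion-matrix metrics; internal arithmetic is exact (Fractions).

    Fields that are undefined for the given margins (e.g. PPV with no
    positive calls) are ``None``.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    plr: Optional[float]
    nlr: Optional[float]
    sensitivity_ci: Optional[tuple[float, float]] = None
    specificity_ci: Optional[tuple[float, float]] = None
    ppv_ci: Optional[tuple[float, float]] = None
    npv_ci: Optional[tuple[float, float]] = None


def wilson_interval(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n == 0:
        raise ParameterError("empty denominator for Wilson interval")
    z = norm.ppf(1 - alpha / 2)
    p = k / n
    denom = 1 + z**2 / n
    centre = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return (max(0.0, centre - half), min(1.0, centre + half))


def binary_metrics(tp: int, fp: int, tn: int, fn: int,
                   with_ci: bool = False) -> BinaryMetrics:
    for name, v in (("tp", tp), ("fp", fp), ("tn", tn), ("fn", fn)):
        if v < 0 or int(v) != v:
            raise ParameterError(f"{name} must be a non-negative integer")
    tp, fp, tn, fn = int(tp), int(fp), int(tn), int(fn)
    if tp + fn == 0 or tn + fp == 0:
        raise ParameterError("need at least one diseased and one healthy subject")

    sens = Fraction(tp, tp + fn)
    spec = Fraction(tn, tn + fp)
    ppv = Fraction(tp, tp + fp) if tp + fp > 0 else None
    npv = Fraction(tn, tn + fn) if tn + fn > 0 else None
    plr = (
        float(sens / (1 - spec)) if spec != 1
        else (np.inf if sens > 0 else None)
    )
    nlr = float((1 - sens) / spec) if spec != 0 else (np.inf if sens != 1 else None)

    kw = {}
    if with_ci:
        kw = dict(
            sensitivity_ci=wilson_interval(tp, tp + fn),
            specificity_ci=wilson_interval(tn, tn + fp),
            ppv_ci=wilson_interval(tp, tp + fp) if tp + fp > 0 else None,
            npv_ci=wilson_interval(tn, tn + fn) if tn + fn > 0 else None,
        )
    return BinaryMetrics(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=float(sens), specificity=float(spec),
        ppv=None if ppv is None else float(ppv),
        npv=None if npv is None else float(npv),
        plr=plr, nlr=nlr, **kw,
    )


def metrics_at_threshold(scores: Sequence[float], labels: Sequence[int],
                         threshold: float, with_ci: bool = False) -> BinaryMetrics:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    positive = scores > threshold
    return binary_metrics(
        tp=int((positive & (labels == 1)).sum()),
        fp=int((positive & (labels == 0)).sum()),
        tn=int((~positive & (labels == 0)).sum()),
        fn=int((~positive & (labels == 1)).sum()),
        with_ci=with_ci,
    )


# --------------------------------------------------------------------------
# Reclassification: NRI and IDI
# --------------------------------------------------------------------------

@dataclass
class NRIResult:
    nri: float
    event_component: float
    nonevent_component: float
    up_events: int
    down_events: int
    up_nonevents: int
    down_nonevents: int
    ci_low: float
    ci_high: float


def _nri_from_moves(up_e: int, down_e: int, n_e: int,
                    up_ne: int, down_ne: int, n_ne: int,
                    alpha: float = 0.05) -> NRIResult:
    if n_e == 0 or n_ne == 0:
        raise ParameterError("both events and non-events must be present")
    ev = (up_e - down_e) / n_e
    ne = (down_ne - up_ne) / n_ne
    nri = ev + ne
    var_e = (up_e + down_e) / n_e**2 - (up_e - down_e) ** 2 / n_e**3
    var_ne = (up_ne + down_ne) / n_ne**2 - (down_ne - up_ne) ** 2 / n_ne**3
    se = np.sqrt(max(var_e, 0.0) + max(var_ne, 0.0))
    z = norm.ppf(1 - alpha / 2)
    return NRIResult(
        nri=float(nri), event_component=float(ev), nonevent_component=float(ne),
        up_events=up_e, down_events=down_e,
        up_nonevents=up_ne, down_nonevents=down_ne,
        ci_low=float(nri - z * se), ci_high=float(nri + z * se),
    )


def categorical_nri(
    old_categories: Sequence[int],
    new_categories: Sequence[int],
    events: Sequence[int],
) -> NRIResult:
    """Categorical NRI on an ordinal category scale (e.g. the four risk
    categories coded 0..3).  Upward moves are towards higher risk."""
    old = np.asarray(old_categories)
    new = np.asarray(new_categories)
    ev = np.asarray(events, dtype=int)
    if old.shape != new.shape or old.shape != ev.shape:
        raise ParameterError("inputs must have equal length")
    if not (np.issubdtype(old.dtype, np.integer) and np.issubdtype(new.dtype, np.integer)):
        raise ParameterError("categories must be integer-coded ordinal levels")
    _check_two_classes(ev)
    up = new > old
    down = new < old
    return _nri_from_moves(
        int((up & (ev == 1)).sum()), int((down & (ev == 1)).sum()), int((ev == 1).sum()),
        int((up & (ev == 0)).sum()), int((down & (ev == 0)).sum()), int((ev == 0).sum()),
    )


def continuous_nri(
    p_old: Sequence[float], p_new: Sequence[float], events: Sequence[int]
) -> NRIResult:
    """Continuous (category-free) NRI: any probability increase is an
    upward move, any decrease a downward move."""
    p_old = np.asarray(p_old, dtype=float)
    p_new = np.asarray(p_new, dtype=float)
    ev = np.asarray(events, dtype=int)
    if p_old.shape != p_new.shape or p_old.shape != ev.shape:
        raise ParameterError("inputs must have equal length")
    _check_two_classes(ev)
    up = p_new > p_old
    down = p_new < p_old
    return _nri_from_moves(
        int((up & (ev == 1)).sum()), int((down & (ev == 1)).sum()), int((ev == 1).sum()),
        int((up & (ev == 0)).sum()), int((down & (ev == 0)).sum()), int((ev == 0).sum()),
    )


@dataclass
class IDIResult:
    idi: float
    ci_low: float
    ci_high: float


def idi(p_old: Sequence[float], p_new: Sequence[float],
        events: Sequence[int], alpha: float = 0.05) -> IDIResult:
    """Integrated discrimination improvement: the change in mean predicted
    probability among events minus the change among non-events."""
    p_old = np.asarray(p_old, dtype=float)
    p_new = np.asarray(p_new, dtype=float)
    ev = np.asarray(events, dtype=int)
    if p_old.shape != p_new.shape or p_old.shape != ev.shape:
        raise ParameterError("inputs must have equal length")
    _check_two_classes(ev)
    d = p_new - p_old
    de, dn = d[ev == 1], d[ev == 0]
    value = float(de.mean() - dn.mean())
    se = np.sqrt(
        (np.var(de, ddof=1) / de.size if de.size > 1 else 0.0)
        + (np.var(dn, ddof=1) / dn.size if dn.size > 1 else 0.0)
    )
    z = norm.ppf(1 - alpha / 2)
    return IDIResult(idi=value, ci_low=float(value - z * se), ci_high=float(value + z * se))
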