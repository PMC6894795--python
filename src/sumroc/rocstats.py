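"""ROC curves, AUROC, and DeLong's test.

The canonical AUROC here is the tie-corrected pair-counting statistic
(Mann-Whitney): the probability that a randomly chosen case outscores a
randomly chosen control, counting ties one half.  The ROC polyline from the
threshold sweep has exactly this area under the trapezoid rule, which the
test suite verifies to 1e-12.

DeLong's method expresses the AUROC as a two-sample U-statistic and derives
its variance from per-observation structural components; two AUROCs are
compared with a normal test statistic.  Both the unpaired (independent
cohorts; variances add) and paired (same individuals under two scores;
covariance subtracted) variants are provided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "ROCCurve",
    "roc_curve",
    "pair_count_auroc",
    "single_binary_auroc",
    "delong_test",
]


@dataclass
class ROCCurve:
    """An ROC curve with the score vectors retained for DeLong's test.

    ``points`` is an (n, 2) array of (1 - specificity, sensitivity) pairs
    ordered from (0, 0) to (1, 1); ``thresholds`` aligns with ``points``
    (the first entry is +inf: nothing called positive).
    """

    points: np.ndarray
    thresholds: np.ndarray
    auroc: float
    scores_case: np.ndarray
    scores_control: np.ndarray

    @property
    def n_case(self) -> int:
        return len(self.scores_case)

    @property
    def n_control(self) -> int:
        return len(self.scores_control)


def _structural_components(scores_case, scores_control):
    """AUROC plus DeLong structural components V10 (per case) and V01 (per
    control), computed with midranks in O((m+n) log(m+n))."""
    x = np.asarray(scores_case, dtype=float)
    y = np.asarray(scores_control, dtype=float)
    m, n = len(x), len(y)
    rz = stats.rankdata(np.concatenate([x, y]))
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    v10 = (rz[:m] - rx) / n            # P(case_i > control) with half-ties
    v01 = 1.0 - (rz[m:] - ry) / m      # P(case > control_j) with half-ties
    auc = float(v10.mean())
    return auc, v10, v01


def pair_count_auroc(scores, labels) -> float:
    """Tie-corrected pair-counting AUROC of ``scores`` against 0/1 labels."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    auc, _, _ = _structural_components(scores[labels == 1], scores[labels == 0])
    return auc


def roc_curve(scores, labels) -> ROCCurve:
    """Build the full ROC curve from a threshold sweep over the distinct
    score values, with the AUROC computed by pair counting."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("roc_curve requires both classes present")
    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    x = scores[labels == 1]
    y = scores[labels == 0]
    auc, _, _ = _structural_components(x, y)
    return ROCCurve(
        points=np.column_stack([fpr, tpr]),
        thresholds=thr.astype(float),
        auroc=auc,
        scores_case=x,
        scores_control=y,
    )


def single_binary_auroc(p_case: float, p_control: float) -> float:
    """Closed-form AUROC of a single 0/1 marker with carrier rates
    ``p_case`` >= ``p_control``: 1/2 * (1 + p_case - p_control).

    Derivation: a case-control pair is concordant when the case carries and
    the control does not (probability p_case * (1 - p_control)); ties (both
    or neither carry) count one half.
    """
    for name, p in (("p_case", p_case), ("p_control", p_control)):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {p}")
    if p_case < p_control:
        raise ValueError("orient the marker so that p_case >= p_control")
    return 0.5 * (1.0 + p_case - p_control)


def _curve_variance(curve: ROCCurve):
    auc, v10, v01 = _structural_components(curve.scores_case, curve.scores_control)
    m, n = len(v10), len(v01)
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    return auc, v10, v01, s10 / m + s01 / n


def delong_test(
    curve_a: ROCCurve, curve_b: ROCCurve, paired: bool = False
) -> tuple[float, float]:
    """Two-sided DeLong test of equal AUROC between two ROC curves.

    With ``paired=False`` (the default) the curves are treated as coming
    from independent cohorts and their variances add with zero covariance.
    With ``paired=True`` both curves must score the same individuals in the
    same order, and the structural-component covariances are subtracted.

    Returns ``(z, p_value)``.  Degenerate zero-variance cases yield p = 1.0
    when the AUROCs are equal and p ~ 0 otherwise.
    """
    auc_a, v10_a, v01_a, var_a = _curve_variance(curve_a)
    auc_b, v10_b, v01_b, var_b = _curve_variance(curve_b)
    var = var_a + var_b
    if paired:
        if len(v10_a) != len(v10_b) or len(v01_a) != len(v01_b):
            raise ValueError("paired DeLong requires identically sized cohorts")
        m, n = len(v10_a), len(v01_a)
        cov = 0.0
        if m > 1:
            cov += float(np.cov(v10_a, v10_b, ddof=1)[0, 1]) / m
        if n > 1:
            cov += float(np.cov(v01_a, v01_b, ddof=1)[0, 1]) / n
        var -= 2.0 * cov
    delta = auc_a - auc_b
    if var <= 0.0:
        return (0.0, 1.0) if delta == 0.0 else (np.inf * np.sign(delta), 0.0)
    z = delta / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))
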