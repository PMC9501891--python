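"""ROC curve, AUC and the DeLong confidence interval.

The curve is built by thresholding at each distinct score (descending);
AUC is the trapezoidal area, which for a staircase with tie-diagonals
equals the Mann–Whitney probability that a random positive outscores a
random negative with ties half-counted — this identity is asserted
internally on every call.  The AUC confidence interval uses DeLong's
placement-value variance estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["ROCResult", "roc_auc", "delong_ci", "roc_with_ci"]


@dataclass
class ROCResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    ci: tuple[float, float] | None = None
    ci_degenerate: bool = False

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        )


def _split(scores, labels):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.size != y.size:
        raise ValueError("scores and labels must have equal length")
    if not set(np.unique(y)).issubset({0, 1}):
        raise ValueError("labels must be binary 0/1")
    pos, neg = s[y == 1], s[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    return pos, neg


def _mann_whitney_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return float((gt + 0.5 * eq) / (pos.size * neg.size))


def roc_auc(scores, labels) -> ROCResult:
    """ROC points and trapezoidal AUC (positives are labels == 1)."""
    pos, neg = _split(scores, labels)
    s = np.concatenate([pos, neg])
    thresholds = np.unique(s)[::-1]
    tpr = [(pos >= t).mean() for t in thresholds]
    fpr = [(neg >= t).mean() for t in thresholds]
    thresholds = np.concatenate([[np.inf], thresholds])
    fpr = np.concatenate([[0.0], fpr])
    tpr = np.concatenate([[0.0], tpr])
    auc = float(np.trapezoid(tpr, fpr))
    mw = _mann_whitney_auc(pos, neg)
    assert abs(auc - mw) < 1e-12, "trapezoid AUC != Mann-Whitney AUC"
    return ROCResult(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


def delong_ci(scores, labels, level: float = 0.95) -> tuple[float, float]:
    """DeLong normal-approximation CI for the AUC, clipped to [0, 1].

    With zero placement-value variance (e.g. perfect separation) the CI
    collapses to the point estimate; :func:`roc_auc` callers can detect
    this via ``ci_degenerate``.
    """
    pos, neg = _split(scores, labels)
    if pos.size < 2 or neg.size < 2:
        raise ValueError("DeLong CI requires >= 2 subjects per class")
    psi = (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
    auc = float(psi.mean())
    v10 = psi.mean(axis=1)  # per-positive placement values
    v01 = psi.mean(axis=0)  # per-negative placement values
    var = v10.var(ddof=1) / pos.size + v01.var(ddof=1) / neg.size
    if var <= 0:
        return auc, auc
    z = sps.norm.ppf(0.5 + level / 2)
    half = z * float(np.sqrt(var))
    return float(np.clip(auc - half, 0, 1)), float(np.clip(auc + half, 0, 1))


def roc_with_ci(scores, labels, level: float = 0.95) -> ROCResult:
    """ROC result with the DeLong CI attached (degenerate variance flagged)."""
    res = roc_auc(scores, labels)
    lo, hi = delong_ci(scores, labels, level=level)
    res.ci = (lo, hi)
    res.ci_degenerate = lo == hi
    return res
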