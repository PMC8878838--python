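"""Confusion-matrix diagnostics, ROC/AUC and the DeLong AUC comparison.

Metric algebra is exact (rational arithmetic) until display, where values
round half away from zero to two decimals. The positive class is CRC
throughout. Likelihood ratios are reported as "ND" (not determinable) when
their denominator is zero. Standard errors use the binomial form
sqrt(p(1-p)/n) with each metric's own denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve

ND = "ND"


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_predictions(cls, y_true, y_pred, positive="CRC") -> "ConfusionMatrix":
        t = np.asarray(y_true).astype(str) == positive
        p = np.asarray(y_pred).astype(str) == positive
        return cls(
            tp=int((t & p).sum()),
            fp=int((~t & p).sum()),
            fn=int((t & ~p).sum()),
            tn=int((~t & ~p).sum()),
        )


@dataclass
class Metric:
    value: Fraction | None  # None encodes ND
    se: Fraction | None = None

    @property
    def nd(self) -> bool:
        return self.value is None

    def as_float(self) -> float | str:
        return ND if self.nd else float(self.value)


def _round2(x: Fraction) -> float:
    """Round half away from zero to 2 decimals, exactly."""
    sign = -1 if x < 0 else 1
    q = abs(x) * 100
    whole = q.numerator // q.denominator
    rem = q - whole
    if rem >= Fraction(1, 2):
        whole += 1
    return sign * whole / 100


@dataclass
class DiagnosticReport:
    cm: ConfusionMatrix
    sensitivity: Metric
    specificity: Metric
    plr: Metric
    nlr: Metric
    ppv: Metric
    npv: Metric
    accuracy: Metric

    _ORDER = ("sensitivity", "specificity", "plr", "nlr", "npv", "ppv", "accuracy")

    def rounded(self) -> dict[str, float | str]:
        """Display values: two decimals, half away from zero; ND preserved."""
        out = {}
        for name in self._ORDER:
            m: Metric = getattr(self, name)
            out[name] = ND if m.nd else _round2(m.value)
        return out

    def to_dict(self) -> dict:
        d = {"tp": self.cm.tp, "fp": self.cm.fp, "fn": self.cm.fn, "tn": self.cm.tn}
        for name in self._ORDER:
            m: Metric = getattr(self, name)
            d[name] = m.as_float()
            d[f"{name}_se"] = None if m.se is None else float(m.se)
        return d


def _binomial(num: int, den: int) -> Metric:
    if den == 0:
        return Metric(value=None)
    p = Fraction(num, den)
    se_sq = p * (1 - p) / den
    # exact sqrt when possible, else float-backed Fraction
    se = Fraction(np.sqrt(float(se_sq))).limit_denominator(10**12)
    return Metric(value=p, se=se)


def diagnostic_report(cm: ConfusionMatrix) -> DiagnosticReport:
    """All seven diagnostic metrics with standard errors.

    PLR = S/(1-Sp) is ND when specificity is 1; NLR = (1-S)/Sp is ND when
    specificity is 0.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    s = _binomial(cm.tp, cm.tp + cm.fn)
    sp = _binomial(cm.tn, cm.tn + cm.fp)
    ppv = _binomial(cm.tp, cm.tp + cm.fp)
    npv = _binomial(cm.tn, cm.tn + cm.fn)
    acc = _binomial(cm.tp + cm.tn, cm.total)

    if s.nd or sp.nd:
        plr = Metric(value=None)
        nlr = Metric(value=None)
    else:
        one_minus_sp = 1 - sp.value
        plr = Metric(value=None) if one_minus_sp == 0 else Metric(value=s.value / one_minus_sp)
        nlr = Metric(value=None) if sp.value == 0 else Metric(value=(1 - s.value) / sp.value)

    return DiagnosticReport(
        cm=cm, sensitivity=s, specificity=sp, plr=plr, nlr=nlr, ppv=ppv, npv=npv,
        accuracy=acc,
    )


def roc_curve(scores, labels, positive: str = "CRC"):
    """ROC coordinates over all unique thresholds plus the trapezoid AUC.

    The trapezoid AUC equals the Mann–Whitney U statistic divided by
    (n_positive * n_negative), with tied scores counted one half.
    """
    y = np.asarray(labels).astype(str) == positive
    s = np.asarray(scores, dtype=float)
    if y.all() or not y.any():
        raise ValueError("both classes must be present for a ROC curve")
    fpr, tpr, thresholds = _sk_roc_curve(y.astype(int), s)
    auc = float(np.trapezoid(tpr, fpr))
    return pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr}), auc


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values: V10 (per positive), V01 (per negative)."""
    m, n = len(pos), len(neg)
    # midrank-based computation; ties count one half
    v10 = np.empty(m)
    v01 = np.empty(n)
    for i, x in enumerate(pos):
        v10[i] = ((x > neg).sum() + 0.5 * (x == neg).sum()) / n
    for j, x in enumerate(neg):
        v01[j] = ((pos > x).sum() + 0.5 * (pos == x).sum()) / m
    return v10, v01


def auc_variance(scores, labels, positive: str = "CRC") -> tuple[float, float]:
    """AUC and its DeLong (placement-value) variance estimate."""
    y = np.asarray(labels).astype(str) == positive
    s = np.asarray(scores, dtype=float)
    pos, neg = s[y], s[~y]
    v10, v01 = _placements(pos, neg)
    auc = float(v10.mean())
    var = v10.var(ddof=1) / len(pos) + v01.var(ddof=1) / len(neg)
    return auc, float(var)


def delong_compare(scores_a, scores_b, labels, positive: str = "CRC") -> dict:
    """DeLong comparison of two paired ROC AUCs on the same samples.

    Returns the two AUCs, their difference, the z statistic and a two-sided
    normal p-value. Identical score vectors (or zero variance of the
    difference) yield p = 1 with a warning note in the result.
    """
    from scipy import stats

    y = np.asarray(labels).astype(str) == positive
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) != len(b) or len(a) != len(y):
        raise ValueError("scores must be paired on the same samples")
    pos_a, neg_a = a[y], a[~y]
    pos_b, neg_b = b[y], b[~y]
    v10a, v01a = _placements(pos_a, neg_a)
    v10b, v01b = _placements(pos_b, neg_b)
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())
    m, n = int(y.sum()), int((~y).sum())
    s10 = np.cov(np.vstack([v10a, v10b]))
    s01 = np.cov(np.vstack([v01a, v01b]))
    cov = s10 / m + s01 / n
    var_diff = float(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1])
    diff = auc_a - auc_b
    note = ""
    if var_diff <= 0:
        z, p = 0.0, 1.0
        note = "zero variance of the AUC difference; p set to 1"
    else:
        z = diff / np.sqrt(var_diff)
        p = float(2 * stats.norm.sf(abs(z)))
    return {
        "auc_a": auc_a, "auc_b": auc_b, "diff": diff,
        "z": float(z), "p": p, "note": note,
    }
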