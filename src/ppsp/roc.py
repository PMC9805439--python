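"""ROC curves, Youden-index cutoffs and diagnostic metrics.

A marker can be abnormal on the high side (test-positive means value >=
threshold; age, CA125, CRP, d-dimer, WBC, WBC difference) or on the low
side (test-positive means value <= threshold; albumin). The AUC is the
Mann-Whitney pairwise probability P(marker_case > marker_control) +
0.5 P(tie), computed from ranks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.stats import norm as _norm
from scipy.stats import rankdata

from .stats import ContingencyTable

HIGH = "high-abnormal"
LOW = "low-abnormal"


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class RocCurve:
    """ROC summary at every distinct observed threshold.

    ``thresholds`` are the distinct marker values in ascending order;
    ``sensitivities[i]`` / ``specificities[i]`` are the operating point when
    test-positive means value >= thresholds[i] (high-abnormal) or
    value <= thresholds[i] (low-abnormal).
    """

    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    auc: float
    direction: str
    n_positive: int
    n_negative: int
    _values: np.ndarray
    _labels: np.ndarray


@dataclass(frozen=True)
class CutoffReport:
    """One marker's row of a cutoff table: ROC summary plus predictive values."""

    marker: str
    cutoff: float
    auc: float
    p_value: float
    sensitivity: float
    specificity: float
    ppv: float  # percent
    npv: float  # percent
    direction: str = HIGH

    def to_dict(self) -> dict:
        return {
            "marker": self.marker,
            "cutoff": self.cutoff,
            "auc": self.auc,
            "p_value": self.p_value,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "direction": self.direction,
        }


def compute_roc(values, labels, direction: str = HIGH) -> RocCurve:
    """Construct the empirical ROC curve of ``values`` against binary ``labels``.

    Raises if the labels contain a single class or the values are not finite.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=int)
    if v.size != y.size:
        raise ValueError("values and labels must have equal length")
    if not np.isfinite(v).all():
        raise ValueError("values must be finite (drop missing pairs first)")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative label")
    if direction not in (HIGH, LOW):
        raise ValueError(f"direction must be {HIGH!r} or {LOW!r}")

    # AUC on the oriented values (low-abnormal mirrors the axis)
    oriented = v if direction == HIGH else -v
    ranks = rankdata(oriented)
    auc = float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))

    thresholds = np.unique(v)
    pos = np.sort(v[y == 1])
    neg = np.sort(v[y == 0])
    if direction == HIGH:
        # test-positive: value >= t
        sens = 1.0 - np.searchsorted(pos, thresholds, side="left") / n_pos
        spec = np.searchsorted(neg, thresholds, side="left") / n_neg
    else:
        # test-positive: value <= t
        sens = np.searchsorted(pos, thresholds, side="right") / n_pos
        spec = 1.0 - np.searchsorted(neg, thresholds, side="right") / n_neg

    return RocCurve(
        thresholds=thresholds,
        sensitivities=np.asarray(sens, dtype=float),
        specificities=np.asarray(spec, dtype=float),
        auc=auc,
        direction=direction,
        n_positive=n_pos,
        n_negative=n_neg,
        _values=v,
        _labels=y,
    )


def youden_cutoff(roc: RocCurve) -> tuple[float, float, float]:
    """Threshold maximising the Youden index J = sensitivity + specificity - 1.

    Ties are broken in favour of higher sensitivity, then the smaller
    threshold (screening use favours catching cases).
    """
    j = roc.sensitivities + roc.specificities - 1.0
    best = None
    for i in range(roc.thresholds.size):
        key = (j[i], roc.sensitivities[i], -roc.thresholds[i])
        if best is None or key > best[0]:
            best = (key, i)
    i = best[1]
    return float(roc.thresholds[i]), float(roc.sensitivities[i]), float(roc.specificities[i])


def predictive_values(sensitivity: float, specificity: float,
                      n_positive: int, n_negative: int) -> tuple[float, float]:
    """PPV and NPV (percent) from rounded sensitivity/specificity and group sizes.

    Integer counts are reconstructed first (TP = round(sens * n_pos),
    TN = round(spec * n_neg)) so the predictive values are exact count ratios.
    """
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise ValueError("rates must be in [0, 1]")
    if n_positive <= 0 or n_negative <= 0:
        raise ValueError("group sizes must be positive")
    tp = _round_half_up(sensitivity * n_positive)
    tn = _round_half_up(specificity * n_negative)
    if not (0 <= tp <= n_positive and 0 <= tn <= n_negative):
        raise ValueError("reconstructed counts outside the group size")
    fn = n_positive - tp
    fp = n_negative - tn
    if tp + fp == 0 or tn + fn == 0:
        raise ValueError("degenerate table: no test-positives or test-negatives")
    return 100.0 * tp / (tp + fp), 100.0 * tn / (tn + fn)


def reconstruct_2x2(sensitivity: float, specificity: float,
                    n_positive: int, n_negative: int) -> ContingencyTable:
    """Recover the integer 2x2 diagnostic table behind 3-decimal rates.

    Verifies the round trip: TP/n_pos and TN/n_neg must round back to the
    stated rates at 3 decimals, otherwise the stated group size cannot be
    the marker's analysis n (per-marker missingness) and an error is raised.
    """
    tp = _round_half_up(sensitivity * n_positive)
    tn = _round_half_up(specificity * n_negative)
    if not (0 <= tp <= n_positive and 0 <= tn <= n_negative):
        raise ValueError("reconstructed counts outside [0, n]")
    if round(tp / n_positive, 3) != round(sensitivity, 3):
        raise ValueError(
            f"inconsistent rates: no integer TP in [0, {n_positive}] yields "
            f"sensitivity {sensitivity:.3f} (marker n likely differs from the group size)"
        )
    if round(tn / n_negative, 3) != round(specificity, 3):
        raise ValueError(
            f"inconsistent rates: no integer TN in [0, {n_negative}] yields "
            f"specificity {specificity:.3f} (marker n likely differs from the group size)"
        )
    return ContingencyTable.from_diagnostic(
        tp=tp, fn=n_positive - tp, fp=n_negative - tn, tn=tn
    )


def auc_pvalue(roc: RocCurve, exact_limit: int = 20000) -> float:
    """Two-sided p-value for H0: AUC = 0.5.

    Uses the tie-corrected normal approximation to the Mann-Whitney U
    statistic; for small samples (label permutations <= ``exact_limit``)
    the exact permutation distribution of the AUC is enumerated instead.
    """
    n1, n0 = roc.n_positive, roc.n_negative
    if min(n1, n0) < 3:
        raise ValueError("need at least 3 observations per class")
    oriented = roc._values if roc.direction == HIGH else -roc._values
    ranks = rankdata(oriented)
    y = roc._labels
    u = float(ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0)
    mu = n1 * n0 / 2.0

    n = n1 + n0
    if math.comb(n, n1) <= exact_limit:
        obs_dev = abs(u - mu)
        count = 0
        total = 0
        idx = np.arange(n)
        for pos in combinations(idx, n1):
            up = float(ranks[list(pos)].sum() - n1 * (n1 + 1) / 2.0)
            total += 1
            if abs(up - mu) >= obs_dev - 1e-9:
                count += 1
        return count / total

    _, tie_counts = np.unique(oriented, return_counts=True)
    tie_term = float((tie_counts**3 - tie_counts).sum() / (n * (n - 1)))
    var = n1 * n0 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    z = abs(u - mu) / math.sqrt(var)
    return min(1.0, 2.0 * float(_norm.sf(z)))


def cutoff_report(marker: str, values, labels, direction: str = HIGH) -> CutoffReport:
    """Full per-marker cutoff row: ROC, Youden cutoff, AUC p, PPV/NPV."""
    roc = compute_roc(values, labels, direction)
    cut, sens, spec = youden_cutoff(roc)
    ppv, npv = predictive_values(sens, spec, roc.n_positive, roc.n_negative)
    return CutoffReport(
        marker=marker, cutoff=cut, auc=roc.auc, p_value=auc_pvalue(roc),
        sensitivity=sens, specificity=spec, ppv=ppv, npv=npv, direction=direction,
    )
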