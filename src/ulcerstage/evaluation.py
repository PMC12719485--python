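"""Discrimination, calibration, error-structure and cross-fold statistics.

All metrics are computed from first principles so they can be checked
against independent references: one-vs-rest ROC curves with trapezoidal
AUC (equal to the Mann-Whitney concordance on the same scores) and
Hanley-McNeil confidence intervals; expected calibration error on 10
uniform confidence bins with the standard grade bands; per-class Brier
scores; severity-weighted misclassification cost; and paired t tests
across cross-validation folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .taxonomy import ClassTaxonomy, DEFAULT_TAXONOMY

AUC_BANDS = [
    (0.90, "Excellent (0.90-1.00)"),
    (0.80, "Good (0.80-0.90)"),
    (0.70, "Fair (0.70-0.80)"),
    (0.60, "Poor (0.60-0.70)"),
    (0.50, "No better than random (0.50-0.60)"),
]

ECE_GRADES = [(0.05, "Excellent"), (0.10, "Good"), (0.15, "Fair")]


def _as_indices(labels, taxonomy: ClassTaxonomy) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "iu":
        return arr.astype(int)
    return np.asarray(taxonomy.to_indices(list(arr)))


# -- classification summary ------------------------------------------------

@dataclass
class MetricsReport:
    accuracy: float
    per_class: dict[str, dict[str, float]]  # label -> precision/recall/f1/support
    macro: dict[str, float]
    weighted: dict[str, float]
    confusion: np.ndarray  # raw counts, rows = true class
    confusion_normalized: np.ndarray  # row-normalized

    @property
    def macro_f1(self) -> float:
        return self.macro["f1"]


def summary_metrics(y_true, y_pred, taxonomy: ClassTaxonomy = DEFAULT_TAXONOMY) -> MetricsReport:
    """Accuracy, per-class and macro/weighted P/R/F1, row-normalized confusion.

    F1 uses the zero convention when precision + recall = 0.
    """
    t = _as_indices(y_true, taxonomy)
    p = _as_indices(y_pred, taxonomy)
    if len(t) == 0:
        raise ValueError("empty input")
    if len(t) != len(p):
        raise ValueError(f"length mismatch: {len(t)} true vs {len(p)} predicted")
    C = taxonomy.n_classes
    conf = np.zeros((C, C), dtype=int)
    np.add.at(conf, (t, p), 1)
    support = conf.sum(axis=1)
    pred_count = conf.sum(axis=0)
    tp = np.diag(conf).astype(float)
    precision = np.divide(tp, pred_count, out=np.zeros(C), where=pred_count > 0)
    recall = np.divide(tp, support, out=np.zeros(C), where=support > 0)
    pr = precision + recall
    f1 = np.divide(2 * precision * recall, pr, out=np.zeros(C), where=pr > 0)
    row_sums = support.astype(float)
    conf_norm = np.divide(conf, row_sums[:, None], out=np.zeros((C, C)),
                          where=row_sums[:, None] > 0)
    w = support / support.sum()
    per_class = {
        lab: {"precision": float(precision[i]), "recall": float(recall[i]),
              "f1": float(f1[i]), "support": int(support[i])}
        for i, lab in enumerate(taxonomy.labels)
    }
    return MetricsReport(
        accuracy=float(tp.sum() / len(t)),
        per_class=per_class,
        macro={"precision": float(precision.mean()), "recall": float(recall.mean()),
               "f1": float(f1.mean())},
        weighted={"precision": float(precision @ w), "recall": float(recall @ w),
                  "f1": float(f1 @ w)},
        confusion=conf,
        confusion_normalized=conf_norm,
    )


# -- ROC / AUC -------------------------------------------------------------

def roc_curve_points(scores: np.ndarray, positives: np.ndarray,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """One-vs-rest ROC sweep over all score thresholds.

    Returns (fpr, tpr) starting at (0, 0) and ending at (1, 1); tied
    scores collapse to a single operating point.
    """
    scores = np.asarray(scores, float)
    pos = np.asarray(positives, bool)
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = pos[order].astype(float)
    tps = np.cumsum(y)
    fps = np.cumsum(1 - y)
    last_of_tie = np.r_[s[1:] != s[:-1], True]
    tpr = np.r_[0.0, tps[last_of_tie] / n_pos]
    fpr = np.r_[0.0, fps[last_of_tie] / n_neg]
    return fpr, tpr


def trapezoidal_auc(fpr: np.ndarray, tpr: np.ndarray) -> float:
    return float(np.trapezoid(tpr, fpr))


def mann_whitney_auc(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """All-pairs concordance probability (ties count one half)."""
    pos = np.asarray(pos_scores, float)[:, None]
    neg = np.asarray(neg_scores, float)[None, :]
    return float(((pos > neg).sum() + 0.5 * (pos == neg).sum()) / (pos.size * neg.size))


def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Closed-form AUC standard error (Hanley & McNeil)."""
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (auc * (1 - auc) + (n_pos - 1) * (q1 - auc * auc)
           + (n_neg - 1) * (q2 - auc * auc)) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def auc_interpretation(auc: float) -> str:
    for lo, band in AUC_BANDS:
        if auc >= lo:
            return band
    return "Worse than random (< 0.50)"


@dataclass
class RocResult:
    per_class: dict[str, dict]  # label -> fpr/tpr/auc/se/ci/band (or undefined)
    macro_auc: float
    micro_auc: float
    micro_curve: tuple[np.ndarray, np.ndarray] = field(default=None, repr=False)


def roc_auc_ovr(probs: np.ndarray, y_true,
                taxonomy: ClassTaxonomy = DEFAULT_TAXONOMY) -> RocResult:
    """Per-class one-vs-rest ROC analysis of an N x C probability matrix.

    Macro AUC is the unweighted mean of the defined per-class AUCs; micro
    AUC pools every (item, class) decision into one binary problem.
    Degenerate classes (no positives or no negatives) are reported as
    undefined, never silently dropped.
    """
    P = np.asarray(getattr(probs, "probs", probs), float)
    t = _as_indices(y_true, taxonomy)
    per_class: dict[str, dict] = {}
    aucs = []
    for c, lab in enumerate(taxonomy.labels):
        pos = t == c
        if pos.all() or not pos.any():
            per_class[lab] = {"auc": None, "reason": "degenerate: needs >=1 positive "
                                                      "and >=1 negative"}
            continue
        fpr, tpr = roc_curve_points(P[:, c], pos)
        auc = trapezoidal_auc(fpr, tpr)
        se = hanley_mcneil_se(auc, int(pos.sum()), int((~pos).sum()))
        ci = (max(0.0, auc - 1.959963984540054 * se), min(1.0, auc + 1.959963984540054 * se))
        per_class[lab] = {"fpr": fpr, "tpr": tpr, "auc": auc, "se": se,
                          "ci95": ci, "band": auc_interpretation(auc)}
        aucs.append(auc)
    onehot = np.zeros_like(P, dtype=bool)
    onehot[np.arange(len(t)), t] = True
    micro_fpr, micro_tpr = roc_curve_points(P.ravel(), onehot.ravel())
    return RocResult(per_class=per_class,
                     macro_auc=float(np.mean(aucs)) if aucs else float("nan"),
                     micro_auc=trapezoidal_auc(micro_fpr, micro_tpr),
                     micro_curve=(micro_fpr, micro_tpr))


# -- calibration -----------------------------------------------------------

def _bin_index(conf: np.ndarray, n_bins: int) -> np.ndarray:
    # uniform bins on (0, 1], right-closed; the first bin also includes 0
    return np.clip(np.ceil(np.asarray(conf, float) * n_bins).astype(int) - 1, 0, n_bins - 1)


def expected_calibration_error(confidences, outcomes, n_bins: int = 10,
                               ) -> tuple[float, list[dict]]:
    """ECE = sum_i |B_i|/n * |acc(B_i) - conf(B_i)| over uniform bins.

    Empty bins contribute zero.  Returns the ECE and the per-bin table
    (count, mean confidence, accuracy).
    """
    conf = np.asarray(confidences, float)
    out = np.asarray(outcomes, float)
    if conf.size == 0:
        raise ValueError("no predictions to calibrate")
    if conf.min() < 0 or conf.max() > 1:
        raise ValueError("confidences must lie in [0, 1]")
    if not np.isin(out, (0.0, 1.0)).all():
        raise ValueError("outcomes must be binary")
    idx = _bin_index(conf, n_bins)
    table = []
    ece = 0.0
    n = conf.size
    for b in range(n_bins):
        sel = idx == b
        cnt = int(sel.sum())
        if cnt:
            acc = float(out[sel].mean())
            avg_conf = float(conf[sel].mean())
            ece += cnt / n * abs(acc - avg_conf)
        else:
            acc, avg_conf = float("nan"), float("nan")
        table.append({"bin": b, "lo": b / n_bins, "hi": (b + 1) / n_bins,
                      "count": cnt, "confidence": avg_conf, "accuracy": acc})
    return float(ece), table


def brier_score(predicted, outcomes) -> float:
    """Mean squared difference between probability and binary outcome."""
    f = np.asarray(predicted, float)
    o = np.asarray(outcomes, float)
    if f.size == 0:
        raise ValueError("no predictions")
    if f.shape != o.shape:
        raise ValueError(f"shape mismatch: {f.shape} vs {o.shape}")
    return float(np.mean((f - o) ** 2))


def calibration_grade(ece: float) -> str:
    """Grade band; lower edges belong to the upper band (0.05 -> Good)."""
    for hi, grade in ECE_GRADES:
        if ece < hi:
            return grade
    return "Poor"


@dataclass
class CalibrationReport:
    per_class: dict[str, dict]  # label -> ece/brier/grade/bins
    overall_ece: float  # top-label confidence against correctness
    overall_grade: str
    n_bins: int = 10


def calibration_report(probs: np.ndarray, y_true, n_bins: int = 10,
                       taxonomy: ClassTaxonomy = DEFAULT_TAXONOMY) -> CalibrationReport:
    """One-vs-rest ECE/Brier per class plus the top-label overall ECE."""
    P = np.asarray(getattr(probs, "probs", probs), float)
    t = _as_indices(y_true, taxonomy)
    per_class = {}
    for c, lab in enumerate(taxonomy.labels):
        outcome = (t == c).astype(float)
        ece, table = expected_calibration_error(P[:, c], outcome, n_bins)
        per_class[lab] = {"ece": ece, "brier": brier_score(P[:, c], outcome),
                          "grade": calibration_grade(ece), "bins": table}
    top_conf = P.max(axis=1)
    correct = (P.argmax(axis=1) == t).astype(float)
    overall, _ = expected_calibration_error(top_conf, correct, n_bins)
    return CalibrationReport(per_class, overall, calibration_grade(overall), n_bins)


# -- severity weighting ----------------------------------------------------

@dataclass(frozen=True)
class SeverityWeightMatrix:
    """Non-negative clinical-cost weights with a zero diagonal."""

    weights: tuple  # 6x6 nested tuple

    def __post_init__(self):
        w = np.asarray(self.weights, float)
        if w.shape != (6, 6):
            raise ValueError(f"expected 6x6 weights, got {w.shape}")
        if (w < 0).any():
            raise ValueError("severity weights must be non-negative")
        if np.diag(w).any():
            raise ValueError("severity weight diagonal must be zero")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.weights, float)


def default_severity_weights() -> SeverityWeightMatrix:
    """Squared ordinal stage distance over (he, s1..s4); 'un' costs 1 vs any.

    The ordinal scale is he=0, s1=1 ... s4=4, so extreme-stage confusions
    (s1 vs s4: cost 9) dominate adjacent ones (cost 1).  The matrix is a
    package default — clinically-elicited costs can replace it.
    """
    stage = [0, 1, 2, 3, 4, None]  # None = undetermined
    w = np.zeros((6, 6))
    for i in range(6):
        for j in range(6):
            if i == j:
                continue
            if stage[i] is None or stage[j] is None:
                w[i, j] = 1.0
            else:
                w[i, j] = (stage[i] - stage[j]) ** 2
    return SeverityWeightMatrix(tuple(map(tuple, w)))


def severity_weighted_error(confusion: np.ndarray, w: SeverityWeightMatrix) -> float:
    """sum_{i != j} W_ij C_ij / sum C; reduces to the error rate for unit costs."""
    c = np.asarray(confusion, float)
    total = c.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return float((w.array * c).sum() / total)


# -- cross-fold statistics -------------------------------------------------

@dataclass
class FoldComparison:
    metric_a: np.ndarray
    metric_b: np.ndarray
    mean_diff: float
    t_statistic: float
    df: int
    p_value: float
    ci95: tuple[float, float]


def paired_fold_test(metric_a, metric_b) -> FoldComparison:
    """Paired t-test of per-fold metrics: t = mean(d) / (sd(d)/sqrt(n)).

    Identically-zero differences report "no difference" (t = 0, p = 1)
    instead of NaN.
    """
    a = np.asarray(metric_a, float)
    b = np.asarray(metric_b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired test needs equal-length 1-D metric vectors")
    n = len(a)
    if n < 2:
        raise ValueError(f"need >= 2 folds, got {n}")
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        if mean == 0.0:
            return FoldComparison(a, b, 0.0, 0.0, df, 1.0, (0.0, 0.0))
        t_stat = float(np.inf) if mean > 0 else float(-np.inf)
        return FoldComparison(a, b, mean, t_stat, df, 0.0, (mean, mean))
    se = sd / np.sqrt(n)
    t_stat = mean / se
    p = float(2 * stats.t.sf(abs(t_stat), df))
    tcrit = float(stats.t.ppf(0.975, df))
    return FoldComparison(a, b, mean, float(t_stat), df, p,
                          (mean - tcrit * se, mean + tcrit * se))
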