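"""Evaluation: patient-level stratified group k-fold, the metric suite
(accuracy, precision/recall/F1, AUROC), confusion matrices in the
clinical-study cell convention, and rater (single-operating-point)
reproduction from row-normalized ratios.

Cell convention.  Rows are truth (row 1 = ASD, row 2 = non-ASD), columns
are prediction (column 1 = ASD).  The four cells are named positionally:
TP = (1,1), FP = (1,2), FN = (2,1), TN = (2,2).  Note that under this
convention "FP" counts ASD patients predicted non-ASD — it is a
row-normalized miss rate, not the usual false-positive count.  All metric
formulas below are written against this convention.

A hard rater (a clinician giving one label per video) has a single ROC
operating point, so their AUROC is the area of the two-segment ROC
polygon: (TPR + TNR) / 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

ASD, NON_ASD = "ASD", "non-ASD"


# ---------------------------------------------------------------------------
# fold assignment

@dataclass
class FoldAssignment:
    """k validation folds of patient ids; the complement of each is train."""

    folds: list[list[str]]

    def __iter__(self):
        return iter(self.folds)

    @property
    def k(self) -> int:
        return len(self.folds)

    def train_val(self, i: int) -> tuple[list[str], list[str]]:
        val = set(self.folds[i])
        train = [p for f in self.folds for p in f if p not in val]
        return train, sorted(val)

    def to_json(self) -> dict:
        return {"k": self.k, "folds": [sorted(f) for f in self.folds]}


def stratified_group_kfold(patient_labels: dict[str, str], k: int = 5,
                           seed: int = 0) -> FoldAssignment:
    """Patient-level stratified k-fold split.

    Greedy label-balanced deal: within each label the (seed-shuffled)
    patients go round-robin to the fold currently holding the fewest
    patients of that label, ties broken toward the smallest fold overall
    and then the lowest fold index.  Every patient lands in exactly one
    validation fold and per-fold class proportions stay within one
    patient of the global proportions.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(patient_labels) < k:
        raise ValueError(f"cannot split {len(patient_labels)} patients into {k} folds")
    labels = sorted(set(patient_labels.values()))
    if len(labels) < 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    folds: list[list[str]] = [[] for _ in range(k)]
    per_label_counts = {lab: [0] * k for lab in labels}
    for lab in labels:
        pids = sorted(p for p, l in patient_labels.items() if l == lab)
        rng.shuffle(pids)
        for pid in pids:
            counts = per_label_counts[lab]
            i = min(range(k), key=lambda j: (counts[j], len(folds[j]), j))
            folds[i].append(pid)
            counts[i] += 1
    return FoldAssignment(folds=folds)


# ---------------------------------------------------------------------------
# confusion matrix and metrics

@dataclass
class ConfusionMatrix:
    n_tp: float  # truth ASD, predicted ASD
    n_fp: float  # truth ASD, predicted non-ASD  (positional naming, see module docstring)
    n_fn: float  # truth non-ASD, predicted ASD
    n_tn: float  # truth non-ASD, predicted non-ASD

    def __post_init__(self):
        if min(self.n_tp, self.n_fp, self.n_fn, self.n_tn) < 0:
            raise ValueError("counts must be >= 0")

    @property
    def n(self) -> float:
        return self.n_tp + self.n_fp + self.n_fn + self.n_tn

    def row_normalized(self) -> np.ndarray:
        """Per-truth-class rates, each row summing to 1."""
        rows = np.array([[self.n_tp, self.n_fp], [self.n_fn, self.n_tn]], float)
        return rows / rows.sum(axis=1, keepdims=True)

    def as_array(self) -> np.ndarray:
        return np.array([[self.n_tp, self.n_fp], [self.n_fn, self.n_tn]], float)


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    auroc: float
    positive_label: str = ASD


@dataclass
class RaterRatios:
    """Row-normalized rates of a hard rater plus the class sizes."""

    tp_rate: float   # truth ASD rated ASD
    fp_rate: float   # truth ASD rated non-ASD
    fn_rate: float   # truth non-ASD rated ASD
    tn_rate: float   # truth non-ASD rated non-ASD
    n_asd: float
    n_non_asd: float

    def __post_init__(self):
        if not (np.isclose(self.tp_rate + self.fp_rate, 1.0)
                and np.isclose(self.fn_rate + self.tn_rate, 1.0)):
            raise ValueError("row rates must sum to 1 per truth class")
        if self.n_asd <= 0 or self.n_non_asd <= 0:
            raise ValueError("class weights must be positive")

    def to_confusion(self) -> ConfusionMatrix:
        """Counts implied by the row rates and class sizes.

        Printed row rates are rounded versions of integer count ratios, so
        each implied count is snapped to the nearest integer when it is
        unambiguously close to one (within 0.05); otherwise the fractional
        value is kept, which leaves every metric ratio unchanged.
        """
        def count(rate, n):
            c = rate * n
            return round(c) if abs(c - round(c)) < 0.05 else c

        return ConfusionMatrix(
            n_tp=count(self.tp_rate, self.n_asd),
            n_fp=count(self.fp_rate, self.n_asd),
            n_fn=count(self.fn_rate, self.n_non_asd),
            n_tn=count(self.tn_rate, self.n_non_asd))


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """Tally labels into the study's cell convention."""
    y_true, y_pred = list(y_true), list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("label sequences must have equal length")
    valid = {ASD, NON_ASD}
    if not set(y_true) <= valid or not set(y_pred) <= valid:
        raise ValueError(f"labels must be in {valid}")
    yt = np.array([t == ASD for t in y_true])
    yp = np.array([p == ASD for p in y_pred])
    return ConfusionMatrix(
        n_tp=int(np.sum(yt & yp)), n_fp=int(np.sum(yt & ~yp)),
        n_fn=int(np.sum(~yt & yp)), n_tn=int(np.sum(~yt & ~yp)))


def accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of agreeing labels: (TP + TN) / N."""
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    return (cm.n_tp + cm.n_tn) / cm.n


def f1(cm: ConfusionMatrix, positive_label: str = ASD) -> float:
    """F1 = 2 * precision * recall / (precision + recall) for the chosen
    positive class; 0 when precision + recall is 0."""
    p, r = precision_recall(cm, positive_label)
    if p + r == 0:
        return 0.0
    return 2 * p * r / (p + r)


def precision_recall(cm: ConfusionMatrix, positive_label: str = ASD
                     ) -> tuple[float, float]:
    if positive_label == ASD:
        correct, predicted, actual = cm.n_tp, cm.n_tp + cm.n_fn, cm.n_tp + cm.n_fp
    elif positive_label == NON_ASD:
        correct, predicted, actual = cm.n_tn, cm.n_tn + cm.n_fp, cm.n_tn + cm.n_fn
    else:
        raise ValueError(f"unknown label {positive_label!r}")
    if actual == 0:
        raise ValueError(f"no actual {positive_label} instances")
    p = correct / predicted if predicted > 0 else 0.0
    return p, correct / actual


def auroc(y_true, scores, positive_label: str = ASD) -> float:
    """Probability that a random positive outscores a random negative,
    ties counted one half (the rank / Mann-Whitney statistic; equal to the
    trapezoidal ROC area)."""
    y = np.array([t == positive_label for t in y_true])
    s = np.asarray(scores, dtype=float)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(s)  # average ranks handle ties at 1/2
    return (ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def rater_auroc(cm: ConfusionMatrix) -> float:
    """Single-operating-point ROC area (TPR + TNR) / 2 for a hard rater."""
    rates = cm.row_normalized()
    return 0.5 * (rates[0, 0] + rates[1, 1])


def report_from_ratios(r: RaterRatios, positive_label: str = NON_ASD
                       ) -> MetricsReport:
    """Full metric report reconstructed from row-normalized rater ratios.

    Accuracy, F1 and the hard-rater AUROC depend only on the row rates and
    the class-size ratio, so printed ratios suffice — no per-video labels
    are needed.
    """
    cm = r.to_confusion()
    p, rec = precision_recall(cm, positive_label)
    return MetricsReport(accuracy=accuracy(cm), precision=p, recall=rec,
                         f1=f1(cm, positive_label), auroc=rater_auroc(cm),
                         positive_label=positive_label)


def aggregate_cv(values) -> float:
    """Cross-validation aggregate: the arithmetic mean of per-fold values."""
    values = list(values)
    if not values:
        raise ValueError("nothing to aggregate")
    return float(np.mean(values))


def evaluate_predictions(y_true, y_pred, scores,
                         positive_label: str = ASD) -> MetricsReport:
    """Report from hard labels plus continuous positive-class scores."""
    cm = confusion(y_true, y_pred)
    p, r = precision_recall(cm, positive_label)
    return MetricsReport(accuracy=accuracy(cm), precision=p, recall=r,
                         f1=f1(cm, positive_label),
                         auroc=auroc(y_true, scores, positive_label),
                         positive_label=positive_label)


def plot_confusion(cm: ConfusionMatrix, path, title: str = ""):
    """Row-normalized confusion-matrix figure (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    rates = cm.row_normalized()
    fig, ax = plt.subplots(figsize=(3.2, 3))
    ax.imshow(rates, cmap="Blues", vmin=0, vmax=1)
    for (i, j), v in np.ndenumerate(rates):
        ax.text(j, i, f"{v:.4f}", ha="center", va="center",
                color="white" if v > 0.5 else "black")
    ax.set_xticks([0, 1], [ASD, NON_ASD])
    ax.set_yticks([0, 1], [ASD, NON_ASD])
    ax.set_xlabel("predicted")
    ax.set_ylabel("truth")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
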