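"""Evaluation metrics: SN/SP/ACC/MCC/AUC, fold aggregation, rank-test comparison.

AUC is computed through the Mann–Whitney identity
``AUC = P(score_pos > score_neg) + 0.5 * P(tie)`` using midranks, which is
exact (no trapezoid discretization). Classification metrics follow the
standard confusion-table definitions with a positive call at
``score >= threshold``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class MetricsReport:
    """One model's performance on one evaluation set."""

    SN: float
    SP: float
    ACC: float
    MCC: float
    AUC: float
    n: int
    threshold: float

    def as_dict(self) -> dict[str, float]:
        return {"SN": self.SN, "SP": self.SP, "ACC": self.ACC,
                "MCC": self.MCC, "AUC": self.AUC}


def confusion_counts(
    labels: Sequence[int], scores: Sequence[float], threshold: float
) -> ConfusionCounts:
    """Tally the confusion table with a positive call at score >= threshold."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {s.shape}")
    if y.size == 0:
        raise ValueError("empty input")
    pred = s >= threshold
    pos = y == 1
    return ConfusionCounts(
        TP=int(np.sum(pred & pos)),
        TN=int(np.sum(~pred & ~pos)),
        FP=int(np.sum(pred & ~pos)),
        FN=int(np.sum(~pred & pos)),
    )


def compute_metrics(c: ConfusionCounts) -> dict[str, float]:
    """SN, SP, ACC and MCC from a confusion table.

    A metric whose denominator is zero is reported as ``nan`` (undefined)
    rather than silently zero.
    """
    def ratio(num: int, den: int) -> float:
        return num / den if den else math.nan

    sn = ratio(c.TP, c.TP + c.FN)
    sp = ratio(c.TN, c.TN + c.FP)
    acc = ratio(c.TP + c.TN, c.total)
    den = (c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    mcc = (c.TP * c.TN - c.FP * c.FN) / math.sqrt(den) if den else math.nan
    return {"SN": sn, "SP": sp, "ACC": acc, "MCC": mcc}


def roc_auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Exact ROC AUC via the midrank Mann–Whitney statistic."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores must have equal length")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(s)  # midranks for ties
    u = float(np.sum(ranks[y == 1])) - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def evaluate(
    labels: Sequence[int], scores: Sequence[float], threshold: float
) -> MetricsReport:
    """Full report (SN/SP/ACC/MCC at ``threshold``, plus AUC)."""
    c = confusion_counts(labels, scores, threshold)
    m = compute_metrics(c)
    return MetricsReport(
        SN=m["SN"], SP=m["SP"], ACC=m["ACC"], MCC=m["MCC"],
        AUC=roc_auc(labels, scores), n=c.total, threshold=threshold,
    )


@dataclass(frozen=True)
class FoldSummary:
    """Per-metric mean and sample standard deviation across fold models."""

    mean: dict[str, float]
    sd: dict[str, float]
    n_folds: int

    def format(self, metric: str, digits: int = 3) -> str:
        return f"{self.mean[metric]:.{digits}f} ± {self.sd[metric]:.{digits}f}"


METRIC_NAMES = ("SN", "SP", "ACC", "MCC", "AUC")


def aggregate_folds(reports: Sequence[MetricsReport]) -> FoldSummary:
    """Mean and sample (n-1) SD of each metric over fold models."""
    if len(reports) < 2:
        raise ValueError("need at least 2 fold reports to aggregate")
    vals = {m: np.array([r.as_dict()[m] for r in reports]) for m in METRIC_NAMES}
    return FoldSummary(
        mean={m: float(v.mean()) for m, v in vals.items()},
        sd={m: float(v.std(ddof=1)) for m, v in vals.items()},
        n_folds=len(reports),
    )


def compare_models(
    samples_a: Sequence[float], samples_b: Sequence[float]
) -> float:
    """Two-sided Mann–Whitney U p-value between two metric samples.

    Uses the exact U distribution for small tie-free samples and the normal
    approximation (with tie correction) otherwise.
    """
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if np.array_equal(np.sort(a), np.sort(b)):
        return 1.0
    return float(mannwhitneyu(a, b, alternative="two-sided", method="auto").pvalue)


def roc_points(
    labels: Sequence[int], scores: Sequence[float],
    path: str | Path | None = None,
) -> pd.DataFrame:
    """ROC curve points (threshold, FPR, TPR); optionally saved as CSV."""
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(labels, scores)
    df = pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})
    if path is not None:
        df.to_csv(path, index=False)
    return df


def summary_table(
    summaries: dict[str, FoldSummary], path: str | Path | None = None
) -> pd.DataFrame:
    """Classifier-by-metric table of "mean ± sd" strings; optionally saved as TSV."""
    rows = [
        {"Classifier": name, **{m: s.format(m) for m in METRIC_NAMES}}
        for name, s in summaries.items()
    ]
    df = pd.DataFrame(rows, columns=["Classifier", *METRIC_NAMES])
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
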