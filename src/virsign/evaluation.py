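"""Classifier benchmark metrics: ROC, PR, matched-FPR TPR, bootstrap.

AUROC is computed exactly as the Mann-Whitney rank statistic
U / (n_pos * n_neg) with ties contributing 1/2 — equivalent to the
trapezoidal area under the ROC curve but free of curve-integration
choices; the curve itself is returned for plotting.  AUPRC uses the
step-wise (non-interpolated) area, i.e. average precision.  TPR at
matched FPR supports fair comparison against an external caller: pick
the most permissive threshold whose FPR does not exceed the
comparator's, and read the TPR there.  Bootstrap replication is
stratified so every resample preserves the evaluation class mixture.

The Bayes-rule precision identity

    P(viral | called) = TPR * rho / (TPR * rho + FPR * (1 - rho))

links the per-class rates to the expected precision at viral fraction
rho; it is identical to precision computed from confusion counts in the
large-sample limit.
"""

from __future__ import annotations

import dataclasses
from typing import Callable

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_curve

__all__ = [
    "LabeledScores",
    "RocResult",
    "PrResult",
    "BootstrapResult",
    "roc_auroc",
    "auroc",
    "pr_auprc",
    "tpr_at_fpr",
    "bootstrap_metric",
    "bayes_precision",
]


@dataclasses.dataclass(frozen=True)
class LabeledScores:
    """Scores with binary ground truth (1 = viral)."""

    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=np.float64)
        y = np.asarray(self.labels)
        if s.shape != y.shape or s.ndim != 1:
            raise ValueError("scores and labels must be equal-length 1-D arrays")
        if not np.isin(y, [0, 1]).all():
            raise ValueError("labels must be binary (0 = host, 1 = virus)")
        object.__setattr__(self, "scores", s)
        object.__setattr__(self, "labels", y.astype(np.int64))

    @property
    def n_pos(self) -> int:
        return int(self.labels.sum())

    @property
    def n_neg(self) -> int:
        return len(self.labels) - self.n_pos


@dataclasses.dataclass(frozen=True)
class RocResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auroc: float


@dataclasses.dataclass(frozen=True)
class PrResult:
    precision: np.ndarray
    recall: np.ndarray
    auprc: float


@dataclasses.dataclass(frozen=True)
class BootstrapResult:
    mean: float
    se: float
    replicates: np.ndarray


def _require_both_classes(ls: LabeledScores) -> None:
    if ls.n_pos == 0 or ls.n_neg == 0:
        raise ValueError(
            f"metric undefined with a single class ({ls.n_pos} positives, "
            f"{ls.n_neg} negatives)"
        )


def auroc(ls: LabeledScores) -> float:
    """AUROC as the Mann-Whitney statistic; ties count 1/2."""
    _require_both_classes(ls)
    ranks = stats.rankdata(ls.scores)
    u = ranks[ls.labels == 1].sum() - ls.n_pos * (ls.n_pos + 1) / 2
    return float(u / (ls.n_pos * ls.n_neg))


def roc_auroc(ls: LabeledScores) -> RocResult:
    """Full ROC sweep plus the exact rank-statistic AUROC."""
    _require_both_classes(ls)
    fpr, tpr, thr = roc_curve(ls.labels, ls.scores, drop_intermediate=False)
    return RocResult(thresholds=thr, fpr=fpr, tpr=tpr, auroc=auroc(ls))


def pr_auprc(ls: LabeledScores) -> PrResult:
    """Precision-recall sweep with step-wise (average precision) area."""
    if ls.n_pos == 0:
        raise ValueError("precision-recall is undefined without positives")
    precision, recall, _ = precision_recall_curve(ls.labels, ls.scores)
    ap = float(average_precision_score(ls.labels, ls.scores))
    return PrResult(precision=precision, recall=recall, auprc=ap)


def tpr_at_fpr(ls: LabeledScores, target_fpr: float) -> float:
    """Largest TPR achievable at any threshold with FPR <= target."""
    _require_both_classes(ls)
    if not 0.0 <= target_fpr <= 1.0:
        raise ValueError(f"target FPR must be in [0, 1], got {target_fpr}")
    fpr, tpr, _ = roc_curve(ls.labels, ls.scores, drop_intermediate=False)
    ok = fpr <= target_fpr + 1e-12
    return float(tpr[ok].max())


def bootstrap_metric(
    ls: LabeledScores,
    metric: Callable[[LabeledScores], float],
    B: int = 30,
    seed: int = 0,
    max_retries: int = 10,
) -> BootstrapResult:
    """Stratified bootstrap of a metric: B resamples with replacement
    preserving class sizes; returns mean, standard error, and the
    replicate vector (for paired tests between conditions)."""
    if B < 2:
        raise ValueError(f"need at least 2 bootstrap replicates, got {B}")
    _require_both_classes(ls)
    rng = np.random.default_rng(seed)
    pos_idx = np.nonzero(ls.labels == 1)[0]
    neg_idx = np.nonzero(ls.labels == 0)[0]
    reps = np.empty(B)
    for b in range(B):
        for attempt in range(max_retries + 1):
            take = np.concatenate(
                [
                    rng.choice(pos_idx, size=len(pos_idx), replace=True),
                    rng.choice(neg_idx, size=len(neg_idx), replace=True),
                ]
            )
            try:
                reps[b] = metric(LabeledScores(ls.scores[take], ls.labels[take]))
                break
            except ValueError:
                if attempt == max_retries:
                    raise
    return BootstrapResult(mean=float(reps.mean()), se=float(reps.std(ddof=1)), replicates=reps)


def bayes_precision(tpr: float, fpr: float, p_virus: float) -> float:
    """Expected precision from the per-class call rates and viral fraction."""
    for name, v in (("tpr", tpr), ("fpr", fpr), ("p_virus", p_virus)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    denom = tpr * p_virus + fpr * (1.0 - p_virus)
    if denom == 0.0:
        raise ValueError("precision undefined: no sequences are called viral")
    return tpr * p_virus / denom
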