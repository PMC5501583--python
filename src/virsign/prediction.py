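"""Scoring query contigs with p-values and false-discovery control.

A contig's score is the fitted probability that it is viral,
logistic(beta0 + sum_w beta(w) V(w)).  Scores from models trained at
different fragment lengths are not directly comparable, so each contig
is routed by length to one of the three length-class models and its
score is converted to an empirical p-value: the fraction of held-out
host ("null") fragments whose score under that same model strictly
exceeds the query's.  The batch of p-values is then converted to
q-values (positive false discovery rates) with Storey's smoother
estimate of the null proportion pi0, making calls comparable across
models and giving each threshold an FDR interpretation.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Sequence, TextIO

import numpy as np
from scipy import interpolate

from .kmer_features import featurize
from .sequence_data import GenomeRecord
from .training import ModelBundle, TrainedModel

__all__ = [
    "PredictionRecord",
    "score_sequence",
    "empirical_pvalue",
    "estimate_pi0",
    "qvalues",
    "predict_contigs",
    "write_prediction_table",
]

#: contigs shorter than this are scored with the 500 bp model but flagged
MIN_EVALUATED_LENGTH = 500


@dataclasses.dataclass
class PredictionRecord:
    """Per-contig prediction: routed model, score, p-value, q-value."""

    contig_id: str
    length: int
    model_L: int | None
    score: float | None
    p_value: float | None
    q_value: float | None = None
    flag: str = ""  # empty = clean; otherwise a reason / caveat code

    @property
    def scored(self) -> bool:
        return self.score is not None


def score_sequence(model: TrainedModel, seq: str) -> float:
    """P(viral) for one sequence under one length-class model.

    Raises ``ValueError`` if the sequence yields no valid k-mer windows
    (shorter than k, or entirely N).
    """
    fv = featurize(seq, model.space)  # raises on empty signature
    return float(model.score_matrix(fv.freqs[None, :])[0])


def empirical_pvalue(
    null_scores: np.ndarray, s: float, smoothed: bool = False
) -> float:
    """Fraction of null (host) scores strictly greater than *s*.

    ``smoothed=True`` uses the add-one variant (#greater + 1)/(n + 1),
    which avoids exact zeros that degrade downstream q-value estimation;
    the default is the plain fraction.
    """
    null_scores = np.asarray(null_scores)
    if null_scores.size == 0:
        raise ValueError("empirical p-value requires a non-empty null distribution")
    n = null_scores.size
    greater = n - int(np.searchsorted(null_scores, s, side="right"))
    if smoothed:
        return (greater + 1) / (n + 1)
    return greater / n


def estimate_pi0(p: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Storey's smoother estimate of the null proportion pi0.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is computed over the
    tuning grid (default 0.05..0.95 step 0.05), a cubic smoothing spline
    is fit, and the fitted value at the largest grid point is returned,
    clamped into (0, 1].
    """
    p = np.asarray(p, dtype=np.float64)
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    m = p.size
    pi0_lam = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    try:
        spline = interpolate.UnivariateSpline(lambdas, pi0_lam, k=3)
        pi0 = float(spline(lambdas[-1]))
    except Exception:
        pi0 = float(pi0_lam[-1])
    if math.isnan(pi0) or not (0.0 < pi0 <= 1.0):
        warnings.warn(
            f"pi0 estimate {pi0:.3g} outside (0, 1]; clamped to 1", stacklevel=2
        )
        pi0 = 1.0
    return pi0


def qvalues(p: Sequence[float], pi0: float | None = None) -> np.ndarray:
    """Positive-FDR q-values for a batch of p-values.

    On the sorted p-values, q_(i) = min_{j >= i} pi0 * m * p_(j) / j,
    mapped back to the input order; the result is monotone non-decreasing
    in p and capped at 1.
    """
    p = np.asarray(p, dtype=np.float64)
    if p.size == 0:
        raise ValueError("q-value estimation requires at least one p-value")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if pi0 is None:
        pi0 = estimate_pi0(p)
    m = p.size
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    q_sorted = pi0 * m * p_sorted / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def predict_contigs(
    bundle: ModelBundle,
    contigs: Sequence[GenomeRecord],
    smoothed_pvalues: bool = False,
) -> list[PredictionRecord]:
    """Route, score, and attach p- and q-values to a batch of contigs.

    Contigs are routed by length (<1 kb -> 500 bp model, 1-3 kb -> 1 kb
    model, >=3 kb -> 3 kb model), scored, p-valued against the routed
    model's null distribution, and the whole batch shares one q-value
    estimation over the pooled p-values.  Output order equals input
    order; unscoreable contigs (all N or shorter than k) carry a reason
    flag and NA values.
    """
    records: list[PredictionRecord] = []
    for contig in contigs:
        length = len(contig.sequence)
        L = bundle.route(length)
        model = bundle.models[L]
        flag = "below_500bp" if length < MIN_EVALUATED_LENGTH else ""
        try:
            s = score_sequence(model, contig.sequence)
        except ValueError:
            records.append(
                PredictionRecord(
                    contig_id=contig.id,
                    length=length,
                    model_L=None,
                    score=None,
                    p_value=None,
                    flag="empty_signature",
                )
            )
            continue
        pv = empirical_pvalue(model.null_scores, s, smoothed=smoothed_pvalues)
        records.append(
            PredictionRecord(
                contig_id=contig.id, length=length, model_L=L, score=s, p_value=pv, flag=flag
            )
        )
    scored = [r for r in records if r.scored]
    if scored:
        qs = qvalues([r.p_value for r in scored])
        for r, qv in zip(scored, qs):
            r.q_value = float(qv)
    return records


def write_prediction_table(records: Sequence[PredictionRecord], handle: TextIO) -> None:
    """Tab-separated prediction report, one row per contig in input order."""
    handle.write("name\tlength\tmodel_L\tscore\tpvalue\tqvalue\treason\n")
    for r in records:
        if r.scored:
            handle.write(
                f"{r.contig_id}\t{r.length}\t{r.model_L}\t{r.score:.6g}\t"
                f"{r.p_value:.6g}\t{r.q_value:.6g}\t{r.flag}\n"
            )
        else:
            handle.write(f"{r.contig_id}\t{r.length}\tNA\tNA\tNA\tNA\t{r.flag}\n")
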