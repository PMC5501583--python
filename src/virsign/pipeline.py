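"""End-to-end experiment workflows on synthetic corpora.

These helpers wire the generator, trainer, predictor, and metrics into
the standard benchmark protocol: generate a two-class genome corpus,
hold out a fraction of genomes (genome-level, never fragment-level) for
evaluation, train a length-class model on the rest, and score the
held-out fragments.  On top of that sit the three classic robustness
experiments: null-calibration of empirical p-values, sensitivity to
point mutations, and behavior across viral-fraction mixtures.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import stats

from . import synthetic
from .evaluation import LabeledScores, auroc, pr_auprc
from .prediction import empirical_pvalue
from .sequence_data import Fragment, GenomeRecord, mutate_sequence, split_genome
from .training import TrainedModel, train_single_model

__all__ = [
    "ExperimentResult",
    "split_genomes",
    "run_benchmark",
    "held_out_scores",
    "calibration_ks",
    "mixture_scores",
    "mutated_scores",
]


@dataclasses.dataclass
class ExperimentResult:
    """A trained model plus its held-out evaluation material."""

    model: TrainedModel
    eval_virus_frags: list[Fragment]
    eval_host_frags: list[Fragment]
    virus_scores: np.ndarray
    host_scores: np.ndarray

    @property
    def labeled_scores(self) -> LabeledScores:
        scores = np.concatenate([self.virus_scores, self.host_scores])
        labels = np.concatenate(
            [np.ones(len(self.virus_scores), dtype=int), np.zeros(len(self.host_scores), dtype=int)]
        )
        return LabeledScores(scores, labels)

    @property
    def held_out_auroc(self) -> float:
        return auroc(self.labeled_scores)


def split_genomes(
    records: Sequence[GenomeRecord], eval_fraction: float, seed: int
) -> tuple[list[GenomeRecord], list[GenomeRecord]]:
    """Random genome-level train/evaluation split."""
    if not 0.0 < eval_fraction < 1.0:
        raise ValueError("eval_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    n_eval = max(1, int(round(eval_fraction * len(records))))
    if n_eval >= len(records):
        raise ValueError("eval split would consume every genome")
    eval_set = [records[i] for i in order[:n_eval]]
    train_set = [records[i] for i in order[n_eval:]]
    return train_set, eval_set


def run_benchmark(
    n_virus: int = 200,
    n_host: int = 200,
    divergence: float = synthetic.DEFAULT_DIVERGENCE,
    genome_length: int = synthetic.DEFAULT_GENOME_LENGTH,
    L: int = 500,
    k: int = 4,
    seed: int = 0,
    eval_fraction: float = 0.3,
    folds: int = 10,
    n_lambda: int = 30,
    lambda_min_ratio: float = 1e-2,
    tol: float = 1e-4,
) -> ExperimentResult:
    """Generate a corpus, train one length-class model, score held-out
    fragments.

    Genomes (not fragments) are split so no evaluation fragment shares a
    parent genome with any training or null fragment.  For the benchmark
    the lambda grid is coarsened to *n_lambda* points with a higher floor
    (lambda_max * 1e-2) and a looser solver tolerance than the production
    defaults; near the production floor the nearly unregularized fits are
    expensive and CV never selects them.
    """
    rng = np.random.default_rng(seed)
    virus, host = synthetic.make_two_class_corpus(
        n_virus=n_virus,
        n_host=n_host,
        divergence=divergence,
        genome_length=genome_length,
        seed=int(rng.integers(2**31)),
    )
    virus_train, virus_eval = split_genomes(virus, eval_fraction, int(rng.integers(2**31)))
    host_train, host_eval = split_genomes(host, eval_fraction, int(rng.integers(2**31)))

    model = train_single_model(
        virus_train,
        host_train,
        L=L,
        k=k,
        seed=int(rng.integers(2**31)),
        folds=folds,
        n_lambda=n_lambda,
        lambda_min_ratio=lambda_min_ratio,
        tol=tol,
    )
    ev_virus = [f for g in virus_eval for f in split_genome(g, L)]
    ev_host = [f for g in host_eval for f in split_genome(g, L)]
    return ExperimentResult(
        model=model,
        eval_virus_frags=ev_virus,
        eval_host_frags=ev_host,
        virus_scores=model.score_sequences([f.sequence for f in ev_virus]),
        host_scores=model.score_sequences([f.sequence for f in ev_host]),
    )


def held_out_scores(result: ExperimentResult) -> LabeledScores:
    return result.labeled_scores


def calibration_ks(result: ExperimentResult, n: int = 1000) -> float:
    """Kolmogorov-Smirnov distance of held-out host p-values from U(0,1).

    Host evaluation fragments come from the same generator as the null
    genomes, so their empirical p-values should be approximately uniform
    when the null distribution is honest.
    """
    scores = result.host_scores[:n]
    pvals = np.array(
        [empirical_pvalue(result.model.null_scores, s) for s in scores]
    )
    return float(stats.kstest(pvals, stats.uniform.cdf).statistic)


def mixture_scores(
    result: ExperimentResult, viral_fraction: float, seed: int = 0
) -> LabeledScores:
    """Evaluation set re-mixed to the requested viral fraction.

    The majority class keeps its full pool; the minority class is
    subsampled to hit the fraction, so mixtures share as many scores as
    possible and differences between them reflect composition, not
    resampling of both classes.
    """
    if not 0.0 < viral_fraction < 1.0:
        raise ValueError("viral_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    v, h = result.virus_scores, result.host_scores
    ratio = viral_fraction / (1.0 - viral_fraction)
    if ratio <= len(v) / len(h):
        n_v = max(1, int(round(ratio * len(h))))
        v = rng.choice(v, size=n_v, replace=False)
    else:
        n_h = max(1, int(round(len(v) / ratio)))
        h = rng.choice(h, size=n_h, replace=False)
    scores = np.concatenate([v, h])
    labels = np.concatenate([np.ones(len(v), dtype=int), np.zeros(len(h), dtype=int)])
    return LabeledScores(scores, labels)


def mutated_scores(result: ExperimentResult, rate: float, seed: int = 0) -> LabeledScores:
    """Held-out scores after injecting point substitutions at *rate*."""
    rng = np.random.default_rng(seed)
    frags = result.eval_virus_frags + result.eval_host_frags
    seqs = [
        mutate_sequence(f.sequence, rate, seed=int(rng.integers(2**31))) for f in frags
    ]
    scores = result.model.score_sequences(seqs)
    labels = np.concatenate(
        [
            np.ones(len(result.eval_virus_frags), dtype=int),
            np.zeros(len(result.eval_host_frags), dtype=int),
        ]
    )
    return LabeledScores(scores, labels)
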