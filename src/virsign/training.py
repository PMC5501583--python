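"""Fitting the virus/host classifier for one fragment-length class.

The model is a logistic regression on canonical k-mer frequencies with a
lasso (L1) penalty:

    minimize  -(1/n) sum_i log l(Y_i | V_i(w), beta(w), beta0)
              + lambda * sum_w |beta(w)|

where Y_i = 1 marks a viral training fragment and V_i(w) is the
normalized word-frequency signature.  Because the frequencies obey the
unit-sum constraint sum_w V(w) = 1, the design matrix is exactly
collinear; before fitting, a two-sample t statistic compares the mean
frequency of each word between classes and the single least significant
word (highest p value) is removed to break the collinearity.

The penalty weight lambda is chosen by stratified 10-fold cross
validation to maximize the mean out-of-fold AUROC over a log-spaced grid
running from lambda_max (the smallest penalty that zeroes every
coefficient) down to lambda_max * 1e-4; ties are broken toward the
larger (sparser) lambda.  Features are left on their natural frequency
scale — no standardization — so beta(w) is directly interpretable as the
log-odds effect of word w's frequency.  The intercept is unpenalized.

After fitting, the score distribution of fragments from held-out host
genomes is stored with the model as its null distribution, the reference
against which query p-values are later computed.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import special, stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .kmer_features import KmerSpace, enumerate_canonical_kmers, feature_matrix
from .sequence_data import Fragment, GenomeRecord, split_genome, subsample_fragments

__all__ = [
    "TrainingSet",
    "TrainedModel",
    "ModelBundle",
    "ScreenResult",
    "build_training_set",
    "t_screen",
    "lambda_max",
    "default_lambda_grid",
    "fit_lasso_logistic",
    "capture_null_scores",
    "train_single_model",
    "train_bundle",
    "MODEL_FORMAT_VERSION",
    "LENGTH_CLASSES",
]

MODEL_FORMAT_VERSION = 1
LENGTH_CLASSES = (500, 1000, 3000)
#: training fragments with more than this fraction of N are discarded
MAX_N_FRACTION = 0.10


@dataclasses.dataclass
class TrainingSet:
    """Balanced labeled feature matrix for one fragment-length class."""

    X: np.ndarray  # (n, space.size) row-normalized signatures
    y: np.ndarray  # 1 = virus, 0 = host
    L: int
    k: int
    space: KmerSpace

    def __post_init__(self) -> None:
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y disagree on sample count")

    @property
    def class_counts(self) -> tuple[int, int]:
        pos = int(self.y.sum())
        return pos, len(self.y) - pos


@dataclasses.dataclass
class ScreenResult:
    t_stats: np.ndarray
    p_values: np.ndarray
    removed_index: int
    removed_word: str


@dataclasses.dataclass
class TrainedModel:
    """A fitted length-class classifier plus its null score distribution."""

    k: int
    L: int
    beta: dict[str, float]  # nonzero coefficients only
    beta0: float
    lambda_: float
    removed_word: str
    null_scores: np.ndarray  # sorted ascending, in [0, 1]
    metadata: dict = dataclasses.field(default_factory=dict)
    _space: KmerSpace | None = dataclasses.field(default=None, repr=False)
    _beta_vec: np.ndarray | None = dataclasses.field(default=None, repr=False)

    @property
    def space(self) -> KmerSpace:
        if self._space is None:
            self._space = enumerate_canonical_kmers(self.k)
        return self._space

    @property
    def beta_vector(self) -> np.ndarray:
        """Coefficients aligned to the canonical word order (removed and
        unselected words are 0)."""
        if self._beta_vec is None:
            vec = np.zeros(self.space.size)
            for word, value in self.beta.items():
                vec[self.space.index_of(word)] = value
            self._beta_vec = vec
        return self._beta_vec

    def score_matrix(self, X: np.ndarray) -> np.ndarray:
        """P(virus | signature) for each row of a feature matrix."""
        return special.expit(X @ self.beta_vector + self.beta0)

    def score_sequences(self, seqs: Sequence[str]) -> np.ndarray:
        return self.score_matrix(feature_matrix(list(seqs), self.space))

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "format_version": MODEL_FORMAT_VERSION,
            "k": self.k,
            "L": self.L,
            "beta0": self.beta0,
            "lambda": self.lambda_,
            "removed_word": self.removed_word,
            "beta": {w: v for w, v in sorted(self.beta.items())},
            "null_scores": [float(s) for s in self.null_scores],
            "metadata": self.metadata,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TrainedModel":
        d = json.loads(text)
        version = d.get("format_version")
        if version != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"unsupported model format version {version!r} "
                f"(this build reads version {MODEL_FORMAT_VERSION})"
            )
        return cls(
            k=d["k"],
            L=d["L"],
            beta={w: float(v) for w, v in d["beta"].items()},
            beta0=float(d["beta0"]),
            lambda_=float(d["lambda"]),
            removed_word=d["removed_word"],
            null_scores=np.asarray(d["null_scores"], dtype=np.float64),
            metadata=d.get("metadata", {}),
        )


@dataclasses.dataclass
class ModelBundle:
    """The three length-class models plus the routing thresholds."""

    models: dict[int, TrainedModel]

    def __post_init__(self) -> None:
        missing = set(LENGTH_CLASSES) - set(self.models)
        if missing:
            raise ValueError(f"bundle is missing length classes: {sorted(missing)}")
        ks = {m.k for m in self.models.values()}
        if len(ks) != 1:
            raise ValueError(f"bundle models disagree on k: {sorted(ks)}")

    @property
    def k(self) -> int:
        return self.models[LENGTH_CLASSES[0]].k

    def route(self, length: int) -> int:
        """Length class for a query contig: the 500 bp model scores
        contigs under 1 kb, the 1 kb model 1-3 kb, the 3 kb model 3 kb
        and above."""
        if length < 1000:
            return 500
        if length < 3000:
            return 1000
        return 3000

    def model_for(self, length: int) -> TrainedModel:
        return self.models[self.route(length)]

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {"format_version": MODEL_FORMAT_VERSION, "k": self.k, "models": {}}
        for L, model in sorted(self.models.items()):
            name = f"model_L{L}.json"
            (directory / name).write_text(model.to_json())
            manifest["models"][str(L)] = name
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "ModelBundle":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        if manifest.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"unsupported bundle format version {manifest.get('format_version')!r}"
            )
        models = {
            int(L): TrainedModel.from_json((directory / name).read_text())
            for L, name in manifest["models"].items()
        }
        return cls(models=models)


# -- training-set construction -------------------------------------------


def _n_fraction(seq: str) -> float:
    return seq.count("N") / len(seq) if seq else 1.0


def filter_high_n(fragments: Sequence[Fragment]) -> list[Fragment]:
    return [f for f in fragments if _n_fraction(f.sequence) <= MAX_N_FRACTION]


def build_training_set(
    virus_frags: Sequence[Fragment],
    host_frags: Sequence[Fragment],
    k: int,
    L: int,
    space: KmerSpace | None = None,
) -> TrainingSet:
    """Assemble the labeled signature matrix from fragment pools."""
    space = space or enumerate_canonical_kmers(k)
    seqs = [f.sequence for f in virus_frags] + [f.sequence for f in host_frags]
    X = feature_matrix(seqs, space)
    y = np.concatenate(
        [np.ones(len(virus_frags), dtype=np.int64), np.zeros(len(host_frags), dtype=np.int64)]
    )
    return TrainingSet(X=X, y=y, L=L, k=k, space=space)


# -- screening ------------------------------------------------------------


def t_screen(train: TrainingSet) -> ScreenResult:
    """Per-word two-sample t test (pooled variance) of virus vs. host
    mean frequencies; the least significant word is marked for removal.

    A word with zero pooled variance gets t = 0, p = 1, making it the
    removal candidate when every other word differs between classes.
    Exactly one word is removed; its purpose is to break the exact
    collinearity induced by the unit-sum constraint on frequencies.
    """
    pos, neg = train.class_counts
    if pos < 2 or neg < 2:
        raise ValueError(f"need at least 2 samples per class, got {pos} virus / {neg} host")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant columns produce nan
        t, p = stats.ttest_ind(train.X[train.y == 1], train.X[train.y == 0], equal_var=True)
    t = np.where(np.isfinite(t), t, 0.0)
    p = np.where(np.isfinite(p), p, 1.0)
    removed = int(np.argmax(p))
    return ScreenResult(
        t_stats=t,
        p_values=p,
        removed_index=removed,
        removed_word=train.space.words[removed],
    )


# -- lasso path -----------------------------------------------------------


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which every coefficient is exactly zero.

    At the null model (intercept only, fitted probability ybar) the
    gradient of the mean log-likelihood w.r.t. beta_j is
    x_j . (y - ybar) / n; the KKT conditions zero all coefficients iff
    lambda dominates the largest such gradient in magnitude.
    """
    resid = y - y.mean()
    return float(np.abs(X.T @ resid).max() / len(y))


def default_lambda_grid(
    X: np.ndarray, y: np.ndarray, n_lambda: int = 100, min_ratio: float = 1e-4
) -> np.ndarray:
    """Log-spaced grid from lambda_max down to lambda_max * min_ratio."""
    lmax = lambda_max(X, y)
    return np.geomspace(lmax, lmax * min_ratio, n_lambda)


def _fit_path(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit the L1 path with warm starts along decreasing lambda.

    Returns (coefs (n_lambda, p), intercepts (n_lambda,), converged mask).
    The mean-log-likelihood objective maps onto scikit-learn's penalized
    sum formulation with C = 1 / (n * lambda * c).

    Internally the columns are centered and the matrix multiplied by one
    global constant c (the penalty by c, the returned coefficients by
    1/c, the intercept corrected for the centering) — an exact
    reparametrization of the stated objective that brings the tiny
    frequency-scale columns to unit order so the coordinate-descent
    solver conditions well.  This is not standardization: no per-column
    scaling is applied and the returned model is the optimum on the raw
    frequencies.
    """
    n = len(y)
    mu = X.mean(axis=0)
    Xc = X - mu
    rms = float(np.sqrt((Xc**2).mean()))
    c = 1.0 / rms if rms > 0 else 1.0
    Xs = Xc * c
    coefs = np.zeros((len(lambdas), X.shape[1]))
    intercepts = np.zeros(len(lambdas))
    converged = np.ones(len(lambdas), dtype=bool)
    for i, lam in enumerate(lambdas):
        est = LogisticRegression(
            penalty="l1",
            solver="liblinear",
            fit_intercept=True,
            # large relative to the unit-scale features: the L1 cost of
            # the intercept becomes negligible, i.e. beta0 is unpenalized
            intercept_scaling=10.0,
            tol=tol,
            max_iter=max_iter,
            C=1.0 / (n * lam * c),
            random_state=0,  # liblinear tie-breaks; fixed for reproducibility
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            est.fit(Xs, y)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            converged[i] = False
            warnings.warn(
                f"lasso path did not converge at lambda={lam:.4g}; "
                "this grid point is excluded from selection",
                stacklevel=2,
            )
        beta = est.coef_[0] * c
        coefs[i] = beta
        intercepts[i] = est.intercept_[0] - float(beta @ mu)
    return coefs, intercepts, converged


def _auroc(y_true: np.ndarray, scores: np.ndarray) -> float:
    # Mann-Whitney rank form; ties contribute 1/2
    pos = y_true == 1
    n_pos = int(pos.sum())
    n_neg = len(y_true) - n_pos
    ranks = stats.rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def fit_lasso_logistic(
    train: TrainingSet,
    lambda_grid: np.ndarray | Sequence[float] | None = None,
    folds: int = 10,
    seed: int = 0,
    tol: float = 1e-5,
    max_iter: int = 5000,
    screen: ScreenResult | None = None,
) -> TrainedModel:
    """Fit the lasso-logistic classifier with CV-selected penalty.

    The word flagged by :func:`t_screen` is removed before fitting;
    lambda is chosen to maximize mean out-of-fold AUROC over the grid
    (stratified folds, fixed assignment seed), ties broken toward larger
    lambda, and the final model is refit on all data at the winner.
    """
    screen = screen or t_screen(train)
    keep = np.ones(train.X.shape[1], dtype=bool)
    keep[screen.removed_index] = False
    X = train.X[:, keep]
    y = train.y
    kept_words = [w for i, w in enumerate(train.space.words) if keep[i]]

    if lambda_grid is None:
        lambda_grid = default_lambda_grid(X, y)
    lambdas = np.sort(np.asarray(lambda_grid, dtype=np.float64))[::-1]
    if (lambdas <= 0).any():
        raise ValueError("lambda grid values must be positive")

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_auroc = np.zeros((folds, len(lambdas)))
    fold_converged = np.ones((folds, len(lambdas)), dtype=bool)
    for fi, (tr, va) in enumerate(skf.split(X, y)):
        coefs, icepts, conv = _fit_path(X[tr], y[tr], lambdas, tol, max_iter)
        scores = special.expit(X[va] @ coefs.T + icepts)  # (n_va, n_lambda)
        fold_converged[fi] = conv
        for li in range(len(lambdas)):
            fold_auroc[fi, li] = _auroc(y[va], scores[:, li])
    usable = fold_converged.all(axis=0)
    if not usable.any():
        raise RuntimeError("lasso fitting failed to converge at every lambda on the grid")
    mean_auroc = fold_auroc.mean(axis=0)
    masked = np.where(usable, mean_auroc, -np.inf)
    best = int(np.argmax(masked))  # grid descending => first max is largest lambda

    coefs, icepts, conv = _fit_path(X, y, lambdas[: best + 1], tol, max_iter)
    if not conv[best]:
        raise RuntimeError(f"final refit did not converge at lambda={lambdas[best]:.4g}")
    beta_final = coefs[best]
    nonzero = {
        kept_words[j]: float(beta_final[j])
        for j in np.nonzero(beta_final)[0]
    }
    pos, neg = train.class_counts
    metadata = {
        "trained": datetime.date.today().isoformat(),
        "n_virus": pos,
        "n_host": neg,
        "seed": seed,
        "folds": folds,
        "tol": tol,
        "max_iter": max_iter,
        "standardized": False,
        "lambda_grid": [float(x) for x in lambdas],
        "cv_mean_auroc": [float(x) for x in mean_auroc],
        "cv_auroc_at_lambda": float(mean_auroc[best]),
        "n_nonzero": len(nonzero),
    }
    return TrainedModel(
        k=train.k,
        L=train.L,
        beta=nonzero,
        beta0=float(icepts[best]),
        lambda_=float(lambdas[best]),
        removed_word=screen.removed_word,
        null_scores=np.empty(0),
        metadata=metadata,
        _space=train.space,
    )


# -- null capture ---------------------------------------------------------


def capture_null_scores(model: TrainedModel, host_eval: Sequence[Fragment]) -> TrainedModel:
    """Attach the sorted score distribution of held-out host fragments.

    These fragments must come from genomes disjoint from the training
    pool; their scores form the null distribution used for empirical
    p-values.
    """
    if len(host_eval) < 100:
        warnings.warn(
            f"only {len(host_eval)} null fragments: empirical p-value "
            "resolution will be coarser than 0.01",
            stacklevel=2,
        )
    scores = model.score_sequences([f.sequence for f in host_eval])
    model.null_scores = np.sort(scores)
    model.metadata["n_null"] = len(host_eval)
    return model


# -- end-to-end training --------------------------------------------------


def train_single_model(
    virus_genomes: Sequence[GenomeRecord],
    host_genomes: Sequence[GenomeRecord],
    L: int,
    k: int = 8,
    seed: int = 0,
    folds: int = 10,
    lambda_grid: np.ndarray | None = None,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-4,
    null_fraction: float = 0.2,
    space: KmerSpace | None = None,
    tol: float = 1e-5,
    max_iter: int = 5000,
) -> TrainedModel:
    """Train one length-class model following the full data protocol.

    A fraction of host genomes (genome-level, not fragment-level) is
    reserved before training; its fragments supply the null score
    distribution.  Virus genomes are tiled exhaustively into length-L
    fragments and an equal number of host fragments is subsampled from
    the remaining (training) host genomes.
    """
    rng = np.random.default_rng(seed)
    space = space or enumerate_canonical_kmers(k)

    order = rng.permutation(len(host_genomes))
    n_null = max(1, int(round(null_fraction * len(host_genomes))))
    if n_null >= len(host_genomes):
        raise ValueError("not enough host genomes to reserve a null split")
    null_hosts = [host_genomes[i] for i in order[:n_null]]
    train_hosts = [host_genomes[i] for i in order[n_null:]]

    virus_frags = filter_high_n(
        [f for g in virus_genomes for f in split_genome(g, L)]
    )
    if not virus_frags:
        raise ValueError(f"no virus fragments of length {L} could be produced")
    # balanced classes: match the smaller of the virus pool and the host
    # slot capacity, subsampling the larger side at random
    capacity = sum(len(g.sequence) // L for g in train_hosts)
    n_bal = min(len(virus_frags), capacity)
    if n_bal < len(virus_frags):
        take = np.sort(rng.choice(len(virus_frags), size=n_bal, replace=False))
        virus_frags = [virus_frags[i] for i in take]
    host_frags = filter_high_n(
        subsample_fragments(train_hosts, L, n_bal, seed=int(rng.integers(2**31)))
    )
    n_bal = min(len(virus_frags), len(host_frags))
    virus_frags, host_frags = virus_frags[:n_bal], host_frags[:n_bal]

    train = build_training_set(virus_frags, host_frags, k=k, L=L, space=space)
    if lambda_grid is None:
        screen = t_screen(train)
        keep = np.ones(train.X.shape[1], dtype=bool)
        keep[screen.removed_index] = False
        lambda_grid = default_lambda_grid(
            train.X[:, keep], train.y, n_lambda=n_lambda, min_ratio=lambda_min_ratio
        )
    else:
        screen = None
    model = fit_lasso_logistic(
        train,
        lambda_grid=lambda_grid,
        folds=folds,
        seed=int(rng.integers(2**31)),
        screen=screen,
        tol=tol,
        max_iter=max_iter,
    )
    null_frags = filter_high_n([f for g in null_hosts for f in split_genome(g, L)])
    return capture_null_scores(model, null_frags)


def train_bundle(
    virus_genomes: Sequence[GenomeRecord],
    host_genomes: Sequence[GenomeRecord],
    k: int = 8,
    seed: int = 0,
    lengths: Sequence[int] = LENGTH_CLASSES,
    **kwargs,
) -> ModelBundle:
    """Train the full multi-length bundle (one model per length class)."""
    if not virus_genomes or not host_genomes:
        raise ValueError("both virus and host genome sets must be non-empty")
    space = enumerate_canonical_kmers(k)
    models = {}
    for i, L in enumerate(lengths):
        try:
            models[L] = train_single_model(
                virus_genomes,
                host_genomes,
                L=L,
                k=k,
                seed=seed + i,
                space=space,
                **kwargs,
            )
        except Exception as exc:
            raise RuntimeError(f"training failed for length class L={L}: {exc}") from exc
    return ModelBundle(models=models)
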