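"""Subject identification from functional-connectivity matrices.

Three engines share one leave-one-out resampling protocol:

* ``pearson`` — correlate upper-triangle vectors against each subject's
  run-averaged training vector, assign the argmax;
* ``geodesic`` — affine-invariant Riemannian distance between the test
  matrix and each subject's run-averaged training matrix, assign the argmin;
* ``linear`` — one-vs-all ridge regression on vectorized matrices, every
  training run an independent sample, assign the argmax output.

Ties break deterministically toward the lowest subject index and are
counted in the result.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .connectivity import vectorize_upper
from .types import (
    FCMatrix,
    IdentificationResult,
    InvalidArgumentError,
    NeuroprintError,
)

__all__ = [
    "ConditioningError",
    "FCSet",
    "TrainTestSplit",
    "LinearClassifierModel",
    "build_fc_set",
    "geodesic_distance",
    "aggregate_training",
    "identify_pearson",
    "identify_geodesic",
    "identify_linear",
    "train_linear_classifier",
    "combine_contrasts",
    "run_identification_experiment",
    "roi_subsample_experiment",
]

_TIE_TOL = 1e-9


class ConditioningError(NeuroprintError):
    """A matrix is not positive definite where the method requires it."""


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def _values(c: FCMatrix | np.ndarray) -> np.ndarray:
    return c.values if isinstance(c, FCMatrix) else np.asarray(c, dtype=float)


def geodesic_distance(
    c1: FCMatrix | np.ndarray,
    c2: FCMatrix | np.ndarray,
    regularize: bool = True,
    squared: bool = False,
) -> float:
    """Affine-invariant distance sqrt(sum_i ln^2 lambda_i) between SPD
    matrices, with lambda_i the eigenvalues of C1^{-1/2} C2 C1^{-1/2}.

    ``regularize`` adds the identity to both matrices first (guards
    near-singular correlation matrices); ``squared`` returns the trace form
    without the square root — a monotone transform, so matcher decisions
    are identical either way.
    """
    a, b = _values(c1), _values(c2)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise InvalidArgumentError("matrices must share a square shape")
    if regularize:
        eye = np.eye(a.shape[0])
        a = a + eye
        b = b + eye
    try:
        eigs = scipy.linalg.eigvalsh(b, a)
    except (scipy.linalg.LinAlgError, ValueError) as exc:
        raise ConditioningError("matrix pair is not SPD") from exc
    if np.any(eigs <= 0) or not np.all(np.isfinite(eigs)):
        raise ConditioningError("matrix pair is not SPD after regularization")
    total = float(np.sum(np.log(eigs) ** 2))
    return total if squared else float(np.sqrt(total))


def _best_index(scores: np.ndarray, mode: str) -> tuple[int, bool]:
    scores = np.asarray(scores, dtype=float)
    tol = _TIE_TOL * max(1.0, float(np.max(np.abs(scores[np.isfinite(scores)]), initial=0.0)))
    if mode == "max":
        best = np.max(scores)
        candidates = np.flatnonzero(scores >= best - tol)
    else:
        best = np.min(scores)
        candidates = np.flatnonzero(scores <= best + tol)
    return int(candidates[0]), len(candidates) > 1


@dataclass
class TrainTestSplit:
    """One leave-one-out repetition: one test matrix per subject, one or
    more training matrices per subject."""

    test: Mapping[str, FCMatrix]
    train: Mapping[str, Sequence[FCMatrix]]
    repetition_seed: int = 0

    def __post_init__(self) -> None:
        if set(self.test) != set(self.train):
            raise InvalidArgumentError("test and train must cover the same subjects")
        for s, fcs in self.train.items():
            if len(fcs) < 1:
                raise InvalidArgumentError(f"subject {s} has no training matrices")
            test_fc = self.test[s]
            for fc in fcs:
                if fc.run_id and test_fc.run_id and fc.run_id == test_fc.run_id:
                    raise InvalidArgumentError(
                        f"subject {s}: test run {test_fc.run_id} appears in training"
                    )

    @property
    def subjects(self) -> list[str]:
        return sorted(self.test)


def aggregate_training(
    fcs: Sequence[FCMatrix], method: str
) -> FCMatrix | list[FCMatrix]:
    """Elementwise mean matrix for pearson/geodesic (diagonal reset to 1);
    pass-through of independent samples for the linear classifier."""
    if not fcs:
        raise InvalidArgumentError("need at least one training matrix")
    if method == "linear":
        return list(fcs)
    if method not in ("pearson", "geodesic"):
        raise InvalidArgumentError(f"unknown method {method!r}")
    mean = np.mean([_values(fc) for fc in fcs], axis=0)
    np.fill_diagonal(mean, 1.0)
    first = fcs[0]
    return FCMatrix(
        values=mean,
        labels=first.labels,
        subject_id=first.subject_id,
        contrast=first.contrast,
    )


def _pearson_scores(test_vec: np.ndarray, ref_vecs: np.ndarray) -> np.ndarray:
    t = test_vec - test_vec.mean()
    t_sd = np.linalg.norm(t)
    r = ref_vecs - ref_vecs.mean(axis=1, keepdims=True)
    r_sd = np.linalg.norm(r, axis=1)
    scores = np.full(len(ref_vecs), -np.inf)
    if t_sd == 0:
        return scores
    ok = r_sd > 0
    scores[ok] = (r[ok] @ t) / (r_sd[ok] * t_sd)
    return scores


def identify_pearson(split: TrainTestSplit) -> tuple[dict[str, str], int]:
    """Predicted label per subject plus the number of flagged ties."""
    subjects = split.subjects
    refs = np.stack(
        [
            vectorize_upper(aggregate_training(split.train[s], "pearson"))
            for s in subjects
        ]
    )
    predictions: dict[str, str] = {}
    ties = 0
    for s in subjects:
        scores = _pearson_scores(vectorize_upper(split.test[s]), refs)
        idx, tie = _best_index(scores, "max")
        predictions[s] = subjects[idx]
        ties += tie
    return predictions, ties


def identify_geodesic(
    split: TrainTestSplit, regularize: bool = True, squared: bool = False
) -> tuple[dict[str, str], int]:
    subjects = split.subjects
    refs = [aggregate_training(split.train[s], "geodesic") for s in subjects]
    predictions: dict[str, str] = {}
    ties = 0
    for s in subjects:
        dists = [
            geodesic_distance(split.test[s], ref, regularize=regularize, squared=squared)
            for ref in refs
        ]
        idx, tie = _best_index(np.asarray(dists), "min")
        predictions[s] = subjects[idx]
        ties += tie
    return predictions, ties


@dataclass
class LinearClassifierModel:
    """One-vs-all ridge model; ``weights`` has shape (n_subjects, dim + 1)
    with the bias in the last column."""

    weights: np.ndarray
    ridge_lambda: float

    def scores(self, features: np.ndarray) -> np.ndarray:
        features = np.atleast_2d(np.asarray(features, dtype=float))
        augmented = np.hstack([features, np.ones((features.shape[0], 1))])
        return augmented @ self.weights.T

    def predict(self, features: np.ndarray) -> tuple[np.ndarray, int]:
        scores = self.scores(features)
        labels = np.empty(scores.shape[0], dtype=int)
        ties = 0
        for i, row in enumerate(scores):
            labels[i], tie = _best_index(row, "max")
            ties += tie
        return labels, ties


def train_linear_classifier(
    features: np.ndarray,
    labels: Sequence[int],
    ridge_lambda: float = 1.0,
    n_classes: int | None = None,
) -> LinearClassifierModel:
    """Closed-form ridge regression of a one-hot target matrix on
    bias-augmented feature vectors (all coefficients penalized).

    Uses the dual solution when samples are fewer than features.
    """
    if ridge_lambda < 0:
        raise InvalidArgumentError("ridge_lambda must be >= 0")
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if features.ndim != 2 or len(labels) != features.shape[0]:
        raise InvalidArgumentError("features/labels shape mismatch")
    n_classes = n_classes or int(labels.max()) + 1
    n, _ = features.shape
    x = np.hstack([features, np.ones((n, 1))])
    y = np.zeros((n, n_classes))
    y[np.arange(n), labels] = 1.0
    d = x.shape[1]
    if n < d:
        gram = x @ x.T
        gram[np.diag_indices_from(gram)] += ridge_lambda
        w = x.T @ np.linalg.solve(gram, y)
    else:
        gram = x.T @ x
        gram[np.diag_indices_from(gram)] += ridge_lambda
        w = np.linalg.solve(gram, x.T @ y)
    return LinearClassifierModel(weights=w.T, ridge_lambda=ridge_lambda)


def identify_linear(
    split: TrainTestSplit, ridge_lambda: float = 1.0
) -> tuple[dict[str, str], int]:
    subjects = split.subjects
    x_rows, y_rows = [], []
    for si, s in enumerate(subjects):
        for fc in split.train[s]:
            x_rows.append(vectorize_upper(fc))
            y_rows.append(si)
    model = train_linear_classifier(
        np.stack(x_rows), y_rows, ridge_lambda, n_classes=len(subjects)
    )
    tests = np.stack([vectorize_upper(split.test[s]) for s in subjects])
    idx, ties = model.predict(tests)
    return {s: subjects[i] for s, i in zip(subjects, idx)}, ties


def combine_contrasts(
    fcs: Mapping[str, FCMatrix] | Sequence[FCMatrix], method: str
) -> np.ndarray | FCMatrix:
    """Combine per-contrast FC matrices of one run.

    pearson/linear: concatenated upper-triangle vectors (k * N(N-1)/2);
    geodesic: block-diagonal (kN x kN) matrix, zero off-blocks.
    """
    if isinstance(fcs, Mapping):
        items = [(k, fcs[k]) for k in fcs]
    else:
        items = [(fc.contrast, fc) for fc in fcs]
    if not items:
        raise InvalidArgumentError("no contrasts to combine")
    n = items[0][1].n
    if any(fc.n != n for _, fc in items):
        raise InvalidArgumentError("all contrasts must share dimension")
    if method in ("pearson", "linear"):
        return np.concatenate([vectorize_upper(fc) for _, fc in items])
    if method == "geodesic":
        block = scipy.linalg.block_diag(*[_values(fc) for _, fc in items])
        labels = [f"{name}:{lab}" for name, fc in items for lab in fc.labels]
        first = items[0][1]
        return FCMatrix(
            values=block,
            labels=labels,
            subject_id=first.subject_id,
            run_id=first.run_id,
            contrast=first.contrast,
        )
    raise InvalidArgumentError(f"unknown method {method!r}")


def combine_fc_sets(fcsets: Mapping[str, "FCSet"], method: str) -> "FCSet":
    """Merge per-contrast FC sets into one combined set, run by run.

    pearson/linear keep the first contrast's matrices but attach
    concatenated feature vectors; geodesic builds block-diagonal matrices.
    Runs missing any contrast are dropped.
    """
    if not fcsets:
        raise InvalidArgumentError("no contrasts to combine")
    names = list(fcsets)
    first = fcsets[names[0]]
    out = FCSet(vectors={} if method in ("pearson", "linear") else None)
    for s in first.subjects():
        per_run = []
        for ri, fc in enumerate(first.matrices[s]):
            try:
                group = {name: fcsets[name].matrices[s][ri] for name in names}
            except (KeyError, IndexError):
                continue
            per_run.append(group)
        if not per_run:
            continue
        if method == "geodesic":
            out.matrices[s] = [combine_contrasts(g, method) for g in per_run]
        else:
            out.matrices[s] = [g[names[0]] for g in per_run]
            out.vectors[s] = [combine_contrasts(g, method) for g in per_run]
    if not out.matrices:
        raise InvalidArgumentError("no runs shared every requested contrast")
    return out


@dataclass
class FCSet:
    """Per-subject run-ordered FC matrices, the unit experiments consume.

    ``vectors`` optionally overrides the per-run feature vectors used by the
    pearson/linear engines (e.g. concatenated multi-contrast vectors); when
    absent, features are the upper-triangle vectorizations of ``matrices``.
    """

    matrices: dict[str, list[FCMatrix]] = field(default_factory=dict)
    vectors: dict[str, list[np.ndarray]] | None = None

    def subjects(self) -> list[str]:
        return sorted(self.matrices)

    def run_vectors(self, subject: str) -> list[np.ndarray]:
        if self.vectors is not None:
            return self.vectors[subject]
        return [vectorize_upper(fc) for fc in self.matrices[subject]]

    @property
    def n_labels(self) -> int:
        return next(iter(self.matrices.values()))[0].n

    @property
    def labels(self) -> list[str]:
        return list(next(iter(self.matrices.values()))[0].labels)

    def n_runs(self, subject: str) -> int:
        return len(self.matrices[subject])

    def select_labels(self, index: Sequence[int]) -> "FCSet":
        return FCSet(
            matrices={
                s: [fc.select(index) for fc in fcs]
                for s, fcs in self.matrices.items()
            }
        )


def build_fc_set(fcs: Iterable[FCMatrix]) -> FCSet:
    out = FCSet()
    for fc in fcs:
        out.matrices.setdefault(fc.subject_id, []).append(fc)
    for runs in out.matrices.values():
        runs.sort(key=lambda fc: fc.run_id)
    return out


def _standardize_rows(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    centered = mat - mat.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    safe = np.where(norms == 0, 1.0, norms)
    return centered / safe[:, None], norms


def run_identification_experiment(
    fcset: FCSet,
    method: str,
    n_train_runs: int | str = "all",
    n_reps: int = 300,
    seed: int = 0,
    ridge_lambda: float = 1.0,
    regularize: bool = True,
    squared: bool = False,
) -> IdentificationResult:
    """Repeat the leave-one-out identification ``n_reps`` times.

    Per repetition and subject, one test run is drawn first, then
    ``n_train_runs`` training runs from the remainder without replacement
    (``"all"`` uses every remaining run). Per-repetition RNG streams are
    derived from ``seed`` by counter, so results are reproducible and test
    draws are shared across methods run with the same seed.
    """
    if method not in ("pearson", "geodesic", "linear"):
        raise InvalidArgumentError(f"unknown method {method!r}")
    subjects = fcset.subjects()
    if len(subjects) < 2:
        raise InvalidArgumentError("need at least 2 subjects")
    n_runs = {s: fcset.n_runs(s) for s in subjects}
    if n_train_runs == "all":
        needed = 2
    else:
        n_train_runs = int(n_train_runs)
        if n_train_runs < 1:
            raise InvalidArgumentError("n_train_runs must be >= 1 or 'all'")
        needed = n_train_runs + 1
    short = [s for s in subjects if n_runs[s] < needed]
    if short:
        raise InvalidArgumentError(
            f"subjects with fewer than {needed} runs: {', '.join(short)}"
        )

    vecs = {s: np.stack(fcset.run_vectors(s)) for s in subjects}
    mats = {s: [fc.values for fc in fcset.matrices[s]] for s in subjects}

    agg_cache: dict[tuple[str, tuple[int, ...]], np.ndarray] = {}
    dist_cache: dict[tuple, float] = {}

    def aggregate_mat(s: str, train_key: tuple[int, ...]) -> np.ndarray:
        cached = agg_cache.get((s, train_key))
        if cached is None:
            cached = np.mean([mats[s][i] for i in train_key], axis=0)
            np.fill_diagonal(cached, 1.0)
            agg_cache[(s, train_key)] = cached
        return cached

    n_subjects = len(subjects)
    accuracies = np.empty(n_reps)
    predictions = np.empty((n_reps, n_subjects), dtype=int)
    tie_count = 0

    for rep in range(n_reps):
        rng = _rng(seed, rep)
        test_idx: dict[str, int] = {}
        train_idx: dict[str, tuple[int, ...]] = {}
        for s in subjects:
            perm = rng.permutation(n_runs[s])
            test_idx[s] = int(perm[0])
            rest = perm[1:] if n_train_runs == "all" else perm[1: 1 + n_train_runs]
            train_idx[s] = tuple(sorted(int(i) for i in rest))

        if method == "pearson":
            refs = np.stack([vecs[s][list(train_idx[s])].mean(axis=0) for s in subjects])
            tests = np.stack([vecs[s][test_idx[s]] for s in subjects])
            rz, r_norm = _standardize_rows(refs)
            tz, t_norm = _standardize_rows(tests)
            corr = tz @ rz.T
            corr[:, r_norm == 0] = -np.inf
            corr[t_norm == 0, :] = -np.inf
            for i in range(n_subjects):
                predictions[rep, i], tie = _best_index(corr[i], "max")
                tie_count += tie
        elif method == "geodesic":
            for i, s in enumerate(subjects):
                dists = np.empty(n_subjects)
                for j, ref_s in enumerate(subjects):
                    key = (s, test_idx[s], ref_s, train_idx[ref_s])
                    d = dist_cache.get(key)
                    if d is None:
                        d = geodesic_distance(
                            mats[s][test_idx[s]],
                            aggregate_mat(ref_s, train_idx[ref_s]),
                            regularize=regularize,
                            squared=squared,
                        )
                        dist_cache[key] = d
                    dists[j] = d
                predictions[rep, i], tie = _best_index(dists, "min")
                tie_count += tie
        else:  # linear
            x_rows = [vecs[s][list(train_idx[s])] for s in subjects]
            y_rows = np.concatenate(
                [np.full(len(train_idx[s]), si) for si, s in enumerate(subjects)]
            )
            model = train_linear_classifier(
                np.concatenate(x_rows), y_rows, ridge_lambda, n_classes=n_subjects
            )
            tests = np.stack([vecs[s][test_idx[s]] for s in subjects])
            predictions[rep], ties = model.predict(tests)
            tie_count += ties

        accuracies[rep] = 100.0 * np.mean(predictions[rep] == np.arange(n_subjects))

    return IdentificationResult(
        method=method,
        accuracies=accuracies,
        predictions=predictions,
        subjects=subjects,
        tie_count=tie_count,
        n_repetitions=n_reps,
        config={
            "n_train_runs": n_train_runs,
            "seed": seed,
            "ridge_lambda": ridge_lambda,
            "regularize": regularize,
            "squared": squared,
        },
    )


def roi_subsample_experiment(
    fcset: FCSet,
    sizes: Sequence[int] = (10, 20, 30, 40, 48),
    n_roi_draws: int = 10,
    method: str = "geodesic",
    n_train_runs: int = 1,
    n_reps: int = 300,
    seed: int = 0,
    **experiment_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Accuracy as a function of random channel/ROI sub-network size.

    For each size, ``n_roi_draws`` random label subsets are drawn (a single
    draw when the size uses every label) and the identification experiment
    is run on the restricted matrices. Returns ``(summary, detail)`` frames:
    summary has mean/sd accuracy per size pooled over draws and repetitions.
    """
    n_total = fcset.n_labels
    if any(size > n_total or size < 2 for size in sizes):
        raise InvalidArgumentError(f"sizes must lie in [2, {n_total}]")
    rows = []
    pooled: dict[int, list[np.ndarray]] = {}
    for si, size in enumerate(sizes):
        draws = 1 if size == n_total else n_roi_draws
        for draw in range(draws):
            if size == n_total:
                subset = fcset
            else:
                idx = np.sort(_rng(seed, si, draw).choice(n_total, size, replace=False))
                subset = fcset.select_labels(idx)
            result = run_identification_experiment(
                subset,
                method=method,
                n_train_runs=n_train_runs,
                n_reps=n_reps,
                seed=seed,
                **experiment_kwargs,
            )
            rows.append(
                {
                    "n_rois": size,
                    "draw": draw,
                    "mean_accuracy": result.mean_accuracy,
                    "sd_accuracy": result.sd_accuracy,
                }
            )
            pooled.setdefault(size, []).append(result.accuracies)
    detail = pd.DataFrame(rows)
    summary = pd.DataFrame(
        [
            {
                "n_rois": size,
                "mean_accuracy": float(np.mean(np.concatenate(accs))),
                "sd_accuracy": float(np.std(np.concatenate(accs), ddof=1)),
            }
            for size, accs in sorted(pooled.items())
        ]
    )
    return summary, detail
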