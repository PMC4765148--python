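"""One-vs-rest multi-label sparse regression: mLASSO and mEN.

Training is a two-stage procedure.  Stage 1 (feature selection) fits M
independent binary one-vs-rest penalized regressions on +/-1 transformed
labels over the full T-dimensional GO term-frequency space; the union of
the GO terms with a nonzero weight in any class forms the set of
*essential* GO terms.  Stage 2 refits the M regressions over the reduced
S-dimensional essential space.  A query is scored per location as
``s_m = intercept_m + beta~_m . x^s`` and the predicted label set is
``{m : s_m > 0}``, falling back to the single best-scoring location when
no score is positive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

from .go_features import (
    GoTerm,
    GoVocabulary,
    NullGoTerms,
    build_feature_matrix,
    build_go_vector,
    build_vocabulary,
)
from .solver import (
    PenaltyParams,
    RegressionProblem,
    SparseFit,
    LassoPath,
    elastic_net_path,
    fit_lasso_path,
)

MODES = ("mlasso", "men")

#: default per-class CV protocol for the L1 penalty
CV_FOLDS = 5
CV_GRID_SIZE = 20
CV_GRID_SPAN = 1e-3  # grid runs from lambda_max down to lambda_max * span
CV_GAMMA_GRID = (0.01, 0.1, 1.0)


class NullFeatureVector(ValueError):
    """Query has no essential-term annotation and hierarchical mapping is off."""


def transform_labels(label_sets: Sequence[Iterable[int]], M: int) -> np.ndarray:
    """Label sets -> N x M matrix of transformed labels y_{i,m} in {-1,+1}."""
    N = len(label_sets)
    Y = -np.ones((N, M), dtype=np.float64)
    for i, labels in enumerate(label_sets):
        labels = set(labels)
        if not labels:
            raise ValueError(f"protein {i}: empty label set")
        for m in labels:
            if not 1 <= m <= M:
                raise ValueError(f"protein {i}: label {m} outside 1..{M}")
            Y[i, m - 1] = 1.0
    return Y


@dataclass
class FeatureSelectionModel:
    """Stage-1 fits: one SparseFit per location over the full T-space."""

    fits: list[SparseFit]
    mode: str
    penalties: list[PenaltyParams]

    @property
    def M(self) -> int:
        return len(self.fits)


@dataclass
class EssentialTermSet:
    """Vocabulary-ordered union of the per-class nonzero supports."""

    indices: np.ndarray  # positions into the vocabulary, ascending
    terms: tuple[GoTerm, ...]

    @property
    def size(self) -> int:
        return len(self.indices)

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class LocalizationModel:
    """Refit weights over the essential space plus everything needed to score."""

    mode: str
    essential: EssentialTermSet
    weights: np.ndarray            # M x S, original data scale
    intercepts: np.ndarray         # length M
    penalties: list[PenaltyParams]
    vocabulary: GoVocabulary
    location_names: tuple[str, ...] | None = None
    seed: Optional[int] = None

    @property
    def M(self) -> int:
        return self.weights.shape[0]

    @property
    def S(self) -> int:
        return self.weights.shape[1]

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "format": "sparseloc-model-v1",
            "mode": self.mode,
            "vocabulary": [[t.id, t.category] for t in self.vocabulary.terms],
            "essential_indices": self.indices_list(),
            "essential_terms": [[t.id, t.category] for t in self.essential.terms],
            "weights": self.weights.tolist(),
            "intercepts": self.intercepts.tolist(),
            "penalties": [
                {"lam": p.lam, "gamma": p.gamma} for p in self.penalties
            ],
            "location_names": list(self.location_names) if self.location_names else None,
            "seed": self.seed,
        }
        return json.dumps(payload, indent=2)

    def indices_list(self) -> list[int]:
        return [int(j) for j in self.essential.indices]

    @classmethod
    def from_json(cls, text: str) -> "LocalizationModel":
        payload = json.loads(text)
        if payload.get("format") != "sparseloc-model-v1":
            raise ValueError("unrecognized model file format")
        terms = tuple(GoTerm(i, c) for i, c in payload["vocabulary"])
        vocab = GoVocabulary(terms, {t.id: j for j, t in enumerate(terms)})
        essential = EssentialTermSet(
            np.asarray(payload["essential_indices"], dtype=int),
            tuple(GoTerm(i, c) for i, c in payload["essential_terms"]),
        )
        return cls(
            mode=payload["mode"],
            essential=essential,
            weights=np.asarray(payload["weights"], dtype=np.float64),
            intercepts=np.asarray(payload["intercepts"], dtype=np.float64),
            penalties=[PenaltyParams(**p) for p in payload["penalties"]],
            vocabulary=vocab,
            location_names=tuple(payload["location_names"]) if payload.get("location_names") else None,
            seed=payload.get("seed"),
        )


@dataclass
class PredictionResult:
    """Per-location scores, the decided label set, and the scored vector."""

    scores: np.ndarray
    labels: set[int]
    features: np.ndarray  # the S-dimensional vector that was scored
    used_hib: bool = False


def _class_path(X: np.ndarray, y: np.ndarray, mode: str, gamma: float) -> LassoPath:
    problem = RegressionProblem(X, y)
    if mode == "mlasso" or gamma == 0:
        return fit_lasso_path(problem)
    return elastic_net_path(problem, gamma)


def _cv_lambda(
    X: np.ndarray,
    y: np.ndarray,
    mode: str,
    gamma: float,
    seed: int,
    folds: int = CV_FOLDS,
    grid_size: int = CV_GRID_SIZE,
) -> float:
    """Per-class K-fold CV of the squared error over a log lambda grid."""
    N = X.shape[0]
    full_path = _class_path(X, y, mode, gamma)
    lmax = max(full_path.lambda_max, 1e-12)
    grid = np.geomspace(lmax, lmax * CV_GRID_SPAN, grid_size)
    rng = np.random.default_rng(seed)
    order = rng.permutation(N)
    fold_ids = np.arange(N) % folds
    errors = np.zeros(grid.size)
    for f in range(folds):
        test = order[fold_ids == f]
        train = order[fold_ids != f]
        if train.size < 2 or test.size == 0:
            continue
        path = _class_path(X[train], y[train], mode, gamma)
        for g, lam in enumerate(grid):
            fit = path.fit_at(lam)
            resid = y[test] - fit.predict(X[test])
            errors[g] += float(resid @ resid)
    return float(grid[int(np.argmin(errors))])


def fit_feature_selection(
    X: np.ndarray,
    labels: np.ndarray,
    mode: str = "mlasso",
    penalties: Sequence[PenaltyParams] | PenaltyParams | str = "cv",
    gamma: float | None = None,
    gamma_grid: Sequence[float] = CV_GAMMA_GRID,
    seed: int = 0,
) -> FeatureSelectionModel:
    """Fit the M one-vs-rest stage-1 regressions.

    ``penalties`` is either a per-class list of :class:`PenaltyParams`, a
    single :class:`PenaltyParams` applied to every class, or ``"cv"`` (the
    default), which tunes lambda_m per class by 5-fold CV over a 20-point
    log grid; for mEN the gamma is tuned over ``gamma_grid`` unless a fixed
    ``gamma`` is given.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    X = np.asarray(X, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if labels.ndim != 2 or labels.shape[0] != X.shape[0]:
        raise ValueError("label matrix must be N x M with N matching X")
    if not np.isin(labels, (-1.0, 1.0)).all():
        raise ValueError("label matrix entries must be +/-1")
    M = labels.shape[1]

    fits: list[SparseFit] = []
    chosen: list[PenaltyParams] = []
    for m in range(M):
        y = labels[:, m]
        try:
            params = _resolve_penalties(
                X, y, mode, penalties, m, gamma, gamma_grid, seed
            )
            path = _class_path(X, y, mode, params.gamma)
            fit = path.fit_at(params.lam)
            fit.penalties = params
        except Exception as exc:
            exc.args = (f"class {m + 1}: {exc}",)
            raise
        fits.append(fit)
        chosen.append(params)
    return FeatureSelectionModel(fits=fits, mode=mode, penalties=chosen)


def _resolve_penalties(X, y, mode, penalties, m, gamma, gamma_grid, seed) -> PenaltyParams:
    if isinstance(penalties, PenaltyParams):
        return penalties
    if isinstance(penalties, str):
        if penalties != "cv":
            raise ValueError(f"unknown penalty spec {penalties!r}")
        if mode == "mlasso":
            lam = _cv_lambda(X, y, mode, 0.0, seed + 1009 * m)
            return PenaltyParams(lam=lam)
        if gamma is not None:
            lam = _cv_lambda(X, y, mode, gamma, seed + 1009 * m)
            return PenaltyParams(lam=lam, gamma=gamma)
        best: tuple[float, PenaltyParams] | None = None
        for g in gamma_grid:
            lam = _cv_lambda(X, y, mode, g, seed + 1009 * m)
            err = _holdout_error(X, y, mode, lam, g, seed + 1009 * m)
            if best is None or err < best[0]:
                best = (err, PenaltyParams(lam=lam, gamma=g))
        return best[1]
    return penalties[m]


def _holdout_error(X, y, mode, lam, gamma, seed, folds: int = CV_FOLDS) -> float:
    N = X.shape[0]
    rng = np.random.default_rng(seed)
    order = rng.permutation(N)
    fold_ids = np.arange(N) % folds
    err = 0.0
    for f in range(folds):
        test, train = order[fold_ids == f], order[fold_ids != f]
        if train.size < 2 or test.size == 0:
            continue
        fit = _class_path(X[train], y[train], mode, gamma).fit_at(lam)
        resid = y[test] - fit.predict(X[test])
        err += float(resid @ resid)
    return err


def select_essential_terms(
    model: FeatureSelectionModel, vocab: GoVocabulary
) -> EssentialTermSet:
    """Union of per-class nonzero supports, in vocabulary order."""
    support = np.zeros(len(vocab), dtype=bool)
    for fit in model.fits:
        support[fit.active_set] = True
    indices = np.flatnonzero(support)
    return EssentialTermSet(indices, tuple(vocab.terms[j] for j in indices))


def project_features(X: np.ndarray, essential: EssentialTermSet) -> np.ndarray:
    """Gather the essential-term columns of X (N x S)."""
    if essential.size == 0:
        raise NullFeatureVector(
            "essential term set is empty; loosen the penalties or enable "
            "hierarchical (HIB) mapping"
        )
    X = np.asarray(X)
    if essential.indices.max() >= X.shape[-1]:
        raise IndexError("essential index exceeds feature dimension")
    return X[..., essential.indices]


def refit_selected(
    Xs: np.ndarray,
    labels: np.ndarray,
    mode: str,
    penalties: Sequence[PenaltyParams] | PenaltyParams,
    essential: EssentialTermSet,
    vocab: GoVocabulary,
    location_names: tuple[str, ...] | None = None,
    seed: Optional[int] = None,
) -> LocalizationModel:
    """Stage-2 refit of the M regressions over the S essential columns."""
    stage2 = fit_feature_selection(Xs, labels, mode=mode, penalties=penalties, seed=seed or 0)
    M, S = labels.shape[1], Xs.shape[1]
    weights = np.zeros((M, S))
    intercepts = np.zeros(M)
    for m, fit in enumerate(stage2.fits):
        weights[m] = fit.beta
        intercepts[m] = fit.intercept
    return LocalizationModel(
        mode=mode,
        essential=essential,
        weights=weights,
        intercepts=intercepts,
        penalties=stage2.penalties,
        vocabulary=vocab,
        location_names=location_names,
        seed=seed,
    )


def score(model: LocalizationModel, xs: np.ndarray) -> np.ndarray:
    """Per-location scores s_m = intercept_m + beta~_m . x^s."""
    xs = np.asarray(xs, dtype=np.float64)
    if xs.shape != (model.S,):
        raise ValueError(f"expected a length-{model.S} essential-space vector")
    return model.intercepts + model.weights @ xs


def decide(scores: np.ndarray) -> set[int]:
    """Threshold-at-zero multi-label decision with argmax fallback.

    Returns {m : s_m > 0} (1-based) when any score is positive; otherwise
    the single best-scoring location (lowest index on exact ties), so the
    prediction is never empty.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if scores.ndim != 1 or scores.size < 1:
        raise ValueError("scores must be a non-empty 1-D vector")
    if np.isnan(scores).any():
        raise ValueError("scores contain NaN")
    positive = np.flatnonzero(scores > 0)
    if positive.size:
        return {int(m) + 1 for m in positive}
    return {int(np.argmax(scores)) + 1}


def predict(
    model: LocalizationModel,
    query,
    hib: Optional[Callable[[object], np.ndarray]] = None,
) -> PredictionResult:
    """Score and decide a query GO multiset (or full-length count vector).

    Builds the term-frequency vector over the model vocabulary, projects it
    onto the essential columns and applies score + decide.  If the
    projection is all-zero, ``hib`` (a callable mapping the query multiset
    to an effective-count vector over the essential terms) is used as the
    fallback; with no fallback a :class:`NullFeatureVector` is raised.
    """
    if isinstance(query, np.ndarray):
        full = np.asarray(query, dtype=np.float64)
        multiset = None
    else:
        multiset = query
        full = build_go_vector(query, model.vocabulary).counts.astype(np.float64)
    xs = project_features(full, model.essential)
    used_hib = False
    if not xs.any():
        if hib is None:
            raise NullFeatureVector(
                "query shares no essential GO term with the model; enable HIB mapping"
            )
        xs = np.asarray(hib(multiset if multiset is not None else query), dtype=np.float64)
        used_hib = True
    s = score(model, xs)
    return PredictionResult(scores=s, labels=decide(s), features=xs, used_hib=used_hib)


def train(
    X: np.ndarray,
    label_sets: Sequence[Iterable[int]],
    M: int,
    vocab: GoVocabulary,
    mode: str = "mlasso",
    penalties: Sequence[PenaltyParams] | PenaltyParams | str = "cv",
    refit_penalties: Sequence[PenaltyParams] | PenaltyParams | None = None,
    gamma: float | None = None,
    location_names: tuple[str, ...] | None = None,
    seed: int = 0,
) -> LocalizationModel:
    """Full two-stage training: selection -> essential set -> refit.

    Refit penalties default to the stage-1 (selection) penalties.
    """
    Y = transform_labels(label_sets, M)
    stage1 = fit_feature_selection(X, Y, mode=mode, penalties=penalties, gamma=gamma, seed=seed)
    essential = select_essential_terms(stage1, vocab)
    Xs = project_features(X, essential)
    refit_p = refit_penalties if refit_penalties is not None else stage1.penalties
    return refit_selected(
        Xs, Y, mode, refit_p, essential, vocab,
        location_names=location_names, seed=seed,
    )


def loocv_localization(
    multisets: Sequence,
    label_sets: Sequence[Iterable[int]],
    M: int,
    mode: str = "mlasso",
    penalties="cv",
    global_selection: bool = False,
    hib_factory: Optional[Callable[[EssentialTermSet, GoVocabulary], Callable]] = None,
    seed: int = 0,
):
    """Leave-one-out evaluation of the full two-stage pipeline.

    With ``global_selection`` off (the default, leakage-free) the GO
    vocabulary, the stage-1 selection and any penalty tuning are redone
    inside every fold from the N-1 training proteins only.  Switching it on
    performs one global vocabulary construction and essential-term
    selection on all N proteins and only refits the per-fold scoring
    weights, which trades honesty for the benchmark-style protocol of a
    single global feature selection.

    ``hib_factory(essential, vocab)`` may supply a hierarchical-mapping
    fallback builder for queries lacking essential terms.
    """
    from . import metrics as _metrics

    if global_selection:
        vocab = build_vocabulary(multisets)
        X = build_feature_matrix(multisets, vocab)
        Y = transform_labels(label_sets, M)
        stage1 = fit_feature_selection(X, Y, mode=mode, penalties=penalties, seed=seed)
        essential = select_essential_terms(stage1, vocab)

        def fit(train_items, train_labels):
            Xs = project_features(build_feature_matrix(train_items, vocab), essential)
            Yt = transform_labels(train_labels, M)
            return refit_selected(
                Xs, Yt, mode, stage1.penalties, essential, vocab, seed=seed
            )
    else:
        def fit(train_items, train_labels):
            vocab = build_vocabulary(train_items)
            X = build_feature_matrix(train_items, vocab)
            return train(
                X, list(train_labels), M, vocab,
                mode=mode, penalties=penalties, seed=seed,
            )

    def predict_one(model, item):
        hib = hib_factory(model.essential, model.vocabulary) if hib_factory else None
        return predict(model, item, hib=hib).labels

    return _metrics.loocv(list(multisets), [set(y) for y in label_sets], M, fit, predict_one)
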