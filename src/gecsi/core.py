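"""The GECSI model: per-reference multinomial lasso ensemble.

One model is trained per reference sample ("training sample").  Its labels
are that sample's chromatin states at a random subsample of genomic
positions; its predictors are the one-hot-encoded states of the L
expression-nearest reference samples ("feature samples") at the same
positions, giving L x S binary columns.  The model is a multinomial
logistic regression with an L1 (lasso) penalty of strength lambda.

To impute a new sample from expression alone, the R reference samples most
correlated with the query are selected, their trained models each produce a
per-position probability vector over states, and the ensemble output is the
unweighted mean of those vectors.  The hard assignment is the per-position
argmax, ties going to the lowest state index.

The lasso penalty follows the glmnet parameterization, where the objective
is ``-(1/n) loglik + lambda * ||coef||_1``; this is mapped onto
scikit-learn's inverse-regularization form as ``C = 1 / (n * lambda)``.
Binary 0/1 features are used as-is (no standardization) and each state has
its own intercept.  States absent from a model's training subsample are
"untrained" for that model and receive probability exactly 0 from it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.linear_model import LogisticRegression

from .compendium import ReferenceCompendium
from .genome_io import MISSING, BinnedGenome, SoftAnnotation, StateAnnotation
from .neighbors import (
    correlate_query,
    rank_neighbors,
    rank_neighbors_from_series,
)


class ConvergenceError(RuntimeError):
    """Raised when the lasso solver fails to converge within max_iter."""


@dataclass
class GecsiModel:
    """A trained per-reference-sample multinomial lasso model.

    ``coef`` has shape (n_trained_classes, L*S) and ``intercept``
    (n_trained_classes,); ``classes`` lists the 0-based state codes present
    in the training subsample, in sorted order.  ``n_states`` is the full
    alphabet size S; states not in ``classes`` are untrained and predicted
    with probability 0.
    """

    train_sample_id: str
    feature_sample_ids: tuple[str, ...]
    lam: float
    n_states: int
    classes: np.ndarray
    coef: np.ndarray
    intercept: np.ndarray
    training_positions: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        if len(self.feature_sample_ids) < 1:
            raise ValueError("need at least one feature sample (L >= 1)")
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        d = len(self.feature_sample_ids) * self.n_states
        if self.coef.shape[1] != d:
            raise ValueError(f"coefficient width {self.coef.shape[1]} != L*S = {d}")

    @property
    def n_features(self) -> int:
        return len(self.feature_sample_ids)

    @property
    def untrained_states(self) -> np.ndarray:
        return np.setdiff1d(np.arange(self.n_states), self.classes)


def sample_positions(genome: BinnedGenome, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` distinct bin indices uniformly without replacement,
    reproducibly from ``seed``.  Returned sorted."""
    total = genome.n_bins
    if n > total:
        raise ValueError(f"cannot sample {n} positions from {total} bins")
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(total, size=n, replace=False))


def encode_features(
    feature_anns: list[StateAnnotation], positions: np.ndarray
) -> sparse.csr_matrix:
    """One-hot encode the states of the L feature samples at the given
    positions into a |positions| x (L*S) binary matrix.

    Column order is slot-major, state-minor: columns [l*S, (l+1)*S) belong
    to feature slot l.  A MISSING state at any requested position is an
    error; callers must pre-filter positions.
    """
    if not feature_anns:
        raise ValueError("need at least one feature annotation")
    positions = np.asarray(positions)
    n = len(positions)
    S = feature_anns[0].n_states
    L = len(feature_anns)
    cols = np.empty((n, L), dtype=np.int64)
    for l, ann in enumerate(feature_anns):
        codes = ann.states[positions]
        if (codes == MISSING).any():
            raise ValueError(
                f"feature sample {ann.sample_id!r} has MISSING states at "
                "requested positions"
            )
        cols[:, l] = l * S + codes
    rows = np.repeat(np.arange(n), L)
    data = np.ones(n * L, dtype=np.float64)
    return sparse.csr_matrix((data, (rows, cols.ravel())), shape=(n, L * S))


def train_model(
    train_ann: StateAnnotation,
    feature_anns: list[StateAnnotation],
    positions: np.ndarray,
    lam: float,
    seed: int,
    *,
    tol: float = 1e-7,
    max_iter: int = 10_000,
) -> GecsiModel:
    """Fit one multinomial lasso model for a training sample.

    Positions where the training annotation is MISSING are dropped.  The
    training labels must contain at least 2 distinct states.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    positions = np.asarray(positions)
    y = train_ann.states[positions]
    keep = y != MISSING
    positions, y = positions[keep], y[keep]
    if len(np.unique(y)) < 2:
        raise ValueError(
            f"training sample {train_ann.sample_id!r} has a single state "
            "class at the sampled positions"
        )
    X = encode_features(feature_anns, positions)
    n = X.shape[0]
    clf = LogisticRegression(
        l1_ratio=1.0,
        C=1.0 / (lam * n),
        solver="saga",
        tol=tol,
        max_iter=max_iter,
        fit_intercept=True,
        random_state=seed % (2**32),
    )
    with warnings.catch_warnings():
        # convergence is re-checked explicitly below via n_iter_
        warnings.simplefilter("ignore")
        clf.fit(X, y)
    n_iter = int(np.max(clf.n_iter_))
    if n_iter >= max_iter:
        raise ConvergenceError(
            f"lasso solver did not converge for {train_ann.sample_id!r} "
            f"after {n_iter} iterations (tol={tol})"
        )
    return GecsiModel(
        train_sample_id=train_ann.sample_id,
        feature_sample_ids=tuple(a.sample_id for a in feature_anns),
        lam=float(lam),
        n_states=train_ann.n_states,
        classes=clf.classes_.astype(np.int64),
        coef=clf.coef_.astype(np.float64),
        intercept=clf.intercept_.astype(np.float64),
        training_positions=positions,
        seed=int(seed),
    )


def predict_probs(
    model: GecsiModel,
    feature_anns: list[StateAnnotation],
    positions: np.ndarray,
) -> np.ndarray:
    """Per-position state probabilities (|positions| x S) from one model.

    ``feature_anns`` must be the annotations of ``model.feature_sample_ids``
    in order.  Untrained states receive probability 0.
    """
    got = tuple(a.sample_id for a in feature_anns)
    if got != model.feature_sample_ids:
        raise ValueError(
            f"feature samples {got} do not match the model's "
            f"{model.feature_sample_ids}"
        )
    X = encode_features(feature_anns, positions)
    z = X @ model.coef.T + model.intercept
    if model.coef.shape[0] == 1:
        # binary fit: single margin for classes[1] vs classes[0]
        p1 = 1.0 / (1.0 + np.exp(-z[:, 0]))
        class_probs = np.column_stack([1.0 - p1, p1])
    else:
        z -= z.max(axis=1, keepdims=True)
        ez = np.exp(z)
        class_probs = ez / ez.sum(axis=1, keepdims=True)
    out = np.zeros((len(positions), model.n_states), dtype=np.float64)
    out[:, model.classes] = class_probs
    return out


def train_reference_models(
    comp: ReferenceCompendium,
    sample_ids: list[str],
    L: int,
    lam: float,
    n_positions: int,
    seed: int,
    *,
    positions: np.ndarray | None = None,
    tol: float = 1e-7,
    max_iter: int = 10_000,
) -> dict[str, GecsiModel]:
    """Train one model per requested reference sample.

    Feature samples are the L nearest annotated samples (by expression
    Spearman correlation within the compendium).  All models share one
    subsample of ``n_positions`` training positions drawn from ``seed``
    unless explicit ``positions`` are given.
    """
    corr = comp.correlations()
    if positions is None:
        positions = sample_positions(comp.genome, n_positions, seed)
    models: dict[str, GecsiModel] = {}
    for sid in sample_ids:
        ranking = rank_neighbors(sid, corr, L)
        feature_anns = [comp.annotations[f] for f in ranking.neighbor_ids]
        models[sid] = train_model(
            comp.annotations[sid], feature_anns, positions, lam, seed,
            tol=tol, max_iter=max_iter,
        )
    return models


def ensemble_predict(
    query_expr: pd.Series,
    comp: ReferenceCompendium,
    R: int,
    models: dict[str, GecsiModel],
    *,
    positions: np.ndarray | None = None,
    query_id: str = "query",
) -> SoftAnnotation | np.ndarray:
    """Impute a query sample's chromatin states from expression alone.

    The R reference samples most correlated with the query are selected;
    their models' probability matrices are averaged with equal weight.  A
    model must exist for every selected reference.  Returns a full-genome
    :class:`SoftAnnotation` by default, or a raw |positions| x S matrix when
    explicit ``positions`` are given.
    """
    ref_ids = comp.sample_ids
    if not 1 <= R <= len(ref_ids):
        raise ValueError(f"R={R} must be in [1, {len(ref_ids)}]")
    corr = correlate_query(
        query_expr,
        comp.expression.data[ref_ids],
    )
    ranking = rank_neighbors_from_series(query_id, corr, R)
    missing = [s for s in ranking.neighbor_ids if s not in models]
    if missing:
        raise ValueError(f"no trained model for selected reference(s): {missing}")
    full = positions is None
    if full:
        positions = np.arange(comp.genome.n_bins)
    acc = np.zeros((len(positions), comp.n_states), dtype=np.float64)
    for sid in ranking.neighbor_ids:
        model = models[sid]
        feature_anns = [comp.annotations[f] for f in model.feature_sample_ids]
        acc += predict_probs(model, feature_anns, positions)
    acc /= R
    if full:
        return SoftAnnotation(
            sample_id=query_id, probs=acc, genome=comp.genome,
            alphabet=comp.alphabet,
        )
    return acc


def hard_assign(soft: SoftAnnotation | np.ndarray, sample_id: str | None = None,
                genome: BinnedGenome | None = None) -> StateAnnotation | np.ndarray:
    """Per-position argmax state; ties go to the lowest state index.

    Accepts a SoftAnnotation (returns a StateAnnotation) or a raw
    probability matrix (returns a code array).
    """
    probs = soft.probs if isinstance(soft, SoftAnnotation) else np.asarray(soft)
    if (probs.sum(axis=1) == 0).any():
        raise ValueError("all-zero probability row")
    codes = probs.argmax(axis=1).astype(np.int16)
    if isinstance(soft, SoftAnnotation):
        return StateAnnotation(
            sample_id=sample_id or soft.sample_id,
            states=codes,
            genome=soft.genome,
            alphabet=soft.alphabet,
        )
    return codes


# ---------------------------------------------------------------------------
# Model serialization (JSON)


def save_model(model: GecsiModel, path: str | Path) -> None:
    payload = {
        "format": "gecsi-model-v1",
        "train_sample_id": model.train_sample_id,
        "feature_sample_ids": list(model.feature_sample_ids),
        "lambda": model.lam,
        "n_states": model.n_states,
        "classes": model.classes.tolist(),
        "coef": model.coef.tolist(),
        "intercept": model.intercept.tolist(),
        "training_positions": model.training_positions.tolist(),
        "seed": model.seed,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path: str | Path) -> GecsiModel:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "gecsi-model-v1":
        raise ValueError(f"not a GECSI model file: {path}")
    return GecsiModel(
        train_sample_id=payload["train_sample_id"],
        feature_sample_ids=tuple(payload["feature_sample_ids"]),
        lam=float(payload["lambda"]),
        n_states=int(payload["n_states"]),
        classes=np.asarray(payload["classes"], dtype=np.int64),
        coef=np.asarray(payload["coef"], dtype=np.float64),
        intercept=np.asarray(payload["intercept"], dtype=np.float64),
        training_positions=np.asarray(payload["training_positions"], dtype=np.int64),
        seed=int(payload["seed"]),
    )
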