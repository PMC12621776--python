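"""Cross-validation folds and two-stage hyperparameter selection.

Evaluation uses 5-fold cross-validation: in each fold ~20% of samples are
held out as the test set and 6% of the remainder form a tuning set; the
rest train the models.  Hyperparameters are chosen in two stages on the
tuning set (by default on the first chromosome only):

1. the lasso penalty lambda maximizes the average number of states that
   receive at least one hard-assigned position per tuning sample, averaged
   over all (R, L) grid cells — this guards against strong shrinkage
   silencing small states entirely;
2. with lambda fixed, (R, L) maximize the median accuracy over tuning
   samples.

Ties break toward the smaller lambda and the smaller (R, then L).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import MISSING, StateAnnotation


@dataclass(frozen=True)
class HyperGrid:
    """Hyperparameter grid: ensemble size R, feature count L, penalty."""

    R_values: tuple[int, ...] = (3, 5, 10)
    L_values: tuple[int, ...] = (5, 10, 15)
    lambda_values: tuple[float, ...] = (0.1, 0.01, 0.001, 0.0001)

    def __post_init__(self) -> None:
        if not (self.R_values and self.L_values and self.lambda_values):
            raise ValueError("grid axes must be non-empty")


@dataclass(frozen=True)
class FoldPlan:
    """Per-fold (test, tuning, training) sample-id partitions."""

    folds: tuple[tuple[tuple[str, ...], tuple[str, ...], tuple[str, ...]], ...]
    seed: int

    def __post_init__(self) -> None:
        all_test = [s for test, _, _ in self.folds for s in test]
        if len(all_test) != len(set(all_test)):
            raise ValueError("a sample appears in more than one test set")
        for test, tune, train in self.folds:
            parts = set(test) | set(tune) | set(train)
            if len(parts) != len(test) + len(tune) + len(train):
                raise ValueError("fold partitions overlap")


def make_folds(
    sample_ids: list[str],
    n_folds: int = 5,
    tuning_frac: float = 0.06,
    seed: int = 0,
) -> FoldPlan:
    """Partition samples into cross-validation folds.

    Each fold holds out ~1/n_folds of the samples for testing; of the
    remainder, ``tuning_frac`` (rounded, at least 1) become the tuning set
    and the rest the training set.  Deterministic from ``seed``.
    """
    ids = list(sample_ids)
    n = len(ids)
    if n < n_folds:
        raise ValueError(f"{n} samples cannot form {n_folds} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    test_sets = [sorted(order[i::n_folds]) for i in range(n_folds)]
    folds = []
    for test_idx in test_sets:
        rest = [i for i in range(n) if i not in set(test_idx)]
        n_tune = max(1, round(tuning_frac * len(rest)))
        if len(rest) - n_tune < 1:
            raise ValueError("too few samples for non-empty training set")
        tune_idx = list(rng.permutation(rest)[:n_tune])
        train_idx = [i for i in rest if i not in set(tune_idx)]
        folds.append(
            (
                tuple(ids[i] for i in test_idx),
                tuple(ids[i] for i in sorted(tune_idx)),
                tuple(ids[i] for i in train_idx),
            )
        )
    return FoldPlan(folds=tuple(folds), seed=seed)


def n_states_assigned(hard: StateAnnotation | np.ndarray, n_states: int | None = None) -> int:
    """Number of distinct states with at least one hard-assigned bin."""
    codes = hard.states if isinstance(hard, StateAnnotation) else np.asarray(hard)
    S = n_states or (hard.n_states if isinstance(hard, StateAnnotation) else int(codes.max()) + 1)
    counts = np.bincount(codes[codes != MISSING], minlength=S)
    return int((counts > 0).sum())


def _check_complete(df: pd.DataFrame, grid: HyperGrid, lambdas: bool) -> None:
    samples = sorted(df["sample"].unique())
    lam_values = grid.lambda_values if lambdas else [None]
    for R in grid.R_values:
        for L in grid.L_values:
            for lam in lam_values:
                sel = (df["R"] == R) & (df["L"] == L)
                if lambdas:
                    sel &= df["lam"] == lam
                present = set(df.loc[sel, "sample"])
                if present != set(samples):
                    cell = (R, L, lam) if lambdas else (R, L)
                    raise ValueError(f"missing tuning results for grid cell {cell}")


def select_lambda(grid: HyperGrid, tuning_results: pd.DataFrame) -> float:
    """Stage 1: choose the lasso penalty by the state-coverage criterion.

    ``tuning_results`` must have columns [R, L, lam, sample,
    n_states_assigned] covering the full grid.  For each lambda the score
    is the mean count of assigned states over all (R, L, sample) cells;
    the argmax wins, ties going to the smaller lambda.
    """
    required = {"R", "L", "lam", "sample", "n_states_assigned"}
    if not required <= set(tuning_results.columns):
        raise ValueError(f"tuning_results needs columns {sorted(required)}")
    _check_complete(tuning_results, grid, lambdas=True)
    scores = {
        lam: tuning_results.loc[
            tuning_results["lam"] == lam, "n_states_assigned"
        ].mean()
        for lam in grid.lambda_values
    }
    best = max(scores.values())
    return min(lam for lam, sc in scores.items() if sc == best)


def select_R_L(
    grid: HyperGrid, lam_star: float, tuning_results: pd.DataFrame
) -> tuple[int, int]:
    """Stage 2: choose (R, L) by median accuracy at the selected lambda.

    ``tuning_results`` must have columns [R, L, sample, accuracy] for all
    grid cells at ``lam_star`` (a ``lam`` column, if present, is filtered).
    Ties go to the smaller R, then the smaller L.
    """
    df = tuning_results
    if "lam" in df.columns:
        df = df[df["lam"] == lam_star]
    required = {"R", "L", "sample", "accuracy"}
    if not required <= set(df.columns):
        raise ValueError(f"tuning_results needs columns {sorted(required)}")
    _check_complete(df, grid, lambdas=False)
    best: tuple[int, int] | None = None
    best_score = -np.inf
    for R in grid.R_values:
        for L in grid.L_values:
            sel = (df["R"] == R) & (df["L"] == L)
            score = float(df.loc[sel, "accuracy"].median())
            if score > best_score + 1e-15:
                best, best_score = (R, L), score
            elif abs(score - best_score) <= 1e-15 and best is not None:
                if (R, L) < best:
                    best = (R, L)
    assert best is not None
    return best


def tuning_region_positions(genome, chroms: tuple[str, ...] | None = None) -> np.ndarray:
    """Bin indices of the tuning region (default: the first chromosome)."""
    if chroms is None:
        chroms = (genome.chrom_names[0],)
    slices = [genome.chrom_bin_slice(c) for c in chroms]
    return np.concatenate([np.arange(s.start, s.stop) for s in slices])


@dataclass
class TuningReport:
    """Grid-search results and the two-stage selection outcome."""

    state_counts: pd.DataFrame  # columns R, L, lam, sample, n_states_assigned
    accuracies: pd.DataFrame  # columns R, L, lam, sample, accuracy
    lambda_star: float
    R_star: int
    L_star: int


def run_tuning(
    comp,
    train_ids: list[str],
    tune_ids: list[str],
    grid: HyperGrid | None = None,
    n_train_positions: int = 3000,
    seed: int = 0,
    region_chroms: tuple[str, ...] | None = None,
    *,
    tol: float = 1e-7,
    max_iter: int = 10_000,
) -> TuningReport:
    """Run the full two-stage selection on a train/tune split.

    Trains the grid's models on the training samples (one lasso model per
    needed reference, L and lambda combination), predicts every tuning
    sample on the tuning region (default: first chromosome), and applies
    :func:`select_lambda` then :func:`select_R_L`.  The same function
    serves both per-fold cross-validation tuning and the production-mode
    single 80/20 split.
    """
    from .core import ensemble_predict, hard_assign, train_reference_models
    from .neighbors import correlate_query, rank_neighbors_from_series

    grid = grid or HyperGrid()
    if set(train_ids) & set(tune_ids):
        raise ValueError("train and tuning sets overlap")
    train_comp = comp.subset(train_ids)
    region = tuning_region_positions(comp.genome, region_chroms)
    max_R = max(grid.R_values)
    # references any tuning sample may select, at the largest ensemble size
    needed: set[str] = set()
    rankings = {}
    for sid in tune_ids:
        corr = correlate_query(
            comp.expression.data[sid], train_comp.expression.data[train_comp.sample_ids]
        )
        rankings[sid] = rank_neighbors_from_series(sid, corr, max_R)
        needed.update(rankings[sid].neighbor_ids)

    rows_counts, rows_acc = [], []
    for L in grid.L_values:
        for lam in grid.lambda_values:
            models = train_reference_models(
                train_comp, sorted(needed), L, lam, n_train_positions, seed,
                tol=tol, max_iter=max_iter,
            )
            for sid in tune_ids:
                neighbor_ids = rankings[sid].neighbor_ids
                per_model = {
                    r: _predict_one(models[r], train_comp, region) for r in neighbor_ids
                }
                for R in grid.R_values:
                    probs = np.mean([per_model[r] for r in neighbor_ids[:R]], axis=0)
                    codes = hard_assign(probs)
                    truth = comp.annotations[sid].states[region]
                    keep = truth != MISSING
                    acc = float(np.mean(codes[keep] == truth[keep]))
                    rows_counts.append(
                        dict(R=R, L=L, lam=lam, sample=sid,
                             n_states_assigned=n_states_assigned(codes, comp.n_states))
                    )
                    rows_acc.append(dict(R=R, L=L, lam=lam, sample=sid, accuracy=acc))
    state_counts = pd.DataFrame(rows_counts)
    accuracies = pd.DataFrame(rows_acc)
    lam_star = select_lambda(grid, state_counts)
    R_star, L_star = select_R_L(grid, lam_star, accuracies)
    return TuningReport(
        state_counts=state_counts,
        accuracies=accuracies,
        lambda_star=lam_star,
        R_star=R_star,
        L_star=L_star,
    )


def _predict_one(model, train_comp, positions: np.ndarray) -> np.ndarray:
    from .core import predict_probs

    feature_anns = [train_comp.annotations[f] for f in model.feature_sample_ids]
    return predict_probs(model, feature_anns, positions)
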