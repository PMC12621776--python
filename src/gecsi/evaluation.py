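"""Evaluation metrics and downstream analyses for chromatin-state tracks.

Covers the comparison of predicted against observed annotations:

* ranking metrics on soft assignments — AUPRC with stepwise interpolation
  (precision held constant between consecutive recall points) and AUROC;
* hard-assignment metrics — accuracy, per-state Jaccard and F1 with
  state-size-weighted averages;
* genome fractions for hard and soft tracks;
* probability calibration (50-bin reliability curves) and observed-state
  composition across 100 probability bins;
* the "near miss" analysis: how often a wrong prediction still falls in the
  observed state's interpretive group, against an analytic chance level;
* fold enrichment of states for external interval annotations, for hard
  tracks and for truncated-and-renormalized soft tracks;
* pairwise sample relationships (agreement, per-state binary/soft Pearson)
  and their within/between-group summaries;
* per-state means of an external per-bin signal (e.g. CpG methylation)
  subject to a coverage filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .genome_io import MISSING, IntervalSet, SoftAnnotation, StateAnnotation
from .states import StateGrouping


def _as_codes(x: StateAnnotation | np.ndarray) -> np.ndarray:
    return x.states if isinstance(x, StateAnnotation) else np.asarray(x)


def _as_probs(x: SoftAnnotation | np.ndarray) -> np.ndarray:
    return x.probs if isinstance(x, SoftAnnotation) else np.asarray(x)


def _common_mask(pred: np.ndarray, obs: np.ndarray) -> np.ndarray:
    return (pred != MISSING) & (obs != MISSING)


# ---------------------------------------------------------------------------
# Ranking metrics


def auprc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall curve with stepwise interpolation.

    Threshold points are the unique score values in decreasing order; at
    each point items with score >= threshold are predicted positive.  The
    area is sum_i (Recall_i - Recall_{i-1}) * Precision_i with Recall_0 = 0.
    Constant scores therefore give the positive prevalence.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    P = int(labels.sum())
    if P == 0 or P == len(labels):
        raise ValueError("labels must contain both classes")
    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], labels[order]
    ends = np.flatnonzero(np.r_[s[1:] != s[:-1], True])
    tp = np.cumsum(y)[ends]
    precision = tp / (ends + 1)
    recall = tp / P
    return float(np.sum((recall - np.r_[0.0, recall[:-1]]) * precision))


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve (linear interpolation between unique
    points; equals P(score_pos > score_neg) + 0.5 P(score_pos = score_neg)).
    """
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("labels must contain both classes")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=np.float64)))


# ---------------------------------------------------------------------------
# Hard-assignment metrics


def accuracy(pred: StateAnnotation | np.ndarray, obs: StateAnnotation | np.ndarray) -> float:
    """Fraction of common non-missing positions with matching labels."""
    p, o = _as_codes(pred), _as_codes(obs)
    mask = _common_mask(p, o)
    if not mask.any():
        raise ValueError("no common non-missing positions")
    return float(np.mean(p[mask] == o[mask]))


#: Pairwise agreement between two hard tracks is the same quantity as
#: accuracy; the alias exists because the two names are used in different
#: analyses (prediction scoring vs. sample-sample similarity).
pairwise_agreement = accuracy


def _confusion(pred: np.ndarray, obs: np.ndarray, S: int) -> np.ndarray:
    mask = _common_mask(pred, obs)
    if not mask.any():
        raise ValueError("no common non-missing positions")
    joint = pred[mask].astype(np.int64) * S + obs[mask]
    return np.bincount(joint, minlength=S * S).reshape(S, S)


def jaccard_per_state(
    pred: StateAnnotation | np.ndarray,
    obs: StateAnnotation | np.ndarray,
    n_states: int | None = None,
) -> np.ndarray:
    """Per-state Jaccard index |pred_s & obs_s| / |pred_s | obs_s|.

    States absent from both tracks are undefined and returned as NaN.
    """
    p, o = _as_codes(pred), _as_codes(obs)
    S = n_states or (pred.n_states if isinstance(pred, StateAnnotation) else int(max(p.max(), o.max())) + 1)
    M = _confusion(p, o, S)
    tp = np.diag(M).astype(np.float64)
    union = M.sum(axis=1) + M.sum(axis=0) - tp
    with np.errstate(invalid="ignore"):
        out = np.where(union > 0, tp / np.maximum(union, 1), np.nan)
    return out


def f1_per_state(
    pred: StateAnnotation | np.ndarray,
    obs: StateAnnotation | np.ndarray,
    n_states: int | None = None,
) -> np.ndarray:
    """Per-state F1 = 2PR/(P+R) treating each state as the positive class.

    Equals 2*tp / (|pred_s| + |obs_s|); NaN when the state is absent from
    both tracks.
    """
    p, o = _as_codes(pred), _as_codes(obs)
    S = n_states or (pred.n_states if isinstance(pred, StateAnnotation) else int(max(p.max(), o.max())) + 1)
    M = _confusion(p, o, S)
    tp = np.diag(M).astype(np.float64)
    denom = M.sum(axis=1) + M.sum(axis=0)
    with np.errstate(invalid="ignore"):
        return np.where(denom > 0, 2.0 * tp / np.maximum(denom, 1), np.nan)


def weighted_state_average(values: np.ndarray, sizes: np.ndarray) -> float:
    """Size-weighted mean of per-state values, sum_i v_i s_i / sum_i s_i.

    NaN values (states undefined in the comparison) are excluded and the
    weights renormalized over the remaining states.
    """
    values = np.asarray(values, dtype=np.float64)
    sizes = np.asarray(sizes, dtype=np.float64)
    if (sizes < 0).any():
        raise ValueError("state sizes must be non-negative")
    defined = ~np.isnan(values)
    total = sizes[defined].sum()
    if total <= 0:
        raise ValueError("all state weights are zero")
    return float(np.sum(values[defined] * sizes[defined]) / total)


def mean_state_sizes(annotations: list[StateAnnotation]) -> np.ndarray:
    """Per-state bin counts averaged over the reference annotations; these
    are the weights s_i of the weighted Jaccard/F1 averages."""
    if not annotations:
        raise ValueError("need at least one reference annotation")
    S = annotations[0].n_states
    counts = np.zeros(S, dtype=np.float64)
    for ann in annotations:
        obs = ann.states[ann.observed_mask]
        counts += np.bincount(obs, minlength=S)
    return counts / len(annotations)


def genome_fraction(track: StateAnnotation | SoftAnnotation | np.ndarray) -> np.ndarray:
    """Per-state genome fraction.

    Hard tracks: bin count per state over non-missing bins.  Soft tracks:
    per-state probability column sum over the number of positions.
    """
    if isinstance(track, StateAnnotation):
        obs = track.states[track.observed_mask]
        counts = np.bincount(obs, minlength=track.n_states)
        return counts / counts.sum()
    probs = _as_probs(track)
    return probs.sum(axis=0) / probs.shape[0]


# ---------------------------------------------------------------------------
# Calibration


@dataclass
class CalibrationCurve:
    """Reliability curve over equally spaced probability bins."""

    edges: np.ndarray
    mean_predicted: np.ndarray  # NaN for empty bins
    observed_frequency: np.ndarray  # NaN for empty bins
    counts: np.ndarray
    pearson_r: float  # NaN when < 2 non-empty bins

    @property
    def nonempty(self) -> np.ndarray:
        return self.counts > 0


def _bin_index(probs: np.ndarray, n_bins: int) -> np.ndarray:
    idx = np.floor(probs * n_bins).astype(np.int64)
    return np.minimum(idx, n_bins - 1)  # probability exactly 1 -> last bin


def calibration_from_pairs(
    probs: np.ndarray, matched: np.ndarray, n_bins: int = 50
) -> CalibrationCurve:
    """Build a reliability curve from (predicted probability, hit) pairs."""
    probs = np.asarray(probs, dtype=np.float64)
    matched = np.asarray(matched).astype(np.float64)
    idx = _bin_index(probs, n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    psum = np.bincount(idx, weights=probs, minlength=n_bins)
    msum = np.bincount(idx, weights=matched, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        mean_p = np.where(counts > 0, psum / np.maximum(counts, 1), np.nan)
        freq = np.where(counts > 0, msum / np.maximum(counts, 1), np.nan)
    ok = counts > 0
    if ok.sum() >= 2 and np.ptp(mean_p[ok]) > 0 and np.ptp(freq[ok]) > 0:
        r = float(np.corrcoef(mean_p[ok], freq[ok])[0, 1])
    else:
        r = float("nan")
    return CalibrationCurve(
        edges=np.linspace(0.0, 1.0, n_bins + 1),
        mean_predicted=mean_p,
        observed_frequency=freq,
        counts=counts,
        pearson_r=r,
    )


def calibration_curve(
    soft: SoftAnnotation | np.ndarray,
    obs: StateAnnotation | np.ndarray,
    state: int,
    n_bins: int = 50,
) -> CalibrationCurve:
    """Reliability curve for one state: predicted probability of the state
    vs the observed frequency of that state within each probability bin."""
    probs = _as_probs(soft)[:, state]
    o = _as_codes(obs)
    mask = o != MISSING
    return calibration_from_pairs(probs[mask], o[mask] == state, n_bins)


def calibration_all_states(
    soft: SoftAnnotation | np.ndarray,
    obs: StateAnnotation | np.ndarray,
    n_bins: int = 50,
) -> CalibrationCurve:
    """Pooled reliability curve over all (position, state) pairs."""
    probs = _as_probs(soft)
    o = _as_codes(obs)
    mask = o != MISSING
    S = probs.shape[1]
    flat_p = probs[mask].ravel()
    flat_m = (o[mask, None] == np.arange(S)[None, :]).ravel()
    return calibration_from_pairs(flat_p, flat_m, n_bins)


@dataclass
class StateComposition:
    """Observed-state composition across probability bins for one state."""

    state: int
    bin_centers: np.ndarray  # surviving bins only
    counts: np.ndarray
    composition: np.ndarray  # surviving bins x S observed-state fractions
    group_fraction: np.ndarray  # among incorrect predictions; NaN if none
    group_fraction_r: float  # Pearson of group_fraction vs bin mean prob


def composition_by_probability(
    soft: SoftAnnotation | np.ndarray,
    obs: StateAnnotation | np.ndarray,
    state: int,
    grouping: StateGrouping | None = None,
    n_bins: int = 100,
    min_count: int = 100,
) -> StateComposition:
    """Observed-state composition across probability bins of one state.

    Positions are binned by the predicted probability of ``state`` into
    ``n_bins`` equal bins; bins with fewer than ``min_count`` positions are
    dropped.  ``group_fraction`` is, among positions where the state was
    *not* observed (incorrect for this state), the fraction whose observed
    state lies in the same interpretive group as ``state``;
    ``group_fraction_r`` is its Pearson correlation with the bins' mean
    predicted probability.
    """
    probs = _as_probs(soft)
    S = probs.shape[1]
    grouping = grouping or StateGrouping(n_states=S)
    o = _as_codes(obs)
    mask = o != MISSING
    p, o = probs[mask, state], o[mask]
    idx = _bin_index(p, n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    surviving = np.flatnonzero(counts >= min_count)
    if len(surviving) == 0:
        raise ValueError(f"no probability bins with >= {min_count} positions")
    comp = np.zeros((len(surviving), S))
    group_frac = np.full(len(surviving), np.nan)
    mean_p = np.full(len(surviving), np.nan)
    group_of = grouping.group_of
    own_group = group_of[state]
    for i, b in enumerate(surviving):
        in_bin = idx == b
        comp[i] = np.bincount(o[in_bin], minlength=S) / counts[b]
        mean_p[i] = p[in_bin].mean()
        wrong = in_bin & (o != state)
        if wrong.any():
            group_frac[i] = np.mean(group_of[o[wrong]] == own_group)
    ok = ~np.isnan(group_frac)
    if ok.sum() >= 2 and np.ptp(mean_p[ok]) > 0 and np.ptp(group_frac[ok]) > 0:
        r = float(np.corrcoef(mean_p[ok], group_frac[ok])[0, 1])
    else:
        r = float("nan")
    centers = (np.arange(n_bins) + 0.5) / n_bins
    return StateComposition(
        state=state,
        bin_centers=centers[surviving],
        counts=counts[surviving],
        composition=comp,
        group_fraction=group_frac,
        group_fraction_r=r,
    )


# ---------------------------------------------------------------------------
# Near-miss (group mismatch) analysis


@dataclass
class GroupMismatchResult:
    variant: str
    n_mismatched: int
    observed_proportion: float
    expected_proportion: float

    @property
    def fold(self) -> float:
        return self.observed_proportion / self.expected_proportion


def group_mismatch_analysis(
    pred: StateAnnotation | np.ndarray,
    obs: StateAnnotation | np.ndarray,
    grouping: StateGrouping | None = None,
    variant: str = "all",
    quiescent_state: int | None = None,
) -> GroupMismatchResult:
    """How often a wrong hard prediction is still in the observed state's
    interpretive group, vs the chance level.

    Variants:

    ``all``
        All mismatched positions.  The chance draw for a position with
        predicted state p is a state sampled from the genome-wide observed
        state frequencies with p itself excluded and the remaining
        frequencies renormalized.
    ``exclude_pred_quiescent`` / ``exclude_obs_quiescent``
        Mismatched positions where the predicted (resp. observed) state is
        quiescent are removed, and the chance draw uses the observed-state
        frequencies of the remaining mismatched positions.

    Expected proportions are computed analytically as the probability that
    the variant's stated random draw lands in the predicted state's group.
    """
    variants = ("all", "exclude_pred_quiescent", "exclude_obs_quiescent")
    if variant not in variants:
        raise ValueError(f"variant must be one of {variants}")
    p, o = _as_codes(pred), _as_codes(obs)
    S = pred.n_states if isinstance(pred, StateAnnotation) else int(max(p.max(), o.max())) + 1
    grouping = grouping or StateGrouping(n_states=S)
    if quiescent_state is None:
        quiescent_state = S - 1
    mask = _common_mask(p, o)
    p, o = p[mask], o[mask]
    group_of = grouping.group_of

    mismatch = p != o
    if variant == "exclude_pred_quiescent":
        mismatch &= p != quiescent_state
    elif variant == "exclude_obs_quiescent":
        mismatch &= o != quiescent_state
    if not mismatch.any():
        raise ValueError("no mismatched positions after the variant filter")
    pm, om = p[mismatch], o[mismatch]
    observed = float(np.mean(group_of[om] == group_of[pm]))

    # analytic chance level
    group_mass = np.zeros(int(group_of.max()) + 1)
    if variant == "all":
        freq = np.bincount(o, minlength=S).astype(np.float64)
        freq /= freq.sum()
        np.add.at(group_mass, group_of, freq)
        # per predicted state: P(draw in group(p), draw != p) renormalized;
        # a state with frequency 1 cannot appear as a mismatch prediction
        with np.errstate(divide="ignore", invalid="ignore"):
            per_state = (group_mass[group_of] - freq) / (1.0 - freq)
        expected = float(np.mean(per_state[pm]))
    else:
        freq = np.bincount(om, minlength=S).astype(np.float64)
        freq /= freq.sum()
        np.add.at(group_mass, group_of, freq)
        expected = float(np.mean(group_mass[group_of[pm]]))
    return GroupMismatchResult(
        variant=variant,
        n_mismatched=int(mismatch.sum()),
        observed_proportion=observed,
        expected_proportion=expected,
    )


# ---------------------------------------------------------------------------
# Fold enrichment


@dataclass
class EnrichmentTable:
    """Per-state fold enrichments for one interval annotation."""

    annotation: str
    fold: np.ndarray  # NaN where state coverage below the floor
    state_fraction: np.ndarray
    annotation_fraction: float


def fold_enrichment(
    ann: StateAnnotation,
    intervals: IntervalSet,
    min_state_coverage: float = 1e-5,
) -> EnrichmentTable:
    """Fold enrichment of each state for an interval annotation.

    fold(s) = P(state s and annotation) / (P(state s) * P(annotation)),
    with probabilities measured as genome fractions over non-missing bins
    and the annotation contributing its per-bin base-coverage fraction.
    States whose genome fraction is below ``min_state_coverage`` (default
    0.001%) are suppressed (NaN).
    """
    cov = intervals.coverage_fraction(ann.genome)
    mask = ann.observed_mask
    if not mask.any():
        raise ValueError("annotation has no observed bins")
    cov, codes = cov[mask], ann.states[mask]
    n = len(codes)
    annot_frac = cov.mean()
    if annot_frac == 0:
        raise ValueError(f"annotation {intervals.name!r} covers no bins")
    S = ann.n_states
    state_frac = np.bincount(codes, minlength=S) / n
    joint = np.bincount(codes, weights=cov, minlength=S) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = joint / (state_frac * annot_frac)
    fold[state_frac < min_state_coverage] = np.nan
    return EnrichmentTable(
        annotation=intervals.name,
        fold=fold,
        state_fraction=state_frac,
        annotation_fraction=float(annot_frac),
    )


def fold_enrichment_soft(
    soft: SoftAnnotation,
    intervals: IntervalSet,
    floor: float = 0.05,
    min_state_coverage: float = 1e-5,
) -> EnrichmentTable:
    """Fold enrichment from soft assignments with low-probability truncation.

    Probabilities below ``floor`` are set to 0 and each position is
    renormalized; positions left with zero total mass are dropped.  State
    fractions become probability-mass fractions.  With a one-hot soft track
    this reduces exactly to :func:`fold_enrichment`.
    """
    cov = intervals.coverage_fraction(soft.genome)
    probs = soft.probs.copy()
    probs[probs < floor] = 0.0
    rowsum = probs.sum(axis=1)
    keep = rowsum > 0
    if not keep.any():
        raise ValueError("all positions have zero mass after truncation")
    probs = probs[keep] / rowsum[keep, None]
    cov = cov[keep]
    n = probs.shape[0]
    annot_frac = cov.mean()
    if annot_frac == 0:
        raise ValueError(f"annotation {intervals.name!r} covers no bins")
    state_frac = probs.sum(axis=0) / n
    joint = (probs * cov[:, None]).sum(axis=0) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = joint / (state_frac * annot_frac)
    fold[state_frac < min_state_coverage] = np.nan
    return EnrichmentTable(
        annotation=intervals.name,
        fold=fold,
        state_fraction=state_frac,
        annotation_fraction=float(annot_frac),
    )


# ---------------------------------------------------------------------------
# Pairwise sample relationships


def _pearson_columns(X: np.ndarray) -> np.ndarray:
    """Column-by-column Pearson matrix; zero-variance columns give NaN."""
    Xc = X - X.mean(axis=0)
    sd = np.sqrt((Xc**2).sum(axis=0))
    # tolerance absorbs float residue of centering an exactly constant column
    flat = sd <= 1e-12 * (np.abs(X).max() + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (Xc.T @ Xc) / np.outer(sd, sd)
    corr[:, flat] = np.nan
    corr[flat, :] = np.nan
    return corr


def pairwise_relationships(
    tracks: dict[str, StateAnnotation] | dict[str, SoftAnnotation],
    mode: str = "agreement",
    state: int | None = None,
    n_positions: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample x sample relationship matrix.

    Modes: ``agreement`` (fraction of positions with identical hard
    labels), ``state_binary_pearson`` (Pearson of 0/1 presence vectors of
    ``state``), ``state_soft_pearson`` (Pearson of the state's probability
    vectors).  ``n_positions`` optionally evaluates on a seeded random
    subsample of positions.  Undefined correlations (zero variance) are
    NaN, never 0.
    """
    if mode not in ("agreement", "state_binary_pearson", "state_soft_pearson"):
        raise ValueError(f"unknown mode {mode!r}")
    ids = list(tracks)
    first = tracks[ids[0]]
    n_bins = first.genome.n_bins
    if n_positions is not None:
        rng = np.random.default_rng(seed)
        positions = np.sort(rng.choice(n_bins, size=n_positions, replace=False))
    else:
        positions = np.arange(n_bins)

    if mode == "state_soft_pearson":
        if state is None:
            raise ValueError("state required for per-state modes")
        X = np.column_stack([_as_probs(tracks[i])[positions, state] for i in ids])
        corr = _pearson_columns(X)
    elif mode == "state_binary_pearson":
        if state is None:
            raise ValueError("state required for per-state modes")
        X = np.column_stack(
            [(_as_codes(tracks[i])[positions] == state).astype(float) for i in ids]
        )
        corr = _pearson_columns(X)
    else:
        codes = np.column_stack([_as_codes(tracks[i])[positions] for i in ids])
        n = len(ids)
        corr = np.eye(n)
        for i in range(n):
            for j in range(i + 1, n):
                mask = _common_mask(codes[:, i], codes[:, j])
                if not mask.any():
                    corr[i, j] = corr[j, i] = np.nan
                else:
                    corr[i, j] = corr[j, i] = np.mean(
                        codes[mask, i] == codes[mask, j]
                    )
    return pd.DataFrame(corr, index=ids, columns=ids)


@dataclass
class GroupRelationshipSummary:
    within_mean: float
    between_mean: float
    difference: float
    same_group_auprc: float


def group_summary(
    matrix: pd.DataFrame, groups: dict[str, str]
) -> GroupRelationshipSummary:
    """Within/between-group means of a pairwise relationship matrix, and the
    AUPRC of the pairwise values for predicting same-group membership.

    Only off-diagonal pairs contribute; groups of size 1 contribute no
    within pairs.
    """
    ids = list(matrix.index)
    labels = [groups[i] for i in ids]
    if len(set(labels)) < 2:
        raise ValueError("need at least 2 groups")
    vals, same = [], []
    M = matrix.to_numpy()
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if np.isnan(M[i, j]):
                continue
            vals.append(M[i, j])
            same.append(labels[i] == labels[j])
    vals = np.asarray(vals)
    same = np.asarray(same)
    if not same.any():
        raise ValueError("no within-group pairs")
    return GroupRelationshipSummary(
        within_mean=float(vals[same].mean()),
        between_mean=float(vals[~same].mean()),
        difference=float(vals[same].mean() - vals[~same].mean()),
        same_group_auprc=auprc(vals, same),
    )


# ---------------------------------------------------------------------------
# Per-state signal means (e.g. DNA methylation)


def mean_signal_per_state(
    ann: StateAnnotation,
    values: np.ndarray,
    coverage: np.ndarray,
    min_coverage: int = 3,
) -> np.ndarray:
    """Per-state mean of a per-bin signal, restricted to bins whose
    measurement coverage is >= ``min_coverage``.

    States with no qualifying positions are NaN.  Cross-sample aggregation
    is the mean of per-sample per-state means (``np.nanmean`` over stacked
    outputs).
    """
    values = np.asarray(values, dtype=np.float64)
    coverage = np.asarray(coverage)
    if values.shape != (ann.genome.n_bins,) or coverage.shape != values.shape:
        raise ValueError("signal arrays must be per-bin")
    mask = (coverage >= min_coverage) & ann.observed_mask & np.isfinite(values)
    S = ann.n_states
    counts = np.bincount(ann.states[mask], minlength=S).astype(np.float64)
    sums = np.bincount(ann.states[mask], weights=values[mask], minlength=S)
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
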