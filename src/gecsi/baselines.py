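"""Comparison methods: Majority State, KNN, and the closest-reference
benchmark.

Majority State assigns every position the most frequent state across the
reference samples.  KNN restricts the vote to the k expression-nearest
references.  Both also return the per-position state frequencies used as
their "soft" scores in ranking evaluations.  The closest reference is the
reference annotation with the highest pairwise agreement with the target —
an upper benchmark, not an imputation method, since it looks at the target
annotation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compendium import ReferenceCompendium
from .evaluation import pairwise_agreement
from .genome_io import MISSING, StateAnnotation
from .neighbors import correlate_query, rank_neighbors_from_series


@dataclass
class StateFrequency:
    """Bins x states frequency matrix over a voting sample set.

    Rows sum to 1 over the non-missing contributors at each bin; rows with
    no contributors are all-zero.
    """

    freqs: np.ndarray
    n_voters: int


def _vote(
    annotations: list[StateAnnotation], seed: int
) -> tuple[np.ndarray, StateFrequency]:
    """Modal state per bin with seeded uniform tie-breaking.

    One seeded generator is consumed at tied bins in bin order; bins whose
    maximum is unique draw nothing, keeping results stable under changes
    elsewhere in the genome only when tie layout is unchanged.
    """
    if not annotations:
        raise ValueError("need at least one reference annotation")
    S = annotations[0].n_states
    n_bins = annotations[0].genome.n_bins
    counts = np.zeros((n_bins, S), dtype=np.int32)
    idx = np.arange(n_bins)
    for ann in annotations:
        valid = ann.observed_mask
        np.add.at(counts, (idx[valid], ann.states[valid]), 1)
    totals = counts.sum(axis=1)
    freqs = np.zeros_like(counts, dtype=np.float64)
    nz = totals > 0
    freqs[nz] = counts[nz] / totals[nz, None]

    best = counts.max(axis=1)
    modal = counts.argmax(axis=1).astype(np.int16)
    modal[~nz] = MISSING
    n_tied = (counts == best[:, None]).sum(axis=1)
    tied_bins = np.flatnonzero(nz & (n_tied > 1))
    rng = np.random.default_rng(seed)
    for b in tied_bins:
        options = np.flatnonzero(counts[b] == best[b])
        modal[b] = options[rng.integers(len(options))]
    return modal, StateFrequency(freqs=freqs, n_voters=len(annotations))


def majority_state(
    reference_anns: list[StateAnnotation], seed: int = 0
) -> tuple[StateAnnotation, StateFrequency]:
    """Most frequent state across all references at each position.

    Frequency ties are resolved by a seeded uniform choice among the tied
    maxima; all-missing bins stay MISSING.
    """
    modal, freq = _vote(reference_anns, seed)
    first = reference_anns[0]
    ann = StateAnnotation(
        sample_id="majority",
        states=modal,
        genome=first.genome,
        alphabet=first.alphabet,
    )
    return ann, freq


def knn_predict(
    query_expr: pd.Series,
    comp: ReferenceCompendium,
    k: int,
    seed: int = 0,
    query_id: str = "query",
) -> tuple[StateAnnotation, StateFrequency]:
    """Modal state over the k expression-nearest reference samples."""
    ref_ids = comp.sample_ids
    if not 1 <= k <= len(ref_ids):
        raise ValueError(f"k={k} must be in [1, {len(ref_ids)}]")
    corr = correlate_query(query_expr, comp.expression.data[ref_ids])
    ranking = rank_neighbors_from_series(query_id, corr, k)
    anns = [comp.annotations[s] for s in ranking.neighbor_ids]
    modal, freq = _vote(anns, seed)
    ann = StateAnnotation(
        sample_id=query_id,
        states=modal,
        genome=comp.genome,
        alphabet=comp.alphabet,
    )
    return ann, freq


def closest_reference(
    target_ann: StateAnnotation, reference_anns: list[StateAnnotation]
) -> tuple[str, float]:
    """Reference with the highest pairwise agreement with the target.

    Ties go to the first reference in input order.  Requires the target
    annotation, so it benchmarks an upper bound rather than imputing.
    """
    if not reference_anns:
        raise ValueError("need at least one reference annotation")
    best_id, best_agree = None, -1.0
    for ref in reference_anns:
        agree = pairwise_agreement(target_ann, ref)
        if agree > best_agree:
            best_id, best_agree = ref.sample_id, agree
    assert best_id is not None
    return best_id, best_agree
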