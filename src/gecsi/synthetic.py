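"""Synthetic compendium generator with latent sample-group structure.

Emulates the statistical structure the imputation method relies on:
samples fall into latent groups (cell-type-like); within a group, both
expression and chromatin-state annotations are similar, so expression
similarity is informative about annotation similarity.

Annotations: each group draws a per-bin prototype state from a skewed,
quiescent-dominant base frequency vector; each sample copies its group
prototype, except with probability ``annotation_noise`` per bin the state
is resampled from the base frequencies.

Expression: TPM-like values are lognormal.  Each gene has a baseline
log-mean; a fraction ``expression_signal_frac`` of genes additionally
carry a group-specific log-offset, and every sample adds i.i.d. Gaussian
log-noise.  Heavy-tailed marginals mean quantile normalization and
log2(x+1) act nontrivially downstream.

Everything is deterministic from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compendium import ReferenceCompendium
from .genome_io import BinnedGenome, ExpressionTable, StateAnnotation
from .states import DEFAULT_STATE_ALPHABET


def default_state_frequencies(n_states: int = 18, quiescent_mass: float = 0.5) -> np.ndarray:
    """Skewed base frequencies: ``quiescent_mass`` on the last state, the
    rest split over the other states with a mild geometric decay."""
    if not 0 < quiescent_mass < 1:
        raise ValueError("quiescent_mass must be in (0, 1)")
    rest = 0.97 ** np.arange(n_states - 1)
    rest = rest / rest.sum() * (1.0 - quiescent_mass)
    return np.r_[rest, quiescent_mass]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a synthetic compendium.

    ``annotation_noise`` is the per-bin probability that a sample's state
    is resampled from the base frequencies instead of copied from its
    group prototype — the difficulty dial of the benchmark.
    """

    n_samples: int = 30
    n_groups: int = 4
    n_genes: int = 500
    n_bins: int = 5000
    n_states: int = 18
    n_chroms: int = 2
    bin_size: int = 200
    state_base_frequencies: tuple[float, ...] | None = None
    annotation_noise: float = 0.1
    expression_signal_frac: float = 0.2
    expression_noise_sd: float = 0.5
    gene_mean_log_sd: float = 1.2
    gene_mean_log_center: float = 1.5
    group_effect_log_sd: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.annotation_noise <= 1:
            raise ValueError("annotation_noise must be in [0, 1]")
        if not 0 <= self.expression_signal_frac <= 1:
            raise ValueError("expression_signal_frac must be in [0, 1]")
        if self.n_groups > self.n_samples:
            raise ValueError("n_groups cannot exceed n_samples")
        if self.state_base_frequencies is not None:
            f = np.asarray(self.state_base_frequencies)
            if len(f) != self.n_states:
                raise ValueError("base frequencies length != n_states")
            if (f < 0).any() or abs(f.sum() - 1.0) > 1e-9:
                raise ValueError("base frequencies must be a distribution")

    @property
    def base_frequencies(self) -> np.ndarray:
        if self.state_base_frequencies is not None:
            return np.asarray(self.state_base_frequencies, dtype=np.float64)
        return default_state_frequencies(self.n_states)

    def make_genome(self) -> BinnedGenome:
        """Split ``n_bins`` across ``n_chroms`` chromosomes (first gets the
        remainder), so chromosome-restricted tuning is exercisable."""
        per = self.n_bins // self.n_chroms
        counts = [per] * self.n_chroms
        counts[0] += self.n_bins - per * self.n_chroms
        return BinnedGenome(
            chrom_names=tuple(f"chr{i+1}" for i in range(self.n_chroms)),
            chrom_lengths=tuple(c * self.bin_size for c in counts),
            bin_size=self.bin_size,
        )

    def alphabet(self) -> tuple[str, ...]:
        if self.n_states == 18:
            return DEFAULT_STATE_ALPHABET
        return tuple(f"E{i+1}" for i in range(self.n_states))


@dataclass
class SyntheticCompendium:
    """A generated compendium plus the latent truth used to build it."""

    compendium: ReferenceCompendium
    groups: dict[str, int]
    prototypes: np.ndarray  # n_groups x n_bins prototype state codes
    config: SimulationConfig
    gene_log_means: np.ndarray = field(repr=False)
    group_effects: np.ndarray = field(repr=False)  # n_groups x n_genes
    signal_genes: np.ndarray = field(repr=False)

    @property
    def expression(self) -> ExpressionTable:
        return self.compendium.expression

    @property
    def annotations(self) -> dict[str, StateAnnotation]:
        return self.compendium.annotations

    @property
    def genome(self) -> BinnedGenome:
        return self.compendium.genome


def _sample_states(
    rng: np.random.Generator, freqs: np.ndarray, size: int
) -> np.ndarray:
    return rng.choice(len(freqs), size=size, p=freqs).astype(np.int16)


def _sample_annotation(
    rng: np.random.Generator,
    prototype: np.ndarray,
    noise: float,
    freqs: np.ndarray,
) -> np.ndarray:
    states = prototype.copy()
    if noise > 0:
        flip = rng.random(len(states)) < noise
        states[flip] = _sample_states(rng, freqs, int(flip.sum()))
    return states


def _sample_expression_column(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    gene_log_means: np.ndarray,
    group_effect: np.ndarray,
) -> np.ndarray:
    log_vals = (
        gene_log_means
        + group_effect
        + rng.normal(0.0, cfg.expression_noise_sd, cfg.n_genes)
    )
    return np.exp(log_vals)


def generate_compendium(cfg: SimulationConfig) -> SyntheticCompendium:
    """Generate matched expression and annotations with group structure.

    Sample ids are ``S00``..; groups are assigned round-robin so group
    sizes differ by at most one.  Expression is on a TPM-like (lognormal)
    scale at stage ``raw_tpm``.
    """
    rng = np.random.default_rng(cfg.seed)
    genome = cfg.make_genome()
    freqs = cfg.base_frequencies
    alphabet = cfg.alphabet()

    prototypes = np.vstack(
        [_sample_states(rng, freqs, cfg.n_bins) for _ in range(cfg.n_groups)]
    )

    gene_log_means = rng.normal(
        cfg.gene_mean_log_center, cfg.gene_mean_log_sd, cfg.n_genes
    )
    n_signal = int(round(cfg.expression_signal_frac * cfg.n_genes))
    signal_genes = np.sort(
        rng.choice(cfg.n_genes, size=n_signal, replace=False)
    )
    group_effects = np.zeros((cfg.n_groups, cfg.n_genes))
    group_effects[:, signal_genes] = rng.normal(
        0.0, cfg.group_effect_log_sd, (cfg.n_groups, n_signal)
    )

    sample_ids = [f"S{i:02d}" for i in range(cfg.n_samples)]
    groups = {sid: i % cfg.n_groups for i, sid in enumerate(sample_ids)}

    expr_cols = {}
    annotations = {}
    for sid in sample_ids:
        g = groups[sid]
        expr_cols[sid] = _sample_expression_column(
            rng, cfg, gene_log_means, group_effects[g]
        )
        states = _sample_annotation(
            rng, prototypes[g], cfg.annotation_noise, freqs
        )
        annotations[sid] = StateAnnotation(
            sample_id=sid, states=states, genome=genome, alphabet=alphabet
        )

    expr = ExpressionTable(
        data=pd.DataFrame(
            expr_cols, index=[f"gene{i:04d}" for i in range(cfg.n_genes)]
        ),
        stage="raw_tpm",
    )
    comp = ReferenceCompendium(
        expression=expr, annotations=annotations, genome=genome,
        alphabet=alphabet,
    )
    return SyntheticCompendium(
        compendium=comp,
        groups=groups,
        prototypes=prototypes,
        config=cfg,
        gene_log_means=gene_log_means,
        group_effects=group_effects,
        signal_genes=signal_genes,
    )


def generate_query(
    synth: SyntheticCompendium,
    group: int,
    seed: int,
    query_id: str = "query",
) -> tuple[pd.Series, StateAnnotation]:
    """Draw a new sample from a group's generative process.

    Returns the expression vector (the imputation input) and the held-out
    true annotation (for benchmarking only).
    """
    cfg = synth.config
    if not 0 <= group < cfg.n_groups:
        raise ValueError(f"unknown group {group}")
    rng = np.random.default_rng(seed)
    expr = pd.Series(
        _sample_expression_column(
            rng, cfg, synth.gene_log_means, synth.group_effects[group]
        ),
        index=synth.expression.gene_ids,
        name=query_id,
    )
    states = _sample_annotation(
        rng, synth.prototypes[group], cfg.annotation_noise, cfg.base_frequencies
    )
    truth = StateAnnotation(
        sample_id=query_id, states=states, genome=synth.genome,
        alphabet=cfg.alphabet(),
    )
    return expr, truth


def generate_signal_track(
    ann: StateAnnotation,
    state_means: np.ndarray,
    noise_sd: float,
    coverage_range: tuple[int, int],
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Methylation-like per-bin signal: clipped Normal(state mean, sd) values
    plus integer coverage uniform in ``coverage_range`` (inclusive)."""
    state_means = np.asarray(state_means, dtype=np.float64)
    if len(state_means) != ann.n_states:
        raise ValueError("state_means length != alphabet size")
    if (state_means < 0).any() or (state_means > 1).any():
        raise ValueError("state means must be in [0, 1]")
    lo, hi = coverage_range
    if lo < 0 or hi < lo:
        raise ValueError("invalid coverage range")
    rng = np.random.default_rng(seed)
    n = ann.genome.n_bins
    means = np.where(ann.observed_mask, state_means[ann.states], np.nan)
    values = np.clip(rng.normal(means, noise_sd), 0.0, 1.0)
    coverage = rng.integers(lo, hi + 1, size=n)
    return values, coverage
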