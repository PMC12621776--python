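"""Data model for binned genomes, state tracks, and expression tables.

A genome is partitioned into fixed-size bins (200 bp by default, matching
ChromHMM segmentations); every genomic quantity in this package is defined
per bin ("position").  This module provides the containers —
:class:`BinnedGenome`, :class:`StateAnnotation` (hard per-bin labels),
:class:`SoftAnnotation` (per-bin state probabilities),
:class:`ExpressionTable` (genes x samples TPM matrix) and
:class:`IntervalSet` — together with readers/writers for the interchange
formats: ChromHMM-style dense BED4 for segmentations, bedGraph for soft
tracks, TSV for expression, GTF for gene annotations.

Coordinates are 0-based half-open (BED convention) everywhere.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .states import DEFAULT_STATE_ALPHABET

#: Sentinel state code for bins without an assigned state.
MISSING: int = -1


@dataclass(frozen=True)
class BinnedGenome:
    """Chromosome lengths partitioned into fixed-size bins.

    Bins are indexed globally, 0-based, in chromosome order; the last bin of
    a chromosome may be shorter than ``bin_size`` and counts as a full
    position.
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    bin_size: int = 200

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths length mismatch")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("duplicate chromosome names")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")

    @property
    def bins_per_chrom(self) -> tuple[int, ...]:
        return tuple(
            math.ceil(l / self.bin_size) for l in self.chrom_lengths
        )

    @property
    def chrom_offsets(self) -> tuple[int, ...]:
        """Global index of the first bin of each chromosome."""
        out, acc = [], 0
        for n in self.bins_per_chrom:
            out.append(acc)
            acc += n
        return tuple(out)

    @property
    def n_bins(self) -> int:
        return sum(self.bins_per_chrom)

    def chrom_index(self, chrom: str) -> int:
        try:
            return self.chrom_names.index(chrom)
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def global_index(self, chrom: str, pos: int) -> int:
        """Global bin index of the bin containing base-pair ``pos``."""
        ci = self.chrom_index(chrom)
        if not 0 <= pos < self.chrom_lengths[ci]:
            raise ValueError(f"position {pos} outside {chrom}")
        return self.chrom_offsets[ci] + pos // self.bin_size

    def bin_interval(self, index: int) -> tuple[str, int, int]:
        """(chrom, start, end) of a global bin index, half-open bp coords."""
        if not 0 <= index < self.n_bins:
            raise IndexError(index)
        offsets = self.chrom_offsets
        ci = int(np.searchsorted(np.asarray(offsets), index, side="right")) - 1
        within = index - offsets[ci]
        start = within * self.bin_size
        end = min(start + self.bin_size, self.chrom_lengths[ci])
        return self.chrom_names[ci], start, end

    def chrom_bin_slice(self, chrom: str) -> slice:
        ci = self.chrom_index(chrom)
        off = self.chrom_offsets[ci]
        return slice(off, off + self.bins_per_chrom[ci])


@dataclass
class StateAnnotation:
    """Hard chromatin-state labels for one sample, one code per bin.

    ``states`` holds 0-based codes into ``alphabet``; ``MISSING`` (-1) marks
    bins without a call.
    """

    sample_id: str
    states: np.ndarray
    genome: BinnedGenome
    alphabet: tuple[str, ...] = DEFAULT_STATE_ALPHABET

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int16)
        if self.states.shape != (self.genome.n_bins,):
            raise ValueError(
                f"annotation length {self.states.shape} does not match "
                f"genome bin count {self.genome.n_bins}"
            )
        bad = (self.states < MISSING) | (self.states >= len(self.alphabet))
        if bad.any():
            raise ValueError("state codes outside alphabet")

    @property
    def n_states(self) -> int:
        return len(self.alphabet)

    @property
    def observed_mask(self) -> np.ndarray:
        return self.states != MISSING


@dataclass
class SoftAnnotation:
    """Per-bin state probability matrix for one sample (bins x states)."""

    sample_id: str
    probs: np.ndarray
    genome: BinnedGenome
    alphabet: tuple[str, ...] = DEFAULT_STATE_ALPHABET

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        expected = (self.genome.n_bins, len(self.alphabet))
        if self.probs.shape != expected:
            raise ValueError(f"probs shape {self.probs.shape} != {expected}")
        if (self.probs < -1e-9).any() or (self.probs > 1 + 1e-9).any():
            raise ValueError("probabilities outside [0, 1]")
        if np.abs(self.probs.sum(axis=1) - 1.0).max() > 1e-6:
            raise ValueError("soft annotation rows must sum to 1 (tol 1e-6)")


@dataclass
class ExpressionTable:
    """Genes x samples expression matrix with a processing-stage tag.

    ``stage`` tracks the preprocessing pipeline: ``raw_tpm`` ->
    ``quantile_normalized`` -> ``log2``.
    """

    data: pd.DataFrame
    stage: str = "raw_tpm"

    STAGES = ("raw_tpm", "quantile_normalized", "log2")

    def __post_init__(self) -> None:
        if self.stage not in self.STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dupes[:5])}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if self.stage != "log2" and (values < 0).any():
            raise ValueError("negative expression values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=np.float64)


@dataclass(frozen=True)
class GeneRecord:
    """Minimal gene annotation record used for the protein-coding filter."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: start >= end")


@dataclass
class IntervalSet:
    """A named set of genomic intervals (0-based half-open), sorted."""

    name: str
    chroms: np.ndarray
    starts: np.ndarray
    ends: np.ndarray

    def __post_init__(self) -> None:
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        if not (len(self.chroms) == len(self.starts) == len(self.ends)):
            raise ValueError("interval columns of unequal length")
        if (self.starts >= self.ends).any():
            raise ValueError("interval start >= end")
        order = np.lexsort((self.starts, self.chroms.astype(str)))
        self.chroms = self.chroms[order]
        self.starts = self.starts[order]
        self.ends = self.ends[order]

    def __len__(self) -> int:
        return len(self.starts)

    def coverage_fraction(self, genome: BinnedGenome) -> np.ndarray:
        """Per-bin fraction of the bin's bases covered by the intervals.

        Intervals on chromosomes absent from ``genome`` are ignored; interval
        ends are clipped at chromosome ends.  Overlapping intervals are
        merged before coverage is computed, so the result is in [0, 1].
        """
        covered = np.zeros(genome.n_bins, dtype=np.float64)
        bs = genome.bin_size
        known = set(genome.chrom_names)
        for chrom in pd.unique(self.chroms):
            if chrom not in known:
                continue
            ci = genome.chrom_index(chrom)
            clen = genome.chrom_lengths[ci]
            off = genome.chrom_offsets[ci]
            mask = self.chroms == chrom
            ivs = _merge_intervals(
                np.clip(self.starts[mask], 0, clen),
                np.clip(self.ends[mask], 0, clen),
            )
            for start, end in ivs:
                if start >= end:
                    continue
                b0, b1 = start // bs, (end - 1) // bs
                for b in range(b0, b1 + 1):
                    bstart = b * bs
                    bend = min(bstart + bs, clen)
                    overlap = min(end, bend) - max(start, bstart)
                    covered[off + b] += overlap / (bend - bstart)
        return np.clip(covered, 0.0, 1.0)


def _merge_intervals(starts: np.ndarray, ends: np.ndarray) -> list[tuple[int, int]]:
    order = np.argsort(starts, kind="mergesort")
    merged: list[tuple[int, int]] = []
    for s, e in zip(starts[order], ends[order]):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], int(e)))
        else:
            merged.append((int(s), int(e)))
    return merged


# ---------------------------------------------------------------------------
# Segmentation (dense BED4) I/O


def read_segmentation(
    path: str | Path,
    genome: BinnedGenome,
    alphabet: tuple[str, ...] = DEFAULT_STATE_ALPHABET,
    sample_id: str | None = None,
    *,
    unknown_chrom: str = "error",
) -> StateAnnotation:
    """Read a ChromHMM-style dense segmentation BED into a StateAnnotation.

    Each record must span whole bins: start is a multiple of ``bin_size``
    and end is a multiple of ``bin_size`` or the chromosome end.  Bins not
    covered by any record are MISSING; overlapping records are rejected.

    Parameters
    ----------
    unknown_chrom
        ``"error"`` (default) rejects records on chromosomes absent from
        ``genome``; ``"skip"`` drops them silently.
    """
    if unknown_chrom not in ("error", "skip"):
        raise ValueError("unknown_chrom must be 'error' or 'skip'")
    path = Path(path)
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "state"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "state": str},
        comment="#",
    )
    code_of = {name: i for i, name in enumerate(alphabet)}
    unknown_states = set(df["state"]) - set(code_of)
    if unknown_states:
        raise ValueError(f"unknown state labels: {sorted(unknown_states)}")

    states = np.full(genome.n_bins, MISSING, dtype=np.int16)
    filled = np.zeros(genome.n_bins, dtype=bool)
    bs = genome.bin_size
    for chrom, grp in df.groupby("chrom", sort=False):
        if chrom not in genome.chrom_names:
            if unknown_chrom == "skip":
                continue
            raise ValueError(f"unknown chromosome {chrom!r} in {path}")
        ci = genome.chrom_index(str(chrom))
        clen = genome.chrom_lengths[ci]
        off = genome.chrom_offsets[ci]
        start = grp["start"].to_numpy()
        end = grp["end"].to_numpy()
        if (start < 0).any() or (end > clen).any() or (start >= end).any():
            raise ValueError(f"coordinates outside {chrom} in {path}")
        if (start % bs != 0).any():
            raise ValueError(f"record start not a multiple of bin size on {chrom}")
        bad_end = (end % bs != 0) & (end != clen)
        if bad_end.any():
            raise ValueError(f"record end not a bin boundary on {chrom}")
        b0 = start // bs
        b1 = np.ceil(end / bs).astype(np.int64)
        counts = b1 - b0
        idx = off + np.repeat(b0, counts) + _concat_aranges(counts)
        if filled[idx].any() or len(np.unique(idx)) != len(idx):
            raise ValueError(f"overlapping segmentation records on {chrom}")
        filled[idx] = True
        codes = np.array([code_of[s] for s in grp["state"]], dtype=np.int16)
        states[idx] = np.repeat(codes, counts)
    return StateAnnotation(
        sample_id=sample_id or path.stem, states=states, genome=genome,
        alphabet=alphabet,
    )


def _concat_aranges(counts: np.ndarray) -> np.ndarray:
    """Concatenate arange(c) for each c in counts, vectorized."""
    total = int(counts.sum())
    out = np.ones(total, dtype=np.int64)
    out[0] = 0
    resets = np.cumsum(counts)[:-1]
    out[resets] = 1 - counts[:-1]
    return np.cumsum(out)


def write_segmentation(ann: StateAnnotation, path: str | Path) -> None:
    """Write a StateAnnotation as dense BED4, merging same-state runs.

    MISSING bins produce no record.  Output is sorted by chromosome (genome
    order) then start.
    """
    path = Path(path)
    g = ann.genome
    with open(path, "w") as fh:
        for chrom in g.chrom_names:
            sl = g.chrom_bin_slice(chrom)
            clen = g.chrom_lengths[g.chrom_index(chrom)]
            for b0, b1, code in _runs(ann.states[sl]):
                if code == MISSING:
                    continue
                start = b0 * g.bin_size
                end = min(b1 * g.bin_size, clen)
                fh.write(f"{chrom}\t{start}\t{end}\t{ann.alphabet[code]}\n")


def _runs(values: np.ndarray):
    """Yield (start, stop, value) maximal constant runs of a 1-D array."""
    if len(values) == 0:
        return
    change = np.flatnonzero(values[1:] != values[:-1]) + 1
    bounds = np.r_[0, change, len(values)]
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        yield int(b0), int(b1), values[b0]


# ---------------------------------------------------------------------------
# Expression TSV I/O


def read_expression(path: str | Path, gene_id_column: str | int = 0) -> ExpressionTable:
    """Read a TSV (gene-id column + one column per sample) of raw TPMs."""
    df = pd.read_csv(path, sep="\t", index_col=gene_id_column)
    df.index = df.index.astype(str)
    df.index.name = None
    try:
        df = df.astype(np.float64)
    except ValueError as exc:
        raise ValueError(f"non-numeric expression value in {path}: {exc}") from exc
    return ExpressionTable(data=df, stage="raw_tpm")


def write_expression(expr: ExpressionTable, path: str | Path) -> None:
    expr.data.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# Interval BED and soft-track I/O


def read_intervals(path: str | Path, name: str | None = None) -> IntervalSet:
    """Read a BED3+ file into an IntervalSet; malformed lines are rejected
    with their line number."""
    path = Path(path)
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from None
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end")
            chroms.append(fields[0])
            starts.append(start)
            ends.append(end)
    return IntervalSet(
        name=name or path.stem,
        chroms=np.array(chroms, dtype=object),
        starts=np.array(starts),
        ends=np.array(ends),
    )


def write_soft_tracks(soft: SoftAnnotation, out_dir: str | Path) -> list[Path]:
    """Write one bedGraph per state with per-bin probabilities of that state.

    Runs of identical values are merged.  Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    g = soft.genome
    paths = []
    for s, state_name in enumerate(soft.alphabet):
        safe = re.sub(r"[^A-Za-z0-9._-]", "_", state_name)
        path = out_dir / f"{soft.sample_id}.{safe}.bedGraph"
        with open(path, "w") as fh:
            for chrom in g.chrom_names:
                sl = g.chrom_bin_slice(chrom)
                clen = g.chrom_lengths[g.chrom_index(chrom)]
                for b0, b1, val in _runs(soft.probs[sl, s]):
                    start = b0 * g.bin_size
                    end = min(b1 * g.bin_size, clen)
                    fh.write(f"{chrom}\t{start}\t{end}\t{float(val)!r}\n")
        paths.append(path)
    return paths


def read_soft_tracks(
    paths: dict[str, str | Path],
    genome: BinnedGenome,
    sample_id: str,
    alphabet: tuple[str, ...] = DEFAULT_STATE_ALPHABET,
) -> SoftAnnotation:
    """Assemble a SoftAnnotation from per-state bedGraph files.

    ``paths`` maps state name -> bedGraph path; every state in the alphabet
    must be present.
    """
    missing = set(alphabet) - set(paths)
    if missing:
        raise ValueError(f"missing bedGraph for states: {sorted(missing)}")
    probs = np.zeros((genome.n_bins, len(alphabet)), dtype=np.float64)
    bs = genome.bin_size
    for s, state_name in enumerate(alphabet):
        df = pd.read_csv(
            paths[state_name], sep="\t", header=None,
            names=["chrom", "start", "end", "value"],
        )
        for chrom, grp in df.groupby("chrom", sort=False):
            off = genome.chrom_offsets[genome.chrom_index(str(chrom))]
            b0 = grp["start"].to_numpy() // bs
            b1 = np.ceil(grp["end"].to_numpy() / bs).astype(np.int64)
            counts = b1 - b0
            idx = off + np.repeat(b0, counts) + _concat_aranges(counts)
            probs[idx, s] = np.repeat(grp["value"].to_numpy(), counts)
    return SoftAnnotation(
        sample_id=sample_id, probs=probs, genome=genome, alphabet=alphabet
    )


# ---------------------------------------------------------------------------
# GTF gene annotation


_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def read_gene_annotation(path: str | Path) -> list[GeneRecord]:
    """Read gene records (id, location, biotype) from a GTF file.

    Only ``gene`` features are kept.  The biotype attribute may be spelled
    ``gene_type`` (GENCODE) or ``gene_biotype`` (Ensembl).  Coordinates are
    converted from GTF 1-based inclusive to 0-based half-open.
    """
    records: list[GeneRecord] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "gene":
                continue
            attrs = dict(_GTF_ATTR.findall(fields[8]))
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                raise ValueError(f"GTF gene record without gene_id: {line!r}")
            biotype = attrs.get("gene_type", attrs.get("gene_biotype", ""))
            records.append(
                GeneRecord(
                    gene_id=gene_id,
                    chrom=fields[0],
                    start=int(fields[3]) - 1,
                    end=int(fields[4]),
                    strand=fields[6],
                    biotype=biotype,
                )
            )
    return records
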