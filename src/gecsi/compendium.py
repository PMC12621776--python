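"""Reference compendium container: matched expression + state annotations.

A reference compendium is the training resource: a set of samples that each
have both a gene-expression profile and a chromatin-state segmentation.  On
disk a compendium is a directory::

    genome.yaml            # chromosomes, lengths, bin size, state alphabet
    expression.tsv         # genes x samples TPM (or transformed) table
    segmentations/<id>.bed # one dense BED4 per sample

"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .genome_io import (
    BinnedGenome,
    ExpressionTable,
    StateAnnotation,
    read_expression,
    read_segmentation,
    write_expression,
    write_segmentation,
)
from .neighbors import spearman_matrix
from .states import DEFAULT_STATE_ALPHABET


@dataclass
class ReferenceCompendium:
    """Matched expression table and per-sample state annotations."""

    expression: ExpressionTable
    annotations: dict[str, StateAnnotation]
    genome: BinnedGenome
    alphabet: tuple[str, ...] = DEFAULT_STATE_ALPHABET
    _corr: pd.DataFrame | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        missing = set(self.annotations) - set(self.expression.sample_ids)
        if missing:
            raise ValueError(f"annotated samples without expression: {sorted(missing)}")
        for sid, ann in self.annotations.items():
            if ann.genome.n_bins != self.genome.n_bins:
                raise ValueError(f"annotation {sid} on a different genome")

    @property
    def sample_ids(self) -> list[str]:
        """Samples with both expression and an annotation, in expression
        column order (the order that governs neighbor tie-breaking)."""
        return [s for s in self.expression.sample_ids if s in self.annotations]

    @property
    def n_states(self) -> int:
        return len(self.alphabet)

    def correlations(self) -> pd.DataFrame:
        """Cached samples x samples Spearman matrix over annotated samples."""
        if self._corr is None:
            sub = ExpressionTable(
                data=self.expression.data[self.sample_ids],
                stage=self.expression.stage,
            )
            self._corr = spearman_matrix(sub)
        return self._corr

    def subset(self, sample_ids: list[str]) -> "ReferenceCompendium":
        """Restrict to the given samples (e.g. a cross-validation fold's
        training set), preserving expression column order."""
        keep = [s for s in self.expression.sample_ids if s in set(sample_ids)]
        return ReferenceCompendium(
            expression=ExpressionTable(
                data=self.expression.data[keep], stage=self.expression.stage
            ),
            annotations={s: self.annotations[s] for s in keep if s in self.annotations},
            genome=self.genome,
            alphabet=self.alphabet,
        )


def save_compendium(comp: ReferenceCompendium, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    (out_dir / "segmentations").mkdir(parents=True, exist_ok=True)
    with open(out_dir / "genome.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "chrom_names": list(comp.genome.chrom_names),
                "chrom_lengths": list(comp.genome.chrom_lengths),
                "bin_size": comp.genome.bin_size,
                "alphabet": list(comp.alphabet),
                "expression_stage": comp.expression.stage,
            },
            fh,
        )
    write_expression(comp.expression, out_dir / "expression.tsv")
    for sid, ann in comp.annotations.items():
        write_segmentation(ann, out_dir / "segmentations" / f"{sid}.bed")


def load_compendium(in_dir: str | Path) -> ReferenceCompendium:
    in_dir = Path(in_dir)
    with open(in_dir / "genome.yaml") as fh:
        meta = yaml.safe_load(fh)
    genome = BinnedGenome(
        chrom_names=tuple(meta["chrom_names"]),
        chrom_lengths=tuple(meta["chrom_lengths"]),
        bin_size=int(meta["bin_size"]),
    )
    alphabet = tuple(meta["alphabet"])
    stage = meta.get("expression_stage", "raw_tpm")
    if stage == "raw_tpm":
        expr = read_expression(in_dir / "expression.tsv")
    else:  # transformed stages may hold negatives; bypass the raw-TPM check
        df = pd.read_csv(in_dir / "expression.tsv", sep="\t", index_col=0)
        df.index = df.index.astype(str)
        expr = ExpressionTable(data=df.astype(float), stage=stage)
    annotations = {}
    for bed in sorted((in_dir / "segmentations").glob("*.bed")):
        ann = read_segmentation(bed, genome, alphabet, sample_id=bed.stem)
        annotations[bed.stem] = ann
    return ReferenceCompendium(
        expression=expr, annotations=annotations, genome=genome, alphabet=alphabet
    )
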