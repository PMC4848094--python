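"""Positional footprint counting.

Ribosome-footprint 5' ends sit ~12 nt upstream of the start codon and their
3' ends ~18 nt upstream of the stop codon, so the legal counting window for a
gene runs from ``orf_start - 12`` to ``orf_end - 18``. To avoid 5'-end
variability the first 30 codons are additionally excluded, which shifts the
window's 5' boundary to ``orf_start - 12 + 90``. A read is counted iff it
maps uniquely and lies entirely inside the window (whole-read containment);
everything else lands in a per-reason discard tally.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import AnnotationSet, TranscriptAnnotation
from .errors import DataError

__all__ = [
    "Offsets",
    "DEFAULT_OFFSETS",
    "ReadAlignment",
    "Library",
    "CountMatrix",
    "counting_window",
    "count_reads",
    "pool_filter_genes",
    "read_alignments_tsv",
    "write_alignments_tsv",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Offsets:
    """Positional counting rule parameters (nt / codons).

    start_off
        Footprint 5' ends start this many nt upstream of the AUG.
    stop_off
        Footprint 3' ends stop this many nt upstream of the stop codon.
    excl_codons
        Number of initial codons excluded from counting.
    """

    start_off: int = 12
    stop_off: int = 18
    excl_codons: int = 30


DEFAULT_OFFSETS = Offsets()


@dataclass(frozen=True)
class ReadAlignment:
    """A read aligned in transcript coordinates (0-based half-open)."""

    gene_id: str
    start: int
    end: int
    unique: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise DataError(
                f"invalid alignment [{self.start}, {self.end}) on {self.gene_id}"
            )


@dataclass(frozen=True)
class Library:
    """Library descriptor; its string id is ``assay:condition:replicate``."""

    assay: str  # "FP" (footprint) or "total" (total RNA)
    condition: str
    replicate: str

    @property
    def id(self) -> str:
        return f"{self.assay}:{self.condition}:{self.replicate}"

    @classmethod
    def parse(cls, library_id: str) -> "Library":
        parts = library_id.split(":")
        if len(parts) != 3:
            raise DataError(
                f"library id {library_id!r} is not of the form assay:condition:replicate"
            )
        return cls(*parts)


class CountMatrix:
    """Genes x libraries integer read counts.

    Wraps a DataFrame whose index is gene_id and whose columns are library
    ids of the form ``assay:condition:replicate``.
    """

    def __init__(self, counts: pd.DataFrame):
        if counts.columns.duplicated().any() or counts.index.duplicated().any():
            raise DataError("CountMatrix: duplicate gene or library ids")
        arr = counts.to_numpy()
        if arr.size and (np.any(arr < 0) or not np.allclose(arr, np.round(arr))):
            raise DataError("CountMatrix: counts must be non-negative integers")
        self.counts = counts.astype(np.int64)
        # validates column format eagerly
        self.libraries: list[Library] = [Library.parse(c) for c in counts.columns]

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CountMatrix) and self.counts.equals(other.counts)

    def select(
        self, assay: Optional[str] = None, condition: Optional[str] = None
    ) -> "CountMatrix":
        """Sub-matrix restricted to libraries matching the given descriptors."""
        cols = [
            lib.id
            for lib in self.libraries
            if (assay is None or lib.assay == assay)
            and (condition is None or lib.condition == condition)
        ]
        return CountMatrix(self.counts[cols])

    def pooled(self) -> pd.Series:
        """Per-gene count summed over all libraries."""
        return self.counts.sum(axis=1)

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t")
        if "gene_id" not in df.columns:
            raise DataError(f"{path}: counts TSV must have a gene_id column")
        try:
            return cls(df.set_index("gene_id"))
        except (ValueError, TypeError) as exc:
            raise DataError(f"{path}: {exc}") from None

    @classmethod
    def concat(cls, matrices: Sequence["CountMatrix"]) -> "CountMatrix":
        """Column-wise concatenation over a shared gene universe."""
        base = matrices[0].counts.index
        for m in matrices[1:]:
            if not m.counts.index.equals(base):
                raise DataError("CountMatrix.concat: inconsistent gene universes")
        return cls(pd.concat([m.counts for m in matrices], axis=1))


def counting_window(
    annotation: TranscriptAnnotation, offsets: Offsets = DEFAULT_OFFSETS
) -> Optional[tuple[int, int]]:
    """Legal counting interval for a gene, or None if the gene is uncountable.

    Returns ``[orf_start - start_off + 3*excl_codons, orf_end - stop_off)``
    clipped to the transcript; an empty or negative interval makes the gene
    uncountable.
    """
    lo = annotation.orf_start - offsets.start_off + 3 * offsets.excl_codons
    hi = annotation.orf_end - offsets.stop_off
    lo = max(lo, 0)
    hi = min(hi, annotation.transcript_length)
    if hi <= lo:
        return None
    return lo, hi


def count_reads(
    alignments: Iterable[ReadAlignment],
    annotations: AnnotationSet,
    offsets: Offsets = DEFAULT_OFFSETS,
) -> tuple[pd.Series, Counter]:
    """Count alignments into one library's per-gene counts.

    A read increments its gene iff it is unique and wholly contained in the
    gene's counting window. Returns ``(counts, discards)`` where counts is
    indexed by every annotated gene (zeros included) and discards tallies
    rejected reads by reason: ``non_unique``, ``outside_window``,
    ``uncountable_gene``, ``unknown_gene``.
    """
    windows = {a.gene_id: counting_window(a, offsets) for a in annotations}
    counts = dict.fromkeys(annotations.gene_ids, 0)
    discards: Counter = Counter()
    for read in alignments:
        if read.gene_id not in counts:
            discards["unknown_gene"] += 1
            continue
        win = windows[read.gene_id]
        if win is None:
            discards["uncountable_gene"] += 1
            continue
        if not read.unique:
            discards["non_unique"] += 1
            continue
        if read.start >= win[0] and read.end <= win[1]:
            counts[read.gene_id] += 1
        else:
            discards["outside_window"] += 1
    return pd.Series(counts, name="count", dtype=np.int64), discards


def pool_filter_genes(
    matrices: Sequence[CountMatrix] | CountMatrix, min_pooled: int = 128
) -> pd.Index:
    """Genes whose count pooled over every listed library reaches ``min_pooled``.

    The cutoff is inclusive: a gene pooling exactly ``min_pooled`` reads is
    retained; one read fewer excludes it.
    """
    if isinstance(matrices, CountMatrix):
        matrices = [matrices]
    pooled = CountMatrix.concat(list(matrices)).pooled()
    return pooled.index[pooled >= min_pooled]


def write_alignments_tsv(path: str | Path, alignments: Iterable[ReadAlignment]) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tstart\tend\tunique\n")
        for a in alignments:
            fh.write(f"{a.gene_id}\t{a.start}\t{a.end}\t{int(a.unique)}\n")


def read_alignments_tsv(path: str | Path) -> Iterator[ReadAlignment]:
    """Stream alignments from TSV; malformed records are hard errors with line numbers."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["gene_id", "start", "end", "unique"]:
            raise DataError(f"{path}: unexpected alignment header {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise DataError(f"{path}:{lineno}: expected 4 fields, got {len(fields)}")
            try:
                yield ReadAlignment(
                    fields[0], int(fields[1]), int(fields[2]), bool(int(fields[3]))
                )
            except (ValueError, DataError) as exc:
                raise DataError(f"{path}:{lineno}: {exc}") from None
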