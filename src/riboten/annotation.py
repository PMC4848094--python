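"""Transcript models with ORF boundaries.

Coordinates are 0-based half-open in transcript space: ``orf_start`` is the
first nt of the AUG, ``orf_end`` the first nt after the stop codon. Genome
coordinates and strand never appear here — alignment to the transcriptome
happens upstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from .errors import DataError

__all__ = ["TranscriptAnnotation", "AnnotationSet"]


@dataclass(frozen=True)
class TranscriptAnnotation:
    """One gene's transcript model.

    Parameters
    ----------
    gene_id : str
        Unique gene identifier.
    transcript_length : int
        Total transcript length in nt (5' UTR + ORF + 3' UTR).
    orf_start, orf_end : int
        ORF boundaries, 0-based half-open.
    """

    gene_id: str
    transcript_length: int
    orf_start: int
    orf_end: int

    def __post_init__(self) -> None:
        if not (0 <= self.orf_start < self.orf_end <= self.transcript_length):
            raise DataError(
                f"{self.gene_id}: invalid ORF [{self.orf_start}, {self.orf_end}) "
                f"on transcript of length {self.transcript_length}"
            )

    @property
    def orf_length(self) -> int:
        """ORF length in nt (start codon through stop codon)."""
        return self.orf_end - self.orf_start


class AnnotationSet:
    """Ordered collection of :class:`TranscriptAnnotation`, unique by gene_id."""

    def __init__(self, records: Iterable[TranscriptAnnotation]):
        self._by_id: dict[str, TranscriptAnnotation] = {}
        for rec in records:
            if rec.gene_id in self._by_id:
                raise DataError(f"duplicate gene_id {rec.gene_id!r} in annotation")
            self._by_id[rec.gene_id] = rec

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self) -> Iterator[TranscriptAnnotation]:
        return iter(self._by_id.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __getitem__(self, gene_id: str) -> TranscriptAnnotation:
        try:
            return self._by_id[gene_id]
        except KeyError:
            raise KeyError(f"gene {gene_id!r} not in annotation") from None

    @property
    def gene_ids(self) -> list[str]:
        return list(self._by_id)

    def orf_lengths(self) -> pd.Series:
        """Per-gene ORF length (nt), indexed by gene_id."""
        return pd.Series(
            {g: a.orf_length for g, a in self._by_id.items()}, name="orf_length"
        )

    def transcript_lengths(self) -> pd.Series:
        return pd.Series(
            {g: a.transcript_length for g, a in self._by_id.items()},
            name="transcript_length",
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": list(self._by_id),
                "transcript_length": [a.transcript_length for a in self],
                "orf_start": [a.orf_start for a in self],
                "orf_end": [a.orf_end for a in self],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AnnotationSet":
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
        required = {"gene_id", "transcript_length", "orf_start", "orf_end"}
        missing = required - set(df.columns)
        if missing:
            raise DataError(f"annotation {path}: missing columns {sorted(missing)}")
        return cls(
            TranscriptAnnotation(
                row.gene_id,
                int(row.transcript_length),
                int(row.orf_start),
                int(row.orf_end),
            )
            for row in df.itertuples(index=False)
        )
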