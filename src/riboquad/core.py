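"""Shared coordinate frame and in-memory containers.

All positions are 0-based, half-open, in transcript coordinates
(5'-UTR | CDS | 3'-UTR laid end to end).  A ribosome footprint is
represented by its P-site nucleotide: the first nucleotide of the codon
held in the ribosomal P site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

RNA_ALPHABET = frozenset("ACGU")

#: Schema of a P-site track: one row per (transcript, replicate,
#: position, read length) cell with a non-negative count.
PSITE_COLUMNS = ["transcript_id", "replicate", "position", "read_length", "count"]

#: Schema of a per-nucleotide coverage profile (RPF or RNA).
COVERAGE_COLUMNS = ["transcript_id", "position", "count"]


def validate_rna(sequence: str) -> None:
    """Raise ``ValueError`` listing offending positions for non-ACGU characters."""
    bad = [i for i, c in enumerate(sequence) if c not in RNA_ALPHABET]
    if bad:
        shown = ", ".join(str(i) for i in bad[:10])
        more = "" if len(bad) <= 10 else f" (+{len(bad) - 10} more)"
        raise ValueError(f"non-ACGU characters at positions {shown}{more}")


@dataclass(frozen=True)
class TranscriptAnnotation:
    """Per-transcript region lengths, the coordinate frame for everything else.

    Parameters
    ----------
    transcript_id, gene_id
        Identifiers; several transcripts may share a gene (isoforms).
    utr5_len, cds_len, utr3_len
        Region lengths in nucleotides.  ``cds_len`` must be divisible by 3
        when a sequence is attached.
    sequence
        Optional RNA sequence (A/C/G/U) whose length must equal the sum of
        the region lengths.
    """

    transcript_id: str
    gene_id: str
    utr5_len: int
    cds_len: int
    utr3_len: int
    sequence: str | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if min(self.utr5_len, self.cds_len, self.utr3_len) < 0:
            raise ValueError(f"{self.transcript_id}: negative region length")
        if self.sequence is not None:
            validate_rna(self.sequence)
            if len(self.sequence) != self.length:
                raise ValueError(
                    f"{self.transcript_id}: sequence length {len(self.sequence)} "
                    f"!= sum of region lengths {self.length}"
                )
            if self.cds_len % 3 != 0:
                raise ValueError(f"{self.transcript_id}: cds_len not divisible by 3")

    @property
    def length(self) -> int:
        return self.utr5_len + self.cds_len + self.utr3_len

    @property
    def cds_start(self) -> int:
        return self.utr5_len

    @property
    def cds_end(self) -> int:
        return self.utr5_len + self.cds_len

    @property
    def utr5_sequence(self) -> str:
        if self.sequence is None:
            raise ValueError(f"{self.transcript_id}: no sequence attached")
        return self.sequence[: self.utr5_len]

    def region_of(self, position: int) -> str:
        """Region ('utr5' | 'cds' | 'utr3') holding a transcript position."""
        if not 0 <= position < self.length:
            raise IndexError(f"position {position} outside {self.transcript_id}")
        if position < self.cds_start:
            return "utr5"
        if position < self.cds_end:
            return "cds"
        return "utr3"


def annotation_frame(annotations: list[TranscriptAnnotation]) -> pd.DataFrame:
    """Tabular view (one row per transcript) of a list of annotations."""
    return pd.DataFrame(
        {
            "transcript_id": [a.transcript_id for a in annotations],
            "gene_id": [a.gene_id for a in annotations],
            "utr5_len": [a.utr5_len for a in annotations],
            "cds_len": [a.cds_len for a in annotations],
            "utr3_len": [a.utr3_len for a in annotations],
        }
    )
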