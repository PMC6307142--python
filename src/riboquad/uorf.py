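"""Upstream ORF enumeration and ORFscore translation calling.

A uORF is any occurrence of a start codon (AUG, CUG, UUG, GUG) in an
annotated 5'-UTR that is in frame with a downstream stop codon (UAA, UAG,
UGA) lying entirely within the 5'-UTR.  Whether the uORF is actively
translated is scored from the reading-frame phasing of ribosome footprint
P-sites with the ORFscore statistic:

    ORFscore = log2( sum_i (F_i - Fbar)^2 / Fbar + 1 )

negated when frame 1 does not dominate (F1 < F2 or F1 < F3), where F_i is
the P-site count in frame i over the uORF interior and Fbar their mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import TranscriptAnnotation, validate_rna

START_CODONS = ("AUG", "CUG", "UUG", "GUG")
STOP_CODONS = ("UAA", "UAG", "UGA")

#: default read lengths pooled for frame counting (the best-phased sizes)
ORFSCORE_READ_LENGTHS = (28, 29)


@dataclass
class UORFRecord:
    """One candidate upstream ORF.

    ``start`` and ``stop`` are offsets within the 5'-UTR: ``start`` points
    at the first nucleotide of the start codon and ``stop`` at the first
    nucleotide of the stop codon, so ``stop - start`` is divisible by 3 and
    the uORF spans [start, stop + 3).
    """

    transcript_id: str
    start: int
    stop: int
    start_codon: str
    length: int = field(init=False)
    frame_counts: tuple[int, int, int] | None = None
    coverage_per_kb: float = float("nan")
    orfscore: float = float("nan")
    klass: str = "unscored"

    def __post_init__(self) -> None:
        if (self.stop - self.start) % 3 != 0:
            raise ValueError("stop - start must be divisible by 3")
        if self.start_codon not in START_CODONS:
            raise ValueError(f"invalid start codon {self.start_codon}")
        self.length = self.stop - self.start + 3

    @property
    def n_coding_codons(self) -> int:
        return (self.stop - self.start) // 3

    @property
    def interior(self) -> tuple[int, int]:
        """Scored interval [start+3, stop-3): coding codons minus the
        first and last."""
        return self.start + 3, self.stop - 3


def find_uorfs(utr5_sequence: str, transcript_id: str = "") -> list[UORFRecord]:
    """Enumerate candidate uORFs in a 5'-UTR sequence.

    Every start-codon occurrence is paired with the *first* in-frame
    downstream stop codon whose last base still lies within the 5'-UTR;
    one record per start (nested/overlapping uORFs are all reported, and
    several starts may share a stop).
    """
    validate_rna(utr5_sequence)
    n = len(utr5_sequence)
    records = []
    for i in range(n - 2):
        codon = utr5_sequence[i : i + 3]
        if codon not in START_CODONS:
            continue
        for j in range(i + 3, n - 2, 3):
            if utr5_sequence[j : j + 3] in STOP_CODONS:
                records.append(UORFRecord(transcript_id, i, j, codon))
                break
    return records


def frame_counts(
    uorf: UORFRecord,
    psites: pd.DataFrame,
    read_lengths=ORFSCORE_READ_LENGTHS,
) -> tuple[int, int, int]:
    """P-site counts per reading frame over the uORF interior.

    Only reads of the stated lengths are counted, replicates are pooled,
    and the first and last coding codons are excluded.  Positions are
    transcript coordinates; the 5'-UTR starts at transcript position 0, so
    uORF offsets are used directly.
    """
    lo, hi = uorf.interior
    if hi <= lo:
        raise ValueError("uORF shorter than 3 codons has no scorable interior")
    sel = psites[
        (psites["position"] >= lo)
        & (psites["position"] < hi)
        & (psites["read_length"].isin(read_lengths))
    ]
    if uorf.transcript_id and "transcript_id" in sel.columns:
        sel = sel[sel["transcript_id"] == uorf.transcript_id]
    frames = ((sel["position"] - uorf.start) % 3).to_numpy()
    counts = sel["count"].to_numpy()
    out = [0, 0, 0]
    for f, c in zip(frames, counts):
        out[f] += int(c)
    return tuple(out)


def orfscore(F) -> float:
    """ORFscore of a frame-count 3-vector (see module docstring)."""
    f1, f2, f3 = (float(x) for x in F)
    if min(f1, f2, f3) < 0:
        raise ValueError("frame counts must be non-negative")
    total = f1 + f2 + f3
    if total == 0:
        raise ValueError("ORFscore undefined for all-zero frame counts")
    fbar = total / 3.0
    chi2 = sum((fi - fbar) ** 2 / fbar for fi in (f1, f2, f3))
    score = math.log2(chi2 + 1.0)
    if f1 < f2 or f1 < f3:
        score = -score
    return score


def score_uorfs(
    records: list[UORFRecord],
    psites: pd.DataFrame,
    read_lengths=ORFSCORE_READ_LENGTHS,
) -> list[UORFRecord]:
    """Attach frame counts, coverage and ORFscore to candidate uORFs.

    A record is marked ``filtered`` (and left unscored) when its interior
    is empty (< 3 coding codons), when any replicate contributes no reads
    within the uORF, or when no interior reads remain after length
    selection.
    """
    replicates = (
        sorted(psites["replicate"].unique()) if "replicate" in psites.columns else []
    )
    for rec in records:
        track = psites
        if rec.transcript_id and "transcript_id" in track.columns:
            track = track[track["transcript_id"] == rec.transcript_id]
        if rec.n_coding_codons < 3:
            rec.klass = "filtered"
            continue
        # replicate-zero exclusion, applied before pooling
        if replicates:
            span = track[
                (track["position"] >= rec.start)
                & (track["position"] < rec.stop + 3)
                & (track["count"] > 0)
            ]
            present = set(span["replicate"].unique())
            if any(r not in present for r in replicates):
                rec.klass = "filtered"
                continue
        F = frame_counts(rec, track, read_lengths=read_lengths)
        rec.frame_counts = F
        lo, hi = rec.interior
        rec.coverage_per_kb = sum(F) * 1000.0 / (hi - lo)
        if sum(F) > 0:
            rec.orfscore = orfscore(F)
    return records


def classify_uorfs(
    records: list[UORFRecord],
    min_coverage_per_kb: float = 350.0,
    threshold: float = 6.0,
) -> list[UORFRecord]:
    """Assign translation classes from ORFscore and coverage.

    filtered  : unscorable, replicate-missing, or coverage below the
                reads-per-kilobase floor
    high      : ORFscore >= threshold (confidently translated)
    low       : 0 <= ORFscore < threshold
    negative  : ORFscore < 0 (phasing inconsistent with the uORF frame)
    """
    for rec in records:
        if rec.klass == "filtered":
            continue
        if (
            not np.isfinite(rec.orfscore)
            or rec.coverage_per_kb < min_coverage_per_kb
        ):
            rec.klass = "filtered"
        elif rec.orfscore >= threshold:
            rec.klass = "high"
        elif rec.orfscore >= 0:
            rec.klass = "low"
        else:
            rec.klass = "negative"
    return records


def uorf_table(records: list[UORFRecord]) -> pd.DataFrame:
    """Tabular view of scored uORF records (one row per uORF)."""
    rows = []
    for r in records:
        F = r.frame_counts or (np.nan, np.nan, np.nan)
        rows.append(
            {
                "transcript_id": r.transcript_id,
                "start": r.start,
                "stop": r.stop,
                "start_codon": r.start_codon,
                "length": r.length,
                "f1": F[0],
                "f2": F[1],
                "f3": F[2],
                "coverage_per_kb": r.coverage_per_kb,
                "orfscore": r.orfscore,
                "klass": r.klass,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "transcript_id", "start", "stop", "start_codon", "length",
            "f1", "f2", "f3", "coverage_per_kb", "orfscore", "klass",
        ],
    )


def call_transcriptome_uorfs(
    annotations: list[TranscriptAnnotation],
    psites: pd.DataFrame,
    read_lengths=ORFSCORE_READ_LENGTHS,
    min_coverage_per_kb: float = 350.0,
    threshold: float = 6.0,
) -> pd.DataFrame:
    """Find, score and classify uORFs for every sequence-backed transcript."""
    records: list[UORFRecord] = []
    for ann in annotations:
        if ann.sequence is None or ann.utr5_len == 0:
            continue
        found = find_uorfs(ann.utr5_sequence, ann.transcript_id)
        track = psites[psites["transcript_id"] == ann.transcript_id]
        score_uorfs(found, track, read_lengths=read_lengths)
        classify_uorfs(found, min_coverage_per_kb, threshold)
        records.extend(found)
    return uorf_table(records)
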