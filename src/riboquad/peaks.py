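"""Positional analyses around binding-site peak centers, motif-density
enrichment between sequence sets, and polysome-fraction peptide tables.

Peaks arrive from an external caller as intervals on transcript
coordinates; the peak *center* is the midpoint of the interval, rounded
down.  Around each center, a per-offset profile of a positional scorer
(quadruplex-motif starts, or windowed G-richness) is averaged across
peaks, mirroring crosslinking-site metaplots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .structure import MOTIF_PATTERNS, g_runs, scan_motifs


@dataclass(frozen=True)
class PeakRecord:
    transcript_id: str
    start: int
    end: int  # half-open
    region: str = "na"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("peak width must be positive")

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    @property
    def width(self) -> int:
        return self.end - self.start


def motif_start_track(sequence: str, pattern_id: str = "G3N7") -> np.ndarray:
    """Per-position indicator of motif starts (counts overlapping parses
    once per distinct start)."""
    track = np.zeros(len(sequence))
    for start in {m.start for m in scan_motifs(sequence, pattern_id)}:
        track[start] = 1.0
    return track


def g_richness_track(sequence: str, window: int = 25, min_run: int = 2) -> np.ndarray:
    """Windowed G-richness: fraction of positions lying inside G-runs of
    length >= ``min_run`` within a centered window (a stand-in for
    guanine-richness scores used around crosslink peaks)."""
    inside = np.zeros(len(sequence))
    for s, e in g_runs(sequence, min_run):
        inside[s:e] = 1.0
    half = window // 2
    out = np.empty(len(sequence))
    for i in range(len(sequence)):
        lo, hi = max(0, i - half), min(len(sequence), i + half + 1)
        out[i] = inside[lo:hi].mean()
    return out


def anchor_profile(
    peaks: list[PeakRecord],
    sequences: dict[str, str],
    scorer: str = "motif",
    flank: int = 100,
    pattern_id: str = "G3N7",
    g_window: int = 25,
) -> pd.DataFrame:
    """Mean positional score around peak centers.

    For each offset in [-flank, +flank] the scorer value is averaged over
    all peaks whose sequence covers that offset (edge peaks are truncated;
    the per-offset support ``n`` is tracked).  Peaks on unknown sequences
    are skipped with a warning.
    """
    offsets = np.arange(-flank, flank + 1)
    acc = np.zeros(len(offsets))
    n = np.zeros(len(offsets), dtype=int)
    track_cache: dict[str, np.ndarray] = {}
    for peak in peaks:
        seq = sequences.get(peak.transcript_id)
        if seq is None or not 0 <= peak.center < len(seq):
            warnings.warn(f"peak on {peak.transcript_id} off-sequence; skipped")
            continue
        if peak.transcript_id not in track_cache:
            track_cache[peak.transcript_id] = (
                motif_start_track(seq, pattern_id)
                if scorer == "motif"
                else g_richness_track(seq, g_window)
            )
        track = track_cache[peak.transcript_id]
        pos = peak.center + offsets
        ok = (pos >= 0) & (pos < len(track))
        acc[ok] += track[pos[ok]]
        n[ok] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n > 0, acc / np.maximum(n, 1), np.nan)
    return pd.DataFrame({"offset": offsets, "mean_score": mean, "n": n})


@dataclass
class EnrichmentResult:
    density_a: float
    density_b: float
    ratio: float  # density_a / density_b; NaN when the motif is absent
    fisher_p: float
    matches_a: int
    matches_b: int
    nt_a: int
    nt_b: int


def motif_density_enrichment(
    set_a: list[str], set_b: list[str], pattern_id: str = "G3N7"
) -> EnrichmentResult:
    """Motif density (occurrences per nucleotide) in two sequence sets with
    a two-sided Fisher exact test on the 2x2 (matches, non-match nt)
    table."""
    if not set_a or not set_b:
        raise ValueError("both sequence sets must be non-empty")
    nt_a = sum(len(s) for s in set_a)
    nt_b = sum(len(s) for s in set_b)
    if nt_a == 0 or nt_b == 0:
        raise ValueError("zero total sequence length")
    matches_a = sum(len(scan_motifs(s, pattern_id)) for s in set_a)
    matches_b = sum(len(scan_motifs(s, pattern_id)) for s in set_b)
    density_a = matches_a / nt_a
    density_b = matches_b / nt_b
    if matches_a == 0 and matches_b == 0:
        warnings.warn("motif absent from both sets; ratio undefined")
        ratio = float("nan")
    else:
        ratio = density_a / density_b if density_b > 0 else float("inf")
    table = [[matches_a, nt_a - matches_a], [matches_b, nt_b - matches_b]]
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return EnrichmentResult(
        density_a, density_b, ratio, p, matches_a, matches_b, nt_a, nt_b
    )


def polysome_enrichment(
    peptide_counts: pd.DataFrame, min_total: int = 10
) -> pd.DataFrame:
    """Relative unique-peptide fractions per protein across gradient
    fractions (e.g. supernatant / monosome / polysome).

    Proteins with fewer than ``min_total`` unique peptides summed over all
    fractions are excluded; retained rows are normalized to sum to 1.
    Expects one row per protein (index or ``protein_id`` column) and one
    column per fraction of non-negative integer counts.
    """
    df = peptide_counts.copy()
    if "protein_id" in df.columns:
        df = df.set_index("protein_id")
    if (df.to_numpy() < 0).any():
        raise ValueError("peptide counts must be non-negative")
    totals = df.sum(axis=1)
    kept = df.loc[totals >= min_total]
    return kept.div(kept.sum(axis=1), axis=0)


def cluster_proteins(fractions: pd.DataFrame, k: int = 3) -> pd.Series:
    """Ward-style hierarchical clustering of relative-fraction rows using
    euclidean distances."""
    if k > len(fractions):
        raise ValueError("k exceeds number of proteins")
    tree = linkage(pdist(fractions.to_numpy(), metric="euclidean"), method="ward")
    return pd.Series(
        fcluster(tree, t=k, criterion="maxclust"), index=fractions.index, name="cluster"
    )
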