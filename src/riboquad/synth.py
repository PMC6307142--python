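"""Synthetic transcriptomes and ribosome-profiling coverage.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage is testable without external sequencing data:

* lognormal (skewed) translation-efficiency distribution;
* 3-nt periodic footprint coverage over translated frames (CDS and any
  active uORF), with read lengths peaked at 28 nt within 24-32;
* planted uORFs obeying the start (AUG/CUG/UUG/GUG) / stop (UAA/UAG/UGA)
  grammar;
* planted quadruplex motifs at periodic offsets downstream of uORF
  starts (default spacing 41 nt);
* 5'-UTR footprint accumulation on quadruplex-bearing transcripts, with
  a compensating CDS reduction (hence higher RPFdist and lower apparent
  TE);
* approximately uniform RNA coverage with multiplicative noise.

All distributional choices are stand-ins chosen for plausibility; they
are not fitted to any dataset (see docs/methods.md).  All randomness
flows from one seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import TranscriptAnnotation
from .structure import _grammar_regex
from .uorf import START_CODONS, STOP_CODONS

NUCLEOTIDES = np.array(["A", "C", "G", "U"])
NON_STOP_CODONS = tuple(
    a + b + c
    for a in "ACGU"
    for b in "ACGU"
    for c in "ACGU"
    if a + b + c not in STOP_CODONS
)

#: planted quadruplex motif: four G3 tracts, single-A loops; contains no U,
#: so inserting it into a uORF body can never create an in-frame stop codon
PLANTED_MOTIF = "GGGAGGGAGGGAGGG"

DEFAULT_READ_LENGTH_PROBS = {
    24: 0.02, 25: 0.03, 26: 0.08, 27: 0.15, 28: 0.35,
    29: 0.20, 30: 0.10, 31: 0.05, 32: 0.02,
}


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator.

    rpf_depth / rna_depth are mean reads per transcript;
    utr_shift_effect multiplies the baseline uORF ribosome load
    (``uorf_base_load``) on quadruplex-bearing transcripts, with a
    compensating reduction of CDS footprints; ``rg4_te_effect``
    multiplies the realized TE of quadruplex-marked transcripts
    (repressed CDS translation).  ``p_site_offset`` records
    the assumed 5'-end-to-P-site offset (12 nt, the community convention
    for 28-nt footprints); emitted tracks are already in P-site
    coordinates, so it is bookkeeping for importing read-level data.
    """

    n_transcripts: int = 100
    seed: int = 0
    utr5_len_range: tuple[int, int] = (180, 280)
    cds_len_range: tuple[int, int] = (300, 600)
    utr3_len_range: tuple[int, int] = (100, 250)
    frac_uorf: float = 0.3
    frac_rg4: float = 0.2
    rg4_period: int = 41
    rg4_jitter: int = 2
    n_rg4_motifs: int = 3
    frame_weights: tuple[float, float, float] = (0.9, 0.05, 0.05)
    rpf_depth: float = 2000.0
    rna_depth: float = 2000.0
    utr_shift_effect: float = 4.0
    uorf_base_load: float = 0.1
    rg4_te_effect: float = 0.5
    te_location: float = 0.0
    te_scale: float = 1.0
    rna_noise_sigma: float = 0.3
    n_replicates: int = 2
    p_site_offset: int = 12
    read_length_probs: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_READ_LENGTH_PROBS)
    )

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("frac_uorf", "frac_rg4", "uorf_base_load"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if abs(sum(self.frame_weights) - 1.0) > 1e-9:
            raise ValueError("frame_weights must sum to 1")
        for name in ("utr5_len_range", "cds_len_range", "utr3_len_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be a positive range")
        if self.rg4_period < 1:
            raise ValueError("rg4_period must be >= 1")
        if self.frac_rg4 > 0:
            if self.rg4_period < len(PLANTED_MOTIF) + 2 * self.rg4_jitter:
                raise ValueError(
                    "configuration error: rg4_period too short for "
                    "non-overlapping planted motifs"
                )
            if self.utr5_len_range[0] < self._uorf_start_max + self._rg4_uorf_len + 3:
                raise ValueError(
                    "configuration error: 5'-UTR range too short to host a "
                    "planted uORF with quadruplex motifs"
                )
        elif self.frac_uorf > 0 and self.utr5_len_range[0] < self._uorf_start_max + 33:
            raise ValueError(
                "configuration error: 5'-UTR range too short to host a planted uORF"
            )

    @property
    def _uorf_start_max(self) -> int:
        return 13

    @property
    def _rg4_uorf_len(self) -> int:
        """uORF length (nt, multiple of 3) hosting all planted motifs."""
        body = (
            self.n_rg4_motifs * self.rg4_period
            + self.rg4_jitter
            + len(PLANTED_MOTIF)
            + 3
        )
        return 3 * ((body + 3 + 2) // 3)  # + stop codon, rounded up


def sample_rg4_offsets(
    n_uorfs: int,
    period: int = 41,
    jitter: int = 2,
    n_motifs: int = 3,
    rng: np.random.Generator | None = None,
) -> list[np.ndarray]:
    """Planted motif offsets downstream of each uORF start.

    Offsets are k*period for k = 1..n_motifs with uniform integer jitter
    of +/- ``jitter`` nt, one array per uORF.  This is the sampler used by
    :func:`generate_transcriptome`.
    """
    if rng is None:
        rng = np.random.default_rng()
    return [
        period * np.arange(1, n_motifs + 1)
        + rng.integers(-jitter, jitter + 1, size=n_motifs)
        for _ in range(n_uorfs)
    ]


def _fix_inframe_stops(seq: list[str], start: int, stop: int) -> None:
    """Remove accidental in-frame stop codons in a uORF body (U -> C).

    Stops begin with U and planted motifs contain no U, so the edited base
    is never inside a motif.
    """
    for c in range(start + 3, stop, 3):
        if "".join(seq[c : c + 3]) in STOP_CODONS:
            seq[c] = "C"


def _scrub_accidental_motifs(
    seq: list[str],
    protected: list[tuple[int, int]],
    rng: np.random.Generator,
    max_attempts: int = 100,
) -> bool:
    """Re-sample windows carrying accidental four-G3-tract motifs.

    Only the violating window is re-sampled (preserving length/GC
    structure elsewhere), skipping positions inside protected spans
    (planted motifs, start/stop codons).  Returns True on success, False
    if a motif persists after ``max_attempts``.
    """
    rx = _grammar_regex(3, 1, 7)
    for _ in range(max_attempts):
        s = "".join(seq)
        dirty = [
            m
            for m in rx.finditer(s)
            if not any(m.start() < e and ps < m.end() for ps, e in protected)
        ]
        if not dirty:
            return True
        for m in dirty:
            for i in range(m.start(), m.end()):
                if not any(ps <= i < e for ps, e in protected):
                    seq[i] = str(rng.choice(NUCLEOTIDES))
    s = "".join(seq)
    return not any(
        not any(m.start() < e and ps < m.end() for ps, e in protected)
        for m in rx.finditer(s)
    )


def generate_transcriptome(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[list[TranscriptAnnotation], pd.DataFrame]:
    """Generate annotated transcript sequences and the planted truth.

    Transcripts flagged ``has_rg4`` always carry the uORF hosting their
    motifs; ``frac_uorf`` applies on top for quadruplex-free transcripts.
    Background sequence is scrubbed of accidental four-G3-tract motifs.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, 0])
    annotations = []
    truth_rows = []
    for idx in range(config.n_transcripts):
        tid = f"TX{idx:05d}"
        gid = f"GENE{idx:05d}"
        utr5 = int(rng.integers(config.utr5_len_range[0], config.utr5_len_range[1] + 1))
        cds = int(rng.integers(config.cds_len_range[0], config.cds_len_range[1] + 1))
        cds -= cds % 3
        utr3 = int(rng.integers(config.utr3_len_range[0], config.utr3_len_range[1] + 1))
        length = utr5 + cds + utr3
        seq = list(rng.choice(NUCLEOTIDES, size=length))

        has_rg4 = rng.random() < config.frac_rg4
        has_uorf = has_rg4 or rng.random() < config.frac_uorf

        # main ORF: AUG ... stop, body free of in-frame stops
        seq[utr5 : utr5 + 3] = "AUG"
        for c in range(utr5 + 3, utr5 + cds - 3, 3):
            seq[c : c + 3] = rng.choice(NON_STOP_CODONS)
        seq[utr5 + cds - 3 : utr5 + cds] = rng.choice(STOP_CODONS)
        protected = [(utr5, utr5 + 3), (utr5 + cds - 3, utr5 + cds)]

        uorf_start = uorf_stop = -1
        offsets: np.ndarray = np.empty(0, dtype=int)
        if has_uorf:
            uorf_start = int(rng.integers(3, config._uorf_start_max + 1))
            if has_rg4:
                uorf_len = config._rg4_uorf_len
            else:
                max_codons = min(30, (utr5 - uorf_start) // 3 - 1)
                uorf_len = 3 * int(rng.integers(10, max(11, max_codons + 1)))
            if uorf_start + uorf_len > utr5:
                raise ValueError(
                    "configuration error: sampled 5'-UTR cannot host the uORF"
                )
            uorf_stop = uorf_start + uorf_len - 3  # stop codon offset
            seq[uorf_start : uorf_start + 3] = rng.choice(START_CODONS)
            for c in range(uorf_start + 3, uorf_stop, 3):
                seq[c : c + 3] = rng.choice(NON_STOP_CODONS)
            seq[uorf_stop : uorf_stop + 3] = rng.choice(STOP_CODONS)
            protected += [(uorf_start, uorf_start + 3), (uorf_stop, uorf_stop + 3)]
            if has_rg4:
                offsets = sample_rg4_offsets(
                    1, config.rg4_period, config.rg4_jitter, config.n_rg4_motifs, rng
                )[0]
                for off in offsets:
                    mstart = uorf_start + int(off)
                    seq[mstart : mstart + len(PLANTED_MOTIF)] = PLANTED_MOTIF
                    protected.append((mstart, mstart + len(PLANTED_MOTIF)))

        scrub_ok = _scrub_accidental_motifs(seq, protected, rng)
        if has_uorf:
            _fix_inframe_stops(seq, uorf_start, uorf_stop)
        _fix_inframe_stops(seq, utr5, utr5 + cds - 3)

        te = float(rng.lognormal(config.te_location, config.te_scale))
        if has_rg4:
            # quadruplex-marked transcripts are inefficiently translated:
            # their realized TE carries a multiplicative repression factor
            te *= config.rg4_te_effect
        if has_uorf:
            load = config.uorf_base_load * (
                config.utr_shift_effect if has_rg4 else 1.0
            )
            load = min(load, 0.8)
        else:
            load = 0.0
        annotations.append(
            TranscriptAnnotation(tid, gid, utr5, cds, utr3, "".join(seq))
        )
        truth_rows.append(
            {
                "transcript_id": tid,
                "has_uorf": has_uorf,
                "uorf_start": uorf_start,
                "uorf_stop": uorf_stop,
                "has_rg4": has_rg4,
                "rg4_offsets": ",".join(str(int(o)) for o in offsets),
                "true_te": te,
                "uorf_load": load,
                "true_rpfdist": load / (1.0 - load),
                "scrub_failed": not scrub_ok,
            }
        )
    return annotations, pd.DataFrame(truth_rows)


def simulate_coverage(
    annotations: list[TranscriptAnnotation],
    truth: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate footprint P-site tracks and RNA coverage.

    Per transcript, total footprint count is Poisson with mean
    rpf_depth * true_te / mean(true_te); a ``uorf_load`` fraction is
    redirected to the uORF.  Within each translated ORF, P-sites fall on a
    uniformly chosen codon with frame drawn from ``frame_weights``.  RNA
    coverage is per-nucleotide Poisson around a lognormal multiplicative
    noise field, approximately uniform along the transcript.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, 1])
    lengths = np.array(list(config.read_length_probs.keys()))
    lprobs = np.array(list(config.read_length_probs.values()))
    lprobs = lprobs / lprobs.sum()
    te_mean = truth["true_te"].mean()
    truth_by_tid = truth.set_index("transcript_id")

    psite_rows = {k: [] for k in ("transcript_id", "replicate", "position", "read_length")}
    rna_rows = {k: [] for k in ("transcript_id", "position", "count")}

    def emit_orf_reads(tid, orf_start, n_codons, n_reads):
        if n_reads == 0 or n_codons == 0:
            return
        codons = rng.integers(0, n_codons, size=n_reads)
        frames = rng.choice(3, size=n_reads, p=np.asarray(config.frame_weights))
        positions = orf_start + 3 * codons + frames
        rls = rng.choice(lengths, size=n_reads, p=lprobs)
        reps = rng.integers(1, config.n_replicates + 1, size=n_reads)
        psite_rows["transcript_id"].extend([tid] * n_reads)
        psite_rows["replicate"].extend(reps.tolist())
        psite_rows["position"].extend(positions.tolist())
        psite_rows["read_length"].extend(rls.tolist())

    for ann in annotations:
        row = truth_by_tid.loc[ann.transcript_id]
        lam = config.rpf_depth * row["true_te"] / te_mean
        n_total = int(rng.poisson(lam))
        load = float(row["uorf_load"])
        n_uorf = int(rng.binomial(n_total, load)) if load > 0 else 0
        emit_orf_reads(
            ann.transcript_id, ann.cds_start, ann.cds_len // 3, n_total - n_uorf
        )
        if n_uorf:
            n_codons = (int(row["uorf_stop"]) - int(row["uorf_start"])) // 3
            emit_orf_reads(ann.transcript_id, int(row["uorf_start"]), n_codons, n_uorf)

        noise = rng.lognormal(0.0, config.rna_noise_sigma, size=ann.length)
        rate = config.rna_depth / ann.length * noise
        counts = rng.poisson(rate)
        nz = np.nonzero(counts)[0]
        rna_rows["transcript_id"].extend([ann.transcript_id] * len(nz))
        rna_rows["position"].extend(nz.tolist())
        rna_rows["count"].extend(counts[nz].tolist())

    psites = (
        pd.DataFrame(psite_rows)
        .groupby(["transcript_id", "replicate", "position", "read_length"])
        .size()
        .rename("count")
        .reset_index()
        .sort_values(["transcript_id", "replicate", "position", "read_length"])
        .reset_index(drop=True)
    )
    rna = pd.DataFrame(rna_rows)
    return psites, rna


@dataclass
class SimResult:
    config: SimConfig
    annotations: list[TranscriptAnnotation]
    truth: pd.DataFrame
    rpf_psites: pd.DataFrame
    rna_coverage: pd.DataFrame


def simulate(config: SimConfig) -> SimResult:
    """Generate a full synthetic dataset from one seeded configuration."""
    annotations, truth = generate_transcriptome(config)
    psites, rna = simulate_coverage(annotations, truth, config)
    return SimResult(config, annotations, truth, psites, rna)


def rna_coverage_vectors(
    rna: pd.DataFrame, annotations: list[TranscriptAnnotation]
) -> dict[str, np.ndarray]:
    """Expand sparse RNA coverage rows into full per-transcript vectors."""
    out = {}
    grouped = dict(iter(rna.groupby("transcript_id"))) if len(rna) else {}
    for ann in annotations:
        vec = np.zeros(ann.length)
        if ann.transcript_id in grouped:
            g = grouped[ann.transcript_id]
            vec[g["position"].to_numpy()] = g["count"].to_numpy()
        out[ann.transcript_id] = vec
    return out
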