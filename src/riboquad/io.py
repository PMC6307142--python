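"""Readers and writers for the plain-text interchange formats.

FASTA (RNA alphabet), annotation/truth/P-site TSVs, transcript-space
bedGraph coverage, BED peaks and peptide-count TSVs.  Sequence I/O goes
through Biopython; tables through pandas.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import TranscriptAnnotation
from .peaks import PeakRecord


def write_fasta(annotations: list[TranscriptAnnotation], path) -> None:
    records = [
        SeqRecord(Seq(a.sequence), id=a.transcript_id, description="")
        for a in annotations
        if a.sequence is not None
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {
        rec.id: str(rec.seq).upper().replace("T", "U")
        for rec in SeqIO.parse(str(path), "fasta")
    }


def write_annotation(annotations: list[TranscriptAnnotation], path) -> None:
    pd.DataFrame(
        {
            "transcript_id": [a.transcript_id for a in annotations],
            "gene_id": [a.gene_id for a in annotations],
            "utr5_len": [a.utr5_len for a in annotations],
            "cds_len": [a.cds_len for a in annotations],
            "utr3_len": [a.utr3_len for a in annotations],
        }
    ).to_csv(path, sep="\t", index=False)


def read_annotation(path, sequences: dict[str, str] | None = None) -> list[TranscriptAnnotation]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        seq = sequences.get(row["transcript_id"]) if sequences else None
        out.append(
            TranscriptAnnotation(
                str(row["transcript_id"]),
                str(row["gene_id"]),
                int(row["utr5_len"]),
                int(row["cds_len"]),
                int(row["utr3_len"]),
                seq,
            )
        )
    return out


def write_psites(psites: pd.DataFrame, path) -> None:
    psites.to_csv(path, sep="\t", index=False)


def read_psites(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bedgraph(coverage: pd.DataFrame, path) -> None:
    """Per-nucleotide counts as transcript-space bedGraph (merging runs of
    equal value)."""
    with open(path, "w") as fh:
        for tid, group in coverage.groupby("transcript_id", sort=True):
            group = group.sort_values("position")
            run_start = run_end = None
            run_val = None
            for pos, val in zip(group["position"], group["count"]):
                if run_val is not None and pos == run_end and val == run_val:
                    run_end = pos + 1
                    continue
                if run_val is not None:
                    fh.write(f"{tid}\t{run_start}\t{run_end}\t{run_val}\n")
                run_start, run_end, run_val = pos, pos + 1, val
            if run_val is not None:
                fh.write(f"{tid}\t{run_start}\t{run_end}\t{run_val}\n")


def read_bedgraph(path) -> pd.DataFrame:
    """bedGraph intervals expanded to per-nucleotide count rows."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["transcript_id", "start", "end", "value"]
    )
    rows = {"transcript_id": [], "position": [], "count": []}
    for _, r in df.iterrows():
        span = np.arange(int(r["start"]), int(r["end"]))
        rows["transcript_id"].extend([r["transcript_id"]] * len(span))
        rows["position"].extend(span.tolist())
        rows["count"].extend([r["value"]] * len(span))
    return pd.DataFrame(rows)


def read_peaks_bed(path) -> list[PeakRecord]:
    df = pd.read_csv(path, sep="\t", header=None)
    return [
        PeakRecord(str(r[0]), int(r[1]), int(r[2]))
        for _, r in df.iterrows()
    ]


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", dtype={"rg4_offsets": str}, keep_default_na=False,
        na_values=[""],
    )


def write_simulation(result, outdir) -> None:
    """Write a :class:`riboquad.synth.SimResult` under an output directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(result.annotations, outdir / "transcripts.fa")
    write_annotation(result.annotations, outdir / "annotation.tsv")
    write_truth(result.truth, outdir / "truth.tsv")
    write_psites(result.rpf_psites, outdir / "rpf_psites.tsv")
    write_bedgraph(result.rna_coverage, outdir / "rna_coverage.bedGraph")
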