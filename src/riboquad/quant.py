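"""Per-transcript translation quantification and meta-transcript profiles.

Definitions (all in transcript coordinates):

* TPM: 1e6 * (c_i / L_i) / sum_j (c_j / L_j), with effective length L.
* TE (translation efficiency): RPF(CDS) / RNA(CDS), both in TPM.
* RPFdist (ribosome distribution): RPF(5'-UTR) / RPF(CDS), both in raw
  counts — a proxy of upstream ribosome loading.

Differential-expression fold changes and P values are consumed from
upstream tools, not re-derived; only Fisher combination of P values and
the group calls derived from them are computed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .core import TranscriptAnnotation

RPF_LENGTH_RANGE = (24, 32)


def compute_tpm(
    counts: Mapping[str, float], effective_lengths: Mapping[str, float]
) -> dict[str, float]:
    """Transcripts-per-million from counts and effective lengths.

    All-zero input yields all-zero TPM (no division error); otherwise the
    values sum to 1e6.
    """
    rates = {}
    for tid, c in counts.items():
        length = effective_lengths[tid]
        if length <= 0:
            raise ValueError(f"{tid}: non-positive effective length")
        if c < 0:
            raise ValueError(f"{tid}: negative count")
        rates[tid] = c / length
    total = sum(rates.values())
    if total == 0:
        return {tid: 0.0 for tid in counts}
    return {tid: 1e6 * r / total for tid, r in rates.items()}


def translation_efficiency(rpf_cds_tpm: float, rna_cds_tpm: float) -> float:
    """TE = RPF(CDS) / RNA(CDS) in TPM; NaN when the transcript has no RNA
    signal (flagged, excluded downstream)."""
    if rpf_cds_tpm < 0 or rna_cds_tpm < 0:
        raise ValueError("TPM inputs must be non-negative")
    if rna_cds_tpm == 0:
        return float("nan")
    return rpf_cds_tpm / rna_cds_tpm


def rpf_distribution(rpf_utr5_counts: float, rpf_cds_counts: float) -> float:
    """RPFdist = RPF(5'-UTR) / RPF(CDS) in raw counts; NaN when the CDS has
    no footprints."""
    if rpf_utr5_counts < 0 or rpf_cds_counts < 0:
        raise ValueError("counts must be non-negative")
    if rpf_cds_counts == 0:
        return float("nan")
    return rpf_utr5_counts / rpf_cds_counts


def filter_rpf_lengths(
    psites: pd.DataFrame, length_range: tuple[int, int] = RPF_LENGTH_RANGE
) -> pd.DataFrame:
    """Retain only footprints within the usable size range (24-32 nt)."""
    lo, hi = length_range
    return psites[(psites["read_length"] >= lo) & (psites["read_length"] <= hi)]


def filter_transcripts(
    tpm: Mapping[str, float],
    gene_map: Mapping[str, str],
    min_tpm: float = 1.0,
    min_isoform_fraction: float = 0.05,
) -> set[str]:
    """Expressed-transcript filter: TPM above 1 and isoform representation
    above 5% of the gene's total TPM (computed from RNA TPM)."""
    gene_total: dict[str, float] = {}
    for tid, v in tpm.items():
        if tid not in gene_map:
            raise KeyError(f"transcript {tid} has no gene assignment")
        gene_total[gene_map[tid]] = gene_total.get(gene_map[tid], 0.0) + v
    kept = set()
    for tid, v in tpm.items():
        if v <= min_tpm:
            continue
        total = gene_total[gene_map[tid]]
        if total > 0 and v / total > min_isoform_fraction:
            kept.add(tid)
    return kept


# ---------------------------------------------------------------------------
# Region counts and the translation table
# ---------------------------------------------------------------------------


def psite_region_counts(
    psites: pd.DataFrame, annotations: list[TranscriptAnnotation]
) -> pd.DataFrame:
    """Footprint counts per region, replicates pooled.

    Each read is assigned to exactly one region by its P-site position
    (reads are never split across regions).
    """
    by_ann = {a.transcript_id: a for a in annotations}
    rows = []
    grouped = dict(iter(psites.groupby("transcript_id"))) if len(psites) else {}
    for tid, ann in by_ann.items():
        utr5 = cds = utr3 = 0
        if tid in grouped:
            g = grouped[tid]
            pos = g["position"].to_numpy()
            cnt = g["count"].to_numpy()
            utr5 = int(cnt[pos < ann.cds_start].sum())
            cds = int(cnt[(pos >= ann.cds_start) & (pos < ann.cds_end)].sum())
            utr3 = int(cnt[pos >= ann.cds_end].sum())
        rows.append(
            {"transcript_id": tid, "rpf_utr5": utr5, "rpf_cds": cds, "rpf_utr3": utr3}
        )
    return pd.DataFrame(rows)


def coverage_region_counts(
    coverage: pd.DataFrame, annotations: list[TranscriptAnnotation]
) -> pd.DataFrame:
    """Summed per-nucleotide coverage per region (RNA signal)."""
    by_ann = {a.transcript_id: a for a in annotations}
    rows = []
    grouped = dict(iter(coverage.groupby("transcript_id"))) if len(coverage) else {}
    for tid, ann in by_ann.items():
        utr5 = cds = utr3 = 0.0
        if tid in grouped:
            g = grouped[tid]
            pos = g["position"].to_numpy()
            cnt = g["count"].to_numpy()
            utr5 = float(cnt[pos < ann.cds_start].sum())
            cds = float(cnt[(pos >= ann.cds_start) & (pos < ann.cds_end)].sum())
            utr3 = float(cnt[pos >= ann.cds_end].sum())
        rows.append(
            {"transcript_id": tid, "rna_utr5": utr5, "rna_cds": cds, "rna_utr3": utr3}
        )
    return pd.DataFrame(rows)


def translation_table(
    annotations: list[TranscriptAnnotation],
    rpf_psites: pd.DataFrame,
    rna_coverage: pd.DataFrame,
    pseudocount: float = 0.0,
    min_tpm: float = 1.0,
    min_isoform_fraction: float = 0.05,
) -> pd.DataFrame:
    """Per-transcript TE / RPFdist table.

    TE uses CDS TPM of footprints over CDS TPM of RNA; RPFdist uses raw
    footprint counts.  Zero-denominator transcripts carry NaN rather than
    a smoothed value unless an explicit ``pseudocount`` is supplied.
    The ``expressed`` flag applies the RNA TPM > 1 and isoform fraction
    > 5% filters.
    """
    rpf_psites = filter_rpf_lengths(rpf_psites)
    rpf = psite_region_counts(rpf_psites, annotations)
    rna = coverage_region_counts(rna_coverage, annotations)
    table = rpf.merge(rna, on="transcript_id")
    cds_len = {a.transcript_id: max(a.cds_len, 1) for a in annotations}
    gene_map = {a.transcript_id: a.gene_id for a in annotations}

    rpf_tpm = compute_tpm(
        dict(zip(table["transcript_id"], table["rpf_cds"])), cds_len
    )
    rna_tpm = compute_tpm(
        dict(zip(table["transcript_id"], table["rna_cds"])), cds_len
    )
    table["rpf_cds_tpm"] = table["transcript_id"].map(rpf_tpm)
    table["rna_cds_tpm"] = table["transcript_id"].map(rna_tpm)
    te = []
    dist = []
    for _, row in table.iterrows():
        te.append(
            translation_efficiency(
                row["rpf_cds_tpm"] + pseudocount, row["rna_cds_tpm"] + pseudocount
            )
        )
        dist.append(
            rpf_distribution(
                row["rpf_utr5"] + pseudocount, row["rpf_cds"] + pseudocount
            )
        )
    table["te"] = te
    table["rpfdist"] = dist
    with np.errstate(divide="ignore", invalid="ignore"):
        table["log2_te"] = np.log2(table["te"])
        table["log2_rpfdist"] = np.log2(table["rpfdist"])
    expressed = filter_transcripts(
        rna_tpm, gene_map, min_tpm=min_tpm, min_isoform_fraction=min_isoform_fraction
    )
    table["expressed"] = table["transcript_id"].isin(expressed)
    return table


# ---------------------------------------------------------------------------
# Meta-transcript profiles
# ---------------------------------------------------------------------------

META_BINS = (15, 90, 75)  # 5'-UTR, CDS, 3'-UTR


@dataclass
class MetaProfile:
    """Binned mean coverage over 5'-UTR / CDS / 3'-UTR (area-normalized)."""

    bins_utr5: np.ndarray
    bins_cds: np.ndarray
    bins_utr3: np.ndarray
    n_transcripts: int

    @property
    def profile(self) -> np.ndarray:
        return np.concatenate([self.bins_utr5, self.bins_cds, self.bins_utr3])


def _bin_means(values: np.ndarray, n_bins: int) -> np.ndarray:
    edges = np.linspace(0, len(values), n_bins + 1).astype(int)
    return np.array([values[edges[k] : edges[k + 1]].mean() for k in range(n_bins)])


def meta_profile(
    coverages: Mapping[str, np.ndarray],
    annotations: list[TranscriptAnnotation],
    bins: tuple[int, int, int] = META_BINS,
    library_size: float | None = None,
    outlier_percentile: float = 99.9,
    area_normalize: bool = True,
) -> MetaProfile:
    """Meta-transcript coverage profile.

    Per-nucleotide coverage vectors (one per transcript, full transcript
    length) are depth-normalized by the library's total estimated counts /
    1e6, sampled region-wise into equal-width bins (means), pooled, purged
    of binned values above the 99.9th percentile, averaged across
    transcripts per bin, and finally normalized to unit area.  Transcripts
    with any region shorter than its bin count are skipped with a warning.
    """
    by_ann = {a.transcript_id: a for a in annotations}
    if library_size is None:
        library_size = float(sum(np.sum(v) for v in coverages.values()))
    scale = library_size / 1e6 if library_size > 0 else 1.0
    binned = []
    for tid, cov in coverages.items():
        ann = by_ann[tid]
        cov = np.asarray(cov, dtype=float)
        if len(cov) != ann.length:
            raise ValueError(f"{tid}: coverage length {len(cov)} != {ann.length}")
        if ann.utr5_len < bins[0] or ann.cds_len < bins[1] or ann.utr3_len < bins[2]:
            warnings.warn(f"{tid}: region shorter than its bin count; skipped")
            continue
        cov = cov / scale
        binned.append(
            np.concatenate(
                [
                    _bin_means(cov[: ann.cds_start], bins[0]),
                    _bin_means(cov[ann.cds_start : ann.cds_end], bins[1]),
                    _bin_means(cov[ann.cds_end :], bins[2]),
                ]
            )
        )
    if not binned:
        raise ValueError("no transcript has all three regions non-empty")
    mat = np.vstack(binned)
    # outlier removal on binned values pooled across transcripts
    cutoff = np.percentile(mat, outlier_percentile)
    masked = np.where(mat > cutoff, np.nan, mat)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        profile = np.nanmean(masked, axis=0)
    profile = np.nan_to_num(profile)
    if area_normalize:
        area = profile.sum()
        if area > 0:
            profile = profile / area
    return MetaProfile(
        profile[: bins[0]],
        profile[bins[0] : bins[0] + bins[1]],
        profile[bins[0] + bins[1] :],
        mat.shape[0],
    )


# ---------------------------------------------------------------------------
# Fisher combination and group calls
# ---------------------------------------------------------------------------


def fisher_combine(p_values: Iterable[float]) -> float:
    """Fisher's method: X = -2 sum ln p_i ~ chi-square with 2k df.

    Zero P values are clamped to the smallest positive float with a
    warning; a single P value is returned unchanged (k = 1 identity).
    """
    ps = [float(p) for p in p_values]
    if not ps:
        raise ValueError("no P values to combine")
    if any(p < 0 or p > 1 for p in ps):
        raise ValueError("P values must lie in (0, 1]")
    clamped = []
    for p in ps:
        if p == 0:
            warnings.warn("P value of 0 clamped to smallest positive float")
            p = np.nextafter(0, 1)
        clamped.append(p)
    x = -2.0 * np.sum(np.log(clamped))
    return float(stats.chi2.sf(x, df=2 * len(clamped)))


GROUPS = ("TEdown_RPFdistUp", "TEup_RPFdistDown", "background", "none")


def call_groups(
    table: pd.DataFrame,
    q_threshold: float = 0.05,
    background_min_q: float = 0.5,
) -> pd.DataFrame:
    """Classify transcripts by joint TE / RPFdist response.

    Requires columns ``fc_te``, ``fc_rpfdist`` (log2 fold changes) and
    ``q_value``.  TEdown_RPFdistUp: fc_te < 0, fc_rpfdist > 0, q <=
    threshold; TEup_RPFdistDown symmetric; background: q at or above the
    configurable non-significance bound; otherwise (or with missing
    values) none.
    """
    out = table.copy()
    groups = []
    for _, row in out.iterrows():
        fc_te, fc_rd, q = row["fc_te"], row["fc_rpfdist"], row["q_value"]
        if any(pd.isna(v) for v in (fc_te, fc_rd, q)):
            groups.append("none")
        elif q <= q_threshold and fc_te < 0 and fc_rd > 0:
            groups.append("TEdown_RPFdistUp")
        elif q <= q_threshold and fc_te > 0 and fc_rd < 0:
            groups.append("TEup_RPFdistDown")
        elif q >= background_min_q:
            groups.append("background")
        else:
            groups.append("none")
    out["group"] = groups
    return out


def combine_condition_pvalues(
    diffexpr: pd.DataFrame, p_columns: Iterable[str]
) -> pd.DataFrame:
    """Fisher-combine per-condition P values into a ``q_value`` column."""
    out = diffexpr.copy()
    out["q_value"] = [
        fisher_combine([row[c] for c in p_columns]) for _, row in out.iterrows()
    ]
    return out
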