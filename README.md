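# riboquad

Ribosome-profiling analysis of RNA G-quadruplexes (rG4) in 5'-UTRs and
their relationship to upstream open reading frame (uORF) translation and
coding-sequence translation efficiency.

Inefficiently translated mRNAs often carry structured 5'-UTRs. When the
structure is a G-quadruplex placed downstream of a uORF start codon, a
scanning pre-initiation complex can pause, ribosomes queue back to the
upstream start, the uORF is translated, and translation of the main ORF
drops. `riboquad` implements the computational side of that analysis for
anyone working with transcript-space ribosome-profiling coverage:

* **Quantification** — per-transcript TPM, translation efficiency
  TE = RPF(CDS)/RNA(CDS) (TPM), upstream ribosome loading
  RPFdist = RPF(5'-UTR)/RPF(CDS) (counts), expressed-transcript filters
  (TPM > 1, isoform fraction > 5%), binned meta-transcript profiles,
  Fisher-combined P values and TE/RPFdist group calls.
* **uORF calling** — enumeration of AUG/CUG/UUG/GUG uORFs in 5'-UTRs and
  the ORFscore frame-phasing statistic

      ORFscore = log2( sum_i (F_i - F̄)² / F̄ + 1 ),   F̄ = (F₁+F₂+F₃)/3,

  negated when frame 1 does not dominate; uORFs with score ≥ 6 at
  ≥ 350 reads/kb are called actively translated.
* **Structure** — four-G-tract motif scanning (G₃₊N₁₋₇ and short-loop
  variants), quadruplex-aware folding energies
  ΔG⁰_rG4 = ΔG⁰_dsRNA − ΔG⁰_dsRNA+rG4, sliding-window (35 nt) energy
  landscapes with smoothed local minima, and Fourier periodograms of
  pooled minima offsets (the analysis that exposes the ~41-nt spacing of
  quadruplexes downstream of translated uORF starts, matching the 38–46
  nt footprint of a scanning ribosome).
* **Modeling** — per-transcript feature tables across seven categories,
  Canberra/Ward transcript clustering, sign-fixed PCA subsetting of
  rG4-marked transcripts, LASSO predictor selection and gradient-boosted
  regression of RPFdist with category-wise variance-explained
  comparison (Kolmogorov–Smirnov on CV resampling distributions).
* **Peaks** — positional motif/G-richness profiles around externally
  called binding-site peak centers, motif-density enrichment with Fisher
  exact tests, and polysome-fraction peptide tables.
* **Synthetic data** — a seeded generator producing transcriptomes,
  P-site tracks and RNA coverage with planted uORFs, periodic quadruplex
  motifs, frame-phased footprints and skewed TE, so every stage is
  testable without external sequencing data.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

```python
from scipy import stats
from riboquad import synth, quant, uorf, structure

cfg = synth.SimConfig(n_transcripts=100, seed=42)
res = synth.simulate(cfg)

table = quant.translation_table(res.annotations, res.rpf_psites, res.rna_coverage)
m = table.merge(res.truth, on="transcript_id")
print("median TE   rg4 %.3f  background %.3f"
      % (m.loc[m.has_rg4, "te"].median(), m.loc[~m.has_uorf, "te"].median()))
print("median RPFdist rg4 %.3f  background %.3f"
      % (m.loc[m.has_rg4, "rpfdist"].median(), m.loc[~m.has_uorf, "rpfdist"].median()))
print("Spearman TE vs truth %.3f" % stats.spearmanr(m.te, m.true_te).statistic)

scored = uorf.call_transcriptome_uorfs(res.annotations, res.rpf_psites)
print(scored["klass"].value_counts().to_dict())

offsets = [int(x) for r in res.truth[res.truth.has_rg4].rg4_offsets
           for x in r.split(",")]
print("dominant period %.1f nt" % structure.periodicity(offsets, 160).dominant_period)
```

prints

```
median TE   rg4 0.195  background 0.648
median RPFdist rg4 0.655  background 0.000
Spearman TE vs truth 0.978
{'filtered': 893, 'high': 77, 'negative': 61, 'low': 34}
dominant period 40.0 nt
```

Quadruplex-marked transcripts show depressed translation efficiency and
elevated upstream ribosome loading; estimated TE tracks the planted
truth; phased planted uORFs score high (e.g. frame counts (92, 3, 3)
give ORFscore 7.35) while candidates without reads or phasing are
filtered or negative; and the pooled quadruplex offsets recover the
planted ~41-nt spacing (40 nt is the nearest period on the 160-nt
frequency grid).

The same workflow is available from a shell:

```sh
riboquad simulate --seed 42 --outdir sim/
riboquad quantify --annot sim/annotation.tsv --rpf sim/rpf_psites.tsv \
                  --rna sim/rna_coverage.bedGraph --outdir quant/
riboquad uorfs --annot sim/annotation.tsv --fasta sim/transcripts.fa \
               --rpf sim/rpf_psites.tsv --out uorfs.tsv
riboquad structure --fasta sim/transcripts.fa --outdir struct/
```

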