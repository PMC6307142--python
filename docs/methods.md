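# Methods

`riboquad` models how RNA G-quadruplexes (rG4) in 5'-UTRs relate to
upstream-ORF translation and reduced coding-sequence translation
efficiency, from ribosome-profiling-style coverage. This note documents
the statistical machinery, the synthetic data it is validated on, the
numerical choices, and the limits of what the tests demonstrate.

## Coordinate conventions

All positions are 0-based, half-open transcript coordinates with the
regions laid out as 5'-UTR | CDS | 3'-UTR. A footprint is represented by
its P-site nucleotide — the first nucleotide of the codon in the
ribosomal P site. When importing read-level data, the conventional
5'-end-to-P-site offset for ~28-nt footprints is 12 nt
(`SimConfig.p_site_offset`); all tracks handled internally are already
in P-site coordinates. Reads are assigned to exactly one region by their
P-site position and never split across regions.

## Quantification

* **TPM**: `1e6 * (c_i/L_i) / sum_j (c_j/L_j)` with the CDS length as the
  effective length. Conserved to 1e6 for any non-empty input.
* **TE** (translation efficiency): RPF(CDS)/RNA(CDS), both in TPM.
* **RPFdist** (upstream ribosome loading): RPF(5'-UTR)/RPF(CDS) in raw
  counts. Both ratios are invariant to library depth.
* Zero denominators yield NaN and a downstream exclusion rather than a
  silent pseudocount; an explicit pseudocount is available but off by
  default.
* Expressed transcripts: RNA TPM > 1 and isoform fraction > 5% of the
  gene total (computed from RNA TPM only).
* Footprints outside 24–32 nt are discarded before any counting.
* **Meta-profiles**: per-library depth normalization (total estimated
  counts / 1e6), region-wise binning into 15 / 90 / 75 equal-width bins
  (means), pooling across transcripts, masking of binned values above the
  pooled 99.9th percentile, per-bin averaging, then area normalization to
  unit sum. Both the depth-normalized and the area-normalized views are
  computed; the area-normalized profile is the default output. Note that
  the percentile mask makes the profile only approximately scale
  invariant; exact scale invariance holds with the mask disabled.
* **Fisher combination**: X = -2 sum ln p_i compared against chi-square
  with 2k df; a single P value passes through unchanged; zeros are
  clamped to the smallest positive float with a warning.
* **Group calls**: TEdown_RPFdistUp requires fc_te < 0, fc_rpfdist > 0
  and combined q <= 0.05 (TEup_RPFdistDown symmetric). "Background" is
  q >= 0.5 by default (configurable); everything else, including rows
  with missing values, is "none". Differential fold changes and
  per-condition P values are consumed from upstream differential tools,
  not re-derived.

## uORF calling and ORFscore

uORFs are every occurrence of AUG/CUG/UUG/GUG in a 5'-UTR paired with the
first in-frame downstream stop (UAA/UAG/UGA) lying entirely within the
UTR. Overlapping and nested uORFs are all reported; multiple starts may
share a stop. The grammar admits zero-codon bodies; any record with fewer
than 3 coding codons has no scorable interior (the first and last coding
codons are excluded) and is always classed `filtered`.

Frame counts pool 28–29-nt reads across replicates over the interior
[start+3, stop-3); a uORF is excluded when any replicate contributes no
reads anywhere within it (checked before pooling). The score is

    ORFscore = log2( sum_{i=1..3} (F_i - Fbar)^2 / Fbar + 1 ),

negated when F1 < F2 or F1 < F3. Coverage is `sum(F) * 1000 /
interior length` (reads/kb; the "10x coverage" phrasing sometimes used
for this filter is an alias for the same reads-per-kilobase rule).
Classes: `filtered` below 350 reads/kb, `high` at score >= 6, `low` in
[0, 6), `negative` below 0.

**Information floor.** Because the chi-square term is bounded by twice
the read total, a score of 6 (chi-square >= 63) is unreachable with fewer
than 32 interior reads no matter how perfect the phasing. A short uORF
can therefore pass the 350 reads/kb filter while being mathematically
unable to reach the threshold. Discrimination analyses in the test suite
use cohorts deep enough (5000 reads/transcript, narrow TE spread) that
passing the coverage filter implies clearing this floor; at lower depth
the coverage filter, not the classifier, limits sensitivity.

## Quadruplex motifs and folding energies

Motif grammars are four G-tracts separated by three loops: `G3N7`
(tracts >= 3 G, loops 1–7 nt; the canonical 5'-UTR rG4 grammar) and the
short-loop variants `G2N1`, `G2N3`, `G2N5`. The scanner reports *every*
substring parseable under the grammar (tracts may exceed the minimum and
matches may start inside longer G-runs); it is verified exactly against
an independent recursive-descent enumerator.

Folding energies come from an internal maximum-stability dynamic
program: canonical pairs (AU/GC/GU) contribute `stack_energy`
(-2 kcal/mol) per stacked pair — a helix of h pairs scores
(h-1)·stack_energy, isolated pairs score nothing — with a minimum
hairpin loop of 3 nt. With quadruplexes enabled, blocks matching the
grammar may additionally be placed with energy

    E(L, l) = a*(L-1) + b*ln(l-2),   a = -18, b = +12 kcal/mol,

for L stacked quartets (minimum tract length, capped at 4) and total
loop length l. These magnitudes are order-of-magnitude stand-ins: no
conclusion in this package depends on their absolute values, only on the
*relaxation contract* — adding the quadruplex option can only stabilize,
so dG_dsRNA+rG4 <= dG_dsRNA <= 0 on every input, with equality whenever
the sequence admits no block under the model grammar. A thermodynamic
engine (e.g. RNAfold) can be plugged in via the `backend` argument; the
internal model is the default so that results are reproducible without
external parameter sets, and the test suite cross-checks it
qualitatively against RNAfold where available.

**Sign convention.** The difference dG0_rG4 = dG0_dsRNA − dG0_dsRNA+rG4
is a non-negative stabilization *gain*. Plots conventionally show the
negated (signed) view in which more negative means a more stable
quadruplex; both views are exposed (`EnergyTriple.dg_g4` vs
`.dg_g4_signed`, and the `view` argument of `landscape`). Cohort z-scores
standardize the length-normalized gain; a zero-variance cohort maps to
z = 0 with a warning.

## Landscapes and periodicity

The landscape scans a 35-nt window one nucleotide at a time, assigning
each window's energy to its *center* position, then smooths with a 10-nt
running mean. Strict local minima of the smoothed track are reported as
offsets relative to an anchor (typically a uORF start codon); plateaus
report their left edge and ties break toward the smaller offset. On the
default signed quadruplex view, a planted motif produces a minimum
within a few nt of the motif center (the plateau-left-edge rule biases
the reported position ~5 nt upstream; this constant offset cancels in
any spacing analysis). Background pairing noise can fragment a single
dip into neighboring minima; pooled periodicity analyses are robust to
this, but single-sequence minima lists should be read with that caveat.

Pooled minima offsets are binned into a per-nucleotide count signal on
[0, max_offset), mean-detrended and transformed with an *unpadded*
discrete Fourier transform; the dominant period is 1/f at maximal power
over f > 0, with ties resolved toward the lowest frequency. Zero-padding
is deliberately not used: with a small number of comb teeth it shifts
the apparent peak by ~1 nt (an exact 40-nt comb reads 41.4 with
padding), whereas the plain DFT returns the constructed period exactly
and recovers planted spacings of 30 / 41 / 50 nt within ±2 nt in 100/100
seeded simulations. An optional 10% cosine taper is available. On a
160-nt signal the frequency grid makes a 41-nt planted spacing read as
40 nt (the nearest grid period).

A scanning ribosome's footprint in nucleotides is
floor(diameter / per-nt spacing); for the human 80S (250–300 Å at
6.5 Å/nt) this is 38–46 nt, bracketing the ~41-nt spacing — consistent
with a queue of ribosomes stacking behind a quadruplex-paused complex.

## Feature modeling

Features span seven categories — abundance (log RNA TPM), lengths (raw
and log), base composition (mono- and GG-dinucleotide fractions, GC),
dsRNA energies, quadruplex energies (raw and per-nt), uORF summaries
(counts by start codon, best ORFscore) and cis-regulatory element counts.
The CERT / PRTE / TOP element patterns shipped as defaults are IUPAC
approximations of published consensi and serve as features only. All
features are z-scored; z-scoring is idempotent and constant features map
to zero.

* **Clustering**: Canberra dissimilarities between (TE, dsRNA, rG4)
  z-score triples are fed to the Ward update formula. Applying a
  Ward-type recurrence to a non-Euclidean dissimilarity is mathematically
  loose (the implied centroids do not exist in the metric); it is used
  here deliberately as a deterministic, widely-used procedure, and
  labels are renumbered by ascending mean quadruplex-energy z-score so
  runs are comparable.
* **PCA subsetting**: principal components of the z-scored features with
  eigenvector signs fixed so the designated quadruplex-energy feature
  loads non-negatively on Dim.1 and the dsRNA feature non-positively on
  Dim.2 — without this the quadrant rule (Dim.1 >= 0, Dim.2 <= 0
  defining the rG4-marked subset) would be convention dependent.
* **Regression**: L1-penalized linear selection (penalty tuned by
  internal 10-fold CV), a collinearity screen dropping one of any pair
  with |r| > 0.85 (keeping the stronger univariate predictor), then a
  gradient-boosted tree regressor tuned by 10-fold CV on a 70% training
  split over a small grid (trees, depth, learning rate, minimum leaf)
  and evaluated on three 10% test splits. The resampling distribution
  (10-fold CV x 10 repeats on the training split) feeds a two-sample
  Kolmogorov–Smirnov comparison between models. All splits and seeds are
  explicit arguments.

With a planted variance decomposition (30% quadruplex, 30% uORF, 40%
noise; n = 800) the category-restricted models recover their shares
within ±0.1, and shuffled targets score at or below 0.05 — a leakage
guard.

## Peak-relative analyses

Externally called peaks enter as BED intervals; the center is the
floored midpoint. Around each center a positional scorer — the
motif-start indicator, or windowed G-richness (fraction of positions
inside G-runs of length >= 2 within a 25-nt window, a configurable
stand-in for published guanine-richness scores whose exact formula is
not public) — is averaged per offset with per-offset support tracked and
edge peaks truncated. The summed indicator profile times support equals
the motif count within the flank. Motif-density enrichment between two
sequence sets uses occurrences per nucleotide and a two-sided Fisher
exact test on the (matches, non-match nt) table. Polysome peptide tables
drop proteins with fewer than 10 unique peptides across fractions and
normalize the rest to relative fractions summing to 1; protein
clustering uses euclidean distances with Ward linkage.

## The synthetic generator

`synth.SimConfig` defines the study conditions; defaults (chosen once
for plausibility, not fitted to any dataset):

| parameter | default | meaning |
|---|---|---|
| n_transcripts | 100 | cohort size |
| utr5/cds/utr3 ranges | 180–280 / 300–600 / 100–250 nt | region lengths |
| frac_uorf / frac_rg4 | 0.3 / 0.2 | planted uORF / rG4-uORF fractions |
| rg4_period, jitter, n motifs | 41 nt, ±2, 3 | motif offsets downstream of uORF start |
| frame_weights | (0.9, 0.05, 0.05) | P-site frame multinomial |
| rpf_depth / rna_depth | 2000 / 2000 | mean reads per transcript |
| uorf_base_load | 0.10 | ribosome fraction diverted to an active uORF |
| utr_shift_effect | 4 | uORF-load multiplier on rG4 transcripts |
| rg4_te_effect | 0.5 | TE repression factor on rG4 transcripts |
| te lognormal | location 0, scale 1 | skewed TE distribution |
| read lengths | peaked at 28 within 24–32 | footprint sizes |

Transcripts flagged rG4 always carry the uORF hosting their motifs
(motif offsets are defined downstream of a uORF start); `frac_uorf`
applies on top for quadruplex-free transcripts. The planted motif
(GGGAGGGAGGGAGGG) contains no U, so inserting it cannot create an
in-frame stop; junction codons that nevertheless gain a stop are
repaired U->C outside motif spans. Background sequence is scrubbed of
accidental four-G3-tract motifs by re-sampling only the violating
window (max 100 attempts, then the transcript is flagged), preserving
length and composition structure elsewhere.

Coverage: per-transcript footprint totals are Poisson with mean
proportional to the realized TE; a `uorf_load` fraction is redirected to
the uORF (raising RPFdist and lowering apparent TE); P-sites fall on a
uniform codon with multinomially drawn frame; RNA coverage is
per-nucleotide Poisson around lognormal multiplicative noise. An active
uORF diverting ~10% of a transcript's ribosomes, a 4-fold increase on
quadruplex-bearing transcripts, and a 2-fold intrinsic TE repression of
quadruplex-marked transcripts reproduce the qualitative contrasts the
analysis is designed to detect at the default depth.

**What the generator does not emulate** — and hence what passing tests
do *not* show about real data: sequencing and alignment error,
multi-mapping, nuclease digestion bias and footprint-length/frame
coupling, isoform mixtures sharing reads, codon-level pause structure
beyond global frame weights, transcript-abundance/TE correlation, and
any thermodynamically realistic folding. Recovery results demonstrate
internal consistency of the pipeline, not accuracy on biological
libraries.

## Reproducibility

All randomness flows from explicit `numpy` generators seeded from
`SimConfig.seed` (sequence generation and coverage draw independent
child streams, so identical seeds give byte-identical FASTA/TSV/bedGraph
outputs). Model fits take explicit seeds controlling splits, CV folds
and boosting. Test problem sizes (60–200 transcripts, 1,000-sequence
scanner/folding sweeps, 100-seed periodogram replicates, n = 800
regression cohorts) were chosen to make the whole suite run in about two
minutes on a single CPU.
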