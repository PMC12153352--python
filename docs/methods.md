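# Methods

## Scope

`photorepair` implements a genome-wide analysis of cyclobutane pyrimidine
dimer (CPD) repair by photolyase and nucleotide excision repair (NER) in
yeast-style genomes: single-nucleotide lesion calling from damage-seq
(CPD-seq) aligned reads, alkaline-gel quantification of bulk repair and
gel-anchored normalization of per-site repair fractions, strand-resolved
repair profiling over genes, nucleosomes and transcription-factor binding
sites (TFBS), and strand-resolved analysis of UV-induced mutations from
passaging experiments.  A synthetic-data module generates complete
experiments with known ground truth so that every stage is testable without
external downloads; it is first-class, tested code, not a fixture.

## Lesion calling

CPD-seq chemistry ligates the sequencing adapter to the free 3′-OH created
immediately upstream of the cleaved lesion, so the lesion occupies the two
bases immediately upstream of a read's 5′ end on the *opposite* strand.
For a plus-strand read with 1-based 5′ end p the candidate lesion covers
plus-coordinates (p−2, p−1) on the minus strand; for a minus-strand read
with 5′ end q it covers (q+1, q+2) on the plus strand.  Candidates whose
dinucleotide is not TT/TC/CT/CC are filtered; reads whose two-base upstream
window leaves the chromosome, or contains an ambiguous base (N), are
dropped and tallied separately (the disposition of such reads is a
convention of this package).

Coordinates are 1-based inclusive internally; BED on disk is 0-based
half-open, converted in one I/O layer.  Each lesion is keyed by the
plus-strand coordinate of its **5′-most base on its own strand** (plus
strand: the left base; minus strand: the right base).  This makes
reverse-complementing the genome the exact coordinate map p → L+1−p with
strands swapped, which the mirror-symmetry tests exploit; keying both
strands by the left base instead would break mirror symmetry at every
region boundary by one base.

Tracks are dense per-chromosome count arrays with every genomic
dipyrimidine present (zero-filled) and non-dipyrimidine positions
structurally zero; the library total N is the count sum.

## Gel quantification and normalization

Under random (Poisson) T4-endonuclease-V cleavage the expected breaks per
nucleotide equal the reciprocal of the number-average fragment length, so

    φ (CPDs/kb) = 1000 · (1/L_T4 − 1/L_mock),

percent repaired R(t) = 100·(1 − φ_t/φ_0) relative to the 0-min lane, and
F_gel(t) = 1 − R(t)/100.  For densitometry lanes the representative length
is the migration distance at the lane's median cumulative intensity mapped
through log-linear interpolation of the ladder (no extrapolation: a median
outside the ladder range is an error).  The median-intensity length is
treated as the number-average length; whether scanned lane profiles are
number- or mass-weighted is an acknowledged approximation of this package.

Sequencing repair fractions are anchored to the gel: with depth-normalized
per-site ratio r_i = (n_i(t)/N_t)/(n_i(0)/N_0), the normalized fraction of
CPDs remaining is f_i = F_gel(t)·r_i.  The genome-wide normalized fraction
equals F_gel(t) identically.  Regions aggregate counts *before* dividing
(robust to zero-count sites); per-site output is undefined (NaN) where
n_i(0) = 0.  Replicate gel measurements are compared by pairwise unpaired
t-tests with Holm–Šidák step-down adjustment (delegated to statsmodels and
cross-checked against the explicit formula in the tests).

## Gene profiles

The transcribed strand (TS) is the template strand — the strand opposite
the annotated mRNA-sense strand; flanks inherit the gene's frame.  Each
coding span (TSS..TES) is split into six equal bins oriented TSS→TES using
rounded cumulative edges (deterministic; remainder bases fall in the last
bin); three fixed 167-bp bins flank each end.  Genes shorter than six bases
are excluded with a log message.  Flank bins that overlap a neighboring
gene are still counted (no masking rule is applied).  Overlapping genes
would each count a position once (gene-centric aggregation); the synthetic
generator never overlaps genes.  Strand asymmetry is per-bin
log₂(f_TS/f_NTS), tested over the six coding bins with a two-sided paired
t-test (all-zero differences give p = 1; a constant nonzero difference is
reported as below machine precision with a degenerate flag).
Transcription cohorts: high > 10 mRNA/h, low < 1 mRNA/h, intermediate
otherwise; missing rates exclude a gene from stratified analyses only.
TSS metaprofiles and the per-gene cluster matrix (rows sorted stably by
descending transcription rate) use the window −500..+640 by default.

## Nucleosome profiles

Dyad-aligned profiles span offsets −90..+90 (core edges ±73; beyond that is
linker), using dyads with positioning score strictly greater than 5.
Offsets are plus-strand coordinates relative to the dyad; `align_strands`
re-indexes the minus strand by offset → −offset so both strands read 5′→3′
(an involution), and `combine_strands` takes the unweighted mean.  The
rotational-setting periodicity is fit by least squares as
value(o) ≈ a + b·cos(2π(o − φ)/P) with period P = 10.3 bp via the
cos/sin linearization; φ is the phase of the fitted maxima, and the fit is
declared unreliable (labels withheld) when |b| < 2·SE(b).  For
fraction-remaining profiles, minima (fast repair) within ±2 bp are labelled
minor-out and maxima minor-in; for accessibility (count-mode, e.g. DNase
cleavage) profiles the assignment reverses.  The phase is always fitted,
never assumed — phase conventions differ between nucleosome maps.  The
3′-side asymmetry index is mean(f, offsets +10..+50) − mean(f, −50..−10) on
the aligned combined profile; positive values mean slower repair on the 3′
side of the nucleosomal DNA.

## TFBS profiles

Sites within 1 kb of a chromosome end are excluded; per-TF midpoint offsets
(a configuration column, default 0) are applied exactly once before the
exclusion.  The core window is ±4 bp around the motif midpoint and the
flank ±100 bp excluding the core; both track strands are pooled and counts
aggregated over all sites of a TF before dividing.  TFs with fewer than 100
core CPDs at either timepoint are excluded.  Per-position site profiles
orient minus-strand motifs by mirroring and mask offsets with fewer than 10
CPDs at either timepoint.  Sites with occupancy strictly below 10 form the
low-occupancy control set.

## Mutation analysis

Substitutions recurring in two or more isolates are treated as ancestral
and removed entirely (a keep-one-representative mode exists behind a flag);
non-SNV records are skipped with a log message, and reference mismatches
against the genome are errors.  All records are standardized once into the
pyrimidine frame (purine references reverse-complemented), giving six
classes × 16 trinucleotide contexts; a channel is flagged as
dipyrimidine-forming when the central pyrimidine has a pyrimidine neighbor.
A mutation in a gene body is a TS mutation when its pyrimidine-frame
reference lies on the template strand (consistent with lesion-on-template
logic).  Transcriptional asymmetry per channel is

    A = (m_TS/k_TS) / (m_NTS/k_NTS),

where k counts the channel's trinucleotide context on each strand across
gene bodies only (the domain of the ratio); channels with fewer than 30
mutations are reported but flagged, and m_NTS = 0 with m_TS > 0 yields an
infinity sentinel.  Class exclusion specs are pyrimidine-frame
(`T>A@NTA` = the four NTA contexts; `@dipy` = dipyrimidine contexts).
Canavanine-resistance frequency is
(colonies_Can·dilution_Can)/(colonies_SC·dilution_SC) with dilution the
fold-dilution of the plated culture.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, not
the library chemistry:

* **Genomes** are i.i.d. bases at a set GC fraction (default 0.40,
  yeast-like).  **Genes** are placed sequentially with jittered intergenic
  gaps (default minimum 400 bp; ~150 bp gives yeast-like genic density of
  roughly 75–85%), rates log-uniform over 0.05–40 mRNA/h so both
  stratification cohorts are populated.  **Dyads** form a jittered regular
  array with ≥165-bp repeat and exponential scores (mean 4) spanning the
  score-5 filter; **TFBS** are placed away from dyads and ≥1.1 kb from
  chromosome ends.
* **Damage** is an independent Poisson count at every dipyrimidine with
  mean dose_scale × propensity(dinucleotide).  Default propensities
  TT:TC:CT:CC = 1:0.35:0.25:0.10 reflect the strong TT skew of CPD
  induction; no published per-dinucleotide values are assumed (they are
  free parameters).  Sites within 60 bp of a chromosome end are left
  undamaged — such lesions could never host a read, and excluding them
  keeps the lesions → reads → calling round trip an exact identity.
* **Repair** is memoryless per lesion: survival to time t with probability
  exp(−k_i t), k_i = k_photolyase(i) + k_NER(i), sampled independently
  (binomial thinning per site).  This is the simplest model consistent with
  fraction-remaining curves and yields closed forms for the tests.  Strain
  labels select pathways: −PR or phr1Δ zero the photolyase rate, rad14Δ
  zeros the NER rate.  Base rates default to the single-pathway regimes:
  photolyase 0.0175/min (≈65% of CPDs removed in 60 min acting alone) and
  NER 0.0029/min (≈16% in 60 min).  These two regimes cannot be combined
  additively to reproduce the ≈92% removal observed when both pathways act
  — real kinetics are not single-exponential — so the WT+PR label
  under-repairs relative to that benchmark; this is a known limitation of
  the exponential model, not a calibration target.
* **Context dependence** multiplies the photolyase rate: ts_occlusion
  (default 0.45) on the template strand in gene bodies (RNA-Pol-II
  occlusion); within nucleosomes a translational dip (deepest at the dyad,
  vanishing at ±73), a rotational cosine (period 10.3 bp, amplitude and
  phase free), and a 3′-side attenuation — all defined on the strand-frame
  offset o′ = +o (plus strand) / −o (minus strand), which encodes the
  nucleosome's pseudo-dyad two-fold symmetry (plus strand at +o is
  structurally equivalent to minus strand at −o) and makes the injected
  rotational phase recoverable from the 5′→3′-combined profile; and at
  TFBS an occupancy-scaled block (linear up to saturation occupancy 50,
  inactive below occupancy 10) over the core ±(4+5) bp.  NER gets a
  template-strand boost (ner_ts_boost, default 2; transcription-coupled
  NER).
* **Reads** are one per lesion occurrence (counts > 1 emit multiple reads),
  placed so lesion calling recovers the lesion exactly; decoy reads whose
  upstream dinucleotide is not a dipyrimidine are added uniformly over
  eligible positions at fraction b of all reads (count ⌈n·b/(1−b)⌋),
  exercising the filter without modeling library chemistry.
* **Gel lanes** cleave molecules (default 50 kb, 10⁴ per lane) with Poisson
  breaks at the true density; mock lanes are uncleaved.  The
  number-average fragment length then equals 1/(φ/1000 + 1/L) in
  expectation, which the density estimator inverts.
* **Passaging mutations** pick a channel (class@context weights; defaults
  dominated by C>T in dipyrimidine contexts at 50–55% and T>A at NTA at
  23%) and then a genomic site.  Within gene bodies, template-strand sites
  carry placement odds ts_fold : 1 (optionally per channel); the biased
  gene-body mass is rescaled back to its context-abundance share so the
  strand bias does not also shift mutations between genic and intergenic
  DNA.  Leaving the T>A@NTA channel unbiased (thymine–adenine photoproducts
  escape photolyase on both strands) while photoproduct channels carry an
  8-fold bias yields an overall gene-body fold near 4 that rises toward 8
  when the NTA class is excluded — the regime the analysis must recover.  A
  configured fraction of records is duplicated across isolates (in pairs)
  to exercise the unique-mutation filter; random cross-isolate collisions
  add a small excess above the configured fraction.

What the generator does **not** emulate: sequencing error, PCR duplicates,
6-4PP-specific chemistry (a second lesion class is representable only as a
rate term), alignment artifacts, diploidy, copy-number or repeat structure,
and real nucleosome positioning sequence preferences.  Passing tests
therefore demonstrate correctness of the analysis logic under the stated
statistical model, not robustness to those real-data complications.

## Numerical choices and degenerate inputs

Aggregation-before-division everywhere a region fraction is formed; NaN for
undefined per-site/bin values; strict inequalities where the filters say
"greater than 5" / "occupancy < 10"; telomere exclusion drops sites at
distance ≤ 1000 bp from an end; rotational labels within ±2 bp of an
extremum; the cosine fit uses ordinary least squares with the amplitude
standard error from the delta method; Holm–Šidák adjusted p-values are
clipped to [0, 1] and monotone.  All generators take explicit integer
seeds; identical seed and configuration reproduce byte-identical outputs.

## Problem sizes

The test suite and the acceptance script run on genomes of 0.1–1.2 Mb with
10⁴–10⁵ lesions, ~5 200 dyads for the rotational-phase recovery, 150 TFBS
per dose-response point, 20 isolates × ~91 mutations for strand folds, and
10⁴ replicates for the type-I-error calibrations — sizes at which every
recovered quantity has comfortably sub-tolerance Monte-Carlo error while
the complete suite runs in about a minute.
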