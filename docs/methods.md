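# Methods

## Genome model

Coordinates are hg19, 0-based half-open internally; the IGV SEG dialect
converts to 1-based inclusive on export and back on import. The arm table
ships chromosome lengths and centromere intervals derived from the UCSC
cytoBand acen bands for chromosomes 1–22 and X. Y is excluded from the
genome model entirely: many contributing experiments lacked gender-matched
references, so Y log2 ratios are uninterpretable and are dropped during
preprocessing. The p arm is `[0, cen_start)`, the q arm
`[cen_end, length)`; the acen interval belongs to neither. Acrocentric
p arms (13, 14, 15, 21, 22) keep their short satellite/stalk extent; no
special pseudoautosomal handling is attempted. An interval is assigned to
the arm holding the strictly longer part; an exact tie goes to q (ties
are a measure-zero construction and the choice is documented rather than
meaningful).

## Preprocessing

* `median_normalize`: subtracts the per-sample median so the neutral state
  sits at log2 = 0. Idempotent and invariant to constant shifts.
* `mask_artefacts`: a probe position is a platform artefact when it is
  outside the platform's gain/loss cutoffs in more than
  `recurrence_fraction` (default 0.20) of the platform's samples **and**
  its cross-sample variance exceeds the `variance_quantile` (default 0.95)
  quantile. Both knobs are exposed because "abundantly recurrent" and
  "high variability" have no canonical values; masking is per position,
  with the report emitted as BED-style intervals. Masking requires ≥2
  samples per platform.

## Segmentation

Exact optimal partitioning: minimize total within-segment squared error
plus `penalty × (number of segments)` by the O(n²) dynamic program, per
chromosome. This is a deterministic, automatic replacement for
interactive/visual breakpoint curation; the pipeline equally ingests
externally produced segment tables and skips this stage, and exact
segment-level agreement with manually curated tables is not expected.

* `penalty="auto"` uses `2·σ̂²·log n` with
  `σ̂ = 1.4826 · MAD(successive differences) / √2` — the Gaussian-consistent
  robust noise estimate, insensitive to true copy-number steps. Zero
  estimated noise (noiseless input) degrades to a minimal positive penalty
  (1e-8) so the fewest-segments optimum is still selected.
* `min_probes_per_segment` defaults to 1 so single-probe amplicon spikes
  can be isolated; chromosomes with fewer probes than the minimum yield a
  single segment with a warning.
* Segment bounds span first-to-last member probe (end = last position + 1);
  the segment value is the plain mean of member probes.
* Subclonal events are not modeled; a subclonal aberration whose mean
  falls below the cutoffs will be missed, which is inherent to cutoff
  calling.

## Calling

Label precedence is fixed so each segment receives exactly one label:
homozygous deletion (log2 strictly < −2) before loss (≤ loss cutoff);
amplification (≥ amp cutoff) before gain (≥ gain cutoff). The strict
inequality for homozygous deletions mirrors the published wording
("lower than −2"); gain/loss/amplification boundaries are taken as
inclusive — the original study does not state inclusivity, and the choice
only matters on exact boundary values.

Gain/loss calibration fits a 3-component 1-D Gaussian mixture
(loss/neutral/gain) to segment means, weighting each segment by its probe
count so short noisy segments do not dominate. EM details: means
initialized at the weighted 10th/50th/90th percentiles, equal initial
variances and mixing weights, relative log-likelihood tolerance 1e-8, max
500 iterations, variance floor 1e-8. The gain cutoff is the density
intersection `π_neutral·N(x; μ_n, σ_n) = π_gain·N(x; μ_g, σ_g)` solved by
Brent root-finding strictly between the two component means; the loss
cutoff symmetrically. If the fit fails to converge, a component weight
falls below 1%, or no usable intersection exists (e.g. single-state
input), the routine warns and falls back to the platform defaults. The
weighted EM is implemented here because the standard library mixture
fitters do not accept per-observation weights.

Amplification calibration scans midpoints between consecutive sorted
MYCN-locus log2 values and returns the threshold with the highest
agreement with FISH/qPCR labels; ties resolve to the largest threshold so
high-level gains stay below the cutoff (the returned value is the
midpoint of the best-separating interval).

`mycn_call` declares a sample amplified when **any** segment overlapping
the MYCN interval reaches the platform's amplification cutoff; samples
without MYCN coverage return `unknown` and are excluded from concordance
denominators (counted separately).

## Arm-level annotation

A segmental aberration is a maximal run of adjacent same-direction
aberrant segments that is (a) longer than 3 Mb (genomic extent of the
merged run, strictly greater), (b) not a whole-chromosome aberration, and
(c) not purely an amplification. Design choices where the rule needed
quantifying:

* **Run merging precedes the length test**, so segmenter fragmentation
  cannot hide a lesion. Homozygous deletions merge into loss runs;
  amplifications merge into gain-direction runs (an amplicon inside a 17q
  gain does not split the lesion) but a run containing *only* amplified
  segments never counts.
* **Whole-chromosome** means a run covering ≥95% (configurable) of the
  chromosome's segment-covered extent. Coverage is measured against
  observed segments, not the chromosome length, so sparse designs are
  handled; consequently profiles are expected to tile chromosomes with
  explicit neutral segments, as segmentation output does.
* **Centromere-spanning** lesions take the arm with the longer part;
  exact ties go to q.
* The flags cover loss of 1p, 3p, 4p, 11q, 14q and gain of 1q, 2p, 17q;
  `any_segmental` applies the same criteria on every arm (X included).
  Cohort summaries report the segmental fraction both ways — any arm vs
  the eight flagged arms — because the two readings of "contains
  segmental aberrations" differ.
* `classify_profile`: `silent` with no aberrant segment, `numerical_only`
  when every aberrant run is whole-chromosome, else `segmental`. A profile
  whose only lesion is a focal amplification is classed `segmental`
  (aberrant, not numerical) even though it sets no arm flag.

Focal aberrations are individual aberrant segments < 5 Mb overlapping a
catalogued gene (MYCN, ALK, LIN28B, CHD5, ODC1; approximate hg19 spans).

## Cohort layers

Frequency tracks use fixed 1 Mb windows by default; gain-class
(gain/amplification) and loss-class (loss/homozygous deletion) fractions
are counted independently per window. Region matrices weight overlapping
segments by `n_probes × overlap_fraction` (the expected probe count
falling in the region); label cells take the highest-precedence
overlapping label. Co-occurrence uses Fisher's exact test (two-sided
hypergeometric), odds ratios with Haldane 0.5 correction on zero cells,
and BH adjustment across the 28 arm-flag pairs. The QC partition labels
profiles `silent` (no aberrant segment), `near_silent` (total aberrant
extent < 10 Mb, a declared proxy for "almost undetectable aberrations" —
the original visual criterion is undocumented, so exact historical counts
are not reproducible), else `retained`.

## Survival

Kaplan–Meier estimation and the two-group log-rank test are delegated to
lifelines behind `km_estimate` / `logrank` / `stratify_by_flag`. Ties
follow the standard convention (events before censorings). Time units are
carried on the curve object and never assumed. Zero total events yields
p = 1 with a warning rather than an error.

## Synthetic cohorts

The generator encodes the study conditions used throughout the tests:

* 200 samples by default — Affymetrix 60, Illumina 50, Agilent 60,
  NimbleGen 30 — with archetype weights 0.40 `mna_type`, 0.35 `11q_type`,
  0.15 `numerical_only`, 0.10 `silent`, roughly matching the archetype
  prevalence of high-risk series.
* Segmental event levels: gains +0.35 / losses −0.45 (SNP), +0.45 / −0.55
  (aCGH); amplification centers 1.0 (Illumina), 2.0
  (Affymetrix/NimbleGen), 3.0 (Agilent); probe noise sd 0.15 / 0.10 /
  0.20 / 0.18 for Affymetrix / Illumina / Agilent / NimbleGen. These
  reproduce the qualitative platform ordering (aCGH dynamic range wider
  than SNP; Illumina amplifications compressed) — they are simulation
  defaults, not measured values.
* Probe spacing 350–500 kb per platform keeps a 200-sample genome-wide
  cohort segmentable in seconds; three probes are additionally placed
  inside each catalogued driver gene, as targeted array designs do, so
  sub-Mb amplicons are always interrogated.
* `mna_type` carries a < 1 Mb MYCN amplicon, 1p loss (0–25 Mb) and 17q
  gain; `11q_type` carries 11q loss, 3p loss (0–45 Mb) and 17q gain;
  `numerical_only` draws 2–4 whole-chromosome events from a fixed pool
  (+7, +17, +6, −14, −4, −21; chromosome 2 deliberately excluded so
  whole-chromosome gains never confound MYCN calling).
* Truth flags are set analytically from the archetype definition, not by
  running the scorer, so flag-recovery tests are non-circular.
* Survival is exponential, baseline hazard 1/60 per month, archetype
  multipliers 3.0 / 2.0 / 0.7 / 1.0 (mna / 11q / numerical / silent),
  administrative censoring at 120 months. EFS is withheld for NimbleGen
  samples to exercise missing-endpoint handling.
* One master `SeedSequence` spawns per-sample substreams, so cohorts are
  reproducible and stable under subsetting.

What the generator does **not** emulate: raw probe intensities, GC waves,
allele ratios/BAF, lab batch effects within a platform, subclonality, and
tumors outside the four archetypes. Passing pipeline-recovery tests on
these cohorts therefore demonstrates correctness of the harmonization,
segmentation, calling and scoring logic under the stated noise model —
not performance on arbitrary clinical data.

## Problem sizes

The test suite and acceptance script use: 100 random ≤12-probe profiles
for the exhaustive segmentation oracle; 5,000 segments per platform for
calibration recovery (tolerance ±0.03 against the analytic density
intersections); 200-sample cohorts (noiseless for exact flag recovery,
default noise for end-to-end recovery and MYCN concordance); and 200
replicates of n = 500 for log-rank power at the simulated hazard ratio
of 2. The full suite runs in about a minute on one CPU.

## Known limitations

* Cutoff calling cannot see subclonal or contaminated events below the
  cutoffs; the QC partition flags, rather than corrects, low-purity
  profiles (no ploidy or purity modeling).
* The segmentation stand-in is exact for its objective but is not the
  interactive curation it replaces; breakpoint-level agreement with
  manually curated tables is approximate.
* Arm flags are a cohort-level scoring device, not a per-patient clinical
  report.
* External segment tables need a user-supplied `label_map` when their
  annotation vocabulary differs from
  `normal/gain/loss/amplification/homozygous_deletion`.
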