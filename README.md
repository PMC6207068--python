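# armcall

Harmonized somatic copy-number aberration calling and chromosome-arm
annotation for multi-platform array profiles of high-risk neuroblastoma.

Neuroblastoma genomes are dominated by DNA copy-number aberrations rather
than point mutations, and the *pattern* of aberrations is prognostic:
tumors with only numerical changes (whole-chromosome gains/losses) fare
well, while segmental lesions — loss of 1p, 3p, 4p, 11q, 14q; gain of 1q,
2p, 17q; *MYCN* amplification — mark poor outcome. Large cohorts are only
reachable by pooling profiles from many labs and array platforms (Agilent
and NimbleGen aCGH, Affymetrix and Illumina SNP arrays), whose log2-ratio
dynamic ranges differ enough that one set of cutoffs cannot serve all.
`armcall` implements the harmonization pipeline for such cohorts, plus a
platform-faithful synthetic-cohort generator with known ground truth so
every stage is testable without access to patient data.

## The method

Per sample, probe-level log2 ratios are **median-normalized**
(`log2 → log2 − median`), chromosome Y is dropped, and recurrent
high-variance platform artefact positions can be masked cohort-wide. Each
chromosome is then **segmented** by exact penalized least-squares
changepoint detection: the partition minimizing

    Σ_segments Σ_probes (x_i − mean(segment))² + λ · (#segments)

found by O(n²) dynamic programming, with λ defaulting to
`2·σ̂²·log n`, σ̂ the MAD estimate of probe noise from successive
differences.

Segment means are **called** with platform-specific cutoffs:

| family | gain | loss | amplification | homozygous deletion |
|---|---|---|---|---|
| Affymetrix SNP | ≥ +0.15 | ≤ −0.25 | ≥ 1.5 | < −2 |
| Illumina SNP | ≥ +0.15 | ≤ −0.25 | ≥ 0.7 | < −2 |
| Agilent aCGH | ≥ +0.20 | ≤ −0.30 | ≥ 2.0 | < −2 |
| NimbleGen aCGH | ≥ +0.20 | ≤ −0.30 | ≥ 1.5 | < −2 |

Gain/loss cutoffs can be recalibrated from the data as the density
intersections of a probe-count-weighted 3-component Gaussian mixture
(loss / neutral / gain) of segment means; amplification cutoffs as the
threshold best separating *MYCN*-amplified from nonamplified samples
against FISH/qPCR labels.

Finally, **arm-level annotation**: a segmental aberration is a merged run
of same-direction aberrant segments longer than 3 Mb that is neither a
whole-chromosome aberration (≥95% of the chromosome's observed coverage)
nor a pure amplification; centromere-spanning lesions belong to the arm
carrying the longer part. Each sample gets the eight recurrent-arm flags
and a profile class (`segmental` / `numerical_only` / `silent`). Cohort
layers add frequency tracks, window/gene matrices, Fisher-exact lesion
co-occurrence with Benjamini–Hochberg correction, and Kaplan–Meier /
log-rank stratification by any flag.

## Worked example

```python
from armcall import (SimulationConfig, simulate_cohort, run_pipeline,
                     cohort_summary, mycn_concordance, stratify_by_flag)

cfg = SimulationConfig(seed=11, n_samples={"affymetrix_snp": 15, "illumina_snp": 15,
                                           "agilent_acgh": 15, "nimblegen_acgh": 15})
cohort = simulate_cohort(cfg)
called, flags = run_pipeline(cohort.probes, cohort.annotations)

summary = cohort_summary(flags, cohort.annotations)
print(f"segmental (any arm): {100 * summary['fraction_any_segmental']:.1f}%")
print(f"17q gain frequency: {100 * summary['flag_frequencies']['17q_gain']:.1f}%")
print(mycn_concordance(called, cohort.annotations).to_string(index=False))
res = stratify_by_flag(flags, cohort.annotations, "any_segmental", endpoint="OS")
print(f"log-rank (segmental vs other): chi2={res['logrank_statistic']:.1f}, p={res['logrank_p']:.2e}")
```

prints

```
segmental (any arm): 76.7%
17q gain frequency: 75.0%
      platform  n_evaluated  n_no_coverage  concordance
affymetrix_snp           15              0          1.0
  agilent_acgh           15              0          1.0
  illumina_snp           15              0          1.0
nimblegen_acgh           15              0          1.0
log-rank (segmental vs other): chi2=15.2, p=9.62e-05
```

76.7% of the 60 simulated tumors carry a segmental aberration (the
simulation draws 75% of samples from segmental archetypes); *MYCN*
amplification status is recovered perfectly on every platform despite
Illumina's compressed amplification signal; and flagged-segmental samples
show significantly worse overall survival, as they do in real high-risk
cohorts.

The same stages are available from the shell:

```bash
armcall simulate --seed 17 --n-total 40 --out-dir fixtures/
armcall run --probes fixtures/probes.tsv --annotations fixtures/annotations.tsv --out-dir out/
armcall summarize --segments out/called_segments.tsv --flags out/arm_flags.tsv --out-dir out/
armcall survival --flags out/arm_flags.tsv --annotations fixtures/annotations.tsv \
    --flag any_segmental --out-dir out/
```

## Scope notes

The pipeline starts from extracted probe-level log2 ratios (no CEL/IDAT
parsing, no genome-build liftOver) and accepts externally produced segment
tables in native TSV or IGV SEG dialects, skipping the segmentation stage.
See `docs/methods.md` for the model details, defaults and limitations.
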