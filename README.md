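# isomirseq

Canonical-miRNA and isomiR quantification with exact negative-binomial
differential abundance, built for small two-group small-RNA-seq cohorts such
as tumor grade comparisons in conventional central chondrosarcoma.

## Scientific problem

Mature miRNAs are excised from hairpin precursors, but sequencing shows each
locus as a cloud of length and sequence variants (isomiRs): 3' trims,
templated 3' extensions, non-templated 3' tails, 5' shifts (which move the
seed, positions 2–8, and can retarget the miRNA), and internal substitutions.
A grade-comparison analysis must therefore (i) decompose every read into
mature arm + end offsets + tail + substitutions, (ii) name and count variants
reproducibly, and (iii) test small, unbalanced groups (e.g. 2 vs 7 donors)
where per-feature variance cannot be estimated feature-by-feature.

The statistical model is the negative binomial: counts for feature *f* in
sample *i* are NB with mean `mu_fi = p_f * L_i` (relative abundance times
library size) and variance `mu + phi * mu^2`. Differential abundance between
groups A and B is assessed with the conditional ("exact") NB test after
library-size equalization, with dispersion `phi` estimated by conditional
maximum likelihood and shrunk toward a common value. Effect size is reported
as `log2(mean CPM in B / mean CPM in A)`; features with `|log2FC| > 2` and
mean CPM ≥ 10 are called strongly modulated, and benchmark-cohort calls are
cross-classified against a validation cohort as confirmed / opposite /
no-difference / not-expressed.

## Worked example 1: published grade-comparison table

The package ships the 34-row grade-comparison table (2 Grade I vs 7 Grade
II+III chondrosarcoma donors: per-group mean CPM, printed log2FC, exact-test
p and BH FDR). Recomputing the fold-changes from the printed means and
re-running the strong-modulation selection:

```python
import pandas as pd
from isomirseq.datasets import load_ccc_grade_table, CCC_GROUP_SIZES
from isomirseq.diffexp import log2fc_from_means, select_strong

table = load_ccc_grade_table()
res = pd.DataFrame({
    "mean_cpm_a": table["mean_cpm_a"],
    "mean_cpm_b": table["mean_cpm_b"],
    "log2fc": log2fc_from_means(table["mean_cpm_a"].values,
                                table["mean_cpm_b"].values),
    "fdr_bh": table["fdr_bh"],
})
strong = select_strong(res, group_sizes=CCC_GROUP_SIZES)
print(len(strong), (strong.direction == "up").sum(), (strong.direction == "down").sum())
```

prints `34 24 10` — all 34 rows pass the |log2FC| > 2 and CPM floors, 24 up
and 10 down. The recomputed log2FCs round to the printed column in every row,
e.g.:

```
                mean_cpm_a  mean_cpm_b  log2fc  significant
hsa-miR-206           5.76      163.17    4.82        False
hsa-miR-31-3p         3.71       47.59    3.68        False
...
hsa-miR-489-3p       495.25       27.07   -4.19         True
```

`hsa-miR-489-3p` is the only feature whose printed FDR clears the
significance flag.

## Worked example 2: synthetic cohort end to end

```python
from isomirseq.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    output_dir="demo_out", seed=42, simulate=True,
    simulation={"n_group_a": 4, "n_group_b": 4, "n_mirnas": 60,
                "library_size_mean": 50000, "dispersion": 0.2,
                "de_fraction": 0.15, "seed": 42},
)
run_pipeline(cfg)
```

This simulates hairpins, mature arms, per-sample FASTQ reads (isomiR mix,
sequencing errors, rRNA-like contaminants), then cleans, aligns, names,
counts, and tests. With seed 42 the run gives, per sample A1:
55,971 raw reads → 2,799 contaminants removed → 53,172 retained → 2
unaligned; cohort-wide, 60 canonical features tested, 9 strong (2 up / 7
down), all 9 significant, against 9 loci simulated with |log2FC| ≈ 3 — for
example `sim-miR-044-3p` estimated −2.66 vs −2.93 injected. The isomiR-level
catalog holds 9,499 named variants. Rerunning the same config reproduces
every table byte-for-byte (`checksums.json`).

The same pipeline runs on real data by setting `simulate: false` and
providing `reference_fasta`, `mature_table`, `fastq`, and `manifest` in the
YAML config. A CLI mirrors the library: `isomirseq simulate | run-all |
align | diffexp | validate | enrich | report`.

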