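# Methods

## Read model and alignment

A read is decomposed against each annotated mature arm as a templated body —
a hairpin substring beginning at `mature_start + offset5` — plus an optional
non-templated 3' tail, with up to `max_mismatch` internal substitutions and
no indels inside the body. Admissibility bounds (package defaults):
`|offset5| ≤ 4`, `|offset3| ≤ 5`, tail ≤ 3 nt, substitutions ≤ 2. Among all
admissible decompositions the winner minimizes

```
score_key = (n_subst, tail_len, |offset5| + |offset3|)
```

with remaining ties broken by `(|offset5|, mature_id, offset5, offset3)`, so
output is deterministic. Because tail length is compared before end offsets,
a 3' base the hairpin can still template is always absorbed into the body
rather than the tail; decompositions of error-free reads are therefore
unique. Multi-mapped reads (exact score ties across arms) either take the
deterministic best hit (default) or are split fractionally.

The aligner enumerates `(mature, offset5, body_length)` triples directly —
read lengths are ≤ 40 nt and references are small, so exhaustive enumeration
with early mismatch cutoffs is fast and exactly matches an independent
brute-force decomposer (tested on ≥1000 random reads).

## IsomiR classes and naming

Each non-canonical read gets a class code: `3` (3' variation only: trim,
templated extension, or non-templated tail), `5` (5' shift only), `53`
(both ends), `0` (internal substitutions only). A 5' shift or a substitution
at mature-relative positions 1–7 flags the seed (positions 2–8, 1-based) as
altered. Names follow `{parent}.{class}.P{n_subst}.S.{serial}`; serials rank
a parent's distinct variant sequences by pooled abundance (descending, ties
lexicographic), so naming is deterministic for identical input but serials
are cohort-relative — names are not comparable across cohorts without
re-anchoring on the variant sequence. Canonical sequences keep the plain
mature id. `parse_name` inverts the grammar (parents may themselves contain
dots; parsing splits from the right).

## Quantification

Library size is the per-sample total of miRNA-assigned reads; CPM and
percentage shares are computed within that compartment. Count matrices exist
at two levels: canonical (one row per mature arm, isomiR reads counted with
their parent; `strict=True` restricts to exact canonical sequences) and
isomir (one row per named variant). A feature is "expressed" when its mean
per-sample library percentage exceeds 0.001% (strict); differential testing
additionally applies a mean-CPM ≥ 10 floor (inclusive).

## Differential abundance

NB model: `Var = mu + phi * mu^2`. The test conditions on each feature's
total after library equalization:

- **Equalization** maps each sample's counts onto the geometric-mean library
  size by a quantile map for NB(mean, phi): the average of the normal and
  gamma maps with matched mean/variance, clipped at zero. Equal library
  sizes are an exact fixed point.
- **Dispersion** is estimated by conditional maximum likelihood. For a group
  of n samples with counts y_i, total z, and r = 1/phi, the per-feature
  conditional log-likelihood (phi-dependent terms) is
  `sum_i lgamma(y_i + r) − n·lgamma(r) + lgamma(n·r) − lgamma(z + n·r)`,
  summed over the two groups. The common phi maximizes the pooled likelihood
  over a log grid on [1e-6, 10] (81 points) with parabolic refinement;
  tagwise values maximize `CL_f + prior_df · mean(CL)` (default prior_df
  = 10), collapsing to the common value as prior_df grows.
- **Exact test**: under H0 the group-A sum given the feature total follows
  the two-category Dirichlet-multinomial (beta-binomial with a = n_A/phi,
  b = n_B/phi), reducing to Binomial(total, n_A/(n_A+n_B)) as phi → 0. The
  two-sided p-value sums all splits whose probability is ≤ the observed one
  (relative tie tolerance 1e-8); probabilities are never doubled. Group sums
  are rounded to integers after equalization to restore discrete support.
  The implementation matches scipy's closed-form binomial and beta-binomial
  laws to < 1e-10 and edgeR's exact test (balanced design, doubletail
  convention, exact path) to ~1e-13.
- **Effect size** is log2 of the ratio of arithmetic group means of
  per-sample CPM, computed independently of the test; zero group means give
  ±inf and are flagged rather than dropped (no pseudocount by default).
- **Multiplicity**: Benjamini–Hochberg step-up (statsmodels).
- **Selection**: strongly modulated = `|log2FC| > 2` (strict) with the CPM
  floor; significance flag = `FDR < threshold` (strict; default 0.1).
- **Concordance** against a validation cohort: not_expressed (below the
  validation expression threshold), no_difference (|validation log2FC|
  < 0.5), confirmed (sign agrees), opposite (sign disagrees).

Over-representation of feature sets uses the upper hypergeometric tail
`P(X ≥ found)` with BH across sets.

## Simulator

`SimulationConfig` defaults define the study conditions: 2 vs 7 samples,
200 loci, mean library 1e6 reads (lognormal, CV 0.3), NB dispersion 0.2,
one dominant locus holding 25% of reads (remaining abundances lognormal,
sigma = 1), 15% DE loci with |log2FC| uniform in [2.5, 4.5], isomiR profile
(canonical 25%, 3' trim 30%, templated 3' extension 15%, non-templated tail
10%, 5' shift 5%, substitution 15%), per-base error 0.001, 5% contaminant
reads.

Identifiability constructions make zero-error reads uniquely decomposable:
the two hairpin bases 5' of each mature arm are fixed to "C" so 5' shifts
are templated and unambiguous; the first base of a non-templated tail is
drawn to differ from the hairpin's templated continuation; substitutions are
placed at least `max_tail + 1` nt from the 3' end so they cannot be
reinterpreted as tails. Two composition-bias safeguards keep group-mean CPM
an unbiased estimate of the injected effect: the dominant locus never
carries an injected effect, and up/down signs are assigned greedily to
balance the total count-mass shift `sum abund·(2^±m − 1)` between groups.
Under these defaults, injected ±3 effects are recovered in CPM log2FC with
mean error < 0.3 and 100% of effect loci pass the strong+significant
selection at n = 10/10.

## Numerical choices and limitations

- All pmf computations run in log space (`gammaln`, `logsumexp`); exact-test
  cost is O(total) per feature, fine for desk-scale totals.
- Dispersion grid bounds [1e-6, 10] act as soft floors/ceilings; Poisson
  data estimate at the floor.
- The equalization quantile map is the classical continuous approximation;
  rounding group sums afterwards introduces at most one-count granularity.
- The aligner models no indels within the templated body and no 5'
  non-templated additions; reads needing either go unaligned.
- Serial-based isomiR names depend on cohort-wide abundance ranking; merge
  cohorts on (parent, sequence), not on names.
- The conditional test assumes a common per-feature mean under H0 across
  samples after equalization; strong residual composition bias between
  groups can bias both the test and the CPM effect size.
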