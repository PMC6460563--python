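# Methods

## The quantity being estimated

In a female, one X chromosome per cell is epigenetically silenced early in
embryogenesis; the choice of maternal versus paternal X is random per cell
and clonally inherited. Blood is therefore a mosaic, and the fraction of
cells expressing the paternal X — the individual's *skew* — need not be
50:50. `xskew` estimates this fraction from bulk RNA-seq as the median
**paternal ratio** `Mx`: at every heterozygous X-chromosomal SNV the reads
are split into paternal and maternal using the trio structure (the father
is hemizygous on non-PAR X, so the paternal allele of a heterozygous
daughter is forced to be whichever allele the father carries; the mother's
genotype serves only as a Mendelian consistency check), and

```
paternal ratio = paternal count / (paternal + maternal count)
Mx             = median over SNVs of the paternal ratio
Sx             = |Mx − 0.5|          (chromosome skew factor)
```

SNVs enter the analysis only if they have at least `min_coverage` (default
10) allele-supporting reads, overlap an annotated exon, and fall outside
the pseudoautosomal regions (which recombine with the Y and are not
inactivated). For mothers, whose parental phase is unknown, the
orientation-free **measure of balance** `min(ref, alt)/(ref+alt)` replaces
the paternal ratio; the median balance supports the mother–daughter
independence check (Pearson correlation over pairs).

## Skew classes

Classification acts on `Mx` with closed boundaries, all configurable
(`SkewThresholds`): maternal-skewed `Mx ≤ 0.35`, paternal-skewed
`Mx ≥ 0.65`, extreme at `≤ 0.15` / `≥ 0.85`, complete at exactly 0 or 1 (a
tolerance option exists, default exact). Mothers are classified by the
mirrored criterion on median balance (`≤ 0.35` ⇒ skewed). Classification
uses medians only; mean ratios are computed and exported but never
classified on.

## The escape test

An inactivated gene is expressed almost entirely from the active
haplotype, so its per-gene median `Mg` tracks `Mx`; a gene escaping
inactivation is transcribed from both X's and is pulled toward 0.5. Across
skewed individuals the test forms, per sample, the signed gene skew
`g = Sg` if `Mg` and `Mx` deviate on the same side of 0.5 and `g = −Sg`
otherwise, then runs a one-sided paired t-test on `d = Sx − g` with
alternative `mean(d) > 0`. Genes need ≥ 5 informative skewed samples;
calls are made at `p < 0.05` without multiple-testing correction (a
Benjamini–Hochberg flag exists). The sign convention makes
`d = ±(Mx − Mg)` exactly, so disagreement (a gene deviating past 0.5 in
the opposite direction) is counted as stronger evidence of biallelic
expression, and the `Mg = 0.5` tie is harmless (`±0 = 0`).

Two deliberate choices here:

* **Test direction.** A literal R reading of `t.test(Sx, Sg,
  alternative="less")` would test `mean(Sx − Sg) < 0`, the opposite of the
  stated alternative that the gene is *closer* to 0.5 than the chromosome.
  The verbal hypotheses win: the default tests `mean(d) > 0`. The literal
  argument-order variant remains available as
  `escape_test(..., direction="gene_more_skewed")` for comparison.
* **`Mx` includes the gene's own SNVs** (no exclusion is applied by
  default; a typical gene contributes ~1 of 30–150 SNVs, so the effect is
  negligible). A leave-gene-out option is easy to add at the audit-table
  level if needed.

Genes whose pooled reads are > 90 % reference allele across samples are
flagged `reference_bias_suspect` (the signature of mis-mapped reads from a
homologous locus, classically a pseudogene) but not removed.

*XIST* is the built-in control: it is expressed from the *inactive* X, so
in skewed individuals its `Mg` should lie on the opposite side of 0.5 from
`Mx`; `xist_check` reports the per-sample opposition flags and fraction.

### Known limitation: calibration of the escape test

Under a pure null (every gene inactivated) the test's false-call rate at
α = 0.05 is close to nominal (≈ 4.5–6 % in the calibration suite), but its
p-values are not exactly uniform: `Mx`, a median over 30–150 discrete
binomial per-site ratios, is slightly biased away from 0.5 relative to a
single-SNV gene median whose expectation is exact, giving
`mean(d) ≈ +0.002` under the null. A Kolmogorov–Smirnov uniformity check
over 1,000 null genes sits right at its α = 0.01 critical value
(D ≈ 0.05) and can fail. The bias is a property of the median-of-medians
construction under read-sampling noise, not of the implementation; it is
unaffected by reference bias and changes sign (turns conservative) when
genes carry several SNVs per sample.

## Precursor-cell model

If the blood lineage descends from `n` precursor cells, each inactivating
one X independently and fairly, an individual's paternal ratio is
`Binomial(n, 1/2)/n`. Closed forms: complete skew in one direction has
probability `2^−n` (1/16 at four cells), in either direction `2^−(n−1)`
(1/8 at four cells; ≈ 5 × 10⁻¹⁰ at 32). `select_precursor_count` simulates
each candidate count (default grid {4, 8, 16, 32}, 10,000 draws each from
named substreams) and scores it against the empirical `Mx` sample with a
two-sample KS test (asymptotic p, appropriate for heavy ties); the
candidate with the highest p wins, ties broken by smaller D then smaller
n. An `exact_cdf` mode replaces simulation by the exact discrete
one-sample sup-distance against the analytic binomial CDF (computed at the
union of jump points — SciPy's `ks_1samp` assumes a continuous CDF and is
wrong under ties).

On noiseless skews the generating count is recovered essentially always at
2,000 individuals. On realistic cohorts the read-noise jitter on `Mx`
smooths the discrete atoms and *every* discrete candidate fits poorly
(D ≈ 0.15–0.25); 8 versus 16 cells can then be ambiguous, especially as
cohorts grow. This mirrors the weak absolute fit the method reports on
real data and is worth remembering when interpreting a selected count.

## The synthetic cohort generator

`generate_cohort` fabricates trio genotypes, allele-specific counts, exon
and PAR annotation, and a full truth table, so each pipeline stage can be
validated against known ground truth. The generative model:

* **Skew**: each individual's `θ` (fraction of cells with the paternal X
  active) is `Binomial(n_cells, 1/2)/n_cells`, default `n_cells = 8`;
  mothers draw independent skews (no transmission).
* **Genes**: `n_genes` (default 120) five-exon genes tiled along a 155-Mb
  synthetic X with GRCh37 PAR coordinates; one mid-chromosome gene is
  XIST; `escapee_fraction` (default 0.15, ≈ the fraction of X-linked genes
  reported to escape) are escapees, of which `variable_escapee_fraction`
  escape per-individual with probability 0.5. Two decoy genes sit inside
  PAR1 (PAR genes are modelled as diploid-expressed, fraction 0.5).
* **Sites**: every daughter receives a uniform 30–150 *informative* sites
  (heterozygous, exonic, non-PAR, guaranteed to pass the coverage filter),
  plus decoys — homozygous (0.4 × informative), PAR (5), non-exonic (10),
  low-coverage (8) — and, when `mendelian_error_rate > 0`,
  mother-inconsistent sites, so every filter and phasing branch fires.
* **Counts**: coverage is negative binomial (mean 50, dispersion 8,
  floored at the coverage filter except for low-coverage decoys; ~50× is a
  typical usable ASE depth in bulk blood RNA-seq). Paternal reads are
  `Binomial(c, f)` with `f = θ` (inactivated), `0.5` (escaping), `1 − θ`
  (XIST). Reference bias is binomial thinning of alternative-allele reads
  with keep probability `β/(1−β)` (default `β = 0.49`, reproducing the
  slight leftward shift of allelic ratios seen in real data);
  informative-designated sites are redrawn until they still pass the
  filter after thinning. Mother counts use the same scheme at her
  heterozygous sites; the per-site coin for which allele rides her
  majority-active haplotype is immaterial because mothers are analysed
  only through the fold-symmetric measure of balance.
* **Randomness**: one master seed; every stage draws from a named
  `SeedSequence` substream, so a fixed seed gives bit-identical bundles.

What the generator does **not** emulate: mapping and alignment artifacts
beyond the global reference-bias thinning, overdispersed (beta-binomial)
allelic counts (pure binomial by default; overdispersion would widen all
ratio distributions), linkage between neighbouring SNVs beyond the shared
`θ`, expression-level differences between genes, clonal haematopoiesis and
age effects. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated model, not robustness to every
artifact of real RNA-seq.

## Numerical conventions

Positions are 1-based; BED intervals 0-based half-open (`p` overlaps
`[start, end)` iff `start < p ≤ end`). "Coverage" means `ref + alt`
allele-supporting reads. Medians of even-length sets average the central
pair. Zero-coverage records keep NaN ratios and die at the coverage
filter. Multi-gene SNVs count once in chromosome summaries and once per
gene in the gene analysis. Thresholds are compared exactly as printed
(closed boundaries). Floating-point output is printed to 6 significant
digits; identical config + seed reproduces outputs byte for byte.

## Problem sizes used in validation

The shipped suites use cohorts of 6–80 trios for unit and property tests,
a 400-trio / 1,000-gene null cohort plus a 150-trio / 120-gene power
cohort for escape-test calibration, 10⁶ draws for simulation/analytic
agreement, 100 replicates × 2,000 individuals for precursor recovery, and
60 replicates × 500 pairs for the mother–daughter independence null. The
acceptance script analyses a 79-trio cohort, matching the scale of a
realistic trio RNA-seq study.
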