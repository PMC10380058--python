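# Methods

## Scope and model

`tgskit` analyses *polygenic profiles*: for a cohort of unrelated diploid
individuals genotyped at a fixed panel of trait-associated SNPs, it scores
each genotype under the co-dominant model (count of the effect allele:
2 / 1 / 0 for effect-homozygote / heterozygote / alternate-homozygote) and
aggregates per sample into

- **TGS** (total genotype score) `= 100 · Σ s_j / (2m)` — the fraction of
  the maximum possible allele count, on a 0–100 scale;
- **TWGS** (weighted) `= 100 · Σ β_j s_j / (2 Σ β_j)` — the same with each
  locus weighted by its GWAS effect size β ≥ 0, so a locus with β = 0.055
  counts ~3× a locus with β = 0.019.

Sums run over the loci typed in that sample. The bundled panel targets
maturity timing in males (39 SNPs with published β in [0.019, 0.055] and
per-group reference minor-allele frequencies for a 240-control / 86 / 73
three-group design); any panel with the same schema works.

## Missing data

The score denominators rescale to the typed loci, keeping the 0–100 scale
comparable across samples with different missingness. To stop a score from
being dominated by a handful of loci, `score_cohort` excludes samples typed
at less than a completeness threshold (default 0.9 of *panel* loci — loci
removed earlier by QC count as untyped, so heavily filtered runs surface in
the exclusion log rather than silently shrinking denominators). Half-called
genotypes collapse to missing: the co-dominant score is undefined on one
allele. Calls whose alleles match neither panel allele (typically strand
flips on arrays) are set missing and tallied per locus rather than raised;
an optional `strand_flip` mode retries such calls after A↔T / C↔G
complementation, off by default because it silently mis-rescues A/T and C/G
panels.

## Quality control

Loci pass only with minor-allele frequency **strictly** above `maf_min`
(default 0.05) and call rate **strictly** above `call_rate_min` (default
0.95); samples need call rate strictly above the same threshold. Strictness
matches the conventional "> 0.05" / "> 95%" phrasing of inclusion criteria.
Thresholds are computed on the pooled analysis matrix.

Hardy–Weinberg equilibrium is tested exactly, conditioning on the observed
allele counts: given `n` typed diploids and `n_a` minor alleles, the
heterozygote count under random mating has

```
P(n_het | n, n_a) = [ n! / (n_hom_minor! n_het! n_hom_major!) · 2^n_het ] / C(2n, n_a)
```

over het counts sharing the parity of `n_a`. The two-sided p-value is the
probability mass of all outcomes no more probable than the observed one
(the standard exact-test convention; not mid-p). Log-space accumulation
(`gammaln` + `logsumexp`) keeps the test stable to n ≥ 10,000; the summed
mass is normalised by the total across all feasible outcomes, which cancels
the shared rounding of the log-factorial constant so the test agrees with
exact rational enumeration to < 1e-12 for n ≤ 500. A tolerance of 1e-9 in
log-probability treats mathematically tied outcomes as ties despite float
noise. The test is conservative: simulated type-I error at α = 0.05 is
≈ 0.038–0.045, never above 0.055 in calibration runs.

By default HWE deviations are *recorded, not exclusionary* — real analyses
of this kind report deviating loci but keep them — and `hwe_alpha` turns the
test into a filter. No multiple-testing correction is applied to the 39
per-locus p-values, deliberately mirroring the single-locus reporting
convention of the field.

## Group comparison

- **Omnibus:** one-way ANOVA (equivalently, the F test of a regression on
  k−1 group indicators), df = (k−1, N−k). For 86/73/240 this yields
  F(2, 396), fixing the df convention.
- **Pairwise:** pooled-variance Student t, df = nA+nB−2 (86 vs 73 → 157).
  Zero pooled variance degenerates to t = 0, p = 1 (equal means) or p → 0
  with an infinity flag (unequal). All p-values two-sided.
- **Tertiles:** cuts at the empirical 1/3 and 2/3 quantiles of the *pooled*
  score set (all groups combined; per-comparison basis is configurable), by
  numpy's default linear-interpolation quantile. Strictly below the lower
  cut → low, strictly above the upper cut → high, ties at a cut → middle —
  a deterministic rule whose cut values are recorded in the report so any
  divergence from another tool's tertiles is visible.
- **Odds ratios:** OR = (A_high·B_low)/(A_low·B_high) on the high/low
  extremes (middle third excluded), Woolf log-normal 95% CI
  `exp(ln OR ± z·√(1/a+1/b+1/c+1/d))`; any empty cell adds 0.5 to all four
  (Haldane–Anscombe), flagged `corrected` in the output.

## Synthetic cohorts

`simulate_cohort` draws each genotype independently per locus and sample:
the 0/1/2 score is Binomial(2, p) at the group's earlier-allele frequency p
— exactly the Hardy–Weinberg null the QC stage tests — then maps scores back
to allele-pair calls using the panel's alleles, with optional uniform
missingness. One seeded generator per cohort makes outputs byte-reproducible.
Analytic companions (`expected_scores`: E[TGS] = 100·mean(p),
E[TWGS] = 100·Σβp/Σβ) support parameter-recovery tests.

`paper_like_spec` mirrors the reference study design: groups CON / U12-16 /
U17-23 with n = 240 / 86 / 73 at the bundled panel's per-group frequencies.
**Allele orientation is an explicit argument** (`minor_is_earlier` per
locus): the published per-group mean scores (~43–45) are incompatible with
the minor allele being uniformly earlier *or* uniformly later, so
orientation is genuinely mixed and unrecoverable without the source GWAS
summary statistics; the generator refuses to guess. Under the all-minor
orientation the analytic mean TGS is ≈ 31 for controls, which is why the
simulated levels in the examples sit below the published ones while every
structural quantity (group sizes, df, test layout) matches.

What the generator does **not** emulate: linkage disequilibrium between
loci (the additive score model itself treats loci independently),
population stratification, relatedness, genotyping error beyond uniform
missingness, and the selection processes that would make groups differ.
Passing tests therefore demonstrate the correctness and calibration of the
pipeline's arithmetic and statistics, not that any real cohorts differ.

## Numerical and design choices

- Scores are kept at full float precision; rounding (means 1 dp, t/F 2 dp,
  OR 2 dp, p 3 dp) happens only in report rendering, and the rendered
  values are asserted to equal the JSON values rounded by those rules.
- VCF records are matched by the ID column (rsID), not position: panels
  identify loci only by rsID and carry no genome build. Multi-allelic
  records at panel loci are set missing with a warning; indel alleles are
  ignored.
- The probability-mass (not mid-p) exact-test convention was chosen because
  it is the dominant convention and is what a brute-force enumeration oracle
  verifies unambiguously.
- Simulation sizes in the test-suite calibrations (5,000 loci for type-I
  error; 1,000 two-group replicates at n = 100; 10,000 per group for
  parameter recovery) were chosen to make 3-SE checks sharp while keeping
  the full suite around ten seconds.

## Known limitations

- The bundled panel cannot reproduce published absolute score levels
  without the true per-SNP orientations (see above); it is a structural and
  statistical test bed, not a clinical scoring instrument.
- No dosage/imputation support: genotypes are hard calls.
- The OR machinery assumes two groups at a time; multi-group effect sizes
  beyond pairwise ORs are out of scope.
- HWE testing assumes autosomal biallelic loci in unrelated individuals.
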