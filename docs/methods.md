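# Methods

## Model and procedure

`somaphyl` treats each patient's tissues as leaves of a simple lineage tree:
zygote → (blood lineage | thyroid lineage) → (tumor | adjacent non-tumor).
A variant's presence pattern across the three samples places it on a branch:

| present in | inferred origin | subset |
|---|---|---|
| PTC ∩ ANT ∩ blood | germline or pre-hematopoietic-split embryogenesis | Common (blood-concordant part) |
| PTC ∩ ANT only | thyroid lineage before the tumor/normal split | Common (blood-discordant part) |
| one tissue only | late somatic events after divergence | Unique-to-PTC / Unique-to-ANT |

All partitioning is set algebra on variant keys `(chrom, pos, ref, alt)`.
Genotypes are deliberately ignored: the unit of analysis is the per-sample
SNS *signature* (site present/absent), and tumor/normal matching is by bare
key. No purity, ploidy or subclonal modeling is attempted — the partition
*is* the phylogeny, nothing more.

### Overlap metric

"Overlap of A with B" is directional: |A ∩ B| / |A| — the fraction of A's
variants also seen in B. This is the natural reading of statements like "a
subset shares x % of its SNSs with blood" and is used for both blood
concordance and the inter-patient heterogeneity matrix. Jaccard similarity
is available as an option (`metric="jaccard"`) but is not the default.
Fractions of empty subsets are reported as missing, not 0, so cohort means
are not dragged toward zero by degenerate patients.

### Statistics

The observational unit for spectrum and burden comparisons is the
*per-patient* proportion (not pooled counts): two groups are compared with
the Welch two-sample t-test, three or more with one-way ANOVA. A pooled-
count chi-square is provided only as a secondary diagnostic. No
transformation is applied to proportions by default; an arcsine-square-root
option exists for proportions near the boundaries. When both groups are
exactly constant and equal, the Welch test is reported as (t = 0, p = 1)
rather than NaN.

Over-representation of a gene set is the one-sided hypergeometric tail
P(X ≥ k) with BH-FDR across pathways. The default background universe is
whatever gene collection the caller supplies; in pipeline use it is all
genes with ≥ 1 coding SNS in the cohort. Because the hypergeometric is
discrete, its null p-values are super-uniform; the calibration test in the
suite applies the standard randomization correction (p − U·P(X = k)) before
testing uniformity.

## Filters

Inclusion requires depth ≥ `min_depth` (default 8, the exome-coverage floor
for this study design), qual ≥ `min_qual` (default 0, i.e. off — "standard
quality cut-offs" are caller-specific and no single number is defensible),
and absence from every named exclusion catalog (dbSNP-style lists, read from
TSV or VCF). Variants lacking a depth/qual annotation pass those criteria
and are tallied separately, since annotation completeness varies between
call sets. Filtering is per-variant and order-independent; the report's
attribution of removals follows the fixed order depth → qual → exclusions.
Whether the depth floor applies per-sample or jointly across a pair is not
standardized; it is applied per-sample here.

## Genetic-code degeneracy

`enumerate_codon_changes` lists all 576 (codon, position, alternate-base)
events under a codon table (standard code by default, via Biopython).
Conventions, fixed because they are the unique simple set under which the
per-class synonymous percentages come out at their commonly printed values
(34.4 % for C>T, 19.8 % for C>A):

- classes are strand-pooled (C>T with G>A, etc.), 96 events per class;
- stop → stop counts as synonymous;
- stop-involving changes remain in the denominator (stopgain/stoploss are
  separate consequence labels, not exclusions).

The unpooled 48-event directed fractions are available (`pooled=False`) for
transparency. The consequence caller labels variants against transcript
models (ordered 1-based closed CDS intervals, minus-strand variants
complemented into transcript orientation before codon lookup) and is proven
equivalent to the enumeration on all 576 changes embedded on both strands.

## Burden and groupings

"Predicted deleterious" defaults to ≥ 1 damaging vote out of the 5 upstream
predictors (`vote_threshold=1`, configurable 1–5; no consensus rule is
canonical). Deleterious counts are bounded by non-synonymous counts by
construction, and rates use the subset's coding-SNS count as denominator.
The age dichotomy is "older than 45" — age exactly 45 falls in the younger
group (configurable). Group comparisons use total per-tumor SNS counts;
with exclusion catalogs configured, totals can be computed both pre- and
post-exclusion by running the pipeline under the corresponding
`FilterConfig`s.

## Synthetic cohorts

The generator emulates the branching model directly. Per patient it draws
five Poisson pools and assigns them to tissues:

| pool | mean (default) | tissues | spectrum |
|---|---|---|---|
| germline | 3800 (+1000 if BRAF-mutant) | PTC, ANT, blood | early |
| early shared | 600 | PTC, ANT, blood | early |
| thyroid shared | 1100 | PTC, ANT | early |
| late PTC / late ANT | 1700 each | one tissue | late |

The early spectrum is C>T-dominant (C>T 0.65, T>C 0.15, transversions 0.05
each) — the deamination-driven profile of germline polymorphism. The late
spectrum is C>A-enriched (C>A 0.40, C>T 0.25) — the oxidative-damage
(8-oxoguanine) profile. These are generator conventions chosen to make the
qualitative early→late shift reproducible at realistic magnitudes, not
estimates of any real cohort. The defaults imply per-tumor totals ≈ 7200,
shared fraction ≈ 5500/7200 ≈ 0.76 (within the 57–88 % range such cohorts
show), and blood/Common overlap ≈ 4400/5500 ≈ 0.80.

Placement: each variant's class is drawn from the stage spectrum, then a
uniformly-chosen unused position carrying the class's pyrimidine base *or
its complement* receives the corresponding directed substitution, so both
strands are represented and the collapsed class is exact by construction.
The toy genome is a 120 kb uniform-random chromosome with 30 non-overlapping
900 bp single-interval CDS genes on alternating strands; consequences follow
mechanically from placement. Per-predictor damaging calls are Bernoulli with
probability 0.5 given a protein-altering consequence and 0.05 otherwise,
drawn once per variant key so the cohort-wide votes table is consistent.
A fraction (0.3) of germline-stage variants is flagged into a cohort-wide
known-variant catalog, giving the filter sweep a realistic dbSNP-style
exclusion list. Covariates (age ≈ N(49, 15) clipped to 16–97, F:M ≈ 2.5,
BRAF-mutant fraction 0.415) mirror the demographic structure of a thyroid
cancer surgical cohort. Every patient receives a blood sample (real cohorts
often have blood for only a subset; analyses handle missing blood, the
generator simply does not exercise it).

Determinism: the same `SimConfig` (including `seed`) yields byte-identical
outputs; the written formats (VCF, YAML manifest, TSV catalogs, FASTA+GFF3)
are exactly the formats `variant_io` reads back.

### What the generator does not model

No sequencing error, no tumor-purity contamination (real Unique-to-ANT
subsets may contain tumor-contaminated calls; nothing corrects for that
here either), no linkage or mutation clustering, no trinucleotide context,
no shared polymorphism between patients beyond chance collisions, and no
blood-private variants (blood = germline + early pool exactly, so simulated
blood overlaps of unique subsets are exactly 0 rather than the ~10–15 %
seen with real sequencing noise). Passing recovery tests therefore
demonstrates correctness of the set algebra, spectra and statistics under
the branching model — not robustness to artifacts of real exome data.

### Recovery tolerances

Recovery tests compare cohort means against closed-form expectations within
3 Monte-Carlo SDs. For a ratio C/(C+L) of independent Poisson counts the
delta-method variance (μ_L²μ_C + μ_C²μ_L)/(μ_C+μ_L)⁴ is used; for class
proportions, binomial p(1−p)/n with the realized subset size. The default
study conditions are 20 patients at the pool means above (~360 k variant
records per cohort, a few seconds to simulate and analyze on one CPU).

## Numerical and edge-case conventions

- Tr:Tv of a transversion-free collection is undefined (`None`), and such
  patients are excluded (with a warning) from fold-change summaries.
- Empty variant collections give total 0 and empty proportion maps.
- Duplicate VCF records and multi-allelic decomposition duplicates collapse
  to one variant per key; indels/MNVs are skipped, not errors.
- Welch tests require ≥ 2 observations per side; below that, summaries are
  returned without a test and a warning is raised.
- BH q-values come from `statsmodels.stats.multitest.multipletests`.

## Design choices that were genuinely open

- **Overlap metric** (directional vs Jaccard): directional, as above.
- **Blood filtering**: blood sets pass through the same `FilterConfig` as
  tissue sets, otherwise fractions are incomparable.
- **Spectrum aggregation**: per-patient averaging rather than pooling, so
  heavily-mutated patients do not dominate cohort spectra; pooled tables
  remain available.
- **BRAF burden offset placement** (simulator): added to the germline pool
  mean, so a flagged patient's totals rise in every tissue while shared
  fractions stay comparable between groups — the offset is then an
  estimable difference in per-tumor totals.
- **Exactly-45 age assignment**: younger group, per the strict "older than
  45" reading; configurable.
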