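# Methods

## The analysis model

The package models a two-arm cohort of unrelated individuals — a small
case series (default 13) against a reference arm (default 100 controls) —
genotyped at exonic variants. The scientific question is whether any gene
accumulates rare, predicted-damaging ("qualifying") variants in cases
beyond what the control arm shows, and whether the mutated genes as a set
concentrate in particular functional categories.

The analysis makes the standard collapsing assumptions: variants act
dominantly at the gene level (a sample with one or more qualifying
alleles in a gene is a carrier, counted once), carrier states are
independent across samples, and the control arm is exchangeable with
cases under the null. No covariates, relatedness or dosage effects are
modelled; the exact conditional test makes no asymptotic approximation,
which matters at these sample sizes where expected carrier counts are
near zero.

## Filter cascade

Four per-variant predicates, reported in a fixed order (consequence →
rarity → panel exclusion → predictors) for a flowchart-style trace, but
mathematically order-free since each predicate is pure:

| Parameter | Default | Meaning |
|---|---|---|
| `maf_threshold` | 0.01 | strict upper bound on each available population MAF |
| `included_consequences` | nonsense, splice_site, missense, frameshift_indel, inframe_indel | retained classes |
| `missing_af_passes` | true | variants absent from reference panels ("novel") pass rarity |
| `require_both_predictors` | true | both predictor calls must be "D" |
| `missing_pred_policy` | fail | a missing predictor call fails (option: pass when the other call is "D") |

Decisions that were genuinely open:

* Missing population frequency passes rarity. A novel variant cannot
  demonstrate a frequency, and excluding novel variants would invert the
  design's intent (the rarest variants are the most interesting).
* The MAF comparison is strict (`<`), and reported alternate-allele
  frequencies are folded to minor-allele frequencies before comparison.
* Unannotated variants are dropped (conservative: they can demonstrate
  neither rarity nor deleteriousness); more than 10% unannotated aborts
  the run, since that signals mismatched genotype/annotation inputs.
* Panel exclusion uses exact (chrom, pos, ref, alt) identity after
  suffix-trimming canonicalisation; no liftover or further normalisation.
* Missing genotypes count as non-carriers in the collapsed tables, which
  admit no missing-data category; X/Y sites are treated like autosomes.

## Gene burden test

The per-gene 2×2 carrier table is tested with a one-sided Fisher exact
test for carrier excess in cases: the tail probability of tables at the
observed margins with at least the observed case-carrier count. The tail
is evaluated with exact integer binomial-coefficient arithmetic
(`fractions.Fraction`), so the only rounding is the final conversion to
float; the test suite checks agreement with an independent enumeration
(scipy's hypergeometric survival function) to 1e-12 over every margin
with N ≤ 60.

One-sided is the default because a burden scan asks specifically about
excess in cases; for the reference table (3/13 vs 0/100) the two-sided
value is identical since no opposite-tail table is as extreme. Dominant
carrier coding is the default; allelic (allele-count, CAST-style) coding
is available. Raw p is the headline; BH q-values accompany every scan
because a genome-wide gene scan requires multiplicity control. Full
precision is kept in all tables; the human-readable report rounds to
three decimals.

## Pathway enrichment

Per term: fold = (k/n)/(K/N) and the EASE score — the one-sided exact
tail with the hit count discounted by one (k → max(k−1, 0)) — over a
background that defaults to the gene-set file's full universe. EASE was
chosen over plain Fisher as the default because it is the documented
convention of the functional-annotation tooling this layer mirrors, and
because its conservatism (single-hit terms score 1.0) suits the very
short gene lists these cohorts produce; plain Fisher is a switch.

Term clustering: Cohen's kappa between hit-gene membership vectors over
the analysed gene list; greedy seed groups (every term with kappa ≥ 0.35
to the seed; groups below 3 members discarded) merged whenever two groups
share ≥ 50% of the smaller group's members, to a fixpoint; terms are
processed in lexicographic order so clustering is deterministic. Each
merge strictly reduces the group count, so termination is guaranteed.
Cluster score = −log10(geometric mean of member EASE p). The three
clustering constants mirror commonly documented defaults of the
annotation-clustering tools this reimplements and are all exposed.

Printed enrichment values from any external annotation database depend on
that database's term definitions and background; they are reproducible
only with the same snapshot. This package therefore treats its gene-set
file as the definition of truth and verifies the statistics against
enumeration instead.

## Network degrees

The interaction subnetwork keeps directed edges between input genes, plus
non-input "linker" nodes adjacent (in any direction) to at least two
distinct input genes — i.e. lying on a path of length two between input
genes. Longer indirect paths are excluded: the construction follows the
single-linker wording of the procedure it mirrors. Degree = in + out over
kept directed edges; anti-parallel pairs count twice. Edge direction in
linker paths is preserved as found.

## Synthetic-data generator

The generator emulates the emulated study's design, not real genomes:

| Parameter | Default | Rationale |
|---|---|---|
| `n_cases` / `n_controls` | 13 / 100 | the target study design |
| `n_genes` | 500 | large enough for realistic multiple-testing competition, small enough for fast replicates |
| `variants_per_gene` | 2 (1 + Poisson(1)) | shifted so every gene owns ≥ 1 variant to assign to carriers |
| `background_carrier_prob` | 0.01 | per-gene, per-sample, both arms |
| `planted_genes` | one gene at (0.25, 0.0) | ≈ 3 expected carrier cases of 13, zero controls — the worked-example regime |
| `rare_af_range` | (1e-5, 0.009) | log-uniform; below the 1% threshold |
| `common_contaminant_frac` | 0.1 | variants given common AFs that the rarity stage must remove |
| `deleterious_frac` | 0.3 | fraction of background variants truly damaging; dual-predictor concordant calls are a conservative filter on real exomes |
| `predictor_concordance` | 0.9 | P(D/D) for a truly damaging variant |
| `predictor_false_pos` | 0.05 | P(D/D) for a benign variant |
| `missing_af_prob` | 0.3 | per reference panel: rare variants are often absent ("novel") |
| `panel_overlap_frac` | 1.0 | fraction of control-observed variants copied into the panel |
| consequence mix | 60% missense, 25% synonymous, 5% nonsense, 5% splice, 5% other | ≈ 2:1 nonsynonymous:synonymous, as in rare exonic variation |
| `planted_term_size` | 40 | a large functional class (ion-transport-like); planting acts on membership odds, not term size |
| `planted_term` odds | 6 vs `list_baseline_prob` 0.15 | yields fold ≈ 3 for the planted term, the regime of interest; odds = 1 disables planting entirely |

All draws flow from one seeded generator; a fixed seed reproduces
byte-identical files. Positions live on a single synthetic contig
("chrS") in disjoint per-gene blocks. Variants are SNVs by default; an
`indel_frac` knob exercises the indel paths. Carriers are heterozygous,
matching the carrier-counting semantics (dominant coding never uses
dosage).

With `panel_overlap_frac = 1.0` and the same simulated controls used as
the burden arm, every control-observed variant is panel-excluded and all
control carrier counts collapse to zero — the generator deliberately
reproduces this circular wiring so its consequences are testable; demo
configurations use disjoint sets (`--panel-overlap-frac 0`).

What the generator does *not* emulate: linkage disequilibrium, site
discovery/genotyping error, population stratification, relatedness, gene
length variation tied to real annotation, or a GO-style term hierarchy
(terms are flat, independent draws). Passing recovery tests therefore
show that the statistics detect the planted structure under idealised
sampling, not that the pipeline is robust to those real-data pathologies.

## Numerical choices

* Exact tails via integer arithmetic with an LRU cache keyed on margins;
  cached fractions make genome-scale scans cheap because small-cohort
  tables repeat heavily.
* BH adjustment is the standard step-up with a reverse cumulative
  minimum; ties and input order preserved.
* Kappa is 0 by definition when expected agreement is 1 (two constant
  identical vectors), avoiding 0/0.
* Result tables are written at `%.17g` so a round-trip re-read is exact
  to float precision; identifiers round-trip string-exact.
* Sorting tie-breaks: burden and enrichment results by (p, identifier);
  cluster members lexicographic; all outputs deterministic.

## Problem sizes used in the checks

The oracle sweeps cover every 2×2 margin with N ≤ 60; calibration uses
2000 null genes; recovery uses 200 replicates of the full generator
defaults (500 genes, 13/100 samples). These sizes give stable rates
(binomial SE ≈ 2% at 200 replicates) while keeping a full run in minutes
on one core.

## Known limitations

* The exact test is conservative for discrete data; calibration checks
  assert the type-I rate stays *below* nominal, not near it.
* Planted-burden recovery at the default effect (carrier probability 0.25
  in 13 cases) sits near its design threshold: with ≈ 12.7% probability
  the planted gene realises fewer than two carrier cases and usually
  cannot top a 500-gene scan, so the measured top-rank rate hovers around
  0.90 and individual 200-replicate batches fluctuate a few points either
  side.
* No covariate adjustment, variance-component (SKAT-family) tests,
  relatedness handling, or GO graph propagation; gene-set files are flat.
* The consequence field is taken from the annotation table as-is; no
  consequence prediction is performed.
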