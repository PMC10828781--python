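# Methods

This note documents the models behind `bloodpeach`, the defaults and why,
what the synthetic data does and does not emulate, and the numerical
choices that make results reproducible bit-for-bit.

## Bulked-segregant Euclidean-distance mapping

### Model

Two pools of phenotypically extreme F1 individuals are sequenced; at each
SNP the pools' A/C/G/T read counts are converted to frequency vectors and
contrasted with the Euclidean distance

ED = √(Σ_b (f_mut,b − f_wt,b)²),  b ∈ {A, C, G, T},

which lies in [0, √2], is symmetric, and is zero iff the pools agree.
Raising ED to a power k (default 5) suppresses drift-scale background
relative to linked signal; windowed aggregation (default: mean of ED^5
over 100 kb windows sliding by 10 kb, anchored at position 1, trailing
windows truncated at the chromosome end) smooths read-sampling noise. The
screening threshold is the empirical quantile (default 0.95, linear
interpolation between order statistics, genome-wide; per-chromosome
optional) of all defined window statistics, and maximal runs of
consecutive supra-threshold windows merge into candidate intervals whose
peak is the member window with the highest statistic (ties to the smaller
start).

### Site filter

The GATK-style hard filter is implemented as a KEEP rule: a site is kept
iff DP ≥ 4 and no quality clause fails (QD < 2.0, FS > 60.0, MQ < 40.0,
MQRankSum < −12.5, ReadPosRankSum < −8.0 each reject). Reading "DP ≥ 4"
as a removal condition would discard every adequately covered site, so the
keep reading is the default; the literal remove reading is available
(`dp_is_remove`), as is strict handling of missing annotations
(`strict_missing`; by default missing values pass, since simulated tables
need not carry them). The rejection log records every failing clause per
dropped site, and kept ∪ rejected partitions the input exactly.

### Localization resolution — what the default design can show

The default synthetic design (`SimConfig`: one 10 Mb chromosome, causal
locus at 5 Mb, 100 F1 offspring, bulks of 15, 30× per pool, uniform
1 cM/Mb map with Haldane crossovers) mirrors the modelled study's bulk
sizes and depth. Its mapping resolution, however, is set by the genetic
map length the bulks sample: the pooled frequency contrast decays with
(1 − 2r) of the recombination fraction r to the causal locus, and the
*realized* contrast is exactly constant on the segment around the locus
containing no crossover in any of the 30 informative gametes — at 1 cM/Mb
that segment has a mean half-width of several megabases. Within it the
argmax window is decided by read-sampling noise, so the top candidate
interval identifies the linked chromosome region but not a sub-megabase
position. The recovery rate of the causal position inside the top interval
at the default design is therefore low, and is reported honestly by
`scripts/acceptance.py` (`bsa_top_interval_recovery_rate`). With a denser
map (e.g. `recomb_rate=10`), contrast decays within the chromosome and the
top interval does land on the locus; the test suite exercises end-to-end
recovery in that regime. Real multi-chromosome data provide genuinely
unlinked null windows, which the one-chromosome miniature cannot.

### Depth model

Per site and pool: total depth ~ Poisson(30), base counts ~
Multinomial(depth, pool base frequencies); pool allele frequency is mean
allele dosage / 2 over the bulk members. This is the simplest model
consistent with pooled sequencing: no read-level error profile, no
mapping/reference bias, no GC or coverage waviness. An optional uniform
miscall rate (`error_rate`) mixes ε/4 into each base probability;
`qc_fail_fraction` plants hard-filter failures to exercise the site
filter. Whether "30×" is per pool or combined is not stated in the
modelled design; the simulator treats it as per pool.

## Cross and phenotype simulation

Gametes are sampled per parent with the Haldane mapping function
(r = (1 − e^(−2d/100))/2 for map distance d in cM; independent assortment
across chromosomes), with parental phases taken as given. Phenotypes follow
a dominant-presence model for the blood-flesh trait (any copy of the
element-bearing haplotype → blood flesh; configurable to recessive), since
carriers and non-carriers split perfectly in the modelled populations. The
fruit-development-period (FDP) effect of the element is an ordinal
one-class advancement (9/9 → 60–90, 0/9 → 90–120, 0/0 → 120–150 days from
the 9 bp-insertion genotype, carriers shifted `te_effect_on_fdp` classes
earlier, floored at the earliest class) — the observed pattern is a class
reassignment, not a quantified day effect, so an ordinal shift is the
faithful minimal model.

## LTR-RT presence/absence classification

### Procedure

Intact elements (total length within [2000, 7000] bp inclusive) are
anchored by their 500 bp flanks. The internal aligner is exact-k-mer
seeded (k = 31, 2-bit packed hashes — injective, so seed hits are exact
matches), with candidate loci formed by clustering seed diagonals within
one flank length and scored by ungapped extension at +1/−1. A hit is
unique iff its score is ≥ min_score (default half the flank length) and
exceeds the runner-up by a margin (default 10% of the flank length). Both
strands are searched. The aligner is deliberately simple to keep
desk-scale runs deterministic; `LtrComparison` accepts externally produced
hits per (element, side) for real assemblies, where a production mapper is
the right tool.

Elements are interpretable only when both flanks anchor uniquely, on the
same target contig, same orientation, within 20 kb. The inner gap g
between the anchors then drives the call: g ≤ 1000 bp (anchors adjacent;
the pre-insertion locus) → INSERTION, reported from the query's
perspective (present in query, absent in target); g within ±20% of the
element length → the locus is present and the element body is aligned
(edlib global alignment) against the target span: identity ≥ 95% and
coverage ≥ 95% → HIGH_SHARED, identity ≥ 80% and coverage ≥ 50% →
LOW_SHARED, else ELIMINATION (present but decayed); any other geometry or
failed anchoring → UNKNOWN. The 95/80% split follows conventional
high/low-identity practice; all thresholds are explicit `LtrParams`
fields because the five classes have no canonical numeric boundaries.
Identity is 1 − edit distance / max(length); coverage is the target-span
length as a fraction of the element length, capped at 1.

### Insertion-age dating

The two LTRs of an element are identical at integration; their divergence
dates it. The copies are globally aligned (Biopython PairwiseAligner,
match 2 / mismatch −1 / gap open −5 / extend −0.5), d is the mismatch
proportion over gap-free columns, corrected with Jukes–Cantor
K = −(3/4)·ln(1 − 4d/3), and T = K / (2µ). d ≥ 0.75 is JC saturation and
an error. µ defaults to 1.5e-8 subs/site/year — a common woody-plant
nuclear rate; no rate is canonical for this system, so the value used is
always echoed in outputs. Age is monotone in d with T(0) = 0.

### Genome fixtures

`plant_elements` inserts 5'LTR + internal + 3'LTR with a duplicated
target-site sequence (TSD, default 5 bp — typical for LTR-RTs) and applies
independent point mutations to each LTR copy at `per_ltr_divergence`.
`derive_target_genome` edits a copy of the query per element: keep
(expect HIGH_SHARED), delete_element (element plus one TSD copy removed —
the clean pre-insertion locus; expect INSERTION), degrade_element to a
configured identity (expected label follows the classifier thresholds),
delete_flank (removes the upstream flank; expect UNKNOWN). Truth tables
are written in the output genome's coordinates and are string-equality
consistent with re-extraction. Fixtures space elements ≥ 4 kb apart so
edits cannot disturb a neighbour's flanks; real nested/tandem TE
architecture is out of scope.

## Segregation statistics

Chi-square goodness-of-fit is plain Pearson Σ(O−E)²/E without Yates
continuity correction — the convention that reproduces the printed worked
examples (9/31/19 vs 1:2:1 → 3.54; 36/20/0 vs 1:2:1 → 50.86) exactly.
Critical values come from the inverse regularized incomplete gamma
(scipy's chi-square quantile; df=2 → 5.99, df=1 → 3.84). A class with
expected count 0 and nonzero observations is an error rather than a
silent collapse. The printed 1:1-ratio statistics of the second modelled
cross (4.39, 31.08) are not reproducible from the printed counts by
Pearson with or without correction and are deliberately not asserted.

FDP bins assign boundary values to the earlier class ([60, 90],
(90, 120], (120, 150]); values outside [60, 150] get an explicit
out-of-range sentinel. The haplotype→colour rules map only the observed
combinations (TE present: D1D1+T1T1 → dark, D1D2+T1T1 → blood,
D2D2+T1T1 → light, D2D2+T1T2 → none; TE absent → none always); unobserved
combinations return "unclassified" rather than an extrapolated class.
Carrier ratios report both the exact percentage and the
nearest-integer form such surveys print.

## Numerical and interface choices

- Coordinates are 1-based inclusive throughout; BED conversion
  (0-based half-open) happens only at output boundaries.
- Quantiles use numpy's linear interpolation between order statistics, so
  thresholds are bit-for-bit reproducible.
- Site tables round-trip exactly through TSV (`%.17g` on write,
  round-trip float parsing on read).
- All randomness flows through `numpy.random.Generator` seeded from the
  configuration; identical config + seed gives byte-identical outputs.
- Problem sizes in the test and acceptance runs (10 Mb single-chromosome
  scans, 2 kb SNP spacing, 51 planted elements of 3 kb on a ~360 kb
  contig) are the package's desk-scale defaults, chosen so the full
  pipeline remains exact-checkable against brute-force oracles.

## Known limitations

- No read-level simulation (FASTQ), alignment or variant calling; the
  pipeline starts from allele-depth tables and consumes external callers'
  outputs in real mode.
- The one-chromosome default BSA design cannot localize below the
  megabase scale (see above); passing tests on it demonstrate pipeline
  correctness, not fine-mapping power on real data.
- The flank aligner is ungapped and exact-seeded; highly repetitive or
  indel-rich flanks in real assemblies should be anchored with an
  external mapper and injected via the `anchors` hook.
- The five-way class boundaries are conventions, not estimates; shared/
  specific counts from real assembly comparisons depend on them and on
  assembly quality.
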