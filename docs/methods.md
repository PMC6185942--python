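# Methods

## Genotype encoding

Genotypes are coded per SNP as 0 = missing, 1 = homozygous major,
2 = heterozygous, 3 = homozygous minor.  Major/minor status is decided
from allele counts over fully called genotypes (a half-called pair is
treated as missing in both the encoding and the allele count, so the
major homozygote is never rarer than the minor homozygote in the encoded
column).  An exact 50/50 allele tie breaks to the lexicographically
smaller allele label, making the encoding deterministic and independent
of sample order.  Multi-allelic sites are rejected: the pattern model
below is defined for biallelic loci only.  Monomorphic SNPs are kept at
read time — their tests are degenerate and report p = 1 — and can be
removed with the scan's optional MAF/call-rate pre-filters.

## The eight-pattern model

The scan assumes that a two-locus interaction acts through a complex of
two bio-molecule subtypes, one per locus, with one allele of each locus
producing the subtype that forms the disease-associated complex.  Two
presence conditions are biologically distinguishable: the complex
matters whenever it can form (each locus carries ≥ 1 copy of its
complex allele), or only when it is the sole complex formed (both loci
homozygous).  Four complexes × two conditions give eight black/white
labellings of the 3×3 joint-genotype table — out of the 512 possible
labellings an unconstrained method such as MDR would search over.  The
presence masks are Cartesian products of carrier-genotype sets (4 black
cells); the solo masks are single corner cells.  The set is closed under
transposition, which is the property that makes scanning unordered
pairs (i < j) under all eight patterns equivalent to scanning ordered
pairs (verified by a dedicated test).

Pattern ids are a package convention: presence patterns 1–4, solo
patterns 5–8, complexes ordered (major,major), (major,minor),
(minor,major), (minor,minor).  Missing genotypes lie outside the mask
domain: a sample missing either genotype of a pair contributes to
neither the black nor the white group of that pair.

## Counting: naive and lookup-table engines

Each SNP column is split into a case vector and a control vector; each
vector is packed 4 genotypes per 8-bit word (2 bits per genotype,
little-endian within the word; trailing pad positions carry the missing
code and never count).  A lookup table indexed by (word value, word
value, pattern) stores how many of the four packed positions are
mutually non-missing and black, and how many are white — 8×256×256
entries × 2 counts ≈ 1 MiB, built vectorised in milliseconds at scan
start and optionally persisted as a versioned `.npz` cache.  The
byte-sized word keeps the table cache-resident; the pattern axis is
innermost so the eight counts of a word pair share a cache line in the
hot loop.

The naive engine walks samples directly and is the oracle: the test
suite asserts bit-identical contingency tables and scan outputs from
both engines.  Both inner loops are compiled with numba; the observed
speed-up of the lookup engine at 1000 SNPs is ~3× on one CPU (the
ratio is hardware-dependent and asserted in tests only as > 1).

## Statistics

Pairwise and single-SNP tests use the uncorrected Pearson 1-d.f.
chi-square; no Yates correction, matching the convention of exhaustive
epistasis scans where the closed form is evaluated billions of times.
Degenerate tables (any zero margin) report χ² = 0, p = 1 and a flag, so
rankings never see missing keys.  p-values are computed through the
log-survival function and carried as log₁₀ p alongside the linear
value: a strong pair in a large scan easily passes the double-precision
underflow floor (~10⁻³⁰⁸), and the improvement metric

improvement = min(p₁, p₂) / p_pair

is therefore evaluated in log space.  It is scale-free in the three
p-values.  The odds ratio ad/bc reports ∞ when only the denominator is
zero and NaN when both are.

The default single-SNP p-value is the better ("best-dichotomy") of the
dominant ({hom-major} vs {het, hom-minor}) and recessive ({hom-major,
het} vs {hom-minor}) collapses — exactly the marginal projections of
the eight patterns, so the improvement metric compares the pair against
the strongest marginal signal the pattern family itself could express.
An allelic (2×2 allele-count) test is available as an alternative,
since a plain "1-d.f. single-SNP chi-square" is ambiguous between the
two readings.

When comparing the chi-square p with a permutation p on small tables
(as the test suite does), the permutation *mid-p* (strict exceedances
plus half the ties) is used: the permutation null is discrete with
large point masses, and the continuous chi-square tail approximates the
mid-p, not the inclusive tail.

## The exhaustive scan

All C(m, 2) unordered pairs are tested under the eight patterns;
`count_pairs`/`count_tests` do this bookkeeping in exact integer
arithmetic (at real-GWAS scale the counts exceed 2⁶³⁄₄ and must not go
through floats).  The default significance threshold is Bonferroni,
0.05 / (8·C(m,2)); fixed thresholds such as the 10⁻¹³/10⁻¹⁴ used on
large real datasets are a config option.  Significant results are
deduplicated to one row per pair (its minimum-p pattern; ties to the
lowest pattern id) by default, with an all-patterns mode available.
Rankings by pairwise p (ascending) and by improvement (descending) use
stable sorts with declared tie-breaks: the other key, then
(snp_i, snp_j, pattern_id).  Single-SNP p-values are computed once per
SNP and cached before the pair loop.

Desk-scale scans keep results in memory; the statistic buffer is
8·C(m,2) doubles (~32 MB at 1000 SNPs, ~3 GB at 10000 SNPs), which
bounds the practical single-process scan size.  Distributing the
10¹¹–10¹²-test real-data scans is out of scope.

## Synthetic data

The generator emulates a case-control GWAS: null SNPs are drawn per
sample from Hardy–Weinberg proportions at per-SNP MAFs uniform on
(0.05, 0.5), mutually independent and independent of phenotype (linkage
equilibrium); one SNP pair is planted with a two-level penetrance model
realising a chosen pattern.  With `p_black` the HWE probability mass of
the pattern's black cells and K the prevalence, the two penetrances are

f_black − f_white = √(h²·K(1−K) / (p_black(1−p_black))),  mean = K,

so the broad-sense heritability of the 0/1 disease indicator equals the
requested h² exactly (a plug-back identity tested directly).
Calibration fails explicitly when a penetrance leaves [0, 1].
Ascertainment is retrospective: individuals are drawn from population
genotype frequencies, assigned disease by their group's penetrance, and
accepted until the case and control quotas are met, so sample counts
are exact and the realized case/control genotype frequencies converge
to p_black·f_black/K and p_black(1−f_black)/(1−K) (checked at
n = 50 000).

Defaults: 1000 SNPs, 1000 cases + 1000 controls, planted pattern 1 at
MAF 0.4/0.4, h² = 0.1, prevalence K = 0.25, no missing data.  Only the
SNP-count grid (1000/5000/10000, `benchmark_configs`) is an external
benchmark convention; the rest are this package's declared study
conditions.  K = 0.25 and MAF 0.4 were chosen because presence patterns
have common black groups (p_black ≈ 0.71 at MAF 0.4): on the disease
scale, h² = 0.1 is infeasible at realistically low prevalence
(f_white < 0), so a cohort-style prevalence keeps the whole h² range up
to ~0.15 calibratable for every pattern.  Sample sizes follow the
common "thousands of cases and controls" design of the GWAS datasets
this emulates.

What the simulator does **not** model: linkage disequilibrium and
haplotype structure (so it cannot produce the long-distance-haplotype
false positives that complicate real HLA-region scans), population
stratification, genotyping batch effects, or covariates.  Passing the
recovery tests therefore shows the scan detects a planted two-locus
penetrance signal of the stated size — not that real-data hits are
immune to LD confounding.

## Gene networks

Each SNP of a top-ranked interaction maps to its nearest gene: distance
0 inside a gene, otherwise the gap to the nearer interval end; ties go
to the smaller gene start, then the lexicographic id.  BED input
(0-based half-open) is converted to 1-based inclusive internally; SNP
positions are 1-based throughout — the coordinate dialects are explicit
because mixing them is the classic failure mode.  An SNP-SNP
interaction becomes an edge between the two mapped genes; multiple
supporting SNP pairs collapse onto one edge with a support list and
best-p/best-improvement aggregates; self-loops are flagged and excluded
from exports by default; intersection keeps edges present in both
networks with supports merged.  There is no distance cutoff by default
(an optional `max_distance` drops far SNPs).  Database verification of
edges is a user-supplied concern, not an API call.

## Test and acceptance problem sizes

The stochastic suites run at desk scale, chosen as the package's own
verification design: engine equivalence on 200 random 50-sample pairs
and a full 100-SNP scan; planted-pair recovery on twenty 1000-SNP,
1000+1000-sample replicates at h² = 0.1 (expected to rank the planted
pair first in ≥ 90% of replicates; in practice it wins every replicate
by many orders of magnitude); null-calibration via 200 two-SNP
replicates at h² = 0 (KS uniformity at α = 0.01) and 2000 disjoint null
pairs for the empirical type-I error (disjointness makes the tests
independent, so the binomial error bound applies).  The acceptance
script re-runs pattern enumeration, the exact bookkeeping, the
closed-form statistics, and ten seeded 1000-SNP recovery scans.

## Known limitations

* Biallelic SNPs only; no VCF or PLINK binary input.
* One process, one CPU; no blocked/streamed output for scans beyond
  ~10⁴ SNPs.
* The pattern family deliberately excludes data-driven (MDR-style)
  risk labellings and interactions above second order.
* Nearest-gene assignment is a convention; different annotation
  pipelines (feature sets, tie rules) can map borderline SNPs to
  different genes.
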