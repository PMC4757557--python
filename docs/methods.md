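# Methods

This note documents the models implemented in `aplnet`, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical conventions that make runs reproducible.

## Somatic filter cascade

The cascade applies seven ordered stages to each patient's annotated
variant calls; every stage's output is a subset of its input, so the
per-patient audit counts are non-increasing by construction.

| stage | predicate | defaults |
|---|---|---|
| Variants detected | all caller output | — |
| Somatic | population-database screen: drop calls with catalogued carrier frequency ≥ `max_pop_freq` | 0.01 |
| Absent in CR | matched: remission subtraction; unmatched: VAF-band germinality test | see below |
| High quality | depth ≥ `min_depth`, qual ≥ `min_qual`, strand bias ≤ `max_strand_bias`, VAF ≥ `min_vaf` | 10, 30, 0.9, 0.05 |
| Coding (SNVs+indels) | consequence ∈ {nonsynonymous, stop_gain, frameshift, inframe_indel, splice_site} | keep-set configurable |
| Deleterious (SNVs+indels) | deleterious flag OR truncating consequence | — |
| Unknown in dbSNP | not in the known-variants catalogue | — |

Design choices:

* **Coverage threshold.** "More than 10 reads" phrasings in sequencing
  protocols are used loosely; the package implements depth ≥ 10
  (inclusive) as the default, overridable in `FilterConfig`.
* **Remission absence is thresholded, not literal zero.** A diagnosis call
  counts as absent from the complete-remission (CR) sample when the
  remission record has alt reads ≤ 1 **and** VAF < 0.02 (or the locus is
  unobserved). At ~60× coverage a single stray alt read is within noise,
  so strict zero would misclassify genuinely somatic calls.
* **Variant identity** for subtraction is the normalized
  (chrom, pos, ref, alt) tuple, 1-based VCF coordinates throughout.
  Normalization trims the shared allele suffix, then the shared prefix
  (advancing the position). This is reference-free; full left-alignment
  of ambiguous indels would need the genome sequence, which this pipeline
  (starting from variant calls) does not have.
* **Deleteriousness is consumed, never computed.** The flag comes from
  upstream annotation; truncating consequences (stop gain, frameshift,
  splice site) are treated as deleterious regardless of the flag, since
  predictor tools routinely leave them unscored.
* **The germinality test** for unmatched samples removes calls catalogued
  at population frequency ≥ 0.01 and calls whose VAF falls in a germline
  band: [0.45, 0.55] (heterozygous) or [0.95, 1.0] (homozygous). Both the
  ceiling and the bands are configuration, not doctrine: at 60× coverage
  binomial VAF noise puts only ~63% of heterozygous germline variants
  inside the default band, so the population-frequency screen carries
  most of the removal (≈ 94% combined on the synthetic unmatched cohort,
  where ~85% of germline variants are catalogued). The "Somatic" stage of
  the published-style audit table is not defined by its source (the large
  detected→somatic drop happens inside the upstream caller); here it is
  implemented as the population-database screen, which is the only
  caller-independent part of that step.
* **Ti/Tv** counts transitions (A↔G, C↔T) over transversions among SNVs
  and is reported as *undefined* (not an error) when no transversion is
  present. It is invariant under strand complementation.

## Recurrence enrichment

Carrier semantics: a patient either carries ≥ 1 qualifying variant in a
gene or does not; $k$ is the column sum of the binary patient × gene
matrix. The test is the one-sided exact binomial tail
$P(X \ge k)$, $X \sim \mathrm{Bin}(n, f_0)$, computed through the
regularized-beta survival function (verified against rational-arithmetic
direct summation to < 1e-10 relative error on a $(k, n \le 50, f_0)$
grid). The binomial is the minimal model consistent with asking whether
the cohort frequency exceeds the reference frequency; a one-sided
two-proportion Fisher variant ($k/n$ vs $\lceil f_0 N_{\mathrm{ref}}
\rfloor / N_{\mathrm{ref}}$) is provided for sensitivity analysis.

* **Zero-frequency floor.** Genes catalogued at 0% in a reference of
  $N_{\mathrm{ref}}$ individuals (default 2504) are floored at
  $1/(N_{\mathrm{ref}}+1)$ — the add-one estimate for zero observed
  carriers — so the tail probability never degenerates to 0. The screen
  applies $f_{0,\mathrm{used}} = \max(f_0, \mathrm{floor})$.
* **Multiple testing.** The raw-p convention (raw $p \le \alpha$)
  drives the significance flag; Benjamini–Hochberg q-values are always
  reported alongside for modern use.
* **Units.** Input tables may carry fractions or percentages; the
  distinction is resolved by the column-header token (`frequency` vs
  `frequency_pct`/`%`), never by magnitude heuristics. Internally
  everything is a fraction; report tables print percent.
* Reference frequencies are assumed to be *carrier* (per-individual)
  frequencies. If the source table actually holds allele frequencies the
  test is conservative for rare variants (carrier ≈ 2 × allele frequency
  under Hardy–Weinberg).

## Co-occurrence network

For each unordered gene pair with at least one carrier each, the 2×2
carrier table is tested with the chi-square statistic computed through
the phi-coefficient identity $\chi^2 = n\varphi^2$ (1 df, no continuity
correction); any zero margin gives statistic 0 and $p = 1$. Fisher's
exact test is available both as a method option and as the small-count
cross-check in the test suite.

* **No Yates correction** is the default deliberately: at $n = 25$ the
  correction materially shifts borderline tables, and the uncorrected
  statistic's exact size under an independence null at these margins is
  0.046 at nominal 0.05 (computed by multinomial enumeration; the
  calibration test verifies the simulation matches this number).
  Fisher's exact test would be far more conservative (size ≈ 0.02).
* Edges with $p \le \alpha$ (default 0.05, raw) form the network; each
  edge records the joint-carrier count $a$, the independence expectation
  $n p_1 p_2$, and direction *above*/*below* expected. Node "size" is the
  significant-degree. Ordering is (p, gene1, gene2) with a stable sort,
  making exports deterministic.
* Exports: TSV, SIF and GraphML (sorted node/edge insertion for
  byte-stable files).

## Functional categories

Category labels come from a user-supplied gene → label map over a fixed
vocabulary (ten labels; unmapped genes fall back to "other cell
functions" with a warning). No live ontology is queried — a deliberate
reproducibility choice; the bundled screen table's own labels ship as the
default example map.

* **Burden excess** (gene-count-normalized): hit-events are
  (patient, gene, label) triples; under the expectation model events are
  multinomial over categories with probability proportional to the
  category's gene-label count, and each category gets a one-sided
  binomial margin test. This is the simplest model consistent with
  "more mutated samples than its gene count predicts". Multi-label genes
  count once per label, which inflates cross-category dependence — hence
  a patient-preserving gene-label permutation null (add-one p over
  `n_permutations` shuffles) is available as the model-free alternative.
* **Reference comparison**: per-category carrier rates are compared with
  one-sided two-proportion Fisher tests in both directions; categories
  are labelled more-mutated / less-mutated / indistinguishable at α.
* **Category co-mutation** reuses the chi-square co-occurrence machinery
  on the patient × category matrix and inherits its conventions.

## Minimal connected network and null

Construction: the MCN contains every seed–seed edge, plus every non-seed
node adjacent to ≥ 2 seeds of which at least one pair lacks a direct edge
(the node enters with its seed-incident edges only, so every MCN edge
touches a seed). Intermediates therefore only ever *merge* seed
components; the seed-component partition is the construction's invariant.

Pruning reduces the intermediate set to minimum cardinality while
preserving that partition: exact search over intermediate subsets in
increasing size and lexicographic order when there are ≤ 16 candidates
(deterministic, verified against exhaustive search in the tests), greedy
removal of the most redundant intermediate (fewest seed neighbors,
lexicographic ties) beyond that. After pruning, removing any retained
intermediate changes the partition — an assertable post-condition.

Statistics: `connected_seed_count` (seeds in components of size ≥ 2; the
primary statistic), `components`, and `mean_seed_degree` within the MCN.
The null draws M random seed sets — uniform over interactome nodes by
default, or matched to the observed seeds' log2-degree bins, because
uniform nulls overstate significance for high-degree seed sets — and
scores each through the same construction. Empirical p-values use the
add-one convention $(1+\#\{\mathrm{null} \ge \mathrm{obs}\})/(M+1)$
(reversed for `components`), bounded away from zero.

Numerical conventions worth knowing:

* The partition statistics are invariant to pruning, so null sampling
  skips pruning by default (`prune=False`); `mean_seed_degree` is then
  measured on the unpruned MCN for observed and null alike.
* Calibration of the add-one p-value is demonstrated with
  `mean_seed_degree`, which is nearly continuous. Coarse integer
  statistics (`connected_seed_count` on small seed sets) tie heavily
  across null draws, which makes the add-one p-value conservative —
  correct, but visibly non-uniform under the null. This is a property of
  discrete resampling p-values, not a defect of the sampler.
* Candidates are the seeds that lie in a component of size ≥ 2 of an MCN
  whose null p ≤ α **and** are recurrence-enriched; they are ordered by
  enrichment p-value and annotated with their co-occurrence
  significant-degree. Enrichment-significant genes absent from the
  interactome are reported separately, never silently dropped.

## Synthetic generators: what they emulate, and what they do not

`CohortSpec` draws independent Bernoulli gene columns at background
carrier rates, multiplies planted enriched genes' rates, and realizes
planted co-occurring pairs by *forcing* the stated number of joint
carriers (clearing accidental extras), so the planted joint count is
exact — chosen over copula-style correlation precisely so tests have
exact truth values. Defaults (25 patients, 72 genes, background carrier
rate 0.08) mirror a small targeted-resequencing leukemia cohort whose
recurrences span roughly 8–44%.

`InteractomeSpec` superimposes a densified module (default within-module
edge probability 0.6) on a background $G(n, p)$ graph (default 150 nodes,
p = 0.02, mean degree ≈ 3 — sparse, like a PPI neighborhood).

`generate_variant_fixtures` writes matched diagnosis/remission VCF pairs
in which every variant either survives the cascade or violates *exactly
one* stage's predicate, carrying a truth tag naming that stage, so the
audit's per-stage removals can be asserted equal to the planted counts.
`generate_unmatched_calls` plants a germline fraction with
binomial-sampled VAFs (heterozygous/homozygous) and realistic catalogue
coverage (85% of germline variants carry a population frequency).

Not emulated: mutational signatures, subclonal architecture and VAF
drift, read-level artifacts, linkage between genes beyond the forced
pairs, and scale-free interactome degree distributions. Passing tests on
these generators therefore validate the *statistics and bookkeeping* —
calibration, power at stated effect sizes, exactness of the audit — not
robustness to every artifact of real sequencing data.

Simulation scales used by the validation suite (chosen to give tight
Monte-Carlo error at interactive runtimes): 500 cohorts for type-I
calibration, 500 repetitions × M = 99 for null-uniformity, 200 cohorts
for enrichment power, 100 for end-to-end planted recovery. The recovery
scenario plants 8 genes at carrier rate 0.3 against a reference rate of
0.01 on a 150-node interactome with background edge probability 0.005;
at these sizes the analytical exact-recovery probability is ≈ 0.9.

## Reproducibility

Every stochastic component takes an explicit integer seed
(`numpy.random.default_rng`), recorded in output metadata, null-summary
JSON, and TSV comment headers together with a hash of the configuration.
Graph exports sort nodes and edges before writing. Re-running any command
with identical inputs and seed reproduces outputs byte for byte; the test
suite asserts this end to end.

## Known limitations

* The enrichment test treats patients as exchangeable and genes as
  independent; it does not model gene length, coverage or mutability, so
  long genes can appear "enriched" for reasons a practitioner should
  vet against the co-occurrence and network evidence.
* The co-occurrence test at n ≈ 25 is slightly anti-nominal (exact size
  0.046 at α = 0.05) and raw-p thresholding reports ~5% false pairs by
  design; the BH option is there when error control matters more than
  fidelity to the published convention.
* Greedy pruning above 16 intermediates is not guaranteed
  minimum-cardinality (exact search is exponential); the partition, and
  hence all reported statistics except mean seed degree, are unaffected.
* The audit's "Somatic" stage is caller-dependent in real pipelines; the
  package's population-screen stand-in reproduces the bookkeeping, not
  any particular caller's behavior.
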