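# Methods

This note documents the models, defaults and numerical choices behind the
package, what the synthetic generators do and do not emulate, and the
design decisions that were genuinely open.

## Indel genotyping from junction-spanning reads

The genotyping question is binary — which of two known alleles does a
line carry — so mapping is re-specified as *exhaustive ungapped overlap
alignment* against the two small references (90 bp deletion allele,
139 bp non-deletion allele) rather than a genome-scale mapper. For every
read, every offset (overhangs included) of the read and of its reverse
complement is scored as `matches − penalty·mismatches` over the
overlapping span (penalty 1.0); the maximum-scoring placement wins, with
a deterministic tie-break (smallest offset, forward strand first). This
is exact, dependency-free, and sufficient because the downstream
classification depends only on which reference a read matches and how it
overlaps the junction, not on the mapper.

Classification rules, in order:

1. equal scores on both references ⇒ *uninformative* (the read lies in
   shared flank sequence and carries no indel information; equal-score
   reads are never randomly assigned, preserving determinism);
2. on the winning reference, the aligned span must extend at least
   `min_overlap` bases on each side of the junction point (deletion
   allele) or of the indel interval (non-deletion allele). Defaults:
   15 bp for ≥100-bp reads, 8 bp for short-read cohorts (45–126 bp). Note
   the asymmetry this creates: a read can only support the non-deletion
   allele if it spans the entire 49-bp insert plus both overlaps, so
   reads shorter than 49 + 2·min_overlap bases can never be informative
   for the insertion allele;
3. mismatch rate over the aligned span ≤ `max_mismatch_rate` (default
   0.1 — generous for ≤1% sequencing error, while rejecting spurious
   placements of foreign sequence).

A line is called when the majority allele holds ≥ `majority_threshold`
(default 0.95) of informative reads; `ambiguous` otherwise, `no_data`
with zero informative reads. Under the 95% rule a pooled line segregating
a minor allele above ~5% is excluded by construction, which is the
intended behavior for inbred panels with residual polymorphism. Paired
mates are classified independently (no pair-aware rescue).

Coordinates are 0-based half-open throughout; the genomic location of the
locus (3R:9,783,407–9,784,370, 1-based inclusive) is carried as metadata
only.

## Population genetics

* Frequency: p̂ = (2·n_DelDel + n_DelNon)/2n; all intervals are binomial
  intervals on the chromosome count, so haploid-line surveys enter
  directly as x successes of n lines.
* CI default is Clopper–Pearson (exact beta-quantile); Wilson is a
  switch. The exact interval reproduces the African survey interval
  (5/192 → 0.009–0.060 at 3 decimals), while the interval quoted for the
  older 1-of-20 survey (0.01–0.24) is a Wilson interval — both are
  therefore exposed.
* HWE χ²: expected (np², 2npq, nq²) with p estimated, df = 1 (three
  classes, one estimated parameter), no continuity correction by default
  (Yates optional). The exact test is the Levene–Haldane conditional
  distribution of the heterozygote count given n and the minor-allele
  count, with the p-value summing all outcomes whose conditional
  probability does not exceed the observed one (relative tie tolerance
  1e-9). Because published HWE P-values for these tables are not
  reproducible from the printed counts under a plain χ² (they are closer
  to an exact-test convention), the report always carries both and the
  test suite asserts the implementation against an independent integer
  enumeration oracle, not against published values.
* Fisher 2×2 comparisons use the hypergeometric exact distribution
  (two-sided: sum of tables with point probability ≤ observed); the
  sample odds ratio is reported. No multiple-testing correction is
  applied anywhere, matching the original analysis style.
* The seasonal report pools strata by element-wise summation. The survey
  text and the genotype table disagree about totals (510 flies/1020
  chromosomes vs table sum 614/1228); the table is taken as
  authoritative and the discrepancy is echoed in the report JSON.

## ΔΔCt expression analysis

Technical replicates are averaged per biological replicate and gene;
ΔCt = Ct_target − Ct_reference; ΔΔCt is taken against the mean ΔCt of
the non-deletion (calibrator) genotype *within the same genetic
background*, so per-background fold changes are
2^(mean ΔCt_non − mean ΔCt_del). Amplification efficiency is fixed at 2;
efficiency-corrected variants are out of scope. The two-factor ANOVA
(background × genotype) runs on the per-replicate fold by default —
matching how such experiments are usually displayed — with `log2_fold`
(= −ΔΔCt) and raw ΔΔCt as options, since the scale actually analyzed in
the original work is not stated; Type II sums of squares are used because
25–28 replicates per group is mildly unbalanced (Type II equals the
classical decomposition when balanced, asserted in the tests). η² is
SS_term over total centered SS. With an empty design cell the interaction
is dropped with a warning.

## Survival association

The Cox proportional-hazards fit maximizes the log partial likelihood by
Newton–Raphson (step halving, max 50 iterations, convergence at
max|gradient| < 1e-7 or |Δloglik| < 1e-9), with Efron's tie correction by
default and Breslow as a switch; with no ties the two coincide (asserted
numerically). Risk-set sums are accumulated in decreasing time order so
memory is O(p²) in the number of covariates. Standard errors come from
the inverse observed information; per-covariate tests are Wald. A
monotone likelihood (complete separation) is flagged rather than raised.
Covariates are centered for conditioning (the partial likelihood is
invariant to constant shifts of the linear predictor).

"Line as a factor" deserves a caveat. Genotype is constant within line,
so with treatment-coded line indicators the genotype column is linearly
dependent on them; like R's model fitter, the implementation drops
aliased columns in order (covariates take precedence over line dummies)
and flags them. The surviving genotype coefficient is then identified
only through the contrast between the aliased line and the reference
line — a single line pair — so in a generator with no line-level hazard
heterogeneity it has essentially no power. The per-agent contrast
therefore reports the sex + genotype model for the genotype test, with
the full line-factor model (and stratification by line) available and
exercised in the analysis driver. Lines with a single expression
replicate in either sex are excluded from the panel before analysis.

Expression–survival association is the Spearman rank correlation
(mid-ranks for ties, t-approximation for the p-value), computed on
observed survival times; censoring is ignored in the correlation, as in
the original analysis.

## Neighbor joining, bootstrap and admixture

Distances are p-distances with pairwise deletion: for each pair, the
proportion of differing sites among columns where both sequences carry an
unambiguous nucleotide (gaps and N excluded per pair). Jukes–Cantor
(−3/4·ln(1 − 4p/3)) and complete deletion are switches, since the
distance model behind the original tree is unstated. NJ is the
Saitou–Nei agglomeration under the Studier–Keppler criterion with
deterministic tie-breaks (first minimum in row-major order = smallest
index pair); negative branch lengths are clamped to zero with the
deficit moved to the sister branch; with additive input the generating
tree is recovered exactly (property-tested on random additive matrices
and cross-checked against scikit-bio's NJ).

Bootstrap support resamples alignment columns with replacement
(multinomial column weights; per-pair difference/comparability counts are
precomputed as matrices so each replicate's distance matrix is two
matrix–vector products), rebuilds the NJ tree per replicate, and counts
internal bipartitions keyed by leaf set (orientation- and
rooting-independent). Supports are percentages mapped onto the reference
tree's internal edges. Outgroup rooting places the root halfway along
the branch to the outgroup's most recent common ancestor; a
non-monophyletic outgroup triggers a warning and roots at the edge that
best separates it.

`is_admixed(tree, focal, source)` returns true iff some internal edge
has a side S with focal ⊆ S ⊆ focal ∪ source that contains at least one
source taxon — i.e. the focal haplotypes attach inside (or sister to)
the source population rather than among their own. Requiring a source
taxon in S prevents a trivially monophyletic focal set, sitting inside
its own population's clade, from counting as admixed. The
best-supported qualifying edge is reported.

## Synthetic data: what it emulates, and what it does not

All generators draw from numpy's PCG64 via explicit seeds; the same seed
reproduces every output byte-for-byte, and per-stage salts keep the
streams independent.

* **Reads**: the chosen allele is embedded in a 2 kb random genomic
  context (only locality matters for a junction classifier), read starts
  are uniform, and the `coverage` parameter is the expected number of
  junction-overlapping reads per line. Substitution errors only, at a
  uniform per-base rate; constant quality strings (qualities are never
  used downstream). Mixed templates (`mixed(f)`) draw each read's allele
  independently — residual polymorphism in a pooled line. Not emulated:
  realistic error profiles, indel sequencing errors, PCR duplicates,
  coverage biases. Passing tests therefore demonstrate the
  classification logic, not robustness to real instrument artifacts.
* **Genotype counts**: one multinomial draw with probabilities
  (p² + Fpq, 2pq(1−F), q² + Fpq); infeasible (p, F) combinations are
  rejected.
* **qPCR**: per biological replicate, reference Ct ~ N(baseline_ref,
  bio_sd) and target Ct ~ N(baseline_target − effect·[deletion], bio_sd),
  independent between genes; technical replicates add N(0, tech_sd).
  Defaults encode the two-background study conditions: effects
  log2(1.85) (M12) and log2(1.20) (M9), 25 biological × 2 technical
  replicates, bio sd 0.3, tech sd 0.1 cycles.
* **Survival panel**: 150 lines × 2 sexes × 2 agents × 5 replicate
  flies; exponential baseline (mean 48 h — any baseline is valid for a
  Cox recovery test since the model is baseline-free) with multiplicative
  hazard ratios: deletion 0.6 on MSB and 1.0 on paraquat, male 0.7;
  administrative censoring at 480 h. Line-level log2 expression with
  sex-specific deletion effects log2(1.33)/log2(1.40), male-biased
  expression log2(1.67), two replicates per line × sex. No line-level
  hazard frailty and no genotype–expression-independent pathway, so the
  expression–survival correlation arises purely through genotype.
* **Admixed alignment**: ancestral uniform-random sequence; population B's
  founder is the ancestor mutated at the divergence rate (each selected
  site replaced by a uniform different base); every haplotype adds
  per-sequence substitutions at diversity/2 so the expected
  within-population pairwise distance ≈ diversity; migrants are drawn
  from the B founder but labelled population A; outgroups diverge at
  15%. The closed-form pairwise-distance expectation of this process is
  asserted in the tests. Defaults: 20+20 haplotypes, 15 kb, 5%
  divergence, 0.5% diversity, 5 migrants, 2 outgroups. This is a
  substitution-only stand-in — no coalescent genealogy, recombination or
  back-migration — sufficient for a clustering signal, not for inference
  about real demography.

## Problem sizes and runtime

The default test suite runs everything at the sizes above; the largest
computations are the 20-seed × 50-line error-rate cohort (≈1 s per
cohort) and the full 15 kb, 1000-replicate bootstrap (≈25 s), keeping
the suite under two minutes on one CPU. The per-agent Cox contrast test
uses 40 lines × 5 replicate flies, which gives the genotype Wald test
near-complete power at hazard ratio 0.5 while keeping each fit fast.
The acceptance script reruns the qPCR recovery (20 seeds) and the full
bootstrap analysis and completes in well under a minute.

## Known limitations

* The aligner is ungapped; a read carrying a true indel sequencing error
  across the junction would lose score rather than be realigned.
* The exact HWE test enumerates heterozygote counts — fine for any
  realistic sample, but O(n) per table.
* The Cox implementation targets panels of at most a few hundred
  covariates (dense O(p²) information matrix).
* Bootstrap supports are attached to clades of the reference tree only;
  splits absent from it are counted internally but not reported.
* The admixture verdict is topological; it uses no branch-length or
  f-statistic evidence.
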