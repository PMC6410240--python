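# mtna

Population-genetic and functional analysis of a 49-bp insertion/deletion
(indel) polymorphism in the 3' UTR of the *Drosophila melanogaster*
*Metallothionein A* (*MtnA*) gene.

The deletion allele is near fixation in temperate populations, rare in the
ancestral sub-Saharan range, and associated with higher *MtnA* expression
and better tolerance of some oxidative stressors. This package implements
the computational stages of that analysis as a tested, reusable pipeline,
together with a synthetic-data generator so every stage runs — and is
verified — without access to the original sequencing archives or
phenotype databases:

1. **Read-based indel genotyping** (`mtna.genotyping`). Short reads are
   aligned exhaustively (ungapped, both strands, every offset) against a
   dual reference: the deletion allele (90 bp = 49 bp upstream + 41 bp
   downstream flank joined at the junction) and the non-deletion allele
   (the same flanks with the 49 inserted bases). A read is *informative*
   only if it spans the junction, or the whole indel interval, with ≥
   `min_overlap` aligned bases on each side (15 bp for ≥100-bp reads, 8 bp
   for short-read cohorts). A line is called for an allele when ≥ 95% of
   its informative reads agree; otherwise it is `ambiguous` and excluded —
   e.g. 1 deletion-supporting vs 18 non-deletion-supporting reads gives
   18/19 ≈ 0.947 < 0.95.
2. **Population genetics** (`mtna.popgen`). Deletion-allele frequency
   p̂ = (2·n_DelDel + n_DelNon)/2n with Clopper–Pearson (exact) or Wilson
   (score) binomial intervals on the chromosome count; Hardy–Weinberg
   tests both as the χ² goodness-of-fit against (np², 2npq, nq²) with
   df = 1 and as the Levene–Haldane exact test on the conditional
   distribution of the heterozygote count; two-sided Fisher exact tests
   between samples; a stratified seasonal report. The Munich genotype
   count tables ship with the package.
3. **qPCR relative expression** (`mtna.qpcr`). Classic ΔΔCt with
   amplification efficiency 2: ΔCt = Ct_target − Ct_reference per
   biological replicate (technical replicates averaged first), calibrated
   against the non-deletion genotype within the same genetic background;
   fold = 2^(−ΔΔCt). Two-factor ANOVA (background × genotype, Type II SS)
   and one-way variance explained (η²).
4. **Genotype–phenotype association** (`mtna.assoc`). Student's t test
   and fold change 2^Δmean on log2 expression; Spearman rank correlation
   between expression and stress survival; a Cox proportional-hazards
   model fit by Newton–Raphson on the partial likelihood with Efron
   (default) or Breslow tie handling, covariates sex + genotype (+ line as
   treatment-coded factors or strata), Wald tests per covariate. The Cox
   fit is cross-validated against `lifelines` in the test suite.
5. **Admixture detection** (`mtna.phylo`). Pairwise p-distances with
   pairwise deletion of gaps (Jukes–Cantor optional), Saitou–Nei neighbor
   joining with the Studier–Keppler criterion
   Q(i,j) = (n−2)d(i,j) − Σₖd(i,k) − Σₖd(j,k), bootstrap support from
   column resampling mapped onto internal edges by bipartition, outgroup
   rooting, and an explicit admixture test: do focal haplotypes (African
   deletion carriers) form a clade with the source population (European
   haplotypes) to the exclusion of their own population?

## Worked example

The numbered scripts under `analysis/` run the full story on packaged
tables and synthetic data, writing tables under `results/`:

```bash
python analysis/01_popgen_survey.py
```

```
Munich pooled deletion frequency: 0.91 (95% CI 0.89-0.92, 1228 chromosomes)
  no change since the 2005 sample (Fisher P = 1.00)
  smallest pairwise Fisher P between collections: 0.57; between sexes: 0.37 -> no seasonal or sexual turnover
  smallest exact HWE P across collections: 0.15 -> no heterozygote excess
Zambia (Siavonga, haploid): 0.026 (95% CI 0.009-0.060); Kafue: 0.000 (upper 0.195)
```

Summing the four seasonal Munich collections gives genotype counts
(510, 96, 8), hence p̂ = 1116/1228 ≈ 0.9088 — a deletion frequency of
0.91 that is stable across seasons, years and sexes, with genotype
frequencies consistent with Hardy–Weinberg equilibrium (no heterozygote
excess, hence no sign of overdominance). In the African haploid survey
the deletion is rare (5 of 192 genomes, exact 95% CI 0.009–0.060).

```bash
python analysis/05_admixture_tree.py
```

```
deletion-bearing 'African' haplotypes cluster with the European sample: True
bootstrap support of the {migrants + source population} clade: 100% of 1000 replicates
```

In a simulated 15 kb alignment (two populations of 20 at 5% divergence,
0.5% within-population diversity) where the five deletion-bearing
"African" haplotypes are actually recent European migrants, the NJ tree
places them inside the European clade with 100% bootstrap support — the
signature used to conclude that the deletion's presence in Africa
reflects recent admixture rather than ancestral variation.

The remaining scripts cover simulated-cohort genotyping with
residual-polymorphism exclusion (`02`), ΔΔCt fold-change estimation and
the background × genotype ANOVA (`03`), and the expression/survival
association panel with the per-agent Cox contrast (`04`).

A `mtna` command-line tool exposes the same stages
(`mtna simulate|genotype|popgen|qpcr|assoc|phylo|report`); every run
writes a JSON provenance record with its parameters and seed.

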