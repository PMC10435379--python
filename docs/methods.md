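# Methods notes

This note records the models behind `qcpop`, the parameters that matter, the
numerical choices made where a published rule under-determines an
implementation, and what the synthetic cohorts do and do not establish.

## Synthetic cohorts

The simulator is a *stated world*, not a fit to any real dataset. Its job is
to produce data with exactly the structure each detector assumes, plus truth
labels, so that recovery can be measured.

**Allele frequencies.** Ancestral frequencies are Uniform(0.05, 0.95). A
north and a south "pole" frequency are drawn from the Balding-Nichols
distribution Beta(p(1−F)/F, (1−p)(1−F)/F) around the ancestral value with
`fst_ns` (default 0.02); each region's frequency is a second Balding-Nichols
draw (`fst`, default 0.01) around the latitude-interpolated cline value.
This yields discrete regional clusters whose leading principal component
tracks latitude — the qualitative geography of a multi-region cohort —
without attempting realistic LD.

**Genomes.** Two autosomes plus chrX, 100 Mbp each at 1 cM/Mbp by default;
sites are independent apart from planted blocks. Founders are drawn in
Hardy-Weinberg equilibrium within region; offspring arise by
gamete-dropping: per chromosome, a Poisson(L/100) number of crossovers
placed uniformly in genetic distance, a random starting haplotype per
gamete. An `unlinked` mode (free recombination) serves the independent-SNP
estimator checks. Males are haploid 0/2 on chrX.

**Planted artifacts and their defaults.**
- *Long-range-LD blocks*: within a block, founder haplotypes are drawn from
  a pool of 4; this produces the loading inflation on leading PCs that real
  long-range LD produces, which is all the detector needs. LD beyond the
  block is absent, so a green recovery test says the detector finds
  loading-inflated intervals — not that it would segment real LD
  architecture perfectly.
- *Plate effects*: two injection models. `af_shift` (default) resamples the
  plate's genotypes from Hardy-Weinberg at a frequency shifted by δ — a
  gross calling failure, detectable by the dosage regression. `miscall`
  flips heterozygous calls into the minor homozygote with probability δ — a
  cluster-boundary failure that leaves the dosage mean nearly unchanged and
  is only detectable by the genotype-class (2-df) test plus cluster
  metrics. The magnitude distribution of real plate effects is unknown; δ
  is a free parameter, and affected (probeset, batch) pairs additionally get
  FLD drawn in (3, 7.5), HetSO in (0.3, 0.6), HomRO in (1, 3).
- *Karyotypes*: mean chrX log-R-ratio shifts of −0.6 (XO), −0.3 (mosaic
  XO), +0.4 (XXX) with SD 0.05 noise; B-allele-frequency het bands at
  {1/3, 2/3} for XXX, {0.35, 0.65} for mosaics, none for XO; the chrY/chrX
  intensity ratio clusters at 2.0 (XY), 0.4 (XX), 1.2 (XXY), 0.55 (XO).
  These separations are generous relative to a real intensity pipeline;
  karyotype-recovery results certify the decision logic, not robustness to
  noisy intensity extraction.
- *Duplicates*: well H12 of each plate is a duplicate of well D1 of the
  previous plate (the plate-tracking design); repeat-participant duplicates
  can be added anywhere.
- *Boxes and ascertainment*: samples map to storage boxes (default 24 per
  box); exactly `box_full_selection_fraction` of boxes are fully genotyped,
  and all disease cases from the remaining boxes are individually added,
  which over-represents cases among genotyped samples the way nested
  case-control selection does.

Determinism: one `numpy.random.Generator` seeded from `SimConfig.seed`
drives everything; identical configs give byte-identical outputs.

## Variant QC

The plate (batch) test regresses plate (batch) membership — each plate in
turn as "case" against the rest of its batch — on genotype, with recruitment
region indicator covariates, and evaluates the genotype term by a
likelihood-ratio test. Two encodings are provided because they have disjoint
blind spots: the 1-df allelic dosage is standard and powerful against
frequency-scale artifacts, but a het→hom miscall that halves the het rate
moves the dosage mean by only ~δ·P(het)/2 and is essentially invisible to
it; the 2-df genotype-class encoding (heterozygote and minor-homozygote
indicators) sees the class counts directly. All regressions run through one
vectorised Newton solver (`_logistic.py`) that fits every variant
simultaneously (covariate-block Hessians via a single GEMM per iteration),
reproduces per-variant `statsmodels` fits to machine precision, and falls
back to a Jeffreys-penalised (Firth) fit under separation.

Fail rules are applied exactly as stated (hard 1e-10; more than 3 plates at
1e-4; 1e-8 with all three cluster metrics degraded; batch limits 2/7 for
array versions 1/2). The manual cluster-plot review tiers cannot be
automated faithfully; they surface as `review` flags so that nothing in the
band passes silently.

Hardy-Weinberg: per region a 1-df genotype-count chi-square; the statistic
is the sum over regions referred to chi-square with df = number of
contributing regions (a region contributes only when it has ≥ 2 genotyped
samples and is polymorphic — the reduced-df convention). ChrX uses females
only. A per-region mid-p exact test is available as a secondary column; only
the chi-square sum has a defined multi-region combination.

Strand-ambiguous (A/T, C/G) variants are compared to the reference without
flipping only when both MAFs are below 0.4, else dropped as ambiguous — the
conservative default when strand cannot be resolved by frequency.

## Sample QC

Heterozygosity is standardised within recruitment region (the north-south
heterozygosity gradient spans more than 1 SD, so a global Z would mask
regional outliers). Low-het samples are rescued when their total ROH is
extreme for the region (ROH-Z ≥ 2): autozygosity, not assay failure.

The ROH caller is windowed: a variant is run-compatible when some covering
window of 50 variants holds ≤ 1 heterozygote and ≤ 5 missing calls; maximal
compatible stretches are reported when they span ≥ 1000 kb and ≥ 50
variants with no gap above 1000 kb. Only the 1000 kb floor is anchored in
the published workflow; the remaining parameters are the cited toolchain's
defaults and are exposed in `RohParams`. Boundaries extend into
chance-homozygous flanking variants by a geometric number of sites (mean
≈ 2 at 50% heterozygosity) — the same behaviour as the reference
implementation of this algorithm family.

Sex inference learns its thresholds from the data (2-component Gaussian
mixture on (F, chrY/chrX ratio)) rather than fixed cutoffs. The chrX
aneuploidy screen standardises mean chrX LRR over reported females with
*robust* location/scale (median/MAD): at desk scale the planted aneuploids
are a visible fraction of all females and would otherwise inflate the
screening SD (in a 100k-sample cohort this choice is immaterial). "BAF
consistently different from 0.5" is operationalised as median |BAF − 0.5| >
0.08 over ≥ 30 het-informative probes; XXX requires the het values to sit
closer to {1/3, 2/3} than to 0.5.

Plate rotation: a plate with ≥ 2 sex-informative mismatches is declared
`rotated_180` iff the 180° well permutation (r, c) → (R+1−r, C+1−c) removes
*all* of them; anything unexplained leaves the block `unresolved` for
wholesale exclusion.

## Relatedness

The method-of-moments estimator inverts the per-variant P(IBS | IBD)
expectations under known allele frequencies, clips negative components to
zero and renormalises (pre-clip values are retained for audit). Clipping
biases null PI_HAT upward by O(1/√m) (≈ 0.016 at 10k SNPs) — documented
rather than corrected, as in the reference implementation. KING-robust
kinship is (N_het,het − 2·N_opp-hom)/(N_het,i + N_het,j).

`expected_ibd` takes a relationship as a set of independent pedigree
connections, each `(meioses, shared ancestors, side)`. Kinship adds across
connections (φ = a·2^−(m+1) each) and E[PI_HAT] = 2Σφ exactly, by linearity.
For the Z components, IBD through distinct ancestor couples at a single
locus is treated as mutually exclusive (one ancestral lineage per allele),
so per-parental-side sharing probabilities add; a full-sibling couple
connection spans both sides. Gene-dropping Monte-Carlo oracles in the test
suite confirm these expectations for every relationship in the battery.

The third-degree band is kinship ∈ (0.0442, 0.0884] (standard degree bins);
the published rules only pin the 0.05 unrelated cutoff. The unrelated set is
greedy: repeatedly remove the sample in the most above-cutoff pairs (ties:
lower call rate, then id); on all random graphs ≤ 15 nodes in the test
fixture the result is maximal (no removed sample can be added back).

## Structure

PCA standardises each variant by mean 2p̂ and scale √(2p̂(1−p̂)), zeroes
missing values after centring, and takes a truncated SVD; loadings are right
singular vectors so projection is a single matrix product, and the training
set reprojects onto its own scores to < 1e-8 relative error.

The LRLD HMM: per PC, loadings are standardised over the current variant
set and a two-component scaled-χ²₁ mixture is fitted to Z² by EM (null scale
fixed at 1; inflated scale free with floor 3; weight free). Two guards
determine whether a PC is scanned at all: the EM must not collapse, and the
two-component fit must beat the single-component null by a BIC margin
(2 extra parameters) — without this gate, chance clusters of large Z² on a
genuinely null PC produced false regions in ~8% of tracks; with it, 0/200
null tracks yield regions while planted-block recovery is unchanged.
Emissions use the *equal-prior* posterior f₁/(f₀+f₁) of the inflated
component: the in-region prior belongs to the HMM's stationary distribution
(π_in = 0.05) and transition kernel (switch mass 1 − exp(−ρΔd), ρ = 1/cM,
split to balance the prior), and must not be double-counted in the
emissions — with the mixture-posterior emissions the planted-block Jaccard
drops from ≈ 0.97 to ≈ 0.18. Variants at posterior > 0.5 form runs;
boundaries extend to the midpoint toward the neighbouring variant; runs
closer than 1 Mbp merge. The iteration re-estimates the informative-PC
count each round (BIC, multinomial on region) and scans one PC beyond it as
a control, stopping when a full round finds nothing new.

Regional outliers use the minimum covariance determinant (75% support) on
the informative PCs; the squared-distance cutoff is the χ²_k quantile
matching the two-sided 3-SD tail mass (0.0027), so "3 SD" keeps its univariate
meaning in k dimensions and the null flag fraction stays below 2% (MCD
inflates distances slightly). Singular scatter falls back to per-PC |Z| > 3.

Pairwise Fst is the Weir-Cockerham variance-components estimator with r = 2,
ratio-of-sums across variants, negative estimates reported as computed. On
Balding-Nichols data (20k variants, 200 per region) it recovers F = 0.02
within 10% relative bias.

## GWAS preparation

The association scan is an ordinary per-variant logistic regression (Wald
p, Firth fallback on separation) and is labelled
`logistic_firth_standin` in its output: it stands in for saddlepoint-
corrected mixed-model software whose contribution (relatedness adjustment at
biobank scale) is out of scope here. The covariate recipe — array version,
sex, age, age², region indicators, leading PCs — is the caller's to supply;
the null calibration test holds λ_GC within [0.95, 1.05] at 20k variants.
Meta-analysis is fixed-effect inverse-variance with Cochran's Q and I²;
MAC_eff and the representative-subset rule are exact arithmetic on their
printed formulas. Sex-restricted ICD-10 codes are restricted *before* the
≥ 100-case check (the other order would admit codes that lose their
controls' sex balance).

## Known limitations

- No realistic LD: pruning and clumping are exercised on block-copied or
  duplicated-column genotypes, not coalescent haplotypes.
- The simulator's intensity summaries (DQC, LRR, BAF, ratio) are drawn from
  the cluster means directly; there is no probe-level intensity model.
- Imputation, phasing, mixed-model association and external annotation are
  out of scope; an `info` column is accepted as given.
- Within-region pairwise relatedness scans scale quadratically in region
  size; the full-scan option is intended for desk-scale synthetic cohorts.
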