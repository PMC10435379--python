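# qcpop

Genotype-array quality control and population-structure analysis for large
multi-region biobank cohorts, with a synthetic-cohort simulator that plants
every artifact class the pipeline is meant to catch.

Community-based biobanks recruited across geographically diverse regions
produce genotype data with three awkward properties at once: technical
artifacts structured by the genotyping process (plates, batches, sample
boxes), extensive cryptic and not-so-cryptic relatedness (families recruited
together, historical consanguinity), and strong population stratification
(discrete regional clusters on a north-south cline, long-range-LD regions
that distort principal components). `qcpop` implements the QC decision rules
and population-genetics machinery for this setting as a tested, reusable
Python library with a thin CLI, and ships a simulator so that every detector
can be scored against planted ground truth.

## What is implemented

**Variant QC** — initial plate QC (DQC < 0.82, QC call rate < 97%, plate mean
call rate < 98.5%); per-plate and per-batch genotype-calling deviation tests
(logistic regression of plate/batch membership on genotype, recruitment
region as covariate, likelihood-ratio test; 1-df dosage or 2-df
genotype-class encodings) with the empirical fail rules
(min p < 1e-10; more than 3 plates at p < 1e-4; p < 1e-8 with degraded
clustering metrics FLD < 8, HetSO < 0.68, HomRO < 3.7; review tiers are
carried as flags, never silent passes); region-stratified Hardy-Weinberg
testing (per-region 1-df chi-square summed, df = contributing regions,
fail at p < 1e-6); reference allele-frequency discordance (|MAF difference| >
0.2 after allele harmonisation with strand flips); duplicate-probeset
resolution by call rate.

**Sample QC** — region-standardised heterozygosity (Z > +3 excluded;
Z < −3 rescued when total runs of homozygosity explain it: ROH-Z ≥ 2);
a windowed ROH caller (PLINK-style, ≥ 1000 kb); sex inference from chrX
heterozygosity F and the chrY/chrX intensity ratio (2-component Gaussian
clusters); chromosome-X aneuploidy karyotyping from mean LRR and BAF
het-band structure (XO, mosaic XO, XXX, XXY-like, structural); plate
180°-rotation tracing from sex-mismatch patterns; ancestry outliers on
reference-projected PCs (> 10 SD); duplicate discovery at PI_HAT > 0.95 on a
thinned variant set; a consolidated exclusion ledger.

**Relatedness** — method-of-moments IBD (Z0, Z1, Z2, PI_HAT =
Z1/2 + Z2) and KING-robust kinship; threshold classification (first degree
> 0.375, second degree > 0.1875; parent-child at Z0 < 0.05 and Z1 > 0.5 with
the parent the older of the pair); analytic pedigree expectations for
arbitrary multi-connection relationships (triple second cousins: PI_HAT =
3 × 2⁻⁵ = 0.09375); family-graph assembly (sibling cliques, trios,
three-quarter-sibling review flags); greedy unrelated-set selection at
kinship cutoff 0.05.

**Structure** — sliding-window LD pruning; PCA on standardised genotypes
with projection by variant loadings; BIC-based informative-PC selection
(multinomial for region, bivariate linear for latitude/longitude, binary);
an iterative long-range-LD detector in which a two-state HMM runs along each
chromosome (transitions proportional to recombination distance, emissions
from a two-component scaled-χ² mixture on squared loading Z-scores,
variants at posterior > 0.5 grouped and regions closer than 1 Mbp merged),
removing detected regions and repeating the PCA until the leading
informative PCs — and one non-informative control PC — are clean; robust
Mahalanobis (MCD) regional ancestry outliers at 3 SD; within-region local
PCA; pairwise Weir-Cockerham Fst.

**GWAS preparation** — the population-representative subset (samples from
storage boxes with ≥ 40% of members genotyped, which removes nested
case-control over-ascertainment); the effective minor-allele-count filter
MAC_eff = 2·MAF·info·N_eff with N_eff = 4/(1/N_cases + 1/N_controls),
threshold 20; ICD-10 case definition (≥ 100 cases, sex-restricted codes);
a per-variant logistic association scan with Firth fallback (a labelled
stand-in for biobank-scale mixed-model software); fixed-effect
region-stratified meta-analysis with Cochran's Q / I²; LD clumping
(p1 5e-8, 5000 kb, r² 0.05, p2 0.05).

**Simulator** (`qcpop.simulate`) — hierarchical Balding-Nichols allele
frequencies over 10 regions on a north-south cline; families by
gamete-dropping with recombination on a genetic map; planted LRLD haplotype
blocks, plate-level calling artifacts with degraded cluster metrics,
aneuploid karyotypes expressed in chrX calls/LRR/BAF, intentional duplicates
at fixed plate positions (H12 ↔ previous plate's D1), box-level genotyping
selection with case over-ascertainment — all recorded in a `TruthLabels`
object for recovery tests.

## Worked example

```python
import numpy as np
from qcpop.relatedness import estimate_ibd, expected_ibd, classify_relationship
from qcpop.simulate import simulate_relationship_pairs

z0, z1, z2, pi = expected_ibd([6, 6, 6])   # three second-cousin connections
print(f"triple second cousins: expected (Z0, Z1, Z2) = "
      f"({z0:.4f}, {z1:.4f}, {z2:.4f}), PI_HAT = {pi}")

a, b, freqs = simulate_relationship_pairs("full_sib", n_pairs=200,
                                          n_snps=10_000, seed=1)
ests = [estimate_ibd(a[k], b[k], freqs, min_overlap=1000) for k in range(200)]
pi_hat = np.array([e.pi_hat for e in ests])
print(f"200 simulated full-sib pairs: mean PI_HAT = {pi_hat.mean():.4f} "
      f"(sd {pi_hat.std(ddof=1):.4f})")
calls = [classify_relationship(e).call for e in ests]
print(f"classified as full_sibling: {calls.count('full_sibling')}/200")
```

prints

```
triple second cousins: expected (Z0, Z1, Z2) = (0.8203, 0.1719, 0.0078), PI_HAT = 0.09375
200 simulated full-sib pairs: mean PI_HAT = 0.5002 (sd 0.0089)
classified as full_sibling: 200/200
```

The analytic 0.09375 is the consanguinity peak that appears between the
second-degree (0.25) and third-degree (0.125) peaks in pairwise-IBD
histograms of populations with a history of cousin marriage; the full-sib
mean of 0.50 is the first-degree peak, and every simulated pair lands in
the correct classification band.

The same machinery is available from the shell:

```bash
qcpop simulate --out cohort/ --seed 3
qcpop relatedness --bfile cohort/cohort --manifest cohort/samples.tsv --out rel/
qcpop variant-qc --bfile cohort/cohort --manifest cohort/samples.tsv \
    --metrics cohort/cluster_metrics.tsv --out vqc/
qcpop pca-lrld --bfile cohort/cohort --manifest cohort/samples.tsv \
    --map cohort/map.tsv --out pca/
```

## Acceptance script

`scripts/acceptance.py` recomputes the package's headline relatedness
quantities from scratch: the closed-form expected IBD proportion of triple
second cousins, and the method-of-moments (Z0, Z1, Z2, PI_HAT) summaries for
freshly simulated full-sibling, parent-offspring, half-sibling and duplicate
pairs (200 pairs each, 10,000 independent SNPs, gamete-dropping with true
allele frequencies; duplicates carry 0.5% independent genotyping error).

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

```
src/qcpop/
  data.py         GenotypeDataset, GeneticMap containers
  io_plink.py     PLINK1 bed/bim/fam codec
  simulate.py     synthetic cohorts + truth labels
  variant_qc.py   plate/batch/HWE/reference-frequency variant QC
  sample_qc.py    het/ROH/sex/karyotype/rotation/duplicate sample QC
  relatedness.py  IBD, kinship, relationship calls, families, unrelated sets
  structure.py    LD pruning, PCA, LRLD HMM, outliers, Fst
  gwas.py         subsets, MAC_eff, association stand-in, meta, clumping
  _logistic.py    vectorised logistic scans (shared engine)
  cli.py          thin click CLI
docs/methods.md   model and procedure notes
tests/            pytest suite incl. acceptance checks
```
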