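# stepstone

Coalescent demographic inference and SNP-panel population genomics for
fragmented population systems, built around a five-population
stepping-stone model with admixed "stepping-stone" populations.

Endangered species that persist as chains of isolated habitat patches —
here, a system of five genetic clusters (SW, SE, C, NC, N) along a
south-to-north montane arc — pose two linked questions: *where did the
populations come from* (origin, dispersal order, admixture) and *how
structured are they today* (differentiation, diversity, isolation by
distance).  `stepstone` implements the full analysis chain for both, from
raw genotypes to ranked demographic models, exercisable end to end on
synthetic data with known truth.

## What it computes

**Demographic inference.**  Demographic models are backward-time event
programs (splits, admixture pulses, migration epochs) over labelled
demes.  Eight named between-cluster scenarios (two origin hypotheses, six
dispersal models, including admixed origins of the SE and NC populations)
and four within-cluster isolation-with-migration models are provided.  A
structured-coalescent simulator generates joint site-frequency spectra
(SFS) under any model; fitting maximizes the multinomial composite
log-likelihood

    lnCL = Σ_i m_i · ln max(p_i, p_min)

over polymorphic SFS cells — observed counts `m_i` against Monte-Carlo
expected per-SNP probabilities `p_i` — by conditional-maximization (ECM)
cycles with common random numbers, and models are ranked by
AIC = 2k − 2 lnCL.  Profile likelihoods and parametric-bootstrap
confidence intervals round out the inference layer.

**Upstream processing.**  Variant-level hard filters (QUAL ≥ 60, FS ≤ 60,
QD ≥ 2, MQ ≥ 40, RankSum bounds, call rate, MAF ≥ 0.05), individual
filters (mean depth ≥ 4x, missingness ≤ 30%), KING-robust kinship with
first-degree pruning (φ > 0.177), and neutral-panel design (gene/CpG
masks, complete genotyping, MAF, exact Hardy–Weinberg P ≥ 0.001, one SNP
per 10 kb).

**Summary statistics.**  Per-individual observed heterozygosity,
pairwise Weir–Cockerham (1984) F_ST, F_ST/(1−F_ST) linearization,
great-circle distances, and one-sided Mantel tests of isolation by
distance.

**Synthetic data.**  A truth-labelled cohort generator (coalescent
genotypes for 20 sampling groups in 5 clusters, planted QC failures and
Mendelian first-degree relatives) so every stage can be validated against
known ground truth.

## Worked example

The numbered scripts under `analysis/` run the study pipeline on
synthetic data (each writes its tables under `results/`):

```bash
python analysis/01_simulate_cohort.py     # cohort VCF + popmap + truth labels
python analysis/02_qc_kinship_panel.py    # filters, kinship pruning, panel
python analysis/03_popgen_stats.py        # Ho, F_ST, Mantel IBD
python analysis/04_fit_models.py          # AIC model comparison
python analysis/05_recover_parameters.py  # profile-likelihood recovery
```

From `02`, on an 89-individual, 5,000-SNP cohort — the hard filters
remove the planted annotation failures plus the (majority) low-MAF tail,
the individual filters catch all six planted low-quality samples, and
kinship pruning resolves both planted parent–offspring pairs:

```
[site_filters] 5000 -> 1942
  QUAL -55  FS -64  QD -58  MQ -52  MQRankSum -32  ReadPosRankSum -51  MAF -2746
[individual_filters] 89 -> 83   (low_depth -3, high_missing -3)
kinship: 2 first-degree pair(s) flagged, 2 individual(s) pruned
[panel_design] 1942 -> 137
```

From `04`, data simulated under the admixed stepping-stone scenario are
decisively assigned back to it (smaller AIC is better; the pure
stepping-stone and single-admixture alternatives trail by 130–4,500 AIC
units):

```
model4_SE_NC_admix     k=6 lnCL=  -24330.6 AIC=   48673.2
model2_SE_admix        k=5 lnCL=  -24396.6 AIC=   48803.2
model1_stepping        k=4 lnCL=  -26388.7 AIC=   52785.3
model3_NC_admix        k=5 lnCL=  -26595.0 AIC=   53200.1
```

From `05`, profiling the composite likelihood over each parameter of the
best-fit scenario (others held at their simulation values) recovers the
truth to within grid resolution plus Monte-Carlo error at desk scale
(5,000 SNPs, 2,000 genealogies per grid point):

```
parameter       truth  recovered  rel err
alpha_SE         0.37       0.35    -5.4%
alpha_NC         0.81       0.85    +4.9%
T1          1.285e+04  1.359e+04    +5.8%
T2          1.063e+04  1.064e+04    +0.1%
T3               1350       1569   +16.2%
T4                820      717.3   -12.5%
```

Here `T1`/`T2` are the deep divergence times in generations (128.5 and
106.3 ka at 10 years/generation), `T3`/`T4` the formation times of the
admixed NC and SE populations (13.5 and 8.2 ka), and `alpha_*` their
admixture fractions (81% N ancestry in NC, 37% SW ancestry in SE).

A `stepstone` CLI exposes the same stages
(`simulate`, `qc`, `panel`, `sfs`, `fit`, `compare`, `profile`,
`bootstrap`, `stats`, `run`); `stepstone run --config cfg.yaml` drives
the whole pipeline from a YAML file with deterministic, seed-reproducible
outputs.

## Layout

```
src/stepstone/     demography, models, coalescent, sfs, genotypes,
                   qc, inference, stats, vcfio, pipeline, cli
analysis/          numbered narrative drivers (see worked example)
scripts/           acceptance.py
tests/             pytest suite (unit, property, oracle and end-to-end)
docs/methods.md    models, conventions, numerical choices, limitations
```
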