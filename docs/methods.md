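# Methods

`stepstone` implements the demographic-inference and population-genomic
workflow for a fragmented five-population system: a structured-coalescent
simulator over named demographic models, SFS-based composite-likelihood
fitting with AIC model selection, and the upstream SNP-panel, QC, kinship
and summary-statistic stages, all exercisable end to end on synthetic
data.  This note records the models, the numerical choices, and what the
synthetic experiments do and do not demonstrate.

## Demographic models

A demography is a list of demes (diploid effective size `Ne`, diploid
sample count) plus an ordered backward-time event program.  Two event
kinds carry the genealogy-shaping semantics:

* **split** — at time `T` (generations), every lineage of the source deme
  moves into the destination deme.  Forward in time this is the founding
  of the source from the destination.
* **admixture pulse** — each lineage of the source moves independently
  with probability `alpha`.  A pulse with `alpha = 1` is exactly a split,
  and the simulator treats it deterministically so the identity holds
  stream-for-stream under a common seed.

An *admixed origin* (a population founded by two parents) compiles to a
pulse into the minor parent followed by a same-time split into the major
parent.  Migration is a backward per-generation rate matrix
`M[i][j]` (probability per generation that a lineage in `i` originated in
`j`); "migrants per generation" in the forward sense is `2*Ne*m` of the
receiving deme.

The named between-cluster models cover two origin hypotheses and six
dispersal scenarios over the clusters SW, SE, C, NC, N (south to north,
SE between SW and C, NC between C and N):

| name | topology (backward) | extras |
|---|---|---|
| `origin_SW` | SE→SW, NC→C, N→C, C→SW | neighbour migration `m` |
| `origin_C` | SE→C, NC→C, N→C, SW→C | neighbour migration `m` |
| `model1_stepping` | SE→SW, NC→N, N→C, C→SW | none |
| `model2_SE_admix` | model1 with admixed SE (pulse to SW, rest to C) | `alpha_SE` |
| `model3_NC_admix` | model1 with admixed NC (pulse to N, rest to C) | `alpha_NC` |
| `model4_SE_NC_admix` | both admixed origins | `alpha_SE`, `alpha_NC` |
| `model5_IM` | model1 topology | neighbour migration `m` |
| `model6_independent` | SE, NC, N, C all split from the SW lineage | all-pairs migration `m` |

The supplementary figures that draw these scenarios in the source study
are not machine-readable, so the exact topologies of the origin models,
model5 and model6 are package defaults chosen to match their verbal
descriptions; model1 merges each stepping-stone daughter into its
single parent such that `model4` with `alpha_SE = alpha_NC = 1` is
identical to `model1` (this boundary identity is tested).

Within-cluster models (`within_SW`, `within_C`, `within_NC`, `within_N`)
are serial-split isolation-with-migration programs over the 2–3
subpopulations each cluster resolves into (3 for SW and NC, 2 for C and
N).  Their divergence-time bounds extend down to 10 generations because
the within-cluster splits of interest are only decades to centuries old.

Parameter bounds follow the study priors: `Ne` uniform in [50, 1e4]
diploids, divergence times uniform in [100, 5e4] generations (bounded
below by the next-younger event), migration log-uniform in [1e-6, 1e-2].
Times are internally in generations; conversions use 10 years per
generation.  The mutation rate is 1.36e-8 per site per generation.

## Coalescent simulation and SFS machinery

The simulator runs the structured coalescent per locus: coalescence at
rate `k(k-1)/(4Ne)` per deme, migration per lineage, with the event
program applied at its scheduled times.  Each branch records the count of
sampled leaves it subtends per population — sufficient for any
infinite-sites mutation scheme.  A hard cap on event steps per locus
(default 1e6, configurable) converts pathological parameter combinations
into a diagnostic error instead of a hang.  Seeding is counter-based: one
root seed, per-locus `SeedSequence` streams, so results do not depend on
how loci are batched.

Three SFS estimators share this core:

* `simulate_sfs` — Poisson(mu × branch length) mutations per locus;
  the regime for theory oracles (the Watterson check E[xi_i] = theta/i).
* `simulate_snp_sfs` — an exact number of segregating sites: pooled
  branch lengths over n_trees genealogies, sites assigned multinomially.
  This equals Poisson mutation conditioned on the total segregating
  count in the small-mu limit, and is how observed datasets are built.
* `expected_sfs_probs` — per-SNP cell probabilities as pooled branch
  length per cell over total pooled length; the Monte-Carlo expectation
  the composite likelihood consumes.  The two latter estimators are
  consistent with each other by construction.

SFS objects support minor-allele folding (cells past half the total
sample fold onto their complements; ties halve), marginalization, and
easySFS-style hypergeometric projection to smaller sample sizes; mass is
conserved by all three (tested to 1e-9 relative).  Monomorphic corner
cells are stored but excluded from likelihoods.  Sites with any missing
genotype among the selected individuals are dropped (complete-case),
matching a panel designed around loci genotyped in all individuals;
projection is available when downsampling is preferred.  Folded spectra
are the natural choice for real data without an outgroup; the synthetic
experiments use unfolded spectra since the simulation knows derived
states.

## Composite likelihood and ECM fitting

The objective is `lnCL = sum_i m_i ln max(p_i, p_min)` over polymorphic
cells, with `p_min = 1/(10 n_sims)` flooring cells the simulation never
visited (configurable; the exact guard value used by comparable tools is
undocumented, so ours is explicit).  AIC = 2k − 2 lnCL on natural logs;
`aic_from_log10` converts likelihoods reported in log10.

Fitting runs ECM cycles: per cycle, one bounded Brent line search per
free parameter, in the order times (oldest first), sizes, admixture
fractions, migration.  All probes within a cycle share one random stream
(common random numbers), so the line search sees a smooth objective;
streams are refreshed across cycles by default (an option keeps them
fixed, making the lnCL trace provably non-decreasing).  Time parameters
are clamped to the ordering constraint of their model during the search.
Independent restarts with distinct seeds guard against local optima;
`compare_models` takes the best restart per model before ranking by AIC.

Profile likelihoods evaluate a one-parameter grid under common random
numbers.  Parametric-bootstrap intervals simulate datasets at the point
estimate with the same number of segregating sites as the data and refit
each at reduced settings, reporting percentile intervals; a refit failure
rate above 20% aborts with a diagnostic.

Ascertainment: the likelihood neither includes monomorphic counts nor
corrects for panel MAF ascertainment by default (both toggles exist in
the SFS layer via masking/folding choices); on the synthetic experiments
the observed and expected spectra are generated by the same process, so
no correction is needed.

## Synthetic cohort generator

`simulate_genotype_matrix` emulates the capture-sequencing cohort: 20
sampling groups nested in the 5 clusters (~90 diploids at default desk
scale, configurable up to the study's ~300), each site an independent
coalescent genealogy with one segregating mutation, haploid lineages
paired into diploids within demes (hence Hardy–Weinberg within demes by
construction).  Truth-labelled failure modes are planted disjointly:

* per-site QUAL/FS/QD/MQ/MQRankSum/ReadPosRankSum drawn from pass
  ranges, with a configurable fraction drawn strictly on the removal
  side of each hard threshold (`truth_fail_rule`); RankSum annotations
  are blanked at sites without a heterozygote, mimicking their GATK
  emission;
* low-depth (mean depth in [1, 3.9]) and high-missingness (~45% missing)
  individuals;
* first-degree relatives: an individual is regenerated as a Mendelian
  child of a sampled parent and an unsampled mate drawn from cluster
  allele frequencies, giving kinship ~0.25 with the parent.

What the generator does **not** emulate: linkage between sites (every
site is an independent genealogy), sequencing-error genotype noise,
batch effects, reference bias, or panel ascertainment from an external
discovery sample.  Passing QC/kinship/statistics tests on this cohort
demonstrates the estimators' correctness under the model, not robustness
to those real-data artifacts.

## QC conventions

Removal conditions are strict inequalities (QUAL < 60, FS > 60, QD < 2,
MQ < 40, MQRankSum < −20, ReadPosRankSum < −8 remove; values at the
threshold pass).  A site failing several rules is attributed to the first
failing rule in that order, then site call-rate, then MAF < 0.05; missing
annotations skip their rule and are counted.  The source study's "SNPs
missing in > 80% of all samples" admits two readings (removing sites
missing in more than 80% of samples, or requiring 80% call rate); the
call-rate reading with a configurable threshold (default: at most 20%
missing) is the default, and the literal reading is available by setting
the threshold to 0.80.  Individuals are removed at mean depth < 4 or
missingness > 30%.

Kinship is the KING-robust between-family estimator
`phi = (N_het,het − 2 N_opp-hom) / (N_het(i) + N_het(j))` over
pairwise-complete sites; pairs with no overlap are NaN, never zero.
First-degree pruning (phi > 0.177) removes greedily by flagged-pair
degree, ties broken by higher missingness then label order — the source
study reports only the number excluded, so the strategy is a package
choice; the post-condition (no surviving pair above threshold) is
asserted on every synthetic cohort.

Panel design applies, in order: autosomal-biallelic restriction, gene
mask, CpG mask (both 0-based half-open BED against 1-based positions),
complete genotyping, MAF ≥ 0.05, Hardy–Weinberg exact P ≥ 0.001, then
thinning to one SNP per 10 kb (windows anchored at position 1 per
chromosome, first surviving SNP kept — deterministic rather than
random).  The HWE test is the exact conditional (Levene) test computed by
ratio recurrence, summing probabilities of all heterozygote counts no
more probable than observed; it is checked against full enumeration for
every configuration up to 200 individuals.

## Summary statistics

Observed heterozygosity is heterozygous calls over non-missing calls per
individual.  F_ST is Weir–Cockerham (1984) from genotype counts with
multilocus ratio-of-averages aggregation; negative estimates are
reported as-is and clamped to zero only when linearized to
F_ST/(1−F_ST).  Geographic distances are great-circle (haversine,
R = 6371.0088 km) between population centroids; the least-cost-path
distances used in the source study depend on a resistance surface that
is out of scope, so externally computed distance matrices can be
supplied instead.  The Mantel test is one-sided (positive association),
p = (1 + #{r_perm ≥ r_obs})/(n_perm + 1) permuting one matrix's labels,
with an exact enumeration mode for few labels.  On a simulated
stepping-stone lattice the IBD signal needs at least five demes: with
four, the chain's reversal symmetry and the 4! = 24 permutation group
bound the achievable p above 0.05.

## Desk-scale experiment sizes

The bundled experiments are sized for a single CPU: cohorts of ~90
diploids at 5,000 sites; observed spectra of 5,000–8,000 SNPs over
3,000–5,000 genealogies with 5 diploids sampled per population; profile
grids of 19–31 points at 1,200–6,000 genealogies per point; ECM at
400–600 simulations per probe, 1–2 cycles, with effective sizes pinned
when the question is topology/times/admixture.  The recovery scenario
fixes all five `Ne` at 2,000 diploids and between-cluster migration at
zero: the published point estimates cover the event times and admixture
fractions only, so these two are package choices (inside the prior
range) and are documented as part of the scenario, not estimated.

The headline synthetic result, recomputed by `scripts/acceptance.py` and
(lighter) `analysis/05_recover_parameters.py`: spectra simulated at the
best-fit scenario — SW–C divergence 128.5 ka, C–N 106.3 ka, admixed
origin of NC at 13.5 ka with 81% N ancestry, of SE at 8.2 ka with 37% SW
ancestry — yield profile-likelihood recoveries of each parameter, others
held at truth, within grid resolution plus Monte-Carlo error.  Model
selection on data simulated under the admixed model prefers it over the
pure stepping-stone model by large AIC margins.

## Known limitations

* Pure-Python event loop: ~0.5 ms per 50-lineage genealogy; fine at desk
  scale, not at the study's 100,000 simulations × 100 restarts scale.
* No recombination within loci and no linkage between them; genotype
  cohorts are LD-free, so LD-based analyses cannot be exercised.
* The ECM fitter assumes a reasonably smooth composite-likelihood
  surface; with very small `n_sims` the p_min floor can flatten it.
* Absolute composite likelihoods (and hence absolute AIC values) depend
  on the observed SNP count and are comparable only within one dataset.
* The within-cluster model topologies and the origin/dispersal model
  details beyond the verbal descriptions are package defaults (above),
  not reproductions of unpublished supplementary figures.
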