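# Methods

This note documents the models, assumptions, defaults and numerical
choices behind `methylsub`, in the spirit of the methods documentation of
mature statistical packages. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Data model

Methylation is represented as beta values — per-CpG methylated fractions
in [0, 1] — in a probes × samples `BetaMatrix`. Missing values are
permitted everywhere and propagated as NaN; no imputation happens except
immediately before distance computations in clustering (per-probe median,
logged). Probe annotation uses 0-based half-open coordinates (BED
convention). Proximity to catalogued variants is precomputed into the
annotation (`snp_distance`, `blacklist_distance`) rather than joined
against a variant catalogue at run time, which keeps the package free of
external downloads; any user-supplied distance annotation is accepted.
Sex chromosomes are matched as {chrX, chrY, X, Y}, case-insensitively.

Probe filtering removes probes with `snp_distance ≤ 5`,
`blacklist_distance ≤ 3` or a sex-chromosome location. The operation is
idempotent, never mutates its input, and degenerates to the identity when
both thresholds are negative and sex-chromosome dropping is off.

## Differential methylation

All differential calls use the same rule: per-probe two-sided unpaired
Welch *t* (Satterthwaite degrees of freedom), Benjamini–Hochberg
correction within the comparison, and a probe is a DMP iff adjusted
*p* < 0.05 **and** |Δβ| ≥ 0.2. The Δ threshold is absolute (not signed):
whether a hemDMP should count only HSC→mature gains is ambiguous, and the
absolute rule is the conservative superset. A variance floor of 1e-12
protects degenerate constant probes, which receive *t* = 0, *p* = 1.
Probes with fewer than two non-missing values in either group are
untestable: excluded and counted, never silently dropped.

The upstream analyses this package emulates delegate differential calling
to array-analysis suites whose internal ranking mixes several statistics;
standardizing on Welch + BH + Δ is a deliberate simplification that
matches the stated thresholds and the test used for group comparisons.

hemDMPs are the union of six pairwise calls (HSC vs granulocyte,
monocyte, NK, CD8⁺ T, CD4⁺ T, B); nvCpGs are their exact complement in
the filtered probe universe, so the two sets always partition it.
Variance ranking ("most variable probes") uses the n−1 sample standard
deviation with lexicographic probe-id tie-breaks, making every top-k
selection deterministic.

## Consensus clustering

Hierarchical clustering uses city-block (Manhattan) distances with
scipy's Ward linkage. Applied to a precomputed distance matrix, scipy's
Lance–Williams recurrence is the distance-squared ("ward.D2") form, so
results match R's `hclust(d, "ward.D2")`. Consensus clustering subsamples
⌈0.8·n⌉ samples without replacement for 500 iterations (the convention of
the standard consensus-clustering implementation, even where the
surrounding literature says "bootstrap"), clusters each subsample at
every candidate k, and records pairwise co-assignment frequencies
normalized by co-sampling counts. Pairs never co-sampled get consensus 0
with a warning (practically impossible at 500 iterations).

Cluster number is chosen by PAC — the proportion of off-diagonal
consensus entries strictly inside (0.1, 0.9) — with ties resolved toward
smaller k. PAC is used because the upstream analyses show consensus
matrices without stating a numeric stability criterion; PAC is the
standard fully-specified choice. Final assignments at the selected k come
from Ward clustering of 1 − consensus. Clusters are named HM/IM/LM by
ranking cluster-mean beta over the clustering probes, descending; the
naming is defined for 2 or 3 clusters only and is invariant to cluster
index permutation.

## Cell-type deconvolution and reference PCA

Deconvolution solves, per sample, min‖A·f − y‖² over marker probes with
f ≥ 0 and Σf ≤ 1 (constrained projection onto reference profiles — the
classical reference-based approach to methylome cell-composition
inference). The Σ ≤ 1 inequality (not equality) follows the cited
algorithm and leaves room for an unexplained component. The QP is solved
with SLSQP at ftol 1e-14, which recovers noiseless mixtures to ±1e-6;
rank-deficient marker designs are rejected with the collinear cell types
named. Markers default to the top-500 probes by across-cell-type variance
of the reference panel; the number of markers the original analyses used
is not recoverable, so it is an exposed parameter. Note that the residual
norm grows (weakly) as markers are added — it is a sum over marker rows —
so residuals are only comparable between samples at a fixed marker set.

Reference PCA ranks probe variance across the six HSPC populations only
(HSC, MPP, L-MPP, CMP, GMP, MEP), fits the PCA on all reference samples
restricted to the top-5,000 such probes (centered, unscaled betas — beta
values share a scale, so no standardization), and projects study samples
as supplementary points: coordinates = (β − center)·loadings, with no
refitting. Loading signs are fixed by forcing each loading's
largest-magnitude entry positive.

## Subtype classifier

Grouped (symmetric) multinomial logistic regression with an L1 penalty on
coefficients, intercepts unpenalized, features standardized internally to
unit variance and coefficients reported back on the beta scale. Features
are the 1,000 most variable subgroup DMPs that map to CpG islands. The
penalty grid has 100 log-spaced values from λ_max (the smallest penalty
zeroing every coefficient, computed from the null-model score gradient)
down four orders of magnitude; the winner minimizes mean 10-fold
cross-validated multinomial deviance (the minimum rule, not the
one-standard-error rule — the choice is recorded in the model and
configurable via the grid). The final model is refit on the full training
data at the selected penalty.

Numerically, the solver is scikit-learn's saga with warm starts along the
descending path. Cross-validation paths run at tolerance 1e-4 — penalty
*selection* is insensitive to the residual coefficient error — and the
final model is polished at tolerance 1e-5 (hard failure if 3·10⁵
iterations do not converge). The signature is the set of probes with a
nonzero coefficient in any class, ordered by max |coefficient|; its size
is data-dependent by construction.

Evaluation uses K = (Acc − AccRand)/(1 − AccRand), with AccRand the mean
accuracy over 1,000 seeded permutations of the *predicted* labels against
the fixed truth. K ≤ 1 always; negative values are preserved, not
clamped; the degenerate single-class case (AccRand = 1) is an explicit
error. As the permutation count grows, AccRand converges to the dot
product of predicted and true class frequency vectors.

## Enrichment

Per category: OF = fraction of foreground probes in the category, OB =
the same for background, effect = log₂(OF/OB) (±∞ sentinels when one
fraction is zero, with the Fisher *p* still finite), significance =
two-sided Fisher exact on the 2×2 in/out × fore/back table,
BH-corrected **within each cell context** (the alternative — a single
global correction across contexts — is slightly more conservative;
context-wise matches treating each cell line as its own family), with
threshold 0.01 on the adjusted *p*. Gene-set over-representation uses the
one-sided hypergeometric tail over a user-supplied universe, BH across
sets. Category maps are user-supplied tables; chromatin-state downloads
and state merging are out of scope.

## Outcomes

Event coding: 0 censored, 1 relapse, 2 treatment-related mortality (TRM)
for post-transplant analyses; {0, 1} for overall survival. Overall
survival runs from diagnosis, relapse/TRM from transplantation; the
outcome table carries the time origin explicitly.

Kaplan–Meier estimates carry Greenwood variance and log-log
(complementary log-log) 95% intervals. Log-rank and Cox go through
lifelines; the Cox model is cause-specific (competing events censored at
their event time) with Efron tie handling (lifelines' default; the
upstream analyses do not state a tie method). Platelet count enters the
Cox model as the < 70 K µl⁻¹ binary indicator by default (the continuous
coding is not stated upstream; configurable).

The Aalen–Johansen cumulative incidence estimator is implemented directly
rather than through a survival library because available implementations
jitter tied event times, which breaks both determinism and the
conservation identity Σ_c CIF_c(t) + S_any(t) = 1. The direct
product-limit implementation satisfies that identity to floating
round-off (< 1e-9) at every event time and reduces exactly to 1 − KM
with a single cause.

Gray's K-sample test (rho = 0) compares subdistribution hazards using the
censoring-weighted risk sets R_j(t) = Y_j(t)(1 − F̂₁ⱼ(t⁻))/Ŝⱼ(t⁻): the
score is z_j = Σ_t [d₁ⱼ(t) − p_j(t)·d₁.(t)] with p = R/R_. The variance
is the martingale predictable-variation estimator Σ_t d₁.(t)[diag(p) −
pp'], which drops the higher-order terms arising from estimating the
censoring distribution. Two checks justify the simplification: with no
competing events and continuous times the statistic reduces exactly to
the standard log-rank statistic, and the null rejection rate at α = 0.05
over 1,000 two-arm simulations (n = 100/arm, competing hazards present)
stays inside the binomial 95% band — both are asserted in the test suite.

Rank comparisons use the Mann–Whitney U with continuity-corrected normal
approximation, switching to exact enumeration when both samples have
n ≤ 8 and no ties. Contingency tables use Fisher's exact test (two-sided,
by summation of tables no more probable than the observed) for 2×2 and
the chi-square test otherwise. Mutation burden counts gene-alteration
events per patient (placeholder "none" rows never count); the multi-hit
fraction is the share of patients with > 1 alterations in RAS/STAT-pathway
genes.

## Synthetic cohort generator

The generator emulates the *structure* of a bulk methylome study of a
myeloproliferative disease, with every parameter a stated default:

* **Reference panel.** 12 hematopoietic cell types. Baseline beta per
  probe follows its CpG-island relation — islands largely unmethylated
  (Beta(0.8, 6)), open sea largely methylated (Beta(5, 1.5)), shores and
  shelves intermediate — reproducing the genome-wide bimodal pattern and
  leaving islands room to *gain* methylation, which is what a
  CpG-island methylator phenotype does. 16% of probes are
  differentiation-dynamic (matching the ~59,000/367,000 proportion in
  450K-scale data): they shift by 0.3 between HSC and a random subset of
  downstream types that always includes a mature type, directed to stay
  inside [0.02, 0.98].
* **Cohort.** Per sample, cell fractions are Dirichlet with a
  myeloid-weighted concentration (granulocytes ≈ 40%, monocytes ≈ 23% in
  expectation, variable HSPC and B admixture) — the composition pattern
  of a myeloproliferative disorder. Beta = fractions × profiles; then
  2% of the clean non-dynamic probes receive planted subgroup shifts
  (HM +0.25, IM +0.12, LM 0 versus baseline, per-probe sign positive
  with probability 0.98 to mirror the ~98% hypermethylation dominance
  observed in this disease, 80% of planted probes on islands), clipped
  to [0, 1]; finally logit-scale Gaussian noise (sd 0.05) is added and
  inverse-transformed, keeping betas in (0, 1) without clipping the
  noise component. Additive-beta planting matches how Δβ thresholds are
  defined; logit-scale noise matches how array noise behaves near the
  boundaries.
* **Labels and outcomes.** Genotype and karyotype are drawn with
  subgroup-conditional probabilities (HM enriched for somatic PTPN11, IM
  for KRAS and monosomy 7, LM for NRAS/CBL/Noonan), qualitative
  enrichments only — the source cohorts report proportions, not a
  generative model, so the strengths are configurable. Outcomes are
  latent exponential competing-risk times with per-group cause-specific
  hazards (relapse/TRM per year: HM 0.18/0.06, IM 0.10/0.06, LM
  0.03/0.05; censoring rate 0.08), giving the HM group a ~3–6× relapse
  hazard and ~0.5 five-year relapse incidence versus ~0.1–0.2 for LM.

One global seed drives a hierarchical `SeedSequence` stream per stage
(reference, panel replicates, cohort, outcomes), so the same seed yields
a bit-identical world and stages can be regenerated independently.

**What a green test does and does not establish.** The generator plants
clean block effects with homogeneous within-group noise and no batch
structure, probe-chemistry bias, age effects or copy-number aberrations;
subgroups are exactly equal-sized and effects are uniform across planted
probes. Recovery of the planted structure therefore validates the
*machinery* — filtering, set algebra, clustering stability, penalty
selection, competing-risk estimators — not the claim that real cohorts
contain three subgroups, which only real data can support.

## Pipeline

`run_pipeline` executes simulate → filter → deconvolve → hemDMP/nvCpG →
consensus + HM/IM/LM naming → subgroup DMPs (union of pairwise calls
between discovered groups) → classifier (4:1 stratified split, 10-fold
CV) → enrichment (CGI relation and genomic feature against the non-DMP
nvCpG background) → outcome statistics, writing every artifact plus a
JSON manifest of SHA-256 hashes, parameters and the seed. There is no
stage cache: every stage is cheap and deterministic given the config, so
a rerun reproduces byte-identical artifacts and manifests, which is the
reproducibility property a cache would otherwise have to protect.

With three discovered groups, the intermediate group's planted effect
(0.12) sits below the Δ ≥ 0.2 threshold by design, so the subgroup DMP
set is typically driven by the HM-vs-LM contrast — the intermediate group
is defined by *partial* hypermethylation of the same probes, as its name
suggests.

## Known limitations

* No raw-intensity processing: the pipeline starts at normalized betas.
* No region-level (DMR) calling or covariate-adjusted differential tests.
* Gray's test drops the censoring-estimation variance terms (see above);
  for heavily censored designs far from the validated regime the p-values
  may be mildly approximate.
* The deconvolution marker count and the exact variant lists behind probe
  filtering are user-supplied knobs, not recoverable constants.
* Fine–Gray subdistribution regression is deliberately absent; the Cox
  model is cause-specific only.
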