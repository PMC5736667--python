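# methylsub

Cell-composition-aware discovery, classification and outcome analysis of
DNA methylation subgroups in leukemia cohorts.

## The problem

Juvenile myelomonocytic leukemia (JMML) and similar myeloproliferative
disorders are profiled from bulk blood or marrow, so every methylome is a
mixture over hematopoietic cell types — stem and progenitor compartments,
granulocytes, monocytes, lymphocytes — in proportions that vary wildly
between patients. Naive clustering of such methylomes recovers cell
composition, not tumor biology. The strategy implemented here removes that
confounder before asking any biological question:

1. **hemDMP removal.** Using reference methylomes of normal hematopoiesis,
   call every CpG that changes during differentiation (HSC versus each of
   six mature cell types; Welch *t*, BH-adjusted *p* < 0.05 and
   |Δβ| ≥ 0.2). The union of these *hematopoiesis-specific differentially
   methylated probes* is discarded; the complement — the **nvCpGs**,
   non-variable in normal hematopoiesis — carries only tumor-intrinsic
   signal.
2. **Consensus subgroup discovery.** Cluster the cohort on the most
   variable nvCpGs with subsampled consensus clustering (Manhattan
   distance, Ward linkage, 500 iterations at 80% subsampling); pick the
   number of clusters by the PAC ambiguity score and name the clusters
   **HM / IM / LM** (high / intermediate / low methylation) by mean β.
3. **Characterize and deploy.** Call subgroup-specific DMPs, test their
   genomic enrichment (log₂(OF/OB) with Fisher exact *p*; a positive
   CpG-island enrichment is the CpG-island methylator phenotype, CIMP),
   train an L1-penalized multinomial classifier on island DMPs evaluated
   by permutation kappa *K* = (Acc − AccRand)/(1 − AccRand), estimate
   per-sample cell fractions by constrained-projection deconvolution, and
   analyze relapse and treatment-related mortality as competing risks
   (Aalen–Johansen incidence, Gray's test, cause-specific Cox).

A seeded synthetic-cohort generator reproduces the whole data structure —
reference panel, Dirichlet cell mixtures, planted CGI-biased subgroup
effects, correlated genotypes, competing-risk outcomes — so every stage is
testable against known truth.

## Worked example

`examples/03_subgroup_discovery.py` runs the discovery chain on the
default synthetic cohort (20,000 probes, three planted subgroups of 20
samples, Δβ of 0.25/0.12 on 2% of nvCpGs) and prints:

```
hemDMPs removed: 3200; nvCpGs kept for clustering: 16402
PAC per k (lower = more stable): {2: 0.452, 3: 0.0, 4: 0.092, 5: 0.156}
selected k = 3
group sizes: {'HM': 20, 'IM': 20, 'LM': 20}
adjusted Rand index vs planted truth: 1.000 (1.0 = perfect recovery)
```

PAC = 0 at k = 3 means every sample pair is co-clustered either always or
never across the 500 subsampled runs — a perfectly stable three-group
structure — and the adjusted Rand index of 1.0 confirms the discovered
groups are exactly the planted ones. `examples/06_outcomes.py` then shows
the clinical consequence on the same cohort:

```
5-year cumulative incidence of relapse (TRM competing):
  HM: 0.58
  IM: 0.33
  LM: 0.23
cause-specific Cox for relapse (reference: LM group):
            coef     rr  ci_lower  ci_upper      p
hm         1.111  3.038     1.097     8.414  0.033
im         0.455  1.576     0.527     4.714  0.415
```

The high-methylation group carries roughly threefold the relapse hazard of
the low-methylation group, matching the hazards planted by the generator.

The other examples cover simulation (`01`), deconvolution and reference
PCA (`02`), the subtype classifier (`04`), enrichment statistics (`05`)
and the one-call pipeline (`07`).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the entire pipeline from scratch on the default synthetic cohort —
simulation, probe filtering, deconvolution, hemDMP/nvCpG derivation,
consensus clustering, subgroup DMP calling, classifier training and
evaluation, enrichment, and competing-risks statistics — prints the full
run report, and writes the JSON acceptance-target object to `--out`.

## Layout

```
src/methylsub/    io, simulate, reference, dmp, consensus,
                  classifier, enrichment, outcomes, pipeline
examples/         one short narrative script per capability
tests/            pytest suite incl. acceptance criteria
docs/methods.md   models, assumptions, numerical choices, limitations
```
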