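# chromsig

From chromatin-profiling peak calls to a cross-validated prognostic
gene signature.

`chromsig` implements, as a tested and reusable pipeline, a
biomarker-discovery strategy for tumor chromatin profiling: compare a
transcription factor's genome-wide binding (ChIP-seq peak calls and
fragment counts) between two clinical groups — for instance primary
prostate tumors versus tumors with acquired resistance to androgen
deprivation — and distill the genes near the differential binding
sites into a small gene-expression signature that stratifies patients
on time to biochemical recurrence. It is aimed at computational
biologists who have peak calls, count matrices, expression tables and
clinical follow-up in hand and want the downstream statistics under
one tested roof.

The pipeline chains five stages, each usable on its own:

1. **Consensus peaks** (`chromsig.intervals`) — per-sample peak calls
   are merged by single-linkage overlap; a region is kept when at
   least *k* samples support it (occupancy ≥ *k*, default 3). Peaks
   are annotated by genomic category (promoter/exon/intron/
   downstream/distal), compared across chromosomes with one-sided
   binomial tests, and quantified as RPKM.
2. **Differential binding** (`chromsig.diffbind`) — per-region
   fragment counts are compared between groups on the log₂
   counts-per-million scale with an empirical-Bayes moderated t-test:
   the pooled variance s²_g is shrunk to
   s̃²_g = (d₀s₀² + d·s²_g)/(d₀ + d), with the prior (d₀, s₀²)
   moment-matched to the observed variances, and regions with
   Benjamini–Hochberg q ≤ 0.10 are called differential. Robustness is
   checked by re-running the test under **every** relabeling of the
   samples (a 5-vs-3 design has C(8,3) = 56); the true labeling should
   yield the most discoveries.
3. **Target genes** — a binding site is assigned to a gene when it
   overlaps the gene body or a 20-kb window upstream of the TSS.
4. **Temporal partition** (`chromsig.temporal`) — target genes are
   clustered on a short stimulation time course against a library of
   integer model profiles (max step c = 2, m = 50 representatives,
   minimum expression change 0.5); profile enrichment is tested
   against a timepoint-permutation null, and significant profiles
   split the genes into induced / unaffected / repressed sets.
5. **Survival signature** (`chromsig.signature`, `chromsig.survival`)
   — on a patient cohort, elastic-net-penalized Cox regression
   (mixing α = 0.5) inside a double cross-validation loop — outer
   leave-one-out, inner 10-fold choosing λ by cross-validated partial-
   likelihood deviance — yields an unbiased prognostic index
   PI = Σᵢ βᵢxᵢ per patient and, from the active set at the average λ
   refit by unpenalized Cox, a final gene panel with hazard ratios.
   Patients with PI ≤ 0 are called low risk; stratification is judged
   by Kaplan–Meier/log-rank, time-horizon ROC AUC (5 years), and
   multivariate Cox adjustment for Gleason score, T stage, node
   status and PSA, alongside the clinical D'Amico classification.

A seeded synthetic-data module (`chromsig.simulate`) emulates every
input — jittered peak landscapes, negative-binomial counts with
planted fold changes, time courses with planted temporal classes, and
expression+survival cohorts with a planted hazard-driving gene subset
— so the entire pipeline is exercised against known ground truth.

## Worked example

Train a signature on a synthetic 80-patient cohort in which 4 of 30
genes truly drive the hazard:

```python
from chromsig.simulate import simulate_cohort
from chromsig.signature import CoxSignatureModel, TrainParams

cohort, truth = simulate_cohort(n_patients=80, n_genes=30,
                                n_signature=4, beta_range=(0.8, 1.2),
                                censoring_rate=0.6, seed=21)
print(dict(zip(truth.signature_genes, [round(b, 2) for b in truth.beta])))
# {'GENE0004': 1.14, 'GENE0009': -1.19, 'GENE0021': -0.84, 'GENE0024': 0.87}

res = CoxSignatureModel(
    cohort, params=TrainParams(n_lambdas=50, lambda_min_ratio=0.05)
).fit(seed=0)
print(res.summary())
```

```
Nested-CV elastic-net Cox signature
  patients              80 (33 events)
  alpha                 0.5
  average lambda        0.09856
  signature genes       12
    GENE0002 (+0.241), GENE0003 (+0.754), GENE0004 (+2.239), ...
  CV risk-split logrank chi2 = 19.077, p = 1.26e-05
```

All four planted genes are in the final panel with the right signs
(GENE0004 +2.24, GENE0009 −1.39, GENE0021 −1.93, GENE0024 +1.01,
each with p < 0.005 in `res.final_fit.summary()`), padded by a few
small-coefficient passengers — the expected behavior of the elastic
net at a CV-chosen penalty. The cross-validated risk split separates
the survival curves at log-rank p ≈ 1e−5 and the prognostic index
reaches a 5-year ROC AUC of 0.82 (`res.auc()`); because every PI is
computed with the patient held out, these numbers are honest estimates
rather than resubstitution optimism. `res.plot_risk_groups()` draws
the two Kaplan–Meier curves.

## Command line

`chromsig` exposes each stage as a subcommand — `simulate`,
`consensus`, `count`, `diffbind`, `targets`, `temporal`, `train`,
`validate` — plus `run-all`, which executes the whole discovery chain
from a YAML config and writes every intermediate table with a
provenance record:

```bash
chromsig simulate --out-dir bundle --seed 5
chromsig run-all --config bundle/config.yaml
chromsig validate --model bundle/results/signature_model.json \
    --expression bundle/expression.tsv --clinical bundle/clinical.tsv \
    --out-dir validation
```

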