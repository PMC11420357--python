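# phenomap

Topological-data-analysis (TDA) phenogrouping of cardiac resynchronization
therapy (CRT) cohorts, with the survival-analysis layer used to compare
defibrillator (CRT-D) against pacemaker-only (CRT-P) devices inside each
phenogroup.

## Who this is for

Heart-failure registries contain thousands of CRT recipients described by
mixed binary/continuous clinical features (demographics, history flags,
labs, echo measures, drug usage) with substantial missingness. Clinically
coherent subgroups in such data rarely follow any single feature; this
package builds a *patient-similarity network* with the Mapper algorithm and
partitions it into phenogroups whose device-effect estimates can then be
compared. Everything runs end to end on a synthetic-cohort generator with
known latent structure, so each stage is testable without access to any
registry.

## The method

1. **Screening and scaling** — features with ≥ 40% missing values are
   discarded; remaining missing entries are mean-imputed; every column is
   z-scored (sample SD).
2. **Distance and lenses** — the distance between patients *i*, *j* is the
   normalized correlation distance *d(i,j) = 1 − r(x_i, x_j)* with *r* the
   Pearson correlation of their feature vectors; the two lens values per
   patient are the leading coordinates of classical (Torgerson) metric MDS
   of that distance matrix.
3. **Mapper network** — the lens plane is covered by a `resolution × resolution`
   grid of overlapping cells (equal-frequency base intervals, widened by
   `gain`; defaults 29 and 1.6). Patients in each cell are clustered by
   single linkage with a first-gap histogram cut; each cluster becomes a
   node, and nodes sharing patients are joined by an edge weighted by the
   overlap.
4. **Phenogroups** — nodes outside the largest connected component are
   outliers (their patients leave the analysis); Louvain community
   detection autogroups the main component; autogroups are merged down to
   *k* = 5 by repeatedly folding the group with the most outbound edges per
   node into the neighbour it shares the most edges with. Patients in
   nodes of two groups belong to both phenogroups.
5. **Survival** — per phenogroup: Kaplan–Meier curves by device arm,
   absolute risk reduction ARR(t) = [(1 − S_P(t)) − (1 − S_D(t))] · 100
   with a Greenwood-variance CI (significant iff 0 lies outside), log-rank
   tests, and Cox proportional-hazards models (Efron ties) with
   study-specific right-censoring (CRT-D upgrade, LVAD, transplantation;
   a composite sensitivity endpoint counts the latter two as events).

## Worked example

```bash
phenomap simulate --n-patients 800 --seed 11 --out-dir demo
phenomap all --features demo/features.csv --survival demo/survival.csv \
             --out-dir demo/out --resolution 7 --seed 11
```

The run report (`demo/out/report.json`) prints, among other counts:

```
"n_patients": 800,          # simulated cohort
"n_features_used": 25,      # 28 generated, 3 junk features over the 40% screen
"n_nodes": 1031,            # Mapper nodes
"n_outlier_patients": 163,  # patients only in disconnected nodes
"n_network_patients": 637,  # 800 − 163
"n_autogroups": 6,          # Louvain communities
"n_phenogroups": 5,         # after connectivity merging
"phenogroup_sizes": [159, 159, 191, 109, 81],
"n_double_assigned": 62     # sizes sum − 62 = 637
```

and `demo/out/cox_device_effect.csv` holds the per-phenogroup adjusted
device hazard ratios, e.g. phenogroup 1: HR 0.68 (95% CI 0.47–1.00) — the
generator plants a protective CRT-D effect in two of its five latent
groups, and the fitted HRs recover that pattern on the patients each
phenogroup captures.

The same stages are available as separate subcommands (`network`,
`phenogroup`, `survival`) reading and writing files, and as a library
(`MDSLens`, `MapperNetwork`, `PhenogroupClusterer` are scikit-learn-style
estimators).

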