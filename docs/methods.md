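# Methods

## Scope and model

The package re-implements, as a reusable pipeline, a TDA phenogrouping
analysis of CRT recipients: Mapper patient-similarity network → Louvain
autogroups → connectivity-based merge to five phenogroups → per-group
survival contrasts of CRT-D vs CRT-P. The registry it models is not
distributable, so a synthetic-cohort generator reproduces the *structure*
of such data and all quantitative claims in this repository are about
behaviour on that generator.

## Preprocessing

Features with a missing fraction ≥ `missing_threshold` (default 0.40,
closed at the boundary: exactly 40% is discarded) are dropped; survivors
are mean-imputed and z-scored. Choices the source analysis leaves open:

- z-scoring uses the sample (n−1) SD, the common statistical-software
  default; zero-variance columns map to all-zeros rather than raising, so
  constant binary flags in small cohorts flow through.
- binary features are imputed with their mean (a fraction), not the mode:
  the chain treats all features identically.
- scaling happens once, up front, before any node/outlier removal.

## Distance and lenses

“Normalized correlation” is read as 1 − Pearson r across the feature axis
(each patient row centred by its own mean) — the convention of the
commercial TDA tool lineage; it equals scipy's `correlation` metric. Rows
with zero variance get r := 0 (distance 1) against everyone. The two
lenses are classical (Torgerson) MDS coordinates: double-centre −D²/2,
eigendecompose, scale the two leading non-negative eigenvectors by
√eigenvalue. Classical MDS was chosen over iterative stress majorization
because it is deterministic and seed-free; each lens column's sign is
fixed (largest-magnitude entry positive) for backend reproducibility.
Note that the lens values are *not* invariant to appending a constant
feature: per-row centring makes the Pearson pattern sensitive to shared
coordinates. This is a property of the metric, not a defect of the
implementation.

## Mapper cover and clustering

Per lens, `resolution` base intervals (default 29); *equalized* means base
boundaries at empirical quantiles (equal-frequency), otherwise equal
width. Each base interval is widened symmetrically so its width is
multiplied by `gain` (default 1.6), giving neighbour overlap
(gain−1)/gain. Cells are the cross product of the two interval lists;
membership is closed-open, closed-closed for the last interval. Within a
cell, single linkage on the restricted distance matrix is cut at the first
empty bin of a 10-bin histogram of merge heights **spanning [min, max]
height** (with the span starting at zero, the first bin is often empty and
everything shatters to singletons — the gap heuristic needs the observed
height range). No empty bin means a single cluster. One node per cluster;
edges join nodes sharing ≥ 1 patient, weighted by the overlap size.

Resolution should scale with cohort size: the reference parameterization
corresponds to roughly 90 patients per base interval (2603/29), and the
package's recovery experiments keep that order (resolution 8 at n = 1000).

## Phenogroups

Outliers are the patients appearing only in nodes outside the largest
connected component (ties broken toward the component holding the lowest
node id). Louvain (networkx implementation, resolution 1, seeded) runs on
the weighted graph; a community that induces a disconnected subgraph — a
rare but documented Louvain artifact — is split into its connected
components, so every autogroup is connected by construction. Merging then
iterates: score each group by (edges with exactly one endpoint inside) /
(node count); fold the top-scoring group (ties → smaller, then lower
label) into the adjacent group sharing the most edges (ties → larger,
then lower label); stop at k groups. Edge *counts* (not patient weights)
are used throughout the merge, matching the “connected with the most
edges” reading. Patients inherit every label of every group whose nodes
contain them; overlap is preserved. For evaluation against a flat
clustering, `labels_` resolves overlap to the lowest label.

## Survival layer

Under the all-cause-death endpoint, CRT-D upgrade, LVAD implantation and
heart transplantation right-censor at the procedure date; the composite
sensitivity endpoint counts LVAD/transplant as events and censors only at
upgrade. KM estimation, log-rank, and Cox PH (Efron tie handling) are
delegated to lifelines; Greenwood variance and the log-transform 95% CI
(S·exp(±1.96·√Σd/(n(n−d))), clipped to [0,1]) are computed from the event
table. ARR(t) is the mortality difference in percentage points; its CI
uses the sum of the two arms' Greenwood variances and the significance
flag is definitionally 0-outside-CI. Horizons are evaluated at the KM
step value at the last event time ≤ t. Two multivariable adjustment sets
are exposed (`caption`: device, age, sex, AF history, VA history —
default; `methods`: etiology replacing AF history), since the source
analysis describes both without resolving them.

## Synthetic cohorts

`default_cohort_config` mimics the registry's published structure: five
latent groups weighted like the published phenogroup sizes, ischemic-
dominant groups 4–5, per-group CRT-D shares from the published table,
25 features whose per-group Bernoulli p / Normal (μ, σ) track the
published group summaries, MCAR missingness per feature (labs ≈ 35%,
drugs ≈ 9%), three junk features guaranteed ≥ 40% missing, exponential
event times with baseline hazard 0.12/year (≈ 45% five-year mortality),
device log-HRs of log 0.61 and log 0.84 in groups 2 and 5 and 0 elsewhere,
administrative censoring at 12 years, and low-rate upgrade/LVAD/transplant
censoring. Event times are exponential so proportional hazards holds
exactly and Cox recovery has a well-defined truth; missingness is MCAR,
under which mean imputation is unbiased. Latent labels are emitted for
evaluation only.

`well_separated_config` is the recovery benchmark: groups sit at five
angles of a latent circle and every feature loads on that circle with its
own phase (mean amplitude 1.6 within-group SDs; binary flags follow the
same circumplex through their Bernoulli p). The circumplex geometry is
deliberate: a correlation distance only sees the *pattern* of a patient's
row, and designs where many features share the same per-group mean
profile collapse to a low-rank pattern after row centring, leaving the
five groups indistinguishable however large the mean separation. The
amplitude trades off valley depth (community separation) against network
connectivity; 1.6 keeps the Mapper graph connected while the adjusted
Rand index between latent groups and recovered phenogroups is ≈ 0.7–0.95
across seeds (median ≈ 0.84 over 30 seeds at n = 1000, resolution 8).

What the generator does *not* emulate: within-group feature correlation
beyond the latent group structure (no copula), informative (MNAR)
missingness, time-varying hazards, and calendar-time effects. Passing
tests therefore demonstrate correctness of the pipeline's mechanics and
estimator consistency under the stated model, not robustness to those
real-data complications.

## Numerical and degenerate-input choices

- Quantile cover boundaries are made monotone under heavy ties.
- A cell with identical merge heights, or no empty histogram bin, is one
  cluster; singleton cells yield singleton nodes.
- Distance matrices are validated symmetric; MDS pads missing
  positive-semidefinite directions with zero columns and warns.
- Cox fits drop constant covariate columns with a warning (they carry no
  partial-likelihood information); non-convergence raises with lifelines'
  diagnostics.
- Reverse-KM quantiles the curve never reaches come back as NaN with a
  warning.
- All randomness (generator draws, Louvain visit order) flows from
  integer seeds; distance, lens, cover, and clustering are deterministic.

## Problem sizes

Tests run cohorts of 300–1000 patients (Mapper resolution 6–8) and
estimator-recovery simulations up to n = 20 000 with 1000-replicate
log-rank calibration; the acceptance script simulates two cohorts of
n = 20 000. These sizes give stable estimates (Cox SE ≈ 0.02 on the log
scale at n = 20 000) while keeping a full run in tens of seconds.

## Known limitations

- The in-cell clusterer is the classic single-linkage/histogram-gap
  heuristic; the commercial tool's clusterer is undisclosed, so node-level
  agreement with it cannot be claimed.
- “Equalized” is implemented in the cover (equal-frequency intervals),
  the only reading that changes behaviour.
- The merge rule is purely connectivity-based; the source analysis also
  consulted mortality patterns when choosing boundaries. Mortality per
  group is surfaced for inspection but never used in the merge.
- Classification of new patients into existing phenogroups is out of
  scope.
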