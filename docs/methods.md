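# Methods

## Scope and model

`ccsrt` covers the annotation-filtering half of an untargeted LC–IMS–HRMS
workflow: given a standards library measured on one platform (one Rt per
compound; one CCS per compound × adduct), it trains structure-based
predictors for both properties, derives matching tolerances from their
validation errors, predicts both properties for an arbitrary candidate
catalogue, and uses the predicted database to prune accurate-mass
annotations. Feature extraction, normalization, and the statistics that
select "interesting" features are upstream and out of scope, as are
fragmentation and isotope-pattern scoring (accepted as optional pre-computed
columns, never computed internally).

## Mass and adduct arithmetic

All masses are monoisotopic. Elemental formulas are parsed strictly (Hill
notation; charges and isotope labels rejected rather than guessed) and
summed over a NIST-derived most-abundant-isotope table. Adduct mass shifts
are derived at import time from elemental compositions plus the electron
mass (0.00054857990924 Da), so every shift constant is consistent with the
formula-mass function by construction; the supported set is the union of the
adducts a travelling-wave vendor pipeline reports and the adducts the CCS
predictor covers. `[M+CH3OO]-` is treated as a vendor-notation alias of the
acetate adduct `[M+CH3COO]-`. A sanity anchor: `[M+H]+` of C28H37N5O7
(leucine enkephalin) evaluates to 556.2766, the standard ESI lock mass.
m/z is reported to 4 decimals and neutral masses to 6; rounding happens only
at I/O.

## Descriptors

The descriptor panel is the full RDKit 2D panel (~209 descriptors:
constitutional and fragment counts, topological indices, Crippen logP/MR,
H-bond donor/acceptor counts, TPSA, EState and partial-charge summaries)
minus `Ipc`, whose unscaled value overflows for larger structures.
Incomputable descriptors are recorded in a missing mask, never imputed;
compounds with missing selected descriptors are excluded from training and
listed in the run log, and prediction for such compounds raises a
"prediction unavailable" signal rather than failing silently.

## Retention model (QSRR)

Retention time is a property of the neutral molecule: compounds detected in
both ESI modes contribute one Rt row (the mean, if replicates disagree).
Descriptors pass a three-step filter — drop any column with missing values,
drop near-zero variance (< 1e-8), then drop the later-indexed member of any
pair with |Pearson r| > 0.95 — before per-fold standardization. The
reference regressor is an RBF-kernel SVR grid-searched over
C ∈ {1, 10, 100, 1000}, γ ∈ {1e-4, 1e-3, 1e-2, scale}, ε ∈ {0.05, 0.1} by a
seeded internal 3-fold CV. The γ grid deliberately reaches values small
enough to make the kernel nearly linear, because with ~100 retained
descriptors and a retention signal carried by a few correlated directions,
moderate-γ RBF kernels dilute the signal.

Two error estimates are reported and labelled separately: the apparent
(in-sample) training R²/MAE of the refit winner, and k-fold CV metrics
(default k = 10) where the entire procedure — standardization and grid
search included — is refit inside each fold. Rows are canonicalized by
compound id before the seeded shuffle, so fold composition is independent of
input row order. The per-fold MAE SD (n−1) feeds the Rt tolerance.
Prediction carries an extrapolation flag when any selected descriptor falls
outside its training range or the prediction leaves the chromatographic
window (default run length 23 min) — the situations where QSRR predictions
are unreliable: unretained compounds, late eluters, chemistry unlike the
training set. Out-of-window database predictions are clipped to the boundary
and flagged, never dropped.

An 80/20 seeded split provides held-out reporting; CV runs on the training
portion.

## CCS model (cluster regression)

The architecture is centroid clustering plus per-cluster regression:
compounds are partitioned by seeded k-means in standardized, filtered
descriptor space, and each cluster fits its own regressor on
(descriptors ⊕ m/z ⊕ one-hot adduct) → CCS. The adduct encoding carries
polarity, so both ESI modes are modelled jointly and two adducts of one
metabolite receive different CCS (they share one Rt). The per-cluster
regressor is a grid-searched RBF SVR by default; the `kernel="linear"`
option is implemented as ordinary least squares, which makes the
single-cluster linear configuration exactly reproducible against a
normal-equations oracle (an ε-insensitive linear SVR would not be). The
cluster count can be fixed (default 3) or selected by mean silhouette over
k ∈ 2..8; clusters falling under the minimum occupancy (10) trigger
automatic reduction of k. Prediction assigns the nearest centroid and flags
entries farther from it than any training member of that cluster.

Known limitation: on realistic metabolite collections, silhouette-based
selection tends to prefer k = 2 (lipids versus the rest) — chemical space is
not a clean mixture of well-separated spherical clusters. The selection
machinery is therefore validated on controlled class mixtures, and on
generated libraries we check instead that k-means at k = 3 aligns with the
latent chemical families (adjusted Rand index well above chance). Grossly
deviating measured CCS values are retained during training: without evidence
of error, outliers are data.

## Tolerance calibration

For a validation set of paired (predicted, measured) values the package
reports the OLS line of predicted on measured (slope, intercept, R²), the
MAE, the SD of signed errors (n−1 denominator), and the SD as a percent of
mean(measured) — the percent denominator is an explicit assumption, flagged
in reports. The annotation window is `MAE + k·SD` with k = 2 by default; a
variant centered on the absolute signed-mean error is available behind a
flag. For CCS the inputs are held-out residuals; for Rt the default inputs
are the CV mean MAE and the SD of per-fold MAE, since those characterize
error on unseen compounds. `relative_band` returns the ±k·SD percent band
around the calibration line. These derivations are pure arithmetic:
MAE 3.94 Å² and SD 6.11 Å² give 16.16 Å²; 0.81 min and 0.15 min give
1.11 min; a 3.36 % relative SD gives a 6.72 % band.

## Annotation

A database row is a hit for a feature iff polarity matches, |Δm/z| ≤ mz_tol
(absolute, default 5 mDa; a ppm mode exists behind a flag) and, per enabled
dimension, |ΔCCS| ≤ ccs_tol and |ΔRt| ≤ rt_tol — all boundaries inclusive.
Features lacking CCS under a CCS-requiring strategy are handled by policy:
"pass" (default; dimension skipped and the hit flagged) or "fail". Matching
uses an m/z-sorted index with binary search; an exhaustive double-loop
oracle is kept in the test suite and the two are asserted equal on random
instances. Hits are per (metabolite, adduct); a per-metabolite collapsed
view supports cross-checking an identification across its ion forms.

Candidates are ranked by the mean of normalized errors
(|Δmz|/mz_tol, |ΔCCS|/ccs_tol, |ΔRt|/rt_tol over enabled, usable
dimensions), ties broken lexicographically by (|Δmz|, |ΔCCS|, |ΔRt|,
candidate id) — fully deterministic. Report aggregates include the
feature-count distribution over {0, 1, 2–10, >10} hits and, between two
strategies over the same features, the percent of hits filtered and the
change of the single-hit and >10-hit bins. Integer percents truncate toward
zero (46/51 → 90, 37/51 → 72); raw fractions are emitted alongside.

## Synthetic data

The generator emulates a commercial standards plate and an untargeted
feature export with full ground truth:

* **Structures** — a curated pool of 309 metabolite structures in three
  chemical families (polar small metabolites; nucleosides and aromatic
  acids; lipids), a hand-curated core extended by homologous-series
  templates. Real structures were chosen over random graph generation so
  descriptors are chemically meaningful.
* **Retention law** — Rt = 0.7 + 16.3·logistic(1.6·z) min, where z is a
  standardized hydrophobicity combination (0.8·z(logP) + 0.2·z(−TPSA)):
  polar compounds elute early, lipids late, bounded by the gradient window.
* **CCS law** — CCS = A_c·(M + adduct shift)^0.5 + δ_adduct, with A_c per
  chemical family (9.0 / 10.2 / 11.8 Å²·Da^−½) and small per-adduct offsets;
  within a family and adduct, CCS increases with mass, as in homologous
  series.
* **Noise** — Gaussian: Rt SD 0.3 min, CCS SD 2 Å², feature m/z jitter
  1 mDa. These defaults put synthetic validation errors on the scale of a
  real travelling-wave platform (CCS MAE a few Å², Rt MAE well under a
  minute), so the derived windows are meaningful numbers rather than
  arbitrary ones. About 3.4 % of standards are flagged
  descriptor-incomplete to exercise the exclusion path.
* **Features** — true features are database rows jittered by (1 mDa,
  0.1 min, 1 Å²); decoy database rows are planted inside the m/z window of a
  true feature but displaced by ≥ 1.5× the matching tolerance in CCS, Rt, or
  both, guaranteeing separability up to jitter (so the decoy-removal
  property is honest by construction, not tuned); noise features are placed
  ≥ 2 windows away from every database m/z. `simulate_feature_table` returns
  the features, the decoy-augmented database, and a label table of every
  intended pairing.

What passing on synthetic data does **not** show: real descriptor–property
relationships are rougher than the generator's smooth laws, real CCS errors
are heteroscedastic across chemical classes, co-elution and in-source
fragmentation create feature artifacts the generator omits, and real decoys
(wrong isomers) are not guaranteed to sit 1.5 tolerances away. The synthetic
study validates the machinery and its statistical bookkeeping, not
instrument-level performance.

## Determinism and problem sizes

Every stochastic operation is a pure function of (inputs, seed); reruns with
one config produce byte-identical database CSVs (fixed column order; m/z to
4 decimals, CCS to 2, Rt to 3). The default study conditions — a
200-compound library (~570 measured CCS rows across six adducts), 10-fold
CV, 3 clusters, 40 true / 30 decoy / 10 noise features — run end to end in
well under a minute on one CPU, which keeps the test suite and the
acceptance script fast while leaving every statistic estimable; the builder
streams candidates in chunks of 10,000 for catalogue-scale runs.

## Error handling conventions

Unparseable structures and formulas flag records as unusable and route them
to rejects tables with reasons — never silent drops. Degenerate inputs
(constant vectors, empty matrices, all-filtered descriptor sets, conflicting
measured duplicates) raise typed exceptions. Pipeline stage failures abort
with the stage name. Logs record the counts at every filtering step
(exclusions, rejects, clipped predictions) so a run's narrative is
recoverable from its artifacts.
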