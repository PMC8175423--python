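# Methods

This note documents the models and procedures implemented in `voctrait`, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic benchmark does and does not demonstrate.

## Data model

An `EmissionMatrix` is a samples × compounds table of non-negative emission
rates from one platform (PTR mass features in ncps cm⁻² s⁻¹, or GC compounds
in pmol cm⁻² h⁻¹), with sample keys `species:replicate`.  Zeros encode
"not detected"; there is no separate missing-value state — absent emissions
enter every downstream statistic as true zeros, which keeps correlation and
evenness computations single-valued.  Units and platform travel with the file
as mandatory `#units=` / `#platform=` pragma lines; silent unit mixing is
treated as the most dangerous failure mode of this kind of data, so a file
without pragmas is rejected.  Values round-trip losslessly at 12 significant
digits.  `merge_platforms` concatenates the two tables (PTR columns first)
over identical sample sets; scale compatibility across platforms is deliberately
deferred to the unit-variance standardization inside the discriminant analysis.

## Synthetic study generator

The generator produces a dual-platform study with known answers.  On the log
scale, for compound *j*, species *s*, replicate *r*:

    x = mu0 + a_j + b_{g(s),j} + lambda·f_{s,c(j)} + eps

with `a_j ~ N(0, 0.5)` a per-compound baseline, `b` the planted biomarker
shift (`delta · sigma` for species carrying the targeted label value), `f_{s,c}
~ N(0,1)` a per-species latent factor shared by all compounds of structural
class *c* inside a covariation block with weight `lambda`, and `eps ~ N(0,
sigma)` replicate noise.  Emission is `exp(x)`, set to exactly 0 with
probability `sparsity` per (species, compound) — a species either emits a
compound in all replicates or never, so replicate profiles act as species
fingerprints.

Defaults (the study conditions used throughout the tests): 43 species × 3
replicates; 200 PTR + 60 GC compounds; `mu0 = 2`, `sigma0 = 1` (so emissions
span several orders of magnitude, matching dominance-prone volatile profiles);
`sparsity = 0.35`; GC noise scaled by 0.6 so GC evenness exceeds PTR evenness;
six single-compound trophic-mode biomarkers at `delta = 3` plus smaller planted
sets for phylum, lifestyle, substrate and host type; one covariation block
(saprotrophic × carboxylic acids, loading 0.8).  The per-species latent factors
are drawn once and shared across platforms, so planted covariation spans a
class's PTR and GC members alike.

Two deliberate choices:

* **Masking never hits a biomarker in its carriers.**  If sparsity silenced a
  planted biomarker in the group it marks, the "ground truth" would stop being
  true; the mask is suppressed for (carrier species, planted compound) pairs
  only.
* **Label schemes are mutually non-nested.**  Balanced label assignment uses
  cycle periods chosen so that no scheme is a deterministic function of
  another; otherwise biomarkers planted for one scheme would be genuine
  predictors of a different scheme and recovery metrics would be meaningless.
  An `unbalanced` preset (2 mycoparasites, 8 mycorrhizal, 13 phytopathogens,
  20 saprotrophs) exercises the minority-upsampling path.

The one-factor construction keeps closed forms available: within a block the
expected pairwise log-scale correlation is `lambda² / (lambda² + sigma²)`, and
planted shifts have effect size `delta` in units of the within-class log-sd.
What the generator does **not** emulate: real compound identities or
fragmentation chemistry, instrument drift, replicate-level (rather than
species-level) detection dropout, phylogenetic autocorrelation among species,
and any correlation between emission intensity and label beyond what is
planted.  Tests passing on this benchmark show the machinery is correct and
well calibrated, not that real volatilomes are this easy.

## Preprocessing chains

PTR, in fixed order: cps × 10⁶ / reagent-ion counts (ncps); natural cubic
spline through the ≥ 4-point background series evaluated at sample timestamps
and subtracted, negatives clipped to 0 (correlations and evenness require
non-negative abundances; the clip is the only information-destroying step and
is documented as such); division by mycelium area × accumulation time (70 min
default).  Optional ncps → pmol conversion divides by a per-compound
calibration sensitivity; compounds without one are flagged and left in ncps,
never dropped.  The exact flow/molar-volume constant of a real instrument is
not hard-coded — the conversion is a configurable linear map.

Isotopologue flagging removes features whose mass sits one ¹³C (+1.00336 Da)
or one ¹⁸O (+2.00425 Da) above a lighter feature within a 3 mDa tolerance
**and** whose mean intensity ratio is within [0.2×, 5×] of the natural-
abundance expectation (carbon count ≈ (m/z − 1.008)/14 × 1.1%).  The ratio
check — switchable off — protects genuine compounds at coincidental mass
spacings.  Fragment grouping connects compounds with squared Pearson
correlation > 0.9 across samples and annotates connected components; groups
are annotated rather than collapsed because mass features remain the analysis
unit (collapsing by summation is an explicit option).  Constant columns have
undefined correlation, treated as 0.

GC: peak areas are rescaled so the internal standard matches its reference
area, then area/time-normalized (16 h = 960 min collection default).
Retention indices use the temperature-programmed linear (van den Dool–Kratz)
form `RI = 100·(n + (rt − rt_n)/(rt_{n+1} − rt_n))` on a C9–C25 alkane ladder
— appropriate for a temperature-programmed oven, unlike the isothermal
logarithmic form — with no extrapolation outside the ladder.

## Diversity

Pielou evenness is computed on the replicate-mean profile of each species (one
J per species), over strictly positive entries, with natural logarithms (J is
base-invariant).  Exactly equal positive entries return exactly 1.0, avoiding
log round-off at the boundary.  Fewer than two detected compounds make J
undefined; it is reported as null.  Whether evenness should be computed per
replicate and averaged instead is genuinely open; the mean-profile convention
was chosen because one value per species is what the summaries report, and it
is documented here rather than hidden.

## Compound clustering

Compounds are clustered on `d = 1 − rho` (Spearman over species-mean
profiles; ties mid-ranked; constant compounds get rho := 0 against
everything), agglomerated with average linkage (UPGMA; complete linkage via
config — the correlation basis, not the linkage, is the method's defining
choice), and cut into exactly `k` clusters (default 17).  Letters are assigned
in dendrogram leaf order, making the labeling invariant to input order up to
relabeling.  Rank correlation makes the whole stage invariant to monotone
transforms of any compound, so the linear-vs-log question does not arise here.

## DAPC

`fit_dapc` centers and scales columns (zero-variance columns dropped with a
warning), takes the top `m` right singular vectors as PC loadings, and solves
the between/within scatter generalized eigenproblem on the PC scores (a tiny
ridge, 1e-9 of the mean within-scatter diagonal, keeps the problem definite
when `m` approaches `n − k`; axis signs are fixed deterministically).
Prediction projects through the stored chain and assigns to the nearest group
centroid in discriminant space; the reported scores are a softmin of squared
centroid distances and are explicitly a heuristic posterior — assignment is
what the analysis rests on, and it is identical under a Gaussian-density
posterior.  Ties are broken by training group order and flagged.

`m` is selected by repeated stratified holdout (default 30 replicates, 90%
training) over ~10 grid values from `k` to `min(n − k, rank)`; the chosen `m`
minimizes `sqrt(mean((1 − success)²))`, ties to the smaller `m`.  The same
splits are reused across the grid so candidates are compared on identical
data.

The pipeline hands DAPC `log1p` profiles by default (config flag).  On
log-normal emissions the linear scale is dominated by a handful of extreme
values and held-out accuracy plateaus well below what the planted signal
supports, while log profiles recover it fully; for data already on a modest
scale the flag can be turned off.  `fit_dapc` itself applies no transform.

## Phenotypic integration

The raw index is the population variance of the correlation-matrix
eigenvalues, `sum((lambda_i − 1)²)/p` (the mean eigenvalue of a correlation
matrix is exactly 1).  Population rather than sample variance makes the
maximum exactly `p − 1`, so the relative index tops out at 100%; a
sample-variance alternative would rescale everything by `p/(p−1)`.  The
correction subtracts `(p − 1)/n`, the expected index under random covariation,
and the relative index divides by `p − 1` and multiplies by 100.  The
permutation loop uses the algebraic identity `sum_{i≠j} r_ij² / p` (from
`sum lambda² = ||R||_F²`), which the tests pin to the brute-force
eigendecomposition to 1e-9.

Null calibration offers two readings of "randomly drawn": `permute` (default)
independently permutes each compound across samples — destroying covariation
while preserving marginals, which is exactly the random-covariation hypothesis
— and `subset` redraws random compound sets of the same size from the full
pool.  Significance is observed > 95% empirical quantile of the null;
`p = (1 + #{null ≥ obs})/(1 + n_null)`; `n_null` defaults to 10,000.

The guild × class panel uses replicate rows as samples (`n` counts
replicates, not species — species means are not collapsed, and the convention
is stated because it materially changes the correction term).  Within each
cell, compounds that are all-zero or constant over the cell's samples are
excluded; cells left with `p < 2` or `n < 3` are reported incomputable with a
reason, and single-species cells (`n = 3`) compute but carry a `low_n` flag.

## Biomarker ensemble

Per task (label scheme) and platform: stratified 75/25 split (every class in
both partitions); minority classes upsampled with replacement to the majority
size in the training partition only; three models — RF-based RFE, bagged-tree
RFE, and a tuned RF ranked by impurity importance.  The RFE implementation is
recursive: per CV fold the estimator is refit and re-ranked at every grid size
(default grid {5, 10, 15, 20, 30, 50, all}); the optimal size maximizes mean
CV accuracy (ties to the smaller size), and the final ranking is the mean over
folds of each feature's elimination rank, ties by first appearance.  The
embedded model tunes features-per-split over 5 CV-scored values spanning
√p..p.  Forests use 100 trees (bagging 50); all estimators are seeded.

Each model is finalized on its top-15 predictors, refit on the balanced
training set and scored once on the untouched test set: accuracy, per-class
sensitivity (one-vs-rest recall; null for classes absent from the test set),
and a one-sided **exact** binomial p-value of the correct count against the
no-information rate (largest test-class prevalence) — exact rather than
normal-approximate because test sets here are ~30 samples.  Models below 80%
accuracy or with p ≥ 0.05 are excluded; the consensus is the intersection of
the survivors' top-15 sets, ordered by mean rank, with aggregated metrics as
plain means over survivors.  By construction no selection or tuning step ever
receives test rows.  Platforms are modeled separately by default (scale and
sparsity regimes differ); a combined mode exists but is off by default.
Cross-task unique-biomarker counts are reported both raw and deduplicated,
since either convention is defensible.

## Pipeline and reproducibility

One JSON config (pydantic-validated, unknown keys rejected) drives all stages.
Per-stage seeds derive from the global seed as
`sha256("{seed}:{stage}")[:4] mod 2³¹`, so a stage rerun in isolation matches
its pipeline-level output.  Artifacts are TSV/JSON with sorted keys and no
timestamps; identical configs produce byte-identical outputs (the config hash
in the manifest excludes the output directory).  A stage failure writes a
status file and preserves completed artifacts.

The shipped `configs/demo.json` runs the default 43-species scenario with
problem sizes chosen for an interactive demonstration: 2,000 null draws per PI
cell, 10 cross-validation replicates per DAPC grid value, and the trophic-mode
biomarker task on both platforms (~1 minute per stage on one CPU).  The
statistical defaults inside the library (10,000 null draws, 30 replicates)
are unchanged; the demo config simply asks for less of the same computation.

## Known limitations

* The PI analysis runs on linear-scale emissions; on strongly log-normal data
  linear Pearson correlations understate log-scale covariation, so relative PI
  values are conservative for the planted blocks.
* The heuristic DAPC posterior is not a calibrated probability.
* The isotopologue carbon-count heuristic ((m/z − 1.008)/14) ignores
  heteroatoms and can over- or under-estimate the expected satellite ratio by
  roughly one carbon's worth; the wide default abundance window absorbs this.
* Consensus false positives of the biomarker ensemble are correlated across
  the three models because all share one training partition; the observed ~1–2
  shared chance selections per task are inherent to the single-split design
  (a repeated-split mode would shrink them at the cost of changing the design).
* `ncps → pmol` conversion is a configurable linear map, not an instrument
  model.
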