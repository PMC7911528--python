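# Methods

## Model

The regressor is a two-level kernel ensemble for log10 *P*app (cm/s).
Level one holds *m* ≥ 2 support vector regression members, each an ε- or
ν-SVR with an RBF kernel fitted on its own descriptor subset of the
normalized matrix. Level two is another SVR whose inputs are exclusively
the member-prediction vector (never the raw descriptors): taking the
descriptors too would blur the local/global division of labor that
motivates the architecture. Members act as local models — each subset
views one mechanistic facet (lipophilicity/polarity, polarity/ionization,
size/aromaticity) — while the meta-regression supplies the global
reconciliation.

Assembly is parsimonious. Candidate members are grid-searched
independently; combinations are then enumerated at sizes 2, 3, 4 (pool
order, lexicographic index tuples) and the first combination whose
meta-model passes the external criteria gate on the held-out test set is
returned. If none passes, the best combination by external q² is returned
with a failed-gate flag. Ties anywhere resolve deterministically (grid
ties toward smaller C, then γ, then ε/ν; equal-fitness RFE removals toward
the lexicographically later column name).

The underlying quadratic-program solver is scikit-learn's libsvm binding
(`SVR`/`NuSVR`); this package does not reimplement it. Default lattices:
C ∈ 2^{−5..15}, γ ∈ 2^{−15..3} (log2 step 2), ε ∈ {0.01, 0.05, 0.1, 0.2,
0.5}, ν ∈ {0.1, 0.25, 0.5, 0.75}. The pipeline convenience layer uses a
coarser 4×4×3 lattice (C ∈ 2^{−1,2,5,8}, γ ∈ 2^{−6,−4,−2,0}) as its
routine default; both are plain arguments.

## Statistics and conventions

All formulas are implemented directly and cross-checked in the tests
against naive loop arithmetic.

- Normalization: x̂ = (x − ⟨x⟩)/s with s the (n−1)-denominator sample
  standard deviation, parameters fit on training rows only and applied to
  all rows (leakage avoidance; the normalization is global, shared by all
  members).
- r²/q² default to the squared Pearson coefficient. The printed-form
  variant (mean *predicted* value in the denominator of the coefficient of
  determination) and the ordinary determination form are both selectable;
  the Pearson default is the only convention consistent with a dataset
  reporting q² and qF2² as distinct values.
- qF1² = 1 − SSres/Σ(y−⟨yTR⟩)² over the external set;
  qF2² uses ⟨yEXT⟩; qF3² = 1 − (SSres/nEXT)/(SSTR/nTR) with SSTR the
  training-set sum of squares about the training mean (the widely used
  form; a variant that sums (y−⟨yTR⟩)² over the external set while
  dividing by nTR is internally inconsistent with qF1 ≈ qF3 on
  well-behaved data and is not used).
- CCC = 2·Sxy / (Sxx + Syy + n(⟨y⟩−⟨ŷ⟩)²) on the external set.
- Through-origin quantities: k = Σyŷ/Σŷ², k′ = Σyŷ/Σy²;
  r0² = 1 − Σ(y − kŷ)²/Σ(y−⟨y⟩)² and r′0² with roles exchanged. The rm²
  family defaults to the radical form rm² = r²(1 − √|r²−r0²|); the literal
  non-radical variant is selectable. Exchanging observed and predicted
  swaps (k, r0², rm²) with their primed counterparts and leaves ⟨rm²⟩ and
  Δrm² invariant (property-tested).
- qCV²: seeded k-fold assignment (k = 10 default; k = n gives
  leave-one-out), the full pipeline refit per fold with fixed
  hyperparameters, out-of-fold predictions pooled into one set before the
  squared correlation is taken.
- Criteria gate: the joint stringent thresholds listed in the README.
  Cross-validation bounds apply only in the training context, the CCC
  floor only externally; non-applicable checks report "N/A", missing
  fields report "cannot evaluate" (never a silent pass). The optional
  `input_decimals` argument widens each boundary comparison by the
  rounding half-ulp of the stated precision; it exists solely for
  evaluating reports populated from *published rounded* values, where
  e.g. r² = 0.91 and qCV² = 0.81 can print |r²−qCV²| = 0.10 although the
  unrounded difference was below 0.10. It defaults to off and plays no
  part in model fitting or gating.

### Y-scrambling

Two protocols are implemented.

- `reapply` (default): the response vector is permuted and correlated
  against the *fixed* predictions of the already-developed model, with
  descriptors and model untouched; ⟨rs²⟩ then estimates pure chance
  correlation, of order 1/n (measured ≈ 0.004 at n = 240).
- `refit`: the model is re-trained on each permuted response with
  identical descriptors and hyperparameters. This variant additionally
  exposes the memorization capacity of the frozen hyperparameters: with
  CV-selected RBF members on ~240 rows, measured ⟨rs²⟩ runs 0.1–0.4, far
  below the genuine training r² ≈ 0.9 but far above chance. A chance-level
  outcome under `refit` is therefore evidence of a *stiff* model, not a
  general property of the protocol.

Failed refits are skipped; at least 80% of repetitions must succeed.

### Classification

Caco-2⁺ iff *P*app ≥ 8×10⁻⁶ cm/s (log10 ≈ −5.0969); the boundary value is
positive by default (configurable). Cooper statistics, MCC, G-mean =
√(Se·Sp), F1 (harmonic mean of precision and sensitivity — the specific
F-measure variant is our choice), and Cohen's κ with chance agreement from
the marginals. A statistic with a zero denominator is reported as
undefined rather than raising; MCC with a fully zero marginal is 0 by the
common convention.

## Preparation choices

- Ion classes from tagged pKa values: acid if all pKa < 7, base if all
  pKa > 7, zwitterion if the strongest acidic pKa (lowest acidic value)
  exceeds 7 while the strongest basic pKa (highest basic value) is below
  7; a compound with no pKa in the 2–12 window, or firing none of those
  rules, is neutral. The one-pKa-equals-neutral reading sometimes seen in
  the literature conflicts with the acid/base rules for single-pKa
  molecules and is not used.
- Intercorrelation filter: pairs with Spearman ρ² ≥ 0.64 are resolved from
  the strongest correlation down; the member with the weaker absolute
  Spearman correlation to the response is dropped (which member of a pair
  to discard is otherwise underdetermined — this rule is our documented
  choice and makes the result column-order-insensitive).
- GA selection: a generic elitist genetic algorithm over binary masks with
  k-fold CV RMSE of a cheap base learner (ridge by default) as fitness.
  It stands in for proprietary genetic function approximation tooling
  whose basis-function details are unpublished; it is plainly named "GA
  selection".
- RFE: leave-one-column-out refits per round, removing the column whose
  absence degrades CV RMSE least.
- Outliers: the union of the structural rule (> 9 rings or > 12 HBAs) and
  a Mahalanobis distance rule in PC space at a χ² quantile (default 0.99).
  Visual inspection of a chemical-space plot is not reproducible; the
  parametric rule is the codified substitute and the structural rule is
  applied regardless of PC position.
- Splitting: seeded uniform 4:1 partition (130 compounds → 104/26);
  optional response-stratification is off by default. A two-sample KS
  report over log P_app, MW, SA, PSA, HBA, HBD and log P quantifies
  train/test similarity.
- 2D descriptors come from RDKit (Crippen log P, topological PSA, strict
  rotatable-bond count, Labute ASA); no parity with proprietary descriptor
  engines is attempted — the framework is descriptor-agnostic, and
  DFT-level quantities are always ingested as precomputed columns. The
  additive atomic-polarizability fallback for α is adequate because α
  tracks molecular weight almost linearly. Descriptor computation
  re-parses the canonical SMILES first so that different writings of the
  same molecule give bit-identical vectors.

## Synthetic data

The generator emulates the mechanistic structure of Caco-2 permeation:

y = −4.2 + 0.35·min(logP, 3) − 0.40·max(logP−3, 0) − 0.010·PSA −
0.15·HBD − 0.60·1[n_ar ≥ 3 ∧ HBD ≥ 2] + ion_offset + N(0, 0.15²)

with logP ~ N(2, 1.5²), PSA ~ Gamma(3, 25), counts Poisson, α ≈ 0.27·MW
(r ≈ 0.98), per-class pKa windows, and ion offsets 0 / −0.35 / −0.30 /
−0.55 for neutral/acid/base/zwitterion (neutral compounds most permeable).
The threshold interaction in n_ar and HBD is the simplest stand-in for
efflux-transporter substrate recognition. Effect sizes were fixed once to
put a well-specified model near r² ≈ 0.9 at noise SD 0.15 and are frozen.

What the generator does *not* emulate: real descriptor covariance beyond
the α–MW and ring–aromatic couplings, assay noise heterogeneity,
inter-laboratory shifts, saturable transporter kinetics, or any actual
membrane biophysics. Passing tests therefore demonstrate that the
machinery recovers a known mechanism of this shape at realistic
signal-to-noise — not that the fitted models transfer to experimental
Caco-2 data.

A pinned 12-compound fixture (`simulate.worked_fixture`) with hand-set
precomputed descriptors — all four ion classes, one ten-ring structural
outlier — carries the documentation examples; its responses are the
generator's noise-free closed form.

## Problem sizes and numerics

Routine runs and the acceptance script use n = 300 compounds (240/60
split), the coarse grid above, 10-fold qCV², 25 scrambling repetitions,
and ten seeded replicates for the local-vs-global comparison; these sizes
are the package's default study conditions. Degenerate inputs are
rejected loudly: zero-variance columns (named, or dropped in lenient
mode), constant vectors in correlation statistics, fewer than 4 rows for
the distance rule, n < 2 for s. Normalize-then-denormalize recovers raw
values to 1e−12 relative error; PCA reconstruction with all components is
exact to 1e−9.

## Known limitations

- The envelope observation — meta predictions lying between the member
  minimum and maximum — holds when members err on opposite sides of the
  response (the regime the scheme targets) and is property-tested there;
  it is *not* a constraint of the meta regression, and fitted ensembles
  whose members agree closely exit the narrow envelope freely.
- The criteria gate evaluates fixed thresholds; it does not correct for
  multiple testing across enumerated ensemble combinations.
- ν-SVR members are implemented and tested but the pipeline default is
  ε-SVR.
- Applicability-domain handling is limited to the outlier rules; no
  per-prediction distance-to-model estimate is produced.
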