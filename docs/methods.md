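# Methods

This note documents the models implemented in `nanosorb`, the assumptions
and parameter choices behind them, what the synthetic-data generators do
and do not emulate, and the numerical conventions adopted where the
underlying methodology leaves the choice open.

## The two-tier QSAR scheme

The quantity of interest throughout is log *k*, the base-10 logarithm of
the adsorption affinity constant of a small molecule for a nanomaterial
surface. (Base 10 is a convention choice: the linear free-energy literature
does not always state the base, but QSAR practice and the frozen models'
coefficient scales are consistent with log₁₀, which the package uses
everywhere, including for PMF-derived affinities.)

**Tier 1 — BSAI.** The biological surface adsorption index treats
adsorption as a sum of independent interaction free energies:

    log k = c + E·r_e + S·p_s + A·a + B·b + V·v

[*E, S, A, B, V*] are the Abraham solute descriptors (excess molar
refraction, dipolarity/polarizability, H-bond acidity, H-bond basicity,
McGowan volume — dimensionless or in the customary Abraham units);
[*c, r_e, p_s, a, b, v*] are nanomaterial-specific regression weights
("nanodescriptors") fitted elsewhere to probe-compound adsorption
measurements. The model is exact-by-construction linear algebra; its
assumptions (additivity, no conformational or isomer effects, no special
functional-group chemistry) bound where it can be applied, which is what
the applicability-domain machinery quantifies. Nanodescriptor values are
experimental data: the package ingests them from a user-supplied YAML/JSON
registry and deliberately ships none.

**Tier 2 — descriptor-based regressions.** Abraham descriptors are
measured, not computed, so they are unavailable for most metabolites.
Tier 2 regresses Tier-1 predictions on molecular descriptors that *can* be
computed from structure, yielding one five-descriptor linear model per
nanomaterial. A frozen registry of 19 such models is packaged
(`data/frozen_models.json`); each stores the intercept, the five named
coefficient terms, and adjusted R² metadata. Evaluating a frozen model at
the all-zero descriptor vector returns its intercept exactly, which the
test suite uses as a transcription check on all 19 rows.

### Training protocol

* **Partition.** The compounds with the global minimum and maximum
  response are forced into the training set (predictions then interpolate
  rather than extrapolate in the response); the remaining compounds are
  binned into 5 response quantiles and each bin is split randomly at the
  train fraction. Supported fractions are 0.9/0.8/0.7/0.6; 0.8 is the
  package default, the ratio at which such models validate best. With too
  few compounds per bin the partitioner reduces the bin count with a
  warning; with two compounds both are extremes and the validation set is
  empty.
* **Forward selection.** At each step the candidate descriptor giving the
  largest R² of the working OLS fit joins the model, restricted to
  candidates whose inclusion keeps every variance-inflation factor of the
  included set ≤ 2 (VIF = 1/(1−R²) of one column regressed with intercept
  on the others; perfect collinearity reports ∞ and is thereby always
  blocked). Selection stops at five terms or when no admissible candidate
  improves the fit. Raw R² (not adjusted) is maximized per step — with a
  fixed one-term increment both orderings agree, and raw R² is the simpler
  invariant (the selection trace is non-decreasing by construction). Ties
  in R² gain are broken lexicographically by descriptor name, making
  training fully deterministic given the seed.
* **Refit and score.** The final model is refit by OLS on the selected
  columns. Adjusted R² = 1 − (1−R²)(n−1)/(n−p−1) is reported for training
  and validation with p = number of selected descriptors; for the
  validation set the same formula is applied with n = validation size
  (there is no universal convention for a validation-set adjustment; this
  one keeps the two numbers comparable).

### Descriptors

Most descriptor columns (topological autocorrelations ATSm/ATSp, Wiener
path count WPATH, E-state fragment counts khs.\*, Kier shape indices, …)
are vendor-toolkit quantities whose exact definitions vary by
implementation and version. The package therefore treats them as opaque
ingested columns, validated only for numeric type and name. A native
RDKit-backed calculator covers the unambiguous subset (atom, donor,
rotatable-bond, acid/base, small-ring counts, Fsp3, C1SP3) with each
definition documented in `descriptors.py`; hydrogens are made explicit
before counting and aromaticity is perceived by RDKit.

## Compound-set cleaning

Raw Abraham-descriptor collections are cleaned in three steps: SMILES
corrections applied by key, recommended exclusions dropped (poor data
quality, metals, salts), then replicate entries of the same compound
collapsed to one seed-controlled random representative and
descriptor-identical isomer groups (equal in all five Abraham values)
collapsed to one. The operation is idempotent. The reference external
collection this targets is a ~2000-compound experimental dataset that the
package does not ship or download; the cleaning logic is unit-tested on
synthetic tables.

## Applicability domains

* **Leverage.** h_ii is the diagonal of X(XᵀX)⁻¹Xᵀ for the design X
  (intercept included), computed via the thin QR factorization. Σh_ii = p
  on every full-rank design, a property test.
* **Critical hat.** h\* = 3(N+1)/n with N the number of descriptors in the
  model and n the reference-set size. For the 5-descriptor BSAI design and
  the 23 probe compounds, h\* = 18/23 = 0.78.
* **Insubria rule** (compounds without measured responses): in-domain iff
  h < h\* (strict: a compound *at* the threshold is out) and, in
  `both_thresholds` mode, the prediction lies within mean ± 3σ of the
  probe-compound predictions. σ is the sample standard deviation (n−1);
  the convention is not dictated by the rule and is documented here. The
  three modes are nested: every compound admitted with both thresholds is
  admitted with the hat threshold alone, and `none` admits everything —
  so in-domain counts are monotone non-decreasing as thresholds are
  dropped, a property the tests assert.
* **Williams rule** (training/validation compounds): in-domain iff
  |standardized cross-validated residual| ≤ 3 and h ≤ h\*. The boundary
  convention deliberately differs from Insubria's ("larger than h\*"
  excludes, so equality stays in); both follow their respective
  formulations literally and the asymmetry is intentional and tested.
  Residuals are leave-one-out standardized residuals computed from the
  single-fit hat identity (e_i/(s·√(1−h_ii))); k-fold alternatives exist
  but LOO is the deterministic choice.
* **Ordination-centroid rule.** Pairwise Mahalanobis distances over the
  full compound set (pooled covariance; pseudo-inverse fallback when
  singular) are embedded in 2-D by non-metric MDS (seeded, 20 random
  restarts, best stress kept; normalized stress > 0.30 raises rather than
  returning a meaningless embedding). A compound is in-domain when its
  distance to the probe centroid is at most the largest probe–centroid
  distance. The reference radius is not prescribed by the construction;
  max probe distance is this package's choice, making every probe
  in-domain by definition. An all-coincident degenerate input returns
  everything in-domain with zero stress.

## Nanomaterial comparison statistics

Predicted log *k* matrices (nanomaterials × compounds) are shifted by the
global minimum so all values are non-negative (idempotent), then converted
to Bray–Curtis dissimilarities d(u,v) = Σ|uᵢ−vᵢ|/Σ(uᵢ+vᵢ).

**dbRDA.** The squared dissimilarities are Gower-centered
(G = −½·J·D²·J). Sums of squares are traces of projections of G: for the
full predictor set with hat matrix H, SS_model = tr(HG) and
SS_res = tr((I−H)G); negative eigenvalues of G are retained in the totals
(the McArdle–Anderson convention — no Lingoes/Cailliez correction, for
simplicity and to match the reference implementation). The marginal
(type-III-like) F for predictor j is

    F_j = [tr(HG) − tr(H₋ⱼG)] / [tr((I−H)G)/(n−p−1)]

with numerator df 1 and denominator df n−p−1 (19 nanomaterials and 5
nanodescriptors give df 13). Permutation p-values freely permute the
items — rows and columns of G jointly — with 999 permutations by default
(p floor 1/1000) under a fixed seed; permuting raw items rather than
reduced-model residuals is the simple exchangeability scheme and is
calibrated by test (KS uniformity of null p-values). The implementation
is cross-checked against the R `vegan` reference on a fixture: marginal F
statistics agree to 4+ decimals.

**Group comparisons.** Kruskal–Wallis (scipy) followed by Dunn's pairwise
z from rank sums with the tie correction
σ² = (N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/nᵢ+1/nⱼ), two-sided normal
p-values, Holm step-down adjustment over all pairs (statsmodels). Holm
never decreases a raw p, a property test. Spearman correlations use
average ranks on ties (scipy) and refuse zero-rank-variance input.

## PMF affinities

For molecules outside the QSAR domain, the adsorption constant comes from
a molecular-dynamics potential of mean force w(z) (kJ/mol) versus
surface–molecule distance z (nm):

    k = ∫_{z_min}^{c} exp(−β·w(z)) dz,   β = 1/(k_B·T)

* k_B is the molar gas constant in kJ/(mol·K) since w is per mole; the
  default T = 310 K matches the physiological thermostat temperature of
  the simulations this ingests.
* The usual material-dependent prefactor is omitted (it must be measured),
  so k carries units of nm and absolute offsets of w act as pure
  multiplicative constants; the profile is therefore shifted so the bulk
  plateau mean is zero before integrating, standardizing comparisons.
  (Offset invariance under this shift is a test.)
* Integration is composite trapezoid on the exp-transformed values,
  evaluated in log-sum-exp form so arbitrarily deep wells cannot overflow;
  the naive and stable paths agree wherever the naive path is
  representable. Trapezoid k converges to the closed form on flat and
  square wells (relative error < 1e−3 at 10⁴ points) and k is monotone
  decreasing in T for attractive wells — both asserted in tests.
* The cutoff c is the onset of the bulk plateau: scanning outward from the
  global minimum of w, the smallest z whose forward window (default 10
  points) fits a line with |slope| ≤ 0.5 kJ/mol/nm and whose value is
  within 1 kJ/mol of the bulk level (mean of the last window). A profile
  still rising at its end raises an error suggesting a longer profile.

MD-vs-QSAR agreement is summarized by a Pearson correlation over shared
molecules with an explicit exclusion set (e.g. a charged species that a
fixed-charge force field handles poorly), requiring ≥ 3 molecules after
exclusion.

## The metabolite inventory

The packaged inventory holds 170 unique metabolites over 13 categories
plus a catch-all ``other``; acetylcholine and 5-hydroxytryptamine are
stored once with dual category membership, and category counts expand such
records (counts sum to 172). The published tallies are internally
inconsistent at the margin — the enumerated per-category counts sum to
exactly 170 while also double-assigning two metabolites and claiming 170
uniques — so the reconstruction keeps 170 uniques and all enumerated
counts except the catch-all (packaged as 23), the category whose count is
least stable in the source material itself. Names and categories follow
the published overview where listed; where a category enumerates fewer
names than its count, clearly-flagged plausible fillers complete it, and
the per-review provenance is a deterministic reconstruction encoding the
cumulative discovery totals 137 (3 reviews) / 161 (5) / 170 (10). The CSV
header states all of this; analyses of real provenance data should load
their own inventory with `load_inventory`.

## Synthetic data: what it does and does not show

The generators produce: uniform (optionally Gaussian-copula-correlated)
Abraham descriptor tables within small-organic ranges; descriptor/response
tables whose response follows a specified linear model exactly or with
Gaussian noise, plus independent decoy columns; and PMF profiles (flat,
square well, parabolic smooth well) with closed-form or dense-quadrature
ground truth. All are pure functions of their configuration.

Passing tests on this data demonstrates algorithmic correctness —
coefficient recovery, AD-set nesting, permutation-test calibration,
quadrature convergence — under independence and within-range assumptions.
It does **not** demonstrate predictive performance on real chemistry: real
descriptor joints are heavy-tailed and collinear, real responses are not
exactly linear, and real PMFs have noise structure a Gaussian perturbation
does not mimic. Quantities that depend on the real external compound
collection or on unpublished simulation output (empirical R² values,
in-domain metabolite counts, MD-vs-QSAR correlation magnitudes) are
exercised only qualitatively, via the monotonicity and calibration
properties above.

## Problem sizes

The test suite and acceptance script run at desk scale by design: n = 200
compounds for pipeline-recovery checks, 19 items × 5 predictors for dbRDA
(the study's own geometry), 200 replicates × 199 permutations for null
calibration, 10⁴-point grids for quadrature checks. These sizes are where
the checked properties already hold tightly; nothing in the methodology
depends on larger inputs.

## Known limitations

* Vendor descriptor parity is out of scope; frozen models applied to
  tables from a different toolkit version than their training tables can
  shift predictions.
* Nanodescriptor uncertainty is not propagated; Tier-2 models inherit
  Tier-1 predictions as error-free responses.
* The NMDS-centroid rule depends on embedding quality; high-dimensional
  isotropic inputs legitimately fail the stress gate.
* `proteins/enzymes` metabolites are inventory-only: their conformational
  behaviour is outside every model here.
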