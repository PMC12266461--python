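# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `oligopeel`.

## Data model

A product spectrum is modelled as a superposition of constituent series.
Constituent *c* (base compound mass *B_c*, sodium adduct) contributes ions at

    m/z(n) = B_c + n · m_EO + m_Na,        n = 0, 1, 2, …

with *m_EO* = 44.0262 Da (monoisotopic; 44.053 average; 58.0419/58.080 for
propoxylates) and envelope weights over the EO count *n* that are bell-shaped.
The *distribution* of constituent *c* is this comb of peaks plus its envelope;
its apex marks the most abundant oligomer.  Spectra additionally contain
¹³C isotopologue combs offset by +k·1.0034 Da, matrix-derived peaks, and
baseline noise.

## Preprocessing

Fixed order: proportional binning → matrix-peak removal → total-integral
normalization → replicate averaging.

* **Binning** (0.1 Da default): a centroid count *c* at mass *m* between bin
  centres *b_lo* and *b_hi* adds *c·(b_hi−m)/Δ* to the lower and
  *c·(m−b_lo)/Δ* to the upper bin.  Total intensity is conserved exactly;
  this matters because the peeling bookkeeping is checked by conservation.
* **Matrix-peak removal**: bins within ±0.3 Da of each configured matrix mass
  are replaced by the mean of the corresponding bins one EO unit away on each
  side (single neighbour at grid edges).  The matrix mass list is run
  configuration; no masses are hard-coded because they depend on the matrix
  and adduct salt in use.
* **Normalization** to total = 1.0 makes intensities comparable across spots
  with different overall ion yields; averaging normalized replicates leaves
  the total unchanged.

The package assumes its input peak lists are already mass-aligned (vendor
export after calibration/alignment); recalibration is deliberately out of
scope.

## Iterative peeling

Each iteration finds the residual's maximum bin (ties to lower *m/z*), walks
the comb outward in ±spacing steps taking the most intense bin within
±0.3 Da of the expected position, and re-anchors on each found member so a
slightly wrong nominal spacing cannot accumulate into a miss over ~40
members.  A direction stops when the candidate bin falls below
max(2% of the apex bin, noise floor); peeling stops when the residual
maximum falls below 5% of the original global maximum.  Both thresholds are
configuration (`PeelConfig`) because no universal values exist; the defaults
were chosen so that a constituent an order of magnitude below the main one
is still detected while baseline noise is not.

The noise floor is median + 3·MAD over all bins — dominated by baseline bins
and therefore robust to the sparse signal peaks; on noiseless spectra it
collapses to zero and the fractional thresholds govern.

**Member intensity and footprints.**  Proportional binning splits a centroid
across two bins, so single-bin intensities carry a nuisance factor between
0.5 and 1.  Every recorded member intensity is therefore the sum over the
member's *footprint*: at least ±0.2 Da, grown outward while bins stay above
10% of the member bin (to cover peaks broadened by replicate averaging under
small residual mass drift) and hard-capped at ±0.5 Da so a footprint can
never swallow the isotope satellite one mass unit away.  Removal zeroes
exactly the footprints, so peeled intensity plus residual equals the input
total to floating-point accuracy.

Two intensity notions are kept per record: `detection_intensity` (the
residual-maximum bin; exactly non-increasing over the peel sequence) and the
envelope features `apex_mz` / `apex_intensity` (the member with maximal
footprint intensity).  The envelope apex is the scientifically meaningful
"distribution maximum"; the detection bin is an algorithmic quantity.

**Width at half height** is measured on the member envelope by linear
interpolation between adjacent members; a side whose envelope never falls
below half maximum contributes the distance from the apex to the outermost
member, and a single-member comb has width 0.

**Termination contract.**  The apex stop threshold is returned with the peel
result (`PeelResult.stop_threshold`).  Re-peeling a residual under the *same*
absolute threshold yields nothing; a fresh relative threshold would rescale
to the residual's own maximum and always find something, which is why
`PeelConfig.apex_stop_abs` exists.

## Cross-spectrum catalog and ratio-scaling

Distributions are matched across spectra into global IDs seeded from the
first spectrum in detection order.  A later record matches an existing ID
when its apex sits on the same comb phase (apex difference reduced modulo
the spacing, within ±0.5 Da) and within 5 EO units — enough to follow a
product type whose envelope mean shifts by 2–3 EO.  Matching is greedy by
smallest apex distance; unmatched records open new IDs.  Near a flat
envelope top the apex can alternate between adjacent comb members across
samples, so mass-matching uses the *modal* observed apex
(`representative_apex`), not the across-sample mean, which can fall between
comb positions.

The feature table holds four columns per ID (apex *m/z*, apex intensity,
width at half height, ratio to the main distribution).  Where an ID is
absent from a sample, intensity and ratio are 0 (the distribution is
genuinely absent) while *m/z* and width are imputed with the ID's
across-sample mean — placeholder zeros would fabricate hundreds of Daltons
of spurious variance in a mass column.

**Ratio-scaling**: weights `w_d = mean(intensity_d) / mean(intensity_1)` are
computed on the unscaled intensities first; then every column is centred,
divided by its standard deviation (n−1) and multiplied by its ID's weight.
After scaling, `sd(column) = w_d` and `mean = 0`; zero-variance columns
become zero.  The per-sample *ratio feature* uses each spectrum's own apex
intensities, while the *weight* uses across-sample averages; both are
deliberate and distinct.  Plain unit-variance scaling is provided for
comparison (`uv_scale`).

## Multivariate analysis

PCA is computed by SVD on centred (optionally unit-variance scaled) data
with a deterministic sign convention (largest-magnitude loading element
positive).  Two-class classification uses single-response PLS regression
(scikit-learn's NIPALS implementation) with classes encoded 1.0/2.0 and
predictions split at 1.5 (the boundary value itself goes to the second
class, a documented tie rule).  Three-class designs are analysed by PCA
only.

Cross-validation is stratified 3-fold, seeded.  The number of latent
components defaults to selection by inner cross-validated RMSEP per training
fold (`n_components="auto"`); a fixed count may be given instead.  VIP scores
follow `VIP_j = sqrt(p · Σ_a SSY_a (w_aj/‖w_a‖)² / Σ_a SSY_a)` with
`SSY_a = ‖t_a‖² q_a²`, so `Σ_j VIP_j² = p` holds identically.

## Compound assignment

Candidate series are enumerated from a user-supplied base-compound
dictionary (elemental formulas parsed via pyteomics; masses from in-package
monoisotopic and standard-atomic-weight tables).  Both mass modes are
supported: average masses suit the apex of a broad isotope-unresolved
envelope, monoisotopic masses suit individual centroids.  An apex is
assigned to the nearest series oligomer within 0.5 *m/z*; when two series
fall within tolerance the assignment is reported as ambiguous with all
candidates ranked (isobaric ethoxylated species are genuinely
indistinguishable by mass alone).  The electron mass is ignored — three
orders of magnitude below tolerance.

Isotope satellites are folded into parents when an ID's apex sits
k·1.0034 Da (k = 1, 2) above a more intense ID's apex, compared modulo the
comb spacing so that apex flicker between adjacent members does not hide
the relationship.  A phase-matching candidate *more intense* than its
putative parent is never merged (a genuine ¹³C satellite is always weaker)
and is logged.

## Synthetic data generator

The generator emulates what the pipeline consumes: several overlapping
combs (Poisson envelopes by default — the natural chain-length statistics of
living alkoxylation; Gaussian available), ¹³C satellites with
Poisson(isotope_lambda) weights collapsed to k ≤ 2, matrix peaks, additive
half-normal baseline noise on a 0.05 Da grid, ±0.02 Da centroid jitter (to
exercise proportional binning), per-peak lognormal replicate variation, and
per-sample lognormal batch variation of component abundances.  An optional
per-replicate global mass offset (`calibration_shift_sd`) emulates residual
calibration error; it defaults to 0 because the package's input contract is
aligned peak lists.

Shipped designs (defaults chosen once, as study conditions):

* `peg_castor_design()` — PEG (base H₂O, mean 18 EO, apex ~*m/z* 834) +
  ethoxylated glycerol (base C₃H₈O₃, mean 29 EO, apex ~1392); glycerol:PEG
  abundance 0.4 vs 0.6 (a 1.5× ratio contrast between types); isotope
  lambdas 0.39/0.65 from ≈1.07% ¹³C per carbon at ~C₃₆/C₆₁; 10% replicate
  CV; 10% batch abundance CV; baseline noise 1e-4 relative to unit
  component abundance (apex-bin signal-to-noise of a few hundred).
* `oleth_design()` — ethoxylated oleyl alcohol (mean 20 EO; 22 for type R1)
  plus ethoxylated cetyl alcohol (more abundant in R3).

What the generator does *not* model: ionization efficiency differences
between constituents, mass-dependent detector response, fragmentation,
profile-mode peak shapes, and full isotopologue fine structure.  Passing
tests on simulated data therefore demonstrate the correctness of the
algorithmic chain under the stated statistical structure, not instrument-
specific behaviour.

## Problem sizes used in tests

The test suite runs entirely on generated data: three-component noiseless
mixtures for recovery and conservation oracles; 6–20 samples per class with
3–4 replicates for pipeline and classification checks; ten seeded
repetitions at 10 samples/class for the features-versus-full-spectrum
direction property (under heavy bin noise and 0.1 Da residual drift, where
bin misalignment defeats peak-level multivariate analysis while the
extracted distribution features remain usable).  These sizes were chosen as
the smallest at which the distributional claims are stable across seeds.

## Known limitations

* Two series sharing the same comb phase with overlapping apexes are peeled
  as one distribution; isotope-pattern-based deconvolution of isobaric
  overlaps is not implemented.
* Quantitation is relative only; no calibration against standards.
* The peeling thresholds are heuristics; heavily noise-dominated spectra
  (noise bins within the apex stop fraction of the signal maximum) will
  yield spurious single-member distributions.
* Manifest handling assumes one product type per sample id.
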