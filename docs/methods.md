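# Methods

This note documents the models, conventions and numerical choices behind
`glycodyn`, and what the synthetic-data experiments do and do not show.

## Mass conventions

Atomic monoisotopic masses: C 12 (exact), H 1.00782503207,
O 15.9949146196, N 14.0030740048, S 31.97207100, Na 22.9897692809 Da;
electron 0.00054857991 Da. The proton is defined as a hydrogen atom minus
an electron (1.00727645 Da), the usual mass-spectrometric convention; it
differs from the free CODATA proton only by the hydrogen binding energy
(~1.5e-8 Da), far below instrument accuracy, and makes the identity
`mz([M-H]-) + m_p = M` exact. Ion m/z is
`(x·M + m(delta) − z·m_e)/|z|` for an adduct `[xM + delta]^z`; the
electron term is required to reproduce printed ppm deviations at the third
decimal.

Fragment "sum formulas" in vendor reports mix two conventions: a neutral
molecule read through its deprotonated ion, and the elemental composition
of the anion itself (one hydrogen fewer, plus an electron). The API
carries an explicit `composition` flag (`"neutral"` / `"ion"`); when a
printed formula must be interpreted, the convention minimising |ppm| is
taken. ppm values are reported to three decimals (round-half-even).

## Formula enumeration

`enumerate_formulas` iterates carbon and oxygen counts over a bounded box
and solves the admissible hydrogen window per (C, O) pair — provably
equivalent to the full triple loop, exhaustively. Two constraint presets:

- **default**: neutral composition, C 0–150, H 0–300, O 0–80, integer
  DBE = C − H/2 + 1 ≥ 0 (even hydrogen counts). The chemically strict
  reading for neutral CHO molecules.
- **vendor** (`FormulaConstraints.vendor()`): ion composition, C 0–150,
  H 0–300, O 0–100, ring-double-bond equivalents of the ion in [−1, 100],
  no hydrogen-parity rule. This mirrors the defaults of the acquisition
  software used in this field (ion-formula RDBE from −1 up, half-integer
  values legal) and is the configuration under which the saponin precursor
  at m/z 1703.71838 admits exactly 19 CHO assignments at 5 ppm; the strict
  default box admits 9. Both are exposed; the worked identifications use
  the default box, the candidate count uses the vendor box.

## Glycan decomposition and spectrum annotation

Residue masses are sugar-minus-water increments (pentosyl 132.04226,
deoxyhexosyl 146.05791, hexosyl 162.05282, uronic acid 176.03209 Da).
`decompose_delta` is a bounded knapsack (default ≤ 6 copies per residue —
comfortably above the ≤ 4 observed in real saponins); ties are broken by
|error|, then fewest residues, then residue name, so output order is
deterministic.

`annotate_glycoside` forms candidate compositions by subtracting each
library aglycone from the precursor neutral mass and decomposing the
remainder at the precursor tolerance (5 ppm default). Each candidate then
explains every fragment as one of: a precursor-side residue loss, an
aglycone-plus-residues ion (the same cleavage seen from the other side —
the tag with fewer residues wins), a detached deprotonated sugar chain
(sum of residue formulas, no extra water — this is how the printed chain
ions are composed), the bare aglycone, or aglycone − H2O − CO2.
Fragment tolerance defaults to 10 ppm: MS² mass accuracy is worse than
MS¹, and the printed sugar-chain ion sits at +9.4 ppm. Unexplainable
fragments are tagged `unassigned`, never dropped. Ranking is by explained
fragment count, then aggregate |ppm|, then library order of the aglycone —
a deliberate abundance prior, because isomeric compositions on different
aglycones (e.g. an acetylated aglycone with one fewer residue) are exactly
isobaric and MS cannot separate them without diagnostic aglycone ions.
Only compositions are claimed, never linkage positions or stereochemistry.

One library caveat: the literature value 541.31787 sometimes quoted as the
zanhic-acid diagnostic ion does not match [C30H46O7 − H]− (517.3174) under
any convention; the library stores the formula-derived value.

## Time axis and study design

Three arms: HEX (extract + enzymes + fecal bacteria), NCHEX (extract +
enzymes, no bacteria), MB (blank + enzymes + bacteria). Colonic samples at
2, 4, 6, 10, 14, 18, 22, 24, 32, 40, 48, 72 h after colon onset (hour 0).
The protocol states no durations for the pre-colon stages, so T0, gastric
(S) and small-intestinal (SI) aliquots are placed ordinally at −3, −2 and
−1 h; these positions are configuration, not biology.

## Deisotoping

Feature j is the isotopologue of i when (mz_j − mz_i) matches
k·1.003355/z for k ∈ {1,2,3}, z ∈ {1,2} within
min(0.05 Da, 5 ppm · mz_j), retention times agree within 10 s (`RTdiff`
is interpreted in seconds — 10 min would merge most of a chromatogram),
and the intensity vectors correlate at r ≥ 0.8 over at least three shared
non-missing samples. Chains are merged union-find style; the lowest-m/z
member stays unflagged. z = 2 is searched because doubly deprotonated
saponins occur.

## Differential profile test

Per feature, log(intensity + 1) is regressed on a natural cubic spline of
time (df = 4 — at most half the colonic time points; boundary knots at the
range ends, interior knots at quantiles) with class-shared coefficients
(null) versus class-specific coefficients (full), by least squares;
missing values are excluded from the fits rather than imputed. The
statistic is the classical F ratio, and significance comes from permuting
class labels within time points (default 499 permutations,
p ≥ 1/(n_perm+1)). Features whose missingness leaves fewer than two
classes or four time points have no defined contrast and report (0, 1) —
a feature absent outside one arm is screened by the trend caller, not by
this test. Benjamini–Hochberg q-values are reported alongside raw p, but
candidate selection uses the score, not p. The table-level routine groups
features by identical missingness patterns and shares permutation shuffles
within a group so class-wise projections are computed once per shuffle;
this changes nothing statistically per feature and keeps 500 features ×
499 permutations under a second.

Under the simulated global null the within-time permutation makes the
test essentially exact: the rejection rate at α = 0.05 is 0.05 ± 0.02.

## Descriptors, scorer, selection

Eight descriptors per feature (documented order in
`timeseries.DESCRIPTOR_NAMES`): Theil–Sen colon slopes of log intensity in
each arm, the time-integrated |HEX − NCHEX| log divergence, mean MB
intensity relative to the feature maximum, missing fraction, Spearman
monotonicity of the HEX colon profile, and the HEX log fold change from T0
to 72 h. The scorer is a 500-tree random forest on these descriptors,
trained on binary expert ratings; the score is the fraction of trees
voting "interesting", deterministic for a fixed seed. Selection takes
score strictly above 0.8, retention time in the inclusive window
[2, 25] min, and an optional minimum intensity (no published value exists
for "reasonable intensity", so the default is 0). Peak-width bounds
[0.05, 1.00] min are read inclusively.

## Trend calling and network inference

Per arm, the colon profile (replicate means) is thresholded at 1% of the
feature's own maximum (scale-free detection limit); direction comes from a
Theil–Sen slope of log intensity (|slope| > 0.05 log-units/h), with a
fallback net first-to-last change of ≥ 0.5 log units for saturating
profiles whose median pairwise slope flattens. Roles: present in MB →
matrix; HEX rise-and-fall around an interior peak (≥ 0.5 log units each
way) with NCHEX not decreasing → intermediate; HEX decrease with NCHEX not
decreasing → substrate; HEX increase with NCHEX not increasing → product.

Edges link source roles {substrate, intermediate} to target roles
{intermediate, product} whenever the m/z difference (same-adduct
assumption) decomposes into at most 3 sugar residues within 5 ppm of the
source m/z — real steps lose 1–2 residues; 3 allows one missed
intermediate. The evidence score averages the relative mass error with the
lagged (0–2 grid steps) anticorrelation of the HEX profiles. Because a
ladder's skip-level difference (step i → i+2) is also a legal ≤ 3-residue
decomposition, a parsimony transitive-reduction pass removes any edge
whose loss equals the summed losses along an existing two-step path:
stepwise elimination is the parsimonious reading, and without it no
multi-step ladder can be recovered at high precision. Pathways are read
out as maximal source-to-sink chains; cycles are reported as anomalies,
never silently broken.

## Hepatic suspect screen

Rules are signed elemental deltas applied breadth-first to the parent
aglycone up to depth 3, capped at 1000 products (deterministic order:
depth, then lexicographic rule path; entries keyed by the rule-name
multiset so application order cannot duplicate). Carboxylic-acid
reduction is chemically ambiguous between the aldehyde (−O) and the
primary alcohol (−O+2H); both variants are in the table. Glutathione
conjugation uses the net addition-with-water-loss delta (+C10H15N3O5S);
conjugation chemistry varies and the rule is configurable.

The volcano screen floors missing/zero intensities at a pseudo-count of
half the smallest nonzero intensity in either arm, computes fold change on
means and p from a pooled-variance two-sample t-test on log10 intensities
(zero variance with equal means → p = 1). Selection is strict:
p < 0.05 and log10(fold change) > 1, i.e. ten-fold enrichment. The
literal source-workflow reading of its threshold ("log 10-fold change
higher than 10", i.e. FC > 1e10) is retained as configuration but cannot
be satisfied together with the half-minimum pseudo-count — the pseudo-count
bounds every fold change orders of magnitude below 1e10 — so the ten-fold
reading is the operative default. Unmatched selected features are kept as
nontarget hits; that route is exactly how metabolites outside the rule set
are found.

## Synthetic data: what it emulates and what it does not

The generator plants three glycoside families by default — a 6-species
ladder on medicagenic acid (uronic acid + 2 pentosyl + 3 deoxyhexosyl +
1 hexosyl), a 4-species ladder on acetylated medicagenic acid (3 hexosyl +
1 deoxyhexosyl), and the isoquercetin → quercetin pair — 12 planted
features among 488 matrix features. The second family's acetylated
aglycone was chosen so that cross-family mass differences are not
sugar-residue decomposable; note that exact elemental identities exist
(uronic acid + 2 deoxyhexose = acetyl + hexose + 2 pentose, element for
element), so such collisions must be audited, not assumed away.

Colon kinetics are first-order sequential conversions solved with the
matrix exponential (exact to machine precision; the single-step case
reproduces I0·e^(−kt) to better than 1e-9 relative). Default rates
0.08–0.12 h⁻¹ place every intermediate's peak well inside the 2–72 h
window with ≥ 0.9 log-unit rises and falls. Pre-colon dynamics are a 10%
uniform decay across S and SI applied identically to HEX and NCHEX, which
stay identical until colon onset; NCHEX holds its pre-colon level through
the colon phase; the blank carries only matrix features, which are of
fecal/enzymatic origin and therefore appear only in the colonic phase of
HEX and MB. M+1 isotopologues are planted at +1.003355 Da with relative
abundance 0.011 × carbon count, inheriting the parent's realised noise
(so they co-vary, r ≈ 1); isotopologues whose intensity could never clear
the detection floor are not emitted, as a peak picker would not produce
them. Noise is multiplicative log-normal with CV 20% (typical untargeted
LC–MS repeatability); the detection floor is 10³ counts; both are
configurable. A fixed seed gives bit-identical tables.

Passing tests on this generator demonstrate internal correctness of the
pipeline under its own assumptions — clean first-order kinetics, exact
isotope spacing, independent noise, no retention-time drift, no adduct
multiplicity, no ion suppression. They do not demonstrate performance on
real chromatograms, where peak picking, alignment and matrix effects
dominate; those upstream steps are outside this package.

The S9 simulator plants the parent in both arms, six rule-derived
metabolites in the incubated arm only, and 200 matrix features in both;
with no planted metabolites the two arms are statistically exchangeable.

## Problem sizes

The shipped experiments run at desk scale, chosen to exercise every code
path while keeping the whole suite fast: 500 non-isotope features × 135
samples for the gastrointestinal design, 500 features × 499 permutations
for the null calibration, 20 seeds for edge precision/recall, 200
spectra for annotation recovery, and 200-feature S9 tables. All sizes are
configuration, not limits.

## Known limitations

- Compositions only: no linkage, stereochemistry or bidesmosidic
  chain-position assignment.
- Same-adduct assumption in network inference; cross-adduct edges are out
  of scope.
- The trend caller's substrate/intermediate boundary depends on where a
  species' peak falls in the observation window; chains much faster or
  slower than the default rates need adjusted thresholds.
- Elements beyond C/H/O/N/S/Na and charge states beyond |z| = 2 are not
  supported; isotope-pattern fitting is not attempted.
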