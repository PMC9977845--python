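# Methods

## Binding model

The package models a ligand binding a DNA duplex host with `n` identical,
independent sites. Mass balance with Langmuir binding gives the free-ligand
concentration `L` as the unique non-negative root of

    L + n·M·L/(Kd + L) = c ,

a quadratic solved in closed form (the numerically stable branch is chosen
by the sign of `Kd + n·M − c`; the residual is verified to < 1e−10·c).
Occupancy is ν = (c − L)/M, so ν·M + L = c holds to machine precision by
construction. All concentrations are µM internally: the titrations of
interest use 10 µM ligand and dissociation constants between 0.03 and
0.6 µM, so µM keeps every quantity near unit scale.

For this model the Scatchard plot (ν/L against ν) is exactly linear —
ν/L = (n − ν)/Kd — at *every* titration point; the familiar saturation
plateau is a finite-noise phenomenon, not a property of the noiseless
model. The piecewise regression therefore usually collapses to a single
line on clean data and engages its plateau segment only when the data bend.

### Piecewise Scatchard regression

Points are ordered by ν and split by exhaustive search over inter-point
midpoints into a binding-regime segment (ordinary least squares in ν/L;
slope must be negative; Kd = −1/slope, n = x-intercept) and a saturation
segment treated as a plateau ν ≈ n (residuals measured in ν, the direction
in which a plateau deviates). Each segment needs at least two points; the
split minimizing the total residual sum of squares wins, and if no split
beats the single-line fit the breakpoint is reported as absent. The
x-intercept n is cross-checked against the plateau mean; a discrepancy
above 20 % is logged rather than reconciled, because the model offers no
principled arbiter. Mixing ν- and ν/L-residuals across segments is a
deliberate plain reading of two-regime fitting; an orthogonal-distance
variant would couple the segments through an extra scale parameter without
changing the estimates on data this well-conditioned.

### Saturated points and the estimate flag

Near saturation the free-ligand fraction x_free = L/c falls below what a
spectral decomposition can quantify, and the relative error of L (hence of
ν/L) diverges. Two thresholds handle this:

- points with x_free < 0.05 are excluded from the regression (the free
  species is no longer quantifiable against instrument noise);
- the fitted Kd is flagged as an *estimation* when fewer than 3 points
  have x_free ≥ 0.10, or when the binding-regime segment holds fewer than
  3 points.

At the standard design (10 µM ligand, ratios 0.25–7) a binder with
Kd ≈ 0.03 µM leaves only the two lowest-ratio points well-determined —
every stronger dilution binds essentially all ligand — so its Kd is
reported but flagged. The 0.05/0.10 values are detectability choices, not
fitted constants: 5 % is roughly the smallest molar fraction a two-species
spectral model resolves at 0.5 % absorbance noise, and 10 % marks points
whose ν/L carries < ~10 % relative noise. Both are exposed in
`AnalysisConfig`.

## Chemometric decomposition

Spectra matrices (wavelength × titration point) are centred across
titration points and decomposed by SVD; eigenvalues are squared singular
values, and a deterministic sign convention (largest-magnitude loading
element positive) makes scores platform-independent. The decomposition is
run twice: pass 1 diagnoses columns whose residual from the rank-1
reconstruction exceeds 5× the median (gross outliers — a mis-pipetted
point, a bubble), pass 2 re-decomposes without them. With no outliers the
passes coincide exactly.

A closed system of s absorbing species has centred rank s − 1, so the
species count is one plus the number of eigenvalues above a threshold
fraction of the largest. The default threshold is 1e−2: a genuine species
must explain ≥ 1 % of the dominant variance. At realistic signal-to-noise
(0.5 % absorbance noise on a ~200-wavelength grid) noise eigenvalues sit
near 1e−3 of the leading one, so a tighter threshold (e.g. 1e−4) would
systematically over-count species and abort the two-species pathway; 1e−2
separates the regimes by an order of magnitude on each side.

### From scores to molar fractions

For two species the first-component score is affine in the bound fraction,
so two anchors fix the conversion: s_free (the ratio-0, ligand-only point,
present in the default design) and s_bound (the fully bound state). Two
anchoring modes are provided:

- **saturation**: s_bound is the score of the largest-ratio point. Simple,
  but biased whenever that point is not fully bound (a 0.6 µM binder is
  only ~99 % bound at ratio 7, which propagates a percent-level error into
  every fraction).
- **fit** (default): a two-species 1:1 binding profile, parameterized by
  the single dimensionless ratio Kd/c, is least-squares fitted to the
  scores (coarse log-grid then bounded scalar minimization), and s_bound
  is the fitted score at full binding. The auxiliary parameter only
  anchors the score axis; the reported Kd and n always come from the
  Scatchard regression. A purely shape-based alternative (choosing the
  anchor by isotonicity of the fractions) is degenerate — fractions are
  affine in the scores, so monotonicity is anchor-invariant — which is why
  the anchor must come from a model, not from ordering constraints.

Fractions are clipped to [0, 1] with the pre-clip range recorded in the
result provenance; silent clipping would hide a miscalibrated anchor.
Closure x_free + x_bound = 1 is exact by construction.

## Restraints

NOE cross-peak classes map to bounds via a conventional calibration:
common lower bound 0.18 nm (van der Waals contact), upper bounds 0.29 /
0.40 / 0.55 nm for strong / medium / weak. Contacts involving methyl
groups get +0.10 nm on the upper bound (pseudo-atom correction for the
three degenerate protons); both the calibration and the correction are
arguments, since published restraint sets vary. Intensity classes are kept
*per complex*: the same proton pair may be strong in one complex and
medium in another, and each complex's restraint set uses its own class.

Watson–Crick restraints pair the canonical donor/acceptor heavy atoms —
G(O6,N1,N2)↔C(N4,N3,O2) and A(N6,N1)↔T(O4,N3) — with default bounds
0.27–0.31 nm bracketing crystallographic N/O···N/O distances. Terminal
base pairs are excluded by default regardless of identity: the exclusion
models end-fraying (unobservable terminal imino protons), which is
positional, not compositional.

The restraint potential is flat-bottomed: zero on [low, up], quadratic
0.5·k·Δ² outside, C¹-continuous at both thresholds, k = 1000 kJ mol⁻¹ nm⁻²
for every restraint by default. The writer emits either a self-describing
TSV or a GROMACS-style `[ distance_restraints ]` block with placeholder
atom indices and a commented label map — mapping string labels to real
topology indices is deliberately a separate, explicit step, since no
universal atom numbering exists.

## Occupancy statistic

Hydrogen-bond occupancy is the exact rational count of frames satisfying
distance ≤ 0.35 nm and (when an angle is recorded) donor–H–acceptor angle
≥ 150°, divided by the frame count. These cutoffs are the most common MD
conventions and are arguments; frames lacking angles are judged on
distance alone, which keeps the statistic usable on distance-only traces.
Occupancy is monotone in both cutoffs, and concatenating traces averages
occupancies with frame weights — both property-tested.

## Synthetic data

The generator emulates the study conditions: constant 10 µM ligand (the
0.01 mM of the titration protocol), DNA:ligand ratios 0.25, 0.5, 1, 1.5,
2, 3, 5, 7, plus a ratio-0 ligand-only reference added by default because
it anchors the free-state score (it can be dropped to mimic the exact
eight-point design). Pure spectra are Gaussian bands — free ligand at
420 nm, bound red-shifted to 440 nm with 20 % hypochromism, on a 350–550 nm
grid at 1 nm — a generic intercalator-like signature in a DNA-transparent
window, explicitly not a measurement of any real chromophore. Noise is
additive i.i.d. Gaussian per matrix element through a single seeded
generator; identical configurations reproduce byte-identical artifacts.

Hydrogen-bond traces place bonded frames at 0.28 nm and unbonded at
0.50 nm with stationary bonded probability p, either i.i.d. or via a
two-state Markov chain whose persistence parameter correlates frames
without moving the stationary distribution.

What the generator does *not* emulate: wavelength-correlated (baseline,
scatter) noise, DNA's own 260 nm absorbance (which would add a third
component — the real analysis would window it out, and `AnalysisConfig`
supports such windows), intermediate-exchange spectral broadening, and
pipetting error in the ratios. Passing recovery tests on these synthetics
therefore demonstrates the correctness and noise behaviour of the
*analysis chain*, not instrument-grade robustness.

## Problem sizes and verification

The Monte-Carlo recovery study runs the full pipeline over the eight
ground-truth Kd values spanning 0.034–0.608 µM at 0.5 % absorbance noise
with 50 seeds each (a few seconds total); noiseless recovery is exact to
< 0.01 % and noisy medians fall well inside 15 % relative error, with the
0.034 µM case flagged as sparse in every run. The free-ligand solver is
property-tested against a bisection oracle, the PCA against a dense
eigendecomposition of the covariance matrix, and the occupancy statistic
against exact rational arithmetic.

## Known limitations

- Only the two-species (free/bound) spectral pathway is implemented; no
  MCR-ALS rotational-ambiguity resolution, no Hill/multi-class/competitive
  binding, no global multi-wavelength hard-model fit.
- The piecewise regression assumes at most one breakpoint.
- Restraint bounds are conventions, not system-specific calibrations; the
  occupancy cutoffs likewise.
- Non-palindromic duplexes are rejected throughout the sequence layer.
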