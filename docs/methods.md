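# Methods

This note records the modelling choices, defaults and known limitations of
the package, in the order the pipeline runs.

## Data model and units

Activities enter as EC50 in nM per receptor subtype (β1, β2, β3) and are
converted once, at full precision, to pEC50 = −log10(EC50·10⁻⁹); rounding
to 3 decimals happens only at presentation. This avoids compounding
rounding error into q²/r²pred. Train/test roles are explicit in the
activity CSV (`role` column); the pipeline never splits randomly — a seeded
role assignment exists only in the synthetic generator. The bundled
25-compound table reproduces its published pEC50 column within 0.002 log
units; the worst printed rounding inconsistency (compound 2: 6.650 printed
vs 6.652 computed) is why cross-checks use a 0.003 tolerance rather than
printed precision.

Structures are consumed pre-minimised with partial charges supplied (MOL2
inline; SDF via a `charges.csv` sidecar, 0-based atom indices). No 2D→3D
generation, charge calculation, or conformer search is performed: those are
upstream decisions this package deliberately treats as inputs.

## Alignment

Atom-fit superposition is unweighted least squares over user-mapped
scaffold atoms (≥3, non-collinear), solved by SVD with det(R) = +1
enforced — reflections are forbidden because the series is chiral
((R)-configuration). The alignment reference is never guessed; callers name
it explicitly. Collinear scaffolds raise an error rather than returning an
arbitrary rotation.

## Similarity fields

Fields follow the Gaussian similarity-index form A_q = −Σ_i w_probe·w_i·
exp(−α·r²) with α = 0.3 Å⁻², unit probe, and 2 Å lattice spacing; the
leading minus (attractive similarity negative) is the literature sign
convention, documented here because it matters for contour-map signs. No
distance cutoff is applied — the Gaussian decays fast enough that exact
summation is affordable at desk scale and removes a discontinuity knob.

Grid construction snaps the origin to integer multiples of the spacing
(anchor at the global origin) so identical inputs always yield identical
columns; the margin default is 4.0 Å (configurable — the method itself only
requires that the whole set be enclosed). Column order is the z-fastest
lattice scan.

Atom weights: steric = vdW radius cubed (Bondi-style per-element table in
`comsiakit/data/atom_params.yaml`, C = 1.70 Å → 4.913 Å³); electrostatic =
supplied partial charge; hydrophobic = a deliberately coarse per-element
contribution table (apolar positive, heteroatoms negative) shipped as a
versioned data file and pluggable via config — the field is regressed, not
interpreted absolutely, so the table's scale matters more than its detail;
donor/acceptor = binary flags (donor: N/O bearing H, flag on the heavy
atom; acceptor: N/O not positively charged, excluding pyrrole-like aromatic
N–H). Pseudo-atom (synthetic) molecules bypass the rule tables with
explicit weights.

The column filter keeps a column iff its training-set range (max − min) is
≥ 2.0 field units, with ≥ at the boundary; a σ-based mode exists behind a
flag since the original workstation software does not document which
spread measure its "filter value" uses. The mask is always derived on
training rows only and reused for test rows.

## PLS, cross-validation, field scan

PLS1 is implemented as NIPALS with sequential deflation; coefficients are
mapped back to original columns via B = W(PᵀW)⁻¹q, so a fitted model
predicts directly from raw (unscaled, uncentered) field matrices. At full
rank the fit coincides with ordinary least squares — an oracle property the
tests exercise at 1e−6.

Cross-validation is the exact leave-one-out loop: every fold refits the
column filter, the centering statistics, and the PLS decomposition on the
remaining n−1 rows. The SAMPLS covariance shortcut used by the original
software is an approximation specific to that implementation; the exact
loop is testable against a brute-force per-fold oracle at 1e−10 and is
affordable here. q²(N) = 1 − PRESS(N)/SS with SS taken about each fold
complement's training mean; N_opt maximises q² with ties broken toward
fewer components (parsimony, determinism); SEP = sqrt(PRESS/(n − N − 1)).
N_max defaults to min(10, n − 2), mirroring the 10-component ceiling seen
in published scan tables; near-saturated N values can and do overfit (the
analysis scripts show one such case failing external validation), which is
precisely why the external battery is part of the pipeline.

The field scan fits one model per non-empty subset of the available blocks
(31 for five fields), ranks rows by q² (NaN rows — e.g. a field whose
columns were all filtered away — sort last), and reports per-field
contributions Σ|c_j|σ_j normalised to 1.

Block-level standardisation (each field block divided by its overall σ,
recomputed inside every LOO fold, applied after filtering) is available via
`block_scale=True` and is **off by default**: the source study does not
state its scaling. It matters when fields live on very different numeric
scales — cubed radii (~5–8 per atom) versus binary flags — where unscaled
NIPALS lets the large-scale block dominate the covariance direction. The
recovery experiments in the test suite and analysis scripts enable it for
exactly that reason.

## 2D (Hansch/Free-Wilson) module

Descriptor monomials (CMR², πx², πy²) are constructed inside the module
from base descriptors, preventing inconsistent CMR-vs-CMR² inputs. Fits are
OLS with intercept; statistics are r², F, residual SE s, per-coefficient
SEs, and exact-LOO q²/SEP. The exhaustive subset search refuses pools above
20 terms, ranks by q² then fewer terms, and warns when the winning model
has fewer than 5 observations per term.

The published equation ships as a frozen model object with its printed
coefficients and standard errors. Its statistics line reports n = 21
although the described training set has 19 compounds and the prediction
table flags 6 test compounds; the 21-row descriptor table is published
nowhere. Freezing the equation (evaluable, not refittable) sidesteps the
discrepancy; recomputing its r²pred from the printed predictions gives
0.933 versus the printed 0.9379, consistent with the same n mismatch, so
the printed value is documented but not pinned as a test expectation.
Similarly, the donor-acceptor residual column of the published prediction
table contradicts its own actual−predicted sign convention for |r| ≤ 0.03
entries; the regression test compares that column on magnitude.

## External validation

r²pred = (SD − PRESS)/SD with SD about the training mean. The
through-origin quantities follow the standard formulation: k = Σyŷ/Σŷ²,
k′ = Σyŷ/Σy², r0² = 1 − Σ(y − kŷ)²/Σ(y − ȳ)² (and symmetrically for
r0′²); each is checked against an independent one-parameter least-squares
oracle. Note r0² ≤ r² does **not** hold in general and is not asserted.
Pass bands: q² > 0.5, r² > 0.6, (r² − r0²)/r² < 0.1 (either direction),
0.85 ≤ k ≤ 1.15 (either slope).

## Contour maps

StDev·Coeff values are σ_j·c_j per kept column, mapped back to the full
lattice with zeros for filtered columns (no variation ⇒ nothing to
display). Favorable/unfavorable contours take the 80th/20th percentiles of
the signed nonzero distribution by default — percentile mode is the
default because absolute iso-values depend on the activity scale; an
iso-value mode is a one-liner on top of the exported grids. Exports are
OpenDX text grids (read back by the package for round-trip tests) and
Gaussian cube.

## Synthetic series: what it emulates, and what it does not

The generator emulates the study conditions: 25 congeners sharing an
identical (pre-aligned) phenylethanolamine-like scaffold of 10 pseudo-atoms,
4 substituent sites, a 19/6 train/test split with the held-out compounds
stratified across the activity range, activity noise sd 0.3 log units
(matching the scale of the published 2D model's residual SE, 0.321), and a
default planted steric+acceptor dependence — the published best model
family — with weights balanced so each planted field contributes a
comparable share of the ~3-log-unit activity spread (field magnitudes
differ ~8-fold between S and A) and intercept 4.6 placing the series at
pEC50 ≈ 6.5–9.9 like the real one.

Substituents are sampled with size (shared vdW radius 1.5–2.0 Å,
2–4 atoms), polarity class (apolar/donor/acceptor; polar groups are 3–4
atoms, as real amide/sulfonamide-like groups are multi-atom — this also
lets their binary-flag columns clear the 2.0 column filter), hydrophobicity
(U[−1, 1]) and per-atom charges (U[−0.6, 0.6]) drawn independently, so no
field is a deterministic alias of another and planted dependencies are
identifiable. Substituents grow outward from probe points snapped to the
2 Å lattice, making the planted activities exactly linear in field-block
columns; the stored ground truth (weights, probe points, noiseless
activities, poses) recomputes the noiseless activities bit-exactly.

What passing tests on this generator do **not** show: real conformational
flexibility, alignment ambiguity, correlated real-chemistry substituent
effects, or charge-model error. The generator validates the statistics and
the plumbing, not force fields.

One RNG stream per generator call, seed recorded in all exported metadata;
identical seeds give bit-identical output.

## Numerical choices and degenerate inputs

- NIPALS stops extracting when the residual covariance norm falls below
  1e−10 of the data scale; requested components are capped at
  min(n − 1, p) with a warning.
- Constant-activity vectors, zero-variance through-origin regressors, SD = 0
  test sets, and exhausted degrees of freedom raise explicit errors rather
  than returning NaN.
- An exact fit reports F = ∞ (flagged) rather than a division error.
- All-zero contour fields and all-false filter masks warn and degrade
  gracefully.
- Field values at shared lattice points are reproducible to a few ulps
  (SIMD summation order), and exported properties CSVs print floats with
  `%.17g` so pseudo-atom weights round-trip exactly.

## Problem sizes

Default analysis and test problem sizes — 25 molecules, ~600 lattice
points per field, 31-model scans, 25-seed recovery replicates, 100–200-seed
simulation batteries for the 2D module — were chosen as comfortable
desk-scale runs (the full suite takes well under a minute on one core)
while keeping every statistical check at the sample sizes the study itself
used (n = 19 training compounds, 6 test).
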