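# Methods

## Model and procedure

The package analyses reversed-phase thin-layer chromatography (RP-TLC)
lipophilicity data. The measured quantity per spot is the retardation
factor R_F ∈ (0, 1); the Bate-Smith–Westall transform R_M = log10(1/R_F − 1)
maps it to a free-energy-like scale on which, for congeneric solutes under
reversed-phase conditions, retention is linear in the organic-modifier
volume fraction C:

    R_M = R_M0 + b·C,    C_0 = −R_M0/b.

All retention fits are ordinary least squares of R_M on C. Replicate spots
are averaged **on the R_F scale before transformation** (the convention of
the experimental protocol being reproduced; `aggregate_replicates` also
offers R_M-scale averaging, which differs for asymmetric replicates because
the transform is convex below R_F = 0.5 and concave above). The tabulated
correlation coefficient is the magnitude |r| — the source tables print
positive r beside negative slopes — with the signed value retained on the
fit object.

Calibration regresses literature logP on R_M0 over reference standards and
reports r, the residual standard error s = √(SSE/(n−2)), the regression
F = r²(n−2)/(1−r²), and the two-sided slope p-value (t, n−2 df). The
published coefficient set (slope 1.2838, intercept 0.2138) is kept as
`REFERENCE_CALIBRATION`, distinct from any refit: it was fitted on unrounded
R_M0 values that are not public, so refitting the rounded standards table
gives slope 1.2905 while reproducing r to ~3×10⁻⁵. Converting tabulated
R_M0 values with the reference line reproduces the published logP_TLC table
exactly at two decimals; this is why the pipeline exposes a
`calibration_source` switch (`refit` | `printed-reference`).

Consensus logP is the arithmetic mean of the per-program predictions with
the sample (n−1) standard deviation; the population convention does not
reproduce the published ± values. A consensus column never feeds its own
computation.

Correlation batteries are simple OLS fits of each prediction program or
molecular descriptor on R_M0 over declarative compound subsets (the full
set of 15 and the three 5-compound isomer series). Exactly the published
equation rows are encoded — absent sub-ranges are not invented — and a
two-sided p < 0.05 marks significance with no multiple-testing correction
(matching the source analysis).

Cluster analyses use Euclidean distances on raw, unstandardized vectors
(all coordinates share the logP scale) merged by single linkage; a
standardization flag and other linkages exist for sensitivity checks only.
Compound vectors are the 8 program predictions plus the consensus mean
(9 dimensions); the nearest-pair identities reported in the tests hold with
or without the consensus column. Dendrograms export as Newick (branch
lengths are merge-height differences, so trees are ultrametric) and as a
merge-table CSV.

Drug-likeness screens implement Lipinski (fail on ≥ 2 violations), Ghose,
Veber, Egan, and Muegge (all-conditions rules). All range bounds are
inclusive — a fixed convention, since the prose statements of these rules
("from 40 to 130") are ambiguous at the boundary. Each verdict records
per-condition threshold provenance: conditions stated numerically by the
reproduced study are tagged `study`; Egan's bounds (TPSA ≤ 131.6,
AlogP98 ≤ 5.88) and Muegge's non-logP conditions come from the rules'
original publications and are tagged `external-default`. Lipinski's logP
input defaults to MLOGP and Ghose/Egan use WLOGP, the conventions of the
screening platform whose verdicts the fixtures carry. Ghose's molar
refractivity is caller-supplied because the two MR sources in the fixture
straddle the 130 bound: the tabulated Chem3D values are all below it, while
the screening platform's values (not published; the bundled
`mr_swissadme_synthetic` column is a synthetic stand-in constructed to be
above 130 exactly for the piperidinylethyl and N-methylpiperidinylethyl
groups) trigger the recorded failures.

## Units, parsing, and rounding

The canonical modifier-concentration unit is the volume fraction in [0, 1).
Input files tag each row `fraction` or `percent` (percent is divided by 100
on ingest); the bundled standards' retention slopes, printed on the percent
scale in the source, are stored ×100 on the fraction scale. Numeric parsing
accepts the Unicode minus sign. All computation runs at full floating
precision; comparisons against printed tables round half-up
(`chromlip.rounding.round_half_up`), because the printed tables resolve
half-way cases upward, and allow one unit in the last printed digit where
the source evidently used unrounded intermediates.

Reproduction tests that target printed regression and clustering numbers
feed the printed two-decimal consensus column rather than recomputed
full-precision means, since the published numbers derive from the printed
matrix; the pipeline's own outputs use full precision.

## Synthetic data

The raw plate measurements behind the tabulated extrapolation parameters
are not deposited, so raw-level code paths are tested on generators that
copy the experimental design: modifier fractions 0.50–0.80 in 0.05 steps,
triplicate spots, Gaussian noise of sd 0.05 added on the R_M scale (where
the model is linear) and back-transformed — sd 0.05 reproduces the observed
|r| ≈ 0.99 retention lines. An alternative beta-noise mode perturbs R_F
directly for robustness checks. Synthetic logP matrices use an additive
base + substituent + series + program-offset model with defaults calibrated
to the bundled matrix's structure (per-program offsets of −0.9…+0.8 around
the compound mean, substituent effects spanning ~0.7 log units with the
dimethylaminopropyl analogue lowest); most real programs predict identical
values for the three ring-fusion isomers, so series effects default to
zero. Synthetic standards sit on a known line over the real ladder's R_M0
grid. All generators are pure functions of (parameters, seed).

What passing synthetic tests show: the estimation chain (aggregate → fit →
calibrate → convert) is unbiased and exact in the noiseless limit under the
assumed model. What they cannot show: robustness to plate-position effects,
spot tailing, densitometry artifacts, or heteroscedastic noise — none of
which the generators simulate.

Monte-Carlo problem sizes were chosen at desk scale: 200 replicate plates
for the bias check (bound: 3× the closed-form OLS standard error of the
mean, with σ_eff = σ/√3 for triplicate averaging) and 500 ladders for the
slope-CI coverage check (accepted band 91–98.5 % around the nominal 95 %);
oracle-agreement property tests use 100 random instances each.

## Numerical choices and degenerate inputs

* R_F is validated to the open interval (0, 1); the transform rejects the
  boundary. Back-transformed synthetic R_F is clipped away from 0/1 at
  1e-12 with a warning (analytically impossible, numerically conceivable).
* Retention fits require ≥ 3 distinct modifier levels; a flat series
  (b = 0) is returned with C_0 undefined (`None`); `compute_c0` raises on
  b = 0.
* Calibration accepts 2 standards as an exact interpolation with r/s/F/p
  suppressed; duplicate-R_M0 designs with zero spread are rejected.
* Single-linkage ties are resolved by the underlying agglomeration order
  (deterministic for fixed input order); `nearest_pair` breaks ties
  lexicographically on row order. Merge heights are nondecreasing by
  construction.
* Report outputs are byte-deterministic for a fixed configuration; every
  artifact carries a 16-hex-digit hash of the analysis-relevant settings
  (output location and log verbosity excluded).

## Known limitations

* Nonlinear (quadratic) retention models and gradient elution are out of
  scope; so are weighted/Deming calibration and multi-solvent transfer.
* The correlation battery deliberately reproduces the published equation
  list; it is not a general model-selection tool.
* Verdict-grid provenance for Ghose under the screening platform's MR
  depends on a synthetic stand-in column (see above); only the verdicts,
  not those MR values, are meaningful.
* The bundled tables inherit their source's printing precision; a few
  printed entries are internally inconsistent with their own inputs, and
  the test suite documents rather than hides those rows.
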