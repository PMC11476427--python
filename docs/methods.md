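# Methods

`carotidrisk` is a desk-scale implementation of a cerebrovascular event-risk
modelling workflow for carotid atherosclerosis: pulsatile blood-flow
simulation in a stenosed carotid bifurcation, hyperelastic stress analysis of
a plaque-bearing cross-section, extraction of hemodynamic/structural risk
features, and an imbalance-corrected gradient-boosting classifier with
Shapley feature attribution.  This note records the models, the parameter
choices with their rationale, the numerical decisions, and what the
synthetic-data experiments do and do not demonstrate.

## Planar embodiment

Clinical workflows of this kind run 3D tetrahedral CFD on MRI-reconstructed
lumens inside commercial solvers.  This package solves the same governing
equations in two dimensions on synthetic planar domains so that every stage
runs in minutes on one CPU and is fully testable.  Two consequences are
documented rather than hidden:

* all "normalized area" features are **boundary-length fractions** of the
  vessel wall, not surface-area fractions;
* flow rates are **per unit out-of-plane depth**: an ultrasound site area is
  mapped to a channel of the geometric width (area = width x unit depth), so
  the mean inlet velocity equals the measured velocity and the Reynolds
  number is physiologic.

## Synthetic data

**Flow geometry.** A bifurcation is a straight CCA trunk splitting at a
flow-divider apex into ICA and ECA branches (default widths 6/5/4 mm,
lengths 2.5 diameters, branch angles drawn uniformly in 20-30 degrees).
The ICA carries a smooth cosine-bump stenosis; severity `s` means the
minimal perpendicular lumen width is `(1 - s)` times the reference width
(the fractional diameter-reduction convention).  Smooth walls avoid
spurious wall-shear singularities at the throat.  Branch blocks use sheared
(vertical) cross-sections conforming exactly with the junction edge; all
lengths scale linearly with the supplied diameters.

**Cross-section.** The maximum-plaque-burden site is idealised as concentric
circles: lumen, outer wall, and a fibrous plaque occupying an annular sector
(default 120 degrees arc, 0.2-0.25 mm cap).  "Plaque burden" has no standard
closed-form definition; the generator exposes the plaque **area fraction**
of the wall ring as its quantitative stand-in and labels it as such.

**Ultrasound records.** PSV is drawn in 0.6-1.6 m/s, EDV as 20-45% of PSV,
pulse rate in 55-95 bpm — typical duplex values in moderate-to-severe
carotid disease.

**Cohort.** The cohort table reproduces the study's feature schema (imaging,
simulation-based and clinical-covariate groups) and its severe class
imbalance (115 event-free vs 19 event rows by default).  Binary covariate
prevalences follow the published demographics (hypertension 0.83, smoking
0.70, diabetes 0.35); continuous marginals are physiologic ranges.  Labels
come from a *known* logistic ground truth: log-odds effects per standard
deviation of each feature plus intercept and logit noise (SD 0.5,
representing unmodelled risk).  Rejection sampling enforces exact class
counts.  Because the generative model is known, feature-importance recovery
can be tested against ground truth — the `dominant_pss_spec` experiment
makes plaque structural stress (PSS) the designed top feature (2.5 log-odds
per SD versus at most 0.6 for all others).

What passing these tests shows: the pipeline recovers a *designed* signal
under the study's sample size and imbalance.  What it does not show: that
the real clinical features carry that signal, that feature correlations in
patients match the independent synthetic marginals, or that the published
patient-level metrics would be reproduced.

## Boundary conditions

A cardiac cycle lasts `T = 60 / pulse rate` seconds.  The velocity waveform
is rebuilt from its two printed landmarks as a half-sine systolic pulse of
duration `systolic_fraction * T` (default 0.3; the systolic/diastolic
timing split is not specified by the source data, so it is an exposed
parameter) over a constant end-diastolic baseline: the simplest continuous
periodic curve with minimum EDV and maximum PSV.  The cycle starts at
end-diastole.  Velocity converts to mass flow pointwise via
`m_dot = rho V A` with blood density 1050 kg/m^3 and dynamic viscosity
0.0035 Pa s (Newtonian).  Inflow (CCA) and the ECA outflow are imposed as
parabolic Dirichlet profiles scaled to the target mass flow; the peak of a
parabolic profile is exactly 1.5 times its mean.

## Flow solver

Incompressible Navier-Stokes with Taylor-Hood elements (P2 velocity / P1
pressure — an inf-sup stable pair), implicit Euler in time and Picard
linearization of convection.  Per time step the Picard sweep stops when the
relative velocity increment falls below 1e-4, with an iteration cap of 150
(reaching the cap is logged, not fatal).  The wall is no-slip; the ICA
outlet is traction-free ("do-nothing"), which acts as the zero gauge
pressure reference.

Carotid flow reaches Reynolds numbers near 10^3, which a plain Galerkin
discretization cannot carry on desk-scale meshes.  The convective operator
therefore carries classic streamline-upwind (SU) stabilization with the
doubly-asymptotic parameter `tau = xi(Pe) h / (2|v|)`, `xi = min(Pe/3, 1)`.
SU adds diffusion only along streamlines and vanishes with the local speed,
so the near-wall shear — the quantity the features are built from — is
essentially unpolluted; the Poiseuille wall-shear benchmark (6 mu U / h,
verified to 3%) runs through the same code path.  The Picard update is
damped adaptively (halved when the fixed-point residual grows).

Wall shear is extracted at wall-edge midpoints as the tangential component
of `2 mu eps(v) n` with the inward normal, signed positive in the forward
(inlet-to-outlet) direction of each of the four wall chains.  Boundary
pressures are edge-length-averaged per tagged boundary.

Defaults: element bound `h_max` 1.2 mm, `dt = T/100`, 2 simulated cycles
with metrics from the final cycle.  These are desk-scale sizes chosen so a
full case completes in about 90 s while the cycle-periodicity diagnostic
(TAWSS difference between the last two cycles <= 2%) passes; the reference
clinical workflow uses a 0.16 mm 3D mesh, which remains the documented
default of `mesh_domain` itself.  Mass conservation (inlet vs outlet flux)
holds to well below 1% per step, and the weak divergence residual to 1e-6,
because the linearized saddle-point systems are solved directly.

## Hemodynamic features

* `TAWSS(s) = (1/T) int_0^T |tau_w| dt` by trapezoidal quadrature.  The
  magnitude convention is used (rather than the signed average) so TAWSS is
  non-negative and the atherogenic low-TAWSS threshold of 0.4 Pa is
  meaningful; the signed mean enters through the OSI instead.
* `OSI = (1/2)(1 - |mean(tau_w)| / mean(|tau_w|))`, in [0, 0.5]; points with
  zero shear over the whole cycle take OSI 0 (the 0/0 case resolved toward
  "no oscillation").
* Wall fractions: length fraction with TAWSS < 0.4 Pa, and with OSI above
  0.2 — the high-OSI cut is not standardised, 0.2 is a common literature
  choice, exposed in config.  Segments are classified by the mean of their
  endpoint values.  A >40 Pa high-TAWSS fraction (endothelial damage level)
  is logged as a diagnostic but is not a model feature.
* Pressure ratios P_ECA/P_CCA and P_ICA/P_CCA use cycle-mean absolute
  pressures: gauge traces plus a diastolic reference offset (default
  80 mmHg).  Without the offset the zero-pressure ICA outlet would force
  P_ICA/P_CCA to zero identically; a systolic-peak statistic is available in
  config.

## Plaque structural analysis

Plane-strain total-Lagrangian finite elements (quadratic triangles) on a
polar block mesh of the cross-section: plaque and wall share interface
nodes (bonded contact by construction) and the radial grid carries two
half-size element layers along the lumen and plaque interfaces in place of
a boundary-layer inflation.  Plane strain is the standard idealisation for
a long vessel's cross-section; it is a config option, not a hard-coded
assumption.  Triangles replace quadrilaterals because they mesh arbitrary
contours robustly; the published 0.05 mm face size is the meshing default,
with 0.25 mm used by the pipeline at desk scale.

Materials are polynomial Mooney-Rivlin solids
`W = sum C_ij (I1b-3)^i (I2b-3)^j + (1/d)(J-1)^2` with isochoric invariants
and orders up to `i+j = 3`, so the published wall constants (C10 = 0.07 MPa,
C20 = 3.2 MPa, C21 = 0.0716 MPa, d = 1e-5 1/Pa) and the five-parameter
fibrosis set are representable verbatim.  The Cauchy stress is derived
analytically from `S = 2 dW/dC` and verified in tests against a finite
difference of `W` to 1e-6 relative.

Boundary conditions: frictionless support on the outer perimeter (zero
normal displacement, free tangential slip) and a follower pressure on the
lumen equal to the cycle-maximum absolute pressure at the stenosis site
from the flow stage (gauge plus the 80 mmHg reference).  With `u.n = 0`
on a circular outer ring, an infinitesimal rigid rotation about the centre
is a zero-energy mode; one outer node's tangential dof is pinned to remove
it (consistent with any non-rotating solution).  Newton iteration uses a
numerically differentiated consistent tangent (central differences of the
analytic stress at each quadrature point), incremental loading with
automatic step halving, and a relative residual tolerance of 1e-6.  The
linear-elastic verification (pressurized homogeneous ring against the
thick-walled-cylinder solution, whose plane-strain stresses are independent
of Poisson ratio) uses a free outer boundary with the three rigid modes
pinned at axis nodes.

**PSS** is reported as the maximum first principal Cauchy stress over the
plaque elements and the fibrous-cap strip (wall between lumen and plaque,
within the plaque sector); an equivalent (von Mises) maximum is reported
alongside because the published quantity is not defined mathematically.
Maximum deformation is the largest nodal displacement magnitude.

## Risk model

Categorical covariates are one-hot encoded (full encoding, no dropped
reference level).  The 70-30 split is stratified per class with fractional
remainders assigned to the test partition, reproducing the (80, 13) /
(35, 6) partition of a 115/19 cohort.  Two imbalance corrections are
implemented exactly as defined: SMOTE (synthetic minority points
`x_i + u (x_nn - x_i)`, `u ~ U(0,1)`, k = 5 nearest minority neighbours
with automatic reduction for tiny minorities; binary columns rounded
half-up then clipped) and random undersampling of the majority without
replacement.  Corrections are applied inside training folds only.

The classifier is gradient boosting with logarithmic loss written from
first principles: `F_0` is the log-odds of the training prevalence,
pseudo-residuals are `y - sigmoid(F)`, each stage fits a depth-3 regression
tree by exhaustive splits maximising the Friedman improvement score, leaf
values take one Newton step `sum r / sum p(1-p)` (toggleable to the literal
least-squares leaf means), and stages are shrunk by the 0.1 learning rate;
100 stages by default.  The test suite verifies equivalence with
scikit-learn's `GradientBoostingClassifier` (same hyper-parameters) to
within 0.02 test AUC on synthetic datasets — in practice the trees often
match split for split.

Evaluation reports the confusion matrix at threshold 0.5 (exposed in
config), sensitivity, specificity, PPV, NPV, macro balanced accuracy, F1,
ROC AUC (rank form, equal to the trapezoidal ROC area with tie handling),
and the support-weighted accuracy/recall/F1 variants.  The weighted
variants are carried because the published aggregate table is arithmetic-
consistent with its printed confusion matrices only under support
weighting (e.g. 36/41 = 88% for a 32/3/2/4 matrix, while the macro
balanced accuracy of that matrix is 0.79); both conventions are always
reported.  Zero-denominator rates are reported as undefined, never as 0.
Cross-validation is stratified 5-fold; the summary row is the arithmetic
mean of the fold rows.

## Shapley attribution

Attributions are computed on the log-odds margin (the model's additive
scale) with interventional feature removal against a fixed background
sample (default: up to 100 training rows).  Two estimators: exact
enumeration over all `2^p` coalitions (capped at p = 15) and a
permutation-sampling estimator that is unbiased for the exact value,
reports per-feature standard errors, and satisfies the efficiency
constraint exactly per permutation (telescoping).  Efficiency, symmetry and
null-player axioms are asserted in tests; global importance is the mean
absolute attribution per feature, ties broken lexicographically.

## Pipeline sizes and determinism

Every stage draws from named substreams of one master seed
(`substream(seed, tag)`), so repeated runs are bit-identical.  The default
single case (1.2 mm flow mesh, T/100 steps, 2 cycles, 0.25 mm structural
mesh) completes in roughly 90 s on one CPU; the cohort study (both
imbalance arms, 5-fold CV, held-out test, sampled Shapley ranking) in
about 10 s.  Test fixtures use coarser meshes and a low-Reynolds waveform
so the full suite stays within minutes.

## Known limitations

* 2D planar flow cannot reproduce secondary (swirling) flows, so OSI
  patterns differ qualitatively from 3D vessels; the OSI *definition* and
  its closed-form limits are exact.
* The SU-stabilized convection operator is first-order consistent; wall
  quantities converge under refinement (verified) but interior fields on
  coarse meshes are smoothed.
* The structural stage is uncoupled from the flow (no fluid-structure
  interaction) and uses only wall + fibrous-plaque materials; lipid,
  calcification and hemorrhage constituents are out of scope.
* Synthetic cohort features are drawn independently; real imaging and
  hemodynamic features are correlated, which generally *raises* the
  difficulty of attribution — recovery results here are a necessary, not
  sufficient, validation.
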