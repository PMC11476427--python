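# carotidrisk

Desk-scale modelling of cerebrovascular event risk in carotid artery
disease.  The package chains three stages that are usually spread across a
clinical imaging pipeline, a commercial solver and an ML notebook:

1. **Hemodynamics** — transient incompressible Navier-Stokes flow
   (Taylor-Hood finite elements, implicit Euler, Picard iteration) in a
   synthetic planar carotid bifurcation with an ICA stenosis, driven by
   ultrasound-derived boundary conditions (`m_dot = rho V A` mass-flow
   waveforms rebuilt from PSV/EDV and pulse rate).
2. **Plaque mechanics** — plane-strain hyperelastic analysis of the
   maximum-plaque-burden cross-section with polynomial Mooney-Rivlin
   materials (arterial wall: C10 = 0.07 MPa, C20 = 3.2 MPa,
   C21 = 0.0716 MPa; fibrotic plaque: published five-parameter set),
   frictionless outer support and a follower luminal pressure load.
3. **Risk modelling** — the feature set
   {peak/average TAWSS, average OSI, low-TAWSS and high-OSI wall fractions,
   P_ECA/P_CCA, P_ICA/P_CCA, plaque structural stress (PSS)} plus imaging
   and clinical covariates feeds a from-scratch gradient-boosted-tree
   classifier (log loss, Friedman-MSE splits, 100 stages, learning rate
   0.1, depth 3) with SMOTE / random-undersampling imbalance handling,
   stratified 70-30 split and 5-fold CV, and Shapley feature attribution.

The core wall-shear metrics are

    TAWSS = (1/T) \int_0^T |tau_w| dt
    OSI   = (1/2) (1 - |\int_0^T tau_w dt| / \int_0^T |tau_w| dt)

with OSI in [0, 0.5] (0: unidirectional shear, 0.5: zero-mean oscillation),
a low-TAWSS threshold of 0.4 Pa and an OSI cut of 0.2.

No patient data are used anywhere: a synthetic-data module generates
geometries, ultrasound records and an imbalanced cohort (115 event-free vs
19 event subjects) with a *known* logistic ground-truth risk model, so the
whole pipeline — including feature-importance recovery — is testable end to
end.  See `docs/methods.md` for models, assumptions and limitations.

## Worked example

One full case (geometry -> waveforms -> pulsatile flow -> wall metrics ->
plaque stress), about 90 s on one CPU:

```python
from carotidrisk import pipeline

cfg = pipeline.PipelineConfig(seed=1)      # 50% ICA stenosis by default
row = pipeline.run_case(cfg, outdir="case1")
```

yields (seed 1):

```
peak_tawss            19.67    # Pa, at the stenotic throat
vessel_avg_tawss       2.50    # Pa, arc-length-weighted wall average
vessel_avg_osi         0.0525
norm_area_low_tawss    0.098   # fraction of wall below 0.4 Pa
norm_area_high_osi     0.099   # fraction of wall above OSI 0.2
p_eca_over_cca         0.979
p_ica_over_cca         0.996
site_pressure      10785.6     # Pa absolute at the stenosis site
pss                 4134.0     # Pa, peak principal stress in plaque/cap
max_deformation     3.1e-05    # m
```

Physiologic wall shear (a few Pa on average, tens of Pa in the jet),
near-unity pressure ratios (the pressure drop is small relative to the
80 mmHg reference), and a kPa-scale cap stress — the biomechanical marker
the risk model weighs most.

The machine-learning study on a synthetic 134-subject cohort
(`pipeline.run_cohort_study(cfg, outdir="study1")`, ~10 s) reproduces the
experimental grid {SMOTE, undersampling} x {5-fold CV, held-out test};
with seed 1 the SMOTE arm dominates (test accuracy 0.83 vs 0.71, AUC 0.81
vs 0.75, specificity 0.94 vs 0.71) and the Shapley ranking puts `pss`
first, matching the generative ground truth.

The same stages are scriptable from the shell:

```bash
carotidrisk synth  --seed 1 --out inputs/
carotidrisk case   --seed 1 --out case1/
carotidrisk cohort --seed 1 --out study1/
carotidrisk report --study study1/
```

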