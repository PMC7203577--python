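# amylv

Image-derived left-ventricle (LV) biomechanics and model-based progression
markers for cardiac amyloidosis.

Amyloid deposition stiffens the myocardium ("stiff-heart" syndrome) and
wall thickness, strain and filling pressure change together as the disease
progresses or responds to therapy.  Routine cine imaging yields LV
geometry and strain but not tissue stiffness or stress; `amylv` closes that
gap with a personalised passive-mechanics model and summarises each
baseline/follow-up scan pair by seven markers whose joint direction of
change predicts the clinical course.

The package implements, end to end:

* **Geometry**: co-registration of diastolic LV mesh series (long-axis
  shift `d_t − min dᵢ`, circumferential alignment at the inferior
  insertion point), rule-based fiber/sheet architecture (±60°/±45°),
  per-element deformation gradients, Green–Lagrange circumferential and
  longitudinal strains averaged over 3 layers × 20 regions, cavity/wall
  volumes and median wall thickness.
* **Mechanics**: the Holzapfel–Ogden orthotropic strain energy

  ψ = a/(2b)[e^{b(I₁−3)} − 1] + Σ_{i=f,s} a_i/(2b_i)[e^{b_i(max(I₄ᵢ,1)−1)²} − 1]
    + a_fs/(2b_fs)[e^{b_fs I₈fs²} − 1],

  a reduced-order quasi-static inflation model under a linear diastolic
  pressure ramp (pluggable forward-model interface), p–V curves, filling
  work W = ∫p dV, principal stresses and pseudo-uniaxial stress–stretch
  response.
* **Inference**: end-diastolic pressure scaling
  P_ED = 19 mmHg · (V_wall/V_LV)/2.678, two-step estimation of the eight
  material constants (trust-region least squares over {a, b, a_f, b_f,
  a_fs} with the healthy second group pinned, then a scalar search of
  ξ = b_f/b_s ∈ [1.44, 2.96] through the closure regressions
  a_s/a_fs = 1.72 a_f/a_s − 3.65 and b_s/b_fs = −0.43 b_f/b_s + 1.61),
  and residual-bootstrap uncertainty propagated to the markers.
* **Markers and score**: V_wall/V_LV, Ē_cc, Ē_ll, W, σ̄₁, f̄ (average
  stress–stretch slope) and the shape-trajectory direction; the recovery
  score is the fraction of markers that changed for the better, and scores
  above 0.5 predict a stable-or-recovery course.
* **Shape statistics**: subjects × 17,376 shape matrices from 5,792-vertex
  endo+epi surface templates, PCA modes, LDA / kernel-SVM classification
  with leave-one-out cross-validation (sensitivity, specificity, F1),
  LDA distance-to-healthy trajectories, Mood's median test.
* **Synthetic data**: a truncated prolate-spheroid LV generator with known
  ground-truth parameters, seeded measurement noise and two-class shape
  cohorts (healthy 0.77 cm vs amyloid 1.11 cm median wall thickness), so
  the whole pipeline is testable without clinical images.

## Worked example

Generate a synthetic ventricle with known material parameters, refit it
from its own noisy volume/strain observations, and compare stiffness:

```python
import numpy as np
from amylv import (
    coarse_template_spec, generate_template, assign_fibers,
    generate_diastolic_series, NoiseModel, closure_consistent_truth,
    MaterialParameterEstimator, ReducedOrderInflation,
    uniaxial_fiber_response, average_slope,
)

truth = closure_consistent_truth()          # a fixed point of the two-step fit
mesh = assign_fibers(generate_template(coarse_template_spec(n_long=5)))
model = ReducedOrderInflation()
rec = generate_diastolic_series(mesh, truth, n_time=7,
                                noise=NoiseModel(0.0, 0.0, seed=0), model=model)
print(f"P_ED = {rec.p_ed:.2f} mmHg, EDV/V0 = "
      f"{rec.volumes_true[-1]/rec.volumes_true[0]:.3f}")

est = MaterialParameterEstimator(forward_model=model, n_starts=2,
                                 max_nfev=120, random_state=1)
est.fit(rec.as_case_data())
f_true = average_slope(uniaxial_fiber_response(truth))
f_fit = average_slope(uniaxial_fiber_response(est.params_))
print(f"F_VE = {est.result_.f_ve:.2e}, xi = {est.xi_:.3f}")
print(f"f-bar truth {f_true:.3f} kPa vs fitted {f_fit:.3f} kPa")
```

Output:

```
P_ED = 8.74 mmHg, EDV/V0 = 1.907
F_VE = 5.38e-13, xi = 2.648
f-bar truth 18.274 kPa vs fitted 18.274 kPa
```

The misfit collapses to numerical zero on noise-free data and the average
stress–stretch slope — the stiffness marker f̄ — is recovered exactly, even
though the eight constants are not individually identifiable.

The packaged reference-cohort arithmetic (pressures, marker calls, recovery
scores, the 6-of-7 agreement with the blinded clinical assessment) can be
recomputed from the command line:

```bash
amylv reproduce-tables
# agreement: 6/7; pressure discrepancies [1, 5] (expected [1, 5]); ...
```

and a full synthetic study (simulate → fit → shapes → markers → score) runs
via `amylv --config my.yaml report`.

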