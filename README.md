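# nirscouple

Assessment of cerebral autoregulation from simultaneous prefrontal fNIRS
and continuous arterial blood pressure (ABP), via dynamical Bayesian
inference of coupling functions between phase oscillators.

## The problem

Cerebral autoregulation keeps cerebral blood flow stable while arterial
pressure fluctuates; when it is impaired — as in cognitive decline —
pressure oscillations pass into cerebral hemodynamics. Given a subject's
resting-state recording (oxy-/deoxyhemoglobin concentrations in the left
and right prefrontal cortex at 20 Hz, ABP at 1000 Hz, 15 min), the package
computes two families of markers:

- **Tissue oxygenation index** TOI = 100·O2Hb/(O2Hb + HHb), summarized as
  the time mean per hemisphere and their average;
- **Coupling strength and direction** between the cardiac ABP phase
  (0.6–2 Hz) and the slow O2Hb oscillations (VLF 0.02–0.07 Hz, LF
  0.07–0.2 Hz). Phases come from complex-Morlet wavelet transforms; the
  coupled dynamics

      dphi_m/dt = sum_k c_k^(m) Phi_k(phi_A, phi_O) + xi_m(t)

  (2-D Fourier basis up to order K = 2, Gaussian dynamical noise) are
  inferred window-by-window with dynamical Bayesian inference. The strength
  CS_AO is the Euclidean norm of the inferred cross-dependence
  coefficients; CD = (CS_AO − CS_OA)/(CS_AO + CS_OA) gives the dominant
  direction.

Cohort-level statistics (Kolmogorov–Smirnov and Levene checks, one-way
ANOVA with Bonferroni pairwise tests at p < 0.0167, Pearson correlations
with the MoCA cognition score, ROC with Youden's J) compare the three MoCA
bands: normal cognition (NC, >= 26), mild (MCI, 15–25), and impaired (CI,
<= 14). Because such human recordings are not public, a first-class
synthetic-cohort generator produces coupled-oscillator recordings with
known ground truth for every stage. See `docs/methods.md` for the full
model description and limitations.

## Worked example

```python
import numpy as np
from nirscouple import (OscillatorSpec, CouplingSpec, simulate_phase_pair,
                        build_basis, infer_window, coupling_strength,
                        directionality)

# cardiac (1.1 Hz) drives a slow oscillator (0.1 Hz) with 0.3*sin(phi_A)
cardiac = OscillatorSpec(natural_frequency=1.1, phase_noise_intensity=0.05)
slow = OscillatorSpec(natural_frequency=0.1, phase_noise_intensity=0.02)
coupling = CouplingSpec(("a", "b"), {(1, 0, "sin"): 0.3})
phi_a, phi_o = simulate_phase_pair(cardiac, slow, coupling,
                                   duration=900, step=0.05, seed=7)

basis = build_basis(K=2)
post = infer_window(phi_a, phi_o, basis)
cs_ao = coupling_strength(post, "ao", basis)
cs_oa = coupling_strength(post, "oa", basis)
print(f"CS_AO = {cs_ao:.3f} rad/s   CS_OA = {cs_oa:.3f} rad/s   "
      f"CD = {directionality(cs_ao, cs_oa):+.2f}")
```

prints

```
CS_AO = 0.297 rad/s   CS_OA = 0.052 rad/s   CD = +0.70
```

i.e. the inference recovers the generative coupling amplitude (0.3 rad/s,
plus a small noise floor), finds almost no reverse coupling, and the
positive directionality index correctly identifies the pressure-to-
hemoglobin direction as dominant.

A full cohort run, from synthesis to the statistical report:

```python
from nirscouple import simulate_cohort, run_pipeline, PipelineConfig

cohort = simulate_cohort({"NC": 15, "MCI": 15, "CI": 15}, seed=1)
metrics, report = run_pipeline(cohort, PipelineConfig(n_boot=500))
print(metrics.groupby("group")["mean_toi"].mean().round(1).to_dict())
print("NC-CI mean TOI significant:",
      report["variables"]["mean_toi"]["anova"]["pairwise"]["NC-CI"]["significant"])
```

prints

```
{'CI': 58.9, 'MCI': 62.4, 'NC': 64.0}
NC-CI mean TOI significant: True
```

The same steps are available from the shell: `nirscouple simulate`,
`nirscouple metrics`, `nirscouple stats`, and `nirscouple run` (see
`nirscouple --help`).

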