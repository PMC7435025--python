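# muscleperf

Quantitative perfusion mapping of exercise-stimulated calf muscle from
dynamic contrast-enhanced (DCE) MRI — tracer-kinetic deconvolution, a
neural-network surrogate for near-instantaneous mapping, and the
synthetic-study machinery to validate both.

After plantar-flexion exercise, a gadolinium bolus is imaged at 1 s per
frame for 40 s in one calf slice. Each voxel's tissue
contrast-enhancement curve TC(t) is modelled as the convolution of the
arterial input function AIF(t) with an adiabatic tissue-homogeneity
impulse retention function

```
IRF(t) = 0                              t <  t0
       = F                              t0 ≤ t < t0 + minTT
       = F·E·e^{−k (t − t0 − minTT)}    t ≥ t0 + minTT
```

whose leading parameter F is perfusion in ml·min⁻¹·100 g⁻¹. Perfusion
maps come from voxelwise nonlinear least squares — either a single-start
**regular fit** (F=350, t0=2 s, minTT=6 s, E=0.4, k=0.15 s⁻¹) or the
**multigrid fit**, 25 restarts over F ∈ {100…300} × t0 ∈ {2…6 s} keeping
the lowest residual. Because per-voxel optimisation is slow, a plain
feed-forward classifier (80 inputs = 40 TC + 40 AIF samples, 7×70 ReLU
hidden layers, softmax over 40 perfusion levels 10…400) is trained on
multigrid-fitted voxels and then predicts whole maps in well under a
second. A calibrated generator produces synthetic exercise cohorts —
gamma-variate AIFs whose first-pass area shrinks with exercise-driven
cardiac output, lognormal regional perfusion, Gaussian concentration
noise — so every stage is testable without human data.

Intended users: researchers in muscle physiology / vascular imaging who
process exercise DCE-MRI, and methodologists studying learned surrogates
for tracer-kinetic inversion.

## Worked example

```python
import numpy as np
from muscleperf import error_metrics, fit_map, load_preset
from muscleperf.simulate import generate_cohort

spec = load_preset("testing", rng_seed=42, voxels_per_dataset=300)
spec.datasets = spec.datasets[:1]          # one simulated study
study = generate_cohort(spec)[0]

maps = fit_map(study.tc, study.mask, study.aif, mode="multigrid")
est = maps["F"][study.mask]                # fitted perfusion per voxel
truth = study.truth_perfusion

m = error_metrics(est, truth, method="multigrid", reference_name="truth")
print(f"n={m.n_voxels}  mean={m.mean:.1f}  median={m.median:.1f}")
print(f"MAE={m.mae:.1f}  RMSE={m.rmse:.1f}  r={m.pearson_r:.3f}")
```

prints

```
n=300  mean=85.2  median=68.6
MAE=10.3  RMSE=27.7  r=0.912
```

i.e. on one 300-voxel simulated study at SNR 20 the multigrid fit
recovers the true perfusion field with a mean absolute error of about
10 ml·min⁻¹·100 g⁻¹ and correlation 0.91; the RMSE is larger than the
MAE because a minority of weakly identified high-perfusion voxels carry
most of the squared error.

The same pipeline is scriptable from the shell:

```bash
muscleperf simulate --preset diverse --seed 7 --out cohort/
muscleperf fit cohort/study_000 --mode multigrid
muscleperf train cohort/study_* --label-source multigrid --model-out net.npz --seed 7
muscleperf predict net.npz cohort/study_000
muscleperf evaluate --reference cohort/study_000/fit_multigrid/F.nii.gz \
                    --method nn cohort/study_000/nn_F.nii.gz --out report
```

Study directories are plain NIfTI + CSV + JSON; trained models are a
single `.npz` whose inference needs only numpy.

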