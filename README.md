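# roiglasso

Multi-subject sparse EEG/MEG source estimation with an ROI-grouped
elastic net.

## The problem

Estimating the cortical sources of EEG/MEG recordings is a heavily
underdetermined inverse problem: thousands of candidate sources, ~128
sensors. The classical minimum-norm (ridge) inverse yields dense, blurry
estimates, and when several subjects are recorded it can only be applied
to each subject separately. `roiglasso` implements a different prior:
cortical activity is organised by functionally defined regions of
interest (ROIs) — an ROI tends to be off entirely or broadly on, and the
*same* ROI should be selected consistently across subjects. It is aimed
at researchers with fMRI-defined ROIs (e.g. retinotopic visual areas)
who want group-level source estimates without warping brains to a
template.

## The method

For subject k with ROI lead-field blocks `F_i^k` and recordings
`Y^k (N x T)`, each centred block is replaced by its top K = 5
principal-component scores `X_i^k = F_i^k P_i^k` (within-ROI spatial
smoothing that respects functional borders), the observations are
projected on the leading right singular vectors `V_d` of the sensor
record (99%-variance rule; typically d = 2), subjects are stacked block
diagonally, and the coefficients solve the matrix group elastic net

    min ½‖Ỹ − 1μᵀ − Σᵢ Xᵢ β̃ᵢ‖²_F + λ Σᵢ γᵢ‖β̃ᵢ‖_F + α‖β̃‖²_F,

where group i collects ROI i's columns across *all* subjects and
`γᵢ = ‖Xᵢ‖_F`. The Frobenius group penalty zeroes whole
ROI-across-subjects blocks, pooling evidence over the cohort; λ is
chosen by generalised cross-validation along a warm-started path, and
estimates are back-projected as `β̂ᵏ = Pᵏ β̃ᵏ V_dᵀ`. A per-subject
minimum-norm baseline, a synthetic multi-subject simulation protocol,
and ROC-based recovery metrics (balanced AUC_close/AUC_far, MSE,
relative energy, ROI-level AUC with cross-subject averaging) are
included. See `docs/methods.md` for the full model and its assumptions.

## Worked example

```python
import numpy as np
from roiglasso import (simulate_dataset, stack_problem, fit_path,
                       select_lambda, backproject, evaluate)
from roiglasso.glasso_solver import PenaltyConfig, fit_minimum_norm

# four subjects, 18 visual ROIs, clusters over 30% of V2v-L and V4-L,
# amplitudes U[1,10], 128 sensors, 91 time points, SNR 0.32
forwards, truths, recordings = simulate_dataset(4, seed=11)

signal = np.concatenate([r.signal for r in recordings], axis=0)
problem = stack_problem(list(zip(forwards, recordings)), signal=signal)
print(f"design {problem.X.shape}, temporal dimension d = {problem.d}")

path = fit_path(problem, PenaltyConfig(n_lambda=40))
j = select_lambda(path.gcv, path.lambdas)
estimates = backproject(path.betas[j], problem)
report = evaluate(estimates, truths, forwards)
```

Output:

```
design (512, 360), temporal dimension d = 2
GCV selects lambda = 319 (15 of 18 ROI groups active, r2 = 0.23)
group lasso:   AUC_close 0.837  AUC_far 0.827  AUC 0.832  MSE 0.014  rel. energy 0.765
minimum norm:  AUC_close 0.717  AUC_far 0.355  AUC 0.536  MSE 0.039  rel. energy 0.184
```

Reading the numbers: the design stacks 4 x 128 sensor rows against
18 ROIs x 5 components x 4 subjects = 360 columns, and two smooth
source time courses survive the 99%-variance rule (d = 2). The group
lasso separates truly active from inactive vertices both near the
activation (AUC_close) and against distant spurious maxima (AUC_far),
and concentrates 77% of estimated energy inside the truly active
vertices; the dense minimum-norm estimate is competitive near the
activation but leaks badly at distance (AUC_far 0.36, 18% energy).

The same pipeline is scriptable from the shell:

```sh
roiglasso simulate --out sim.h5 --subjects 4 --seed 11
roiglasso filter --in sim.h5 --out filt.h5
roiglasso fit --in filt.h5 --out path.csv
roiglasso evaluate --sim sim.h5 --filtered filt.h5 --out metrics.csv
roiglasso benchmark --out results.csv --summary summary.csv --seed 0
```

`roiglasso benchmark` reproduces the multi-subject studies: combined
AUC as a function of cohort size for both methods (the group lasso
improves with subjects, the decoupled minimum norm stays flat) and
ROI-level AUC with vs without sign-preserving cross-subject averaging
(both methods get a boost). `--paper-scale` switches from the
desk-scale defaults (20 replicates, up to 8 subjects) to 50 replicates
and cohorts up to 25.

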