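# ssvb — stochastic variational Bayes for multi-PLD ASL perfusion MRI

Arterial spin labelling (ASL) MRI measures brain perfusion by magnetically
labelling inflowing blood water. Sampling the inflow curve at multiple
post-label delays (PLDs) allows both cerebral blood flow (CBF, *f*) and
arterial transit time (ATT, Δt) to be estimated, but the data have very low
SNR and the kinetic model is non-linear, which makes ATT estimation in
particular fragile. This package is for researchers quantifying multi-PLD
PCASL data who want voxelwise CBF/ATT maps with principled, adaptive spatial
regularisation — plus the standard comparator fitters and a simulation
benchmark harness.

## The method

The difference signal is modelled with the Buxton single-compartment PCASL
model: ΔM(t) = 0 for t < Δt, rises as
2·M0a·f·T1app·e^(−Δt/T1b)·(1 − e^(−(t−Δt)/T1app)) while the bolus arrives
(Δt ≤ t < Δt+τ), and decays as
2·M0a·f·T1app·e^(−Δt/T1b)·e^(−(t−Δt−τ)/T1app)·(1 − e^(−τ/T1app)) afterwards,
with 1/T1app = 1/T1 + f/λ.

SSVB fits a diagonal-Gaussian approximate posterior q(f, Δt) per voxel by
directly maximising a Monte-Carlo estimate of the variational free energy
(ELBO),

    F ≈ (1/L) Σ_l [ log p(y|θ*_l) − log( q(θ*_l) / p(θ*_l) ) ],

with reparametrised samples θ* = μ + σ·ε and RMSProp ascent on all
variational parameters. Both parameter maps carry an adaptive spatial prior
built from the first-order graph Laplacian D over the brain mask,
log p(θ) = (v/2)·log α − (α/2)·θᵀ(−D)θ, whose precision α is itself
optimised — the data determine how much smoothing is applied. Convergence
uses a patience schedule: after 50 epochs without a new best cost the state
reverts to the best snapshot and the Monte-Carlo sample size grows by one,
stopping after five such reversions.

Comparators: unconstrained voxelwise non-linear least squares
(Levenberg–Marquardt, multi-start over ATT), and signal-weighted delay
(first temporal moment of the PLD curve, inverted through a
schedule-specific noiseless calibration, followed by a fixed-ATT linear
CBF solve).

## Worked example

```python
import numpy as np
from ssvb import (TissueConstants, get_schedule, simulate_dataset,
                  SSVBFitter)

schedule = get_schedule("grey_paper")   # τ=2.05 s, 9 PLDs x 4 repeats
constants = TissueConstants()           # T1=1.3 s, T1b=1.65 s, λ=0.9
ds = simulate_dataset(schedule, constants, grid_shape=(5, 5, 5),
                      true_cbf=60.0, true_att=1.5, noise_sd=20.0, rng=42)

est = SSVBFitter(schedule, constants, rng_seed=7).fit(ds.data, grid=ds.grid)
res = est.result_
print(f"CBF {est.cbf_.mean():.1f}  ATT {est.att_.mean():.3f}  "
      f"epochs {res.epochs_run}  reversions {res.reversions}")
```

prints

```
CBF 59.0  ATT 1.495  epochs 564  reversions 5
```

i.e. on a 125-voxel phantom with true CBF 60 and ATT 1.5 s at noise SD 20,
the posterior-mean maps average 59.0 and 1.495 s (bias under 2%), and the
optimiser ran 564 epochs before completing its five reversions.

The same models are exposed as a command-line tool:

```bash
ssvb simulate --schedule grey_paper --seed 1 --out sims/
ssvb fit --data sims/att1.50_sd20/asl_diff.nii.gz \
         --mask sims/att1.50_sd20/mask.nii.gz \
         --schedule grey_paper --method ssvb --seed 7 --out fits/
ssvb evaluate --fits fits/ --truths sims/ --out bias.csv
ssvb report --table bias.csv --out figs/
```

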