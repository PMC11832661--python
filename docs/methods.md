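# Methods

## Signal model

The label–control difference signal of a pseudo-continuous ASL experiment is
modelled with the Buxton single-compartment kinetic model. With `t` the time
since the start of labelling, `τ` the label duration, `f` perfusion (CBF) and
`Δt` the arterial transit time (ATT):

* `t < Δt`: ΔM = 0 (bolus not yet arrived);
* `Δt ≤ t < Δt+τ`: ΔM = 2·M0a·f·T1app·e^(−Δt/T1b)·(1 − e^(−(t−Δt)/T1app));
* `t ≥ Δt+τ`: ΔM = 2·M0a·f·T1app·e^(−Δt/T1b)·e^(−(t−Δt−τ)/T1app)·(1 − e^(−τ/T1app));

with 1/T1app = 1/T1 + f_rate/λ. The label-decay factor e^(−Δt/T1b) is applied
to both post-arrival branches; this is the standard form and is what makes
the curve continuous at the end of the bolus (a form that omits the factor
from the inflow branch is discontinuous there).

**Units.** CBF is carried in the conventional ml/100g/min scale: it enters
the signal amplitude directly (with M0a = 1, so inversion efficiency and
calibration are absorbed into the arbitrary signal units) and enters the
apparent relaxation rate as `f/6000` (the ml/100g/min → s⁻¹ conversion)
divided by λ. At CBF 60 this puts the peak difference signal near 50 signal
units, so the benchmark noise SDs of 10–40 correspond to per-volume SNR of
roughly 5 down to ~1 — the low-SNR regime multi-PLD ASL actually lives in.
The f/λ coupling perturbs amplitude-linearity in f by only a few percent, so
results are insensitive to the exact conversion.

**Tissue constants** default to 3 T consensus values — T1 (tissue water)
1.3 s, T1b (arterial blood) 1.65 s, λ = 0.9, M0a = 1 — and are overridable
via `TissueConstants` or the YAML config.

**Negative parameters.** Samplers and the unconstrained NLLS fitter can
produce negative CBF or ATT. The piecewise formulas are evaluated as
written (negative ATT simply places every timepoint post-arrival); nothing
is clamped inside the model, which keeps the objective smooth for gradient
descent. The only guards are numerical: exponent arguments are clipped at
±500 and the apparent rate is floored at 1e−9 s⁻¹ in the vectorised path so
that extreme excursions yield finite values instead of overflow.

## Acquisition schedules

A schedule is a label duration, a list of PLDs and per-PLD repeat counts;
the model time of PLD i is t_i = τ + PLD_i. Two presets ship:

* `grey_paper` — τ = 2.05 s; PLDs 0.200, 0.775, 0.775, 0.775, 1.800, 2.275,
  2.475, 2.675, 2.800 s; 4 repeats each (N = 36). The triplicated 0.775 s
  entry is intentional (an optimal-sampling design); the implementation
  keeps it verbatim.
* `hcp_asl` — τ = 1.5 s; PLDs 0.2, 0.7, 1.2, 1.7, 2.2 s; repeats
  6, 6, 6, 10, 15 (N = 43).

## The SSVB objective

Per voxel the posterior over (CBF, ATT) is an independent (no covariance)
Gaussian with free means and log-SDs. The noise is zero-mean Gaussian with a
per-voxel variance treated as a log-parametrised point estimate; the two
spatial precisions are global log-parametrised scalars. The free energy is
estimated with L reparametrised samples θ* = μ + e^{log σ}·ε; because the
spatial prior couples voxels, each sample is a full map.

Terms and conventions:

* Likelihood: (N/2)·log φ − (φ/2)·Σ(y−M(θ*))², with the 2π constant
  omitted (a fixed offset). Repeats of one PLD share a model value, so the
  sum of squares is evaluated from per-PLD sufficient statistics — the
  model is evaluated once per distinct PLD entry, not per volume.
* Spatial priors on both maps: (v/2)·log α − (α/2)·θᵀ(−D)θ, where D is the
  6-connectivity graph Laplacian over the mask (off-diagonal 1 for
  face-adjacent pairs, diagonal = −neighbour count; −D is PSD and the
  quadratic form is the sum of squared neighbour differences, so the prior
  penalises roughness). D is singular, so this is an improper prior; the
  (v/2)·log α normalisation is the per-map constant that lets α trade data
  fit against smoothing when it is optimised. One α per map, point-optimised
  on the log scale with no hyperprior.
* Noise prior: a broad Gaussian on each voxel's log noise variance, centred
  on the log of that voxel's observed data variance with SD 4 in log space
  (≈ e^±4 in variance) — weakly-informative scale anchoring only.
* Entropy / −log q: evaluated with full Gaussian constants so that the
  prior-minus-q term is an exact KL sample for proper priors. Through the
  reparametrisation the Mahalanobis part reduces to ε²/2, whose gradient
  w.r.t. μ and log σ vanishes — the low-variance ("sticking the landing")
  form of the entropy gradient.

All gradients are computed analytically (the Buxton branches have
closed-form partials in f and Δt) and are verified against central finite
differences in the test suite; no autodiff framework is involved.

## Optimisation schedule

RMSProp (learning rate 0.1, decay 0.9, epsilon 1e−8) ascends the free
energy over all state fields simultaneously. The Monte-Carlo sample size
starts at L = 2 and the run tracks the best (lowest) cost seen:

* after 50 consecutive epochs without a new best cost, the state reverts to
  the best snapshot, L grows by 1, and the RMSProp accumulators are reset
  (fresh step-size adaptation from the restored state);
* the run ends after 5 reversions (or a 5000-epoch safety cap), returning
  the best snapshot.

Within each epoch the ε draws are antithetic pairs (ε, −ε): the estimator is
unchanged in expectation, but odd-order fluctuations cancel, which lowers
the variance of both the cost (so the best-cost ratchet can register small
genuine improvements instead of reacting to sampling noise) and the
gradients. A single integer seed drives all draws; two runs with the same
seed are bit-identical on one thread. On a 125-voxel simulated dataset the
schedule terminates after roughly 450–650 epochs in ~1–2 s; the epoch count
grows with image size because larger images yield richer best-cost
improvement dynamics.

## Initialisation

The means are set by per-voxel template matching: candidate ATT values span
0.2 s to `max(t) − τ` in ~0.4 s steps (beyond that cap every sampled
timepoint lies on the inflow ramp, where amplitude and delay are degenerate
and a start point is meaningless); for each candidate the CBF amplitude has
a closed-form least-squares solution. Selection between candidates uses a
ridge-shrunk amplitude (zero-mean prior of SD 60 ml/100g/min, noise taken
from the within-PLD scatter) so that weakly-sampled late-ATT templates
cannot win by fitting noise with huge amplitudes; the winning candidate's
amplitude is then the plain least-squares value. Posterior log-SDs start at
log 10 (CBF) and log 0.5 s (ATT), both spatial precisions at 1e−2, and the
log noise variance at the log of the per-voxel variance about the per-PLD
means. All of these are constructor arguments.

The single-point alternative (ATT initialised to 1.3 s everywhere) was
found to under-converge badly at long transit times: the optimiser's fixed
step scale and the patience schedule terminate the run while CBF is still
tens of units from the optimum (truth-initialised runs reach strictly lower
cost). Data-driven initialisation removes that artifact.

## Comparator fitters

**NLLS** minimises the per-voxel sum of squares over (CBF, ATT) by
Levenberg–Marquardt with the analytic Jacobian, completely unconstrained,
multi-started from ATT ∈ {0.7, 1.3, 2.0, 2.7} s (the landscape is
multimodal at low SNR) with best-SSD selection. SD maps come from the
linearised covariance at the optimum; a voxel failing all starts is NaN.
The suite checks it against an exhaustive grid-search-plus-polish oracle.

**Weighted delay** estimates ATT from the first temporal moment
Σ t̄_i·ΔM̄_i / Σ ΔM̄_i of the repeat-averaged signal over distinct PLDs
(duplicate PLD entries are merged), inverted through a monotone calibration
curve: the same moment computed from the noiseless model on an ATT grid
(default 0.2–4.0 s, 0.01 s steps). Grid points beyond the schedule's last
timepoint — where the noiseless signal vanishes or the moment saturates —
are trimmed to the strictly-increasing prefix; a schedule whose curve has
no such prefix (e.g. a single PLD) is rejected. Data moments outside the
calibrated range are clipped to the range ends with a warning; non-positive
moment denominators give NaN. CBF then comes from a linear amplitude solve
at the fixed ATT, iterated once to refresh the T1app coupling. Because the
calibration is built from the same kinetic model that generates the data,
this estimator is exact on noiseless data by construction — implementations
that invert the moment through an approximate analytic relation instead
inherit a systematic short-ATT bias that this design deliberately removes.

## Simulator and what it does (not) emulate

One dataset = a fully-masked isotropic grid (default 5×5×5) in which every
voxel shares the same (CBF, ATT); iid zero-mean Gaussian noise is added
directly to the difference signal of every acquired volume. The benchmark
factorial holds CBF at 60, sweeps true ATT 0.5–3.0 s in 0.25 s steps and
noise SD 10–40 in steps of 10 (44 cells), with deterministic per-cell child
seeds. CBF is not varied because the signal is (near-)linear in it, so
varying CBF is equivalent to varying SNR.

The simulator reproduces the estimation problem's geometry (non-linear
kinetics, low SNR, spatial homogeneity that the spatial prior can exploit)
but not real-data complications: no anatomy or partial volume, no label–
control pair noise structure, no motion, no physiological noise, and
Gaussian rather than Rician magnitude noise. Passing benchmarks therefore
demonstrate correct inference under the model, not robustness to
acquisition artifacts.

## Evaluation

For each (fitter, schedule, true ATT, noise SD) cell the mean across voxels
(NaN voxels excluded and counted) of each parameter map is compared with
truth as a percentage bias; curves are summarised per true ATT by the mean
over noise SDs with the min–max envelope across noise levels as the
uncertainty fan. `scripts/acceptance.py` recomputes the full factorial for
both schedules from scratch. Problem sizes there are the study's own:
125-voxel grids, 44 grey-schedule cells, 32 HCP-schedule cells (true ATT
0.5–2.25 s), four noise levels per cell.

## Known limitations

* At true ATT beyond the schedule's design range (e.g. 3.0 s on the
  grey-paper scheme) the likelihood is nearly flat along a correlated
  CBF–ATT ridge; the summed-likelihood optimum of a whole dataset is then
  weakly identified and the spatially-coupled estimate can sit ~10% from
  truth at any noise level (per-voxel NLLS shows a comparable bias of the
  opposite sign there). This is a property of the estimation problem, not
  of the optimiser.
* The diagonal posterior cannot represent the CBF–ATT ridge covariance, so
  posterior SDs are conditional rather than marginal in flat-ridge regimes.
* The noise model is Gaussian; Rician noise is out of scope.
* The reversion schedule's epoch count depends on image size; the defaults
  are tuned to nothing beyond the published procedure (patience 50,
  L: 2→7, 5 reversions).
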