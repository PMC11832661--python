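"""Voxelwise fitters for multi-PLD ASL: SSVB, NLLS and weighted delay.

All three are scikit-learn style estimators: the acquisition schedule,
tissue constants and tuning parameters are constructor arguments, ``fit``
takes the (voxels x timepoints) difference-signal matrix (plus the voxel
grid, where the fitter uses spatial structure), and results live in
trailing-underscore attributes (``cbf_``, ``att_``, ...).  The module-level
``fit_ssvb`` / ``fit_nlls`` / ``fit_wd`` functions are thin wrappers taking
an :class:`~ssvb.simulate.ASLDataset`.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator

from .kinetics import (
    AcquisitionSchedule,
    KineticParams,
    TissueConstants,
    buxton_signal_grad,
    signal_vector,
)
from .spatial import VoxelGrid, build_laplacian
from .variational import (
    RMSProp,
    VariationalState,
    _buxton_model_grad,
    _data_stats,
    _default_noise_prior_mean,
    _free_energy_core,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FitResult",
    "SSVBFitter",
    "NLLSFitter",
    "WeightedDelayFitter",
    "WDCalibration",
    "build_wd_calibration",
    "fit_ssvb",
    "fit_nlls",
    "fit_wd",
]


@dataclass
class FitResult:
    """Parameter maps and run metadata from one voxelwise fit."""

    cbf_map: np.ndarray
    att_map: np.ndarray
    cbf_sd_map: np.ndarray
    att_sd_map: np.ndarray
    noise_var_map: np.ndarray
    cost_trace: list
    fitter_name: str
    epochs_run: int = 0
    reversions: int = 0
    n_failed: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = len(self.cbf_map)
        for name in ("att_map", "cbf_sd_map", "att_sd_map", "noise_var_map"):
            if len(getattr(self, name)) != v:
                raise ValueError(f"{name} length mismatch")
        if not self.cost_trace:
            raise ValueError("cost_trace must be non-empty")


def _linear_cbf_solve(ysum, sumsq_repeats, template):
    """Per-voxel amplitude of the signal template by least squares.

    ``ysum`` is (v, n_pld) repeat sums, ``sumsq_repeats`` the repeat counts
    and ``template`` the per-PLD unit-CBF prediction; the model is linear in
    the amplitude at fixed ATT.
    """
    denom = float(np.sum(sumsq_repeats * template**2))
    if denom <= 0:
        return np.zeros(ysum.shape[0])
    return ysum @ template / denom


class SSVBFitter(BaseEstimator):
    """Stochastic variational-Bayes fitter with graph-Laplacian priors.

    Maximises an L-sample Monte-Carlo estimate of the free energy over a
    diagonal-Gaussian posterior on (CBF, ATT) per voxel, a per-voxel
    log-variance noise point estimate, and one log spatial precision per
    map, using RMSProp.  After ``patience`` consecutive epochs without
    improving the best cost the state reverts to the best snapshot and the
    sample size L grows by 1; the run terminates after ``max_reversions``
    such reversions (or at ``max_epochs``).

    Parameters
    ----------
    schedule : AcquisitionSchedule
    constants : TissueConstants, optional
    learning_rate : float
        RMSProp learning rate (default 0.1).
    initial_sample_size : int
        Starting Monte-Carlo sample size L (default 2).
    patience : int
        Epochs without a new best cost before a reversion (default 50).
    max_reversions : int
        Reversions before termination (default 5).
    max_epochs : int
        Hard safety cap on epochs (default 5000).
    rng_seed : int
        Seed for all stochasticity; equal seeds give bit-identical runs
        on one thread.
    init_att, init_log_sd_cbf, init_log_sd_att, init_log_alpha :
        Initialisation knobs; defaults are scale-appropriate for the
        simulation unit convention.

    Attributes
    ----------
    cbf_, att_ : (v,) posterior mean maps
    cbf_sd_, att_sd_ : (v,) posterior SD maps
    noise_var_ : (v,) noise variance point estimates
    result_ : FitResult with the cost trace and run metadata
    """

    def __init__(
        self,
        schedule: AcquisitionSchedule,
        constants: TissueConstants | None = None,
        learning_rate: float = 0.1,
        initial_sample_size: int = 2,
        patience: int = 50,
        max_reversions: int = 5,
        max_epochs: int = 5000,
        rng_seed: int = 0,
        init_att: float = 1.3,
        init_att_candidates: tuple[float, ...] | None = None,
        init_log_sd_cbf: float = math.log(10.0),
        init_log_sd_att: float = math.log(0.5),
        init_log_alpha: float = math.log(1e-2),
        init_cbf_prior_sd: float = 60.0,
        noise_prior_log_sd: float = 4.0,
    ):
        self.schedule = schedule
        self.constants = constants
        self.learning_rate = learning_rate
        self.initial_sample_size = initial_sample_size
        self.patience = patience
        self.max_reversions = max_reversions
        self.max_epochs = max_epochs
        self.rng_seed = rng_seed
        self.init_att = init_att
        self.init_att_candidates = init_att_candidates
        self.init_log_sd_cbf = init_log_sd_cbf
        self.init_log_sd_att = init_log_sd_att
        self.init_log_alpha = init_log_alpha
        self.init_cbf_prior_sd = init_cbf_prior_sd
        self.noise_prior_log_sd = noise_prior_log_sd

    # -- state <-> flat dict plumbing ------------------------------------
    @staticmethod
    def _to_params(state: VariationalState) -> dict:
        return {
            "mean_cbf": state.mean_cbf,
            "mean_att": state.mean_att,
            "log_sd_cbf": state.log_sd_cbf,
            "log_sd_att": state.log_sd_att,
            "log_noise_var": state.log_noise_var,
            "log_alpha_cbf": state.log_alpha_cbf,
            "log_alpha_att": state.log_alpha_att,
        }

    @staticmethod
    def _from_params(params: dict) -> VariationalState:
        return VariationalState(
            np.asarray(params["mean_cbf"], dtype=float),
            np.asarray(params["mean_att"], dtype=float),
            np.asarray(params["log_sd_cbf"], dtype=float),
            np.asarray(params["log_sd_att"], dtype=float),
            np.asarray(params["log_noise_var"], dtype=float),
            float(params["log_alpha_cbf"]),
            float(params["log_alpha_att"]),
        )

    def _initial_state(self, stats) -> VariationalState:
        constants = self.constants or TissueConstants()
        v = stats.ysum.shape[0]
        data_var = stats.sumsq / stats.n_total - (
            (stats.ysum / stats.repeats * stats.ysum).sum(axis=1)
            / stats.n_total
        )
        # data_var is the within-voxel variance about the per-PLD means,
        # a noise estimate that is free of the kinetic-curve shape
        # data-driven start: per voxel, solve the CBF amplitude at each
        # candidate ATT template and keep the best-SSD combination.  The
        # amplitude is ridge-shrunk with a zero-mean Gaussian prior of
        # physiological scale so that templates the schedule barely samples
        # (late ATT, few live timepoints) cannot win the selection by
        # fitting noise with huge amplitudes.
        # candidates beyond max(t) - tau leave every sampled timepoint on
        # the inflow ramp, where amplitude and delay are degenerate; do not
        # start the optimiser there
        att_cap = float(self.schedule.timepoints.max()
                        - self.schedule.label_duration)
        if self.init_att_candidates is not None:
            candidates = [a for a in self.init_att_candidates if a <= att_cap]
            if not candidates:
                candidates = [min(self.init_att, att_cap)]
        else:
            # ~0.4 s spacing over the plausible ATT range (0.2 s up to the
            # schedule's support cap)
            lo = min(0.2, att_cap)
            n = max(int(round((att_cap - lo) / 0.4)) + 1, 2)
            candidates = list(np.linspace(lo, att_cap, n))
        ridge = data_var / self.init_cbf_prior_sd**2
        best_ssd = np.full(v, np.inf)
        cbf0 = np.zeros(v)
        att0 = np.full(v, self.init_att)
        for a in candidates:
            template = buxton_signal_grad(
                self.schedule.timepoints, 1.0, a, constants,
                self.schedule.label_duration,
            )[0]
            energy = float(np.sum(stats.repeats * template**2))
            num = stats.ysum @ template
            amp_sel = num / (energy + ridge)
            ssd = stats.sumsq - 2.0 * amp_sel * num + amp_sel**2 * energy
            take = ssd < best_ssd
            best_ssd[take] = ssd[take]
            # winner amplitude: plain least squares at the selected ATT
            cbf0[take] = (num / energy)[take] if energy > 0 else 0.0
            att0[take] = a
        return VariationalState(
            mean_cbf=cbf0,
            mean_att=att0,
            log_sd_cbf=np.full(v, self.init_log_sd_cbf),
            log_sd_att=np.full(v, self.init_log_sd_att),
            log_noise_var=np.log(np.maximum(data_var, 1e-6)),
            log_alpha_cbf=self.init_log_alpha,
            log_alpha_att=self.init_log_alpha,
        )

    def fit(self, X, grid: VoxelGrid | None = None):
        """Fit the posterior to a (v, N) signal matrix.

        ``grid`` supplies the voxel adjacency for the spatial priors; with
        ``grid=None`` the voxels are treated as spatially unconnected (the
        priors reduce to their normalisation terms).
        """
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be (voxels, timepoints)")
        constants = self.constants or TissueConstants()
        stats = _data_stats(X, self.schedule)
        v = X.shape[0]
        if grid is not None:
            if grid.n_voxels != v:
                raise ValueError(
                    f"grid has {grid.n_voxels} masked voxels, X has {v} rows"
                )
            lap_penalty = (-build_laplacian(grid)).tocsr().astype(float)
        else:
            from scipy import sparse
            lap_penalty = sparse.csr_matrix((v, v))

        rng = np.random.default_rng(self.rng_seed)
        model = _buxton_model_grad(self.schedule, constants)
        noise_prior_mean = np.log(np.maximum(np.var(X, axis=1), 1e-12))
        noise_prior_var = self.noise_prior_log_sd**2

        state = self._initial_state(stats)
        opt = RMSProp(self.learning_rate)
        L = int(self.initial_sample_size)
        best_cost = np.inf
        best_state = state.copy()
        best_epoch = 0
        no_improve = 0
        reversions = 0
        cost_trace: list[float] = []

        epoch = 0
        for epoch in range(1, self.max_epochs + 1):
            # antithetic pairs (eps, -eps): unbiased, and the variance
            # reduction lets the best-cost ratchet register small true
            # improvements that raw MC noise would hide
            half = (L + 1) // 2
            eps_f = rng.standard_normal((half, v))
            eps_a = rng.standard_normal((half, v))
            eps_f = np.concatenate([eps_f, -eps_f])[:L]
            eps_a = np.concatenate([eps_a, -eps_a])[:L]
            F, grads = _free_energy_core(
                state, stats, eps_f, eps_a, model, lap_penalty,
                noise_prior_mean, noise_prior_var,
            )
            cost = -F
            if not np.isfinite(cost):
                raise FloatingPointError(self._diagnose(state, grads, epoch))
            cost_trace.append(cost)

            if cost < best_cost:
                best_cost = cost
                best_state = state.copy()
                best_epoch = epoch
                no_improve = 0
            else:
                no_improve += 1

            if no_improve >= self.patience:
                reversions += 1
                logger.info(
                    "reversion %d at epoch %d (best cost %.4f, L -> %d)",
                    reversions, epoch, best_cost, L + 1,
                )
                if reversions >= self.max_reversions:
                    break
                state = best_state.copy()
                L += 1
                no_improve = 0
                opt.reset()
                continue

            params = opt.step(
                self._to_params(state),
                {k: -np.asarray(g) for k, g in grads.items()},
            )
            state = self._from_params(params)

        self.state_ = best_state
        self.cbf_ = best_state.mean_cbf
        self.att_ = best_state.mean_att
        self.cbf_sd_ = np.exp(best_state.log_sd_cbf)
        self.att_sd_ = np.exp(best_state.log_sd_att)
        self.noise_var_ = np.exp(best_state.log_noise_var)
        self.result_ = FitResult(
            cbf_map=self.cbf_,
            att_map=self.att_,
            cbf_sd_map=self.cbf_sd_,
            att_sd_map=self.att_sd_,
            noise_var_map=self.noise_var_,
            cost_trace=cost_trace,
            fitter_name="ssvb",
            epochs_run=epoch,
            reversions=reversions,
            metadata={
                "best_cost": float(best_cost),
                "best_epoch": int(best_epoch),
                "final_sample_size": int(L),
                "rng_seed": int(self.rng_seed),
                "learning_rate": self.learning_rate,
                "rmsprop_decay": 0.9,
                "rmsprop_epsilon": 1e-8,
                "log_alpha_cbf": float(best_state.log_alpha_cbf),
                "log_alpha_att": float(best_state.log_alpha_att),
            },
        )
        return self

    @staticmethod
    def _diagnose(state: VariationalState, grads: dict, epoch: int) -> str:
        for name, arr in SSVBFitter._to_params(state).items():
            arr = np.atleast_1d(np.asarray(arr, dtype=float))
            bad = np.flatnonzero(~np.isfinite(arr))
            if bad.size:
                return (f"non-finite cost at epoch {epoch}: state field "
                        f"{name!r} is non-finite at voxel {bad[0]}")
        for name, arr in grads.items():
            arr = np.atleast_1d(np.asarray(arr, dtype=float))
            bad = np.flatnonzero(~np.isfinite(arr))
            if bad.size:
                return (f"non-finite cost at epoch {epoch}: gradient of "
                        f"{name!r} is non-finite at voxel {bad[0]}")
        return f"non-finite cost at epoch {epoch}"


class NLLSFitter(BaseEstimator):
    """Unconstrained voxelwise non-linear least squares (Levenberg-Marquardt).

    Minimises the SSD between the data and the kinetic model over
    (cbf, att) independently per voxel with an analytic Jacobian and no
    parameter constraints.  The landscape is multimodal at low SNR, so a
    small multi-start over ATT is used with best-SSD selection.  SD maps
    come from the linearised covariance at the optimum; voxels that fail to
    converge from every start are recorded as NaN.
    """

    def __init__(
        self,
        schedule: AcquisitionSchedule,
        constants: TissueConstants | None = None,
        att_starts: tuple[float, ...] = (0.7, 1.3, 2.0, 2.7),
    ):
        self.schedule = schedule
        self.constants = constants
        self.att_starts = att_starts

    def fit(self, X, grid=None):
        X = np.asarray(X, dtype=float)
        constants = self.constants or TissueConstants()
        stats = _data_stats(X, self.schedule)
        tbar = self.schedule.timepoints
        tau = self.schedule.label_duration
        R = stats.repeats.astype(float)
        sqrt_r = np.sqrt(R)
        v, n_total = X.shape[0], stats.n_total

        templates = {
            a: buxton_signal_grad(tbar, 1.0, a, constants, tau)[0]
            for a in self.att_starts
        }

        cbf = np.full(v, np.nan)
        att = np.full(v, np.nan)
        cbf_sd = np.full(v, np.nan)
        att_sd = np.full(v, np.nan)
        n_failed = 0

        for i in range(v):
            ybar = stats.ysum[i] / R
            best = None
            for a0 in self.att_starts:
                tmpl = templates[a0]
                denom = float(np.sum(R * tmpl**2))
                c0 = float(stats.ysum[i] @ tmpl / denom) if denom > 0 else 0.0

                def resid(p):
                    m = buxton_signal_grad(tbar, p[0], p[1], constants, tau)[0]
                    return sqrt_r * (ybar - m)

                def jac(p):
                    _, dc, da = buxton_signal_grad(
                        tbar, p[0], p[1], constants, tau)
                    return np.column_stack((-sqrt_r * dc, -sqrt_r * da))

                try:
                    sol = optimize.least_squares(
                        resid, x0=[c0, a0], jac=jac, method="lm",
                        max_nfev=200,
                    )
                except Exception:
                    continue
                if not np.all(np.isfinite(sol.x)):
                    continue
                if best is None or sol.cost < best.cost:
                    best = sol
            if best is None:
                n_failed += 1
                continue
            cbf[i], att[i] = best.x
            # linearised covariance; full-N dof including repeat scatter
            ssd_full = float(stats.sumsq[i]
                             - np.sum(R * ybar**2)
                             + 2.0 * best.cost)
            dof = max(n_total - 2, 1)
            J = jac(best.x)
            try:
                cov = np.linalg.inv(J.T @ J) * ssd_full / dof
                cbf_sd[i] = math.sqrt(max(cov[0, 0], 0.0))
                att_sd[i] = math.sqrt(max(cov[1, 1], 0.0))
            except np.linalg.LinAlgError:
                pass

        if n_failed:
            warnings.warn(f"NLLS failed to converge at {n_failed} voxels")
        self.cbf_, self.att_ = cbf, att
        self.cbf_sd_, self.att_sd_ = cbf_sd, att_sd
        resid_var = np.full(v, np.nan)
        ok = np.isfinite(cbf)
        self.noise_var_ = resid_var
        self.result_ = FitResult(
            cbf_map=cbf, att_map=att, cbf_sd_map=cbf_sd, att_sd_map=att_sd,
            noise_var_map=resid_var, cost_trace=[float(np.nan)],
            fitter_name="nlls", n_failed=n_failed,
            metadata={"att_starts": list(self.att_starts),
                      "n_converged": int(ok.sum())},
        )
        return self


@dataclass(frozen=True)
class WDCalibration:
    """Monotone map from true ATT to the noiseless signal first moment."""

    att_grid: np.ndarray
    wd_values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "att_grid",
                           np.asarray(self.att_grid, dtype=float))
        object.__setattr__(self, "wd_values",
                           np.asarray(self.wd_values, dtype=float))
        if self.att_grid.size < 2:
            raise ValueError("calibration needs at least two grid points")
        if np.any(np.diff(self.att_grid) <= 0):
            raise ValueError("att_grid must be strictly increasing")
        if np.any(np.diff(self.wd_values) <= 0):
            raise ValueError(
                "weighted delay is not monotone increasing over the ATT "
                "grid; schedule unsuitable for WD estimation"
            )

    def invert(self, wd: np.ndarray):
        """Map observed first moments back to ATT; clip outside the range."""
        wd = np.asarray(wd, dtype=float)
        att = np.interp(wd, self.wd_values, self.att_grid)
        clipped = (wd < self.wd_values[0]) | (wd > self.wd_values[-1])
        return att, clipped


def _unique_timepoints(schedule: AcquisitionSchedule):
    """Distinct model times with their total repeat counts (merges duplicate
    PLD entries such as the triplicated 0.775 s of the grey-paper schedule)."""
    tbar = schedule.timepoints
    repeats = np.asarray(schedule.repeats, dtype=float)
    uniq, inv = np.unique(np.round(tbar, 9), return_inverse=True)
    counts = np.zeros(uniq.size)
    np.add.at(counts, inv, repeats)
    return uniq, counts, inv


def build_wd_calibration(
    schedule: AcquisitionSchedule,
    constants: TissueConstants | None = None,
    att_grid: np.ndarray | None = None,
) -> WDCalibration:
    """Tabulate the noiseless first-moment delay WD(att) for one schedule.

    WD(att) = sum_i tbar_i * M_i / sum_i M_i over the schedule's distinct
    timepoints.  Grid points beyond the last timepoint, where the noiseless
    signal vanishes and the moment is undefined, are trimmed before the
    monotonicity check.
    """
    constants = constants or TissueConstants()
    if att_grid is None:
        att_grid = np.arange(0.2, 4.0 + 1e-9, 0.01)
    att_grid = np.asarray(att_grid, dtype=float)
    uniq_t, _, _ = _unique_timepoints(schedule)
    M = buxton_signal_grad(
        uniq_t, 60.0, att_grid[:, None], constants, schedule.label_duration
    )[0]
    denom = M.sum(axis=1)
    valid = denom > 1e-12
    if valid.sum() < 2:
        raise ValueError("schedule yields no usable WD calibration range")
    att_grid = att_grid[valid]
    wd = (M[valid] * uniq_t).sum(axis=1) / denom[valid]
    # past the last usable delay the moment saturates towards the final
    # timepoint; keep the strictly increasing prefix of the curve
    diffs = np.diff(wd)
    bad = np.flatnonzero(diffs <= 0)
    if bad.size:
        att_grid = att_grid[: bad[0] + 1]
        wd = wd[: bad[0] + 1]
    return WDCalibration(att_grid=att_grid, wd_values=wd)


class WeightedDelayFitter(BaseEstimator):
    """Signal-weighted-delay ATT estimation plus a fixed-ATT CBF solve.

    Per voxel: average the repeats at each distinct PLD, take the first
    temporal moment of the averaged signal, invert it through the
    schedule-specific noiseless calibration curve to obtain ATT, then solve
    for CBF by linear least squares at that fixed ATT (one refresh of the
    T1app coupling).  The ATT estimate is invariant to global scaling of
    the data.
    """

    def __init__(
        self,
        schedule: AcquisitionSchedule,
        constants: TissueConstants | None = None,
        calibration: WDCalibration | None = None,
    ):
        self.schedule = schedule
        self.constants = constants
        self.calibration = calibration

    def fit(self, X, grid=None):
        X = np.asarray(X, dtype=float)
        constants = self.constants or TissueConstants()
        calibration = self.calibration or build_wd_calibration(
            self.schedule, constants)
        stats = _data_stats(X, self.schedule)
        uniq_t, counts, inv = _unique_timepoints(self.schedule)
        tau = self.schedule.label_duration
        v = X.shape[0]

        # repeat-averaged signal at each distinct timepoint
        ysum_u = np.zeros((v, uniq_t.size))
        np.add.at(ysum_u.T, inv, stats.ysum.T)
        ybar = ysum_u / counts

        denom = ybar.sum(axis=1)
        att = np.full(v, np.nan)
        n_clipped = 0
        ok = denom > 0
        if ok.any():
            wd = (ybar[ok] * uniq_t).sum(axis=1) / denom[ok]
            att_ok, clipped = calibration.invert(wd)
            att[ok] = att_ok
            n_clipped = int(clipped.sum())
            if n_clipped:
                warnings.warn(
                    f"WD moment outside calibration range at {n_clipped} "
                    "voxels; ATT clipped to the range end")

        cbf = np.full(v, np.nan)
        fin = np.isfinite(att)
        if fin.any():
            ref = 60.0
            cbf_est = np.full(fin.sum(), ref)
            atts = att[fin]
            for _ in range(2):  # second pass refreshes the T1app coupling
                tmpl = buxton_signal_grad(
                    uniq_t, cbf_est[:, None], atts[:, None], constants, tau
                )[0]
                num = np.sum(counts * ybar[fin] * tmpl, axis=1)
                den = np.sum(counts * tmpl**2, axis=1)
                scale = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
                cbf_est = cbf_est * scale
            cbf[fin] = cbf_est

        nan_count = int(np.sum(~fin))
        self.cbf_, self.att_ = cbf, att
        self.cbf_sd_ = np.full(v, np.nan)
        self.att_sd_ = np.full(v, np.nan)
        self.noise_var_ = np.full(v, np.nan)
        self.result_ = FitResult(
            cbf_map=cbf, att_map=att,
            cbf_sd_map=self.cbf_sd_, att_sd_map=self.att_sd_,
            noise_var_map=self.noise_var_, cost_trace=[float(np.nan)],
            fitter_name="wd", n_failed=nan_count,
            metadata={"n_clipped": n_clipped,
                      "calibration_range": [float(calibration.att_grid[0]),
                                            float(calibration.att_grid[-1])]},
        )
        return self


# ---------------------------------------------------------------------------
# thin functional wrappers over the estimators


def fit_ssvb(dataset, schedule=None, constants=None, **config) -> FitResult:
    """Fit SSVB to an ASLDataset; keyword args go to :class:`SSVBFitter`."""
    schedule = schedule or dataset.schedule
    est = SSVBFitter(schedule, constants, **config)
    est.fit(dataset.data, grid=dataset.grid)
    return est.result_


def fit_nlls(dataset, schedule=None, constants=None, **config) -> FitResult:
    """Unconstrained voxelwise NLLS on an ASLDataset."""
    schedule = schedule or dataset.schedule
    est = NLLSFitter(schedule, constants, **config)
    est.fit(dataset.data)
    return est.result_


def fit_wd(dataset, schedule=None, constants=None,
           calibration: WDCalibration | None = None) -> FitResult:
    """Weighted-delay ATT + fixed-ATT CBF solve on an ASLDataset."""
    schedule = schedule or dataset.schedule
    est = WeightedDelayFitter(schedule, constants, calibration)
    est.fit(dataset.data)
    return est.result_
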