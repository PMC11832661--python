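"""Monte-Carlo free energy for the per-voxel diagonal-Gaussian posterior.

The approximate posterior q(theta) is an independent Gaussian per voxel over
(CBF, ATT), parametrised by means and log-SDs; the per-voxel noise variance
is a log-parametrised point estimate and the two spatial precisions are
log-parametrised scalars.  The free energy (ELBO)

    F ~= (1/L) sum_l [ log p(y | theta*_l) - log( q(theta*_l) / p(theta*_l) ) ]

is estimated by drawing L reparametrised samples theta* = mu + exp(log_sd)*eps
per voxel; because the spatial prior couples voxels, each sample is a full
map.  Gradients with respect to every variational parameter are available in
closed form through the reparametrisation, so the objective can be ascended
with RMSProp without an autodiff framework.

Constant conventions: the Gaussian likelihood omits its 2*pi constant (it is
a fixed offset); the entropy (-log q) and all Gaussian prior terms keep their
full constants so that their difference is an exact KL sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import sparse

from .kinetics import AcquisitionSchedule, TissueConstants, buxton_signal_grad
from .spatial import normal_logpdf

__all__ = [
    "VariationalState",
    "log_likelihood",
    "sample_posterior",
    "free_energy_estimate",
    "RMSProp",
]

LOG_2PI = math.log(2.0 * math.pi)


@dataclass
class VariationalState:
    """All optimised quantities of one SSVB run.

    Per-voxel: posterior means and log-SDs for CBF and ATT, and the
    log noise variance (point estimate).  Global: one log spatial
    precision per regularised map.
    """

    mean_cbf: np.ndarray
    mean_att: np.ndarray
    log_sd_cbf: np.ndarray
    log_sd_att: np.ndarray
    log_noise_var: np.ndarray
    log_alpha_cbf: float
    log_alpha_att: float

    def __post_init__(self) -> None:
        v = len(self.mean_cbf)
        for name in ("mean_cbf", "mean_att", "log_sd_cbf", "log_sd_att",
                     "log_noise_var"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (v,):
                raise ValueError(f"{name} must have shape ({v},)")
            setattr(self, name, arr)

    @property
    def n_voxels(self) -> int:
        return len(self.mean_cbf)

    def copy(self) -> "VariationalState":
        return VariationalState(
            self.mean_cbf.copy(), self.mean_att.copy(),
            self.log_sd_cbf.copy(), self.log_sd_att.copy(),
            self.log_noise_var.copy(),
            float(self.log_alpha_cbf), float(self.log_alpha_att),
        )


def log_likelihood(y: np.ndarray, prediction: np.ndarray,
                   noise_precision: float) -> float:
    """Gaussian log-likelihood (N/2) log(phi) - (phi/2) * SSD.

    The 2*pi constant is omitted; it cancels in optimisation.
    """
    y = np.asarray(y, dtype=float)
    prediction = np.asarray(prediction, dtype=float)
    if y.shape != prediction.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {prediction.shape}")
    if noise_precision <= 0:
        raise ValueError("noise_precision must be positive")
    ssd = float(np.sum((y - prediction) ** 2))
    return 0.5 * y.size * math.log(noise_precision) - 0.5 * noise_precision * ssd


def sample_posterior(state: VariationalState, L: int,
                     rng: np.random.Generator):
    """Draw L reparametrised posterior samples of (cbf, att) per voxel.

    Returns two (L, v) arrays ``mu + exp(log_sd) * eps`` with eps standard
    normal, independent across samples and voxels.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    v = state.n_voxels
    eps_f = rng.standard_normal((L, v))
    eps_a = rng.standard_normal((L, v))
    cbf = state.mean_cbf + np.exp(state.log_sd_cbf) * eps_f
    att = state.mean_att + np.exp(state.log_sd_att) * eps_a
    return cbf, att


@dataclass(frozen=True)
class _DataStats:
    """Sufficient statistics of (v, N) data for the Gaussian likelihood.

    Repeats of one PLD share a model prediction M_i, so the SSD reduces to
    sumsq - 2 sum_i M_i * ysum_i + sum_i R_i * M_i^2 with per-PLD repeat
    sums ysum; the model only needs evaluating once per distinct PLD entry.
    """

    ysum: np.ndarray   # (v, n_pld) sum of data over repeats of each PLD
    sumsq: np.ndarray  # (v,) sum of squared data
    repeats: np.ndarray  # (n_pld,)
    n_total: int


def _data_stats(data: np.ndarray, schedule: AcquisitionSchedule) -> _DataStats:
    data = np.asarray(data, dtype=float)
    repeats = np.asarray(schedule.repeats)
    if data.shape[1] != repeats.sum():
        raise ValueError(
            f"data has {data.shape[1]} timepoints, schedule expects "
            f"{int(repeats.sum())}"
        )
    edges = np.concatenate(([0], np.cumsum(repeats)))
    ysum = np.add.reduceat(data, edges[:-1], axis=1)
    return _DataStats(
        ysum=ysum,
        sumsq=np.sum(data**2, axis=1),
        repeats=repeats,
        n_total=int(repeats.sum()),
    )


def _free_energy_core(
    state: VariationalState,
    stats: _DataStats,
    eps_f: np.ndarray,
    eps_a: np.ndarray,
    model_grad: Callable,
    lap_penalty: sparse.spmatrix | None,
    noise_prior_mean: np.ndarray,
    noise_prior_var: float,
    cbf_prior: tuple[float, float] | None = None,
    att_prior: tuple[float, float] | None = None,
):
    """Free-energy estimate and its analytic gradients for given noise draws.

    ``model_grad(cbf, att)`` maps (L, v, 1)-shaped parameter samples to
    per-PLD predictions and their partials, shape (L, v, n_pld).
    ``lap_penalty`` is the positive-semidefinite -D; ``None`` disables the
    spatial terms (used by single-voxel diagnostics).  ``cbf_prior`` /
    ``att_prior`` are optional (mean, variance) Gaussian priors.
    Returns (F, grads) with grads keyed like the state fields.
    """
    v = state.n_voxels
    L = eps_f.shape[0]
    sf = np.exp(state.log_sd_cbf)
    sa = np.exp(state.log_sd_att)
    theta_f = state.mean_cbf + sf * eps_f  # (L, v)
    theta_a = state.mean_att + sa * eps_a

    M, dMf, dMa = model_grad(theta_f[..., None], theta_a[..., None])

    R = stats.repeats
    ssd = (
        stats.sumsq
        - 2.0 * np.einsum("lvn,vn->lv", M, stats.ysum)
        + np.einsum("lvn,n->lv", M**2, R)
    )
    # residual-weighted gradient of the log-likelihood w.r.t. the samples
    w = stats.ysum - R * M  # (L, v, n)
    phi = np.exp(-state.log_noise_var)  # (v,)
    loglik = 0.5 * stats.n_total * (-state.log_noise_var) - 0.5 * phi * ssd
    g_theta_f = phi * np.einsum("lvn,lvn->lv", w, dMf)
    g_theta_a = phi * np.einsum("lvn,lvn->lv", w, dMa)

    F_samples = loglik.sum(axis=1)  # (L,)

    # spatial priors (couple voxels within each sample)
    g_alpha_f = g_alpha_a = 0.0
    if lap_penalty is not None:
        alpha_f = math.exp(state.log_alpha_cbf)
        alpha_a = math.exp(state.log_alpha_att)
        Lt_f = (lap_penalty @ theta_f.T).T  # (L, v)
        Lt_a = (lap_penalty @ theta_a.T).T
        Qf = np.einsum("lv,lv->l", theta_f, Lt_f)
        Qa = np.einsum("lv,lv->l", theta_a, Lt_a)
        F_samples += 0.5 * v * state.log_alpha_cbf - 0.5 * alpha_f * Qf
        F_samples += 0.5 * v * state.log_alpha_att - 0.5 * alpha_a * Qa
        g_theta_f = g_theta_f - alpha_f * Lt_f
        g_theta_a = g_theta_a - alpha_a * Lt_a
        g_alpha_f = 0.5 * v - 0.5 * alpha_f * float(Qf.mean())
        g_alpha_a = 0.5 * v - 0.5 * alpha_a * float(Qa.mean())

    # optional distributional priors (full Gaussian constants kept)
    for prior, theta, which in ((cbf_prior, theta_f, "f"),
                                (att_prior, theta_a, "a")):
        if prior is None:
            continue
        m0, v0 = prior
        F_samples += normal_logpdf(theta, m0, v0).sum(axis=1)
        g = -(theta - m0) / v0
        if which == "f":
            g_theta_f = g_theta_f + g
        else:
            g_theta_a = g_theta_a + g

    # -log q of each sample (exact through the reparametrisation: the
    # Mahalanobis part reduces to eps^2/2, constant in mu and log_sd)
    F_samples += (
        np.sum(state.log_sd_cbf + state.log_sd_att)
        + 0.5 * np.sum(eps_f**2 + eps_a**2, axis=1)
        + v * LOG_2PI
    )

    # point-estimated noise: broad Gaussian prior on the log variance
    noise_prior = float(
        np.sum(normal_logpdf(state.log_noise_var, noise_prior_mean,
                             noise_prior_var))
    )
    F = float(F_samples.mean()) + noise_prior

    grads = {
        "mean_cbf": g_theta_f.mean(axis=0),
        "mean_att": g_theta_a.mean(axis=0),
        "log_sd_cbf": (g_theta_f * eps_f).mean(axis=0) * sf + 1.0,
        "log_sd_att": (g_theta_a * eps_a).mean(axis=0) * sa + 1.0,
        "log_noise_var": (
            (-0.5 * stats.n_total + 0.5 * phi * ssd).mean(axis=0)
            - (state.log_noise_var - noise_prior_mean) / noise_prior_var
        ),
        "log_alpha_cbf": g_alpha_f,
        "log_alpha_att": g_alpha_a,
    }
    return F, grads


def _buxton_model_grad(schedule: AcquisitionSchedule,
                       constants: TissueConstants) -> Callable:
    tbar = schedule.timepoints
    tau = schedule.label_duration

    def model(cbf, att):
        return buxton_signal_grad(tbar, cbf, att, constants, tau)

    return model


def free_energy_estimate(
    state: VariationalState,
    dataset,
    schedule: AcquisitionSchedule,
    constants: TissueConstants,
    laplacian: sparse.spmatrix | None,
    L: int,
    rng: np.random.Generator,
    noise_prior_mean: np.ndarray | None = None,
    noise_prior_var: float = 16.0,
) -> float:
    """L-sample Monte-Carlo estimate of the free energy of ``state``.

    ``laplacian`` is the graph Laplacian D (or ``None`` for no spatial
    prior).  The default noise prior is centred on each voxel's observed
    log data variance with a broad SD of 4 in log space.
    """
    stats = _data_stats(dataset.data, schedule)
    if noise_prior_mean is None:
        noise_prior_mean = _default_noise_prior_mean(dataset.data)
    eps_f = rng.standard_normal((L, state.n_voxels))
    eps_a = rng.standard_normal((L, state.n_voxels))
    lap_penalty = None if laplacian is None else (-laplacian).tocsr()
    F, _ = _free_energy_core(
        state, stats, eps_f, eps_a,
        _buxton_model_grad(schedule, constants),
        lap_penalty, noise_prior_mean, noise_prior_var,
    )
    return F


def _default_noise_prior_mean(data: np.ndarray) -> np.ndarray:
    var = np.var(data, axis=1)
    return np.log(np.maximum(var, 1e-12))


class RMSProp:
    """Minimal RMSProp over a dict of named arrays/scalars."""

    def __init__(self, learning_rate: float = 0.1, decay: float = 0.9,
                 epsilon: float = 1e-8):
        self.learning_rate = learning_rate
        self.decay = decay
        self.epsilon = epsilon
        self._acc: dict[str, np.ndarray] = {}

    def reset(self) -> None:
        self._acc.clear()

    def step(self, params: dict, grads: dict) -> dict:
        """One update minimising the objective whose gradients are given."""
        out = {}
        for name, p in params.items():
            g = np.asarray(grads[name], dtype=float)
            acc = self._acc.get(name)
            if acc is None:
                acc = np.zeros_like(g)
            acc = self.decay * acc + (1.0 - self.decay) * g**2
            self._acc[name] = acc
            step = self.learning_rate * g / (np.sqrt(acc) + self.epsilon)
            out[name] = p - step
        return out
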