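"""Buxton single-compartment PCASL kinetic model.

The label-control difference signal :math:`\\Delta M(t)` produced by a
pseudo-continuous ASL experiment with label duration ``tau`` is modelled as a
three-branch piecewise function of time ``t`` since the start of labelling:
zero before the labelled bolus arrives (``t < att``), an inflow branch while
the bolus is arriving (``att <= t < att + tau``) and an exponential outflow
branch afterwards.  Both post-arrival branches carry the label-decay factor
``exp(-att / t1_blood)``, which makes the curve continuous at the end of the
bolus.

CBF enters the amplitude directly in the simulation's arbitrary units
(``m0a = 1``) and enters the apparent relaxation rate as ``cbf / 6000``
(the ml/100g/min -> 1/s conversion) divided by the partition coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "TissueConstants",
    "AcquisitionSchedule",
    "KineticParams",
    "t1_apparent",
    "buxton_signal",
    "buxton_signal_grad",
    "signal_vector",
    "get_schedule",
    "SCHEDULE_PRESETS",
]

#: ml/100g/min -> 1/s conversion used in the apparent-T1 outflow term.
CBF_RATE_CONVERSION = 6000.0

# exp() argument clip for branches that are masked out anyway; keeps
# intermediate arrays finite when samplers hand in extreme parameter values.
_EXP_CLIP = 500.0


@dataclass(frozen=True)
class TissueConstants:
    """Fixed tissue/blood parameters of the kinetic model.

    Defaults are consensus values for 3 T grey matter: T1 of tissue water
    1.3 s, T1 of arterial blood 1.65 s, blood-brain partition coefficient
    0.9, and unit equilibrium arterial magnetisation (inversion efficiency
    is absorbed into ``m0a``).
    """

    t1_tissue: float = 1.3
    t1_blood: float = 1.65
    partition_coeff: float = 0.9
    m0a: float = 1.0

    def __post_init__(self) -> None:
        for name in ("t1_tissue", "t1_blood", "partition_coeff", "m0a"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class KineticParams:
    """Physiological parameters of one voxel: perfusion and transit time."""

    cbf: float
    att: float


@dataclass(frozen=True)
class AcquisitionSchedule:
    """Label duration, post-label delays and repeats of one ASL experiment.

    The model timepoint of PLD ``i`` is ``t_i = label_duration + plds[i]``,
    time since the start of label creation.  Repeats are noise-independent
    replicates at identical timepoints; the flattened timepoint vector is
    PLD-major, repeat-minor.
    """

    label_duration: float
    plds: tuple[float, ...]
    repeats: tuple[int, ...]
    name: str = "custom"

    def __post_init__(self) -> None:
        object.__setattr__(self, "plds", tuple(float(p) for p in self.plds))
        object.__setattr__(self, "repeats", tuple(int(r) for r in self.repeats))
        if self.label_duration <= 0:
            raise ValueError("label_duration must be positive")
        if len(self.plds) != len(self.repeats):
            raise ValueError("plds and repeats must have equal length")
        if any(p < 0 for p in self.plds):
            raise ValueError("plds must be non-negative")
        if any(r < 1 for r in self.repeats):
            raise ValueError("repeats must be positive integers")
        if self.n_timepoints <= 0:
            raise ValueError("schedule defines no timepoints")

    @property
    def timepoints(self) -> np.ndarray:
        """Per-PLD model times ``label_duration + pld`` (one per PLD entry)."""
        return self.label_duration + np.asarray(self.plds, dtype=float)

    @property
    def n_timepoints(self) -> int:
        """Total number of acquired volumes N = sum of repeats."""
        return int(sum(self.repeats))

    def expand(self, per_pld: np.ndarray) -> np.ndarray:
        """Expand per-PLD values to the flat length-N acquisition ordering."""
        per_pld = np.asarray(per_pld)
        return np.repeat(per_pld, np.asarray(self.repeats), axis=-1)


SCHEDULE_PRESETS: dict[str, AcquisitionSchedule] = {
    # Optimal sampling scheme for ATT in 0.5-2.5 s.
    "grey_paper": AcquisitionSchedule(
        label_duration=2.05,
        plds=(0.200, 0.775, 0.775, 0.775, 1.800, 2.275, 2.475, 2.675, 2.800),
        repeats=(4,) * 9,
        name="grey_paper",
    ),
    # HCP Lifespan ASL sampling scheme.
    "hcp_asl": AcquisitionSchedule(
        label_duration=1.5,
        plds=(0.2, 0.7, 1.2, 1.7, 2.2),
        repeats=(6, 6, 6, 10, 15),
        name="hcp_asl",
    ),
}


def get_schedule(name: str) -> AcquisitionSchedule:
    """Return a shipped schedule preset by name."""
    try:
        return SCHEDULE_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown schedule {name!r}; available: {sorted(SCHEDULE_PRESETS)}"
        ) from None


def _apparent_rate(cbf, constants: TissueConstants):
    """1/T1app = 1/T1 + (cbf/6000)/lambda, vectorised."""
    return 1.0 / constants.t1_tissue + (
        np.asarray(cbf, dtype=float) / CBF_RATE_CONVERSION
    ) / constants.partition_coeff


def t1_apparent(params: KineticParams, constants: TissueConstants) -> float:
    """Apparent tissue T1 including the perfusion outflow term.

    Raises
    ------
    ValueError
        If a pathological negative ``cbf`` makes the apparent rate
        non-positive.
    """
    rate = float(_apparent_rate(params.cbf, constants))
    if rate <= 0:
        raise ValueError(
            f"apparent relaxation rate {rate:.4g} <= 0 for cbf={params.cbf}"
        )
    return 1.0 / rate


def _cexp(x):
    return np.exp(np.clip(x, -_EXP_CLIP, _EXP_CLIP))


def _signal_core(t, cbf, att, constants: TissueConstants, tau: float,
                 with_grad: bool):
    """Vectorised piecewise signal (and optionally d/dcbf, d/datt).

    All inputs broadcast.  The apparent rate is floored at a tiny positive
    value so that extreme negative perfusion samples from an unconstrained
    optimiser yield finite (if meaningless) values rather than NaNs.
    """
    t = np.asarray(t, dtype=float)
    cbf = np.asarray(cbf, dtype=float)
    att = np.asarray(att, dtype=float)
    t, cbf, att = np.broadcast_arrays(t, cbf, att)

    k = np.maximum(_apparent_rate(cbf, constants), 1e-9)  # 1/T1app
    t1app = 1.0 / k
    dk_dcbf = 1.0 / (CBF_RATE_CONVERSION * constants.partition_coeff)

    u = t - att  # time since bolus arrival
    decay = _cexp(-att / constants.t1_blood)  # label T1b decay
    amp = 2.0 * constants.m0a * cbf * t1app * decay

    e_u = _cexp(-u * k)
    e_tau = _cexp(-np.full_like(u, tau) * k)
    e_out = _cexp(-(u - tau) * k)

    inflow = amp * (1.0 - e_u)
    outflow = amp * e_out * (1.0 - e_tau)

    pre = u < 0
    during = (~pre) & (u < tau)
    signal = np.where(pre, 0.0, np.where(during, inflow, outflow))

    if not with_grad:
        return signal

    b = 2.0 * constants.m0a * decay  # amplitude without cbf * t1app

    # d/datt: amplitude decay term plus the shift of the bolus window.
    d_att_in = -inflow / constants.t1_blood - b * cbf * e_u
    d_att_out = outflow * (k - 1.0 / constants.t1_blood)

    # d/dcbf: direct amplitude term plus the k(cbf) coupling.
    g_in = t1app * (1.0 - e_u)
    dg_in = -t1app**2 * (1.0 - e_u) + t1app * u * e_u
    d_cbf_in = b * (g_in + cbf * dk_dcbf * dg_in)

    g_out = t1app * e_out * (1.0 - e_tau)
    dg_out = e_out * (
        -t1app**2 * (1.0 - e_tau)
        - (u - tau) * t1app * (1.0 - e_tau)
        + t1app * tau * e_tau
    )
    d_cbf_out = b * (g_out + cbf * dk_dcbf * dg_out)

    d_att = np.where(pre, 0.0, np.where(during, d_att_in, d_att_out))
    d_cbf = np.where(pre, 0.0, np.where(during, d_cbf_in, d_cbf_out))
    return signal, d_cbf, d_att


def buxton_signal(t, params: KineticParams, constants: TissueConstants,
                  tau: float):
    """Evaluate the piecewise PCASL difference signal at time(s) ``t``.

    ``t`` is time since the start of labelling.  Scalar in, scalar out;
    array in, array out.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    out = _signal_core(t, params.cbf, params.att, constants, tau,
                       with_grad=False)
    return float(out) if np.ndim(t) == 0 else out


def buxton_signal_grad(t, cbf, att, constants: TissueConstants, tau: float):
    """Signal and its partial derivatives w.r.t. cbf and att (broadcasting).

    Returns ``(signal, d_signal/d_cbf, d_signal/d_att)``.  Used by the
    variational engine and the NLLS Jacobian.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    return _signal_core(t, cbf, att, constants, tau, with_grad=True)


def signal_vector(schedule: AcquisitionSchedule, params: KineticParams,
                  constants: TissueConstants) -> np.ndarray:
    """Noise-free model prediction for every acquired volume (length N).

    Entries for the repeats of one PLD are identical; ordering is PLD-major,
    repeat-minor.
    """
    per_pld = _signal_core(
        schedule.timepoints, params.cbf, params.att, constants,
        schedule.label_duration, with_grad=False,
    )
    return schedule.expand(per_pld)
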