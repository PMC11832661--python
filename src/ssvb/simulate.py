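"""Synthetic multi-PLD ASL datasets with known ground truth.

Each dataset is a fully-masked isotropic voxel grid (default 5x5x5) in which
every voxel shares the same true (CBF, ATT); the observed data are the
noise-free Buxton predictions plus iid zero-mean Gaussian noise on the
difference signal.  A full study suite crosses true ATT from 0.5 to 3.0 s in
0.25 s steps with noise SDs 10-40 in steps of 10 at constant CBF = 60 —
CBF is not varied because the PCASL signal is linear in it, so varying CBF
is equivalent to varying SNR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .kinetics import (
    AcquisitionSchedule,
    KineticParams,
    TissueConstants,
    get_schedule,
    signal_vector,
)
from .spatial import VoxelGrid

__all__ = ["ASLDataset", "SimulationConfig", "simulate_dataset", "simulate_suite"]


@dataclass
class ASLDataset:
    """Masked voxel grid with one signal vector per voxel.

    ``data`` has shape (v, N) where v is the number of masked voxels and N
    the schedule's total timepoint count.  For synthetic data the per-voxel
    ground truth and the noise SD are carried along.
    """

    grid: VoxelGrid
    data: np.ndarray
    schedule: AcquisitionSchedule
    true_cbf: np.ndarray | None = None
    true_att: np.ndarray | None = None
    noise_sd: float | None = None
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != (self.grid.n_voxels, self.schedule.n_timepoints):
            raise ValueError(
                f"data shape {self.data.shape} does not match "
                f"{self.grid.n_voxels} voxels x "
                f"{self.schedule.n_timepoints} timepoints"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")

    @property
    def n_voxels(self) -> int:
        return self.grid.n_voxels


@dataclass(frozen=True)
class SimulationConfig:
    """Factorial design of one simulation study."""

    schedule: AcquisitionSchedule | str = "grey_paper"
    grid_shape: tuple[int, int, int] = (5, 5, 5)
    true_cbf: float = 60.0
    true_att_values: tuple[float, ...] = tuple(np.arange(0.5, 3.01, 0.25))
    noise_sds: tuple[float, ...] = (10.0, 20.0, 30.0, 40.0)
    rng_seed: int = 0

    def resolved_schedule(self) -> AcquisitionSchedule:
        if isinstance(self.schedule, str):
            return get_schedule(self.schedule)
        return self.schedule


def simulate_dataset(
    schedule: AcquisitionSchedule,
    constants: TissueConstants,
    grid_shape: Sequence[int] = (5, 5, 5),
    true_cbf: float = 60.0,
    true_att: float = 1.5,
    noise_sd: float = 20.0,
    rng: np.random.Generator | int | None = None,
) -> ASLDataset:
    """Simulate one homogeneous-truth dataset.

    Every voxel shares (``true_cbf``, ``true_att``); noise is iid
    ``N(0, noise_sd^2)`` added directly to the difference signal of each
    acquired volume.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(rng)
    grid = VoxelGrid.full(tuple(grid_shape))
    v = grid.n_voxels
    clean = signal_vector(schedule, KineticParams(true_cbf, true_att), constants)
    data = np.tile(clean, (v, 1))
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=data.shape)
    return ASLDataset(
        grid=grid,
        data=data,
        schedule=schedule,
        true_cbf=np.full(v, float(true_cbf)),
        true_att=np.full(v, float(true_att)),
        noise_sd=float(noise_sd),
    )


def simulate_suite(
    config: SimulationConfig,
    constants: TissueConstants | None = None,
) -> Iterator[ASLDataset]:
    """Yield one dataset per (true ATT, noise SD) cell of the factorial.

    Child seeds are spawned deterministically from ``config.rng_seed`` so the
    cells are mutually independent and the whole suite is reproducible.
    """
    constants = constants or TissueConstants()
    schedule = config.resolved_schedule()
    seed_seq = np.random.SeedSequence(config.rng_seed)
    children = seed_seq.spawn(len(config.true_att_values) * len(config.noise_sds))
    i = 0
    for att in config.true_att_values:
        for sd in config.noise_sds:
            yield simulate_dataset(
                schedule,
                constants,
                grid_shape=config.grid_shape,
                true_cbf=config.true_cbf,
                true_att=att,
                noise_sd=sd,
                rng=np.random.default_rng(children[i]),
            )
            i += 1
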