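"""Bias scoring of fitters against simulation ground truth.

For each (fitter, schedule, true ATT, noise SD) cell the mean across voxels
of the CBF and ATT estimates is compared with ground truth and expressed as
a percentage bias; the long-format table is then summarised per true ATT by
the mean over noise SDs together with the min-max envelope (the "fan" of the
bias-versus-ATT curves).
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

from .estimators import FitResult

logger = logging.getLogger(__name__)

__all__ = [
    "compute_bias",
    "bias_table",
    "noise_averaged",
    "plot_bias_curves",
    "benchmark_suite",
]

_BIAS_COLUMNS = [
    "fitter_name", "schedule_name", "true_att", "noise_sd",
    "parameter", "truth", "mean_estimate", "bias_pct", "n_excluded",
]


def compute_bias(fit: FitResult, truth: tuple[float, float]) -> list[dict]:
    """Percentage bias of the mean-across-voxel CBF and ATT estimates.

    ``truth`` is the (cbf, att) shared by all voxels; NaN voxels (possible
    for NLLS/WD) are excluded from the mean with the exclusion count
    reported.  bias_pct = 100 * (mean_estimate - truth) / truth.
    """
    records = []
    for parameter, est_map, truth_val in (
        ("cbf", fit.cbf_map, truth[0]),
        ("att", fit.att_map, truth[1]),
    ):
        if truth_val == 0:
            raise ValueError(f"zero ground truth for {parameter}")
        est_map = np.asarray(est_map, dtype=float)
        finite = np.isfinite(est_map)
        if not finite.any():
            raise ValueError(f"all-NaN {parameter} map from {fit.fitter_name}")
        n_excluded = int((~finite).sum())
        if n_excluded:
            logger.info("%s: excluded %d NaN voxels from %s mean",
                        fit.fitter_name, n_excluded, parameter)
        mean_est = float(est_map[finite].mean())
        records.append({
            "fitter_name": fit.fitter_name,
            "parameter": parameter,
            "truth": float(truth_val),
            "mean_estimate": mean_est,
            "bias_pct": 100.0 * (mean_est - truth_val) / truth_val,
            "n_excluded": n_excluded,
        })
    return records


def bias_table(
    results: Iterable[tuple[FitResult, dict]],
) -> pd.DataFrame:
    """Long-format bias table over a full simulation suite.

    ``results`` yields (fit, meta) pairs where meta carries
    ``schedule_name``, ``true_att``, ``noise_sd``, ``true_cbf``.  Raises if
    the (fitter, true_att, noise_sd) factorial has missing cells.
    """
    rows = []
    for fit, meta in results:
        for rec in compute_bias(fit, (meta["true_cbf"], meta["true_att"])):
            rec.update(
                schedule_name=meta["schedule_name"],
                true_att=float(meta["true_att"]),
                noise_sd=float(meta["noise_sd"]),
            )
            rows.append(rec)
    if not rows:
        raise ValueError("no fit results supplied")
    table = pd.DataFrame(rows)[_BIAS_COLUMNS]

    missing = []
    for (fitter, sched), group in table.groupby(["fitter_name", "schedule_name"]):
        atts = sorted(group["true_att"].unique())
        sds = sorted(group["noise_sd"].unique())
        have = set(zip(group["true_att"], group["noise_sd"]))
        for a in atts:
            for s in sds:
                if (a, s) not in have:
                    missing.append((fitter, sched, a, s))
    if missing:
        raise ValueError(f"incomplete factorial; missing cells: {missing}")
    return table


def noise_averaged(table: pd.DataFrame) -> pd.DataFrame:
    """Per-(fitter, schedule, true_att, parameter) mean bias over noise SDs
    plus the min-max envelope across noise levels."""
    g = table.groupby(
        ["fitter_name", "schedule_name", "true_att", "parameter"],
        as_index=False,
    )["bias_pct"]
    out = g.mean().rename(columns={"bias_pct": "bias_pct_mean"})
    out["bias_pct_min"] = g.min()["bias_pct"]
    out["bias_pct_max"] = g.max()["bias_pct"]
    return out


def benchmark_suite(
    schedule="grey_paper",
    fitters=("ssvb",),
    true_att_values=None,
    noise_sds=(10.0, 20.0, 30.0, 40.0),
    seed: int = 0,
    grid_shape=(5, 5, 5),
    constants=None,
) -> pd.DataFrame:
    """Simulate a (true ATT x noise SD) factorial and score fitters on it.

    Reproduces the paper-style simulation benchmark: homogeneous-truth
    5x5x5 datasets at CBF 60, each fitted by the requested methods, scored
    as percentage bias of the mean-across-voxel estimate.  All randomness
    (simulation noise and SSVB sampling) derives from ``seed``.
    """
    from .estimators import SSVBFitter, NLLSFitter, WeightedDelayFitter, \
        build_wd_calibration
    from .kinetics import TissueConstants, get_schedule
    from .simulate import SimulationConfig, simulate_suite

    sched = get_schedule(schedule) if isinstance(schedule, str) else schedule
    constants = constants or TissueConstants()
    if true_att_values is None:
        true_att_values = tuple(np.arange(0.5, 3.01, 0.25))
    root = np.random.SeedSequence(seed)
    sim_seed = int(root.spawn(1)[0].generate_state(1)[0] % 2**31)
    config = SimulationConfig(
        schedule=sched, grid_shape=tuple(grid_shape),
        true_att_values=tuple(true_att_values),
        noise_sds=tuple(noise_sds), rng_seed=sim_seed,
    )
    wd_cal = (build_wd_calibration(sched, constants)
              if "wd" in fitters else None)
    fit_seeds = root.spawn(len(true_att_values) * len(noise_sds))
    results = []
    for i, ds in enumerate(simulate_suite(config, constants)):
        for fitter in fitters:
            if fitter == "ssvb":
                est = SSVBFitter(
                    sched, constants,
                    rng_seed=int(fit_seeds[i].generate_state(1)[0] % 2**31))
                est.fit(ds.data, grid=ds.grid)
            elif fitter == "nlls":
                est = NLLSFitter(sched, constants).fit(ds.data)
            elif fitter == "wd":
                est = WeightedDelayFitter(sched, constants, wd_cal)
                est.fit(ds.data)
            else:
                raise ValueError(f"unknown fitter {fitter!r}")
            results.append((est.result_, {
                "schedule_name": sched.name,
                "true_att": float(ds.true_att[0]),
                "noise_sd": float(ds.noise_sd),
                "true_cbf": float(ds.true_cbf[0]),
            }))
    return bias_table(results)


def plot_bias_curves(table: pd.DataFrame, out_dir) -> list:
    """Bias-versus-true-ATT panels, one per (schedule, parameter), with the
    noise-level min-max fan around each fitter's noise-averaged line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    if table.empty:
        raise ValueError("empty bias table")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary = noise_averaged(table)
    paths = []
    for (sched, parameter), panel in summary.groupby(
            ["schedule_name", "parameter"]):
        fig, ax = plt.subplots(figsize=(5, 4))
        for fitter, curve in panel.groupby("fitter_name"):
            curve = curve.sort_values("true_att")
            ax.plot(curve["true_att"], curve["bias_pct_mean"], label=fitter)
            ax.fill_between(curve["true_att"], curve["bias_pct_min"],
                            curve["bias_pct_max"], alpha=0.2)
        ax.axhline(0.0, color="k", lw=0.5)
        ax.set_xlabel("true ATT (s)")
        ax.set_ylabel(f"{parameter.upper()} bias (%)")
        ax.set_title(f"{sched}: {parameter.upper()}")
        ax.legend()
        path = out_dir / f"bias_{sched}_{parameter}.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        paths.append(path)
    return paths
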