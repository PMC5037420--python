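"""On-disk formats for trajectory tables, CN-correlation tables, barcodes and run configs.

All files are UTF-8 CSV with a header row and "." as decimal separator
(one dialect only, so golden files stay stable). Coordinates are in
micrometres with an arbitrary origin; times are in minutes. The time
column is authoritative — the frame index is bookkeeping only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TrajectoryPair",
    "RunConfig",
    "FormatError",
    "ValidationError",
    "TRAJECTORY_COLUMNS",
    "CN_COLUMNS",
    "read_trajectories",
    "write_trajectories",
    "read_cn_table",
    "write_cn_table",
    "read_barcode_table",
    "write_barcode_table",
    "load_config",
    "save_config",
]


class FormatError(ValueError):
    """A file does not follow the expected dialect (e.g. a missing column)."""


class ValidationError(ValueError):
    """A file parses but violates a data invariant (spacing, length, finiteness)."""


TRAJECTORY_COLUMNS = (
    "frame",
    "time_min",
    "cell_x_um",
    "cell_y_um",
    "nuc_x_um",
    "nuc_y_um",
    "cell_id",
)

CN_COLUMNS = ("cell_id", "interval_index", "ccd_um", "ncd_par_um", "theta_deg", "region")

#: relative tolerance on uniform time spacing
_SPACING_RTOL = 1e-9


@dataclass
class TrajectoryPair:
    """Paired cell and nucleus centroid tracks for one cell.

    Positions are 2-D (the analysis is planar), in micrometres; ``times``
    are minutes on a uniform grid with spacing ``tau``.
    """

    cell_id: str
    times: np.ndarray  # (T,) minutes, uniformly spaced
    cell_xy: np.ndarray  # (T, 2) um
    nuc_xy: np.ndarray  # (T, 2) um

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.cell_xy = np.asarray(self.cell_xy, dtype=float)
        self.nuc_xy = np.asarray(self.nuc_xy, dtype=float)
        validate_trajectory(self)

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def tau(self) -> float:
        """Sampling interval in minutes."""
        return float(self.times[1] - self.times[0])


def validate_trajectory(traj: TrajectoryPair) -> None:
    """Enforce the TrajectoryPair invariants; raise :class:`ValidationError`."""
    t = traj.times
    if t.ndim != 1 or len(t) < 2:
        raise ValidationError(
            f"cell {traj.cell_id!r}: a trajectory needs at least 2 frames, got {len(t)}"
        )
    for name, arr in (("cell_xy", traj.cell_xy), ("nuc_xy", traj.nuc_xy)):
        if arr.shape != (len(t), 2):
            raise ValidationError(
                f"cell {traj.cell_id!r}: {name} has shape {arr.shape}, expected {(len(t), 2)}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValidationError(f"cell {traj.cell_id!r}: non-finite values in {name}")
    if not np.all(np.isfinite(t)):
        raise ValidationError(f"cell {traj.cell_id!r}: non-finite time values")
    dt = np.diff(t)
    if np.any(dt <= 0):
        bad = int(np.argmax(dt <= 0)) + 1
        raise ValidationError(
            f"cell {traj.cell_id!r}: times not strictly increasing at frame index {bad}"
        )
    tau = dt[0]
    off = np.abs(dt - tau) > _SPACING_RTOL * max(abs(tau), 1.0)
    if np.any(off):
        bad = int(np.argmax(off)) + 1
        raise ValidationError(
            f"cell {traj.cell_id!r}: non-uniform time spacing at frame index {bad} "
            f"(expected tau={tau:g} min, got {dt[bad - 1]:g})"
        )


@dataclass
class RunConfig:
    """Run configuration mirrored by the YAML config file.

    tau_min
        sampling interval in minutes.
    region_scheme
        ``"four"`` (Regions I-IV) or ``"five"`` (with Region V, Stationary Mode).
    rng_seed
        seed for every stochastic step of a run.
    msd_fit_fraction
        fraction of the maximum lag used when fitting the PRW model.
    noise_bins
        bin count per axis of the 2-D positioning-noise histogram.
    """

    tau_min: float = 1.0
    region_scheme: str = "four"
    rng_seed: int = 0
    msd_fit_fraction: float = 0.10
    noise_bins: int = 32
    units: str = "um/min"

    def __post_init__(self) -> None:
        if self.tau_min <= 0:
            raise ValidationError(f"tau_min must be positive, got {self.tau_min}")
        if not 0 < self.msd_fit_fraction <= 1:
            raise ValidationError(
                f"msd_fit_fraction must be in (0, 1], got {self.msd_fit_fraction}"
            )
        if self.noise_bins < 4:
            raise ValidationError(f"noise_bins must be >= 4, got {self.noise_bins}")
        if self.region_scheme not in ("four", "five"):
            raise ValidationError(f"region_scheme must be 'four' or 'five', got {self.region_scheme!r}")


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")


def read_trajectories(path, tau_expected: float | None = None) -> list[TrajectoryPair]:
    """Read a trajectory CSV into one :class:`TrajectoryPair` per cell_id.

    Rows are sorted by time within each cell; uniform spacing is enforced.
    If ``tau_expected`` is given, the observed spacing must match it to
    relative tolerance 1e-9.
    """
    df = pd.read_csv(path)
    _require_columns(df, TRAJECTORY_COLUMNS, path)
    out: list[TrajectoryPair] = []
    for cell_id, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("time_min")
        traj = TrajectoryPair(
            cell_id=str(cell_id),
            times=grp["time_min"].to_numpy(dtype=float),
            cell_xy=grp[["cell_x_um", "cell_y_um"]].to_numpy(dtype=float),
            nuc_xy=grp[["nuc_x_um", "nuc_y_um"]].to_numpy(dtype=float),
        )
        if tau_expected is not None:
            if abs(traj.tau - tau_expected) > _SPACING_RTOL * max(abs(tau_expected), 1.0):
                raise ValidationError(
                    f"cell {traj.cell_id!r}: spacing {traj.tau:g} min does not match "
                    f"expected tau={tau_expected:g} min"
                )
        out.append(traj)
    if not out:
        raise ValidationError(f"{path}: no trajectory rows")
    return out


def write_trajectories(trajs: Iterable[TrajectoryPair], path) -> None:
    """Write trajectories in the standard CSV dialect (round-trips with the reader)."""
    frames = []
    for traj in trajs:
        frames.append(
            pd.DataFrame(
                {
                    "frame": np.arange(traj.n_frames),
                    "time_min": traj.times,
                    "cell_x_um": traj.cell_xy[:, 0],
                    "cell_y_um": traj.cell_xy[:, 1],
                    "nuc_x_um": traj.nuc_xy[:, 0],
                    "nuc_y_um": traj.nuc_xy[:, 1],
                    "cell_id": traj.cell_id,
                }
            )
        )
    if not frames:
        raise ValidationError("no trajectories to write")
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.9g")


def write_cn_table(points: pd.DataFrame, path) -> None:
    """Write a CN-correlation table (one row per interval).

    Columns: cell_id, interval_index, ccd_um, ncd_par_um, theta_deg, region.
    Values survive a round-trip to at least 6 decimals.
    """
    if len(points) == 0:
        raise ValidationError("refusing to write an empty CN table")
    _require_columns(points, CN_COLUMNS, "<CN table>")
    points[list(CN_COLUMNS)].to_csv(path, index=False, float_format="%.9g")


def read_cn_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, CN_COLUMNS, path)
    # theta is NaN on degenerate (zero-CCD) intervals
    df["region"] = df["region"].astype(str)
    return df


def write_barcode_table(interval_index: np.ndarray, labels: Sequence[str], path) -> None:
    pd.DataFrame({"interval_index": interval_index, "region": list(labels)}).to_csv(
        path, index=False
    )


def read_barcode_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ("interval_index", "region"), path)
    return df


def load_config(path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise FormatError(f"{path}: config must be a YAML mapping")
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
    return RunConfig(**data)


def save_config(cfg: RunConfig, path) -> None:
    data = {k: getattr(cfg, k) for k in cfg.__dataclass_fields__}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True), encoding="utf-8")
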