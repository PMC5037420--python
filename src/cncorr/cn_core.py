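"""Cell-nucleus (CN) correlation computation.

For each fixed sampling interval the cell centroid displacement (CCD) sets a
transient reference direction; the concurrent nucleus centroid displacement
(NCD) is projected onto it, giving the signed scalar NCD_//. The pair
(NCD_//, CCD) is one CN-correlation datum. Its polar angle

    theta = atan2(CCD, NCD_//)     (NCD_// is the abscissa, CCD the ordinate)

classifies the interval's dominant subcellular activity:

    Region I    0 < theta <= 45      detachment mode
    Region II   45 < theta <= 75     mixed detachment/protrusion mode
    Region III  75 < theta <= 105    protrusion/retraction mode
    Region IV   105 < theta <= 180   large-angle side protrusion mode

Boundary angles belong to the lower-numbered region (closed upper bound).
An interval with CCD = 0 has no direction and is labelled UNDEFINED; with
real fixed-precision centroid data this is measure-zero. Region V
(stationary mode) is assigned only by the Monte-Carlo noise filter in
:mod:`cncorr.stationary_filter`.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import TrajectoryPair

__all__ = [
    "REGIONS_FOUR",
    "REGIONS_FIVE",
    "UNDEFINED",
    "ZERO_CCD_TOL",
    "displacement_pairs",
    "project_ncd",
    "theta_degrees",
    "classify_region",
    "cn_series",
    "cn_series_from_pairs",
    "series_autocorrelation",
]

REGIONS_FOUR = ("I", "II", "III", "IV")
REGIONS_FIVE = ("I", "II", "III", "IV", "V")
UNDEFINED = "UNDEFINED"

#: a CCD magnitude below this (um) has no usable direction
ZERO_CCD_TOL = 1e-12

#: upper region bounds in degrees, closed above
_REGION_BOUNDS = ((45.0, "I"), (75.0, "II"), (105.0, "III"), (180.0, "IV"))


def displacement_pairs(traj: TrajectoryPair, lag_steps: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Consecutive (stride-1, overlapping) displacement vectors at ``lag_steps``.

    Returns ``(ccd_vecs, ncd_vecs)``, each of shape (T - lag_steps, 2):
    pair k is ``(cell_xy[k+lag] - cell_xy[k], nuc_xy[k+lag] - nuc_xy[k])``.
    """
    lag_steps = int(lag_steps)
    if lag_steps < 1:
        raise ValueError(f"lag_steps must be >= 1, got {lag_steps}")
    if lag_steps >= traj.n_frames:
        raise ValueError(
            f"lag_steps={lag_steps} must be smaller than the track length T={traj.n_frames}"
        )
    ccd_vecs = traj.cell_xy[lag_steps:] - traj.cell_xy[:-lag_steps]
    ncd_vecs = traj.nuc_xy[lag_steps:] - traj.nuc_xy[:-lag_steps]
    return ccd_vecs, ncd_vecs


def project_ncd(ccd_vec, ncd_vec) -> tuple[np.ndarray, np.ndarray]:
    """CCD magnitude and signed projection of the NCD onto the CCD direction.

    Accepts single 2-vectors or (n, 2) stacks. For a degenerate interval
    (|CCD| = 0) the projection direction is undefined; the NCD magnitude is
    returned in its place and the classifier maps the point to UNDEFINED.
    """
    ccd_vec = np.asarray(ccd_vec, dtype=float)
    ncd_vec = np.asarray(ncd_vec, dtype=float)
    if not (np.all(np.isfinite(ccd_vec)) and np.all(np.isfinite(ncd_vec))):
        raise ValueError("displacement vectors must be finite")
    ccd = np.linalg.norm(ccd_vec, axis=-1)
    dot = np.sum(ccd_vec * ncd_vec, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ncd_par = np.where(ccd > ZERO_CCD_TOL, dot / np.where(ccd > 0, ccd, 1.0),
                           np.linalg.norm(ncd_vec, axis=-1))
    return ccd, ncd_par


def theta_degrees(ccd, ncd_par) -> np.ndarray:
    """Polar angle of the (NCD_//, CCD) point, degrees in (0, 180]; NaN when CCD = 0."""
    ccd = np.asarray(ccd, dtype=float)
    ncd_par = np.asarray(ncd_par, dtype=float)
    theta = np.degrees(np.arctan2(ccd, ncd_par))
    return np.where(ccd > ZERO_CCD_TOL, theta, np.nan)


def classify_region(ccd, ncd_par):
    """Region label(s) for CN point(s) by the four-region angular rule.

    Scalar inputs give a scalar label; arrays give an object array.
    """
    ccd_arr = np.atleast_1d(np.asarray(ccd, dtype=float))
    npar_arr = np.atleast_1d(np.asarray(ncd_par, dtype=float))
    if not (np.all(np.isfinite(ccd_arr)) and np.all(np.isfinite(npar_arr))):
        raise ValueError("ccd and ncd_par must be finite")
    if np.any(ccd_arr < 0):
        raise ValueError("ccd is a magnitude and must be >= 0")
    theta = np.degrees(np.arctan2(ccd_arr, npar_arr))
    labels = np.full(ccd_arr.shape, UNDEFINED, dtype=object)
    defined = ccd_arr > ZERO_CCD_TOL
    lower = 0.0
    for upper, region in _REGION_BOUNDS:
        labels[defined & (theta > lower) & (theta <= upper)] = region
        lower = upper
    if np.isscalar(ccd) or np.ndim(ccd) == 0:
        return labels.item()
    return labels


def cn_series(traj: TrajectoryPair, lag_steps: int = 1) -> pd.DataFrame:
    """Full CN-correlation series of one trajectory as a tidy table.

    Columns: cell_id, interval_index, ccd_um, ncd_par_um, theta_deg, region —
    one row per interval, in time order. A T-frame track yields T - lag_steps
    rows (a 61-frame one-hour movie at 1-min spacing gives 60 points).
    """
    ccd_vecs, ncd_vecs = displacement_pairs(traj, lag_steps)
    return cn_series_from_pairs(ccd_vecs, ncd_vecs, cell_id=traj.cell_id)


def cn_series_from_pairs(ccd_vecs, ncd_vecs, cell_id: str = "cell") -> pd.DataFrame:
    """CN series from precomputed displacement pairs (used by the noise-injection path)."""
    ccd, ncd_par = project_ncd(ccd_vecs, ncd_vecs)
    return pd.DataFrame(
        {
            "cell_id": cell_id,
            "interval_index": np.arange(len(ccd)),
            "ccd_um": ccd,
            "ncd_par_um": ncd_par,
            "theta_deg": theta_degrees(ccd, ncd_par),
            "region": classify_region(ccd, ncd_par),
        }
    )


def series_autocorrelation(values: Sequence[float], max_lag: int) -> np.ndarray:
    """Normalized autocorrelation r(0..max_lag) of a CN feature series.

    Intended for the per-interval theta or NCD_// sequences; NaN entries
    (UNDEFINED intervals) are excluded pairwise. A zero-variance series is
    perfectly self-similar and returns r = 1 at every lag. Linear (not
    circular) correlation is used for angles as well; see the methods note.
    """
    x = np.asarray(values, dtype=float)
    if len(x) <= max_lag + 2:
        raise ValueError(
            f"series of length {len(x)} too short for max_lag={max_lag} (need > max_lag + 2)"
        )
    out = np.empty(max_lag + 1)
    out[0] = 1.0
    for k in range(1, max_lag + 1):
        a, b = x[:-k], x[k:]
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() < 3:
            out[k] = np.nan
            continue
        a, b = a[ok], b[ok]
        va, vb = a.var(), b.var()
        if va == 0 or vb == 0:
            out[k] = 1.0  # zero-variance guard: constant series
            continue
        out[k] = np.mean((a - a.mean()) * (b - b.mean())) / np.sqrt(va * vb)
    return out
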