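"""Monte-Carlo stationary-mode (Region V) filter for positioning noise.

A chemically fixed cell cannot move, so its CN-correlation cloud is pure
acquisition noise. Its empirical distribution over the (NCD_//, CCD) plane,
max-normalised to [0, 1], serves as a noise score p(NCD_//, CCD): a
live-cell datum indistinguishable from the most probable pure-noise outcome
scores p = 1, one far outside the fixed-cell hull scores 0. For each
live-cell interval a uniform deviate u is drawn; if u > p the original
region label is kept (effective motion), otherwise the interval is
relabelled Region V (stationary mode). The filter only ever maps I-IV to V —
never between I and IV — and is bit-reproducible under a fixed seed.

Isolated stationary intervals are expected during normal locomotion; only a
prolonged run (more than five consecutive intervals, at 1-min spacing more
than five minutes) marks a genuinely stationary cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cn_core import UNDEFINED

__all__ = ["NoiseDensity", "fit_noise_density", "noise_probability",
           "monte_carlo_filter", "prolonged_stationary_segments",
           "save_noise_density", "load_noise_density"]


@dataclass
class NoiseDensity:
    """Empirical positioning-noise score over the (NCD_//, CCD) plane.

    ``p_grid[i, j]`` is the max-normalised relative frequency of fixed-cell
    CN points in NCD_// bin i and CCD bin j; queries outside the fixed-cell
    data hull return 0.
    """

    bin_edges_ncd_par: np.ndarray  # (nb+1,) um
    bin_edges_ccd: np.ndarray  # (nb+1,) um
    p_grid: np.ndarray  # (nb_ncd, nb_ccd), values in [0, 1]
    n_source_points: int

    def __post_init__(self) -> None:
        self.p_grid = np.asarray(self.p_grid, dtype=float)
        if self.p_grid.min() < 0 or self.p_grid.max() > 1 + 1e-12:
            raise ValueError("p_grid values must lie in [0, 1]")


def fit_noise_density(fixed_points: pd.DataFrame, bins: int = 32) -> NoiseDensity:
    """Fit the noise score from a fixed-cell CN series.

    A 2-D histogram of (ncd_par, ccd) over the data hull, normalised by its
    maximum bin count so the mode maps to p = 1 (scaling every count equally
    leaves the grid unchanged). Deterministic for fixed input. Fewer than
    100 source points triggers a warning; fewer than 2 is an error.
    """
    pts = fixed_points[fixed_points["region"] != UNDEFINED]
    npar = pts["ncd_par_um"].to_numpy(dtype=float)
    ccd = pts["ccd_um"].to_numpy(dtype=float)
    if len(npar) < 2:
        raise ValueError(f"need at least 2 fixed-cell points, got {len(npar)}")
    if len(npar) < 100:
        warnings.warn(
            f"only {len(npar)} fixed-cell points; the noise density will be coarse",
            stacklevel=2,
        )
    counts, ex, ey = np.histogram2d(npar, ccd, bins=bins)
    return NoiseDensity(
        bin_edges_ncd_par=ex,
        bin_edges_ccd=ey,
        p_grid=counts / counts.max(),
        n_source_points=len(npar),
    )


def _bin_index(edges: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Bin index per value; -1 outside the hull.

    A value landing exactly on an interior bin edge belongs to the
    lower-index bin; the two outermost edges are inclusive.
    """
    v = np.asarray(v, dtype=float)
    idx = np.searchsorted(edges, v, side="left") - 1
    idx = np.where(v == edges[0], 0, idx)  # leftmost edge is part of bin 0
    outside = (v < edges[0]) | (v > edges[-1])
    return np.where(outside, -1, np.clip(idx, 0, len(edges) - 2))


def noise_probability(density: NoiseDensity, ncd_par, ccd) -> np.ndarray:
    """Piecewise-constant lookup of p(NCD_//, CCD); 0 outside the hull."""
    i = _bin_index(density.bin_edges_ncd_par, np.atleast_1d(ncd_par))
    j = _bin_index(density.bin_edges_ccd, np.atleast_1d(ccd))
    inside = (i >= 0) & (j >= 0)
    p = np.zeros(i.shape)
    p[inside] = density.p_grid[i[inside], j[inside]]
    if np.isscalar(ncd_par) or np.ndim(ncd_par) == 0:
        return float(p[0])
    return p


def monte_carlo_filter(points: pd.DataFrame, density: NoiseDensity,
                       seed: int | None = None) -> pd.DataFrame:
    """Relabel likely-noise intervals of a live-cell CN series to Region V.

    One uniform deviate u ~ U[0, 1] is drawn per interval in time order from
    a single RNG stream (so a fixed seed gives bit-identical output); the
    interval keeps its label when u > p and becomes Region V otherwise.
    UNDEFINED intervals consume their draw but are never relabelled. The
    original labels are retained in ``region_original``.
    """
    rng = np.random.default_rng(seed)
    pts = points.sort_values("interval_index").reset_index(drop=True)
    p = noise_probability(density, pts["ncd_par_um"].to_numpy(),
                          pts["ccd_um"].to_numpy())
    u = rng.uniform(size=len(pts))
    out = pts.copy()
    out["region_original"] = pts["region"]
    stationary = (u <= p) & (pts["region"] != UNDEFINED).to_numpy()
    out["region"] = np.where(stationary, "V", pts["region"])
    out["noise_p"] = p
    return out


def prolonged_stationary_segments(labels, min_run: int = 5) -> list[tuple[int, int]]:
    """Maximal runs of Region V strictly longer than ``min_run`` intervals.

    Returns half-open index ranges (start, stop). At 1-min sampling the
    default keeps only cells stationary for more than five minutes.
    """
    labels = list(labels)
    segments: list[tuple[int, int]] = []
    start = None
    for k, lab in enumerate(labels + [None]):  # sentinel flushes a trailing run
        if lab == "V":
            if start is None:
                start = k
        elif start is not None:
            if k - start > min_run:
                segments.append((start, k))
            start = None
    return segments


def save_noise_density(density: NoiseDensity, path) -> None:
    """Serialize the density grid to a long-form CSV (one row per bin)."""
    ni, nj = density.p_grid.shape
    ii, jj = np.meshgrid(np.arange(ni), np.arange(nj), indexing="ij")
    pd.DataFrame(
        {
            "ncd_par_lo": density.bin_edges_ncd_par[ii.ravel()],
            "ncd_par_hi": density.bin_edges_ncd_par[ii.ravel() + 1],
            "ccd_lo": density.bin_edges_ccd[jj.ravel()],
            "ccd_hi": density.bin_edges_ccd[jj.ravel() + 1],
            "p": density.p_grid.ravel(),
            "n_source_points": density.n_source_points,
        }
    ).to_csv(path, index=False, float_format="%.9g")


def load_noise_density(path) -> NoiseDensity:
    df = pd.read_csv(path)
    ncd_lo = np.unique(df["ncd_par_lo"])
    ccd_lo = np.unique(df["ccd_lo"])
    ni, nj = len(ncd_lo), len(ccd_lo)
    edges_ncd = np.append(ncd_lo, df["ncd_par_hi"].max())
    edges_ccd = np.append(ccd_lo, df["ccd_hi"].max())
    p = df["p"].to_numpy().reshape(ni, nj)
    return NoiseDensity(edges_ncd, edges_ccd, p, int(df["n_source_points"].iloc[0]))
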