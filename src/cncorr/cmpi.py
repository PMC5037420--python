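"""Cell Migration Potential Index (CMPI).

CMPI accumulates the effective nuclear translocation of a cell: the regions
whose events drive net migration are Region I (detachment) and Region II
(mixed detachment/protrusion), so

    CMPI = sum_{i in {I, II}}  o_i * <NCD_//>_i

where o_i is the occurrence fraction of region i among defined intervals and
<NCD_//>_i is the mean signed nuclear projection within region i. Units are
um per sampling interval at the stated tau (an optional per-minute
normalisation divides by tau). Algebraically this equals the mean over ALL
defined intervals of NCD_// restricted to 0 < theta <= 75, which is the
identity the implementation is tested against.

Higher CMPI means higher motility; a cell whose nucleus never moves has
NCD_// = 0 everywhere, hence theta = 90 (Region III) and CMPI = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cn_core import REGIONS_FOUR, REGIONS_FIVE, UNDEFINED

__all__ = ["CMPIResult", "ConvergenceCurve", "cell_cmpi", "population_cmpi",
           "pooled_cmpi", "running_cmpi", "convergence_curve", "CMPI_REGIONS"]

#: the regions whose nuclear translocation counts toward motility
CMPI_REGIONS = ("I", "II")


@dataclass
class CMPIResult:
    """Per-cell CMPI decomposition at a given sampling interval."""

    cell_id: str
    o: dict[str, float]  # region -> occurrence fraction
    region_mean_ncd_par: dict[str, float]  # region -> mean NCD_// (um)
    cmpi: float  # um per interval
    tau: float  # minutes
    n_intervals: int  # defined intervals

    @property
    def cmpi_per_min(self) -> float:
        """Optional cross-tau normalisation, um/min."""
        return self.cmpi / self.tau


def cell_cmpi(points: pd.DataFrame, scheme: str = "four", tau: float = 1.0) -> CMPIResult:
    """CMPI of one cell from its CN series table.

    o_i is counted over defined (non-UNDEFINED) intervals; an empty region
    contributes o_i = 0 with mean 0. Region V intervals (stationary mode,
    scheme "five") count in the denominator but never in Regions I/II.
    """
    regions = REGIONS_FOUR if scheme == "four" else REGIONS_FIVE
    defined = points[points["region"] != UNDEFINED]
    n = len(defined)
    if n == 0:
        raise ValueError("CN series has no defined points; CMPI is undefined")
    o: dict[str, float] = {}
    means: dict[str, float] = {}
    for r in regions:
        sel = defined[defined["region"] == r]
        o[r] = len(sel) / n
        means[r] = float(sel["ncd_par_um"].mean()) if len(sel) else 0.0
    value = float(sum(o[r] * means[r] for r in CMPI_REGIONS))
    cell_ids = points["cell_id"].unique()
    cell_id = str(cell_ids[0]) if len(cell_ids) == 1 else "pooled"
    return CMPIResult(cell_id=cell_id, o=o, region_mean_ncd_par=means,
                      cmpi=value, tau=tau, n_intervals=n)


def population_cmpi(results: list[CMPIResult]) -> tuple[float, float, int]:
    """Population mean CMPI with its standard error: (mean, SEM, n).

    SEM = sd / sqrt(n) with the sample (ddof=1) standard deviation.
    """
    n = len(results)
    if n < 2:
        raise ValueError("population_cmpi needs at least 2 cells (SEM undefined)")
    vals = np.array([r.cmpi for r in results])
    return float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(n)), n


def pooled_cmpi(points: pd.DataFrame, scheme: str = "four", tau: float = 1.0) -> CMPIResult:
    """Pooled-population variant: all cells' intervals pooled into one series."""
    return cell_cmpi(points, scheme=scheme, tau=tau)


def running_cmpi(points: pd.DataFrame, window_intervals: int,
                 scheme: str = "four", tau: float = 1.0) -> np.ndarray:
    """Moving-window CMPI over consecutive windows (stride 1).

    Short windows (e.g. 10 intervals) reveal transient migration phases;
    the full-length window reproduces the whole-track CMPI. Windows with no
    defined interval yield NaN.
    """
    n = len(points)
    if not 1 <= window_intervals <= n:
        raise ValueError(
            f"window_intervals={window_intervals} must be in [1, {n}] for this series"
        )
    pts = points.sort_values("interval_index").reset_index(drop=True)
    out = np.empty(n - window_intervals + 1)
    for k in range(len(out)):
        win = pts.iloc[k:k + window_intervals]
        try:
            out[k] = cell_cmpi(win, scheme=scheme, tau=tau).cmpi
        except ValueError:
            out[k] = np.nan
    return out


@dataclass
class ConvergenceCurve:
    """Sample-size convergence of the population mean CMPI."""

    table: pd.DataFrame  # columns: sample_size, mean, sem
    converged_at: int | None  # smallest sample size with SEM < 10% of mean


def convergence_curve(pool: list[CMPIResult], step: int = 5,
                      n_iterations: int = 200, seed: int | None = None,
                      sem_fraction: float = 0.10) -> ConvergenceCurve:
    """Subsampling convergence of <CMPI> against sample size.

    For each sample size s = step, 2*step, ... <= len(pool), draw s cells
    without replacement, n_iterations times independently; report the mean
    of the subsample means and the mean subsample SEM. The convergence flag
    is the smallest s at which mean SEM < sem_fraction * |mean|.
    """
    if len(pool) < step:
        raise ValueError(f"pool of {len(pool)} cells is smaller than step={step}")
    if step < 2:
        raise ValueError("step must be >= 2 so that the SEM is defined")
    rng = np.random.default_rng(seed)
    vals = np.array([r.cmpi for r in pool])
    rows = []
    converged_at = None
    for s in range(step, len(pool) + 1, step):
        means = np.empty(n_iterations)
        sems = np.empty(n_iterations)
        for it in range(n_iterations):
            draw = vals[rng.choice(len(vals), size=s, replace=False)]
            means[it] = draw.mean()
            sems[it] = draw.std(ddof=1) / np.sqrt(s)
        m, sem = float(means.mean()), float(sems.mean())
        rows.append({"sample_size": s, "mean": m, "sem": sem})
        if converged_at is None and sem < sem_fraction * abs(m):
            converged_at = s
    return ConvergenceCurve(table=pd.DataFrame(rows), converged_at=converged_at)
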