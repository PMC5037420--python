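"""Persistent-random-walk (PRW) trajectory analysis.

The PRW model describes motile cells through the Fürth mean-squared
displacement

    <r^2>(t) = 2 S^2 P [ t - P (1 - exp(-t/P)) ]

with S the root-mean-square speed (um/min) and P the persistence time
(min). The curve is ballistic (<r^2> ~ S^2 t^2, log-log slope 2) at lags
much shorter than P and diffusive (slope 1) at lags much longer. The
motility summary is the diffusion coefficient

    mu = S^2 P / n,   n = 2 spatial dimensions.

Fitting uses unweighted Levenberg-Marquardt least squares on the raw MSD
(an n_pairs weighting option is available); long lags are excluded by
default because MSD estimates there average few displacement pairs and are
noise-dominated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = ["MSDCurve", "PRWFit", "furth_msd", "compute_msd", "average_msd",
           "fit_prw", "loglog_slope", "instantaneous_speed", "N_DIM"]

N_DIM = 2


@dataclass
class MSDCurve:
    lags: np.ndarray  # minutes, strictly increasing, starting at tau
    msd: np.ndarray  # um^2
    n_pairs_per_lag: np.ndarray
    overlapping: bool


@dataclass
class PRWFit:
    S: float  # um/min rms speed
    P: float  # minutes persistence time
    mu: float  # um^2/min, = S^2 P / 2
    n_dim: int
    residual_norm: float
    converged: bool
    message: str = ""


def furth_msd(t, S: float, P: float) -> np.ndarray:
    """Closed-form PRW mean-squared displacement, um^2."""
    t = np.asarray(t, dtype=float)
    return 2.0 * S**2 * P * (t - P * (1.0 - np.exp(-t / P)))


def compute_msd(positions: np.ndarray, tau: float, overlapping: bool = True,
                max_lag_fraction: float = 0.10) -> MSDCurve:
    """Time-averaged MSD of one 2-D track.

    Lags run from tau up to ``max_lag_fraction`` of the track duration.
    ``overlapping`` uses every start frame; otherwise start frames step by
    the lag (independent displacement pairs). The default 10% cap keeps the
    fitted lag window inside the regime where each track still contributes
    many effectively independent displacement pairs; MSD values at longer
    lags carry large correlated errors that would dominate an unweighted
    fit (see the methods note).
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 2:
        raise ValueError(f"positions must be (T, 2), got {pos.shape}")
    T = len(pos)
    if T < 8:
        raise ValueError(f"track too short for an MSD curve (T={T} < 8)")
    max_k = max(1, int(np.floor(max_lag_fraction * (T - 1))))
    lags = np.arange(1, max_k + 1) * tau
    msd = np.empty(max_k)
    n_pairs = np.empty(max_k, dtype=int)
    for k in range(1, max_k + 1):
        if overlapping:
            d = pos[k:] - pos[:-k]
        else:
            starts = np.arange(0, T - k, k)
            d = pos[starts + k] - pos[starts]
        sq = np.sum(d**2, axis=1)
        msd[k - 1] = sq.mean()
        n_pairs[k - 1] = len(sq)
    return MSDCurve(lags=lags, msd=msd, n_pairs_per_lag=n_pairs, overlapping=overlapping)


def average_msd(curves: list[MSDCurve]) -> MSDCurve:
    """Average several MSD curves over their common lag range (per-lag mean).

    Used to pool the tracks of one cell type before fitting, so the fitted
    S, P, mu describe the type rather than a single track.
    """
    if not curves:
        raise ValueError("no MSD curves to average")
    n = min(len(c.lags) for c in curves)
    lags = curves[0].lags[:n]
    for c in curves:
        if not np.allclose(c.lags[:n], lags):
            raise ValueError("MSD curves have incompatible lag grids")
    msd = np.mean([c.msd[:n] for c in curves], axis=0)
    pairs = np.sum([c.n_pairs_per_lag[:n] for c in curves], axis=0)
    return MSDCurve(lags=lags, msd=msd, n_pairs_per_lag=pairs,
                    overlapping=curves[0].overlapping)


def fit_prw(msd: MSDCurve, weight_by_pairs: bool = False) -> PRWFit:
    """Levenberg-Marquardt fit of (S, P) in the Fürth equation.

    Initial values: S0 = sqrt(msd at the first lag)/tau (short-lag speed),
    P0 = 5 tau. S enters the model squared, so a sign-flipped optimum is
    folded back to S > 0; a non-positive persistence time marks the fit as
    non-converged (diagnostics preserved, never a silent NaN).
    """
    if len(msd.lags) < 5:
        raise ValueError(f"need at least 5 lags to fit, got {len(msd.lags)}")
    tau = float(msd.lags[0])
    S0 = max(np.sqrt(max(msd.msd[0], 1e-12)) / tau, 1e-6)
    P0 = 5.0 * tau
    w = np.sqrt(msd.n_pairs_per_lag) if weight_by_pairs else np.ones_like(msd.msd)

    def residuals(x):
        return w * (furth_msd(msd.lags, x[0], x[1]) - msd.msd)

    try:
        res = least_squares(residuals, x0=[S0, P0], method="lm", max_nfev=10000)
    except Exception as exc:  # optimizer blow-up: report, don't raise
        return PRWFit(S=np.nan, P=np.nan, mu=np.nan, n_dim=N_DIM,
                      residual_norm=np.nan, converged=False, message=str(exc))
    S, P = float(abs(res.x[0])), float(res.x[1])
    ok = bool(res.success) and S > 0 and P > 0
    msg = res.message
    total_span = msd.lags[-1]
    if ok and P > 10 * total_span:
        msg += " [P exceeds 10x the fitted lag window: near-ballistic, P poorly constrained]"
    mu = S**2 * P / N_DIM if ok else np.nan
    return PRWFit(S=S if ok else float(res.x[0]), P=P, mu=mu, n_dim=N_DIM,
                  residual_norm=float(np.linalg.norm(res.fun)), converged=ok,
                  message=msg)


def loglog_slope(msd: MSDCurve, lag_range: tuple[float, float] | None = None) -> float:
    """Least-squares slope of log(MSD) vs log(lag) over ``lag_range``.

    Slope 2 indicates ballistic (directed) motion, 1 diffusive, <1
    sub-diffusive; a cell's and nucleus' slopes index their motility.
    """
    if lag_range is None:
        sel = np.ones(len(msd.lags), dtype=bool)
    else:
        lo, hi = lag_range
        sel = (msd.lags >= lo) & (msd.lags <= hi)
    if sel.sum() < 3:
        raise ValueError("need at least 3 lags in range for a log-log slope")
    if np.any(msd.msd[sel] <= 0):
        raise ValueError("MSD must be positive in the requested lag range")
    slope, _ = np.polyfit(np.log(msd.lags[sel]), np.log(msd.msd[sel]), 1)
    return float(slope)


def instantaneous_speed(positions: np.ndarray, tau: float) -> np.ndarray:
    """Per-interval speed |dx|/tau in um/min; equals the CN series' CCD/tau."""
    pos = np.asarray(positions, dtype=float)
    if len(pos) < 2:
        raise ValueError("need at least 2 frames")
    return np.linalg.norm(np.diff(pos, axis=0), axis=1) / tau
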