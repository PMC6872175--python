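"""Time-averaged mean-squared displacement and the fits derived from it.

The MSD of a track of N frames at lag n (in frame units) is the average of
the squared displacement over all N - n overlapping pairs,

    msd(n*dt) = (1/(N-n)) * sum_j [ (x_{j+n}-x_j)^2 + (y_{j+n}-y_j)^2 ],

computed for every lag n = 1..N-1.  Two estimators are fitted to it:

* the microscopic diffusion coefficient ``D_24`` from an ordinary
  least-squares line ``msd = 4*D_24*t + offset`` through the first four
  lags (the short-lag slope is 4D for every motion mode);
* the anomalous exponent ``alpha`` from a nonlinear fit of
  ``msd = 4*D_alpha*t^alpha`` over the whole curve (alpha < 1 signals
  subdiffusion/confinement, alpha ~ 1 Brownian motion).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .tracks import Trajectory

#: Track length above which the FFT autocorrelation path is used.
_FFT_THRESHOLD = 1024


@dataclass(frozen=True)
class MSDCurve:
    """Time-averaged MSD of one trajectory.

    ``lags`` are in seconds (multiples of dt), ``msd`` in um^2, and
    ``n_pairs[k] = N - (k+1)`` is the number of displacement pairs averaged
    at each lag.
    """

    lags: np.ndarray
    msd: np.ndarray
    n_pairs: np.ndarray
    N: int
    dt: float

    def __len__(self) -> int:
        return len(self.lags)

    def at_lag(self, n: int) -> float:
        """MSD value at integer lag ``n`` (frames)."""
        if not 1 <= n <= self.N - 1:
            raise ValueError(f"lag {n} outside 1..{self.N - 1}")
        return float(self.msd[n - 1])


@dataclass(frozen=True)
class PowerLawFit:
    """Result of the anomalous-diffusion fit msd = 4*D_alpha*t^alpha."""

    D_alpha: float
    alpha: float
    converged: bool
    residual: float


def _msd_1d_direct(z: np.ndarray, max_lag: int) -> np.ndarray:
    out = np.empty(max_lag)
    for n in range(1, max_lag + 1):
        d = z[n:] - z[:-n]
        out[n - 1] = np.mean(d * d)
    return out


def _msd_1d_fft(z: np.ndarray, max_lag: int) -> np.ndarray:
    # msd(n) = [S1(n) - 2*S2(n)] / (N - n) with S2 the linear autocorrelation
    # (FFT) and S1 the running sum of squared endpoints; identical to the
    # direct double sum up to floating-point rounding.
    N = len(z)
    nfft = 1 << int(np.ceil(np.log2(2 * N)))
    fz = np.fft.rfft(z, nfft)
    s2 = np.fft.irfft(fz * np.conj(fz), nfft)[:N]
    d = z * z
    q = 2.0 * d.sum()
    s1 = np.empty(N)
    s1[0] = q
    for m in range(1, N):
        q -= d[m - 1] + d[N - m]
        s1[m] = q
    counts = N - np.arange(N)
    msd = (s1 - 2.0 * s2) / counts
    return msd[1 : max_lag + 1]


def compute_msd(traj: Trajectory, max_lag: int | None = None,
                method: str = "auto") -> MSDCurve:
    """Time-averaged MSD over all overlapping displacement pairs.

    Parameters
    ----------
    traj : Trajectory
        A reindexed (contiguous-frame) track with N >= 2 points.
    max_lag : int, optional
        Largest lag (frames) to evaluate; default N - 1.
    method : {'auto', 'direct', 'fft'}
        'direct' evaluates the per-lag sum explicitly; 'fft' uses the
        autocorrelation identity (O(N log N), preferred for long tracks);
        'auto' picks by track length.
    """
    N = len(traj)
    if N < 2:
        raise ValueError("MSD needs at least 2 points")
    if not traj.is_contiguous:
        raise ValueError(
            f"track {traj.track_id} has frame gaps; reindex_blink_gaps first"
        )
    if max_lag is None:
        max_lag = N - 1
    max_lag = min(int(max_lag), N - 1)
    if method == "auto":
        method = "fft" if N > _FFT_THRESHOLD else "direct"
    f = {"direct": _msd_1d_direct, "fft": _msd_1d_fft}[method]
    msd = f(traj.x, max_lag) + f(traj.y, max_lag)
    lags_n = np.arange(1, max_lag + 1)
    return MSDCurve(lags=lags_n * traj.dt, msd=msd, n_pairs=N - lags_n,
                    N=N, dt=traj.dt)


def ensemble_msd(tracks, max_lag: int, method: str = "auto") -> tuple[np.ndarray, np.ndarray]:
    """Mean of the per-track time-averaged MSDs at lags 1..max_lag.

    All tracks must have at least ``max_lag + 1`` points.  Returns
    ``(lag_times_s, mean_msd_um2)``.
    """
    curves = [compute_msd(tr, max_lag=max_lag, method=method) for tr in tracks]
    msd = np.mean([c.msd for c in curves], axis=0)
    return curves[0].lags, msd


def fit_d24(msd: MSDCurve) -> tuple[float, float]:
    """Short-lag diffusion coefficient from the first four MSD points.

    Ordinary least squares of ``msd = 4*D_24*t + offset`` over lags 1-4;
    returns ``(D_24, offset)`` in (um^2/s, um^2).  The offset absorbs the
    localization-noise floor (~4 sigma^2).
    """
    if msd.N < 5:
        raise ValueError("fit_d24 needs lags 1..4, i.e. N >= 5")
    t = msd.lags[:4]
    y = msd.msd[:4]
    slope, intercept = np.polyfit(t, y, 1)
    return float(slope / 4.0), float(intercept)


def fit_alpha(msd: MSDCurve, max_lag: int | None = None,
              n_restarts: int = 3) -> PowerLawFit:
    """Anomalous-diffusion fit ``msd = 4*D_alpha*t^alpha``.

    Nonlinear least squares with bounds ``alpha in [0, 2]``, ``D_alpha > 0``,
    initialized at alpha = 1 with D from the short-lag fit; a few perturbed
    restarts guard against local minima.  Fits the whole curve by default
    (``max_lag`` caps it, e.g. N // 2).
    """
    if msd.N < 10:
        raise ValueError("fit_alpha needs N >= 10")
    t = msd.lags if max_lag is None else msd.lags[:max_lag]
    y = msd.msd if max_lag is None else msd.msd[:max_lag]
    pos = y > 0
    if pos.sum() < 3:
        return PowerLawFit(np.nan, np.nan, False, np.inf)
    d0 = max(fit_d24(msd)[0], 1e-8)

    def model(t, D, a):
        return 4.0 * D * np.power(t, a)

    best = None
    starts = [(d0, 1.0)] + [
        (d0 * f, a0) for f, a0 in ((0.5, 0.6), (2.0, 1.4), (1.0, 0.3))
    ][: max(0, n_restarts - 1)]
    for D0, a0 in starts:
        try:
            popt, _ = optimize.curve_fit(
                model, t[pos], y[pos], p0=[D0, a0],
                bounds=([1e-12, 0.0], [np.inf, 2.0]), maxfev=2000,
            )
        except (RuntimeError, ValueError):
            continue
        res = float(np.sum((model(t[pos], *popt) - y[pos]) ** 2))
        if best is None or res < best[2]:
            best = (float(popt[0]), float(popt[1]), res)
    if best is None:
        return PowerLawFit(np.nan, np.nan, False, np.inf)
    return PowerLawFit(D_alpha=best[0], alpha=best[1], converged=True,
                       residual=best[2])
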