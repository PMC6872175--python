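"""Relative-deviation (RD) motion-type classification.

For a Brownian track the MSD grows linearly, so the MSD observed at a
probe lag n should match the short-lag extrapolation ``4 * D_24 * n * dt``.
The relative deviation

    RD(N, n) = MSD(n*dt) / (4 * D_24 * n * dt)

is therefore ~1 for free diffusion, < 1 when confinement caps the MSD, and
> 1 when drift inflates it.  Because a finite track's time-averaged MSD is
noisy, the null band of RD depends on track length N; it is calibrated by
Monte-Carlo simulation of Brownian tracks (D = 0.1 um^2/s) at a ladder of
experimentally relevant lengths, recording the 2.5th and 97.5th empirical
percentiles of RD(N, 25) per length.  A straight line fitted to the 2.5th
percentiles versus N is the lower boundary: tracks with RD below it are
classified *restricted*, everything else *free* (directed transport is
deliberately ignored for membrane proteins, so values above the 97.5th
percentile curve still count as free; the 4th-order polynomial fitted to
the upper percentiles is retained for audit).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .msd import compute_msd, fit_d24
from .simulate import SimConfig, simulate_brownian
from .tracks import Trajectory

logger = logging.getLogger(__name__)

#: Probe lag (frames) at which RD is evaluated.
DEFAULT_RD_LAG = 25

DEFAULT_CALIB_LENGTHS = (100, 200, 300, 400, 500, 600)
DEFAULT_CALIB_N_PER_LENGTH = 1000
DEFAULT_CALIB_D = 0.1

#: How far (frames) outside the calibrated N range boundaries may be
#: evaluated before a warning is issued.
EXTRAPOLATION_MARGIN = 50

MOTION_LABELS = ("immobile", "restricted", "free")


@dataclass(frozen=True)
class RDValue:
    """Relative deviation of one track at probe lag n."""

    rd: float
    n: int
    N: int
    d24: float

    @property
    def valid(self) -> bool:
        return np.isfinite(self.rd)


def compute_rd(traj: Trajectory, n: int = DEFAULT_RD_LAG) -> RDValue:
    """RD(N, n) = MSD(n*dt) / (4 * D_24 * n * dt).

    The denominator uses the short-lag slope only; the fitted offset is not
    part of the Brownian extrapolation.  Tracks whose D_24 estimate is not
    positive get ``rd = nan`` (unclassifiable) rather than an error, since
    they occur at low rates in any noisy ensemble.
    """
    N = len(traj)
    if N < 2 * n:
        raise ValueError(f"track length {N} < 2*n = {2 * n}; lag-{n} MSD too noisy")
    curve = compute_msd(traj, max_lag=n)
    d24, _ = fit_d24(curve)
    if d24 <= 0:
        logger.info("track %s: non-positive D_24 (%.3g), RD undefined",
                    traj.track_id, d24)
        return RDValue(rd=np.nan, n=n, N=N, d24=d24)
    rd = curve.at_lag(n) / (4.0 * d24 * n * traj.dt)
    return RDValue(rd=float(rd), n=n, N=N, d24=d24)


@dataclass
class RDCalibration:
    """Simulated null percentiles of RD versus track length and their fits.

    ``lower_fit`` holds (slope, intercept) of the line through the 2.5th
    percentile points; ``upper_fit`` the 4th-order polynomial coefficients
    (numpy order, highest power first) through the 97.5th percentile points.
    """

    lengths: list
    p2_5: list
    p97_5: list
    lower_fit: list
    upper_fit: list
    sim_params: dict = field(default_factory=dict)

    def lower_boundary(self, N) -> np.ndarray | float:
        slope, intercept = self.lower_fit
        return slope * np.asarray(N, dtype=float) + intercept

    def upper_boundary(self, N) -> np.ndarray | float:
        return np.polyval(self.upper_fit, np.asarray(N, dtype=float))

    def check_range(self, N: int) -> None:
        lo = min(self.lengths) - EXTRAPOLATION_MARGIN
        hi = max(self.lengths) + EXTRAPOLATION_MARGIN
        if not lo <= N <= hi:
            warnings.warn(
                f"track length {N} outside calibrated range "
                f"[{min(self.lengths)}, {max(self.lengths)}]; boundary "
                "extrapolated", stacklevel=3,
            )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "lengths": list(self.lengths),
                    "p2_5": list(self.p2_5),
                    "p97_5": list(self.p97_5),
                    "lower_fit": list(self.lower_fit),
                    "upper_fit": list(self.upper_fit),
                    "sim_params": self.sim_params,
                },
                fh, indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "RDCalibration":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def calibrate_cutoffs(
    lengths=DEFAULT_CALIB_LENGTHS,
    n_per_length: int = DEFAULT_CALIB_N_PER_LENGTH,
    D: float = DEFAULT_CALIB_D,
    dt: float = 0.1,
    n: int = DEFAULT_RD_LAG,
    seed: int = 0,
    upper_order: int = 4,
) -> RDCalibration:
    """Monte-Carlo calibration of the RD null band versus track length.

    For each length N, simulates ``n_per_length`` noise-free Brownian
    tracks at diffusivity D, computes RD(N, n) for each, and records the
    empirical 2.5th / 97.5th percentiles.  RD is dimensionless, so the
    resulting boundaries are insensitive to the D and dt used.
    """
    lengths = sorted(int(N) for N in lengths)
    if len(lengths) < 2:
        raise ValueError("need at least 2 distinct lengths")
    if n_per_length < 100:
        raise ValueError("need at least 100 tracks per length for stable percentiles")
    if len(lengths) < upper_order + 1:
        raise ValueError(
            f"{len(lengths)} length points cannot determine an order-"
            f"{upper_order} upper fit"
        )
    p_lo, p_hi = [], []
    for i, N in enumerate(lengths):
        cfg = SimConfig(n_tracks=n_per_length, n_steps=N, dt=dt, D=D,
                        mode="brownian", seed=seed + i)
        rds = np.array([compute_rd(tr, n=n).rd for tr in simulate_brownian(cfg)])
        rds = rds[np.isfinite(rds)]
        p_lo.append(float(np.percentile(rds, 2.5)))
        p_hi.append(float(np.percentile(rds, 97.5)))
    arr_N = np.asarray(lengths, dtype=float)
    lower = np.polyfit(arr_N, p_lo, 1)
    upper = np.polyfit(arr_N, p_hi, upper_order)
    return RDCalibration(
        lengths=lengths, p2_5=p_lo, p97_5=p_hi,
        lower_fit=[float(c) for c in lower],
        upper_fit=[float(c) for c in upper],
        sim_params={"n_per_length": n_per_length, "D": D, "dt": dt,
                    "n": n, "seed": seed},
    )


def classify_track(rd: RDValue, calib: RDCalibration) -> str:
    """'restricted' when RD falls below the fitted lower boundary, else 'free'."""
    if not rd.valid:
        raise ValueError("RD undefined (non-positive D_24); track unclassifiable")
    calib.check_range(rd.N)
    return "restricted" if rd.rd < float(calib.lower_boundary(rd.N)) else "free"


@dataclass
class ClassificationSummary:
    labels: dict           # track_id -> label in MOTION_LABELS or 'unclassifiable'
    fractions: dict        # label -> fraction of all analyzed tracks
    counts: dict


def classify_trackset(trackset, calib: RDCalibration, d_mle: dict | None = None,
                      immobile_threshold: float | None = None,
                      n: int = DEFAULT_RD_LAG) -> ClassificationSummary:
    """Label every track immobile / restricted / free.

    ``d_mle`` maps track_id to a precomputed MLE diffusion coefficient; when
    given, tracks below the immobile threshold are labelled immobile and
    excluded from RD analysis, mirroring the immobilized-emitter filter.
    """
    from .diffusion import IMMOBILE_THRESHOLD

    thr = IMMOBILE_THRESHOLD if immobile_threshold is None else immobile_threshold
    labels = {}
    for tr in trackset:
        if d_mle is not None and d_mle[tr.track_id] < thr:
            labels[tr.track_id] = "immobile"
            continue
        rd = compute_rd(tr, n=n)
        labels[tr.track_id] = classify_track(rd, calib) if rd.valid else "unclassifiable"
    total = max(len(labels), 1)
    counts = {}
    for lab in labels.values():
        counts[lab] = counts.get(lab, 0) + 1
    fractions = {lab: c / total for lab, c in counts.items()}
    return ClassificationSummary(labels=labels, fractions=fractions, counts=counts)
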