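"""Synthetic 2D trajectory generation with known ground truth.

Emulates the statistical structure of quantum-dot SPT data on live-cell
membranes: Brownian walks at D ~ 0.01-0.1 um^2/s, confinement in ~200 nm
domains (reflective square well or parabolic trap), directed drift,
immobilized emitters, Markov switching between diffusive states, Gaussian
localization noise (sigma ~ 25 nm) and blink gaps of at most 10 frames.

Every stochastic operation takes an explicit seed; a fixed seed gives
bit-identical output.  Per-dimension Brownian steps have variance
``2 * D * dt`` so the 2D ensemble MSD is ``4 * D * t``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace as _dc_replace

import numpy as np

from .tracks import MAX_BLINK_GAP, TrackSet, Trajectory

MODES = ("brownian", "confined_square", "confined_parabolic", "directed",
         "immobile", "switching")


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Scenario parameters for trajectory simulation.

    Attributes
    ----------
    n_tracks, n_steps : int
        Number of trajectories and frames per trajectory.
    dt : float
        Frame interval in seconds.
    D : float
        Diffusion coefficient in um^2/s.
    mode : str
        One of ``brownian, confined_square, confined_parabolic, directed,
        immobile, switching``.
    L : float
        Side of the reflective square well in um (confined_square).
    trap_size : float
        Confinement-domain diameter in um for the parabolic trap; the
        stationary spread is ``trap_size / 4`` per dimension so ~95% of
        positions fall inside the domain.
    v : tuple of float
        Drift velocity (um/s) for directed motion.
    loc_sigma : float
        Localization-noise standard deviation in um.
    blink_p : float
        Per-frame blink-off probability.
    blink_max_gap : int
        Longest run of frames that blinking may remove.
    blur_substeps : int
        Camera-exposure emulation: each emitted position is the average of
        this many within-frame sub-positions.  1 (default) models an
        instantaneous exposure (blur coefficient R = 0); large values
        approach full-frame continuous exposure, R -> 1/6 (the discrete
        average of s sub-positions has R = (1 - 1/s^2) / 6).
    seed : int
        Seed for all randomness in the scenario.
    """

    n_tracks: int = 100
    n_steps: int = 300
    dt: float = 0.1
    D: float = 0.1
    mode: str = "brownian"
    L: float = 0.2
    trap_size: float = 0.2
    v: tuple = (0.0, 0.0)
    loc_sigma: float = 0.0
    blink_p: float = 0.0
    blink_max_gap: int = MAX_BLINK_GAP
    blur_substeps: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_steps < 2:
            raise SimConfigError("n_steps must be >= 2")
        if self.dt <= 0:
            raise SimConfigError("dt must be positive")
        if self.D < 0:
            raise SimConfigError("D must be non-negative")
        if self.mode not in MODES:
            raise SimConfigError(f"unknown mode {self.mode!r}")
        if self.mode == "confined_square" and self.L <= 0:
            raise SimConfigError("L must be positive for confined_square")
        if self.mode == "confined_parabolic" and self.trap_size <= 0:
            raise SimConfigError("trap_size must be positive for confined_parabolic")
        if not (0 <= self.blink_p < 1):
            raise SimConfigError("blink_p must be in [0, 1)")
        if self.loc_sigma < 0:
            raise SimConfigError("loc_sigma must be non-negative")
        if self.blur_substeps < 1:
            raise SimConfigError("blur_substeps must be >= 1")

    def replace(self, **kw) -> "SimConfig":
        return _dc_replace(self, **kw)


@dataclass
class GroundTruth:
    """Per-track truth labels for parameter-recovery tests.

    ``state_sequence[track_id]`` gives one hidden-state label per simulated
    frame (switching mode only).
    """

    true_mode: dict = field(default_factory=dict)
    true_D: dict = field(default_factory=dict)
    state_sequence: dict = field(default_factory=dict)


def _tracks_from_xy(xs, ys, cfg: SimConfig) -> TrackSet:
    frames = np.arange(cfg.n_steps, dtype=np.int64)
    tracks = [
        Trajectory(track_id=i, frames=frames, x=xs[i], y=ys[i], dt=cfg.dt)
        for i in range(cfg.n_tracks)
    ]
    return TrackSet(tracks, dt=cfg.dt, loc_sigma=cfg.loc_sigma,
                    source=f"sim:{cfg.mode}")


def simulate_brownian(cfg: SimConfig) -> TrackSet:
    """Unconfined 2D random walks with per-dimension step variance 2*D*dt.

    With ``blur_substeps > 1`` the walk is generated on a finer time grid
    and each emitted position is the within-frame average, emulating the
    motion blur of a finite camera exposure.
    """
    if cfg.mode not in ("brownian", "immobile"):
        raise SimConfigError(f"simulate_brownian requires mode='brownian', got {cfg.mode!r}")
    rng = np.random.default_rng(cfg.seed)
    s = cfg.blur_substeps
    if s == 1:
        step_sd = np.sqrt(2.0 * cfg.D * cfg.dt)
        steps = rng.normal(0.0, step_sd, size=(cfg.n_tracks, cfg.n_steps - 1, 2))
        pos = np.zeros((cfg.n_tracks, cfg.n_steps, 2))
        np.cumsum(steps, axis=1, out=pos[:, 1:, :])
    else:
        fine_sd = np.sqrt(2.0 * cfg.D * cfg.dt / s)
        n_fine = cfg.n_steps * s
        steps = rng.normal(0.0, fine_sd, size=(cfg.n_tracks, n_fine - 1, 2))
        fine = np.zeros((cfg.n_tracks, n_fine, 2))
        np.cumsum(steps, axis=1, out=fine[:, 1:, :])
        pos = fine.reshape(cfg.n_tracks, cfg.n_steps, s, 2).mean(axis=2)
    return _tracks_from_xy(pos[:, :, 0], pos[:, :, 1], cfg)


def simulate_immobile(cfg: SimConfig) -> TrackSet:
    """Emitters fixed in space (D = 0); pair with localization noise."""
    return simulate_brownian(cfg.replace(D=0.0, mode="brownian"))


def _reflect(pos: np.ndarray, L: float) -> np.ndarray:
    # Fold positions into [0, L] by reflection (triangle wave, period 2L);
    # exact for steps of any size.
    y = np.mod(pos, 2.0 * L)
    return np.where(y > L, 2.0 * L - y, y)


def simulate_confined(cfg: SimConfig) -> TrackSet:
    """Brownian motion confined to a small membrane domain.

    ``confined_square``: reflective boundaries at [0, L]^2 (infinitely high
    square well).  ``confined_parabolic``: exact Ornstein-Uhlenbeck updates
    with stationary standard deviation ``trap_size / 4`` per dimension and
    short-time diffusivity D.  Initial positions are drawn from the
    stationary distribution so ensemble statistics are equilibrated from
    frame 0.
    """
    if cfg.mode not in ("confined_square", "confined_parabolic"):
        raise SimConfigError("simulate_confined requires a confined mode")
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_tracks, cfg.n_steps
    step_sd = np.sqrt(2.0 * cfg.D * cfg.dt)
    if cfg.mode == "confined_square":
        pos = np.empty((n, m, 2))
        pos[:, 0, :] = rng.uniform(0.0, cfg.L, size=(n, 2))
        steps = rng.normal(0.0, step_sd, size=(n, m - 1, 2))
        for j in range(1, m):
            pos[:, j, :] = _reflect(pos[:, j - 1, :] + steps[:, j - 1, :], cfg.L)
    else:
        sd_stat = cfg.trap_size / 4.0
        if cfg.D == 0:
            a, noise_sd = 1.0, 0.0
        else:
            theta = cfg.D / sd_stat**2  # relaxation rate, 1/s
            a = np.exp(-theta * cfg.dt)
            noise_sd = sd_stat * np.sqrt(1.0 - a**2)
        pos = np.empty((n, m, 2))
        pos[:, 0, :] = rng.normal(0.0, sd_stat, size=(n, 2))
        noise = rng.normal(0.0, 1.0, size=(n, m - 1, 2))
        for j in range(1, m):
            pos[:, j, :] = a * pos[:, j - 1, :] + noise_sd * noise[:, j - 1, :]
    return _tracks_from_xy(pos[:, :, 0], pos[:, :, 1], cfg)


def simulate_directed(cfg: SimConfig) -> TrackSet:
    """Brownian walk plus constant drift ``v`` (um/s)."""
    if cfg.mode != "directed":
        raise SimConfigError("simulate_directed requires mode='directed'")
    base = simulate_brownian(cfg.replace(mode="brownian"))
    vx, vy = cfg.v
    tracks = []
    for tr in base:
        tracks.append(
            Trajectory(track_id=tr.track_id, frames=tr.frames,
                       x=tr.x + vx * tr.t, y=tr.y + vy * tr.t, dt=tr.dt)
        )
    return TrackSet(tracks, dt=cfg.dt, loc_sigma=cfg.loc_sigma, source="sim:directed")


def simulate_switching(cfg: SimConfig, D_states, trans_matrix):
    """Markov switching between diffusive states.

    The hidden state evolves as a discrete Markov chain with row-stochastic
    ``trans_matrix``; each displacement is drawn from the active state's
    isotropic Gaussian (per-dimension variance ``2 * D_state * dt``).
    The initial state is drawn from the chain's stationary distribution.

    Returns ``(TrackSet, GroundTruth)`` with one state label per frame.
    """
    D_states = np.asarray(D_states, dtype=float)
    P = np.asarray(trans_matrix, dtype=float)
    K = len(D_states)
    if np.any(D_states < 0):
        raise SimConfigError("all D_states must be non-negative")
    if P.shape != (K, K) or np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0):
        raise SimConfigError("trans_matrix must be row-stochastic and match D_states")
    rng = np.random.default_rng(cfg.seed)
    # stationary distribution: left eigenvector of P for eigenvalue 1
    w, vl = np.linalg.eig(P.T)
    pi = np.real(vl[:, np.argmin(np.abs(w - 1.0))])
    pi = np.abs(pi) / np.abs(pi).sum()
    n, m = cfg.n_tracks, cfg.n_steps
    step_sds = np.sqrt(2.0 * D_states * cfg.dt)
    truth = GroundTruth()
    xs = np.empty((n, m))
    ys = np.empty((n, m))
    for i in range(n):
        states = np.empty(m, dtype=np.int64)
        states[0] = rng.choice(K, p=pi)
        for j in range(1, m):
            states[j] = rng.choice(K, p=P[states[j - 1]])
        # displacement j -> j+1 governed by the state occupied at frame j
        sd = step_sds[states[:-1], None]
        steps = rng.normal(0.0, 1.0, size=(m - 1, 2)) * sd
        pos = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        xs[i], ys[i] = pos[:, 0], pos[:, 1]
        truth.true_mode[i] = "switching"
        truth.true_D[i] = D_states.tolist()
        truth.state_sequence[i] = states
    return _tracks_from_xy(xs, ys, cfg), truth


def simulate(cfg: SimConfig, D_states=None, trans_matrix=None):
    """Dispatch on ``cfg.mode``; returns a TrackSet (plus GroundTruth for switching)."""
    if cfg.mode == "brownian":
        return simulate_brownian(cfg)
    if cfg.mode == "immobile":
        return simulate_immobile(cfg)
    if cfg.mode in ("confined_square", "confined_parabolic"):
        return simulate_confined(cfg)
    if cfg.mode == "directed":
        return simulate_directed(cfg)
    if cfg.mode == "switching":
        if D_states is None or trans_matrix is None:
            raise SimConfigError("switching mode needs D_states and trans_matrix")
        return simulate_switching(cfg, D_states, trans_matrix)
    raise SimConfigError(f"unknown mode {cfg.mode!r}")


def add_localization_noise(trackset: TrackSet, loc_sigma: float, seed: int = 0) -> TrackSet:
    """Add i.i.d. Gaussian noise (sd ``loc_sigma`` um) to each coordinate.

    Returns a new TrackSet; the input is not modified.
    """
    if loc_sigma < 0:
        raise SimConfigError("loc_sigma must be non-negative")
    if loc_sigma == 0:
        return trackset
    rng = np.random.default_rng(seed)
    tracks = []
    for tr in trackset:
        noise = rng.normal(0.0, loc_sigma, size=(len(tr), 2))
        tracks.append(
            Trajectory(track_id=tr.track_id, frames=tr.frames,
                       x=tr.x + noise[:, 0], y=tr.y + noise[:, 1],
                       dt=tr.dt, t=tr.t)
        )
    return TrackSet(tracks, dt=trackset.dt, loc_sigma=loc_sigma,
                    source=trackset.source)


def draw_per_track_sigma(n: int, seed: int = 0, mean: float = 0.025,
                         sd: float = 0.010, floor: float = 0.005) -> np.ndarray:
    """Per-track localization sigmas from a floored Gaussian (25 +/- 10 nm)."""
    rng = np.random.default_rng(seed)
    out = np.empty(n)
    for i in range(n):
        s = rng.normal(mean, sd)
        while s < floor:
            s = rng.normal(mean, sd)
        out[i] = s
    return out


def add_blinking(trackset: TrackSet, blink_p: float,
                 blink_max_gap: int = MAX_BLINK_GAP, seed: int = 0) -> TrackSet:
    """Remove frames in blink runs of length <= ``blink_max_gap``.

    First and last frames are always retained and surviving frame indices
    are unchanged, mimicking detector-side gaps that the reindexing step
    later collapses.
    """
    if not (0 <= blink_p < 1):
        raise SimConfigError("blink_p must be in [0, 1)")
    if blink_max_gap > MAX_BLINK_GAP:
        warnings.warn(
            f"blink_max_gap={blink_max_gap} exceeds the {MAX_BLINK_GAP}-frame "
            "continuity window; downstream reindexing will reject such gaps",
            stacklevel=2,
        )
    if blink_p == 0:
        return trackset
    rng = np.random.default_rng(seed)
    tracks = []
    for tr in trackset:
        n = len(tr)
        keep = np.ones(n, dtype=bool)
        off = rng.random(n) < blink_p
        run = 0
        for j in range(1, n - 1):
            if off[j] and run < blink_max_gap:
                keep[j] = False
                run += 1
            else:
                run = 0
        if keep.sum() < 2:
            keep[:] = True
        tracks.append(
            Trajectory(track_id=tr.track_id, frames=tr.frames[keep],
                       x=tr.x[keep], y=tr.y[keep], dt=tr.dt,
                       t=np.asarray(tr.t)[keep])
        )
    return TrackSet(tracks, dt=trackset.dt, loc_sigma=trackset.loc_sigma,
                    source=trackset.source)


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Write per-frame truth labels as CSV (track_id, frame, true_state, true_D)."""
    import pandas as pd

    rows = []
    for tid, states in truth.state_sequence.items():
        Ds = truth.true_D[tid]
        for f, s in enumerate(states):
            rows.append((tid, f, int(s), Ds[int(s)]))
    pd.DataFrame(rows, columns=["track_id", "frame", "true_state", "true_D"]).to_csv(
        path, index=False
    )
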