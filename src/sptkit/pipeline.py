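"""End-to-end analysis driver: tracks in, per-track metrics and reports out.

Stages: split tracks at over-long blink gaps -> reindex onto continuous
frame grids -> drop tracks shorter than 50 frames -> per-track diffusion
and geometry metrics -> immobile filter (D_MLE cutoff) -> relative-
deviation motion classification -> group summaries.  Every input track
lands in exactly one terminal category (too_short, immobile,
unclassifiable, restricted, free) and the stage counts are recorded in the
run log, so the bookkeeping is auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import geometry
from .diffusion import DEFAULT_BLUR_R, DEFAULT_LOC_SIGMA, IMMOBILE_THRESHOLD, DiffusionMLE
from .motion import DEFAULT_RD_LAG, RDCalibration, classify_track, compute_rd
from .msd import compute_msd, fit_alpha, fit_d24
from .tracks import MAX_BLINK_GAP, MIN_TRACK_LENGTH, TrackSet, Trajectory, reindex_blink_gaps

logger = logging.getLogger(__name__)

METRIC_COLUMNS = [
    "track_id", "N", "D_mle", "D_24", "offset", "alpha", "D_alpha",
    "aspect_ratio", "explored_area", "rd", "immobile", "category",
]

TERMINAL_CATEGORIES = ("too_short", "immobile", "unclassifiable",
                       "restricted", "free")


@dataclass
class PipelineConfig:
    """Knobs of the standard analysis pipeline (units: um, s)."""

    loc_sigma: float = DEFAULT_LOC_SIGMA
    blur_r: float = DEFAULT_BLUR_R
    immobile_threshold: float = IMMOBILE_THRESHOLD
    min_frames: int = MIN_TRACK_LENGTH
    rd_lag: int = DEFAULT_RD_LAG
    max_gap: int = MAX_BLINK_GAP
    calibration: RDCalibration | None = None
    classify: bool = True


@dataclass
class PipelineResult:
    metrics: pd.DataFrame
    counts: dict = field(default_factory=dict)
    fractions: dict = field(default_factory=dict)
    log: list = field(default_factory=list)


def split_at_long_gaps(traj: Trajectory, max_gap: int = MAX_BLINK_GAP):
    """Split a track wherever a frame gap exceeds the continuity window.

    Detections separated by more than ``max_gap`` missing frames are
    treated as distinct particles; segment ids get a ``.k`` suffix.
    Segments with fewer than 2 points are dropped.
    """
    gaps = np.diff(traj.frames) - 1
    cut = np.nonzero(gaps > max_gap)[0]
    if cut.size == 0:
        return [traj]
    pieces = []
    start = 0
    bounds = list(cut + 1) + [len(traj)]
    for k, stop in enumerate(bounds):
        if stop - start >= 2:
            pieces.append(replace(
                traj,
                track_id=f"{traj.track_id}.{k}",
                frames=traj.frames[start:stop],
                x=traj.x[start:stop], y=traj.y[start:stop],
                t=np.asarray(traj.t)[start:stop],
            ))
        start = stop
    return pieces


def run_pipeline(trackset: TrackSet, config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full per-track analysis; deterministic given inputs and config."""
    cfg = config or PipelineConfig()
    if cfg.classify and cfg.calibration is None:
        raise ValueError("classification requested but no RD calibration given")
    log = [f"input: {len(trackset)} track(s)"]

    segments = []
    for tr in trackset:
        segments.extend(split_at_long_gaps(tr, cfg.max_gap))
    if len(segments) != len(trackset):
        log.append(f"gap splitting: {len(trackset)} -> {len(segments)} segment(s)")
    segments = [reindex_blink_gaps(tr, cfg.max_gap) for tr in segments]

    counts = dict.fromkeys(TERMINAL_CATEGORIES, 0)
    rows = []
    n_retained = 0
    for tr in segments:
        if len(tr) < cfg.min_frames:
            counts["too_short"] += 1
            rows.append({"track_id": tr.track_id, "N": len(tr),
                         "category": "too_short"})
            continue
        n_retained += 1
        curve = compute_msd(tr)
        d24, offset = fit_d24(curve)
        pl = fit_alpha(curve)
        geo = geometry.aspect_ratio(tr)
        mle = DiffusionMLE(tr, loc_sigma=cfg.loc_sigma, blur_r=cfg.blur_r).fit()
        row = {
            "track_id": tr.track_id, "N": len(tr), "D_mle": mle.D_mle,
            "D_24": d24, "offset": offset, "alpha": pl.alpha,
            "D_alpha": pl.D_alpha, "aspect_ratio": geo.aspect_ratio,
            "explored_area": geometry.explored_area(tr),
            "immobile": mle.D_mle < cfg.immobile_threshold,
        }
        if row["immobile"]:
            row["category"] = "immobile"
        elif cfg.classify:
            rd = compute_rd(tr, n=cfg.rd_lag)
            row["rd"] = rd.rd
            row["category"] = (classify_track(rd, cfg.calibration)
                               if rd.valid else "unclassifiable")
        else:
            row["category"] = "free"  # mobile, classification disabled
        counts[row["category"]] += 1
        rows.append(row)

    log.append(f"retained after >= {cfg.min_frames}-frame filter: {n_retained}")
    log.append(f"immobile (D_MLE < {cfg.immobile_threshold:g}): {counts['immobile']}")
    if cfg.classify:
        log.append(f"restricted: {counts['restricted']}, free: {counts['free']}, "
                   f"unclassifiable: {counts['unclassifiable']}")
    for line in log:
        logger.info("pipeline: %s", line)

    metrics = pd.DataFrame(rows, columns=METRIC_COLUMNS) if rows else \
        pd.DataFrame(columns=METRIC_COLUMNS)
    if not rows:
        import warnings

        warnings.warn("no tracks survived filtering; empty metrics table",
                      stacklevel=2)
    mobile = sum(counts[c] for c in ("restricted", "free", "unclassifiable"))
    denom = mobile + counts["immobile"]
    fractions = {c: counts[c] / denom for c in TERMINAL_CATEGORIES if denom} \
        if denom else {}
    return PipelineResult(metrics=metrics, counts=counts, fractions=fractions,
                          log=log)
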