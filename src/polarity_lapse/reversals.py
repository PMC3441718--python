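"""Single-cell reversal detection and reversal-frequency statistics.

Gliding cells move along their long axis and occasionally reverse: the
leading and lagging poles swap and the cell moves back the way it came.
Reversal frequency (reversals per 15-min observation window, frames every
30 s) is the standard single-cell readout for the Frz–RomR–MglA/MglB
polarity circuit; strains are compared with box plots whose boxes span the
25th–75th percentiles, whiskers the 10th–90th, with the mean drawn as a
line and points outside the whiskers shown as outliers.

Detection projects each between-frame displacement onto the cell's long
axis.  A frame moves "+" or "-" when the projected step exceeds
``min_step`` pixels, otherwise it is paused.  A reversal is scored when a
sustained run (``min_run`` frames or more) of one sign follows a sustained
run of the opposite sign; pauses and sub-threshold jitter between runs are
ignored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Trajectory",
    "ReversalEvents",
    "ReversalSummary",
    "detect_reversals",
    "reversal_stats",
    "summarize_tracks",
    "compare_strains",
]

DEFAULT_FRAME_INTERVAL_S = 30.0
DEFAULT_WINDOW_MIN = 15.0


@dataclass
class Trajectory:
    """Per-frame centroid track of one cell.

    positions: (n_frames, 2) x/y in pixels; axis_angle: radians per frame
    (the long-axis orientation, modulo pi); frames are uniformly spaced
    ``frame_interval_s`` apart.  ``true_reversal_frames`` is filled by the
    synthetic generator and holds the frame index at which each planted
    reversal takes effect.
    """

    cell_id: str
    positions: np.ndarray
    axis_angle: np.ndarray
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S
    true_reversal_frames: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.axis_angle = np.asarray(self.axis_angle, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be an (n_frames, 2) array")
        if len(self.axis_angle) != len(self.positions):
            raise ValueError("axis_angle length must match positions")
        if len(self.positions) < 2:
            raise ValueError("a trajectory needs at least 2 frames")

    @property
    def n_frames(self) -> int:
        return len(self.positions)

    @property
    def duration_min(self) -> float:
        return (self.n_frames - 1) * self.frame_interval_s / 60.0


@dataclass
class ReversalEvents:
    """Detected reversals for one track."""

    cell_id: str
    count: int
    event_frames: np.ndarray


@dataclass
class ReversalSummary:
    """Box-plot summary of per-cell reversal counts.

    Percentiles use linear interpolation between order statistics; outliers
    are counts strictly outside the [p10, p90] whiskers.
    """

    per_cell_counts: np.ndarray
    mean: float
    p10: float
    p25: float
    p75: float
    p90: float
    outliers: np.ndarray

    @property
    def n_cells(self) -> int:
        return len(self.per_cell_counts)


def _signed_steps(traj: Trajectory, min_step: float) -> np.ndarray:
    """Sign (+1/-1/0) of each between-frame displacement along the long axis."""
    disp = np.diff(traj.positions, axis=0)
    angles = traj.axis_angle[:-1]
    axis = np.stack([np.cos(angles), np.sin(angles)], axis=1)
    proj = np.einsum("ij,ij->i", disp, axis)
    signs = np.zeros(len(proj), dtype=int)
    signs[proj >= min_step] = 1
    signs[proj <= -min_step] = -1
    return signs


def detect_reversals(
    traj: Trajectory, min_run: int = 2, min_step: float = 1.0
) -> ReversalEvents:
    """Count direction reversals in one track.

    Parameters
    ----------
    min_run : frames of sustained same-direction movement required on each
        side of a reversal (default 2, i.e. 1 min at 30-s frames; suppresses
        jitter-induced sign flips).  Use 1 for noiseless data.
    min_step : minimum projected displacement in pixels for a frame to count
        as moving rather than paused.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    if traj.n_frames < 2 * min_run:
        raise ValueError(
            f"track {traj.cell_id!r} has {traj.n_frames} frames; "
            f"need at least {2 * min_run} for min_run={min_run}"
        )
    signs = _signed_steps(traj, min_step)
    # maximal runs of identical nonzero sign, pauses dropped
    runs: list[tuple[int, int, int]] = []  # (sign, length, start_frame)
    for i, s in enumerate(signs):
        if s == 0:
            continue
        if runs and runs[-1][0] == s and _gap_is_pause(signs, runs[-1], i):
            sign, length, start = runs[-1]
            runs[-1] = (sign, length + 1, start)
        else:
            runs.append((s, 1, i))
    kept = [r for r in runs if r[1] >= min_run]
    events = []
    prev_sign = None
    for sign, _length, start in kept:
        if prev_sign is not None and sign != prev_sign:
            # reversal takes effect at the first frame of the new run
            events.append(start + 1)
        prev_sign = sign
    return ReversalEvents(
        cell_id=traj.cell_id, count=len(events), event_frames=np.asarray(events)
    )


def _gap_is_pause(signs: np.ndarray, last_run: tuple[int, int, int], i: int) -> bool:
    """True when every step between the end of last_run and step i is paused."""
    end = last_run[2] + last_run[1]
    return bool(np.all(signs[end:i] == 0))


def reversal_stats(counts) -> ReversalSummary:
    """Mean, 10/25/75/90th percentiles and outliers of per-cell counts."""
    arr = np.asarray(list(counts), dtype=float)
    if arr.size == 0:
        raise ValueError("reversal_stats requires at least one count")
    p10, p25, p75, p90 = np.percentile(arr, [10, 25, 75, 90], method="linear")
    outliers = arr[(arr < p10) | (arr > p90)]
    return ReversalSummary(
        per_cell_counts=arr,
        mean=float(arr.mean()),
        p10=float(p10),
        p25=float(p25),
        p75=float(p75),
        p90=float(p90),
        outliers=outliers,
    )


def summarize_tracks(
    trajectories,
    min_run: int = 2,
    min_step: float = 1.0,
    window_min: float = DEFAULT_WINDOW_MIN,
    min_coverage: float = 0.8,
) -> tuple[ReversalSummary, list[ReversalEvents]]:
    """Detect reversals on each track and summarize per-window counts.

    Tracks covering at least ``min_coverage`` of the observation window are
    normalized to reversals per window; shorter tracks are excluded and
    logged.
    """
    events: list[ReversalEvents] = []
    counts: list[float] = []
    for traj in trajectories:
        coverage = traj.duration_min / window_min
        if coverage < min_coverage:
            logger.warning(
                "excluding track %s: covers %.0f%% of the %g-min window",
                traj.cell_id, 100 * coverage, window_min,
            )
            continue
        ev = detect_reversals(traj, min_run=min_run, min_step=min_step)
        events.append(ev)
        counts.append(ev.count / coverage)
    if not counts:
        raise ValueError("no track covers the observation window")
    return reversal_stats(counts), events


def compare_strains(
    summaries: dict[str, ReversalSummary],
    reference: str,
    factor: float = 2.0,
) -> list[dict]:
    """Order strains by mean reversal frequency and flag against a reference.

    A strain is flagged hyper-reversing when its mean exceeds the reference
    mean by more than ``factor``, hypo-reversing when the reference mean
    exceeds it by more than ``factor``.
    """
    if len(summaries) < 2:
        raise ValueError("compare_strains requires at least two strains")
    if reference not in summaries:
        raise ValueError(f"unknown reference strain {reference!r}")
    ref_mean = summaries[reference].mean
    report = []
    for strain, summary in sorted(summaries.items(), key=lambda kv: kv[1].mean):
        flag = "none"
        if strain != reference:
            if summary.mean > factor * ref_mean:
                flag = "hyper-reversing"
            elif ref_mean > factor * summary.mean:
                flag = "hypo-reversing"
        report.append(
            {
                "strain": strain,
                "mean": summary.mean,
                "p25": summary.p25,
                "p75": summary.p75,
                "n_cells": summary.n_cells,
                "flag": flag,
                "reference": strain == reference,
            }
        )
    return report
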