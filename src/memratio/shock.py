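"""Hyposmotic-shock time-lapse analysis.

Cell swelling after medium dilution flattens the plasma membrane and
releases curvature-coupled proteins; the readout is the loss of
integrated membrane fluorescence over time. This module builds per-cell
integrated-intensity traces from a time-lapse stack using a membrane ROI
frozen on a pre-shock frame, normalizes each trace to the mean of its
first three points, and computes the percentage intensity change

    delta_I = ((I1 - I0) / I0) * 100

where I0 is the mean of the first three (pre-shock) points and I1 is
either the mean from point 4 to the end of the trace (the "methods"
window convention) or the mean of the last four points (the "caption"
convention). The two conventions disagree on traces that are still
decaying at point 4, so every result records which one was used.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import TimeLapse
from .segment import ROIPair

__all__ = [
    "ShockProtocol",
    "Trace",
    "DeltaIResult",
    "build_trace",
    "normalize_trace",
    "delta_I",
    "summarize_shock",
    "diluted_osmolarity",
]

WINDOW_CONVENTIONS = ("methods", "caption")


@dataclass
class ShockProtocol:
    """Timing and osmolarity of the shock experiment.

    Defaults: one frame every 30 s, shock after 1 min of imaging (three
    pre-shock frames at t = 0, 30, 60 s), 5 min of post-shock imaging,
    medium diluted 1:6 from 300 mM. A control run (fresh full-osmolarity
    medium) is ``dilution_ratio = 1``.
    """

    frame_interval: float = 30.0  # s
    pre_shock_duration: float = 60.0  # s
    post_shock_duration: float = 300.0  # s
    stock_osmolarity: float = 300.0  # mM
    dilution_ratio: float = 6.0  # unitless

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.n_pre_frames < 3:
            raise ValueError(
                "pre-shock window must contain at least 3 frames "
                f"(got {self.n_pre_frames} at {self.frame_interval} s cadence)"
            )

    @property
    def n_pre_frames(self) -> int:
        """Frames acquired at or before the shock (t = 0 .. pre_shock_duration)."""
        return int(self.pre_shock_duration // self.frame_interval) + 1

    @property
    def n_post_frames(self) -> int:
        return int(self.post_shock_duration // self.frame_interval)

    def frame_times(self) -> np.ndarray:
        n = self.n_pre_frames + self.n_post_frames
        return np.arange(n) * self.frame_interval


@dataclass
class Trace:
    """Integrated membrane intensity versus time for one cell."""

    cell_id: int
    values: np.ndarray  # a.u. per frame
    times: np.ndarray  # s
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if len(self.values) != len(self.times):
            raise ValueError("values and times must have equal length")
        if len(self.values) < 4:
            raise ValueError("a trace needs at least 4 points")
        if np.any(self.values < 0):
            raise ValueError("trace values must be non-negative")


@dataclass
class DeltaIResult:
    cell_id: int
    I0: float  # a.u., pre-shock window mean
    I1: float  # a.u., post window mean
    delta_I: float  # percent
    window_convention: str


def build_trace(stack: TimeLapse, rois: ROIPair, protocol: ShockProtocol | None = None,
                ) -> Trace:
    """Sum raw intensity over the frozen membrane ROI in every frame.

    The ROI comes from a pre-shock frame and is reused unchanged across
    the movie (the same cells are re-imaged); late-frame membrane drift
    off the ROI registers as intensity loss, which is the intended
    readout.
    """
    mem = rois.membrane_mask
    if mem.shape != stack.frames.shape[1:]:
        raise ValueError(
            f"cell {rois.cell_id}: ROI shape {mem.shape} does not match "
            f"frame shape {stack.frames.shape[1:]}"
        )
    values = stack.frames[:, mem].sum(axis=1)
    return Trace(cell_id=rois.cell_id, values=values, times=stack.times)


def normalize_trace(t: Trace) -> Trace:
    """Divide a trace by the mean of its first three points.

    Makes shock responses comparable across cells with different
    expression levels; the mean of the first three normalized points is
    exactly 1.
    """
    if len(t.values) < 3:
        raise ValueError("normalization needs at least 3 points")
    baseline = t.values[:3].mean()
    if baseline <= 0:
        raise ValueError(f"cell {t.cell_id}: zero pre-shock baseline")
    return replace(t, values=t.values / baseline, normalized=True)


def delta_I(t: Trace, convention: str = "methods") -> DeltaIResult:
    """Percentage membrane-intensity change between pre- and post-shock windows.

    I0 is always the mean of points 1-3. Under the "methods" convention
    I1 is the mean from point 4 to the end (needs >= 4 points); under the
    "caption" convention I1 is the mean of the last 4 points (needs >= 7
    so the windows cannot overlap). delta_I is invariant to trace
    normalization because the baseline factor cancels in the ratio.
    """
    if convention not in WINDOW_CONVENTIONS:
        raise ValueError(f"convention must be one of {WINDOW_CONVENTIONS}")
    v = t.values
    min_len = 4 if convention == "methods" else 7
    if len(v) < min_len:
        raise ValueError(
            f"cell {t.cell_id}: trace of {len(v)} points too short for the "
            f"{convention!r} convention (needs >= {min_len})"
        )
    I0 = float(v[:3].mean())
    if I0 <= 0:
        raise ValueError(f"cell {t.cell_id}: non-positive pre-shock mean")
    I1 = float(v[3:].mean()) if convention == "methods" else float(v[-4:].mean())
    return DeltaIResult(cell_id=t.cell_id, I0=I0, I1=I1,
                        delta_I=(I1 - I0) / I0 * 100.0,
                        window_convention=convention)


def summarize_shock(results: list[DeltaIResult]) -> tuple[float, float, int]:
    """Cohort mean and sample SD (n-1 denominator) of per-cell delta_I values."""
    if len(results) < 2:
        raise ValueError("need at least 2 cells to summarize")
    conventions = {r.window_convention for r in results}
    if len(conventions) > 1:
        raise ValueError(f"mixed window conventions in one cohort: {conventions}")
    deltas = np.array([r.delta_I for r in results])
    return float(deltas.mean()), float(deltas.std(ddof=1)), len(deltas)


def diluted_osmolarity(protocol: ShockProtocol) -> float:
    """Post-shock medium osmolarity in mM: stock divided by the dilution ratio."""
    if protocol.dilution_ratio < 1:
        raise ValueError("dilution_ratio must be >= 1")
    return protocol.stock_osmolarity / protocol.dilution_ratio
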