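"""Behavioral metrics: activation, recruitment, preference index, occupancy maps.

All three metrics are computed from filtered 3D trajectories against the
run schedule.  Approach to a floor stimulus is scored by passage through a
fictive vertical cylinder (default 14 cm diameter x 4 cm height) centered
on the stimulus with its base on the tunnel floor.  Dwell times count
discrete 60 Hz samples divided by the frame rate; there is no sub-frame
interpolation of entries and exits.  Undefined ratios (zero denominators)
propagate as NaN, never as 0 — they carry no weight downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import RunRecord, StimulusPeriod, Trajectory, TunnelGeometry

#: Default occupancy bin area, cm^2 (bin side = sqrt(area)).
DEFAULT_BIN_AREA_CM2 = 0.3


class ConfigurationError(ValueError):
    """Metric configuration violates a geometric precondition."""


@dataclass(frozen=True)
class ResponseVolume:
    """Fictive vertical cylinder over a floor stimulus used to score approach."""

    center_xy: tuple[float, float]
    z_base: float = 0.0
    diameter: float = 14.0
    height: float = 4.0

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.height <= 0:
            raise ConfigurationError("ResponseVolume diameter and height must be > 0")
        object.__setattr__(self, "center_xy", tuple(float(v) for v in self.center_xy))

    def contains(self, x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
        """Boundary-inclusive membership per sample."""
        dx = np.asarray(x, float) - self.center_xy[0]
        dy = np.asarray(y, float) - self.center_xy[1]
        r2 = dx * dx + dy * dy
        radius = self.diameter / 2.0
        return (
            (r2 <= radius * radius)
            & (np.asarray(z, float) >= self.z_base)
            & (np.asarray(z, float) <= self.z_base + self.height)
        )


@dataclass(frozen=True)
class PreferenceRecord:
    """Per-trajectory, per-period dwell times and the derived preference index.

    ``pi = (t_test - t_control) / (t_test + t_control)``; NaN when the
    trajectory never entered either volume (weight 0).
    """

    run_id: str
    traj_id: str
    period_id: str
    t_test: float
    t_control: float
    weight: float
    pi: float


@dataclass(frozen=True)
class PeriodSummary:
    """Run x period counts: activation, recruitment and stimulus metadata."""

    run_id: str
    period_id: str
    phase: str
    test_channel: str
    control_channel: str
    intensity: float
    co2_percent: float
    odor: str
    n_trajectories: int
    n_recruited: int
    recruitment: float  # NaN when no trajectories were active


@dataclass
class OccupancyMap:
    """Normalized 2D residency histogram (percent), top or side projection."""

    view: str
    bin_size: float
    x_edges: np.ndarray
    y_edges: np.ndarray
    grid: np.ndarray  # percent, shape (len(x_edges)-1, len(y_edges)-1)
    n_points: int = 0

    @property
    def empty(self) -> bool:
        return self.n_points == 0

    def save_text(self, path: str | Path) -> None:
        header = (
            f"view={self.view} bin_size={self.bin_size:.6g} "
            f"n_points={self.n_points} rows=x cols={'y' if self.view == 'top' else 'z'}"
        )
        np.savetxt(path, self.grid, header=header)


def filter_trajectories(
    trajectories: Iterable[Trajectory], min_frames: int = 90
) -> list[Trajectory]:
    """Keep trajectories with at least ``min_frames`` samples (default 90 = 1.5 s).

    Order is preserved; an empty result is allowed.
    """
    if min_frames < 1:
        raise ValueError("min_frames must be >= 1")
    return [tr for tr in trajectories if len(tr) >= min_frames]


def time_in_volume(
    trajectory: Trajectory,
    volume: ResponseVolume,
    period: StimulusPeriod | None = None,
    frame_rate: float = 60.0,
) -> float:
    """Seconds of dwell inside ``volume`` during ``period`` (whole trajectory if None)."""
    inside = volume.contains(trajectory.x, trajectory.y, trajectory.z)
    if period is not None:
        inside &= period.contains_t(trajectory.t)
    return float(inside.sum()) / frame_rate


def preference_index(
    trajectory: Trajectory,
    test_volume: ResponseVolume,
    control_volume: ResponseVolume,
    period: StimulusPeriod,
    frame_rate: float = 60.0,
) -> PreferenceRecord:
    """Preference of one trajectory for the test over the control stimulus.

    The two cylinders must be disjoint (center separation greater than the
    diameter).  ``pi`` is NaN — flagged undefined, not 0 — when the
    trajectory entered neither volume during the period.
    """
    sep = float(np.hypot(
        test_volume.center_xy[0] - control_volume.center_xy[0],
        test_volume.center_xy[1] - control_volume.center_xy[1],
    ))
    if sep <= max(test_volume.diameter, control_volume.diameter):
        raise ConfigurationError(
            f"test and control volumes overlap (center separation {sep:.1f} cm)"
        )
    t_test = time_in_volume(trajectory, test_volume, period, frame_rate)
    t_control = time_in_volume(trajectory, control_volume, period, frame_rate)
    weight = t_test + t_control
    pi = (t_test - t_control) / weight if weight > 0 else float("nan")
    return PreferenceRecord(
        run_id=trajectory.run_id,
        traj_id=trajectory.traj_id,
        period_id=period.period_id,
        t_test=t_test,
        t_control=t_control,
        weight=weight,
        pi=pi,
    )


def volumes_for_period(
    period: StimulusPeriod,
    diameter: float = 14.0,
    height: float = 4.0,
) -> tuple[ResponseVolume, ResponseVolume]:
    """Response cylinders centered on the period's test and control stimuli."""
    return (
        ResponseVolume(period.test.center_xy, diameter=diameter, height=height),
        ResponseVolume(period.control.center_xy, diameter=diameter, height=height),
    )


def summarize_period(
    run: RunRecord,
    period: StimulusPeriod,
    test_volume: ResponseVolume | None = None,
    control_volume: ResponseVolume | None = None,
) -> PeriodSummary:
    """Activation and recruitment counts for one stimulus period.

    Activation counts trajectories with at least one sample in the period;
    a trajectory spanning period boundaries contributes to every period it
    overlaps.  Recruitment counts those with at least one in-period sample
    inside either response volume (single-sample entry).  The recruitment
    proportion is NaN when no trajectories were active.
    """
    if test_volume is None or control_volume is None:
        test_volume, control_volume = volumes_for_period(period)
    fps = run.geometry.frame_rate
    n_active = 0
    n_recruited = 0
    for tr in run.trajectories:
        in_period = period.contains_t(tr.t)
        if not in_period.any():
            continue
        n_active += 1
        inside = (
            test_volume.contains(tr.x, tr.y, tr.z)
            | control_volume.contains(tr.x, tr.y, tr.z)
        )
        if (inside & in_period).any():
            n_recruited += 1
    del fps
    return PeriodSummary(
        run_id=run.run_id,
        period_id=period.period_id,
        phase=period.phase,
        test_channel=period.test.label,
        control_channel=period.control.label,
        intensity=period.test.intensity,
        co2_percent=period.odor.co2_percent,
        odor=period.odor.odor,
        n_trajectories=n_active,
        n_recruited=n_recruited,
        recruitment=(n_recruited / n_active) if n_active else float("nan"),
    )


def summarize_run(run: RunRecord, min_frames: int = 90) -> list[PeriodSummary]:
    """Per-period summaries for one run, on length-filtered trajectories."""
    filtered = RunRecord(
        run_id=run.run_id,
        cohort=run.cohort,
        schedule=run.schedule,
        trajectories=filter_trajectories(run.trajectories, min_frames),
        geometry=run.geometry,
    )
    return [summarize_period(filtered, p) for p in run.schedule]


def preference_records(
    run: RunRecord,
    periods: Sequence[StimulusPeriod] | None = None,
    min_frames: int = 90,
    swap_labels: bool = False,
) -> pd.DataFrame:
    """Per-trajectory preference records for each (filtered) trajectory x period.

    Returns a DataFrame with dwell times, the preference index, and integer
    frame counts (``frames_test``, ``frames_total``) that implement the
    paper-style time weighting of trajectories in downstream models.
    ``swap_labels=True`` exchanges the test/control roles (for antisymmetry
    checks and negative controls).
    """
    periods = list(periods) if periods is not None else run.schedule
    fps = run.geometry.frame_rate
    trajectories = filter_trajectories(run.trajectories, min_frames)
    rows = []
    for period in periods:
        p = period.swapped() if swap_labels else period
        test_vol, ctrl_vol = volumes_for_period(p)
        for tr in trajectories:
            if not period.contains_t(tr.t).any():
                continue
            rec = preference_index(tr, test_vol, ctrl_vol, period, fps)
            rows.append(
                {
                    "run_id": rec.run_id,
                    "traj_id": rec.traj_id,
                    "period_id": rec.period_id,
                    "phase": p.phase,
                    "test_channel": p.test.label,
                    "control_channel": p.control.label,
                    "intensity": p.test.intensity,
                    "co2_percent": p.odor.co2_percent,
                    "odor": p.odor.odor,
                    "t_test": rec.t_test,
                    "t_control": rec.t_control,
                    "weight": rec.weight,
                    "pi": rec.pi,
                    "frames_test": int(round(rec.t_test * fps)),
                    "frames_total": int(round(rec.weight * fps)),
                }
            )
    columns = [
        "run_id", "traj_id", "period_id", "phase", "test_channel",
        "control_channel", "intensity", "co2_percent", "odor",
        "t_test", "t_control", "weight", "pi", "frames_test", "frames_total",
    ]
    return pd.DataFrame(rows, columns=columns)


def occupancy_map(
    trajectories: Iterable[Trajectory],
    view: str = "top",
    bin_area: float = DEFAULT_BIN_AREA_CM2,
    geometry: TunnelGeometry | None = None,
) -> OccupancyMap:
    """Percent-residency histogram of all samples, top (x,y) or side (x,z) view.

    Bins are squares of area ``bin_area`` cm^2 tiling the working section;
    occurrences are normalized by the total count so a non-empty map sums
    to 100%.
    """
    if view not in ("top", "side"):
        raise ValueError("view must be 'top' or 'side'")
    if bin_area <= 0:
        raise ValueError("bin_area must be > 0")
    geometry = geometry or TunnelGeometry()
    side = float(np.sqrt(bin_area))
    xb = geometry.x_bounds
    ob = geometry.y_bounds if view == "top" else geometry.z_bounds
    x_edges = np.arange(xb[0], xb[1] + side, side)
    y_edges = np.arange(ob[0], ob[1] + side, side)
    xs, os_ = [], []
    for tr in trajectories:
        xs.append(tr.x)
        os_.append(tr.y if view == "top" else tr.z)
    if xs:
        x = np.concatenate(xs)
        o = np.concatenate(os_)
    else:
        x = np.empty(0)
        o = np.empty(0)
    counts, _, _ = np.histogram2d(x, o, bins=[x_edges, y_edges])
    total = counts.sum()
    grid = counts / total * 100.0 if total > 0 else counts
    return OccupancyMap(
        view=view,
        bin_size=side,
        x_edges=x_edges,
        y_edges=y_edges,
        grid=grid,
        n_points=int(total),
    )
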