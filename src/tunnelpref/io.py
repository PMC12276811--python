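"""Data model and tabular I/O for wind-tunnel flight trajectories and run schedules.

Coordinate convention: origin at the center of the working-section floor,
+x downwind, +y cross-wind, +z up, all in cm.  The two floor stimuli are
placed symmetrically about y=0.  Frames are 0-based and ``t = frame /
frame_rate``; stimulus-period membership uses half-open intervals
``[t_start, t_end)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields as dc_fields, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Symbolic (non-LED) stimulus channels.
SYMBOLIC_CHANNELS = ("gray", "neutral_gray", "mid_gray", "black_tulle")

#: Odor conditions delivered with the CO2 plume.
ODOR_LEVELS = ("none", "floral", "host", "oviposition", "humidity")

#: Serialized NA token used by every table writer/reader in the package.
NA_TOKEN = "NA"


class FormatError(ValueError):
    """A file does not conform to the expected tabular layout."""


class ValidationError(ValueError):
    """Parsed data violate a structural invariant."""


@dataclass(frozen=True)
class TunnelGeometry:
    """Working-section geometry and acquisition constants.

    Defaults are the 224x61x61 cm low-speed wind tunnel with 40 cm/s
    laminar flow and 60 Hz 3D tracking.
    """

    length: float = 224.0
    width: float = 61.0
    height: float = 61.0
    wind_speed: float = 40.0
    frame_rate: float = 60.0

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            if getattr(self, f.name) <= 0:
                raise ValidationError(f"TunnelGeometry.{f.name} must be > 0")

    @property
    def x_bounds(self) -> tuple[float, float]:
        return (-self.length / 2.0, self.length / 2.0)

    @property
    def y_bounds(self) -> tuple[float, float]:
        return (-self.width / 2.0, self.width / 2.0)

    @property
    def z_bounds(self) -> tuple[float, float]:
        return (0.0, self.height)

    def contains(self, x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
        return (
            (x >= self.x_bounds[0]) & (x <= self.x_bounds[1])
            & (y >= self.y_bounds[0]) & (y <= self.y_bounds[1])
            & (z >= self.z_bounds[0]) & (z <= self.z_bounds[1])
        )


@dataclass(frozen=True)
class TrackPoint:
    """One 3D tracking sample."""

    frame: int
    t: float
    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        if self.frame < 0:
            raise ValidationError("frame must be >= 0")
        if not all(math.isfinite(v) for v in (self.t, self.x, self.y, self.z)):
            raise ValidationError("TrackPoint coordinates must be finite")


class Trajectory:
    """One tracked flight path: ordered 3D samples at a fixed frame rate.

    Stores points as column arrays for vectorized metric computation;
    ``points`` exposes them as :class:`TrackPoint` objects.
    """

    __slots__ = ("traj_id", "run_id", "frames", "t", "x", "y", "z")

    def __init__(
        self,
        traj_id: str,
        run_id: str,
        frames: np.ndarray,
        x: np.ndarray,
        y: np.ndarray,
        z: np.ndarray,
        t: np.ndarray | None = None,
        frame_rate: float = 60.0,
    ) -> None:
        frames = np.asarray(frames, dtype=np.int64)
        if frames.size and np.any(np.diff(frames) <= 0):
            raise ValidationError(
                f"trajectory {traj_id!r}: frames must be strictly increasing"
            )
        if frames.size and frames[0] < 0:
            raise ValidationError(f"trajectory {traj_id!r}: negative frame index")
        self.traj_id = str(traj_id)
        self.run_id = str(run_id)
        self.frames = frames
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.z = np.asarray(z, dtype=float)
        self.t = (
            np.asarray(t, dtype=float)
            if t is not None
            else frames / float(frame_rate)
        )
        n = len(frames)
        if not (len(self.x) == len(self.y) == len(self.z) == len(self.t) == n):
            raise ValidationError(f"trajectory {traj_id!r}: ragged columns")
        if n and not (
            np.all(np.isfinite(self.x))
            and np.all(np.isfinite(self.y))
            and np.all(np.isfinite(self.z))
        ):
            raise ValidationError(f"trajectory {traj_id!r}: non-finite coordinates")

    def __len__(self) -> int:
        return len(self.frames)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Trajectory):
            return NotImplemented
        return (
            self.traj_id == other.traj_id
            and self.run_id == other.run_id
            and np.array_equal(self.frames, other.frames)
            and np.array_equal(self.x, other.x)
            and np.array_equal(self.y, other.y)
            and np.array_equal(self.z, other.z)
            and np.allclose(self.t, other.t, atol=1e-12)
        )

    @property
    def points(self) -> list[TrackPoint]:
        return [
            TrackPoint(int(f), float(t), float(x), float(y), float(z))
            for f, t, x, y, z in zip(self.frames, self.t, self.x, self.y, self.z)
        ]

    @property
    def duration(self) -> float:
        """Elapsed time between first and last sample, seconds."""
        return float(self.t[-1] - self.t[0]) if len(self) else 0.0

    def validate_bounds(self, geometry: TunnelGeometry, strict: bool = False) -> int:
        """Count (and optionally reject) samples outside the working section."""
        inside = geometry.contains(self.x, self.y, self.z)
        n_out = int((~inside).sum())
        if n_out:
            msg = f"trajectory {self.traj_id!r}: {n_out} samples outside tunnel bounds"
            if strict:
                raise ValidationError(msg)
            logger.warning(msg)
        return n_out


@dataclass(frozen=True)
class StimulusSpec:
    """A floor stimulus: LED wavelength channel (nm) or symbolic target.

    ``intensity`` is in relative units where 1.0 is the isoquantal /
    background-matched level; ``center_xy`` is the floor position (cm).
    """

    channel: float | str
    intensity: float = 1.0
    center_xy: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if isinstance(self.channel, str):
            if self.channel not in SYMBOLIC_CHANNELS:
                raise ValidationError(
                    f"unknown channel {self.channel!r}; valid symbolic channels: "
                    f"{SYMBOLIC_CHANNELS} or a wavelength in [390, 743] nm"
                )
        else:
            if not 390.0 <= float(self.channel) <= 743.0:
                raise ValidationError(
                    f"wavelength channel {self.channel} nm outside the 390-743 nm LED range"
                )
        if not 0.0 <= self.intensity <= 3.0:
            raise ValidationError("intensity must lie in [0, 3]")
        object.__setattr__(self, "center_xy", tuple(float(v) for v in self.center_xy))

    @property
    def label(self) -> str:
        if isinstance(self.channel, str):
            return self.channel
        return f"{self.channel:g}nm"


@dataclass(frozen=True)
class OdorCondition:
    """Olfactory context of a stimulus period: CO2 fraction of the plume and odor."""

    co2_percent: float = 0.0
    odor: str = "none"

    def __post_init__(self) -> None:
        if self.co2_percent < 0:
            raise ValidationError("co2_percent must be >= 0")
        if self.odor not in ODOR_LEVELS:
            raise ValidationError(f"odor must be one of {ODOR_LEVELS}")


PHASES = ("pre_clean_air", "main", "post_clean_air")


@dataclass(frozen=True)
class StimulusPeriod:
    """One presentation window of a test/control stimulus pair."""

    period_id: str
    t_start: float
    t_end: float
    test: StimulusSpec
    control: StimulusSpec
    odor: OdorCondition = OdorCondition()
    phase: str = "main"

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValidationError(
                f"period {self.period_id!r}: t_start must be < t_end"
            )
        if self.phase not in PHASES:
            raise ValidationError(f"phase must be one of {PHASES}")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    def contains_t(self, t: np.ndarray) -> np.ndarray:
        """Half-open membership [t_start, t_end)."""
        t = np.asarray(t, dtype=float)
        return (t >= self.t_start) & (t < self.t_end)

    def swapped(self) -> "StimulusPeriod":
        """Same period with test and control labels exchanged."""
        return replace(self, test=self.control, control=self.test)


@dataclass
class RunRecord:
    """One bioassay release (nominally 50 mosquitos): schedule + trajectories."""

    run_id: str
    cohort: str
    schedule: list[StimulusPeriod]
    trajectories: list[Trajectory]
    geometry: TunnelGeometry = field(default_factory=TunnelGeometry)

    def __post_init__(self) -> None:
        validate_schedule(self.schedule)
        for tr in self.trajectories:
            if tr.run_id != self.run_id:
                raise ValidationError(
                    f"trajectory {tr.traj_id!r} carries run_id {tr.run_id!r}, "
                    f"expected {self.run_id!r}"
                )

    @property
    def main_periods(self) -> list[StimulusPeriod]:
        return [p for p in self.schedule if p.phase == "main"]

    @property
    def clean_air_periods(self) -> list[StimulusPeriod]:
        return [p for p in self.schedule if p.phase != "main"]


def validate_schedule(schedule: Sequence[StimulusPeriod]) -> None:
    """Reject unordered or overlapping stimulus periods."""
    for a, b in zip(schedule, schedule[1:]):
        if b.t_start < a.t_start:
            raise ValidationError(
                f"schedule not time-ordered at period {b.period_id!r}"
            )
        if b.t_start < a.t_end:
            raise ValidationError(
                f"periods {a.period_id!r} and {b.period_id!r} overlap"
            )


# ---------------------------------------------------------------------------
# Trajectory tables (CSV: run_id, traj_id, frame, x, y, z[, t])
# ---------------------------------------------------------------------------

TRAJECTORY_COLUMNS = ("run_id", "traj_id", "frame", "x", "y", "z")


def read_trajectories(
    path: str | Path,
    geometry: TunnelGeometry | None = None,
    strict_bounds: bool = False,
) -> list[Trajectory]:
    """Read a trajectory table, grouping rows into per-``traj_id`` tracks.

    ``t`` is reconstructed as ``frame / frame_rate`` when absent.  Rows may
    be interleaved across trajectories; points are sorted by frame within
    each track and frames must then be strictly increasing.
    """
    geometry = geometry or TunnelGeometry()
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s) {missing}; "
            f"expected {list(TRAJECTORY_COLUMNS)}"
        )
    trajectories: list[Trajectory] = []
    if df.empty:
        logger.info("%s: 0 trajectories", path)
        return trajectories
    for (run_id, traj_id), g in df.groupby(["run_id", "traj_id"], sort=False):
        g = g.sort_values("frame", kind="stable")
        frames = g["frame"].to_numpy(dtype=np.int64)
        if np.any(np.diff(frames) <= 0):
            raise ValidationError(
                f"{path}: duplicate/non-monotone frames in trajectory {traj_id!r}"
            )
        tr = Trajectory(
            traj_id=str(traj_id),
            run_id=str(run_id),
            frames=frames,
            x=g["x"].to_numpy(float),
            y=g["y"].to_numpy(float),
            z=g["z"].to_numpy(float),
            t=g["t"].to_numpy(float) if "t" in g.columns else None,
            frame_rate=geometry.frame_rate,
        )
        tr.validate_bounds(geometry, strict=strict_bounds)
        trajectories.append(tr)
    logger.info(
        "%s: %d trajectories, lengths %s", path, len(trajectories),
        [len(t) for t in trajectories],
    )
    return trajectories


def write_trajectories(trajectories: Iterable[Trajectory], path: str | Path) -> None:
    """Write trajectories to the canonical CSV dialect (with explicit ``t``)."""
    rows = []
    for tr in trajectories:
        rows.append(
            pd.DataFrame(
                {
                    "run_id": tr.run_id,
                    "traj_id": tr.traj_id,
                    "frame": tr.frames,
                    "x": tr.x,
                    "y": tr.y,
                    "z": tr.z,
                    "t": tr.t,
                }
            )
        )
    out = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=list(TRAJECTORY_COLUMNS) + ["t"])
    )
    out.to_csv(path, index=False, float_format="%.17g")  # lossless round-trip


# ---------------------------------------------------------------------------
# Run schedules (YAML/JSON: geometry block + ordered period list)
# ---------------------------------------------------------------------------

def _stimulus_from_dict(d: dict) -> StimulusSpec:
    return StimulusSpec(
        channel=d["channel"],
        intensity=float(d.get("intensity", 1.0)),
        center_xy=tuple(d.get("center_xy", (0.0, 0.0))),
    )


def read_run_schedule(path: str | Path) -> list[StimulusPeriod]:
    """Read and validate a stimulus schedule from a YAML (or JSON) config.

    The alternation order of periods is preserved exactly as listed.
    """
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "periods" not in cfg:
        raise FormatError(f"{path}: schedule config must contain a 'periods' list")
    periods: list[StimulusPeriod] = []
    for i, p in enumerate(cfg["periods"]):
        odor = p.get("odor", {})
        periods.append(
            StimulusPeriod(
                period_id=str(p.get("period_id", f"P{i:02d}")),
                t_start=float(p["t_start"]),
                t_end=float(p["t_end"]),
                test=_stimulus_from_dict(p["test"]),
                control=_stimulus_from_dict(p["control"]),
                odor=OdorCondition(
                    co2_percent=float(odor.get("co2_percent", 0.0)),
                    odor=odor.get("odor", "none"),
                ),
                phase=p.get("phase", "main"),
            )
        )
    validate_schedule(periods)
    return periods


def _stimulus_to_dict(s: StimulusSpec) -> dict:
    return {
        "channel": s.channel,
        "intensity": float(s.intensity),
        "center_xy": list(s.center_xy),
    }


def write_run_schedule(
    schedule: Sequence[StimulusPeriod],
    path: str | Path,
    geometry: TunnelGeometry | None = None,
) -> None:
    cfg: dict = {"periods": []}
    if geometry is not None:
        cfg["geometry"] = {
            f.name: getattr(geometry, f.name) for f in dc_fields(geometry)
        }
    for p in schedule:
        cfg["periods"].append(
            {
                "period_id": p.period_id,
                "t_start": float(p.t_start),
                "t_end": float(p.t_end),
                "phase": p.phase,
                "test": _stimulus_to_dict(p.test),
                "control": _stimulus_to_dict(p.control),
                "odor": {"co2_percent": p.odor.co2_percent, "odor": p.odor.odor},
            }
        )
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Generic result tables
# ---------------------------------------------------------------------------

def write_table(records: pd.DataFrame | Iterable, path: str | Path) -> None:
    """Write result records as CSV, serializing missing values as ``NA``.

    Accepts a DataFrame or an iterable of dataclass instances; round-trips
    losslessly through :func:`read_table`.
    """
    if not isinstance(records, pd.DataFrame):
        records = list(records)
        if records and hasattr(records[0], "__dataclass_fields__"):
            records = pd.DataFrame(
                [
                    {f.name: getattr(r, f.name) for f in dc_fields(r)}
                    for r in records
                ]
            )
        else:
            records = pd.DataFrame(records)
    records.to_csv(path, index=False, na_rep=NA_TOKEN, float_format="%.17g")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table` (``NA`` token -> NaN)."""
    return pd.read_csv(path, na_values=[NA_TOKEN], keep_default_na=True,
                       float_precision="round_trip")
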