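"""Agent-based generator of wind-tunnel runs with the statistical structure
the analysis assumes.

Each run releases a group of mosquitos (default 50) against a stimulus
schedule with pre/post clean-air periods.  Per period, activation follows a
Poisson count process whose rate rises with CO2; each trajectory is
recruited to the paired floor stimuli with a logistic probability gated by
CO2 (recruitment is rare without it); a recruited trajectory's dwell is
split between the test and control response volumes by a beta-binomial
draw whose mean follows the configured preference surface

    logit(p_test) = base(wavelength) + odor_shift + intensity term + run effect,

where base() is an inverted Gaussian centered near 525 nm (lowest
preference in the green band, rising toward the violet and red ends), odor
shifts boost the green band (floral/oviposition) or everything uniformly
(host), the intensity term follows the four-parameter log-logistic, and
the run effect is a Normal intercept drawn once per run x stimulus pair.
Flight paths are fixed-speed correlated random walks with reflecting
walls; wind advection is not modelled.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit, logit

from .dose_response import LL4Params, ll4
from .io import (
    OdorCondition,
    RunRecord,
    StimulusPeriod,
    StimulusSpec,
    Trajectory,
    TunnelGeometry,
    write_run_schedule,
    write_trajectories,
)

__all__ = [
    "LED_CHANNELS",
    "SimConfig",
    "spectral_sweep_schedule",
    "intensity_ramp_schedule",
    "preference_logit",
    "relative_intensity",
    "simulate_trajectory",
    "simulate_run",
    "simulate_cohort",
]

#: Peak wavelengths (nm) of the 17 LED channels, spanning 390-743 nm.
LED_CHANNELS = (
    390.0, 405.0, 420.0, 435.0, 450.0, 467.0, 478.0, 500.0, 527.0,
    552.0, 575.0, 590.0, 621.0, 660.0, 680.0, 700.0, 743.0,
)

#: Green band (nm) where spectral preference is lowest.
GREEN_BAND = (475.0, 575.0)

#: Default floor positions of the test and control stimuli (cm, about y=0).
TEST_CENTER = (30.0, -15.0)
CONTROL_CENTER = (30.0, 15.0)


@dataclass
class SimConfig:
    """Study conditions for the generator.

    Rates are per stimulus period; preferences are on the logit scale of
    the test-volume dwell fraction.  The run random effect applies per
    run x stimulus pair, matching the preference model's random structure.
    """

    geometry: TunnelGeometry = field(default_factory=TunnelGeometry)
    n_mosquitos: int = 50
    test_center: tuple[float, float] = TEST_CENTER
    control_center: tuple[float, float] = CONTROL_CENTER

    # activation (trajectory count) process
    activation_base_rate: float = 6.0      # mean trajectories/period, clean air
    activation_co2_gain: float = 1.0       # multiplicative gain at 10% CO2
    activation_run_sd: float = 0.25        # lognormal run effect on the rate

    # recruitment (logistic, CO2-gated)
    recruit_base_logit: float = -5.3       # expit ~ 0.5% without CO2
    recruit_co2_gain: float = 2.8          # added logit at 10% CO2
    recruit_run_sd: float = 0.3            # Normal run intercept, recruitment

    # spectral preference surface (inverted Gaussian, lowest in the green)
    spectral_center_nm: float = 525.0
    spectral_width_nm: float = 60.0
    spectral_edge_logit: float = 0.25      # preference at the spectral extremes
    spectral_depth: float = 1.0            # dip depth at the center
    black_tulle_logit: float = 0.8         # dark target strongly preferred
    gray_logit: float = 0.0                # background-matched gray: indifferent

    # odor shifts added to the spectral surface
    odor_green_shift: float = 0.6          # floral/oviposition: green-band boost
    odor_uniform_shift: float = 0.3        # host odor: uniform boost

    # intensity dependence (preference-index-scale log-logistic)
    # inflection at the isoquantal level (relative intensity 6 = LED 1.0),
    # mid-range of the measured ramp so both shoulders are observable
    intensity_ll4: LL4Params = field(
        default_factory=lambda: LL4Params(b=1.5, c=-0.5, d=0.5, e=6.0)
    )
    ambient_intensity: float = 0.2         # ambient light on the tulle target

    # trajectory-level dispersion and run effects
    preference_run_sd: float = 0.5         # Normal intercept per run x pair
    betabinom_phi: float = 8.0             # beta-binomial precision of the split
    mean_dwell_frames: float = 80.0        # mean total frames in both volumes

    # flight kinematics
    speed_cm_s: float = 40.0
    turn_sd: float = 0.35                  # heading perturbation scale per frame
    short_track_fraction: float = 0.15     # wander tracks censored below 90 frames

    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["intensity_ll4"] = asdict(self.intensity_ll4)
        return d


def relative_intensity(intensity: float, ambient: float = 0.2) -> float:
    """Stimulus intensity relative to the unilluminated black tulle target.

    The tulle reflects ambient light only, so relative intensity is
    (intensity + ambient) / ambient and strictly positive.
    """
    return (intensity + ambient) / ambient


def _spectral_dip(config: SimConfig, wavelength: float) -> float:
    w = (wavelength - config.spectral_center_nm) / config.spectral_width_nm
    return math.exp(-w * w)


def preference_logit(
    config: SimConfig, test: StimulusSpec, odor: OdorCondition
) -> float:
    """Configured logit of the expected test-volume dwell fraction."""
    if isinstance(test.channel, str):
        base = (
            config.black_tulle_logit
            if test.channel == "black_tulle"
            else config.gray_logit
        )
        dip = 0.0
    else:
        wl = float(test.channel)
        dip = _spectral_dip(config, wl)
        base = config.spectral_edge_logit - config.spectral_depth * dip
    shift = 0.0
    if odor.odor in ("floral", "oviposition"):
        shift = config.odor_green_shift * dip
    elif odor.odor == "host":
        shift = config.odor_uniform_shift
    # intensity term: log-logistic effect relative to the isoquantal level
    if test.intensity != 1.0:
        x = relative_intensity(test.intensity, config.ambient_intensity)
        x1 = relative_intensity(1.0, config.ambient_intensity)
        p_x = (ll4(x, config.intensity_ll4) + 1.0) / 2.0
        p_1 = (ll4(x1, config.intensity_ll4) + 1.0) / 2.0
        base += float(logit(np.clip(p_x, 1e-6, 1 - 1e-6))
                      - logit(np.clip(p_1, 1e-6, 1 - 1e-6)))
    return base + shift


# ---------------------------------------------------------------------------
# Schedule templates
# ---------------------------------------------------------------------------

def spectral_sweep_schedule(
    co2_percent: float = 10.0,
    odor: str = "none",
    channels: Sequence[float] = LED_CHANNELS,
    period_s: float = 120.0,
    clean_air_s: float = 120.0,
    intensity: float = 1.0,
    test_center: tuple[float, float] = TEST_CENTER,
    control_center: tuple[float, float] = CONTROL_CENTER,
    reverse: bool = False,
) -> list[StimulusPeriod]:
    """Spectral sweep: every LED channel at isoquantal intensity vs mid-gray.

    Pre/post clean-air periods present an unilluminated black tulle target
    with no odor; ``reverse=True`` alternates the channel order across runs
    to control for responsiveness drift.
    """
    chans = list(channels)[::-1] if reverse else list(channels)
    main_odor = OdorCondition(co2_percent=co2_percent, odor=odor)
    clean = OdorCondition(co2_percent=0.0, odor="none")
    control = StimulusSpec("mid_gray", 0.5, control_center)
    periods = [
        StimulusPeriod(
            "pre", 0.0, clean_air_s,
            test=StimulusSpec("black_tulle", 0.0, test_center),
            control=control, odor=clean, phase="pre_clean_air",
        )
    ]
    t = clean_air_s
    for i, ch in enumerate(chans):
        periods.append(
            StimulusPeriod(
                f"M{i:02d}", t, t + period_s,
                test=StimulusSpec(ch, intensity, test_center),
                control=control, odor=main_odor,
            )
        )
        t += period_s
    periods.append(
        StimulusPeriod(
            "post", t, t + clean_air_s,
            test=StimulusSpec("black_tulle", 0.0, test_center),
            control=control, odor=clean, phase="post_clean_air",
        )
    )
    return periods


def intensity_ramp_schedule(
    wavelength: float = 527.0,
    intensities: Sequence[float] = (0.0, 0.25, 0.5, 1.0, 1.5, 2.0, 3.0),
    co2_percent: float = 10.0,
    odor: str = "none",
    period_s: float = 120.0,
    clean_air_s: float = 120.0,
    test_center: tuple[float, float] = TEST_CENTER,
    control_center: tuple[float, float] = CONTROL_CENTER,
    reverse: bool = False,
) -> list[StimulusPeriod]:
    """Intensity ramp: one channel at graded intensities (0-3) vs mid-gray."""
    levels = list(intensities)[::-1] if reverse else list(intensities)
    main_odor = OdorCondition(co2_percent=co2_percent, odor=odor)
    clean = OdorCondition(co2_percent=0.0, odor="none")
    control = StimulusSpec("mid_gray", 0.5, control_center)
    periods = [
        StimulusPeriod(
            "pre", 0.0, clean_air_s,
            test=StimulusSpec("black_tulle", 0.0, test_center),
            control=control, odor=clean, phase="pre_clean_air",
        )
    ]
    t = clean_air_s
    for i, lv in enumerate(levels):
        periods.append(
            StimulusPeriod(
                f"M{i:02d}", t, t + period_s,
                test=StimulusSpec(wavelength, lv, test_center),
                control=control, odor=main_odor,
            )
        )
        t += period_s
    periods.append(
        StimulusPeriod(
            "post", t, t + clean_air_s,
            test=StimulusSpec("black_tulle", 0.0, test_center),
            control=control, odor=clean, phase="post_clean_air",
        )
    )
    return periods


# ---------------------------------------------------------------------------
# Flight kinematics
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.linalg.norm(v))
    return v / n if n > 0 else np.array([1.0, 0.0, 0.0])


class _Flier:
    """Fixed-speed correlated random walk with reflecting tunnel walls."""

    def __init__(self, config: SimConfig, rng: np.random.Generator,
                 start: np.ndarray | None = None):
        g = config.geometry
        self.g = g
        self.rng = rng
        self.step = config.speed_cm_s / g.frame_rate
        self.turn_sd = config.turn_sd
        self.lo = np.array([g.x_bounds[0], g.y_bounds[0], g.z_bounds[0]])
        self.hi = np.array([g.x_bounds[1], g.y_bounds[1], g.z_bounds[1]])
        if start is None:
            margin = 5.0
            start = rng.uniform(self.lo + margin, self.hi - margin)
        self.pos = np.asarray(start, float)
        self.heading = _unit(rng.normal(size=3))
        self.track: list[np.ndarray] = [self.pos.copy()]

    def _advance(self, direction: np.ndarray) -> None:
        self.heading = _unit(direction)
        nxt = self.pos + self.step * self.heading
        # reflect off the walls, component-wise
        for k in range(3):
            if nxt[k] < self.lo[k]:
                nxt[k] = 2 * self.lo[k] - nxt[k]
                self.heading[k] = -self.heading[k]
            elif nxt[k] > self.hi[k]:
                nxt[k] = 2 * self.hi[k] - nxt[k]
                self.heading[k] = -self.heading[k]
        self.pos = np.clip(nxt, self.lo, self.hi)
        self.track.append(self.pos.copy())

    def wander(self, n: int) -> None:
        for _ in range(n):
            d = self.heading + self.turn_sd * self.rng.normal(size=3)
            if self.pos[2] < 8.0:  # cruising flight stays off the floor
                d[2] += 0.3
            self._advance(d)

    def approach(self, center_xy: tuple[float, float], max_frames: int = 1200,
                 capture_r: float = 6.8, capture_z: float = 3.9) -> bool:
        """Steer toward a floor stimulus until inside its response volume."""
        target = np.array([center_xy[0], center_xy[1], 2.0])
        for _ in range(max_frames):
            d = _unit(target - self.pos)
            self._advance(
                0.75 * self.heading + 0.6 * d
                + 0.15 * self.turn_sd * self.rng.normal(size=3)
            )
            dx = self.pos[0] - center_xy[0]
            dy = self.pos[1] - center_xy[1]
            if dx * dx + dy * dy <= capture_r ** 2 and self.pos[2] <= capture_z:
                return True
        return False

    def dwell(self, center_xy: tuple[float, float], n: int,
              r_max: float = 6.5, z_max: float = 3.8) -> None:
        """Confined walk inside the response cylinder for n frames."""
        center = np.array([center_xy[0], center_xy[1], 1.8])
        for _ in range(n):
            d = self.heading + 0.8 * self.rng.normal(size=3)
            cand = self.pos + self.step * _unit(d)
            dx, dy = cand[0] - center_xy[0], cand[1] - center_xy[1]
            if dx * dx + dy * dy > r_max ** 2 or not 0.1 <= cand[2] <= z_max:
                d = center - self.pos  # turn back toward the cylinder core
            self._advance(d)

    def leave(self, n: int = 20) -> None:
        up = np.array([0.0, 0.0, 1.0])
        for _ in range(n):
            self._advance(self.heading + up + self.turn_sd * self.rng.normal(size=3))


def simulate_trajectory(
    config: SimConfig,
    mode: str,
    rng: np.random.Generator,
    t0: float = 0.0,
    n_frames: int = 240,
    dwell_test: int = 0,
    dwell_control: int = 0,
    traj_id: str = "T0000",
    run_id: str = "R00",
) -> Trajectory:
    """Generate one flight path.

    ``wander`` is a plain correlated random walk of ``n_frames``;
    ``approach_test`` / ``approach_control`` steer to the corresponding
    stimulus first and realize the requested in-volume dwell frames there
    (then the other volume, if its budget is positive).  Starts at the
    frame nearest ``t0``.
    """
    if mode not in ("wander", "approach_test", "approach_control"):
        raise ValueError(f"unknown mode {mode!r}")
    flier = _Flier(config, rng)
    if mode == "wander":
        flier.wander(n_frames - 1)
    else:
        first_is_test = mode == "approach_test"
        order = [
            (config.test_center, dwell_test),
            (config.control_center, dwell_control),
        ]
        if not first_is_test:
            order.reverse()
        flier.wander(min(30, n_frames))
        for center, frames in order:
            if frames <= 0:
                continue
            if flier.approach(center):
                flier.dwell(center, frames - 1)  # capture frame is in-volume
            flier.leave()
        flier.wander(10)
        while len(flier.track) < 90:  # never censor a recruited track
            flier.wander(10)
    pts = np.asarray(flier.track)
    frame0 = max(0, int(round(t0 * config.geometry.frame_rate)))
    frames = frame0 + np.arange(len(pts))
    return Trajectory(
        traj_id=traj_id,
        run_id=run_id,
        frames=frames,
        x=pts[:, 0], y=pts[:, 1], z=pts[:, 2],
        frame_rate=config.geometry.frame_rate,
    )


# ---------------------------------------------------------------------------
# Runs and cohorts
# ---------------------------------------------------------------------------

def simulate_run(
    config: SimConfig,
    seed: int | np.random.SeedSequence,
    schedule: list[StimulusPeriod] | None = None,
    run_id: str = "R00",
    cohort: str = "sim",
) -> RunRecord:
    """Simulate one bioassay release against a schedule (default: spectral sweep).

    The same seed reproduces the run bit-identically.
    """
    rng = np.random.default_rng(seed)
    if schedule is None:
        schedule = spectral_sweep_schedule()
    fps = config.geometry.frame_rate
    act_re = math.exp(rng.normal(0.0, config.activation_run_sd))
    rec_re = rng.normal(0.0, config.recruit_run_sd)
    trajectories: list[Trajectory] = []
    counter = 0
    for period in schedule:
        co2 = period.odor.co2_percent / 10.0
        u_pref = rng.normal(0.0, config.preference_run_sd)
        rate = config.activation_base_rate * (1.0 + config.activation_co2_gain * co2)
        rate *= act_re * period.duration / 120.0
        n_act = int(rng.poisson(rate))
        n_act = min(n_act, config.n_mosquitos)
        q = expit(config.recruit_base_logit + config.recruit_co2_gain * co2 + rec_re)
        p_mean = expit(preference_logit(config, period.test, period.odor) + u_pref)
        for _ in range(n_act):
            counter += 1
            tid = f"{run_id}-T{counter:04d}"
            margin = 120.0 / fps  # keep starts clear of the period's end
            t0 = rng.uniform(period.t_start, max(period.t_start + 1e-6,
                                                 period.t_end - margin))
            if rng.random() < q:
                phi = config.betabinom_phi
                p = rng.beta(p_mean * phi, (1.0 - p_mean) * phi)
                total = 1 + int(rng.poisson(max(config.mean_dwell_frames - 1, 0)))
                k_test = int(rng.binomial(total, p))
                mode = "approach_test" if k_test * 2 >= total else "approach_control"
                trajectories.append(
                    simulate_trajectory(
                        config, mode, rng, t0=t0,
                        dwell_test=k_test, dwell_control=total - k_test,
                        traj_id=tid, run_id=run_id,
                    )
                )
            else:
                if rng.random() < config.short_track_fraction:
                    n_frames = int(rng.integers(30, 90))
                else:
                    n_frames = 90 + int(rng.poisson(150))
                trajectories.append(
                    simulate_trajectory(
                        config, "wander", rng, t0=t0, n_frames=n_frames,
                        traj_id=tid, run_id=run_id,
                    )
                )
    return RunRecord(
        run_id=run_id, cohort=cohort, schedule=schedule,
        trajectories=trajectories, geometry=config.geometry,
    )


def simulate_cohort(
    config: SimConfig,
    n_runs: int,
    seed: int,
    schedule_template: str = "spectral_sweep",
    schedule_kwargs: dict | None = None,
    cohort: str = "sim",
    out_dir: str | Path | None = None,
) -> list[RunRecord]:
    """Simulate independent replicate runs (stimulus order alternates by run).

    With ``out_dir`` set, writes the trajectory CSV, schedule YAML and a
    JSON manifest of every parameter and seed alongside the returned runs.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    kw = dict(schedule_kwargs or {})
    builders = {
        "spectral_sweep": spectral_sweep_schedule,
        "intensity_ramp": intensity_ramp_schedule,
    }
    if schedule_template not in builders:
        raise ValueError(f"unknown schedule template {schedule_template!r}")
    runs = []
    for i in range(n_runs):
        schedule = builders[schedule_template](**kw, reverse=bool(i % 2))
        runs.append(
            simulate_run(
                config,
                seed=np.random.SeedSequence([int(seed), i]),
                schedule=schedule,
                run_id=f"{cohort}-R{i:02d}",
                cohort=cohort,
            )
        )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        all_trajs = [tr for run in runs for tr in run.trajectories]
        write_trajectories(all_trajs, out / "trajectories.csv")
        for i, run in enumerate(runs):
            write_run_schedule(run.schedule, out / f"schedule_{run.run_id}.yaml",
                               geometry=config.geometry)
        manifest = {
            "cohort": cohort,
            "n_runs": n_runs,
            "seed": int(seed),
            "schedule_template": schedule_template,
            "schedule_kwargs": {k: (list(v) if isinstance(v, tuple) else v)
                                for k, v in kw.items()},
            "config": _jsonable(config.to_dict()),
        }
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2)
    return runs


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
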