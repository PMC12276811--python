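import json

import numpy as np
import pytest
from scipy import stats

import tunnelpref as tp
from tunnelpref.metrics import ResponseVolume


class TestTrajectoryKinematics:
    def test_fixed_step_length(self, sim_config, rng):
        tr = tp.simulate_trajectory(sim_config, "wander", rng, n_frames=400)
        steps = np.sqrt(np.diff(tr.x) ** 2 + np.diff(tr.y) ** 2
                        + np.diff(tr.z) ** 2)
        nominal = sim_config.speed_cm_s / sim_config.geometry.frame_rate
        # wall reflections fold the step, never lengthen it
        assert steps.max() <= nominal + 1e-9
        assert np.quantile(steps, 0.05) >= nominal - 1e-9

    def test_io_invariants_hold(self, small_run):
        g = small_run.geometry
        for tr in small_run.trajectories:
            assert np.all(np.diff(tr.frames) > 0)
            assert tr.validate_bounds(g) == 0

    def test_wander_dwell_at_or_below_uniform_baseline(self, sim_config, rng):
        """Cruising flight avoids the floor, so incidental dwell in the
        response cylinders stays below the uniform-occupancy fraction."""
        g = sim_config.geometry
        vol = ResponseVolume(sim_config.test_center)
        vol_frac = (np.pi * 7 ** 2 * 4) / (g.length * g.width * g.height)
        frames_in = total = 0
        for i in range(300):
            tr = tp.simulate_trajectory(sim_config, "wander", rng, n_frames=200)
            frames_in += int(vol.contains(tr.x, tr.y, tr.z).sum())
            total += len(tr)
        assert frames_in / total <= vol_frac

    def test_exclusive_test_dwell_yields_pi_plus_one(self, sim_config, rng):
        period = tp.StimulusPeriod("P", 0.0, 1e5,
                                   tp.StimulusSpec(527.0, 1.0, sim_config.test_center),
                                   tp.StimulusSpec("mid_gray", 0.5,
                                                   sim_config.control_center))
        tvol, cvol = tp.volumes_for_period(period)
        for i in range(10):
            tr = tp.simulate_trajectory(sim_config, "approach_test", rng,
                                        dwell_test=60, dwell_control=0)
            rec = tp.preference_index(tr, tvol, cvol, period)
            assert rec.pi == 1.0 and rec.t_test >= 1.0

    def test_unknown_mode_rejected(self, sim_config, rng):
        with pytest.raises(ValueError):
            tp.simulate_trajectory(sim_config, "hover", rng)


class TestRun:
    def test_same_seed_bit_identical(self, sim_config):
        sched = tp.spectral_sweep_schedule(channels=(450.0, 527.0), period_s=60,
                                           clean_air_s=60)
        a = tp.simulate_run(sim_config, seed=3, schedule=sched)
        b = tp.simulate_run(sim_config, seed=3, schedule=sched)
        assert a.trajectories == b.trajectories

    def test_different_seeds_differ(self, sim_config):
        sched = tp.spectral_sweep_schedule(channels=(450.0,), period_s=60,
                                           clean_air_s=60)
        a = tp.simulate_run(sim_config, seed=3, schedule=sched)
        b = tp.simulate_run(sim_config, seed=4, schedule=sched)
        assert a.trajectories != b.trajectories

    def test_short_track_fraction_exercises_filter(self, small_run):
        lengths = [len(t) for t in small_run.trajectories]
        assert any(n < 90 for n in lengths)
        kept = tp.filter_trajectories(small_run.trajectories)
        assert 0 < len(kept) < len(small_run.trajectories)

    def test_no_co2_recruitment_below_one_percent(self, sim_config):
        """Without CO2 almost no trajectories investigate the visual targets."""
        sched = tp.spectral_sweep_schedule(channels=(450.0, 527.0, 621.0),
                                           co2_percent=0.0, period_s=60,
                                           clean_air_s=60)
        n_act = n_rec = 0
        for s in range(20):
            run = tp.simulate_run(sim_config, seed=100 + s, schedule=sched,
                                  run_id=f"R{s}")
            for summ in tp.summarize_run(run):
                n_act += summ.n_trajectories
                n_rec += summ.n_recruited
        assert n_act > 200
        assert n_rec / n_act < 0.01

    def test_recruited_counts_binomial_when_run_sd_zero(self):
        """With the run effect off, per-run recruited counts show no
        overdispersion beyond binomial sampling."""
        cfg = tp.SimConfig(recruit_run_sd=0.0, activation_run_sd=0.0)
        sched = tp.spectral_sweep_schedule(channels=(450.0, 527.0), period_s=120,
                                           clean_air_s=60)
        ks, ns = [], []
        for s in range(25):
            run = tp.simulate_run(cfg, seed=300 + s, schedule=sched,
                                  run_id=f"R{s}")
            summ = [x for x in tp.summarize_run(run) if x.phase == "main"]
            ks.append(sum(x.n_recruited for x in summ))
            ns.append(sum(x.n_trajectories for x in summ))
        ks, ns = np.array(ks), np.array(ns)
        p = ks.sum() / ns.sum()
        chi2 = np.sum((ks - ns * p) ** 2 / (ns * p * (1 - p)))
        assert stats.chi2.sf(chi2, len(ks) - 1) > 0.05


class TestCohort:
    def test_default_sweep_has_17_main_periods(self, sim_config):
        runs = tp.simulate_cohort(
            sim_config, 2, seed=1,
            schedule_kwargs=dict(period_s=30, clean_air_s=30))
        for run in runs:
            assert len(run.main_periods) == 17
            labels = [p.test.label for p in run.main_periods]
            assert len(set(labels)) == 17
        # stimulus order alternates between consecutive runs
        assert [p.test.label for p in runs[1].main_periods] == \
            [p.test.label for p in runs[0].main_periods][::-1]

    def test_manifest_and_files_written(self, sim_config, tmp_path):
        out = tmp_path / "cohort"
        tp.simulate_cohort(sim_config, 2, seed=9,
                           schedule_kwargs=dict(channels=(527.0,), period_s=30,
                                                clean_air_s=30),
                           out_dir=out)
        manifest = json.loads((out / "manifest.json").read_text())
        assert manifest["seed"] == 9 and manifest["n_runs"] == 2
        assert manifest["config"]["n_mosquitos"] == 50
        trajs = tp.read_trajectories(out / "trajectories.csv")
        assert trajs  # emitted CSV is consumable by the reader
        scheds = sorted(out.glob("schedule_*.yaml"))
        assert len(scheds) == 2
        assert tp.read_run_schedule(scheds[0])

    def test_n_runs_must_be_positive(self, sim_config):
        with pytest.raises(ValueError):
            tp.simulate_cohort(sim_config, 0, seed=1)


class TestPreferenceSurface:
    def test_green_band_dip(self, sim_config):
        odor = tp.OdorCondition(10.0, "none")
        vals = {c: tp.preference_logit(sim_config, tp.StimulusSpec(c), odor)
                for c in tp.LED_CHANNELS}
        assert min(vals, key=vals.get) == 527.0  # lowest preference in the green
        assert vals[390.0] > vals[527.0] and vals[743.0] > vals[527.0]

    def test_floral_odor_boosts_green_band_only(self, sim_config):
        none = tp.OdorCondition(10.0, "none")
        floral = tp.OdorCondition(10.0, "floral")
        shift_green = (tp.preference_logit(sim_config, tp.StimulusSpec(527.0), floral)
                       - tp.preference_logit(sim_config, tp.StimulusSpec(527.0), none))
        shift_red = (tp.preference_logit(sim_config, tp.StimulusSpec(743.0), floral)
                     - tp.preference_logit(sim_config, tp.StimulusSpec(743.0), none))
        assert shift_green > 0.5 * sim_config.odor_green_shift
        assert shift_red < 0.1 * sim_config.odor_green_shift

    def test_host_odor_shift_is_uniform(self, sim_config):
        none = tp.OdorCondition(10.0, "none")
        host = tp.OdorCondition(10.0, "host")
        shifts = [
            tp.preference_logit(sim_config, tp.StimulusSpec(c), host)
            - tp.preference_logit(sim_config, tp.StimulusSpec(c), none)
            for c in (405.0, 527.0, 700.0)
        ]
        assert np.allclose(shifts, sim_config.odor_uniform_shift)

    def test_intensity_term_darker_preferred(self, sim_config):
        odor = tp.OdorCondition(10.0, "none")
        low = tp.preference_logit(sim_config, tp.StimulusSpec(527.0, 0.25), odor)
        high = tp.preference_logit(sim_config, tp.StimulusSpec(527.0, 3.0), odor)
        mid = tp.preference_logit(sim_config, tp.StimulusSpec(527.0, 1.0), odor)
        assert low > mid > high
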