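import numpy as np
import pandas as pd
import pytest

import tunnelpref as tp

#: Channel subset spanning the spectrum with three channels in the green band.
SWEEP_CHANNELS = (405.0, 450.0, 500.0, 527.0, 552.0, 621.0, 700.0)


@pytest.fixture(scope="session")
def sim_config():
    return tp.SimConfig()


@pytest.fixture(scope="session")
def small_run(sim_config):
    """One simulated run against a 3-channel sweep (60 s periods)."""
    schedule = tp.spectral_sweep_schedule(
        channels=(450.0, 527.0, 621.0), period_s=60, clean_air_s=60
    )
    return tp.simulate_run(sim_config, seed=7, schedule=schedule, run_id="R00")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_trajectory(rng, n=100, run_id="R00", traj_id="T0", geometry=None):
    """Uniform random point cloud inside the tunnel, as a Trajectory."""
    g = geometry or tp.TunnelGeometry()
    return tp.Trajectory(
        traj_id=traj_id,
        run_id=run_id,
        frames=np.arange(n),
        x=rng.uniform(*g.x_bounds, n),
        y=rng.uniform(*g.y_bounds, n),
        z=rng.uniform(*g.z_bounds, n),
        frame_rate=g.frame_rate,
    )


def cohort_preference_records(config, n_runs, seed, odor="none",
                              channels=SWEEP_CHANNELS, period_s=60.0):
    """Main-period preference records with positive weight from a simulated cohort."""
    runs = tp.simulate_cohort(
        config, n_runs, seed,
        schedule_kwargs=dict(channels=channels, period_s=period_s,
                             clean_air_s=period_s, odor=odor),
        cohort=f"c{seed}-{odor}",
    )
    recs = pd.concat([tp.preference_records(r) for r in runs], ignore_index=True)
    return recs[(recs.phase == "main") & (recs.frames_total > 0)]
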