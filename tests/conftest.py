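import numpy as np
import pytest

import deadreckon as dr


@pytest.fixture(scope="session")
def land_scenario():
    """One hour of the terrestrial walker preset with its sensor streams."""
    cfg = dr.land_walker(seed=1, duration_s=3600)
    truth = dr.simulate_truth(cfg)
    imu = dr.simulate_imu(truth, cfg)
    vps = dr.simulate_vps(truth, cfg)
    return cfg, truth, imu, vps


@pytest.fixture(scope="session")
def land_processed(land_scenario):
    """The land scenario pushed through the full sensor -> track chain."""
    cfg, truth, imu, vps = land_scenario
    split = dr.separate_acceleration(imu, 2.0)
    vedba = dr.compute_vedba(split, 2.0)
    ori = dr.estimate_pitch_roll(split)
    cal = dr.CalibrationModel()
    heading = dr.tilt_compensated_heading(ori, cal.apply_magnetic(imu.magnetism()), cal, 1.0)
    speeds = dr.vedba_speed(imu.t, vedba, dr.SpeedModelConfig(m=cfg.m_true, c=cfg.c_true))
    tv = dr.TravelVectorSeries(t=imu.t, heading=heading, speed=speeds.speed)
    track = dr.integrate_track((truth.track.lat[0], truth.track.lon[0], 0.0), tv)
    return dict(
        cfg=cfg,
        truth=truth,
        imu=imu,
        vps=vps,
        split=split,
        vedba=vedba,
        ori=ori,
        heading=heading,
        speeds=speeds,
        tv=tv,
        track=track,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
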