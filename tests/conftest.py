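"""Shared fixtures.

The heavier fixtures (full 30-lap simulations) are session-scoped so each
is computed once; everything is seeded and deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest

import thetasweeps as ts


@pytest.fixture(scope="session")
def params() -> ts.NetworkParams:
    return ts.NetworkParams()


@pytest.fixture(scope="session")
def default_config() -> ts.RunConfig:
    return ts.RunConfig(master_seed=0)


@pytest.fixture(scope="session")
def std_run(default_config):
    """One standard 30-lap closed-loop simulation (traces kept)."""
    from thetasweeps.experiment import derive_seeds

    cfg = default_config
    seed_beh, seed_feat = derive_seeds(cfg.master_seed, 0)
    bank = ts.generate_features(cfg.track, cfg.features, seed_feat)
    traj = ts.simulate_trajectory(
        cfg.track, cfg.profile, cfg.noise, cfg.theta_freq, seed_beh
    )
    sim = ts.run_simulation(traj, bank, cfg.network, cfg.theta_freq)
    return cfg, traj, bank, sim


@pytest.fixture(scope="session")
def short_traj() -> ts.Trajectory:
    """A cheap 3-lap trajectory for behavioral unit tests."""
    import dataclasses

    track = dataclasses.replace(ts.TrackSpec(), n_laps=3)
    return ts.simulate_trajectory(track, ts.SpeedProfile(), ts.SpeedNoiseSpec(), 8.0, 7)


def bump_com_at_cycle_starts(sim_sigma: np.ndarray, trajectory, threshold=0.5):
    """Center of mass of the first supra-threshold population state in each
    theta cycle (helper for propagation tests)."""
    from thetasweeps.decoding import segment_cycles

    cyc = segment_cycles(trajectory)
    n_units = sim_sigma.shape[1]
    units = np.arange(n_units)
    out = {}
    lo = 0
    for cid in range(cyc.max() + 1):
        hi = np.searchsorted(cyc, cid, side="right")
        sub = sim_sigma[lo:hi]
        on = sub.max(axis=1) > threshold
        if on.any():
            first = sub[np.flatnonzero(on)[0]]
            out[cid] = (lo, hi, float((first * units).sum() / first.sum()))
        lo = hi
    return out
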