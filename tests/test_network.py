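"""Network dynamics: drives, weights, STP, integration, emergent sequences."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import thetasweeps as ts
from conftest import bump_com_at_cycle_starts

P = ts.NetworkParams()


# ---------------------------------------------------------------------------
# analytic micro-oracles


class TestDrives:
    def test_theta_drive_extrema(self):
        assert ts.theta_drive(0.0, P) == pytest.approx(-1.0)
        assert ts.theta_drive(np.pi, P) == pytest.approx(1.6 - 2.6 * np.exp(-24))
        assert ts.theta_drive(np.pi / 2, P) == pytest.approx(1.6 - 2.6 * np.exp(-12))

    def test_theta_gate_values(self):
        assert ts.theta_gate(np.pi / 2, P) == pytest.approx(1.0)
        assert ts.theta_gate(0.0, P) == pytest.approx(np.exp(-2))
        assert ts.theta_gate(3 * np.pi / 2, P) == pytest.approx(np.exp(-4))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(theta=st.floats(0, 2 * np.pi))
    def test_gate_bounded_peaks_at_half_pi(self, theta):
        b = ts.theta_gate(theta, P)
        assert 0 < b <= 1
        if abs(theta - np.pi / 2) > 1e-6:
            assert b < 1

    def test_logistic(self):
        assert ts.logistic(0.5, P.alpha_r, P.x_r) == pytest.approx(0.5)
        assert ts.logistic(1.0, P.alpha_r, P.x_r) == pytest.approx(
            1 / (1 + np.exp(-3))
        )
        assert ts.logistic(0.7, P.alpha_s, P.x_s) == pytest.approx(0.5)


class TestRecurrentWeights:
    def test_known_entries(self):
        W = ts.recurrent_weights(P)
        assert W[1, 0] == pytest.approx(3.3 * np.exp(-0.16 / 50) - 2.8, abs=1e-9)
        assert W[1, 0] == pytest.approx(0.4895, abs=1e-4)
        assert W[0, 0] == pytest.approx(0.4763, abs=1e-4)
        assert W[0, 20] == pytest.approx(P.w_rec_min, abs=2e-3)

    def test_forward_asymmetry(self):
        W = ts.recurrent_weights(P)
        # peak shifted by delta toward i > j: forward weight beats self weight
        assert W[1, 0] > W[0, 0]
        assert W[10, 9] > W[9, 10]


class TestSTP:
    def test_single_euler_step_hand_values(self):
        f = np.array([0.14])
        d = np.array([0.0])
        f1, d1 = ts.stp_step(f, d, np.array([1.0]), P, 0.001)
        assert f1[0] == pytest.approx(0.14 + (0.001 / 0.32) * (-0.14 + 0.86 + 0.14))
        assert f1[0] == pytest.approx(0.142688, abs=1e-6)
        assert d1[0] == pytest.approx(0.001 / 0.06, rel=1e-9)

    @pytest.mark.parametrize("s, f_star, d_star", [(0.0, 0.14, 0.0), (1.0, 0.57, 1.0)])
    def test_fixed_points_by_long_integration(self, s, f_star, d_star):
        f = np.array([0.5])
        d = np.array([0.5])
        sig = np.array([s])
        for _ in range(20_000):
            f, d = ts.stp_step(f, d, sig, P, 0.001)
        assert f[0] == pytest.approx((s + P.f0) / (1 + s), abs=1e-6)
        assert f[0] == pytest.approx(f_star, abs=1e-6)
        assert d[0] == pytest.approx(d_star, abs=1e-6)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        sigs=arrays(
            float, 200, elements=st.floats(0, 1, allow_nan=False)
        )
    )
    def test_bounds_invariant(self, sigs):
        """f stays in [0, 1) and d in [0, 1] for any activation sequence."""
        f = np.array([P.f0])
        d = np.array([0.0])
        for s in sigs:
            f, d = ts.stp_step(f, d, np.array([s]), P, 0.001)
            assert 0.0 <= f[0] < 1.0
            assert 0.0 <= d[0] <= 1.0


class TestInputs:
    def test_external_input_zero_weights(self):
        s = np.ones(128)
        W = np.zeros((P.n_units, 128))
        i_ext = ts.external_input(s, W, np.pi / 2, P)
        expected = 0.4 * 1.0 / (1 + np.exp(12 * 0.7))
        assert np.allclose(i_ext, expected)
        assert np.all(i_ext >= 0)

    def test_external_input_maximal(self):
        s = np.ones(4)
        W = np.full((2, 4), 100.0)  # saturates sigma_s at 1
        i_ext = ts.external_input(s, W, np.pi / 2, P)
        assert np.allclose(i_ext, P.beta_max)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            ts.external_input(np.ones(5), np.zeros((3, 4)), 0.0, P)

    def test_init_current_window(self):
        i = ts.init_current(np.pi / 2, step_in_lap=50, p=P)  # 0.05 s < 0.125 s
        assert np.allclose(i[:5], 1.0)
        assert np.all(i[5:] == 0.0)
        assert np.all(ts.init_current(0.3, step_in_lap=200, p=P) == 0.0)


class TestPlasticity:
    def test_single_step_hand_value(self):
        state = ts.NetworkState(
            r=np.full(P.n_units, 100.0),  # sigma_r stays ~1 after one step
            f=np.full(P.n_units, P.f0),
            d=np.zeros(P.n_units),
            W_s=np.zeros((P.n_units, 3)),
        )
        drive = ts.DriveSnapshot(
            i_theta=0.0, beta_theta=1.0,
            i_init=np.zeros(P.n_units), i_ext=np.zeros(P.n_units),
        )
        W_rec = np.zeros((P.n_units, P.n_units))
        s = np.array([1.0, -1.0, 0.5])
        ts.network_step(state, drive, W_rec, P, 0.001, s=s)
        assert state.W_s[0] == pytest.approx([5e-5, -5e-5, 2.5e-5], rel=1e-6)

    def test_zero_when_gated_or_balanced(self):
        state = ts.NetworkState.initial(P, 2)
        drive = ts.DriveSnapshot(
            i_theta=0.0, beta_theta=0.0,
            i_init=np.zeros(P.n_units), i_ext=np.zeros(P.n_units),
        )
        ts.network_step(
            state, drive, np.zeros((P.n_units, P.n_units)), P, 0.001,
            s=np.ones(2),
        )
        assert np.all(state.W_s == 0.0)


# ---------------------------------------------------------------------------
# integration behavior


def _theta_of(t):
    return np.mod(2 * np.pi * 8.0 * t, 2 * np.pi)


def _free_run(state, p, dt, n_steps, t0=0.0, W_rec=None, i_theta=None):
    W_rec = ts.recurrent_weights(p) if W_rec is None else W_rec
    for k in range(n_steps):
        th = _theta_of(t0 + k * dt)
        drive = ts.DriveSnapshot(
            i_theta=ts.theta_drive(th, p) if i_theta is None else i_theta,
            beta_theta=ts.theta_gate(th, p),
            i_init=np.zeros(p.n_units),
            i_ext=np.zeros(p.n_units),
        )
        ts.network_step(state, drive, W_rec, p, dt)
    return state


class TestIntegration:
    def test_inhibition_shuts_down_activity(self):
        """Holding the trough drive silences the network within 50 ms."""
        rng = np.random.default_rng(0)
        state = ts.NetworkState(
            r=rng.uniform(0, 1.5, P.n_units),
            f=np.full(P.n_units, 0.4),
            d=np.full(P.n_units, 0.3),
            W_s=np.zeros((P.n_units, 1)),
        )
        _free_run(state, P, 0.001, 50, i_theta=-1.0)
        assert ts.logistic(state.r, P.alpha_r, P.x_r).max() < 0.02

    def test_relaxation_to_quiescent_fixed_point(self):
        """With zero drives the state settles (10 tau_r ~ within 1%)."""
        state = ts.NetworkState.initial(P, 1)
        _free_run(state, P, 0.001, 50, i_theta=0.0)
        r_50 = state.r.copy()
        _free_run(state, P, 0.001, 100, i_theta=0.0)
        denom = max(np.abs(state.r).max(), 1e-3)
        assert np.abs(state.r - r_50).max() / denom < 0.01

    def test_step_halving_accuracy(self):
        """Halving dt changes the r trajectory by < 1% over a theta cycle."""
        warm = ts.NetworkState.initial(P, 1)
        warm.r[:5] = 1.0  # seed a bump
        _free_run(warm, P, 0.001, 500)
        a = ts.NetworkState(warm.r.copy(), warm.f.copy(), warm.d.copy(),
                            warm.W_s.copy())
        b = ts.NetworkState(warm.r.copy(), warm.f.copy(), warm.d.copy(),
                            warm.W_s.copy())
        _free_run(a, P, 0.001, 125, t0=0.5)
        _free_run(b, P, 0.0005, 250, t0=0.5)
        scale = np.abs(a.r).max()
        assert np.abs(a.r - b.r).max() / scale < 0.01

    def test_non_finite_state_aborts(self):
        state = ts.NetworkState.initial(P, 1)
        state.r[0] = np.inf
        drive = ts.DriveSnapshot(0.0, 0.0, np.zeros(P.n_units), np.zeros(P.n_units))
        with pytest.raises(FloatingPointError):
            ts.network_step(state, drive, ts.recurrent_weights(P), P, 0.001)


class TestBackendEquivalence:
    def test_jit_matches_numpy_reference(self, short_traj):
        """The fast integrator and the plain-numpy stepper agree."""
        bank = ts.generate_features(ts.TrackSpec(), seed=3)
        cut = dataclasses.replace(ts.TrackSpec(), n_laps=1)
        sub = ts.Trajectory(
            t=short_traj.t[:2000], x=short_traj.x[:2000], v=short_traj.v[:2000],
            lap_id=short_traj.lap_id[:2000],
            theta_phase=short_traj.theta_phase[:2000],
            dt=short_traj.dt, track_length=short_traj.track_length,
        )
        a = ts.run_simulation(sub, bank, P, backend="numpy")
        b = ts.run_simulation(sub, bank, P, backend="numba")
        assert np.abs(a.sigma - b.sigma).max() < 1e-4
        assert np.abs(a.W_s - b.W_s).max() < 1e-8


# ---------------------------------------------------------------------------
# emergent sequence properties (full standard run)


class TestEmergentDynamics:
    def test_theta_rhythmicity(self, std_run):
        """Summed activation oscillates at the 8 Hz drive after warm-up."""
        cfg, traj, bank, sim = std_run
        keep = traj.t >= 80.0
        pop = sim.sigma[keep].sum(axis=1).astype(float)
        pop -= pop.mean()
        freqs = np.fft.rfftfreq(pop.size, d=traj.dt)
        spec = np.abs(np.fft.rfft(pop))
        dom = freqs[1:][np.argmax(spec[1:])]
        assert dom == pytest.approx(8.0, abs=0.25)

    def test_within_cycle_forward_propagation(self, std_run):
        """Inside a cycle the bump center of mass moves up the unit index."""
        cfg, traj, bank, sim = std_run
        from thetasweeps.decoding import segment_cycles

        cyc = segment_cycles(traj)
        units = np.arange(sim.sigma.shape[1])
        checked = 0
        for cid in range(900, 950):
            m = cyc == cid
            sub = sim.sigma[m]
            on = sub.max(axis=1) > 0.5
            if on.sum() < 20:
                continue
            act = sub[on][6:]  # skip the bump-formation transient
            com = (act * units).sum(axis=1) / act.sum(axis=1)
            assert np.all(np.diff(com) > -1.0)  # monotone up to 1-unit jitter
            checked += 1
        assert checked > 20

    def test_across_cycle_advance_within_lap(self, std_run):
        """The unit where the bump forms advances across a lap's cycles."""
        cfg, traj, bank, sim = std_run
        coms = bump_com_at_cycle_starts(sim.sigma, traj)
        lap = traj.lap_id.max() - 1  # a late, fully trained lap
        in_lap = sorted(
            c for (c, (lo, hi, com)) in coms.items() if traj.lap_id[lo] == lap
        )[4:]  # drop the lap-start re-initialization transient
        starts = np.array([coms[c][2] for c in in_lap])
        assert starts.size > 20
        assert np.all(np.diff(starts) > -1.0)
        assert starts[-1] - starts[0] > 30  # net forward progress

    def test_early_laps_behave_like_time_cells(self, std_run):
        """Pre-anchoring, propagation depth tracks lap duration."""
        cfg, traj, bank, sim = std_run
        durations, depths = [], []
        for lap in range(5):
            m = traj.lap_id == lap
            durations.append(m.sum() * traj.dt)
            active = np.flatnonzero(sim.sigma[m].max(axis=0) > 0.5)
            depths.append(active.max() if active.size else 0)
        r = np.corrcoef(durations, depths)[0, 1]
        assert r > 0

    def test_late_lap_maps_are_stable(self, std_run):
        """After learning, successive-lap rate maps correlate > 0.9."""
        cfg, traj, bank, sim = std_run
        last = traj.lap_id.max()
        maps = []
        for lap in (last - 1, last):
            m = traj.lap_id == lap
            sub = ts.Trajectory(
                traj.t[m], traj.x[m], traj.v[m], traj.lap_id[m],
                traj.theta_phase[m], traj.dt, traj.track_length,
            )
            maps.append(ts.activation_map(sim.sigma[m], sub, warmup_s=0.0))
        a, b = maps[0].values, maps[1].values
        keep = (a.max(axis=1) > 0.2) & (b.max(axis=1) > 0.2)
        r = np.corrcoef(a[keep].ravel(), b[keep].ravel())[0, 1]
        assert r > 0.9

    def test_elastic_anchoring_of_bump_to_position(self, std_run):
        """After learning, the cycle-start bump position in unit space is an
        anchored function of the animal's position: residuals around the
        learned unit<->position map stay small (bounded error), and the next
        cycle's advance corrects the current error (negative feedback)."""
        cfg, traj, bank, sim = std_run
        coms = bump_com_at_cycle_starts(sim.sigma, traj)
        lap_start: dict = {}
        for c, (lo, hi, com) in coms.items():
            lap_start.setdefault(traj.lap_id[lo], c)
        rows = []
        for cid in sorted(coms):
            if cid + 1 not in coms:
                continue
            lo, hi, com = coms[cid]
            lo2, _, com2 = coms[cid + 1]
            lap = traj.lap_id[lo]
            if (
                traj.t[lo] < 80.0
                or traj.lap_id[lo2] != lap
                or cid - lap_start[lap] < 4
            ):
                continue
            rows.append((float(traj.x[lo:hi].mean()), com, com2 - com))
        x, com, adv = map(np.asarray, zip(*rows))
        assert len(rows) > 200
        # learned map: position-binned mean bump position
        xbin = (x // 5).astype(int)
        expect = np.zeros_like(com)
        for b in np.unique(xbin):
            expect[xbin == b] = com[xbin == b].mean()
        resid = com - expect
        assert resid.std() < 5.0  # anchored: a few units of jitter only
        assert np.corrcoef(resid, adv)[0, 1] < 0  # error-correcting advance

    def test_weights_remain_bounded(self, std_run):
        cfg, traj, bank, sim = std_run
        assert np.isfinite(sim.W_s).all()
        assert np.abs(sim.W_s).max() < 10.0

    def test_ws_snapshots_per_lap(self, short_traj):
        bank = ts.generate_features(ts.TrackSpec(), seed=3)
        sim = ts.run_simulation(short_traj, bank, P, record_ws_per_lap=True)
        assert len(sim.W_s_per_lap) == 3
        assert np.all(sim.W_s_per_lap[0] == 0.0)
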