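"""Recurrent place-cell network with short-term plasticity and Hebbian
spatial anchoring.

The model is a 1-D continuous-attractor rate network of ``n_units`` units.
Unit activation r follows

    tau_r dr/dt = -r + i_theta + W_rec ((1-d) * f * sigma_r(r)) + i_init + i_ext

driven by (i) a theta-rhythmic global excitation/inhibition ``i_theta``
(excitation peaks at theta = pi, inhibition at theta = 0), (ii) recurrent
input through a Gaussian weight profile with a small forward asymmetry
``delta`` that makes activity bumps propagate, modulated presynaptically by
short-term facilitation f (slow) and depression d (fast), (iii) a lap-start
kick ``i_init`` to the first few units, and (iv) spatial input
``i_ext = beta_max * beta_theta * sigma_s(W_s s)`` from frozen weakly tuned
features s, gated to the early part of each theta cycle by ``beta_theta``
(peak at theta = pi/2).  The input weights W_s start at zero and learn with
a normalized Hebbian rule

    tau_w dW_s/dt = beta_theta * (sigma_r(r) - i_ext) (x) s

so that over laps each unit becomes anchored to the locations where it is
internally active, at a density inversely proportional to the typical
running speed (elastic mapping).

Integration is forward Euler at the trajectory's time step.  A numba-jitted
loop is used when available; an equivalent pure-numpy stepper
(:func:`network_step`) serves as the reference implementation and is what
the tests cross-check the fast path against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .behavior import Trajectory, target_speed
from .config import NetworkParams, SpeedProfile, TrackSpec
from .features import FeatureBank, feature_bin_index

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):  # type: ignore
        def deco(f):
            return f

        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


__all__ = [
    "NetworkState",
    "DriveSnapshot",
    "SimResult",
    "theta_drive",
    "theta_gate",
    "recurrent_weights",
    "logistic",
    "stp_step",
    "external_input",
    "init_current",
    "network_step",
    "run_simulation",
]


# ---------------------------------------------------------------------------
# elementary pieces


def theta_drive(theta: float | np.ndarray, p: NetworkParams) -> float | np.ndarray:
    """Rhythmic drive i_theta: trough i_theta_min at theta=0, peak near
    i_theta_max at theta=pi."""
    return (
        -(p.i_theta_max - p.i_theta_min)
        * np.exp(p.kappa_theta * np.cos(theta))
        / np.exp(p.kappa_theta)
        + p.i_theta_max
    )


def theta_gate(theta: float | np.ndarray, p: NetworkParams) -> float | np.ndarray:
    """Input/plasticity gate beta_theta in (0, 1], peaking at theta=pi/2."""
    return np.exp(p.kappa_s * np.sin(theta)) / np.exp(p.kappa_s)


def logistic(x: float | np.ndarray, alpha: float, x0: float) -> float | np.ndarray:
    """1 / (1 + exp(-alpha (x - x0))); sigma_r and sigma_s."""
    return 1.0 / (1.0 + np.exp(-alpha * (np.asarray(x, dtype=float) - x0)))


def _offset_profile(offsets: np.ndarray, p: NetworkParams, delta: float) -> np.ndarray:
    return (p.w_rec_max - p.w_rec_min) * np.exp(
        -((offsets - delta) ** 2) / (2.0 * p.sigma_rec**2)
    ) + p.w_rec_min


def recurrent_weights(p: NetworkParams) -> np.ndarray:
    """W_rec[i, j]: Gaussian in (i - j - delta), shifted by delta toward
    i > j so bumps propagate up the unit index."""
    idx = np.arange(p.n_units)
    return _offset_profile(idx[:, None] - idx[None, :], p, p.delta)


def stp_step(
    f: np.ndarray,
    d: np.ndarray,
    sigma_r_of_r: np.ndarray,
    p: NetworkParams,
    dt: float,
) -> tuple[np.ndarray, np.ndarray]:
    """One Euler step of facilitation and depression.

    tau_f df/dt = -f + (1 - f) s + f0 ;  tau_d dd/dt = -d + s,
    with s = sigma_r(r).  Fixed points: f* = (s + f0)/(1 + s), d* = s.
    """
    s = sigma_r_of_r
    f_new = f + dt / p.tau_f * (-f + (1.0 - f) * s + p.f0)
    d_new = d + dt / p.tau_d * (-d + s)
    return f_new, d_new


def external_input(
    s: np.ndarray, W_s: np.ndarray, theta: float, p: NetworkParams
) -> np.ndarray:
    """Spatial input i_ext = beta_max * beta_theta * sigma_s(W_s s) >= 0."""
    if W_s.shape[1] != s.shape[0]:
        raise ValueError("W_s and feature vector shapes do not match")
    return p.beta_max * theta_gate(theta, p) * logistic(W_s @ s, p.alpha_s, p.x_s)


def init_current(
    theta: float,
    step_in_lap: int,
    p: NetworkParams,
    theta_freq: float = 8.0,
    dt: float = 0.001,
) -> np.ndarray:
    """Lap-start kick: beta_theta on the first ``n_init_units`` units while
    the lap-elapsed time is under one theta cycle, else zero."""
    if step_in_lap < 0:
        raise ValueError("step_in_lap must be >= 0")
    out = np.zeros(p.n_units)
    if step_in_lap * dt < 1.0 / theta_freq:
        out[: p.n_init_units] = theta_gate(theta, p)
    return out


# ---------------------------------------------------------------------------
# state containers


@dataclass
class NetworkState:
    """r: activation; f: facilitation; d: depression; W_s: plastic input
    weights, oriented unit x feature."""

    r: np.ndarray
    f: np.ndarray
    d: np.ndarray
    W_s: np.ndarray

    @classmethod
    def initial(cls, p: NetworkParams, n_features: int) -> "NetworkState":
        return cls(
            r=np.zeros(p.n_units),
            f=np.full(p.n_units, p.f0),
            d=np.zeros(p.n_units),
            W_s=np.zeros((p.n_units, n_features)),
        )

    def reset_lap(self, p: NetworkParams) -> None:
        """Lap-start reset: r -> 0, d -> 0, f -> f0 (W_s persists)."""
        self.r[:] = 0.0
        self.d[:] = 0.0
        self.f[:] = p.f0


@dataclass
class DriveSnapshot:
    """Per-step drives entering the rate equation."""

    i_theta: float
    beta_theta: float
    i_init: np.ndarray
    i_ext: np.ndarray


def network_step(
    state: NetworkState,
    drive: DriveSnapshot,
    W_rec: np.ndarray,
    p: NetworkParams,
    dt: float,
    s: np.ndarray | None = None,
) -> NetworkState:
    """One forward-Euler step of the full network (reference implementation).

    Order: r is updated with the pre-update f, d, sigma_r(r); f and d with
    the pre-update sigma_r(r); W_s with the post-update sigma_r(r) (if the
    feature vector ``s`` is given).  Mutates ``state`` in place and returns
    it.
    """
    sig = logistic(state.r, p.alpha_r, p.x_r)
    rec = W_rec @ ((1.0 - state.d) * state.f * sig)
    state.r = state.r + dt / p.tau_r * (
        -state.r + drive.i_theta + rec + drive.i_init + drive.i_ext
    )
    state.f, state.d = stp_step(state.f, state.d, sig, p, dt)
    if not np.all(np.isfinite(state.r)):
        raise FloatingPointError("network state became non-finite")
    if s is not None:
        sig_post = logistic(state.r, p.alpha_r, p.x_r)
        state.W_s = state.W_s + (dt / p.tau_w * drive.beta_theta) * np.outer(
            sig_post - drive.i_ext, s
        )
    return state


# ---------------------------------------------------------------------------
# full simulation


@dataclass
class SimResult:
    """Per-step traces of one closed-loop run.

    sigma : (n_steps, n_units) float32, post-update sigma_r(r) — the
        activation all analyses operate on.
    i_ext : (n_steps, n_units) float32 spatial drive (the "true" tuning).
    W_s : final plastic input weights.
    W_s_per_lap : optional W_s snapshots taken at each lap start.
    """

    sigma: np.ndarray
    i_ext: np.ndarray
    W_s: np.ndarray
    trajectory: Trajectory
    W_s_per_lap: list[np.ndarray] = field(default_factory=list)


@njit(cache=True)
def _integrate_jit(
    W_rec,
    W_s,
    featT,
    feat_idx,
    i_theta_arr,
    beta_arr,
    init_on,
    lap_start,
    delta_eff,
    w_amp,
    w_min,
    sigma_rec,
    use_dynamic_delta,
    tau_r,
    alpha_r,
    x_r,
    tau_f,
    tau_d,
    f0,
    beta_max,
    alpha_s,
    x_s,
    tau_w,
    n_init_units,
    dt,
    out_sig,
    out_iext,
):  # pragma: no cover - compiled; covered via run_simulation
    n_steps = feat_idx.shape[0]
    n = W_rec.shape[0]
    nf = W_s.shape[1]
    r = np.zeros(n)
    f = np.full(n, f0)
    d = np.zeros(n)
    for t in range(n_steps):
        if lap_start[t]:
            for i in range(n):
                r[i] = 0.0
                d[i] = 0.0
                f[i] = f0
        s = featT[feat_idx[t]]
        sig = 1.0 / (1.0 + np.exp(-alpha_r * (r - x_r)))
        u = W_s @ s
        bm = beta_max * beta_arr[t]
        iext = bm / (1.0 + np.exp(-alpha_s * (u - x_s)))
        h = (1.0 - d) * f * sig
        if use_dynamic_delta:
            rec = np.zeros(n)
            dlt = delta_eff[t]
            for i in range(n):
                acc = 0.0
                for j in range(n):
                    off = i - j - dlt
                    acc += (
                        w_amp * np.exp(-(off * off) / (2.0 * sigma_rec * sigma_rec))
                        + w_min
                    ) * h[j]
                rec[i] = acc
        else:
            rec = W_rec @ h
        ith = i_theta_arr[t]
        kick = beta_arr[t] if init_on[t] else 0.0
        for i in range(n):
            ii = kick if i < n_init_units else 0.0
            r[i] += dt / tau_r * (-r[i] + ith + rec[i] + ii + iext[i])
            f[i] += dt / tau_f * (-f[i] + (1.0 - f[i]) * sig[i] + f0)
            d[i] += dt / tau_d * (-d[i] + sig[i])
        coef = dt / tau_w * beta_arr[t]
        for i in range(n):
            sig2 = 1.0 / (1.0 + np.exp(-alpha_r * (r[i] - x_r)))
            c = coef * (sig2 - iext[i])
            for j in range(nf):
                W_s[i, j] += c * s[j]
            out_sig[t, i] = sig2
            out_iext[t, i] = iext[i]
    return r, f, d


def _integrate_numpy(
    W_rec,
    W_s,
    featT,
    feat_idx,
    i_theta_arr,
    beta_arr,
    init_on,
    lap_start,
    p: NetworkParams,
    dt,
    out_sig,
    out_iext,
):
    n = W_rec.shape[0]
    r = np.zeros(n)
    f = np.full(n, p.f0)
    d = np.zeros(n)
    for t in range(feat_idx.shape[0]):
        if lap_start[t]:
            r[:] = 0.0
            d[:] = 0.0
            f[:] = p.f0
        s = featT[feat_idx[t]]
        sig = 1.0 / (1.0 + np.exp(-p.alpha_r * (r - p.x_r)))
        iext = (p.beta_max * beta_arr[t]) / (
            1.0 + np.exp(-p.alpha_s * (W_s @ s - p.x_s))
        )
        rec = W_rec @ ((1.0 - d) * f * sig)
        i_init = np.zeros(n)
        if init_on[t]:
            i_init[: p.n_init_units] = beta_arr[t]
        r += dt / p.tau_r * (-r + i_theta_arr[t] + rec + i_init + iext)
        f += dt / p.tau_f * (-f + (1.0 - f) * sig + p.f0)
        d += dt / p.tau_d * (-d + sig)
        sig2 = 1.0 / (1.0 + np.exp(-p.alpha_r * (r - p.x_r)))
        W_s += (dt / p.tau_w * beta_arr[t]) * ((sig2 - iext)[:, None] * s[None, :])
        out_sig[t] = sig2
        out_iext[t] = iext
    return r, f, d


def run_simulation(
    trajectory: Trajectory,
    bank: FeatureBank,
    p: NetworkParams,
    theta_freq: float = 8.0,
    backend: str = "auto",
    record_ws_per_lap: bool = False,
    profile: SpeedProfile | None = None,
    track: TrackSpec | None = None,
) -> SimResult:
    """Integrate the network along a precomputed trajectory.

    At each lap start r and d are reset to 0 and f to f0, W_s persists, and
    the first ``n_init_units`` units receive the beta_theta kick for the
    duration of one theta cycle of lap-elapsed time (theta itself is
    free-running).  Returns per-step sigma_r(r) and i_ext traces (float32)
    plus the final W_s.

    backend: "auto" (numba if available), "numba", or "numpy" (reference).
    ``profile``/``track`` are only needed when ``p.delta_speed_gain`` != 0,
    to form the v / v̄ ratio that modulates the propagation asymmetry.
    """
    n_steps = trajectory.n_steps
    dt = trajectory.dt
    feat_idx = feature_bin_index(bank, trajectory.x)
    featT = np.ascontiguousarray(bank.values.T)  # (n_bins, n_features)
    i_theta_arr = theta_drive(trajectory.theta_phase, p)
    beta_arr = theta_gate(trajectory.theta_phase, p)

    lap_start = np.zeros(n_steps, dtype=np.bool_)
    lap_start[0] = True
    lap_start[1:] = trajectory.lap_id[1:] != trajectory.lap_id[:-1]
    # steps since the current lap started
    starts = np.flatnonzero(lap_start)
    step_in_lap = np.arange(n_steps) - np.repeat(
        starts, np.diff(np.append(starts, n_steps))
    )
    init_on = step_in_lap * dt < 1.0 / theta_freq

    use_dyn = p.delta_speed_gain != 0.0
    if use_dyn:
        if profile is None or track is None:
            raise ValueError("delta_speed_gain needs profile and track")
        vbar = target_speed(trajectory.x, profile, track)
        ratio = trajectory.v / vbar
        delta_eff = p.delta * (1.0 + p.delta_speed_gain * (ratio - 1.0))
    else:
        delta_eff = np.full(1, p.delta)

    W_rec = recurrent_weights(p)
    W_s = np.zeros((p.n_units, bank.n_features))
    out_sig = np.empty((n_steps, p.n_units), dtype=np.float32)
    out_iext = np.empty((n_steps, p.n_units), dtype=np.float32)

    if backend == "auto":
        backend = "numba" if _HAVE_NUMBA else "numpy"
    if backend == "numba" and not _HAVE_NUMBA:
        raise RuntimeError("numba backend requested but numba is unavailable")

    snapshots: list[np.ndarray] = []
    if record_ws_per_lap:
        # run lap by lap through the same core so snapshots are cheap
        for s0, s1 in zip(starts, np.append(starts[1:], n_steps)):
            snapshots.append(W_s.copy())
            _run_core(
                backend, W_rec, W_s, featT, feat_idx[s0:s1], i_theta_arr[s0:s1],
                beta_arr[s0:s1], init_on[s0:s1], lap_start[s0:s1],
                delta_eff if not use_dyn else delta_eff[s0:s1], use_dyn, p, dt,
                out_sig[s0:s1], out_iext[s0:s1],
            )
    else:
        _run_core(
            backend, W_rec, W_s, featT, feat_idx, i_theta_arr, beta_arr,
            init_on, lap_start, delta_eff, use_dyn, p, dt, out_sig, out_iext,
        )

    if not (np.isfinite(W_s).all() and np.isfinite(out_sig[-1]).all()):
        raise FloatingPointError("simulation diverged: non-finite state")
    return SimResult(
        sigma=out_sig,
        i_ext=out_iext,
        W_s=W_s,
        trajectory=trajectory,
        W_s_per_lap=snapshots,
    )


def _run_core(
    backend, W_rec, W_s, featT, feat_idx, i_theta_arr, beta_arr, init_on,
    lap_start, delta_eff, use_dyn, p: NetworkParams, dt, out_sig, out_iext,
):
    if backend == "numba":
        _integrate_jit(
            W_rec, W_s, featT, feat_idx.astype(np.int64),
            np.ascontiguousarray(i_theta_arr), np.ascontiguousarray(beta_arr),
            init_on, lap_start, np.ascontiguousarray(delta_eff, dtype=float),
            p.w_rec_max - p.w_rec_min, p.w_rec_min, p.sigma_rec, use_dyn,
            p.tau_r, p.alpha_r, p.x_r, p.tau_f, p.tau_d, p.f0, p.beta_max,
            p.alpha_s, p.x_s, p.tau_w, p.n_init_units, dt, out_sig, out_iext,
        )
    elif backend == "numpy":
        if use_dyn:
            raise NotImplementedError(
                "delta_speed_gain is only implemented in the numba backend"
            )
        _integrate_numpy(
            W_rec, W_s, featT, feat_idx, i_theta_arr, beta_arr, init_on,
            lap_start, p, dt, out_sig, out_iext,
        )
    else:
        raise ValueError(f"unknown backend {backend!r}")
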