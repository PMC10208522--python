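"""Simulated running behavior on the linear track.

The virtual rat runs laps on a 1-D track with a position-dependent target
mean speed (triangular profile: slow at both ends, fast in the middle) and
smooth multiplicative lap-to-lap speed variability.  On reaching the track
end it is teleported back to the start.  Theta phase is free-running at a
fixed frequency and is *not* reset at lap boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .config import SpeedNoiseSpec, SpeedProfile, TrackSpec

__all__ = [
    "Trajectory",
    "target_speed",
    "speed_noise_factor",
    "simulate_trajectory",
]


@dataclass
class Trajectory:
    """Per-time-step behavioral state.

    t : time since session start, s.  x : position, cm (0-based, resets to 0
    at each teleport).  v : instantaneous speed, cm/s.  lap_id : 0-based lap
    counter, non-decreasing.  theta_phase : radians in [0, 2*pi).
    """

    t: np.ndarray
    x: np.ndarray
    v: np.ndarray
    lap_id: np.ndarray
    theta_phase: np.ndarray
    dt: float
    track_length: float

    @property
    def n_steps(self) -> int:
        return self.t.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "x": self.x,
                "v": self.v,
                "lap_id": self.lap_id,
                "theta_phase": self.theta_phase,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def target_speed(
    x: float | np.ndarray, profile: SpeedProfile, track: TrackSpec
) -> float | np.ndarray:
    """Target mean running speed v̄(x) in cm/s.

    Piecewise-linear between (0, v_end), (length/2, v_mid), (length, v_end).
    """
    xa = np.asarray(x, dtype=float)
    if np.any(xa < 0) or np.any(xa > track.length):
        raise ValueError("position outside the track")
    half = track.length / 2.0
    out = np.where(
        xa <= half,
        profile.v_end + (profile.v_mid - profile.v_end) * xa / half,
        profile.v_end + (profile.v_mid - profile.v_end) * (track.length - xa) / half,
    )
    return float(out) if np.isscalar(x) else out


def speed_noise_factor(
    n_steps: int,
    spec: SpeedNoiseSpec,
    seed: int | np.random.Generator,
    dt: float = 0.001,
    _raw: np.ndarray | None = None,
) -> np.ndarray:
    """Smooth multiplicative speed-noise series of length ``n_steps``.

    White Gaussian noise (one sample per time step) is convolved with a
    Gaussian kernel (std ``spec.kernel_std`` seconds, truncated at +-4 std,
    reflective boundaries) and affinely rescaled over the whole series so
    that its minimum is ``spec.lo``, its maximum ``spec.hi``, and the
    pre-scaling midpoint maps to ``spec.center``.  A zero-variance series
    maps to the constant ``spec.center``.

    ``_raw`` injects a deterministic pre-convolution noise series (testing
    hook).
    """
    if n_steps <= 0:
        raise ValueError("n_steps must be positive")
    sigma_steps = spec.kernel_std / dt
    if n_steps < sigma_steps:
        raise ValueError(
            f"series of {n_steps} steps is shorter than the smoothing kernel "
            f"std ({sigma_steps:.0f} steps); cannot be scaled meaningfully"
        )
    if _raw is None:
        rng = np.random.default_rng(seed)
        raw = rng.standard_normal(n_steps)
    else:
        raw = np.asarray(_raw, dtype=float)
        if raw.size != n_steps:
            raise ValueError("_raw length mismatch")
    smooth = gaussian_filter1d(raw, sigma=sigma_steps, mode="reflect", truncate=4.0)
    lo, hi = smooth.min(), smooth.max()
    if hi - lo < 1e-12:  # degenerate: no variation to rescale
        return np.full(n_steps, spec.center)
    # affine map: lo -> spec.lo, hi -> spec.hi (midpoint -> spec.center)
    return spec.lo + (smooth - lo) * (spec.hi - spec.lo) / (hi - lo)


def simulate_trajectory(
    track: TrackSpec,
    profile: SpeedProfile,
    noise: SpeedNoiseSpec,
    theta_freq: float = 8.0,
    seed: int | np.random.Generator = 0,
    noise_factors: np.ndarray | None = None,
) -> Trajectory:
    """Simulate ``track.n_laps`` laps by forward-Euler position updates.

    Each step the instantaneous speed is v = v̄(x) * noise_factor; the
    position advances by v*dt; on reaching the track end the rat is
    teleported to x = 0 and the lap counter increments.  The noise-factor
    series is generated up front for the worst-case session duration
    (factor >= lo everywhere bounds the lap time) and consumed sequentially.

    ``noise_factors`` overrides the generated series (testing hook).
    """
    if theta_freq <= 0:
        raise ValueError("theta_freq must be positive")
    dt = track.dt
    if noise_factors is None:
        # worst-case lap time: factor >= lo throughout
        t_lap = _deterministic_lap_time(track, profile)
        n_max = int(np.ceil(track.n_laps * t_lap / noise.lo / dt)) + 1000
        factors = speed_noise_factor(n_max, noise, seed, dt=dt)
    else:
        factors = np.asarray(noise_factors, dtype=float)
        n_max = factors.size

    half = track.length / 2.0
    slope = (profile.v_mid - profile.v_end) / half
    x_arr = np.empty(n_max)
    v_arr = np.empty(n_max)
    lap_arr = np.empty(n_max, dtype=np.int32)

    x = 0.0
    lap = 0
    i = 0
    while lap < track.n_laps:
        if i >= n_max:
            raise RuntimeError("noise-factor series exhausted before last lap")
        vbar = profile.v_end + slope * (x if x <= half else track.length - x)
        v = vbar * factors[i]
        x_arr[i] = x
        v_arr[i] = v
        lap_arr[i] = lap
        x += v * dt
        if x >= track.length:
            x = 0.0
            lap += 1
        i += 1

    n = i
    t = np.arange(n) * dt
    theta = np.mod(2.0 * np.pi * theta_freq * t, 2.0 * np.pi)
    return Trajectory(
        t=t,
        x=x_arr[:n],
        v=v_arr[:n],
        lap_id=lap_arr[:n],
        theta_phase=theta,
        dt=dt,
        track_length=track.length,
    )


def _deterministic_lap_time(track: TrackSpec, profile: SpeedProfile) -> float:
    """Time to cross the track at the target profile speed (closed form)."""
    half = track.length / 2.0
    slope = (profile.v_mid - profile.v_end) / half
    if slope == 0:
        return track.length / profile.v_end
    return 2.0 / slope * np.log(profile.v_mid / profile.v_end)
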