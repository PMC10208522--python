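"""Population-vector decoding and theta-sweep metrics.

Represented position is decoded per time step by Pearson-correlating the
instantaneous population activation against the template population vector
of each spatial bin (the smoothed measured activation map).  Theta cycles
are segmented at the inhibition trough (theta = 0); within each cycle the
decoded trajectory is summarized by where the sweep starts relative to the
animal (look-behind), where it ends (look-ahead) and its total length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .behavior import Trajectory, target_speed
from .config import SpeedProfile, TrackSpec
from .placefields import ActivationMap

__all__ = [
    "DecodedTrajectory",
    "decode",
    "decode_step",
    "segment_cycles",
    "sweep_metrics",
    "lookbehind_vs_shift",
]


@dataclass
class DecodedTrajectory:
    """Per-step decoding result: decoded position (cm, NaN if invalid),
    decoded bin index (-1 if invalid), validity flag and winning
    correlation."""

    pos: np.ndarray
    bin: np.ndarray
    valid: np.ndarray
    best_corr: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "decoded_pos": self.pos,
                "decoded_bin": self.bin,
                "valid": self.valid,
                "best_corr": self.best_corr,
            }
        )


def _zscore_rows(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = a.mean(axis=1, keepdims=True)
    sd = a.std(axis=1, keepdims=True)
    ok = sd[:, 0] > 0
    z = np.zeros_like(a)
    np.divide(a - mu, sd, out=z, where=sd > 0)
    return z, ok


def decode(
    sigma: np.ndarray,
    templates: ActivationMap,
    min_activation: float = 0.1,
) -> DecodedTrajectory:
    """Decode every time step of ``sigma`` (steps x units) against the
    spatial-bin templates.

    A step is decodable only if at least one unit's activation exceeds
    ``min_activation`` (this drops the inhibited troughs between theta
    cycles) and its population vector has nonzero variance.  The bin with
    the highest Pearson correlation wins; ties go to the lowest bin index.
    """
    n_steps, n_units = sigma.shape
    T = templates.values.T  # (n_bins, n_units)
    if T.shape[1] != n_units:
        raise ValueError("template/population sizes differ")
    Tz, t_ok = _zscore_rows(T)
    Tz[~t_ok] = 0.0  # zero-variance template bins can never win

    valid = sigma.max(axis=1) > min_activation
    pop = np.asarray(sigma[valid], dtype=float)
    Pz, p_ok = _zscore_rows(pop)
    corr = (Pz @ Tz.T) / n_units  # (n_valid, n_bins)
    corr[:, ~t_ok] = -np.inf
    best = np.argmax(corr, axis=1)
    best_corr = corr[np.arange(best.size), best]

    bin_out = np.full(n_steps, -1, dtype=np.int64)
    pos_out = np.full(n_steps, np.nan)
    corr_out = np.full(n_steps, np.nan)
    vidx = np.flatnonzero(valid)
    ok = p_ok
    bin_out[vidx[ok]] = best[ok]
    pos_out[vidx[ok]] = templates.centers[best[ok]]
    corr_out[vidx[ok]] = best_corr[ok]
    valid_out = np.zeros(n_steps, dtype=bool)
    valid_out[vidx[ok]] = True
    return DecodedTrajectory(
        pos=pos_out, bin=bin_out, valid=valid_out, best_corr=corr_out
    )


def decode_step(
    pop_vector: np.ndarray,
    templates: ActivationMap,
    min_activation: float = 0.1,
) -> tuple[int, float, bool]:
    """Single-step convenience wrapper around :func:`decode`."""
    d = decode(pop_vector[None, :], templates, min_activation)
    return int(d.bin[0]), float(d.best_corr[0]), bool(d.valid[0])


def segment_cycles(trajectory: Trajectory) -> np.ndarray:
    """Theta-cycle id per step; boundaries at the phase wrap (theta = 0,
    the inhibition trough, so each cycle contains one contiguous active
    epoch)."""
    ph = trajectory.theta_phase
    wrap = np.zeros(ph.size, dtype=bool)
    wrap[1:] = ph[1:] < ph[:-1]
    return np.cumsum(wrap)


def sweep_metrics(
    decoded: DecodedTrajectory,
    trajectory: Trajectory,
    profile: SpeedProfile | None = None,
    track: TrackSpec | None = None,
    warmup_s: float = 80.0,
    n_phase_bins: int = 10,
    n_track_bins: int | None = None,
) -> pd.DataFrame:
    """Per-theta-cycle sweep statistics.

    Each cycle is split into ``n_phase_bins`` equal phase windows (36
    degrees by default) anchored at the cycle start.  The sweep start/end
    are the first/last windows containing at least one valid decoded step;
    look_behind = mean real - mean decoded position in the first window,
    look_ahead = mean decoded - mean real position in the last window,
    length = mean decoded(last) - mean decoded(first).  Cycles are excluded
    if they fall in the warm-up, contain a lap teleport, have no valid
    decoded step, or if the first or last spatial bin of the track wins the
    correlation anywhere in the cycle (boundary artifacts).
    """
    cyc = segment_cycles(trajectory)
    max_bin = (n_track_bins - 1) if n_track_bins else decoded.bin.max()
    ph_bin = np.minimum(
        (trajectory.theta_phase / (2 * np.pi) * n_phase_bins).astype(np.int64),
        n_phase_bins - 1,
    )
    rows = []
    order = np.arange(trajectory.n_steps)
    for cid in range(cyc.max() + 1):
        lo = np.searchsorted(cyc, cid, side="left")
        hi = np.searchsorted(cyc, cid, side="right")
        sl = order[lo:hi]
        if trajectory.t[sl[0]] < warmup_s:
            continue
        if trajectory.lap_id[sl[-1]] != trajectory.lap_id[sl[0]]:
            continue  # spans a teleport
        vmask = decoded.valid[sl]
        if not vmask.any():
            continue
        bins_here = decoded.bin[sl][vmask]
        if bins_here.min() == 0 or bins_here.max() == max_bin:
            excluded, reason = True, "boundary_bin"
        else:
            excluded, reason = False, ""
        pb = ph_bin[sl]
        valid_pb = pb[vmask]
        first_b, last_b = valid_pb.min(), valid_pb.max()
        m_first = vmask & (pb == first_b)
        m_last = vmask & (pb == last_b)
        dec_first = decoded.pos[sl][m_first].mean()
        dec_last = decoded.pos[sl][m_last].mean()
        real_first = trajectory.x[sl][m_first].mean()
        real_last = trajectory.x[sl][m_last].mean()
        mean_real = trajectory.x[sl].mean()
        rows.append(
            dict(
                cycle_id=cid,
                look_behind=real_first - dec_first,
                look_ahead=dec_last - real_last,
                length=dec_last - dec_first,
                mean_real_pos=mean_real,
                mean_speed_at_pos=(
                    float(target_speed(min(mean_real, track.length), profile, track))
                    if profile is not None and track is not None
                    else np.nan
                ),
                excluded=excluded,
                reason=reason,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cycle_id", "look_behind", "look_ahead", "length",
            "mean_real_pos", "mean_speed_at_pos", "excluded", "reason",
        ],
    )


def lookbehind_vs_shift(
    sweeps: pd.DataFrame,
    shifts: pd.DataFrame,
    track_length: float = 200.0,
    bin_size: float = 10.0,
    min_samples: int = 5,
) -> dict:
    """Compare the look-behind distance of sweeps with the backward place
    field shift, both binned by track position.

    Sweeps are binned by their mean real position, shifts by the measured
    field peak.  Returns the per-bin paired means plus the slope/intercept
    and Pearson r of regressing mean look-behind on mean shift (identity
    slope ~ 1 means the two quantities agree).
    """
    sw = sweeps[~sweeps.excluded]
    edges = np.arange(0.0, track_length + bin_size / 2, bin_size)
    lb_means, sh_means, centers = [], [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        m_sw = (sw.mean_real_pos >= lo) & (sw.mean_real_pos < hi)
        m_sh = (shifts.measured_peak >= lo) & (shifts.measured_peak < hi)
        if m_sw.sum() >= min_samples and m_sh.sum() >= min_samples:
            lb_means.append(sw.look_behind[m_sw].mean())
            sh_means.append(shifts.backward_shift_cm[m_sh].mean())
            centers.append((lo + hi) / 2.0)
    lb = np.asarray(lb_means)
    sh = np.asarray(sh_means)
    if lb.size < 3:
        return dict(slope=np.nan, intercept=np.nan, r=np.nan,
                    bin_centers=centers, look_behind=lb, shift=sh)
    slope, intercept = np.polyfit(sh, lb, 1)
    r = np.corrcoef(sh, lb)[0, 1]
    return dict(slope=slope, intercept=intercept, r=r,
                bin_centers=centers, look_behind=lb, shift=sh)
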