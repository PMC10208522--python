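"""Place-field analysis: activation maps, field extraction, shifts,
phase precession, instantaneous-speed invariance and field density.

"Measured" fields are computed from the units' output activation
sigma_r(r); "true" fields from the spatial drive i_ext using the identical
pipeline.  The backward shift between the two, divided by the typical
running speed through the field, is the temporal field shift the decoding
analysis inherits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.odr
from scipy.ndimage import gaussian_filter1d

from .behavior import Trajectory, target_speed
from .config import AnalysisParams, SpeedProfile, TrackSpec

__all__ = [
    "field_peaks",
    "ActivationMap",
    "activation_map",
    "extract_fields",
    "field_mean_speeds",
    "field_shifts",
    "phase_map",
    "precession_slope",
    "precession_slopes",
    "speed_quantile_masks",
    "instantaneous_speed_ratios",
    "field_density",
    "density_speed_fit",
]


# ---------------------------------------------------------------------------
# activation maps


@dataclass
class ActivationMap:
    """Mean activation per unit per spatial bin.

    values : (n_units, n_bins), Gaussian-smoothed along space.
    raw : same before smoothing (NaN where a bin was never visited).
    occupancy : steps per bin.
    """

    values: np.ndarray
    raw: np.ndarray
    occupancy: np.ndarray
    bin_size: float
    track_length: float

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def centers(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_size


def _bin_means(
    signal: np.ndarray, bin_idx: np.ndarray, n_bins: int
) -> tuple[np.ndarray, np.ndarray]:
    counts = np.bincount(bin_idx, minlength=n_bins).astype(float)
    sums = np.zeros((n_bins, signal.shape[1]))
    np.add.at(sums, bin_idx, signal)
    with np.errstate(invalid="ignore"):
        means = sums / counts[:, None]
    return means.T, counts  # (n_units, n_bins)


def _fill_nan(row: np.ndarray) -> np.ndarray:
    bad = np.isnan(row)
    if bad.any():
        idx = np.arange(row.size)
        row = row.copy()
        row[bad] = np.interp(idx[bad], idx[~bad], row[~bad])
    return row


def activation_map(
    signal: np.ndarray,
    trajectory: Trajectory,
    warmup_s: float = 80.0,
    bin_size: float = 2.0,
    smooth_std: float = 3.0,
    gate: np.ndarray | None = None,
) -> ActivationMap:
    """Mean of ``signal`` (steps x units) per spatial bin, after discarding
    the warm-up period, Gaussian-smoothed along space (std in cm; kernel
    normalized, reflective boundaries).  Never-visited bins are flagged NaN
    in ``raw`` and linearly interpolated before smoothing.

    ``gate``: optional per-step modulation series the signal is known to be
    multiplied by (the theta gate beta_theta for the spatial drive i_ext).
    When given, each bin's mean signal is divided by that bin's mean gate,
    recovering the spatial modulation envelope on its natural scale — for
    i_ext that is beta_max * sigma_s(W_s s(x)) — so the same peak threshold
    applies to measured and true maps.
    """
    if signal.shape[0] != trajectory.n_steps:
        raise ValueError("signal and trajectory are not aligned")
    keep = trajectory.t >= warmup_s
    n_bins = int(round(trajectory.track_length / bin_size))
    bin_idx = np.minimum(
        (trajectory.x[keep] / bin_size).astype(np.int64), n_bins - 1
    )
    raw, occ = _bin_means(np.asarray(signal[keep], dtype=float), bin_idx, n_bins)
    if gate is not None:
        gate_mean, _ = _bin_means(
            np.asarray(gate[keep], dtype=float)[:, None], bin_idx, n_bins
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            raw = raw / gate_mean[0][None, :]
    filled = np.array([_fill_nan(row) for row in raw])
    smooth = gaussian_filter1d(
        filled, sigma=smooth_std / bin_size, axis=1, mode="reflect"
    )
    return ActivationMap(
        values=smooth,
        raw=raw,
        occupancy=occ,
        bin_size=bin_size,
        track_length=trajectory.track_length,
    )


# ---------------------------------------------------------------------------
# field extraction


def _crossing(centers, row, k_out, k_in, thr):
    """Interpolated position where the profile crosses ``thr`` between the
    outside bin k_out (below) and inside bin k_in (above)."""
    v0, v1 = row[k_out], row[k_in]
    if v1 == v0:
        return centers[k_in]
    frac = (thr - v0) / (v1 - v0)
    return centers[k_out] + frac * (centers[k_in] - centers[k_out])


def field_peaks(amap: ActivationMap, peak_min: float = 0.2) -> pd.DataFrame:
    """Peak position/value of every unit whose map peak reaches
    ``peak_min`` (no edge filtering — a peak is well defined even when the
    field's tail is cut off by a track end; used for field density)."""
    peak_idx = np.argmax(amap.values, axis=1)
    peak_val = amap.values[np.arange(amap.values.shape[0]), peak_idx]
    keep = peak_val >= peak_min
    return pd.DataFrame(
        {
            "unit": np.flatnonzero(keep),
            "peak_pos": amap.centers[peak_idx[keep]],
            "peak_val": peak_val[keep],
        }
    )


def extract_fields(
    amap: ActivationMap,
    peak_min: float = 0.2,
    edge_drop_frac: float = 0.5,
    size_frac: float = 0.1,
) -> pd.DataFrame:
    """Extract one place field per retained unit from an activation map.

    A unit is retained if its map peak is at least ``peak_min`` and the
    profile falls below ``edge_drop_frac`` of the peak on *both* sides
    before the track ends (fields substantially cut off by the track are
    discarded).  The field extent is the region above ``size_frac`` of the
    peak, with sub-bin threshold crossings by linear interpolation.  If the
    threshold is only reached on one side, size = 2 x distance from peak to
    that crossing and the field is flagged incomplete; downstream analyses
    use complete fields only.

    Returns a DataFrame with columns unit, peak_pos, peak_val, start_pos,
    end_pos, size, complete.
    """
    centers = amap.centers
    rows = []
    for unit in range(amap.values.shape[0]):
        row = amap.values[unit]
        k = int(np.argmax(row))
        peak = row[k]
        if peak < peak_min:
            continue
        left = row[: k + 1]
        right = row[k:]
        if left.min() >= edge_drop_frac * peak or right.min() >= edge_drop_frac * peak:
            continue  # field cut off by a track end
        thr = size_frac * peak
        below_l = np.flatnonzero(left < thr)
        below_r = np.flatnonzero(right < thr)
        start = end = np.nan
        if below_l.size:
            kl = below_l[-1]
            start = _crossing(centers, row, kl, kl + 1, thr)
        if below_r.size:
            kr = k + below_r[0]
            end = _crossing(centers, row, kr, kr - 1, thr)
        complete = below_l.size > 0 and below_r.size > 0
        if complete:
            size = end - start
        elif below_l.size:
            size = 2.0 * (centers[k] - start)
            end = np.nan
        elif below_r.size:
            size = 2.0 * (end - centers[k])
            start = np.nan
        else:
            continue  # never drops below threshold: no measurable size
        rows.append(
            dict(
                unit=unit,
                peak_pos=centers[k],
                peak_val=peak,
                start_pos=start,
                end_pos=end,
                size=size,
                complete=complete,
            )
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "unit", "peak_pos", "peak_val", "start_pos", "end_pos", "size",
            "complete",
        ],
    )
    return df.astype({"unit": int, "complete": bool}) if len(df) else df.astype(
        {"complete": bool}
    )


def field_mean_speeds(
    fields: pd.DataFrame,
    trajectory: Trajectory,
    profile: SpeedProfile,
    track: TrackSpec,
    warmup_s: float = 80.0,
) -> np.ndarray:
    """Occupancy-weighted mean of the *target* speed profile v̄(x) over the
    steps spent inside each field's [start_pos, end_pos)."""
    keep = trajectory.t >= warmup_s
    x = trajectory.x[keep]
    vbar = target_speed(x, profile, track)
    out = np.full(len(fields), np.nan)
    for i, (_, fld) in enumerate(fields.iterrows()):
        lo = fld.start_pos if np.isfinite(fld.start_pos) else fld.peak_pos - fld.size / 2
        hi = fld.end_pos if np.isfinite(fld.end_pos) else fld.peak_pos + fld.size / 2
        m = (x >= lo) & (x < hi)
        if m.any():
            out[i] = vbar[m].mean()
    return out


def field_shifts(
    measured: pd.DataFrame,
    true: pd.DataFrame,
    mean_speeds: np.ndarray | None = None,
) -> pd.DataFrame:
    """Pair measured and true fields per unit and compute the backward
    shift.

    backward_shift_cm = true peak - measured peak (positive when the
    measured field lags the spatial input in the running direction);
    backward_shift_ms divides by the mean running speed through the
    measured field; onset_lookahead_ms is the temporal distance from the
    measured field start to the true peak — how far ahead the unit starts
    signalling its anchor point.  Only units with complete fields in both
    maps are kept.
    """
    meas = measured[measured.complete.astype(bool)].set_index("unit")
    if mean_speeds is not None:
        meas = meas.assign(mean_speed=mean_speeds[measured.complete.to_numpy()])
    tru = true[true.complete.astype(bool)].set_index("unit")
    units = meas.index.intersection(tru.index)
    out = pd.DataFrame(index=units)
    out["measured_peak"] = meas.loc[units, "peak_pos"]
    out["true_peak"] = tru.loc[units, "peak_pos"]
    out["measured_start"] = meas.loc[units, "start_pos"]
    out["backward_shift_cm"] = out.true_peak - out.measured_peak
    out["onset_lookahead_cm"] = out.true_peak - out.measured_start
    if mean_speeds is not None:
        v = meas.loc[units, "mean_speed"]
        out["mean_speed"] = v
        out["backward_shift_ms"] = out.backward_shift_cm / v * 1000.0
        out["onset_lookahead_ms"] = out.onset_lookahead_cm / v * 1000.0
    return out.reset_index().rename(columns={"index": "unit"})


# ---------------------------------------------------------------------------
# phase precession


def phase_map(
    signal: np.ndarray,
    trajectory: Trajectory,
    warmup_s: float = 80.0,
    bin_size: float = 2.0,
    phase_bin_deg: float = 20.0,
    step_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Mean activation per (unit, spatial bin, theta-phase bin).

    Returns (n_units, n_xbins, n_phasebins); NaN where unvisited.
    ``step_mask`` restricts the steps entering the average (used for the
    instantaneous-speed analysis).
    """
    keep = trajectory.t >= warmup_s
    if step_mask is not None:
        keep = keep & step_mask
    n_x = int(round(trajectory.track_length / bin_size))
    n_ph = int(round(360.0 / phase_bin_deg))
    xb = np.minimum((trajectory.x[keep] / bin_size).astype(np.int64), n_x - 1)
    pb = np.minimum(
        (trajectory.theta_phase[keep] / (2 * np.pi) * n_ph).astype(np.int64),
        n_ph - 1,
    )
    flat = xb * n_ph + pb
    means, _ = _bin_means(
        np.asarray(signal[keep], dtype=float), flat, n_x * n_ph
    )
    return means.reshape(signal.shape[1], n_x, n_ph)


def _odr_line(x, y, w, beta0):
    data = scipy.odr.Data(x, y, wd=w, we=w)
    odr = scipy.odr.ODR(data, scipy.odr.unilinear, beta0=beta0)
    out = odr.run()
    return out.beta, out.sum_square


def precession_slope(
    unit_pmap: np.ndarray,
    start_pos: float,
    end_pos: float,
    bin_size: float = 2.0,
    phase_bin_deg: float = 20.0,
    weight_frac: float = 0.1,
) -> float:
    """Phase-precession slope (degrees/cm) of one unit by weighted
    orthogonal distance regression.

    The point cloud is the (position, phase) bin centers of the unit's
    phase map inside the field extent whose activation is at least
    ``weight_frac`` of the in-field maximum, weighted by activation.  ODR
    minimizes perpendicular distances, so near-vertical clouds keep their
    steep slope instead of being flattened as ordinary least squares would.
    Phase is periodic, so the fit is repeated over all 360-degree branch
    cuts (one per phase bin) and the branch with the smallest weighted
    orthogonal residual wins.  Returns NaN with fewer than 3 points.
    """
    n_x, n_ph = unit_pmap.shape
    centers_x = (np.arange(n_x) + 0.5) * bin_size
    centers_ph = (np.arange(n_ph) + 0.5) * phase_bin_deg
    in_field = (centers_x >= start_pos) & (centers_x <= end_pos)
    sub = unit_pmap[in_field]
    if sub.size == 0 or np.all(np.isnan(sub)):
        return np.nan
    mx = np.nanmax(sub)
    sel = np.where(np.nan_to_num(sub) >= weight_frac * mx)
    if sel[0].size < 3:
        return np.nan
    xs = centers_x[in_field][sel[0]]
    phs = centers_ph[sel[1]]
    ws = sub[sel]
    sl0, ic0 = np.polyfit(xs, phs, 1)
    beta0 = [sl0, ic0]
    best = (np.inf, np.nan)
    for cut in centers_ph - phase_bin_deg / 2.0:
        ph_b = np.mod(phs - cut, 360.0) + cut
        try:
            beta, ss = _odr_line(xs, ph_b, ws, beta0)
        except Exception:
            continue
        if ss < best[0]:
            best = (ss, beta[0])
    return best[1]


def precession_slopes(
    pmap: np.ndarray,
    fields: pd.DataFrame,
    bin_size: float = 2.0,
    phase_bin_deg: float = 20.0,
) -> pd.DataFrame:
    """Slopes for every complete field; adds inv_slope_cm_per_deg (the
    magnitude-signed reciprocal used in the speed analyses)."""
    rows = []
    for _, fld in fields[fields.complete].iterrows():
        slope = precession_slope(
            pmap[int(fld.unit)], fld.start_pos, fld.end_pos, bin_size,
            phase_bin_deg,
        )
        rows.append(
            dict(
                unit=int(fld.unit),
                slope_deg_per_cm=slope,
                inv_slope_cm_per_deg=1.0 / slope if slope else np.nan,
            )
        )
    return pd.DataFrame(
        rows, columns=["unit", "slope_deg_per_cm", "inv_slope_cm_per_deg"]
    )


# ---------------------------------------------------------------------------
# instantaneous-speed (in)variance


def speed_quantile_masks(
    trajectory: Trajectory,
    warmup_s: float = 80.0,
    bin_size: float = 2.0,
    quantile: float = 0.2,
) -> tuple[np.ndarray, np.ndarray]:
    """Step masks selecting the top / bottom ``quantile`` of instantaneous
    speeds *within each spatial bin* (full-length masks; warm-up steps are
    False in both)."""
    n_bins = int(round(trajectory.track_length / bin_size))
    keep = trajectory.t >= warmup_s
    bin_idx = np.minimum((trajectory.x / bin_size).astype(np.int64), n_bins - 1)
    top = np.zeros(trajectory.n_steps, dtype=bool)
    bot = np.zeros(trajectory.n_steps, dtype=bool)
    for b in range(n_bins):
        m = keep & (bin_idx == b)
        if not m.any():
            continue
        v = trajectory.v[m]
        q_lo, q_hi = np.quantile(v, [quantile, 1.0 - quantile])
        idx = np.flatnonzero(m)
        top[idx[v >= q_hi]] = True
        bot[idx[v <= q_lo]] = True
    return top, bot


def instantaneous_speed_ratios(
    sigma: np.ndarray,
    trajectory: Trajectory,
    params: AnalysisParams | None = None,
) -> pd.DataFrame:
    """Top/bottom instantaneous-speed ratios of field size and inverse
    precession slope, one row per unit with complete fields under both
    conditions.

    Field sizes and phase-precession slopes are recomputed twice, using
    only the steps in the top (resp. bottom) 20% of instantaneous speeds at
    each spatial bin; near-invariance to instantaneous speed shows up as
    ratios close to 1.
    """
    a = params or AnalysisParams()
    top, bot = speed_quantile_masks(
        trajectory, a.warmup_s, a.map_bin, a.speed_quantile
    )
    out = {}
    for name, mask in (("top", top), ("bot", bot)):
        keep_traj = _masked_trajectory(trajectory, mask)
        amap = activation_map(
            sigma[mask], keep_traj, 0.0, a.map_bin, a.map_smooth_std
        )
        fields = extract_fields(amap, a.peak_min, a.edge_drop_frac, a.size_frac)
        pmap = phase_map(sigma, trajectory, a.warmup_s, a.map_bin,
                         a.phase_bin_deg, step_mask=mask)
        slopes = precession_slopes(pmap, fields, a.map_bin, a.phase_bin_deg)
        comp = fields[fields.complete.astype(bool)]
        out[name] = comp.merge(slopes, on="unit").set_index("unit")
    units = out["top"].index.intersection(out["bot"].index)
    df = pd.DataFrame(index=units)
    df["size_ratio"] = out["top"].loc[units, "size"] / out["bot"].loc[units, "size"]
    df["inv_slope_ratio"] = (
        out["top"].loc[units, "inv_slope_cm_per_deg"]
        / out["bot"].loc[units, "inv_slope_cm_per_deg"]
    )
    return df.reset_index().rename(columns={"index": "unit"})


def _masked_trajectory(trajectory: Trajectory, mask: np.ndarray) -> Trajectory:
    return Trajectory(
        t=trajectory.t[mask],
        x=trajectory.x[mask],
        v=trajectory.v[mask],
        lap_id=trajectory.lap_id[mask],
        theta_phase=trajectory.theta_phase[mask],
        dt=trajectory.dt,
        track_length=trajectory.track_length,
    )


# ---------------------------------------------------------------------------
# field density


def field_density(
    fields: pd.DataFrame,
    profile: SpeedProfile,
    track: TrackSpec,
    window: float = 10.0,
    stride: float = 2.0,
) -> pd.DataFrame:
    """Number of place-field peaks (one per retained unit) in overlapping
    windows fully inside the track, with the window-mean target speed."""
    peaks = fields.peak_pos.to_numpy()
    starts = np.arange(0.0, track.length - window + 1e-9, stride)
    rows = []
    for s0 in starts:
        inside = (peaks >= s0) & (peaks < s0 + window)
        xs = np.linspace(s0, s0 + window, 21)
        rows.append(
            dict(
                window_start=s0,
                window_center=s0 + window / 2.0,
                count=int(inside.sum()),
                mean_speed=float(np.mean(target_speed(xs, profile, track))),
            )
        )
    return pd.DataFrame(rows)


def density_speed_fit(density: pd.DataFrame) -> dict:
    """Compare a hyperbolic (density ~ a + b/v̄) with a linear
    (density ~ a + b v̄) description of field density vs window speed.

    Returns the two R² values, the hyperbolic coefficient, and the Pearson
    correlation between density and speed.
    """
    v = density.mean_speed.to_numpy()
    y = density["count"].to_numpy().astype(float)

    def r2(pred):
        ss_res = np.sum((y - pred) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        return 1.0 - ss_res / ss_tot

    A_h = np.column_stack([np.ones_like(v), 1.0 / v])
    coef_h, *_ = np.linalg.lstsq(A_h, y, rcond=None)
    A_l = np.column_stack([np.ones_like(v), v])
    coef_l, *_ = np.linalg.lstsq(A_l, y, rcond=None)
    r = np.corrcoef(v, y)[0, 1]
    return dict(
        r2_hyperbolic=r2(A_h @ coef_h),
        r2_linear=r2(A_l @ coef_l),
        hyperbolic_coef=coef_h[1],
        pearson_r=r,
    )
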