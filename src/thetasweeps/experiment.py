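"""Reproducible experiments: seeding, multi-run batches, pooling, reports.

One *experiment* is ``n_runs`` independent simulations (fresh feature bank
and speed noise per run, derived deterministically from the master seed),
each followed by the full analysis pipeline, with the per-run tables pooled
the way the figures pool them.  Everything is deterministic under a fixed
master seed.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .behavior import simulate_trajectory
from .config import RunConfig
from .decoding import decode, lookbehind_vs_shift, sweep_metrics
from .features import generate_features
from .network import run_simulation
from .placefields import (
    activation_map,
    density_speed_fit,
    extract_fields,
    field_density,
    field_mean_speeds,
    field_peaks,
    field_shifts,
    instantaneous_speed_ratios,
    phase_map,
    precession_slopes,
)

__all__ = ["RunResult", "run_single", "run_experiment", "summarize"]


def derive_seeds(master_seed: int, run_index: int) -> tuple[int, int]:
    """Independent (behavior, features) seeds for one run."""
    ss = np.random.SeedSequence([master_seed, run_index])
    c1, c2 = ss.spawn(2)
    return (
        int(c1.generate_state(1, dtype=np.uint32)[0]),
        int(c2.generate_state(1, dtype=np.uint32)[0]),
    )


@dataclass
class RunResult:
    """Analysis tables of one simulation run."""

    run_index: int
    fields_measured: pd.DataFrame
    fields_true: pd.DataFrame
    shifts: pd.DataFrame
    slopes: pd.DataFrame
    density: pd.DataFrame
    sweeps: pd.DataFrame
    ratios: pd.DataFrame | None = None
    tables: dict = field(default_factory=dict)

    def named_tables(self) -> dict[str, pd.DataFrame]:
        out = {
            "fields_measured": self.fields_measured,
            "fields_true": self.fields_true,
            "shifts": self.shifts,
            "slopes": self.slopes,
            "density": self.density,
            "sweeps": self.sweeps,
        }
        if self.ratios is not None:
            out["ratios"] = self.ratios
        return out


def run_single(
    config: RunConfig,
    run_index: int = 0,
    with_decoding: bool = True,
    with_phase: bool = True,
    with_ratios: bool = False,
    backend: str = "auto",
) -> RunResult:
    """Simulate one run and compute its analysis tables.

    ``with_ratios`` additionally runs a separate longer session
    (``analysis.ratio_n_laps`` laps) for the instantaneous-speed ratio
    analysis.  Setting ``with_decoding``/``with_phase`` False skips the
    corresponding (more expensive) analyses.
    """
    a = config.analysis
    seed_beh, seed_feat = derive_seeds(config.master_seed, run_index)
    bank = generate_features(config.track, config.features, seed_feat)
    traj = simulate_trajectory(
        config.track, config.profile, config.noise, config.theta_freq, seed_beh
    )
    sim = run_simulation(
        traj, bank, config.network, config.theta_freq, backend=backend,
        profile=config.profile, track=config.track,
    )

    from .network import theta_gate

    amap = activation_map(sim.sigma, traj, a.warmup_s, a.map_bin, a.map_smooth_std)
    # true maps: i_ext is multiplied by the theta gate, so its raw time
    # average is capped at beta_max * <beta_theta> ~ 0.12 and the absolute
    # peak threshold could never retain a field; dividing each bin by its
    # mean gate recovers the spatial envelope beta_max * sigma_s(W_s s(x))
    # on a scale where the same threshold is meaningful.
    gate = np.asarray(theta_gate(traj.theta_phase, config.network), dtype=float)
    tmap = activation_map(
        sim.i_ext, traj, a.warmup_s, a.map_bin, a.map_smooth_std, gate=gate
    )
    fields_m = extract_fields(amap, a.peak_min, a.edge_drop_frac, a.size_frac)
    fields_t = extract_fields(tmap, a.peak_min, a.edge_drop_frac, a.size_frac)
    speeds = field_mean_speeds(fields_m, traj, config.profile, config.track, a.warmup_s)
    fields_m = fields_m.assign(mean_speed=speeds)
    shifts = field_shifts(fields_m, fields_t, speeds)
    density = field_density(
        field_peaks(amap, a.peak_min), config.profile, config.track,
        a.density_window, a.density_stride,
    )

    if with_phase:
        pmap = phase_map(sim.sigma, traj, a.warmup_s, a.map_bin, a.phase_bin_deg)
        slopes = precession_slopes(pmap, fields_m, a.map_bin, a.phase_bin_deg)
        slopes = slopes.merge(
            fields_m[["unit", "mean_speed", "peak_pos"]], on="unit", how="left"
        )
    else:
        slopes = pd.DataFrame(
            columns=["unit", "slope_deg_per_cm", "inv_slope_cm_per_deg",
                     "mean_speed", "peak_pos"]
        )

    if with_decoding:
        dec = decode(sim.sigma, amap, a.decode_min_activation)
        sweeps = sweep_metrics(
            dec, traj, config.profile, config.track, a.warmup_s,
            a.sweep_phase_bins, n_track_bins=amap.n_bins,
        )
    else:
        sweeps = pd.DataFrame(
            columns=["cycle_id", "look_behind", "look_ahead", "length",
                     "mean_real_pos", "mean_speed_at_pos", "excluded", "reason"]
        )

    ratios = None
    if with_ratios:
        ratios = run_ratio_analysis(config, run_index, backend)

    res = RunResult(
        run_index=run_index,
        fields_measured=fields_m,
        fields_true=fields_t,
        shifts=shifts,
        slopes=slopes,
        density=density,
        sweeps=sweeps,
        ratios=ratios,
    )
    return res


def run_ratio_analysis(
    config: RunConfig, run_index: int = 0, backend: str = "auto"
) -> pd.DataFrame:
    """Instantaneous-speed (in)variance analysis for one run.

    Simulates a longer session (``analysis.ratio_n_laps`` laps, 45 by
    default) and returns the per-unit top/bottom-20% instantaneous-speed
    ratios of field size and inverse precession slope.
    """
    import dataclasses as _dc

    a = config.analysis
    seed_beh, seed_feat = derive_seeds(config.master_seed, run_index)
    bank = generate_features(config.track, config.features, seed_feat)
    long_track = _dc.replace(config.track, n_laps=a.ratio_n_laps)
    traj = simulate_trajectory(
        long_track, config.profile, config.noise, config.theta_freq, seed_beh
    )
    sim = run_simulation(
        traj, bank, config.network, config.theta_freq, backend=backend,
        profile=config.profile, track=long_track,
    )
    return instantaneous_speed_ratios(sim.sigma, traj, a)


def _pool(results: list[RunResult], name: str) -> pd.DataFrame:
    frames = []
    for r in results:
        df = r.named_tables().get(name)
        if df is not None and len(df):
            frames.append(df.assign(run=r.run_index))
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


def run_experiment(
    config: RunConfig,
    outdir: str | Path | None = None,
    with_decoding: bool = True,
    with_phase: bool = True,
    with_ratios: bool = False,
    backend: str = "auto",
    progress: bool = False,
) -> dict[str, pd.DataFrame]:
    """Run ``config.n_runs`` simulations and pool their tables.

    Returns a dict of pooled DataFrames (keys: fields_measured, fields_true,
    shifts, slopes, density, sweeps and, if requested, ratios).  If
    ``outdir`` is given, per-run and pooled tables are written as CSV along
    with a manifest (config + versions).
    """
    results = []
    for k in range(config.n_runs):
        if progress:
            print(f"run {k + 1}/{config.n_runs} ...", flush=True)
        res = run_single(config, k, with_decoding, with_phase, with_ratios, backend)
        results.append(res)
        if outdir is not None:
            rd = Path(outdir) / f"run{k:02d}"
            rd.mkdir(parents=True, exist_ok=True)
            for name, df in res.named_tables().items():
                df.to_csv(rd / f"{name}.csv", index=False)

    names = ["fields_measured", "fields_true", "shifts", "slopes", "density",
             "sweeps"]
    if with_ratios:
        names.append("ratios")
    pooled = {name: _pool(results, name) for name in names}

    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in pooled.items():
            df.to_csv(out / f"pooled_{name}.csv", index=False)
        config.to_yaml(out / "config.yaml")
        manifest = {
            "package_version": _pkg_version,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "python": platform.python_version(),
            "n_runs": config.n_runs,
            "master_seed": config.master_seed,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return pooled


def summarize(pooled: dict[str, pd.DataFrame] | str | Path) -> dict:
    """Headline statistics of a (possibly reloaded) pooled experiment.

    Accepts the dict returned by :func:`run_experiment` or an experiment
    output directory.  Returns a JSON-serializable report with the pooled
    mean temporal field shift, the pooled mean onset look-ahead, and the
    speed-dependence statistics of sizes, slopes, densities and sweeps.
    """
    if not isinstance(pooled, dict):
        out = Path(pooled)
        pooled = {}
        for f in out.glob("pooled_*.csv"):
            try:
                pooled[f.stem.removeprefix("pooled_")] = pd.read_csv(f)
            except pd.errors.EmptyDataError:
                pooled[f.stem.removeprefix("pooled_")] = pd.DataFrame()

    report: dict = {}
    shifts = pooled.get("shifts", pd.DataFrame())
    if len(shifts):
        report["mean_backward_shift_ms"] = float(shifts.backward_shift_ms.mean())
        report["mean_onset_lookahead_ms"] = float(shifts.onset_lookahead_ms.mean())
        report["n_fields"] = int(len(shifts))

    fm = pooled.get("fields_measured", pd.DataFrame())
    if len(fm):
        comp = fm[fm.complete & fm.mean_speed.notna()]
        if len(comp) > 2:
            r = np.corrcoef(comp.mean_speed, comp["size"])[0, 1]
            sl = np.polyfit(comp.mean_speed, comp["size"], 1)[0]
            report["size_vs_speed"] = {"pearson_r": float(r), "slope": float(sl)}

    slopes = pooled.get("slopes", pd.DataFrame())
    if len(slopes):
        ok = slopes.dropna(subset=["inv_slope_cm_per_deg", "mean_speed"])
        ok = ok[ok.slope_deg_per_cm < 0]  # precessing fields
        if len(ok) > 2:
            mag = -ok.inv_slope_cm_per_deg  # positive cm/degree
            report["inv_slope_vs_speed"] = {
                "pearson_r": float(np.corrcoef(ok.mean_speed, mag)[0, 1]),
                "slope": float(np.polyfit(ok.mean_speed, mag, 1)[0]),
            }

    density = pooled.get("density", pd.DataFrame())
    if len(density):
        by_win = density.groupby("window_center", as_index=False).agg(
            count=("count", "mean"), mean_speed=("mean_speed", "first")
        )
        report["density_vs_speed"] = {
            k: float(v) for k, v in density_speed_fit(by_win).items()
        }

    sweeps = pooled.get("sweeps", pd.DataFrame())
    if len(sweeps):
        ok = sweeps[~sweeps.excluded]
        trends = {}
        for metric in ("look_behind", "look_ahead", "length"):
            b = _binned_trend(ok.mean_speed_at_pos, ok[metric])
            trends[metric] = b
        report["sweep_trends"] = trends
        if len(shifts):
            cmp_ = lookbehind_vs_shift(sweeps, shifts)
            report["lookbehind_vs_shift"] = {
                "slope": float(cmp_["slope"]),
                "r": float(cmp_["r"]),
            }

    ratios = pooled.get("ratios", pd.DataFrame())
    if ratios is not None and len(ratios):
        report["speed_ratio_means"] = {
            "size": float(ratios.size_ratio.mean()),
            "inv_slope": float(ratios.inv_slope_ratio.mean()),
        }
    return report


def _binned_trend(speed, value, n_bins: int = 10) -> dict:
    """Slope of the binned metric-vs-speed relation (equal-count bins)."""
    speed = np.asarray(speed, dtype=float)
    value = np.asarray(value, dtype=float)
    ok = np.isfinite(speed) & np.isfinite(value)
    speed, value = speed[ok], value[ok]
    if speed.size < 2 * n_bins:
        return {"slope": float("nan"), "r": float("nan")}
    qs = np.quantile(speed, np.linspace(0, 1, n_bins + 1))
    xs, ys = [], []
    for lo, hi in zip(qs[:-1], qs[1:]):
        m = (speed >= lo) & (speed <= hi)
        if m.sum() >= 3:
            xs.append(speed[m].mean())
            ys.append(value[m].mean())
    xs, ys = np.asarray(xs), np.asarray(ys)
    slope = np.polyfit(xs, ys, 1)[0]
    return {"slope": float(slope), "r": float(np.corrcoef(xs, ys)[0, 1])}
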