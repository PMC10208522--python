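"""Parameter containers and config-file round-tripping.

Every quantity the simulation and the analyses depend on lives in one of the
dataclasses below; :class:`RunConfig` bundles them together with the master
seed and the number of pooled simulation runs.  Defaults are the standard
model values.  Configs serialize losslessly to YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "TrackSpec",
    "SpeedProfile",
    "SpeedNoiseSpec",
    "FeatureParams",
    "NetworkParams",
    "AnalysisParams",
    "RunConfig",
]


@dataclass
class TrackSpec:
    """Linear-track geometry and integration step.

    length : track length in cm.
    bin_size_features : spatial discretization of the input features, cm.
    n_laps : number of laps the simulated rat runs.
    dt : integration time step in seconds.
    """

    length: float = 200.0
    bin_size_features: float = 1.0
    n_laps: int = 30
    dt: float = 0.001

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("track length must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_laps < 1:
            raise ValueError("n_laps must be >= 1")

    @property
    def n_feature_bins(self) -> int:
        return int(round(self.length / self.bin_size_features))


@dataclass
class SpeedProfile:
    """Triangular target mean-speed profile v̄(x): slow at the track ends,
    fast in the middle."""

    v_end: float = 15.0
    v_mid: float = 80.0
    shape: str = "triangular"

    def __post_init__(self) -> None:
        if self.v_end <= 0:
            raise ValueError("v_end must be positive")
        if self.v_mid < self.v_end:
            raise ValueError("v_mid must be >= v_end")


@dataclass
class SpeedNoiseSpec:
    """Smooth multiplicative speed noise: white Gaussian noise convolved with
    a Gaussian kernel (std in seconds), then affinely mapped to [lo, hi]
    with the midpoint sent to ``center``."""

    kernel_std: float = 2.0
    lo: float = 0.5
    hi: float = 1.5
    center: float = 1.0

    def __post_init__(self) -> None:
        if not (self.lo < self.center < self.hi):
            raise ValueError("need lo < center < hi")
        if self.kernel_std <= 0:
            raise ValueError("kernel_std must be positive")


@dataclass
class FeatureParams:
    """Frozen weakly-spatially-tuned input features."""

    n_features: int = 128
    std_min: float = 2.0
    std_max: float = 20.0


@dataclass
class NetworkParams:
    """Parameters of the recurrent place-cell network.

    Rate dynamics: tau_r (s).  Theta drive i_theta: von-Mises-shaped
    excitation/inhibition with concentration kappa_theta between i_theta_min
    (trough, theta=0) and i_theta_max (peak, theta=pi).  Recurrent weights:
    Gaussian profile over unit-index offset with forward asymmetry delta,
    width sigma_rec and range [w_rec_min, w_rec_max].  Activation
    nonlinearity sigma_r: logistic with gain alpha_r and threshold x_r.
    Short-term plasticity: facilitation (tau_f, baseline f0) and depression
    (tau_d).  Spatial input: gate beta_theta with concentration kappa_s
    peaking at theta=pi/2, amplitude beta_max, dendritic logistic
    (alpha_s, x_s).  Hebbian input-weight learning time constant tau_w (s).
    n_init_units: number of leading units receiving the lap-start kick.
    """

    n_units: int = 250
    tau_r: float = 0.005
    kappa_theta: float = 12.0
    i_theta_max: float = 1.6
    i_theta_min: float = -1.0
    delta: float = 0.6
    sigma_rec: float = 5.0
    w_rec_max: float = 0.5
    w_rec_min: float = -2.8
    alpha_r: float = 6.0
    x_r: float = 0.5
    tau_f: float = 0.32
    tau_d: float = 0.06
    f0: float = 0.14
    kappa_s: float = 2.0
    beta_max: float = 0.4
    alpha_s: float = 12.0
    x_s: float = 0.7
    tau_w: float = 20.0
    n_init_units: int = 5
    # optional multiplier making within-cycle propagation follow v/v̄
    # (speed-invariance extension); 0 disables it
    delta_speed_gain: float = 0.0

    def __post_init__(self) -> None:
        for name in ("tau_r", "tau_f", "tau_d", "tau_w"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.i_theta_min >= self.i_theta_max:
            raise ValueError("i_theta_min must be < i_theta_max")
        if self.w_rec_min >= self.w_rec_max:
            raise ValueError("w_rec_min must be < w_rec_max")
        if not (0 < self.f0 < 1):
            raise ValueError("f0 must be in (0, 1)")


@dataclass
class AnalysisParams:
    """Settings of the place-field / decoding analysis pipeline."""

    warmup_s: float = 80.0
    map_bin: float = 2.0           # cm, activation-map bin
    map_smooth_std: float = 3.0    # cm, Gaussian smoothing of maps
    peak_min: float = 0.2          # discard units with lower map peak
    edge_drop_frac: float = 0.5    # must drop below this fraction both sides
    size_frac: float = 0.1         # field extent threshold (of peak)
    phase_bin_deg: float = 20.0    # phase-precession map resolution
    decode_min_activation: float = 0.1
    sweep_phase_bins: int = 10     # 36 deg windows per theta cycle
    density_window: float = 10.0   # cm
    density_stride: float = 2.0    # cm
    speed_quantile: float = 0.2    # top/bottom instantaneous-speed fraction
    ratio_n_laps: int = 45         # laps for the instantaneous-speed analysis


@dataclass
class RunConfig:
    """Everything needed to reproduce a batch of simulation runs."""

    track: TrackSpec = field(default_factory=TrackSpec)
    profile: SpeedProfile = field(default_factory=SpeedProfile)
    noise: SpeedNoiseSpec = field(default_factory=SpeedNoiseSpec)
    features: FeatureParams = field(default_factory=FeatureParams)
    network: NetworkParams = field(default_factory=NetworkParams)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    theta_freq: float = 8.0
    master_seed: int = 0
    n_runs: int = 10

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        kwargs = {}
        for name, sub in [
            ("track", TrackSpec),
            ("profile", SpeedProfile),
            ("noise", SpeedNoiseSpec),
            ("features", FeatureParams),
            ("network", NetworkParams),
            ("analysis", AnalysisParams),
        ]:
            if name in d:
                kwargs[name] = sub(**d.pop(name))
        kwargs.update(d)
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
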