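"""Frozen weakly-spatially-tuned input features.

Each feature is independent Gaussian white noise over 1 cm spatial bins,
smoothed with its own Gaussian kernel (std drawn uniformly from a range),
then affinely mapped so it spans [-1, 1] with the range midpoint at 0.
The bank is frozen: generated once per run and never changed, standing in
for a mixture of entorhinal inputs (grid, border, object cells) of
different spatial scales.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .config import FeatureParams, TrackSpec

__all__ = ["FeatureBank", "generate_features", "features_at"]


@dataclass
class FeatureBank:
    """values: (n_features, n_bins) in [-1, 1]; one column per 1 cm bin."""

    values: np.ndarray
    bin_size: float
    smoothing_stds: np.ndarray  # cm, one per feature

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values).to_csv(path, index=False)

    def save(self, path: str | Path) -> None:
        np.savez_compressed(
            path, values=self.values, bin_size=self.bin_size,
            smoothing_stds=self.smoothing_stds,
        )

    @classmethod
    def load(cls, path: str | Path) -> "FeatureBank":
        with np.load(path) as z:
            return cls(
                values=z["values"],
                bin_size=float(z["bin_size"]),
                smoothing_stds=z["smoothing_stds"],
            )


def generate_features(
    track: TrackSpec,
    params: FeatureParams | None = None,
    seed: int | np.random.Generator = 0,
) -> FeatureBank:
    """Generate the frozen feature bank for one run.

    Per feature: white noise (std 1) in each spatial bin, Gaussian-smoothed
    with a kernel std drawn uniformly from [std_min, std_max] cm (reflective
    boundaries, truncated at +-4 std), then scaled and shifted to range
    [-1, 1] with midpoint 0.  Identical seeds give bit-identical banks.
    """
    params = params or FeatureParams()
    if params.n_features < 1:
        raise ValueError("n_features must be >= 1")
    if not (0 < params.std_min <= params.std_max < track.length):
        raise ValueError("smoothing std range must lie within (0, track length)")
    rng = np.random.default_rng(seed)
    n_bins = track.n_feature_bins
    stds = rng.uniform(params.std_min, params.std_max, size=params.n_features)
    values = np.empty((params.n_features, n_bins))
    for k in range(params.n_features):
        raw = rng.standard_normal(n_bins)
        sm = gaussian_filter1d(
            raw, sigma=stds[k] / track.bin_size_features,
            mode="reflect", truncate=4.0,
        )
        lo, hi = sm.min(), sm.max()
        if hi - lo < 1e-12:
            values[k] = 0.0
        else:
            # midpoint -> 0, so min -> -1 and max -> +1
            values[k] = 2.0 * (sm - (lo + hi) / 2.0) / (hi - lo)
    return FeatureBank(
        values=values, bin_size=track.bin_size_features, smoothing_stds=stds
    )


def feature_bin_index(bank: FeatureBank, x: float | np.ndarray) -> np.ndarray:
    """Index of the half-open spatial bin [lo, hi) containing ``x``."""
    xa = np.asarray(x, dtype=float)
    track_len = bank.n_bins * bank.bin_size
    if np.any(xa < 0) or np.any(xa >= track_len):
        raise ValueError("position outside the track")
    return np.minimum((xa / bank.bin_size).astype(np.int64), bank.n_bins - 1)


def features_at(bank: FeatureBank, x: float) -> np.ndarray:
    """Feature vector s at position ``x`` (nearest-bin lookup)."""
    return bank.values[:, int(feature_bin_index(bank, x))]
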