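"""Intra-brain seed-to-voxel functional connectivity on band-passed
residuals.

The residual series still carries task-locked power near the block
fundamental (1/15 s ~ 0.067 Hz) because no HRF model is exact; the
connectivity band-pass therefore closes at 0.06 Hz, just below that
fundamental, and opens at 0.01 Hz to reject scanner drift. Filtering is
zero-phase (forward-backward Butterworth), so pass-band timing is
preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from dyadscan.core import DyadscanError, flatten_spatial
from dyadscan.group import permutation_cluster_fwe, two_sample_t_map
from dyadscan.interbrain import fisher_z

__all__ = [
    "BandpassSpec",
    "bandpass_filter",
    "seed_to_voxel_map",
    "connectivity_group_compare",
    "connectivity_behavior_correlation",
    "cluster_mean_strength",
    "SeedMap",
]


@dataclass
class BandpassSpec:
    """Band-pass of the connectivity analysis: 0.01-0.06 Hz by default.

    ``order`` is the order of the underlying Butterworth low/high-pass
    prototype; the filter is applied forward-backward (zero phase), which
    squares its magnitude response. The default order is chosen so that
    the applied filter attenuates the 0.067 Hz task fundamental by at
    least 20 dB while keeping the 0.02-0.05 Hz pass-band within 3 dB.
    """

    low: float = 0.01
    high: float = 0.06
    order: int = 8

    def validate(self, tr: float) -> None:
        nyquist = 0.5 / tr
        if not 0.0 < self.low < self.high:
            raise DyadscanError("need 0 < low < high")
        if self.high >= nyquist:
            raise DyadscanError(
                f"high cut {self.high} Hz is at or above Nyquist {nyquist} Hz"
            )


def bandpass_filter(series, spec: BandpassSpec | None = None, tr: float = 3.0):
    """Zero-phase Butterworth band-pass along the time axis (axis 0)."""
    if spec is None:
        spec = BandpassSpec()
    spec.validate(tr)
    x = np.asarray(series, dtype=float)
    fs = 1.0 / tr
    sos = signal.butter(
        spec.order, [spec.low, spec.high], btype="bandpass", fs=fs, output="sos"
    )
    padlen = min(x.shape[0] - 1, 3 * (2 * spec.order + 1))
    return signal.sosfiltfilt(sos, x, axis=0, padlen=padlen)


@dataclass
class SeedMap:
    """Fisher-z correlation of every voxel with the seed series."""

    z: np.ndarray
    valid: np.ndarray
    subject: str = ""
    seed_label: str = ""
    spatial_shape: tuple[int, int, int] | None = None

    def z_map(self) -> np.ndarray:
        if self.spatial_shape is not None:
            return self.z.reshape(self.spatial_shape)
        return self.z


def seed_to_voxel_map(
    residuals,
    seed_series,
    spec: BandpassSpec | None = None,
    tr: float = 3.0,
    subject: str = "",
    seed_label: str = "",
) -> SeedMap:
    """Band-pass both the seed and every voxel, then correlate.

    The seed series is typically the ROI-mean residual course from
    :func:`dyadscan.interbrain.roi_mean_series`. A zero-variance seed is
    an error; zero-variance voxels get z = 0 with valid = False.
    """
    arr = np.asarray(residuals, dtype=float)
    spatial_shape = arr.shape[:3] if arr.ndim == 4 else None
    x = flatten_spatial(arr)
    s = np.asarray(seed_series, dtype=float)
    if s.ndim != 1 or s.shape[0] != x.shape[0]:
        raise DyadscanError("seed series must be 1-D with the residual length")
    if s.std() == 0:
        raise DyadscanError("seed series has zero variance")
    xf = bandpass_filter(x, spec, tr)
    sf = bandpass_filter(s, spec, tr)
    sf = (sf - sf.mean()) / sf.std()
    xf = xf - xf.mean(axis=0)
    sd = xf.std(axis=0)
    valid = sd > 0
    r = np.where(
        valid, (sf @ xf) / (x.shape[0] * np.where(valid, sd, 1.0)), 0.0
    )
    z = np.where(valid, fisher_z(np.clip(r, -1.0, 1.0)), 0.0)
    return SeedMap(
        z=z,
        valid=valid,
        subject=subject,
        seed_label=seed_label,
        spatial_shape=spatial_shape,
    )


def connectivity_group_compare(
    maps_group1,
    maps_group2,
    threshold: float = 3.0,
    n_perm: int = 1000,
    seed=None,
):
    """Two-sample comparison of seed maps with cluster-level FWE.

    ``maps_group*`` are stacks of 3-D z maps (or SeedMap lists). Returns
    (t map, df, ClusterResult).
    """
    def as_stack(maps):
        if len(maps) and isinstance(maps[0], SeedMap):
            return np.stack([m.z_map() for m in maps])
        return np.asarray(maps, dtype=float)

    a = as_stack(maps_group1)
    b = as_stack(maps_group2)
    t, df, _ = two_sample_t_map(a, b)
    clusters = permutation_cluster_fwe(a, b, threshold=threshold, n_perm=n_perm, seed=seed)
    return t, df, clusters


def connectivity_behavior_correlation(strengths, accuracies):
    """Pearson correlation between per-subject connectivity strength and
    task accuracy. Returns (r, two-sided p)."""
    x = np.asarray(strengths, dtype=float)
    y = np.asarray(accuracies, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DyadscanError("strengths and accuracies must be paired 1-D arrays")
    if x.shape[0] < 3:
        raise DyadscanError("need at least 3 subjects")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise DyadscanError("non-finite values")
    if x.std() == 0 or y.std() == 0:
        raise DyadscanError("zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def cluster_mean_strength(maps, cluster_mask) -> np.ndarray:
    """Connectivity strength per subject: mean z inside the cluster mask.

    The mask is usually the significant cluster of the group comparison;
    this operationalises "connectivity strength" for the behaviour
    correlation.
    """
    m = np.asarray(cluster_mask).astype(bool)
    if not m.any():
        raise DyadscanError("empty cluster mask")
    out = []
    for smap in maps:
        z = smap.z_map() if isinstance(smap, SeedMap) else np.asarray(smap)
        if z.shape != m.shape:
            raise DyadscanError("map and mask shapes differ")
        out.append(float(z[m].mean()))
    return np.asarray(out)
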