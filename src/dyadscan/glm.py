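"""First-level GLM: HRF regressors, drift modelling, AR(1) prewhitening,
contrast estimation, smoothing and residual extraction.

The model follows the summary-statistics approach standard in task fMRI:
condition boxcars are convolved with the canonical double-gamma HRF, slow
scanner drift is absorbed by a per-run discrete-cosine basis (high-pass
cut-off period 128 s), serial correlation is removed by a single pooled
AR(1) coefficient, and whitened least squares yields per-voxel
coefficients. The whitened residual series — with the first two volumes of
every run discarded to avoid filter transients — is the substrate of all
inter-brain and connectivity analyses downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal, stats

from dyadscan.core import CONDITIONS, MODELED_CONDITIONS, DyadscanError, flatten_spatial

__all__ = [
    "canonical_hrf",
    "build_design_matrix",
    "concat_designs",
    "design_for_runs",
    "estimate_ar1",
    "whiten_ar1",
    "fit_glm",
    "compute_contrast",
    "contrast_weights",
    "primed_contrast",
    "effect_contrast",
    "gaussian_smooth",
    "power_spectrum",
    "DesignMatrix",
    "GlmResult",
    "ContrastImage",
]

#: Primed contrasts: each task condition against the simultaneous-ball
#: control of its own run type.
PRIMED_CONTRASTS = {
    "ES'": {"ES": 1.0, "SBNc": -1.0},
    "BS'": {"BS": 1.0, "SBNc": -1.0},
    "EN'": {"EN": 1.0, "SBNd": -1.0},
    "BN'": {"BN": 1.0, "SBNd": -1.0},
}

#: 2 (cue) x 2 (attention) effects expressed on the primed contrasts.
FACTORIAL_EFFECTS = {
    "eye_cued": {"ES": 1, "EN": 1, "BS": -1, "BN": -1},
    "shared": {"ES": 1, "BS": 1, "EN": -1, "BN": -1},
    "interaction": {"ES": 1, "EN": -1, "BS": -1, "BN": 1},
}


def canonical_hrf(
    tr: float,
    oversampling: int = 16,
    time_length: float = 32.0,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    peak_disp: float = 1.0,
    undershoot_disp: float = 1.0,
    undershoot_ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Canonical double-gamma haemodynamic response function.

    Sampled on a grid of step ``tr / oversampling`` over ``time_length``
    seconds and normalised to unit peak. Default shape parameters are the
    conventional ones (response peaking near 5 s, undershoot near 15 s,
    undershoot one sixth of the peak).
    """
    if tr <= 0:
        raise DyadscanError("TR must be positive")
    dt = tr / oversampling
    t = np.arange(0, time_length, dt)
    peak = stats.gamma.pdf(t, peak_delay / peak_disp, scale=peak_disp)
    undershoot = stats.gamma.pdf(
        t, undershoot_delay / undershoot_disp, scale=undershoot_disp
    )
    h = peak - undershoot_ratio * undershoot
    return h / h.max()


def _dct_basis(n: int, k_max: int) -> np.ndarray:
    """Orthonormal DCT-II columns k = 1..k_max on n samples."""
    n_grid = np.arange(n)
    cols = [
        np.sqrt(2.0 / n) * np.cos(np.pi * k * (2 * n_grid + 1) / (2 * n))
        for k in range(1, k_max + 1)
    ]
    if not cols:
        return np.empty((n, 0))
    return np.column_stack(cols)


@dataclass
class DesignMatrix:
    """T x P design with labelled columns and a run-block index."""

    matrix: np.ndarray
    columns: list[str]
    run_index: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.run_index = np.asarray(self.run_index, dtype=int)
        if self.matrix.shape[0] != self.run_index.shape[0]:
            raise DyadscanError("run_index length must equal design rows")
        if self.matrix.shape[1] != len(self.columns):
            raise DyadscanError("column labels must match design width")

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def condition_columns(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.columns) if c in CONDITIONS}

    def check_rank(self) -> None:
        rank = np.linalg.matrix_rank(self.matrix)
        if rank < self.matrix.shape[1]:
            raise DyadscanError(
                f"design matrix is rank deficient (rank {rank} < "
                f"{self.matrix.shape[1]} columns)"
            )


def build_design_matrix(
    events,
    tr: float,
    n_vols: int,
    hp_cutoff: float = 128.0,
    oversampling: int = 16,
    conditions: tuple[str, ...] | None = None,
    model_ec: bool = False,
    run_label: int = 0,
    hrf_kwargs: dict | None = None,
) -> DesignMatrix:
    """Build a single-run design matrix.

    Parameters
    ----------
    events:
        DataFrame with columns ``onset``, ``duration``, ``trial_type``
        (onsets in seconds from the first retained volume).
    hp_cutoff:
        High-pass cut-off period in seconds; the drift basis contains the
        ``floor(2 * run_duration / hp_cutoff)`` lowest discrete-cosine
        frequencies, i.e. everything below ``1 / hp_cutoff`` Hz.
    model_ec:
        If True, eye-contact-only trials get their own regressor instead of
        remaining implicit baseline.
    """
    allowed = conditions if conditions is not None else CONDITIONS
    labels = list(events["trial_type"]) if len(events) else []
    unknown = sorted(set(labels) - set(allowed))
    if unknown:
        raise DyadscanError(f"unknown condition labels: {unknown}")
    duration = n_vols * tr
    onsets = np.asarray(events["onset"], dtype=float) if len(events) else np.empty(0)
    durs = np.asarray(events["duration"], dtype=float) if len(events) else np.empty(0)
    if len(onsets) and (onsets.min() < 0 or (onsets + durs).max() > duration):
        raise DyadscanError("events must fall inside the run")

    modeled = [c for c in MODELED_CONDITIONS if c in labels]
    if model_ec and "ec_only" in labels:
        modeled.append("ec_only")

    dt = tr / oversampling
    n_hi = n_vols * oversampling
    hrf = canonical_hrf(tr, oversampling=oversampling, **(hrf_kwargs or {}))
    sample_idx = np.arange(n_vols) * oversampling

    cols, names = [], []
    for cond in modeled:
        box = np.zeros(n_hi)
        for onset, dur in zip(onsets[np.asarray(labels) == cond],
                              durs[np.asarray(labels) == cond]):
            i0 = int(round(onset / dt))
            i1 = int(round((onset + dur) / dt))
            box[i0:i1] = 1.0
        reg = np.convolve(box, hrf)[:n_hi]
        cols.append(reg[sample_idx])
        names.append(cond)

    k_drift = int(np.floor(2.0 * duration / hp_cutoff))
    drift = _dct_basis(n_vols, k_drift)
    for k in range(drift.shape[1]):
        cols.append(drift[:, k])
        names.append(f"drift{k + 1}_run{run_label}")
    cols.append(np.ones(n_vols))
    names.append(f"const_run{run_label}")

    dm = DesignMatrix(
        matrix=np.column_stack(cols),
        columns=names,
        run_index=np.full(n_vols, run_label),
    )
    dm.check_rank()
    return dm


def concat_designs(designs: list[DesignMatrix]) -> DesignMatrix:
    """Stack per-run designs: condition columns are shared across runs,
    drift and intercept columns stay run-specific (block diagonal)."""
    if not designs:
        raise DyadscanError("no designs to concatenate")
    cond_names = []
    for d in designs:
        for c in d.condition_columns:
            if c not in cond_names:
                cond_names.append(c)
    cond_names = [c for c in CONDITIONS if c in cond_names]
    nuis_names = []
    for d in designs:
        nuis_names.extend(n for n in d.columns if n not in CONDITIONS)
    if len(set(nuis_names)) != len(nuis_names):
        raise DyadscanError("run labels must be unique across concatenated runs")

    total_rows = sum(d.n_rows for d in designs)
    names = cond_names + nuis_names
    out = np.zeros((total_rows, len(names)))
    run_index = np.concatenate([d.run_index for d in designs])
    col_of = {n: i for i, n in enumerate(names)}
    row = 0
    for d in designs:
        for j, n in enumerate(d.columns):
            out[row : row + d.n_rows, col_of[n]] = d.matrix[:, j]
        row += d.n_rows
    dm = DesignMatrix(matrix=out, columns=names, run_index=run_index)
    dm.check_rank()
    return dm


def design_for_runs(
    events_per_run,
    tr: float,
    n_vols: int,
    **kwargs,
) -> DesignMatrix:
    """Convenience: one concatenated design from per-run event tables."""
    designs = [
        build_design_matrix(ev, tr, n_vols, run_label=r, **kwargs)
        for r, ev in enumerate(events_per_run)
    ]
    return concat_designs(designs)


def estimate_ar1(resid, mask=None, run_index=None) -> float:
    """Pooled lag-1 autoregression coefficient.

    The coefficient is pooled over voxels (and run segments) as the ratio
    of summed lag-1 cross-products to summed squares, after per-segment
    demeaning — the global-pooling convention of standard fMRI packages.
    Constant input is degenerate and returns 0 with a warning.
    """
    x = flatten_spatial(np.asarray(resid, dtype=float))
    if mask is not None:
        x = x[:, np.asarray(mask).reshape(-1).astype(bool)]
    if x.shape[0] < 3:
        raise DyadscanError("need at least 3 time points for AR(1)")
    if run_index is None:
        run_index = np.zeros(x.shape[0], dtype=int)
    num = 0.0
    den = 0.0
    for r in np.unique(run_index):
        seg = x[run_index == r]
        seg = seg - seg.mean(axis=0)
        num += float(np.sum(seg[1:] * seg[:-1]))
        den += float(np.sum(seg * seg))
    if den <= 0:
        warnings.warn("constant series: AR(1) coefficient undefined, using 0")
        return 0.0
    return float(np.clip(num / den, -0.999, 0.999))


def whiten_ar1(x: np.ndarray, rho: float, run_index=None) -> np.ndarray:
    """Apply the exact AR(1) inverse covariance square root per run:
    y_0 = sqrt(1 - rho^2) x_0, y_t = x_t - rho x_{t-1}."""
    x = np.asarray(x, dtype=float)
    if run_index is None:
        run_index = np.zeros(x.shape[0], dtype=int)
    y = np.empty_like(x)
    for r in np.unique(run_index):
        sel = np.flatnonzero(run_index == r)
        seg = x[sel]
        out = seg.copy()
        out[0] = np.sqrt(1.0 - rho**2) * seg[0]
        out[1:] = seg[1:] - rho * seg[:-1]
        y[sel] = out
    return y


@dataclass
class GlmResult:
    """Whitened least-squares fit of one subject's concatenated runs."""

    beta: np.ndarray  # (P, V)
    columns: list[str]
    rho: float
    sigma2: np.ndarray  # (V,)
    whitened_residuals: np.ndarray  # (T, V), all rows
    run_index: np.ndarray
    xtx_inv: np.ndarray
    df_resid: int
    drop_initial: int = 2
    spatial_shape: tuple[int, int, int] | None = None

    @property
    def residual_series(self) -> np.ndarray:
        """Whitened residuals with the first ``drop_initial`` volumes of
        every run discarded, runs concatenated — the series used by all
        inter-brain and connectivity analyses."""
        keep = np.ones(len(self.run_index), dtype=bool)
        for r in np.unique(self.run_index):
            sel = np.flatnonzero(self.run_index == r)
            keep[sel[: self.drop_initial]] = False
        return self.whitened_residuals[keep]

    def beta_map(self, name: str) -> np.ndarray:
        i = self.columns.index(name)
        b = self.beta[i]
        if self.spatial_shape is not None:
            return b.reshape(self.spatial_shape)
        return b


@dataclass
class ContrastImage:
    """Voxelwise contrast estimate with an optional t map."""

    effect: np.ndarray
    t: np.ndarray
    label: str = ""
    spatial_shape: tuple[int, int, int] | None = field(default=None)

    def effect_map(self) -> np.ndarray:
        if self.spatial_shape is not None:
            return self.effect.reshape(self.spatial_shape)
        return self.effect


def fit_glm(
    data,
    design: DesignMatrix,
    rho: float | None = None,
    drop_initial: int = 2,
    mask=None,
) -> GlmResult:
    """Fit the prewhitened GLM voxelwise.

    ``data`` is (T, V) or (X, Y, Z, T) with T matching the design rows.
    If ``rho`` is not given it is estimated by a two-pass procedure: OLS
    residuals first, then the pooled lag-1 coefficient, then generalised
    least squares under the exact AR(1) covariance.
    """
    arr = np.asarray(data, dtype=float)
    spatial_shape = arr.shape[:3] if arr.ndim == 4 else None
    y = flatten_spatial(arr)
    x = design.matrix
    if y.shape[0] != x.shape[0]:
        raise DyadscanError(
            f"data has {y.shape[0]} volumes but design has {x.shape[0]} rows"
        )
    design.check_rank()
    if rho is None:
        beta0, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid0 = y - x @ beta0
        rho = estimate_ar1(resid0, mask=mask, run_index=design.run_index)
    wx = whiten_ar1(x, rho, design.run_index)
    wy = whiten_ar1(y, rho, design.run_index)
    beta, *_ = np.linalg.lstsq(wx, wy, rcond=None)
    resid = wy - wx @ beta
    df = y.shape[0] - x.shape[1]
    sigma2 = np.sum(resid**2, axis=0) / df
    xtx_inv = np.linalg.inv(wx.T @ wx)
    return GlmResult(
        beta=beta,
        columns=list(design.columns),
        rho=float(rho),
        sigma2=sigma2,
        whitened_residuals=resid,
        run_index=design.run_index.copy(),
        xtx_inv=xtx_inv,
        df_resid=df,
        drop_initial=drop_initial,
        spatial_shape=spatial_shape,
    )


def contrast_weights(columns: list[str], spec: dict[str, float]) -> np.ndarray:
    """Expand a {column name: weight} mapping to a full weight vector."""
    missing = sorted(set(spec) - set(columns))
    if missing:
        raise DyadscanError(f"contrast names a column not in the design: {missing}")
    w = np.zeros(len(columns))
    for name, val in spec.items():
        w[columns.index(name)] = val
    return w


def compute_contrast(result: GlmResult, weights, label: str = "") -> ContrastImage:
    """Voxelwise weighted sum of coefficients and its t statistic."""
    if isinstance(weights, dict):
        weights = contrast_weights(result.columns, weights)
    w = np.asarray(weights, dtype=float)
    if w.shape[0] != result.beta.shape[0]:
        raise DyadscanError(
            f"contrast length {w.shape[0]} != {result.beta.shape[0]} coefficients"
        )
    effect = w @ result.beta
    var = result.sigma2 * float(w @ result.xtx_inv @ w)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(var > 0, effect / np.sqrt(var), 0.0)
    return ContrastImage(
        effect=effect, t=t, label=label, spatial_shape=result.spatial_shape
    )


def primed_contrast(result: GlmResult, name: str) -> ContrastImage:
    """ES', BS', EN' or BN': a condition minus its run-type control."""
    if name not in PRIMED_CONTRASTS:
        raise DyadscanError(f"unknown primed contrast {name!r}")
    return compute_contrast(result, PRIMED_CONTRASTS[name], label=name)


def effect_contrast(result: GlmResult, effect: str) -> ContrastImage:
    """Factorial effect on the primed contrasts.

    eye_cued = (ES' + EN') - (BS' + BN'); shared = (ES' + BS') - (EN' + BN');
    interaction = (ES' - EN') - (BS' - BN'). Control conditions cancel in
    all three, so the weights reduce to the task conditions themselves.
    """
    if effect not in FACTORIAL_EFFECTS:
        raise DyadscanError(f"unknown effect {effect!r}")
    return compute_contrast(result, FACTORIAL_EFFECTS[effect], label=effect)


def gaussian_smooth(image, fwhm: float = 8.0, voxel_size: float = 4.0) -> np.ndarray:
    """Spatial Gaussian smoothing with reflective boundaries.

    ``fwhm`` and ``voxel_size`` in mm; 4-D input is smoothed volume by
    volume. fwhm -> 0 is the identity. Reflective boundary handling keeps
    the image mean (hence ROI means on small grids) unbiased at the edges.
    """
    img = np.asarray(image, dtype=float)
    if fwhm < 0:
        raise DyadscanError("fwhm must be non-negative")
    if fwhm == 0:
        return img.copy()
    if fwhm < voxel_size:
        warnings.warn("smoothing fwhm below voxel size: near-identity kernel")
    sigma_vox = fwhm / (np.sqrt(8.0 * np.log(2.0)) * voxel_size)
    if img.ndim == 4:
        sigma = (sigma_vox, sigma_vox, sigma_vox, 0.0)
    elif img.ndim == 3:
        sigma = sigma_vox
    else:
        raise DyadscanError("expected a 3-D or 4-D image")
    return ndimage.gaussian_filter(img, sigma=sigma, mode="reflect")


def power_spectrum(series, tr: float):
    """Periodogram of a 1-D series; returns (frequencies Hz, power)."""
    x = np.asarray(series, dtype=float)
    freqs, power = signal.periodogram(x, fs=1.0 / tr, detrend="constant")
    return freqs, power
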