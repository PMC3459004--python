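"""Core containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Condition vocabulary of the joint-attention paradigm.
#: ES/EN: eye-cued shared / non-shared attention; BS/BN: ball-cued shared /
#: non-shared; SBNc/SBNd: simultaneous-ball controls of the concordant and
#: discordant runs; ec_only: plain eye-contact trials (the baseline state).
CONDITIONS = ("ES", "BS", "EN", "BN", "SBNc", "SBNd", "ec_only")

#: Conditions entered into the GLM by default. Eye-contact-only trials are
#: the implicit baseline and are not modelled.
MODELED_CONDITIONS = ("ES", "BS", "EN", "BN", "SBNc", "SBNd")


class DyadscanError(Exception):
    """Base class for validation errors raised by this package."""


@dataclass
class BoldRun:
    """One 4-D BOLD run on a regular voxel grid.

    Parameters
    ----------
    data:
        Array of shape (X, Y, Z, T).
    tr:
        Repetition time in seconds.
    affine:
        4x4 voxel-to-world affine (NIfTI convention).
    """

    data: np.ndarray
    tr: float
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise DyadscanError(
                f"BoldRun requires a 4-D array, got ndim={self.data.ndim}"
            )
        if self.tr <= 0:
            raise DyadscanError("TR must be positive")
        if self.affine is None:
            self.affine = np.eye(4)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise DyadscanError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    def timeseries(self) -> np.ndarray:
        """Return the run as a (T, V) matrix, voxels flattened C-order."""
        x, y, z, t = self.data.shape
        return self.data.reshape(x * y * z, t).T

    def drop_leading(self, n: int) -> "BoldRun":
        """Discard the first ``n`` volumes (magnetisation stabilisation)."""
        if not 0 <= n < self.n_volumes:
            raise DyadscanError(f"cannot drop {n} of {self.n_volumes} volumes")
        return BoldRun(self.data[..., n:], tr=self.tr, affine=self.affine)


def flatten_spatial(arr: np.ndarray) -> np.ndarray:
    """(X, Y, Z, T) -> (T, V); a (T, V) array passes through unchanged."""
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 4:
        x, y, z, t = arr.shape
        return arr.reshape(x * y * z, t).T
    if arr.ndim == 2:
        return arr
    if arr.ndim == 1:
        return arr[:, None]
    raise DyadscanError(f"expected 1-D, 2-D or 4-D array, got ndim={arr.ndim}")
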