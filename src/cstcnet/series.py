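"""4-D BOLD-like series container with NIfTI round-tripping."""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np


@dataclass
class Series4D:
    """A voxel-grid x time BOLD-like image.

    ``data`` has shape (X, Y, Z, T); ``tr_seconds`` is the sampling
    interval (repetition time).
    """

    data: np.ndarray
    tr_seconds: float
    affine: np.ndarray = field(default_factory=lambda: np.diag([3.0, 3.0, 3.0, 1.0]))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4-D data, got shape {self.data.shape}")
        if self.data.shape[3] < 1:
            raise ValueError("series must contain at least one timepoint")
        if not np.isfinite(self.data).all():
            raise ValueError("series contains non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def grid_dims(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def nyquist_hz(self) -> float:
        return 0.5 / self.tr_seconds

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine)
        img.header.set_zooms((*img.header.get_zooms()[:3], self.tr_seconds))
        return img

    @classmethod
    def from_nifti(cls, path) -> "Series4D":
        img = nib.load(str(path))
        tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 2.0
        return cls(np.asarray(img.dataobj, dtype=np.float64), tr, np.asarray(img.affine))
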