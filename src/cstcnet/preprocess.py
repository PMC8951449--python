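"""Temporal preprocessing of BOLD series.

The chain applied before connectivity analysis is: discard of the
initial non-equilibrium volumes, motion screening (exclusion when any
translation exceeds 1.5 mm or any rotation 1.5 degrees), nuisance
regression (six motion parameters, white-matter and CSF compartment
means, the global brain mean, an intercept and a linear trend), and an
ideal frequency-domain band-pass at 0.01-0.08 Hz.

The band-pass is a pure DFT-mask projector: every Fourier bin outside
the pass band (including DC) is zeroed.  Because it is an orthogonal
projection it is exactly idempotent; linear drift is handled by the
trend column of the nuisance design rather than inside the filter.
Edge effects of the implicit periodic extension are therefore the only
distortion, and are negligible once the trend and mean have been
regressed out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import AtlasBundle
from .series import Series4D
from .simulate import MOTION_COLUMNS, ConfigurationError, SubjectDataset


@dataclass
class NuisanceDesign:
    """Timepoints x k design matrix with named columns."""

    matrix: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.names):
            raise ValueError("design matrix shape does not match column names")
        if not np.isfinite(self.matrix).all():
            raise ValueError("design contains non-finite values")
        rank = np.linalg.matrix_rank(self.matrix)
        if rank < self.matrix.shape[1]:
            bad = self._collinear_columns()
            raise ValueError(f"rank-deficient nuisance design; collinear columns: {bad}")

    def _collinear_columns(self) -> list[str]:
        _, r = np.linalg.qr(self.matrix)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(self.matrix.shape) * np.finfo(float).eps
        return [name for name, d in zip(self.names, diag) if d < tol]


@dataclass
class MotionCheck:
    keep: bool
    max_translation_mm: float
    max_rotation_deg: float


def discard_initial_volumes(series: Series4D, n_discard: int) -> Series4D:
    """Drop the first ``n_discard`` volumes (signal-equilibrium rule)."""
    if not 0 <= n_discard < series.n_timepoints:
        raise ValueError(
            f"n_discard={n_discard} outside [0, {series.n_timepoints})"
        )
    return Series4D(series.data[..., n_discard:], series.tr_seconds, series.affine)


def check_motion_exclusion(
    motion, trans_mm: float = 1.5, rot_deg: float = 1.5
) -> MotionCheck:
    """Flag a session for exclusion when head motion exceeded threshold."""
    arr = np.asarray(motion, dtype=float) if not isinstance(motion, pd.DataFrame) else motion.to_numpy(dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 6:
        raise ValueError(f"motion table must have 6 columns, got shape {arr.shape}")
    if not np.isfinite(arr).all():
        raise ValueError("motion table contains non-finite values")
    max_trans = float(np.abs(arr[:, :3]).max())
    max_rot = float(np.abs(arr[:, 3:]).max())
    keep = max_trans <= trans_mm and max_rot <= rot_deg
    return MotionCheck(keep=keep, max_translation_mm=max_trans, max_rotation_deg=max_rot)


def compartment_signals(
    series: Series4D, atlas: AtlasBundle
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean WM, CSF and global (all labeled voxels) series."""
    if series.grid_dims != atlas.shape:
        raise ValueError("series and atlas geometry differ")
    data = series.data
    wm = data[atlas.wm].mean(axis=0)
    csf = data[atlas.csf].mean(axis=0)
    brain = (
        (atlas.cortical_labels > 0)
        | atlas.striatum
        | atlas.thalamus
        | atlas.cerebellum
        | atlas.wm
        | atlas.csf
    )
    global_ = data[brain].mean(axis=0)
    return wm, csf, global_


def build_nuisance_design(
    motion,
    wm: np.ndarray,
    csf: np.ndarray,
    global_signal: np.ndarray | None,
    include_trend: bool = True,
) -> NuisanceDesign:
    """Assemble the nuisance design: 6 motion + WM + CSF (+ global)
    columns plus intercept (and linear trend by default).

    Global-signal regression is on by default; pass ``None`` to omit it.
    """
    arr = motion.to_numpy(dtype=float) if isinstance(motion, pd.DataFrame) else np.asarray(motion, dtype=float)
    if arr.shape[1] != 6:
        raise ValueError("motion table must have 6 columns")
    t = arr.shape[0]
    cols = [np.ones(t)]
    names = ["intercept"]
    if include_trend:
        cols.append(np.linspace(-1.0, 1.0, t))
        names.append("trend")
    for k, name in enumerate(MOTION_COLUMNS):
        cols.append(arr[:, k])
        names.append(name)
    cols += [np.asarray(wm, float), np.asarray(csf, float)]
    names += ["wm", "csf"]
    if global_signal is not None:
        cols.append(np.asarray(global_signal, float))
        names.append("global")
    return NuisanceDesign(np.column_stack(cols), tuple(names))


def regress_nuisance(series: Series4D, design: NuisanceDesign) -> Series4D:
    """Replace every voxel series by its least-squares residual."""
    if design.matrix.shape[0] != series.n_timepoints:
        raise ValueError("design rows must equal series timepoints")
    x = design.matrix
    y = series.data.reshape(-1, series.n_timepoints).T  # (T, V)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = (y - x @ beta).T.reshape(series.data.shape)
    return Series4D(resid.astype(series.data.dtype, copy=False), series.tr_seconds, series.affine)


def bandpass_filter(
    series: Series4D, low_hz: float = 0.01, high_hz: float = 0.08
) -> Series4D:
    """Ideal rectangular band-pass (DFT-mask projection, DC removed)."""
    nyquist = series.nyquist_hz
    if not (0 < low_hz < high_hz < nyquist):
        raise ConfigurationError(
            f"band ({low_hz}, {high_hz}) Hz outside (0, Nyquist={nyquist})"
        )
    t = series.n_timepoints
    freqs = np.fft.rfftfreq(t, d=series.tr_seconds)
    mask = (freqs >= low_hz) & (freqs <= high_hz)
    coef = np.fft.rfft(series.data, axis=-1)
    coef[..., ~mask] = 0.0
    out = np.fft.irfft(coef, n=t, axis=-1)
    return Series4D(out.astype(series.data.dtype, copy=False), series.tr_seconds, series.affine)


def preprocess_subject(
    dataset: SubjectDataset,
    atlas: AtlasBundle,
    n_discard: int = 10,
    band: tuple[float, float] = (0.01, 0.08),
    trans_mm: float = 1.5,
    rot_deg: float = 1.5,
    global_signal: bool = True,
) -> tuple[Series4D | None, MotionCheck]:
    """Full chain for one subject; returns ``(None, check)`` when the
    session fails motion screening."""
    check = check_motion_exclusion(dataset.motion, trans_mm, rot_deg)
    if not check.keep:
        return None, check
    series = discard_initial_volumes(dataset.series, n_discard)
    motion = dataset.motion.iloc[n_discard:].reset_index(drop=True)
    wm, csf, global_ = compartment_signals(series, atlas)
    design = build_nuisance_design(
        motion, wm, csf, global_ if global_signal else None
    )
    series = regress_nuisance(series, design)
    series = bandpass_filter(series, *band)
    return series, check
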