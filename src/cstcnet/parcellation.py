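"""Winner-take-all parcellation of subcortical structures.

Every striatum/thalamus/cerebellum voxel is correlated with each of the
five cortical system mean signals by partial correlation (the other four
systems serve as covariates) and labeled by the system with the highest
signed coefficient.  The dynamic variant computes the same coefficients
per sliding window and applies winner-take-all to the window average.
Label maps are compared with Dice coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import CORTICAL_SYSTEMS, AtlasBundle
from .network import sliding_windows
from .series import Series4D


@dataclass
class ParcelSignals:
    """Timepoints x 5 mean series, one column per cortical system."""

    matrix: np.ndarray
    systems: tuple[str, ...] = CORTICAL_SYSTEMS

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 5:
            raise ValueError("parcel signal matrix must have exactly 5 columns")


@dataclass
class WTAMap:
    """Per-voxel winning labels plus the underlying coefficients.

    ``labels`` holds one entry per voxel of ``mask`` (row-major order of
    ``np.nonzero(mask)``): the winning cortical system 1..5, or 0 for
    voxels whose series had zero variance ("unassigned", excluded from
    Dice).  ``coeffs`` stores the 5 partial-correlation coefficients
    (NaN for unassigned voxels).
    """

    structure: str
    mask: np.ndarray
    labels: np.ndarray
    coeffs: np.ndarray
    mode: str  # "static" | "dynamic-mean"

    @classmethod
    def from_coeffs(cls, structure, mask, coeffs, mode) -> "WTAMap":
        coeffs = np.asarray(coeffs, dtype=float)
        assigned = np.isfinite(coeffs).all(axis=1)
        labels = np.zeros(coeffs.shape[0], dtype=np.int16)
        if assigned.any():
            # argmax on signed coefficients; ties resolve to the lowest index
            labels[assigned] = np.argmax(coeffs[assigned], axis=1) + 1
        return cls(structure, mask, labels, coeffs, mode)

    def label_volume(self) -> np.ndarray:
        vol = np.zeros(self.mask.shape, dtype=np.int16)
        vol[self.mask] = self.labels
        return vol

    @property
    def assigned(self) -> np.ndarray:
        return self.labels > 0


def parcel_mean_signals(series: Series4D, atlas: AtlasBundle) -> ParcelSignals:
    """Mean series of the five cortical systems."""
    if series.grid_dims != atlas.shape:
        raise ValueError("series and atlas geometry differ")
    cols = []
    for c in range(1, 6):
        vox = atlas.cortical_labels == c
        if not vox.any():
            raise ValueError(f"cortical parcel {c} is empty")
        cols.append(series.data[vox].mean(axis=0, dtype=np.float64))
    return ParcelSignals(np.column_stack(cols))


def _partial_coeffs(x: np.ndarray, signals: np.ndarray) -> np.ndarray:
    """Partial correlation of every column of ``x`` (T x V) with each of
    the 5 parcel signals, conditioning on the other four.

    Both the voxel series and the target signal are projected off the
    covariates (intercept + other four systems) with a QR basis and the
    residuals correlated.  Zero-variance residuals yield NaN.
    """
    t, v = x.shape
    out = np.empty((v, 5))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for c in range(5):
            others = np.delete(signals, c, axis=1)
            z = np.column_stack([np.ones(t), others])
            q, _ = np.linalg.qr(z)
            rx = x - q @ (q.T @ x)
            ry = signals[:, c] - q @ (q.T @ signals[:, c])
            nx = np.linalg.norm(rx, axis=0)
            ny = np.linalg.norm(ry)
            out[:, c] = (rx.T @ ry) / (nx * ny)
    return out


def voxel_partial_wta(
    series: Series4D,
    structure_mask: np.ndarray,
    signals: ParcelSignals,
    structure: str = "structure",
) -> WTAMap:
    """Static winner-take-all labeling of one subcortical structure."""
    if not structure_mask.any():
        raise ValueError("structure mask is empty")
    if series.n_timepoints < 7:
        raise ValueError("need at least 7 timepoints for 4-covariate partialing")
    x = series.data[structure_mask].T.astype(float)  # (T, V)
    coeffs = _partial_coeffs(x, signals.matrix)
    return WTAMap.from_coeffs(structure, structure_mask, coeffs, "static")


def windowed_voxel_wta(
    series: Series4D,
    structure_mask: np.ndarray,
    signals: ParcelSignals,
    window_tr: int = 50,
    step_tr: int = 5,
    structure: str = "structure",
) -> WTAMap:
    """Dynamic (window-averaged) winner-take-all labeling.

    Per-window partial coefficients are computed exactly as in the
    static case and averaged across windows before the argmax.
    """
    if not structure_mask.any():
        raise ValueError("structure mask is empty")
    wins = sliding_windows(series.n_timepoints, window_tr, step_tr)
    x = series.data[structure_mask].T.astype(float)
    acc = np.zeros((x.shape[1], 5))
    for a, b in wins:
        acc += _partial_coeffs(x[a:b], signals.matrix[a:b])
    coeffs = acc / len(wins)
    return WTAMap.from_coeffs(structure, structure_mask, coeffs, "dynamic-mean")


def group_wta(maps: list[WTAMap]) -> WTAMap:
    """Group map: voxel-wise average of subject coefficients, then WTA.

    Voxels unassigned in some subjects contribute their remaining
    subjects' coefficients (NaN-aware mean); voxels unassigned in every
    subject stay unassigned.
    """
    if not maps:
        raise ValueError("no maps given")
    first = maps[0]
    for m in maps[1:]:
        if m.structure != first.structure:
            raise ValueError("cannot mix structures in a group map")
        if m.mask.shape != first.mask.shape or not np.array_equal(m.mask, first.mask):
            raise ValueError("maps have mismatched geometry")
        if m.mode != first.mode:
            raise ValueError("cannot mix static and dynamic maps")
    stack = np.stack([m.coeffs for m in maps])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
    mean[~np.isfinite(mean).all(axis=1)] = np.nan
    return WTAMap.from_coeffs(first.structure, first.mask, mean, first.mode)


def dice(map_a: WTAMap, map_b: WTAMap, label: int) -> float:
    """Dice overlap 2|A&B| / (|A|+|B|) of one label's voxel sets.

    Unassigned voxels are excluded; a label absent from both maps has an
    undefined Dice and raises.
    """
    if map_a.mask.shape != map_b.mask.shape or not np.array_equal(map_a.mask, map_b.mask):
        raise ValueError("maps have mismatched geometry")
    a = map_a.labels == label
    b = map_b.labels == label
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        raise ValueError(f"label {label} absent from both maps; Dice undefined")
    return 2.0 * int((a & b).sum()) / (na + nb)


@dataclass
class DiceReport:
    """Per (structure, label) Dice table; ``standardized`` divides each
    value by a reference (healthy-control) Dice for the same cell."""

    table: pd.DataFrame  # columns: structure, label, dice, standardized

    def cell(self, structure: str, label: int) -> float:
        row = self.table[
            (self.table.structure == structure) & (self.table.label == label)
        ]
        if row.empty:
            raise KeyError((structure, label))
        return float(row.dice.iloc[0])


def dice_profile(
    static_maps: dict[str, WTAMap],
    dynamic_maps: dict[str, WTAMap],
    reference: DiceReport | None = None,
) -> DiceReport:
    """Static-vs-dynamic Dice per structure and label.

    Labels missing from one of the two maps are reported as absent
    (NaN), not as 0.  With a reference report, each value is divided by
    the reference cell (an all-healthy-control profile); a zero
    reference cell raises.
    """
    rows = []
    for structure, smap in static_maps.items():
        dmap = dynamic_maps[structure]
        for label in range(1, 6):
            present_s = (smap.labels == label).any()
            present_d = (dmap.labels == label).any()
            if present_s and present_d:
                value = dice(smap, dmap, label)
            else:
                value = np.nan
            std = np.nan
            if reference is not None and np.isfinite(value):
                ref = reference.cell(structure, label)
                if ref == 0:
                    raise ValueError(
                        f"reference Dice is 0 for ({structure}, {label})"
                    )
                std = value / ref
            rows.append(
                {
                    "structure": structure,
                    "label": label,
                    "system": CORTICAL_SYSTEMS[label - 1],
                    "dice": value,
                    "standardized": std,
                }
            )
    return DiceReport(pd.DataFrame(rows))
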