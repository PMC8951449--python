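"""20-ROI cortico-striato-thalamo-cerebellar network construction.

Static connectivity is the full partial correlation between region mean
series (conditioning each pair on the remaining 18 regions, via the
inverse covariance), Fisher r-to-z transformed.  Dynamic connectivity is
plain Pearson correlation within sliding windows (50 TR window, 5 TR
step by default); its flexibility index is the entrywise standard
deviation of the windowed z values.  The per-window estimator is plain
rather than partial correlation because 50 samples cannot support
18-covariate partialing stably.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .atlas import CORTICAL_SYSTEMS, ROI_NAMES, SUBCORTICAL_STRUCTURES, AtlasBundle
from .series import Series4D

if TYPE_CHECKING:  # pragma: no cover
    from .parcellation import WTAMap

R_CLIP = 1.0 - 1e-6


@dataclass
class RoiSet:
    """The 20 analysis regions: 5 cortical systems plus the 5
    winner-take-all subregions of each subcortical structure."""

    names: tuple[str, ...]
    masks: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        if len(self.names) != 20 or len(self.masks) != 20:
            raise ValueError("a RoiSet must contain exactly 20 regions")
        for name, mask in zip(self.names, self.masks):
            if not mask.any():
                raise ValueError(f"ROI {name!r} is empty")


@dataclass
class ConnectivityMatrix:
    """Symmetric 20x20 Fisher-z matrix with zero diagonal."""

    values: np.ndarray
    kind: str  # static_z | dfc_mean_z | dfc_sd_z
    labels: tuple[str, ...] = ROI_NAMES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"expected {(n, n)} matrix, got {self.values.shape}")
        if not np.isfinite(self.values).all():
            raise ValueError("connectivity matrix contains non-finite values")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("diagonal must be zero")

    def edge_vector(self) -> np.ndarray:
        """The 190 unique off-diagonal entries (upper triangle, row-major)."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def flatten_features(self) -> np.ndarray:
        """Full row-major flattening (400 entries, duplicates and zero
        diagonal included) -- the classifier feature convention."""
        return self.values.reshape(-1)


def edge_names(labels: Sequence[str] = ROI_NAMES) -> list[tuple[str, str]]:
    iu = np.triu_indices(len(labels), k=1)
    return [(labels[i], labels[j]) for i, j in zip(*iu)]


@dataclass
class DynamicConnectivity:
    """Ordered per-window Fisher-z matrices."""

    matrices: np.ndarray  # (n_windows, 20, 20)
    window_tr: int
    step_tr: int
    windows: tuple[tuple[int, int], ...]
    labels: tuple[str, ...] = ROI_NAMES

    @property
    def n_windows(self) -> int:
        return self.matrices.shape[0]


def define_rois(hc_group_maps: dict[str, "WTAMap"], atlas: AtlasBundle) -> RoiSet:
    """Fix the 20 regions from the atlas plus the healthy-control static
    group winner-take-all maps; the same set is reused for every group."""
    names: list[str] = []
    masks: list[np.ndarray] = []
    for c, system in enumerate(CORTICAL_SYSTEMS, start=1):
        names.append(f"cortex-{system}")
        masks.append(atlas.cortical_labels == c)
    missing = []
    for structure in SUBCORTICAL_STRUCTURES:
        wta = hc_group_maps[structure]
        if wta.mode != "static":
            raise ValueError(f"{structure} map is {wta.mode!r}; static maps required")
        vol = wta.label_volume()
        for c, system in enumerate(CORTICAL_SYSTEMS, start=1):
            mask = vol == c
            names.append(f"{structure}-{system}")
            masks.append(mask)
            if not mask.any():
                missing.append((structure, c))
    if missing:
        raise ValueError(f"empty winner-take-all subregions: {missing}")
    return RoiSet(tuple(names), tuple(masks))


def roi_mean_signals(series: Series4D, rois: RoiSet) -> np.ndarray:
    """Timepoints x 20 matrix of region mean series, in fixed ROI order."""
    for mask in rois.masks:
        if mask.shape != series.grid_dims:
            raise ValueError("ROI geometry does not match series")
    return np.column_stack(
        [series.data[m].mean(axis=0, dtype=np.float64) for m in rois.masks]
    )


def fisher_z(r: np.ndarray) -> np.ndarray:
    """atanh with clipping at |r| = 1 - 1e-6 to keep z finite."""
    return np.arctanh(np.clip(r, -R_CLIP, R_CLIP))


def static_network(
    roi_signals: np.ndarray,
    shrinkage: bool = False,
    labels: tuple[str, ...] = ROI_NAMES,
) -> ConnectivityMatrix:
    """Static partial-correlation network over the full series.

    The pairwise partial correlation conditioning on the other 18
    regions is read off the inverse covariance (precision) matrix:
    ``r_ij = -P_ij / sqrt(P_ii P_jj)``.  With ``shrinkage=True`` a
    Ledoit-Wolf covariance estimate is used, which keeps the inversion
    well posed on short or collinear inputs.
    """
    x = np.asarray(roi_signals, dtype=float)
    t, p = x.shape
    if p != len(labels):
        raise ValueError(f"expected {len(labels)} columns, got {p}")
    if t <= p + 1:
        raise ValueError(f"need more than {p + 1} timepoints, got {t}")
    if shrinkage:
        from sklearn.covariance import LedoitWolf

        cov = LedoitWolf().fit(x).covariance_
    else:
        cov = np.cov(x, rowvar=False)
    if not shrinkage and np.linalg.cond(cov) > 1e12:
        raise np.linalg.LinAlgError(
            "ROI covariance is singular or near-singular; retry with shrinkage=True"
        )
    prec = np.linalg.inv(cov)
    d = np.sqrt(np.diag(prec))
    r = -prec / np.outer(d, d)
    np.fill_diagonal(r, 0.0)
    r = (r + r.T) / 2
    z = fisher_z(r)
    return ConnectivityMatrix(z, kind="static_z", labels=labels)


def sliding_windows(
    n_timepoints: int, window_tr: int, step_tr: int
) -> list[tuple[int, int]]:
    """Half-open index ranges [k*step, k*step + window)."""
    if not 0 < window_tr <= n_timepoints:
        raise ValueError(
            f"window_tr={window_tr} must be in (0, {n_timepoints}]"
        )
    if step_tr < 1:
        raise ValueError("step_tr must be >= 1")
    return [
        (start, start + window_tr)
        for start in range(0, n_timepoints - window_tr + 1, step_tr)
    ]


def dynamic_network(
    roi_signals: np.ndarray,
    window_tr: int = 50,
    step_tr: int = 5,
    labels: tuple[str, ...] = ROI_NAMES,
) -> DynamicConnectivity:
    """Sliding-window Pearson connectivity, Fisher-z per window."""
    x = np.asarray(roi_signals, dtype=float)
    wins = sliding_windows(x.shape[0], window_tr, step_tr)
    mats = np.empty((len(wins), x.shape[1], x.shape[1]))
    for k, (a, b) in enumerate(wins):
        r = np.corrcoef(x[a:b], rowvar=False)
        z = fisher_z(r)
        np.fill_diagonal(z, 0.0)
        mats[k] = z
    return DynamicConnectivity(
        matrices=mats,
        window_tr=window_tr,
        step_tr=step_tr,
        windows=tuple(wins),
        labels=labels,
    )


def dfc_mean(dyn: DynamicConnectivity) -> ConnectivityMatrix:
    m = dyn.matrices.mean(axis=0)
    np.fill_diagonal(m, 0.0)
    return ConnectivityMatrix((m + m.T) / 2, kind="dfc_mean_z", labels=dyn.labels)


def dfc_variability(dyn: DynamicConnectivity) -> ConnectivityMatrix:
    """Connectivity flexibility: entrywise sample SD (ddof=1) of the
    windowed z values."""
    if dyn.n_windows < 2:
        raise ValueError("variability needs at least 2 windows")
    sd = dyn.matrices.std(axis=0, ddof=1)
    np.fill_diagonal(sd, 0.0)
    return ConnectivityMatrix((sd + sd.T) / 2, kind="dfc_sd_z", labels=dyn.labels)
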