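"""Toy label atlas on a small voxel grid.

The analysis operates on five bilateral cortical systems (prefrontal,
motor/premotor, somatosensory, parietal/occipital, temporal), three
subcortical structures (striatum, thalamus, cerebellum) and two nuisance
compartments (white matter, CSF).  For simulation and testing these live
on a small 3-D grid as disjoint rectangular blocks; real atlases can be
substituted as long as the same label conventions are used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CORTICAL_SYSTEMS = (
    "prefrontal",
    "motor",
    "somatosensory",
    "parietal_occipital",
    "temporal",
)
SUBCORTICAL_STRUCTURES = ("striatum", "thalamus", "cerebellum")

#: ROI order used everywhere downstream: 5 cortical systems, then the five
#: winner-take-all subregions of striatum, thalamus and cerebellum.
ROI_NAMES = tuple(
    [f"cortex-{s}" for s in CORTICAL_SYSTEMS]
    + [f"{st}-{s}" for st in SUBCORTICAL_STRUCTURES for s in CORTICAL_SYSTEMS]
)


def roi_index(name: str) -> int:
    return ROI_NAMES.index(name)


@dataclass
class AtlasBundle:
    """Label/mask volumes shared by every pipeline stage.

    ``cortical_labels`` holds integers 0 (background) and 1..5 following
    the order of :data:`CORTICAL_SYSTEMS`; the remaining fields are
    boolean masks on the same grid.
    """

    cortical_labels: np.ndarray
    striatum: np.ndarray
    thalamus: np.ndarray
    cerebellum: np.ndarray
    wm: np.ndarray
    csf: np.ndarray
    voxel_size_mm: float = 3.0

    def __post_init__(self) -> None:
        shape = self.cortical_labels.shape
        masks = {
            "striatum": self.striatum,
            "thalamus": self.thalamus,
            "cerebellum": self.cerebellum,
            "wm": self.wm,
            "csf": self.csf,
        }
        stack = np.zeros(shape, dtype=int)
        stack += (self.cortical_labels > 0).astype(int)
        for name, m in masks.items():
            if m.shape != shape:
                raise ValueError(f"mask {name!r} shape {m.shape} != {shape}")
            if not m.any():
                raise ValueError(f"mask {name!r} is empty")
            stack += m.astype(int)
        if (stack > 1).any():
            raise ValueError("atlas label sets overlap")
        for lab in range(1, 6):
            if not (self.cortical_labels == lab).any():
                raise ValueError(f"cortical label {lab} is empty")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.cortical_labels.shape

    def structure_mask(self, structure: str) -> np.ndarray:
        if structure not in SUBCORTICAL_STRUCTURES:
            raise ValueError(f"unknown structure {structure!r}")
        return getattr(self, structure)

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size_mm
        return aff


def _frac_slice(n: int, lo: float, hi: float) -> slice:
    return slice(int(round(lo * n)), int(round(hi * n)))


def make_toy_atlas(
    grid_dims: tuple[int, int, int] = (24, 24, 16),
) -> tuple[AtlasBundle, dict[str, np.ndarray]]:
    """Build the block-shaped toy atlas and the planted subcortical labels.

    Returns the bundle and, for each subcortical structure, an integer
    volume assigning every structure voxel a cortical-system label in
    1..5 (the ground truth that winner-take-all parcellation should
    recover).  Blocks are placed by fractional coordinates so smaller
    test grids keep the same topology.
    """

    nx, ny, nz = grid_dims
    cortical = np.zeros(grid_dims, dtype=np.int16)
    zc = _frac_slice(nz, 0.625, 1.0)
    x_strips = np.array_split(np.arange(nx), 5)
    for lab, xs in enumerate(x_strips, start=1):
        cortical[xs[0] : xs[-1] + 1, :, zc] = lab

    def block(xf, yf, zf):
        m = np.zeros(grid_dims, dtype=bool)
        m[_frac_slice(nx, *xf), _frac_slice(ny, *yf), _frac_slice(nz, *zf)] = True
        return m

    striatum = block((1 / 12, 5 / 12), (1 / 12, 5 / 12), (1 / 8, 1 / 2))
    thalamus = block((7 / 12, 11 / 12), (1 / 12, 5 / 12), (1 / 8, 1 / 2))
    cerebellum = block((1 / 12, 5 / 12), (7 / 12, 11 / 12), (1 / 8, 1 / 2))
    wm = block((7 / 12, 11 / 12), (7 / 12, 11 / 12), (1 / 8, 5 / 16))
    csf = block((7 / 12, 11 / 12), (7 / 12, 11 / 12), (5 / 16, 1 / 2))

    atlas = AtlasBundle(cortical, striatum, thalamus, cerebellum, wm, csf)

    planted: dict[str, np.ndarray] = {}
    for structure in SUBCORTICAL_STRUCTURES:
        mask = atlas.structure_mask(structure)
        labels = np.zeros(grid_dims, dtype=np.int16)
        ys = np.unique(np.nonzero(mask)[1])
        for lab, chunk in enumerate(np.array_split(ys, 5), start=1):
            sub = mask.copy()
            keep = np.isin(np.arange(grid_dims[1]), chunk)
            sub &= keep[None, :, None]
            labels[sub] = lab
        if set(np.unique(labels[mask])) != {1, 2, 3, 4, 5}:
            raise ValueError(
                f"grid {grid_dims} too small to plant 5 labels in {structure}"
            )
        planted[structure] = labels
    return atlas, planted
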