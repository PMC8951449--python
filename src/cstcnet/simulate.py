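"""Ground-truth BOLD cohort simulator.

Generates cohorts of 4-D BOLD-like sessions in which everything the
downstream analysis estimates is planted by construction:

* each subcortical voxel is assigned one of the five cortical systems and
  couples to that system's latent signal with gain ``alpha_win`` (and to
  the other four latents with the weaker gain ``beta_cross``), so
  winner-take-all parcellation has a known right answer;
* group-specific static edge effects add a shared band-limited component
  to a pair of regions, shifting their coupling for that group;
* group-specific dynamic effects gate such a shared component with a slow
  two-state switching process, creating time-varying coupling that shows
  up as sliding-window connectivity variability;
* disease-duration slopes make an edge's coupling drift linearly with a
  patient's epilepsy duration.

The emulated acquisition is a 2 s repetition time, 250 volumes per
session, with signal content restricted to the 0.01-0.08 Hz band.  A
linear scanner drift, a shared global component, white-matter and CSF
compartment signals and six pseudo motion-parameter series are included
so the nuisance-regression stage has real work to do.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .atlas import (
    CORTICAL_SYSTEMS,
    ROI_NAMES,
    SUBCORTICAL_STRUCTURES,
    AtlasBundle,
    make_toy_atlas,
    roi_index,
)
from .series import Series4D

GROUPS = ("HC", "GE", "FE")
MOTION_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")


class ConfigurationError(ValueError):
    """Invalid simulation or filtering configuration."""


@dataclass(frozen=True)
class EdgeEffect:
    """A planted group-specific effect on one network edge.

    ``static_delta`` is a signed coupling increment (shared-variance
    units); ``dynamic_amplitude`` scales a gated component that switches
    on and off slowly, producing excess windowed-connectivity
    variability.
    """

    roi_i: str
    roi_j: str
    group: str
    static_delta: float = 0.0
    dynamic_amplitude: float = 0.0


@dataclass(frozen=True)
class DurationSlope:
    """Coupling drift of one edge with epilepsy duration (per year)."""

    roi_i: str
    roi_j: str
    group: str
    slope: float


def default_edge_effects() -> tuple[EdgeEffect, ...]:
    """Planted group effects mirroring the qualitative clinical pattern:
    thalamo-cortical motor/somatosensory coupling raised in generalized
    epilepsy, cerebellar coupling raised in focal epilepsy, plus one
    dynamically gated edge per patient group."""
    return (
        EdgeEffect("cortex-motor", "thalamus-motor", "GE", static_delta=0.3),
        EdgeEffect("cortex-somatosensory", "thalamus-somatosensory", "GE", static_delta=0.3),
        EdgeEffect("cortex-motor", "cerebellum-motor", "FE", static_delta=0.3),
        EdgeEffect("cortex-somatosensory", "cerebellum-somatosensory", "FE", static_delta=0.3),
        EdgeEffect("cortex-prefrontal", "thalamus-motor", "GE", dynamic_amplitude=2.0),
        EdgeEffect("cortex-prefrontal", "cerebellum-motor", "FE", dynamic_amplitude=2.0),
    )


def default_duration_slopes() -> tuple[DurationSlope, ...]:
    """Duration effects: opposite-sign somatosensory-thalamic slopes in
    the two patient groups, and a shared negative striato-thalamic
    slope."""
    return (
        DurationSlope("cortex-somatosensory", "thalamus-somatosensory", "GE", +0.01),
        DurationSlope("cortex-somatosensory", "thalamus-somatosensory", "FE", -0.01),
        DurationSlope("striatum-motor", "thalamus-motor", "GE", -0.01),
        DurationSlope("striatum-motor", "thalamus-motor", "FE", -0.01),
    )


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic cohort.

    Defaults emulate the acquisition (TR 2 s, 250 volumes, 0.01-0.08 Hz
    band) and a signal-to-noise regime in which winner-take-all label
    recovery is near-certain per voxel (``alpha_win`` 1.0 vs
    ``beta_cross`` 0.2 at ``noise_sd`` 0.5).
    """

    grid_dims: tuple[int, int, int] = (24, 24, 16)
    tr_seconds: float = 2.0
    n_volumes: int = 250
    n_per_group: int = 30
    groups: tuple[str, ...] = GROUPS
    band: tuple[float, float] = (0.01, 0.08)
    alpha_win: float = 1.0
    beta_cross: float = 0.2
    noise_sd: float = 0.5
    edge_effects: tuple[EdgeEffect, ...] = field(default_factory=default_edge_effects)
    duration_slopes: tuple[DurationSlope, ...] = field(default_factory=default_duration_slopes)
    seed: int = 0
    # cohort demographics (means/SDs in years, per-month frequency)
    female_fraction: float = 39 / 114
    age_mean: float = 26.0
    age_sd: float = 7.0
    duration_mean_sd: dict = field(
        default_factory=lambda: {"GE": (7.98, 8.32), "FE": (9.42, 6.56)}
    )
    seizure_mean_sd: dict = field(
        default_factory=lambda: {"GE": (2.212, 10.76), "FE": (2.34, 6.21)}
    )
    # nuisance structure
    mean_dwell_tr: float = 40.0
    global_sd: float = 0.5
    drift_sd: float = 0.3
    motion_step_mm: float = 0.01
    motion_step_deg: float = 0.01
    motion_leak: float = 0.1

    def __post_init__(self) -> None:
        low, high = self.band
        nyquist = 0.5 / self.tr_seconds
        if not (0 < low < high < nyquist):
            raise ConfigurationError(
                f"band {self.band} must satisfy 0 < low < high < Nyquist ({nyquist} Hz)"
            )
        if not (self.alpha_win > self.beta_cross >= 0):
            raise ConfigurationError(
                "alpha_win > beta_cross >= 0 required for identifiable WTA labels"
            )
        if self.n_volumes <= 10:
            raise ConfigurationError("n_volumes must exceed the 10-volume discard")
        if self.n_per_group < 1:
            raise ConfigurationError("n_per_group must be positive")
        unknown = {e.group for e in self.edge_effects} | {
            s.group for s in self.duration_slopes
        }
        unknown -= set(GROUPS)
        if unknown:
            raise ConfigurationError(f"effects reference unknown groups {sorted(unknown)}")


@dataclass
class GroundTruth:
    """What was planted: voxel labels, edge effects, duration slopes and
    the subject table."""

    voxel_labels: dict[str, np.ndarray]
    edge_effects: tuple[EdgeEffect, ...]
    duration_slopes: tuple[DurationSlope, ...]
    subject_table: pd.DataFrame


@dataclass
class SubjectDataset:
    series: Series4D
    motion: pd.DataFrame
    phenotype: pd.Series

    def __post_init__(self) -> None:
        if len(self.motion) != self.series.n_timepoints:
            raise ValueError("motion table rows must match series timepoints")


# ---------------------------------------------------------------------------
# primitive signal generators


def _band_mask(n: int, tr: float, low: float, high: float) -> np.ndarray:
    nyquist = 0.5 / tr
    if not (0 < low < high < nyquist):
        raise ConfigurationError(
            f"band ({low}, {high}) Hz outside (0, Nyquist={nyquist}) for TR {tr} s"
        )
    freqs = np.fft.rfftfreq(n, d=tr)
    mask = (freqs >= low) & (freqs <= high)
    if not mask.any():
        raise ConfigurationError("band contains no resolvable frequency bins")
    return mask


def _bandlimited(
    n: int, tr: float, low: float, high: float, rng: np.random.Generator, size=()
) -> np.ndarray:
    """Zero-mean unit-variance series with spectral support in [low, high]."""
    if n < 4:
        raise ConfigurationError("need at least 4 timepoints")
    mask = _band_mask(n, tr, low, high)
    shape = tuple(np.atleast_1d(size)) if size != () else ()
    coef = np.zeros(shape + (mask.size,), dtype=complex)
    m = int(mask.sum())
    coef[..., mask] = rng.standard_normal(shape + (m,)) + 1j * rng.standard_normal(
        shape + (m,)
    )
    x = np.fft.irfft(coef, n=n, axis=-1)
    x -= x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    return x / sd


def bandlimited_signal(
    n_timepoints: int,
    tr_seconds: float,
    low_hz: float,
    high_hz: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Band-limited standardized noise series (the BOLD stand-in)."""
    return _bandlimited(n_timepoints, tr_seconds, low_hz, high_hz, rng)


def two_state_gate(
    n: int, mean_dwell: float, rng: np.random.Generator, size=()
) -> np.ndarray:
    """0/1 switching process with geometric dwell times (mean in samples)."""
    shape = tuple(np.atleast_1d(size)) if size != () else ()
    flips = rng.random(shape + (n,)) < 1.0 / mean_dwell
    start = rng.integers(0, 2, size=shape + (1,))
    return ((start + np.cumsum(flips, axis=-1)) % 2).astype(float)


# ---------------------------------------------------------------------------
# phenotypes


def generate_phenotypes(
    config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Subject table with sex/age matched across groups by construction.

    The same age vector and sex assignment is reused in every group, so
    cohort-balance tests are null by design; durations and seizure
    frequencies are lognormal with the configured group means/SDs.
    """
    n = config.n_per_group
    n_female = int(round(n * config.female_fraction))
    sexes = np.array(["F"] * n_female + ["M"] * (n - n_female))
    ages = np.clip(rng.normal(config.age_mean, config.age_sd, size=n), 18.0, 55.0)
    rows = []
    for group in config.groups:
        for k in range(n):
            rec = {
                "id": f"sub-{group}{k:03d}",
                "group": group,
                "sex": sexes[k],
                "age": round(float(ages[k]), 2),
            }
            if group in config.duration_mean_sd:
                mean, sd = config.duration_mean_sd[group]
                rec["duration_years"] = round(float(_lognormal(mean, sd, rng)), 2)
                fmean, fsd = config.seizure_mean_sd[group]
                rec["seizure_freq_per_month"] = round(float(_lognormal(fmean, fsd, rng)), 3)
            else:
                rec["duration_years"] = np.nan
                rec["seizure_freq_per_month"] = np.nan
            rows.append(rec)
    return pd.DataFrame(rows)


def _lognormal(mean: float, sd: float, rng: np.random.Generator) -> float:
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2
    return float(np.exp(rng.normal(mu, np.sqrt(sigma2))))


# ---------------------------------------------------------------------------
# per-subject generation


def _subject_couplings(
    config: SimulationConfig, group: str, duration: float
) -> tuple[dict[tuple[int, int], float], dict[tuple[int, int], float]]:
    """Resolve the planted effect tables into per-edge couplings for one
    subject: a signed static coupling and a dynamic gate amplitude."""
    static: dict[tuple[int, int], float] = {}
    dynamic: dict[tuple[int, int], float] = {}
    for eff in config.edge_effects:
        key = tuple(sorted((roi_index(eff.roi_i), roi_index(eff.roi_j))))
        static.setdefault(key, 0.0)
        dynamic.setdefault(key, 0.0)
        if eff.group == group:
            static[key] += eff.static_delta
            dynamic[key] += eff.dynamic_amplitude
    for ds in config.duration_slopes:
        key = tuple(sorted((roi_index(ds.roi_i), roi_index(ds.roi_j))))
        static.setdefault(key, 0.0)
        dynamic.setdefault(key, 0.0)
        if ds.group == group and np.isfinite(duration):
            static[key] += ds.slope * duration
    return static, dynamic


def _roi_additions(
    config: SimulationConfig,
    group: str,
    duration: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Shared edge-effect components, one additive series per ROI (20 x T).

    The same number of random draws is consumed for every subject so that
    subject streams stay aligned regardless of group membership.
    """
    T = config.n_volumes
    low, high = config.band
    add = np.zeros((len(ROI_NAMES), T))
    static, dynamic = _subject_couplings(config, group, duration)
    for key in static:
        i, j = key
        e = _bandlimited(T, config.tr_seconds, low, high, rng)
        c = static[key]
        if c != 0.0:
            amp = np.sqrt(abs(c))
            add[i] += amp * e
            add[j] += np.sign(c) * amp * e
        e2 = _bandlimited(T, config.tr_seconds, low, high, rng)
        gate = two_state_gate(T, config.mean_dwell_tr, rng)
        a = dynamic[key]
        if a != 0.0:
            add[i] += a * gate * e2
            add[j] += a * gate * e2
    return add


def generate_subject(
    config: SimulationConfig,
    truth: GroundTruth,
    subject_record: pd.Series,
    subject_seed,
    atlas: AtlasBundle | None = None,
) -> SubjectDataset:
    """One full 4-D session with planted structure.

    ``subject_seed`` may be an integer or a ``numpy.random.SeedSequence``.
    """
    group = subject_record["group"]
    if group not in config.groups:
        raise ValueError(f"unknown group label {group!r}")
    if atlas is None:
        atlas, _ = make_toy_atlas(config.grid_dims)
    rng = np.random.default_rng(subject_seed)
    T = config.n_volumes
    low, high = config.band
    tr = config.tr_seconds

    latents = _bandlimited(T, tr, low, high, rng, size=5)  # (5, T)
    wm_sig, csf_sig, global_sig = _bandlimited(T, tr, low, high, rng, size=3)
    duration = float(subject_record.get("duration_years", np.nan))
    roi_add = _roi_additions(config, group, duration, rng)

    steps = rng.normal(0.0, 1.0, size=(T, 6))
    scale = np.array([config.motion_step_mm] * 3 + [config.motion_step_deg] * 3)
    motion = pd.DataFrame(np.cumsum(steps, axis=0) * scale, columns=MOTION_COLUMNS)
    leak_w = rng.normal(0.0, 1.0, size=6)
    motion_z = (motion.to_numpy() - motion.to_numpy().mean(0)) / (
        motion.to_numpy().std(0) + 1e-12
    )
    leak = config.motion_leak * (motion_z @ leak_w) / np.sqrt(6)

    drift = config.drift_sd * np.linspace(-1.0, 1.0, T)
    base = config.global_sd * global_sig + drift + leak

    data = rng.normal(0.0, config.noise_sd, size=(*config.grid_dims, T)).astype(
        np.float32
    )
    for c in range(5):
        vox = atlas.cortical_labels == c + 1
        data[vox] += (latents[c] + roi_add[c] + base).astype(np.float32)
    others = latents.sum(axis=0)
    for s_idx, structure in enumerate(SUBCORTICAL_STRUCTURES):
        planted = truth.voxel_labels[structure]
        mask = atlas.structure_mask(structure)
        for c in range(5):
            vox = mask & (planted == c + 1)
            sig = (
                config.alpha_win * latents[c]
                + config.beta_cross * (others - latents[c])
                + roi_add[5 + 5 * s_idx + c]
                + base
            )
            data[vox] += sig.astype(np.float32)
    data[atlas.wm] += (wm_sig + base).astype(np.float32)
    data[atlas.csf] += (csf_sig + base).astype(np.float32)

    series = Series4D(data, tr, atlas.affine)
    return SubjectDataset(series=series, motion=motion, phenotype=subject_record)


def iter_cohort(config: SimulationConfig):
    """Yield ``(SubjectDataset, GroundTruth, AtlasBundle)`` lazily.

    Memory-friendly form of :func:`generate_cohort`: each 4-D session can
    be processed and released before the next is generated.
    """
    atlas, planted = make_toy_atlas(config.grid_dims)
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(1 + config.n_per_group * len(config.groups))
    phen = generate_phenotypes(config, np.random.default_rng(children[0]))
    truth = GroundTruth(
        planted, tuple(config.edge_effects), tuple(config.duration_slopes), phen
    )
    for k, (_, record) in enumerate(phen.iterrows()):
        yield generate_subject(config, truth, record, children[1 + k], atlas), truth, atlas


def generate_cohort(
    config: SimulationConfig,
) -> tuple[list[SubjectDataset], GroundTruth, AtlasBundle]:
    """Full cohort (three groups of ``n_per_group``), reproducible from
    ``config.seed``."""
    subjects = []
    truth = atlas = None
    for dataset, truth, atlas in iter_cohort(config):
        subjects.append(dataset)
    return subjects, truth, atlas


# ---------------------------------------------------------------------------
# region-level fast path


@dataclass
class RoiCohort:
    """Cohort generated directly at the 20-region level.

    Skips the voxel grid and the nuisance structure (which averaging and
    regression would remove) and carries the same planted edge effects;
    used for statistics- and classification-scale simulations where
    voxelwise parcellation is not under study.
    """

    signals: np.ndarray  # (n_subjects, T, 20)
    phenotype: pd.DataFrame
    config: SimulationConfig


def generate_roi_cohort(config: SimulationConfig, seed=None) -> RoiCohort:
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    phen = generate_phenotypes(config, rng)
    n = len(phen)
    T = config.n_volumes
    low, high = config.band
    tr = config.tr_seconds

    latents = _bandlimited(T, tr, low, high, rng, size=(n, 5))  # (n, 5, T)
    # ROI averaging shrinks voxel noise by ~sqrt(voxels per region)
    roi_noise_sd = config.noise_sd / np.sqrt(48.0)
    sig = np.empty((n, len(ROI_NAMES), T))
    sig[:, :5] = latents
    total = latents.sum(axis=1)
    for s_idx in range(len(SUBCORTICAL_STRUCTURES)):
        for c in range(5):
            sig[:, 5 + 5 * s_idx + c] = config.alpha_win * latents[:, c] + (
                config.beta_cross * (total - latents[:, c])
            )
    sig += rng.normal(0.0, roi_noise_sd, size=sig.shape)

    group = phen["group"].to_numpy()
    duration = phen["duration_years"].to_numpy(dtype=float)
    duration = np.where(np.isfinite(duration), duration, 0.0)

    static: dict[tuple[int, int], np.ndarray] = {}
    dynamic: dict[tuple[int, int], np.ndarray] = {}
    for eff in config.edge_effects:
        key = tuple(sorted((roi_index(eff.roi_i), roi_index(eff.roi_j))))
        static.setdefault(key, np.zeros(n))
        dynamic.setdefault(key, np.zeros(n))
        member = group == eff.group
        static[key][member] += eff.static_delta
        dynamic[key][member] += eff.dynamic_amplitude
    for ds in config.duration_slopes:
        key = tuple(sorted((roi_index(ds.roi_i), roi_index(ds.roi_j))))
        static.setdefault(key, np.zeros(n))
        dynamic.setdefault(key, np.zeros(n))
        member = group == ds.group
        static[key][member] += ds.slope * duration[member]

    for key in static:
        i, j = key
        e = _bandlimited(T, tr, low, high, rng, size=(n,))
        c = static[key]
        amp = np.sqrt(np.abs(c))[:, None]
        sig[:, i] += amp * e
        sig[:, j] += (np.sign(c)[:, None]) * amp * e
        e2 = _bandlimited(T, tr, low, high, rng, size=(n,))
        gate = two_state_gate(T, config.mean_dwell_tr, rng, size=(n,))
        a = dynamic[key][:, None]
        sig[:, i] += a * gate * e2
        sig[:, j] += a * gate * e2

    return RoiCohort(signals=sig.transpose(0, 2, 1), phenotype=phen, config=config)


# ---------------------------------------------------------------------------
# on-disk layout


def write_dataset(
    dataset: SubjectDataset,
    atlas: AtlasBundle,
    directory,
    truth: GroundTruth | None = None,
) -> dict:
    """Write one subject (NIfTI + TSV) and the atlas; returns a manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sid = dataset.phenotype["id"]
    manifest: dict = {"id": sid}

    bold = directory / f"{sid}_bold.nii.gz"
    nib.save(dataset.series.to_nifti(), str(bold))
    manifest["bold"] = str(bold)

    motion = directory / f"{sid}_motion.tsv"
    dataset.motion.to_csv(motion, sep="\t", index=False, float_format="%.6f")
    manifest["motion"] = str(motion)

    pheno = directory / f"{sid}_phenotype.tsv"
    dataset.phenotype.to_frame().T.to_csv(pheno, sep="\t", index=False)
    manifest["phenotype"] = str(pheno)

    manifest["atlas"] = {}
    vols = {
        "cortical": atlas.cortical_labels,
        **{s: atlas.structure_mask(s).astype(np.int16) for s in SUBCORTICAL_STRUCTURES},
        "wm": atlas.wm.astype(np.int16),
        "csf": atlas.csf.astype(np.int16),
    }
    for name, vol in vols.items():
        p = directory / f"atlas_{name}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(vol, dtype=np.int16), atlas.affine), str(p))
        manifest["atlas"][name] = str(p)

    if truth is not None:
        for structure, vol in truth.voxel_labels.items():
            p = directory / f"truth_labels_{structure}.nii.gz"
            nib.save(
                nib.Nifti1Image(np.asarray(vol, dtype=np.int16), atlas.affine), str(p)
            )
            manifest[f"truth_labels_{structure}"] = str(p)
        p = directory / "truth_effects.json"
        payload = {
            "edge_effects": [asdict(e) for e in truth.edge_effects],
            "duration_slopes": [asdict(s) for s in truth.duration_slopes],
        }
        p.write_text(json.dumps(payload, indent=2, sort_keys=True))
        manifest["truth_effects"] = str(p)
    return manifest


def read_subject(manifest: dict) -> SubjectDataset:
    series = Series4D.from_nifti(manifest["bold"])
    motion = pd.read_csv(manifest["motion"], sep="\t")
    pheno = pd.read_csv(manifest["phenotype"], sep="\t").iloc[0]
    return SubjectDataset(series=series, motion=motion, phenotype=pheno)


def read_atlas(manifest: dict) -> AtlasBundle:
    vols = {
        name: np.asarray(nib.load(p).dataobj) for name, p in manifest["atlas"].items()
    }
    return AtlasBundle(
        cortical_labels=vols["cortical"].astype(np.int16),
        striatum=vols["striatum"].astype(bool),
        thalamus=vols["thalamus"].astype(bool),
        cerebellum=vols["cerebellum"].astype(bool),
        wm=vols["wm"].astype(bool),
        csf=vols["csf"].astype(bool),
    )
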