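"""End-to-end orchestration: simulate -> preprocess -> parcellate ->
network -> stats -> classify -> reproduce.

Every stage writes its artifacts under the work directory and the run
manifest records a SHA-256 hash per file, so a rerun with the same
configuration and seed can be verified hash-for-hash.  All randomness
derives from the single root seed: the simulator consumes spawned
seed-sequence streams and the classifier folds use ``seed`` directly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, network, parcellation, preprocess, reproducibility, stats
from .atlas import SUBCORTICAL_STRUCTURES
from .simulate import SimulationConfig, iter_cohort

log = logging.getLogger("cstcnet")


@dataclass
class PipelineConfig:
    """Stage parameters; defaults follow the study protocol (10-volume
    discard, 0.01-0.08 Hz band, 50/5 TR windows, 10 folds, q < 0.05)."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    n_discard: int = 10
    band: tuple[float, float] = (0.01, 0.08)
    max_translation_mm: float = 1.5
    max_rotation_deg: float = 1.5
    global_signal: bool = True
    window_tr: int = 50
    step_tr: int = 5
    n_folds: int = 10
    q_threshold: float = 0.05
    k_grid: tuple = classify.DEFAULT_K_GRID
    svm_c: float = 1.0
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = SimulationConfig(**raw.pop("simulation", {}))
        for key in ("band", "k_grid"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(simulation=sim, **raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _matrix_tsv(mat: network.ConnectivityMatrix, path: Path) -> None:
    df = pd.DataFrame(mat.values, index=mat.labels, columns=mat.labels)
    df.to_csv(path, sep="\t", float_format="%.10g")


def run_pipeline(config: PipelineConfig, workdir) -> dict:
    """Run every stage on a synthetic cohort; returns the manifest."""
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    sim = dataclasses.replace(config.simulation, seed=config.seed)
    wtag = f"w{config.window_tr}"
    artifacts: dict[str, str] = {}
    timings: dict[str, float] = {}

    def save(name: str, path: Path) -> None:
        artifacts[name] = str(path.relative_to(workdir))

    # --- simulate + preprocess + subject-level parcellation (streamed) ---
    t0 = time.time()
    phen_rows, parcel_signals, clean_series = [], [], []
    subject_maps: dict[str, list] = {s: [] for s in SUBCORTICAL_STRUCTURES}
    truth = atlas = None
    excluded = []
    for dataset, truth, atlas in iter_cohort(sim):
        series, check = preprocess.preprocess_subject(
            dataset,
            atlas,
            n_discard=config.n_discard,
            band=config.band,
            trans_mm=config.max_translation_mm,
            rot_deg=config.max_rotation_deg,
            global_signal=config.global_signal,
        )
        if series is None:
            excluded.append(dataset.phenotype["id"])
            continue
        phen_rows.append(dataset.phenotype)
        sigs = parcellation.parcel_mean_signals(series, atlas)
        parcel_signals.append(sigs)
        clean_series.append(series)
        if dataset.phenotype["group"] == "HC":
            for structure in SUBCORTICAL_STRUCTURES:
                subject_maps[structure].append(
                    parcellation.voxel_partial_wta(
                        series, atlas.structure_mask(structure), sigs, structure
                    )
                )
    phen = pd.DataFrame(phen_rows).reset_index(drop=True)
    timings["simulate_preprocess"] = time.time() - t0
    log.info("preprocessed %d subjects (%d excluded for motion)", len(phen), len(excluded))
    _write_tsv(phen, workdir / "phenotypes.tsv")
    save("phenotypes", workdir / "phenotypes.tsv")

    # --- group winner-take-all maps (HC) and the fixed ROI set ---
    t0 = time.time()
    hc_maps = {
        s: parcellation.group_wta(subject_maps[s]) for s in SUBCORTICAL_STRUCTURES
    }
    # static-vs-dynamic similarity profile on the first healthy subject
    hc_idx = phen.index[phen.group == "HC"][0]
    dyn_maps = {
        s: parcellation.windowed_voxel_wta(
            clean_series[hc_idx],
            atlas.structure_mask(s),
            parcel_signals[hc_idx],
            window_tr=config.window_tr,
            step_tr=config.step_tr,
            structure=s,
        )
        for s in SUBCORTICAL_STRUCTURES
    }
    stat_maps = {s: subject_maps[s][0] for s in SUBCORTICAL_STRUCTURES}
    dice_report = parcellation.dice_profile(stat_maps, dyn_maps)
    _write_tsv(dice_report.table, workdir / "dice_profile.tsv")
    save("dice_profile", workdir / "dice_profile.tsv")
    rois = network.define_rois(hc_maps, atlas)
    timings["parcellation"] = time.time() - t0

    # --- 20-ROI networks ---
    t0 = time.time()
    static_mats, dfc_sd_mats = [], []
    for series in clean_series:
        sig = network.roi_mean_signals(series, rois)
        static_mats.append(network.static_network(sig, shrinkage=True))
        dyn = network.dynamic_network(sig, config.window_tr, config.step_tr)
        dfc_sd_mats.append(network.dfc_variability(dyn))
    for tag, mats in (("static", static_mats), (f"dfc_sd_{wtag}", dfc_sd_mats)):
        for group in sim.groups:
            idx = phen.index[phen.group == group]
            gm = reproducibility.mean_matrix([mats[i] for i in idx])
            p = workdir / f"network_{tag}_{group}_mean.tsv"
            _matrix_tsv(gm, p)
            save(f"network_{tag}_{group}_mean", p)
    timings["network"] = time.time() - t0

    # --- edgewise statistics ---
    t0 = time.time()
    by_group = {g: phen.index[phen.group == g].tolist() for g in sim.groups}
    for tag, mats in (("static", static_mats), ("dynamic", dfc_sd_mats)):
        pairs = [("GE", "HC"), ("FE", "HC"), ("GE", "FE")]
        for a, b in pairs:
            if a not in by_group or b not in by_group:
                continue
            res = stats.edgewise_ttest(
                [mats[i] for i in by_group[a]],
                [mats[i] for i in by_group[b]],
                q_threshold=config.q_threshold,
            )
            p = workdir / f"stats_{tag}_{a}_vs_{b}.tsv"
            _write_tsv(res.table, p)
            save(f"stats_{tag}_{a}_vs_{b}", p)
        for g in ("GE", "FE"):
            if g not in by_group:
                continue
            idx = by_group[g]
            res = stats.edgewise_duration_correlation(
                [mats[i] for i in idx],
                phen.loc[idx, "duration_years"].to_numpy(),
                q_threshold=config.q_threshold,
            )
            p = workdir / f"stats_{tag}_duration_{g}.tsv"
            _write_tsv(res.table, p)
            save(f"stats_{tag}_duration_{g}", p)
        if "GE" in by_group and "FE" in by_group:
            idx = by_group["GE"] + by_group["FE"]
            res = stats.interaction_model(
                [mats[i] for i in idx],
                phen.loc[idx, "group"].to_numpy(),
                phen.loc[idx, "duration_years"].to_numpy(),
                q_threshold=config.q_threshold,
            )
            p = workdir / f"stats_{tag}_interaction.tsv"
            _write_tsv(res.table, p)
            save(f"stats_{tag}_interaction", p)
    balance = stats.cohort_balance(phen)
    (workdir / "cohort_balance.json").write_text(
        json.dumps(dataclasses.asdict(balance), indent=2, sort_keys=True)
    )
    save("cohort_balance", workdir / "cohort_balance.json")
    timings["stats"] = time.time() - t0

    # --- classification GE vs FE ---
    t0 = time.time()
    classification: dict[str, dict] = {}
    if "GE" in by_group and "FE" in by_group:
        idx = by_group["GE"] + by_group["FE"]
        labels = np.where(phen.loc[idx, "group"] == "GE", 1, -1)
        ids = phen.loc[idx, "id"].tolist()
        tables = {
            "static": classify.build_feature_table(
                [static_mats[i] for i in idx], None, labels, ids
            ),
            "dynamic": classify.build_feature_table(
                None, [dfc_sd_mats[i] for i in idx], labels, ids
            ),
            "combined": classify.build_feature_table(
                [static_mats[i] for i in idx],
                [dfc_sd_mats[i] for i in idx],
                labels,
                ids,
            ),
        }
        for name, table in tables.items():
            if min((labels == 1).sum(), (labels == -1).sum()) < config.n_folds:
                log.warning("skipping classification (%s): too few subjects", name)
                continue
            result = classify.crossvalidated_svm(
                table,
                n_folds=config.n_folds,
                seed=config.seed,
                k_grid=config.k_grid,
                c=config.svm_c,
            )
            classification[name] = {
                "accuracy": result.accuracy,
                "sensitivity": result.sensitivity,
                "specificity": result.specificity,
                "auc": result.auc,
                "chosen_k": result.chosen_k,
            }
            p = workdir / f"classification_{name}_importance.tsv"
            _write_tsv(result.importance_ranking().head(50), p)
            save(f"classification_{name}_importance", p)
        (workdir / "classification.json").write_text(
            json.dumps(classification, indent=2, sort_keys=True)
        )
        save("classification", workdir / "classification.json")
    timings["classification"] = time.time() - t0

    # --- reproducibility ---
    t0 = time.time()
    split = reproducibility.split_half(phen, seed=config.seed)
    _write_tsv(split.assignments, workdir / "split_half.tsv")
    save("split_half", workdir / "split_half.tsv")
    split_rows = []
    for group in sim.groups:
        ids_a = set(split.half_ids("A"))
        idx_a = [i for i in by_group[group] if phen.loc[i, "id"] in ids_a]
        idx_b = [i for i in by_group[group] if phen.loc[i, "id"] not in ids_a]
        for tag, mats in (("static", static_mats), ("dynamic", dfc_sd_mats)):
            r, pval = reproducibility.pattern_correlation(
                reproducibility.mean_matrix([mats[i] for i in idx_a]),
                reproducibility.mean_matrix([mats[i] for i in idx_b]),
            )
            split_rows.append({"group": group, "kind": tag, "pattern_r": r, "pattern_p": pval})
    _write_tsv(pd.DataFrame(split_rows), workdir / "split_half_patterns.tsv")
    save("split_half_patterns", workdir / "split_half_patterns.tsv")
    timings["reproducibility"] = time.time() - t0

    manifest = {
        "config": {
            **{
                k: v
                for k, v in dataclasses.asdict(config).items()
                if k != "simulation"
            },
            "simulation": dataclasses.asdict(sim),
        },
        "excluded_subjects": excluded,
        "artifacts": artifacts,
        "hashes": {name: _sha256(workdir / rel) for name, rel in artifacts.items()},
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    manifest["config"] = json.loads(json.dumps(manifest["config"], default=list))
    (workdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
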