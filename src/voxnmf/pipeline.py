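"""End-to-end study orchestration from a single YAML configuration.

Stages (``simulate``, ``rank-scan``, ``fit``, ``project``, ``predict``,
``maps``, ``evaluate``) each read their prerequisites from the output
directory and write serialized artifacts plus a JSON log, so re-running
with the same config and seed reproduces the same outputs.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import voxnmf
from voxnmf.clinical import (
    ClinicalTable,
    OutcomeSpec,
    assemble_design,
    compare_paired_errors,
    fdr_adjust,
    fit_elastic_net,
    loads_to_frame,
    predict_outcome,
    summarize_binary,
    summarize_continuous,
)
from voxnmf.coefficient_maps import build_coefficient_map
from voxnmf.errors import ArgumentError, StageError
from voxnmf.imaging_io import MaskedGrid, load_image_set, save_component_maps, save_volume
from voxnmf.minvol_nmf import NMFConfig, fit_minvol_nmf, project_loads
from voxnmf.rank_selection import cv_rank_scan
from voxnmf import synthetic

ALL_STAGES = ("simulate", "rank-scan", "fit", "project", "predict", "maps", "evaluate")


@dataclass
class StudyConfig:
    """Validated study settings (see ``StudyConfig.from_yaml``)."""

    output_dir: Path
    seed: int = 0
    mask: str | None = None
    clinical_csv: str | None = None
    modalities: dict = field(default_factory=dict)  # name -> {"images": [...]} or rank
    binary_outcomes: list = field(default_factory=list)
    continuous_outcomes: list = field(default_factory=list)
    test_size: int = 0
    test_subjects: list | None = None
    nmf: dict = field(default_factory=dict)  # vol_weight, max_iter, rel_tol, init
    rank_scan: dict = field(default_factory=lambda: {"ranks": list(range(4, 21)), "k": 5, "repeats": 5})
    prediction: dict = field(
        default_factory=lambda: {
            "alpha_single": 0.2,
            "alpha_combined": 0.8,
            "cv_folds": 5,
            "error_summary": "median",
        }
    )
    comparison: dict = field(default_factory=lambda: {"n_perm": 10000, "fdr_alpha": 0.05})
    simulate: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "StudyConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ArgumentError(f"unknown config fields: {sorted(unknown)}")
        if "output_dir" not in raw:
            raise ArgumentError("config requires 'output_dir'")
        raw = dict(raw)
        raw["output_dir"] = Path(raw["output_dir"])
        defaults = cls(output_dir=raw["output_dir"])
        for key in ("rank_scan", "prediction", "comparison"):
            merged = dict(getattr(defaults, key))
            merged.update(raw.get(key) or {})
            raw[key] = merged
        return cls(**raw)


def _log(out: Path, stage: str, started: float, **info) -> None:
    entry = {
        "stage": stage,
        "version": voxnmf.__version__,
        "wall_seconds": round(time.time() - started, 3),
        **info,
    }
    log_path = out / "log.json"
    entries = json.loads(log_path.read_text()) if log_path.exists() else []
    entries.append(entry)
    log_path.write_text(json.dumps(entries, indent=2))


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise StageError(f"stage {stage!r}: missing prerequisite artifact {path}")
    return path


def draw_test_split(
    subject_ids_by_modality: dict, test_size: int, seed: int
) -> tuple[list, list]:
    """Seeded random test split among subjects with every modality available."""
    ids = None
    for mod_ids in subject_ids_by_modality.values():
        ids = set(mod_ids) if ids is None else ids & set(mod_ids)
    eligible = sorted(ids)
    if test_size > len(eligible):
        raise ArgumentError(
            f"test_size {test_size} exceeds {len(eligible)} dual-modality subjects"
        )
    rng = np.random.default_rng(seed)
    test = sorted(rng.choice(eligible, size=test_size, replace=False))
    all_ids = sorted(set().union(*map(set, subject_ids_by_modality.values())))
    train = [s for s in all_ids if s not in set(test)]
    return train, list(test)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_simulate(cfg: StudyConfig, out: Path) -> None:
    sim = cfg.simulate
    n = int(sim.get("n", 60))
    rank = int(sim.get("rank", 4))
    noise_sd = float(sim.get("noise_sd", 0.02))
    grid_size = int(sim.get("grid_size", 16))
    grid = synthetic.default_grid(grid_size)
    mods = list(cfg.modalities) or ["MRI", "FDG"]

    links = [
        synthetic.OutcomeLink("symptom_present", "binary", intercept=-1.0,
                              load_coefs=tuple([4.0] + [0.0] * (rank - 1))),
        synthetic.OutcomeLink("severity_score", "continuous", intercept=10.0,
                              age_coef=0.05, load_coefs=tuple([8.0] + [0.0] * (rank - 1)),
                              noise_sd=0.5),
    ]
    img_dir = out / "images"
    rng_root = np.random.SeedSequence([cfg.seed, 7])
    clinical = None
    truth_info = {}
    for mi, mod in enumerate(mods):
        D = synthetic.generate_components(grid, rank, seed=int(rng_root.generate_state(1)[0] % 2**31) + mi)
        X, table, truth = synthetic.generate_cohort(
            D, n, grid, noise_sd=noise_sd, outcome_links=links if mi == 0 else [],
            seed=cfg.seed, modality=mod,
        )
        if mi == 0:
            clinical = table
        mod_dir = img_dir / mod
        mod_dir.mkdir(parents=True, exist_ok=True)
        for i, sid in enumerate(X.subject_ids):
            save_volume(
                voxnmf.imaging_io.devectorize(X.values[i], grid, fill=0.0),
                grid, mod_dir / f"{sid}.nii",
            )
        truth_info[mod] = {"rank": rank, "noise_sd": noise_sd}
    save_volume(grid.mask.astype(float), grid, out / "mask.nii")
    clinical.to_csv(out / "clinical.csv")
    (out / "truth.json").write_text(json.dumps({"seed": cfg.seed, "modalities": truth_info}, indent=2))
    cfg.mask = str(out / "mask.nii")
    cfg.clinical_csv = str(out / "clinical.csv")
    cfg.binary_outcomes = ["symptom_present"]
    cfg.continuous_outcomes = ["severity_score"]
    merged = {}
    for mod in mods:
        spec = dict(cfg.modalities.get(mod, {}))
        spec["images"] = sorted(str(p) for p in (img_dir / mod).glob("*.nii"))
        merged[mod] = spec
    cfg.modalities = merged


def _load_matrices(cfg: StudyConfig) -> dict:
    grid = MaskedGrid.from_nifti(_require(Path(cfg.mask), "load"))
    matrices = {}
    for mod, spec in cfg.modalities.items():
        paths = sorted(spec["images"])
        matrices[mod] = load_image_set(paths, grid, mod)
    return matrices


def _split(cfg: StudyConfig, matrices: dict) -> tuple[list, list]:
    if cfg.test_subjects is not None:
        test = list(cfg.test_subjects)
        all_ids = sorted(set().union(*(set(m.subject_ids) for m in matrices.values())))
        return [s for s in all_ids if s not in set(test)], test
    return draw_test_split(
        {m: mat.subject_ids for m, mat in matrices.items()}, cfg.test_size,
        seed=cfg.seed + 101,
    )


def _subset(matrix, keep_ids: list):
    from voxnmf.imaging_io import VoxelMatrix

    keep = [i for i, s in enumerate(matrix.subject_ids) if s in set(keep_ids)]
    return VoxelMatrix(
        values=matrix.values[keep],
        subject_ids=[matrix.subject_ids[i] for i in keep],
        modality=matrix.modality,
        grid=matrix.grid,
    )


def _stage_rank_scan(cfg: StudyConfig, out: Path) -> None:
    matrices = _load_matrices(cfg)
    train_ids, _ = _split(cfg, matrices)
    rs = cfg.rank_scan
    chosen = {}
    for mod, matrix in matrices.items():
        train = _subset(matrix, train_ids)
        template = NMFConfig(rank=min(rs["ranks"]), **cfg.nmf)
        result = cv_rank_scan(
            train, rs["ranks"], k=rs["k"], m=rs["repeats"],
            config_template=template, seed=cfg.seed + 13,
        )
        result.to_csv(out / f"rank_scan_{mod}.csv")
        chosen[mod] = int(result.chosen_rank)
    (out / "chosen_ranks.json").write_text(json.dumps(chosen, indent=2))


def _chosen_rank(cfg: StudyConfig, out: Path, mod: str) -> int:
    explicit = cfg.modalities[mod].get("rank")
    if explicit:
        return int(explicit)
    ranks_file = _require(out / "chosen_ranks.json", "fit")
    return int(json.loads(ranks_file.read_text())[mod])


def _stage_fit(cfg: StudyConfig, out: Path) -> None:
    matrices = _load_matrices(cfg)
    train_ids, _ = _split(cfg, matrices)
    for mod, matrix in matrices.items():
        train = _subset(matrix, train_ids)
        config = NMFConfig(rank=_chosen_rank(cfg, out, mod), seed=cfg.seed + 29, **cfg.nmf)
        model, summary = fit_minvol_nmf(train, config)
        save_component_maps(model.dictionary, matrix.grid, out / f"components_{mod}.nii")
        loads_to_frame(model.loads, train.subject_ids, mod.lower()).to_csv(
            out / f"loads_train_{mod}.csv"
        )
        np.save(out / f"dictionary_{mod}.npy", model.dictionary)
        (out / f"fit_{mod}.json").write_text(json.dumps({
            "rank": config.rank,
            "seed": config.seed,
            "vol_weight_abs": model.vol_weight_abs,
            "converged": bool(model.converged),
            "reconstruction_mae": summary.reconstruction_mae,
            "iterations": summary.iterations_run,
            "objective_trace": [float(v) for v in model.objective_trace],
        }, indent=2))


def _stage_project(cfg: StudyConfig, out: Path) -> None:
    matrices = _load_matrices(cfg)
    _, test_ids = _split(cfg, matrices)
    for mod, matrix in matrices.items():
        D = np.load(_require(out / f"dictionary_{mod}.npy", "project"))
        test = _subset(matrix, test_ids)
        loads = project_loads(test, D)
        loads_to_frame(loads, test.subject_ids, mod.lower()).to_csv(out / f"loads_test_{mod}.csv")


def _modality_sets(mods: list) -> list:
    sets = [(m,) for m in mods]
    if len(mods) > 1:
        sets.append(tuple(mods))
    return sets


def _stage_predict(cfg: StudyConfig, out: Path) -> None:
    clinical = ClinicalTable.from_csv(
        _require(Path(cfg.clinical_csv), "predict"),
        binary=cfg.binary_outcomes, continuous=cfg.continuous_outcomes,
    )
    mods = list(cfg.modalities)
    train_loads = {
        m: pd.read_csv(_require(out / f"loads_train_{m}.csv", "predict"),
                       dtype={"subject_id": str}).set_index("subject_id")
        for m in mods
    }
    test_loads = {
        m: pd.read_csv(_require(out / f"loads_test_{m}.csv", "predict"),
                       dtype={"subject_id": str}).set_index("subject_id")
        for m in mods
    }
    pred_cfg = cfg.prediction
    rows = []
    model_dir = out / "models"
    model_dir.mkdir(exist_ok=True)
    for outcome in clinical.outcome_specs():
        for mset in _modality_sets(mods):
            alpha = pred_cfg["alpha_combined"] if len(mset) > 1 else pred_cfg["alpha_single"]
            blocks = {m: train_loads[m] for m in mset}
            design, y, _ = assemble_design(blocks, clinical, outcome)
            model = fit_elastic_net(
                design, y, outcome.family, alpha,
                cv_folds=pred_cfg["cv_folds"], seed=cfg.seed + 57,
                n_lambda=pred_cfg.get("n_lambda", 100),
                outcome=outcome, modalities=mset,
            )
            tag = f"{outcome.name}__{'_'.join(mset)}"
            model.to_json(model_dir / f"{tag}.json")
            test_blocks = {m: test_loads[m] for m in mset}
            test_design, y_test, test_subjects = assemble_design(
                test_blocks, clinical, outcome, min_cases=1, require_variance=False
            )
            if outcome.family == "binary":
                prob, label = predict_outcome(model, test_design)
                for sid, yt, pr, lb in zip(test_subjects, y_test, prob, label):
                    rows.append({"outcome": outcome.name, "family": outcome.family,
                                 "modalities": "+".join(mset), "subject_id": sid,
                                 "y_true": yt, "y_prob": pr, "y_pred": lb})
            else:
                y_hat = predict_outcome(model, test_design)
                for sid, yt, yh in zip(test_subjects, y_test, y_hat):
                    rows.append({"outcome": outcome.name, "family": outcome.family,
                                 "modalities": "+".join(mset), "subject_id": sid,
                                 "y_true": yt, "y_prob": np.nan, "y_pred": yh})
    pd.DataFrame(rows).to_csv(out / "test_predictions.csv", index=False)


def _stage_maps(cfg: StudyConfig, out: Path) -> None:
    from voxnmf.clinical import PredictionModel

    grid = MaskedGrid.from_nifti(_require(Path(cfg.mask), "maps"))
    map_dir = out / "coefficient_maps"
    map_dir.mkdir(exist_ok=True)
    for model_file in sorted((out / "models").glob("*.json")):
        model = PredictionModel.from_json(model_file)
        for mod in model.modalities:
            D = np.load(_require(out / f"dictionary_{mod}.npy", "maps"))
            cmap = build_coefficient_map(model, D, grid, prefix=mod.lower())
            cmap.save(map_dir / f"{model_file.stem}__{mod}.nii")


def _stage_evaluate(cfg: StudyConfig, out: Path) -> None:
    preds = pd.read_csv(_require(out / "test_predictions.csv", "evaluate"),
                        dtype={"subject_id": str})
    err_kind = cfg.prediction["error_summary"]
    rows = []
    for (outcome, family, mset), grp in preds.groupby(["outcome", "family", "modalities"]):
        if family == "binary":
            summary = summarize_binary(grp["y_true"], grp["y_pred"])
        else:
            summary = summarize_continuous(grp["y_true"], grp["y_pred"], error_summary=err_kind)
        rows.append({"outcome": outcome, "family": family, "modalities": mset, **summary})
    report = pd.DataFrame(rows)

    # paired single-modality comparisons on shared test subjects
    comparisons = []
    mods = [m for m in preds["modalities"].unique() if "+" not in m]
    for outcome, grp in preds.groupby("outcome"):
        if len(mods) != 2:
            break
        a = grp[grp["modalities"] == mods[0]].set_index("subject_id")
        b = grp[grp["modalities"] == mods[1]].set_index("subject_id")
        shared = a.index.intersection(b.index)
        if len(shared) < 5:
            continue
        fam = grp["family"].iloc[0]
        if fam == "binary":
            ea = (a.loc[shared, "y_true"] != a.loc[shared, "y_pred"]).astype(float)
            eb = (b.loc[shared, "y_true"] != b.loc[shared, "y_pred"]).astype(float)
        else:
            ea = (a.loc[shared, "y_true"] - a.loc[shared, "y_pred"]).abs()
            eb = (b.loc[shared, "y_true"] - b.loc[shared, "y_pred"]).abs()
        p = compare_paired_errors(ea.to_numpy(), eb.to_numpy(),
                                  n_perm=cfg.comparison["n_perm"], seed=cfg.seed + 91)
        comparisons.append({"outcome": outcome, "modality_a": mods[0],
                            "modality_b": mods[1], "p_value": p})
    if comparisons:
        comp = pd.DataFrame(comparisons)
        comp["q_value"] = fdr_adjust(comp["p_value"].to_numpy())
        comp.to_csv(out / "modality_comparisons.csv", index=False)
    report.to_csv(out / "evaluation.csv", index=False)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "rank-scan": _stage_rank_scan,
    "fit": _stage_fit,
    "project": _stage_project,
    "predict": _stage_predict,
    "maps": _stage_maps,
    "evaluate": _stage_evaluate,
}


def run_study(config: StudyConfig, stages=ALL_STAGES) -> Path:
    """Run the requested stages in canonical order; returns the output dir."""
    bad = [s for s in stages if s not in ALL_STAGES]
    if bad:
        raise ArgumentError(f"unknown stages: {bad}")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    for stage in ALL_STAGES:
        if stage not in stages:
            continue
        started = time.time()
        _STAGE_FUNCS[stage](config, out)
        _log(out, stage, started, seed=config.seed)
    return out
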