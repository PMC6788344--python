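"""End-to-end orchestration with reproducible run directories.

A run directory holds one subdirectory per stage
(simulate, preprocess, train, evaluate, baseline, explain, aggregate,
adjust), a resolved copy of the configuration, and a manifest recording the
config hash, per-stage seeds and timings, and software versions.  Stages
are idempotent: a completed stage (marked by ``.done``) is skipped unless
forced.  Per-stage seeds derive from the master seed by fixed offsets.

The configuration defaults describe a desk-scale experiment: the phantom
cohort at a 16^3 grid, the default 1-before/1-after module topology at a
CPU-friendly width, and shortened early stopping.  Every value is
overridable from YAML.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from pathlib import Path
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from . import __version__
from .baselines import voxel_feature
from .confound import adjust as confound_adjust
from .confound import records_from_frame
from .errors import MissingArtifactError
from .evalstats import (
    CvScheme,
    ensemble_score,
    evaluate_scores,
    make_splits,
)
from .lrp import LRPConfig, RelevanceMap, relevance
from .nn import DeepSymNetConfig, DeepSymNetModel, InceptionSpec, TrainConfig, build, train
from .phantom import (
    PhantomConfig,
    SubjectRecord,
    ToyAtlas,
    generate_cohort,
    load_cohort_bids,
    write_cohort_bids,
)
from .preproc import PreprocessedPair, preprocess_pair
from .regions import accumulate, aggregate_by_region
from .volume import Volume

__all__ = ["RunConfig", "run_pipeline", "STAGES"]

STAGES = (
    "simulate",
    "preprocess",
    "train",
    "evaluate",
    "baseline",
    "explain",
    "aggregate",
    "adjust",
)

_SEED_OFFSETS = {name: 1000 + 100 * i for i, name in enumerate(STAGES)}


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PhantomSection(_Section):
    grid_shape: tuple[int, int, int] = (16, 16, 16)
    n_regions: int = 6
    class_atrophy_fraction: dict[str, float] = {
        "progressor": 0.4,
        "non-progressor": 0.0,
        "intermediate": 0.2,
    }
    target_regions: tuple[int, ...] = (3,)
    noise_sd: float = 0.05
    misalign_translation_mm: float = 2.0
    misalign_rotation_deg: float = 2.0
    n_per_class: dict[str, int] = {"progressor": 20, "non-progressor": 20}


class PreprocSection(_Section):
    fraction: float = 1.0
    register_sessions: bool = True
    threshold_fraction: float = 0.2


class NetworkSection(_Section):
    modules_before: int = 1
    modules_after: int = 1
    filters_per_branch: int = 16


class TrainSection(_Section):
    learning_rate: float = 1e-3
    batch_size: int = 4
    max_epochs: int = 20
    early_stop_patience: int = 5


class EvalSection(_Section):
    n_folds: int = 10
    ci_iters: int = 1000
    ci_frac: float = 0.8
    baseline_kinds: tuple[str, ...] = ("linear_svm", "random_forest")
    baseline_repeats: int = 10


class LRPSection(_Section):
    epsilon: float = 1e-9


class RunConfig(_Section):
    seed: int = 0
    phantom: PhantomSection = PhantomSection()
    preproc: PreprocSection = PreprocSection()
    network: NetworkSection = NetworkSection()
    training: TrainSection = TrainSection()
    evaluation: EvalSection = EvalSection()
    lrp: LRPSection = LRPSection()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})

    def resolved_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


# ---- manifest helpers -------------------------------------------------------


def _stage_dir(run_dir: Path, stage: str) -> Path:
    d = run_dir / stage
    d.mkdir(parents=True, exist_ok=True)
    return d


def _done(run_dir: Path, stage: str) -> bool:
    return (run_dir / stage / ".done").exists()


def _mark_done(run_dir: Path, stage: str) -> None:
    (run_dir / stage / ".done").write_text("ok\n")


def _require(path: Path, producing_stage: str) -> Path:
    if not path.exists():
        raise MissingArtifactError(
            f"missing artifact {path}; run the '{producing_stage}' stage first"
        )
    return path


def _update_manifest(run_dir: Path, config: RunConfig, stage: str, seconds: float) -> None:
    path = run_dir / "manifest.json"
    manifest = json.loads(path.read_text()) if path.exists() else {
        "config_hash": config.resolved_hash(),
        "master_seed": config.seed,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "longisym": __version__,
        "stages": {},
    }
    manifest["stages"][stage] = {
        "seed": config.seed + _SEED_OFFSETS[stage],
        "seconds": round(seconds, 3),
        "finished_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    path.write_text(json.dumps(manifest, indent=1))


def _phantom_config(cfg: RunConfig) -> PhantomConfig:
    p = cfg.phantom
    return PhantomConfig(
        grid_shape=p.grid_shape,
        n_regions=p.n_regions,
        class_atrophy_fraction=dict(p.class_atrophy_fraction),
        target_regions=p.target_regions,
        noise_sd=p.noise_sd,
        misalign_max=(p.misalign_translation_mm, p.misalign_rotation_deg),
        seed=cfg.seed + _SEED_OFFSETS["simulate"],
    )


# ---- stage implementations --------------------------------------------------


def stage_simulate(cfg: RunConfig, run_dir: Path) -> Path:
    out = _stage_dir(run_dir, "simulate")
    atlas, records = generate_cohort(_phantom_config(cfg), dict(cfg.phantom.n_per_class))
    write_cohort_bids(out / "cohort", atlas, records)
    return out


def preprocess_records(
    records: list[SubjectRecord], cfg: RunConfig
) -> list[PreprocessedPair]:
    """Preprocess every pair, then crop all subjects to one shared box.

    The crop box is the bounding box of the union of all subjects' brain
    masks, so every preprocessed grid is voxel-aligned with every other —
    a requirement for group-level relevance accumulation and for feeding
    one network.
    """
    from .preproc import crop_pair

    uncropped = [
        preprocess_pair(
            r.session1,
            r.session2,
            fraction=cfg.preproc.fraction,
            register=cfg.preproc.register_sessions,
            threshold_fraction=cfg.preproc.threshold_fraction,
            crop=False,
        )
        for r in records
    ]
    union = np.zeros(uncropped[0].brain_mask.shape, dtype=bool)
    for p in uncropped:
        union |= np.asarray(p.brain_mask.data, bool)
    union_vol = uncropped[0].brain_mask.like(union.astype(np.uint8))
    pairs = []
    for p in uncropped:
        cropped = crop_pair(
            p.session1, p.session2, union_vol, estimated_transform=p.estimated_transform
        )
        cropped.normalization_percentiles = p.normalization_percentiles
        pairs.append(cropped)
    return pairs


def stage_preprocess(cfg: RunConfig, run_dir: Path) -> Path:
    cohort_dir = _require(run_dir / "simulate" / "cohort", "simulate")
    out = _stage_dir(run_dir, "preprocess")
    atlas, records = load_cohort_bids(cohort_dir)
    pairs = preprocess_records(records, cfg)
    sidecars = {}
    arrays = {}
    for rec, pair in zip(records, pairs):
        arrays[f"{rec.subject_id}_s1"] = np.asarray(pair.session1.data, dtype=np.float32)
        arrays[f"{rec.subject_id}_s2"] = np.asarray(pair.session2.data, dtype=np.float32)
        sidecars[rec.subject_id] = {
            "estimated_transform": {
                "rotations_deg": list(pair.estimated_transform.rotations_deg),
                "translations_mm": list(pair.estimated_transform.translations_mm),
            },
            "crop_box": [list(b) for b in pair.crop_box],
            "normalization_percentiles": pair.normalization_percentiles,
            "class_label": rec.class_label,
        }
    np.savez_compressed(out / "pairs.npz", **arrays)
    (out / "sidecars.json").write_text(json.dumps(sidecars, indent=1))
    return out


def _load_preprocessed(run_dir: Path):
    pairs_path = _require(run_dir / "preprocess" / "pairs.npz", "preprocess")
    sidecars = json.loads((run_dir / "preprocess" / "sidecars.json").read_text())
    arrays = np.load(pairs_path)
    subjects = sorted(sidecars)
    data = {
        sid: (arrays[f"{sid}_s1"], arrays[f"{sid}_s2"], sidecars[sid]["class_label"])
        for sid in subjects
    }
    return data


_LABEL_CODE = {"non-progressor": 0, "progressor": 1}


def stage_train(cfg: RunConfig, run_dir: Path) -> Path:
    """Single stratified 10-fold (80/10/10) training of the network."""
    data = _load_preprocessed(run_dir)
    out = _stage_dir(run_dir, "train")
    binary = [(sid, v) for sid, v in data.items() if v[2] in _LABEL_CODE]
    ids = [sid for sid, _ in binary]
    dataset = [(v[0], v[1], _LABEL_CODE[v[2]]) for _, v in binary]
    y = np.array([d[2] for d in dataset])
    input_shape = dataset[0][0].shape
    scheme = CvScheme(
        kind="single_10fold_with_val",
        n_folds=cfg.evaluation.n_folds,
        seed=cfg.seed + _SEED_OFFSETS["train"],
    )
    net_cfg = DeepSymNetConfig(
        input_shape=tuple(input_shape),
        modules_before=cfg.network.modules_before,
        modules_after=cfg.network.modules_after,
        inception=InceptionSpec(filters_per_branch=cfg.network.filters_per_branch),
        resolution_fraction=cfg.preproc.fraction,
    )
    tc_base = cfg.training
    rows = []
    for fold, (tr, va, te) in enumerate(make_splits(y, scheme)):
        model = build(net_cfg, seed=cfg.seed + _SEED_OFFSETS["train"] + fold)
        tc = TrainConfig(
            learning_rate=tc_base.learning_rate,
            batch_size=tc_base.batch_size,
            max_epochs=tc_base.max_epochs,
            early_stop_patience=tc_base.early_stop_patience,
            seed=cfg.seed + _SEED_OFFSETS["train"] + fold,
        )
        train(model, dataset, tr, va, tc)
        model.save(out / f"fold-{fold}.model.zip")
        pd.DataFrame(model.training_history).to_csv(
            out / f"fold-{fold}.history.tsv", sep="\t", index=False
        )
        x1 = np.stack([dataset[i][0] for i in te])
        x2 = np.stack([dataset[i][1] for i in te])
        probs = model.predict_proba(x1, x2)
        for i, p in zip(te, probs):
            rows.append(
                {"subject_id": ids[i], "fold": fold, "label": int(y[i]), "probability": float(p)}
            )
    pd.DataFrame(rows).to_csv(out / "test_scores.tsv", sep="\t", index=False)
    return out


def stage_evaluate(cfg: RunConfig, run_dir: Path) -> Path:
    scores_path = _require(run_dir / "train" / "test_scores.tsv", "train")
    out = _stage_dir(run_dir, "evaluate")
    scores = pd.read_csv(scores_path, sep="\t", dtype={"subject_id": str})
    report = evaluate_scores(
        scores["probability"],
        scores["label"],
        ci_iters=cfg.evaluation.ci_iters,
        ci_frac=cfg.evaluation.ci_frac,
        seed=cfg.seed + _SEED_OFFSETS["evaluate"],
    )
    (out / "metrics.json").write_text(json.dumps(report.to_dict(), indent=1))

    # Intermediate-class generalizability: 10 fold-models averaged per subject.
    data = _load_preprocessed(run_dir)
    intermediate = {s: v for s, v in data.items() if v[2] == "intermediate"}
    if intermediate:
        models = [
            DeepSymNetModel.load(run_dir / "train" / f"fold-{k}.model.zip")
            for k in range(cfg.evaluation.n_folds)
        ]
        sids = sorted(intermediate)
        scoreset = ensemble_score(
            models,
            [(intermediate[s][0], intermediate[s][1]) for s in sids],
            subject_ids=sids,
            expected_models=cfg.evaluation.n_folds,
        )
        pd.DataFrame(
            {"subject_id": scoreset.subject_ids, "probability": scoreset.probabilities}
        ).to_csv(out / "intermediate_scores.tsv", sep="\t", index=False)
    return out


def stage_baseline(cfg: RunConfig, run_dir: Path) -> Path:
    data = _load_preprocessed(run_dir)
    out = _stage_dir(run_dir, "baseline")
    binary = [(sid, v) for sid, v in data.items() if v[2] in _LABEL_CODE]
    ids = [sid for sid, _ in binary]
    X = np.stack([voxel_feature((v[0], v[1])) for _, v in binary])
    y = np.array([_LABEL_CODE[v[2]] for _, v in binary])
    scheme = CvScheme(
        kind="repeated_10fold",
        n_folds=cfg.evaluation.n_folds,
        n_repeats=cfg.evaluation.baseline_repeats,
        seed=cfg.seed + _SEED_OFFSETS["baseline"],
    )
    results = {}
    from .evalstats import cross_validate_features

    for kind in cfg.evaluation.baseline_kinds:
        scoreset = cross_validate_features(X, y, kind, scheme, scale_iqr=False, subject_ids=ids)
        report = evaluate_scores(
            scoreset.probabilities,
            scoreset.labels,
            ci_iters=cfg.evaluation.ci_iters,
            ci_frac=cfg.evaluation.ci_frac,
            seed=cfg.seed + _SEED_OFFSETS["baseline"],
        )
        results[kind] = report.to_dict()
        pd.DataFrame(
            {
                "subject_id": scoreset.subject_ids,
                "label": scoreset.labels,
                "probability": scoreset.probabilities,
            }
        ).to_csv(out / f"{kind}_scores.tsv", sep="\t", index=False)
    (out / "metrics.json").write_text(json.dumps(results, indent=1))
    return out


def stage_explain(cfg: RunConfig, run_dir: Path) -> Path:
    """Relevance maps for every binary-class subject, from its own test-fold model."""
    scores_path = _require(run_dir / "train" / "test_scores.tsv", "train")
    data = _load_preprocessed(run_dir)
    out = _stage_dir(run_dir, "explain")
    scores = pd.read_csv(scores_path, sep="\t", dtype={"subject_id": str})
    models: dict[int, DeepSymNetModel] = {}
    lrp_cfg = LRPConfig(epsilon=cfg.lrp.epsilon)
    arrays = {}
    for _, row in scores.iterrows():
        sid, fold = str(row["subject_id"]), int(row["fold"])
        if fold not in models:
            models[fold] = DeepSymNetModel.load(run_dir / "train" / f"fold-{fold}.model.zip")
        x1, x2, _ = data[sid]
        rmap = relevance(models[fold], (x1, x2), lrp_cfg, subject_id=sid)
        arrays[f"{sid}_s1"] = rmap.session1_relevance.astype(np.float32)
        arrays[f"{sid}_s2"] = rmap.session2_relevance.astype(np.float32)
        for ses in (1, 2):
            Volume(arrays[f"{sid}_s{ses}"]).save(out / f"sub-{sid}_ses-{ses}_relevance.nii.gz")
    np.savez_compressed(out / "relevance.npz", **arrays)
    return out


def stage_aggregate(cfg: RunConfig, run_dir: Path) -> Path:
    rel_path = _require(run_dir / "explain" / "relevance.npz", "explain")
    cohort_dir = _require(run_dir / "simulate" / "cohort", "simulate")
    out = _stage_dir(run_dir, "aggregate")
    arrays = np.load(rel_path)
    sids = sorted({k[:-3] for k in arrays.files})
    maps = [
        RelevanceMap(
            subject_id=sid,
            session1_relevance=np.asarray(arrays[f"{sid}_s1"], dtype=np.float64),
            session2_relevance=np.asarray(arrays[f"{sid}_s2"], dtype=np.float64),
            target_score=np.nan,
        )
        for sid in sids
    ]
    group = accumulate(maps)
    atlas, _ = load_cohort_bids(cohort_dir)
    labels = _crop_labels_to(atlas, group.M_N.shape, run_dir)
    table = aggregate_by_region(
        group, labels, region_names=atlas.region_names, region_groups=atlas.region_groups
    )
    table.to_tsv(out / "region_relevance.tsv")
    Volume(group.M_N.astype(np.float32)).save(out / "M_N.nii.gz")
    return out


def _crop_labels_to(atlas: ToyAtlas, shape: tuple[int, ...], run_dir: Path) -> np.ndarray:
    """Apply the preprocessing crop box to the atlas labels (nearest labels)."""
    sidecars = json.loads((run_dir / "preprocess" / "sidecars.json").read_text())
    first = sidecars[sorted(sidecars)[0]]
    box = first["crop_box"]
    sl = tuple(slice(a, b) for a, b in box)
    labels = np.asarray(atlas.labels.data)[sl]
    pad = [(0, t - s) for t, s in zip(shape, labels.shape)]
    return np.pad(labels, pad)


def stage_adjust(cfg: RunConfig, run_dir: Path) -> Path:
    scores_path = _require(run_dir / "train" / "test_scores.tsv", "train")
    cohort_dir = _require(run_dir / "simulate" / "cohort", "simulate")
    out = _stage_dir(run_dir, "adjust")
    scores = pd.read_csv(scores_path, sep="\t", dtype={"subject_id": str})
    participants = pd.read_csv(
        cohort_dir / "participants.tsv", sep="\t", dtype={"subject_id": str}
    )
    merged = scores.merge(participants, on="subject_id")
    frame = pd.DataFrame(
        {
            "Y": merged["label"],
            "X1": merged["time_between_sessions_years"],
            "X2": merged["gender"],
            "X3": merged["age"],
            "X4": merged["probability"],
        }
    )
    result = confound_adjust(records_from_frame(frame))
    result.to_frame().to_csv(out / "adjustment.tsv", sep="\t", index=False)
    (out / "adjustment.json").write_text(
        json.dumps(
            {
                name: {
                    "estimate": c.estimate,
                    "ci_low": c.ci_low,
                    "ci_high": c.ci_high,
                    "p_value": c.p_value,
                }
                for name, c in result.coefficients.items()
            },
            indent=1,
        )
    )
    return out


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "train": stage_train,
    "evaluate": stage_evaluate,
    "baseline": stage_baseline,
    "explain": stage_explain,
    "aggregate": stage_aggregate,
    "adjust": stage_adjust,
}


def run_pipeline(
    config: RunConfig,
    run_dir: str | Path,
    stages: tuple[str, ...] = STAGES,
    force: bool = False,
) -> Path:
    """Execute the requested stages in order inside ``run_dir``.

    Completed stages are skipped unless ``force``; every invocation writes
    the resolved configuration and updates the manifest.
    """
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    (run_dir / "config.yaml").write_text(yaml.safe_dump(config.model_dump()))
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}; choose from {STAGES}")
    for stage in STAGES:  # canonical order regardless of request order
        if stage not in stages:
            continue
        if _done(run_dir, stage) and not force:
            continue
        t0 = time.perf_counter()
        _STAGE_FUNCS[stage](config, run_dir)
        _update_manifest(run_dir, config, stage, time.perf_counter() - t0)
        _mark_done(run_dir, stage)
    return run_dir
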