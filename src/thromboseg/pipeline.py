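"""Reproducible generate -> attention -> train -> predict -> evaluate workflow.

Each stage is a plain function over a :class:`RunConfig`; the CLI is a
thin wrapper.  All randomness flows from ``RunConfig.seed`` through
counter-based derived seeds, so two identical runs produce identical
outputs.  Layout under ``out_dir``:

    cohort/<study_id>/          NIfTI volumes + per-study metadata
    cohort/manifest.json        ids, per-study seeds, phantom params
    attention/fold_<k>/         cached attention maps (.npz per study)
    checkpoints/fold_<k>_*.npz  backbone and head parameters
    traces/fold_<k>.json        per-step training losses
    evaluation/metrics.csv      slice/study/fold/overall rows
    evaluation/summary.json     aggregated five-metric report
"""

from __future__ import annotations

import csv
import json
import logging
import shutil
import tempfile
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .augment import AugmentationSpec, augment_pair_sequence, build_sequences
from .backbone import (
    AttentionMap,
    DetectorConfig,
    LightweightBackbone,
    SingleInstanceDetector,
    extract_attention_map,
    train_backbone,
)
from .checkpoint import load_model, save_model
from .core_data import PatientStudy, filter_slices_with_roi, load_study, write_study
from .head import BiCLSTMHead, HeadConfig, predict, train_head
from .metrics import MetricsReport, aggregate, compute_metrics, make_cv_folds
from .phantom import PhantomParams, generate_cohort
from .training import TrainConfig

__all__ = [
    "RunConfig",
    "run_generate",
    "run_attention",
    "run_train",
    "run_predict",
    "run_evaluate",
    "run_report",
    "load_cohort",
]

log = logging.getLogger("thromboseg")


def derive_seed(base: int, *path: int) -> int:
    """Counter-based seed derivation (stable across stage order)."""
    return int(np.random.SeedSequence([base, *path]).generate_state(1)[0] % 2**31)


@dataclass
class RunConfig:
    """All stage parameters of one reproducible run."""

    out_dir: str = "runs/default"
    seed: int = 0
    n_studies: int = 4
    n_slices_range: tuple[int, int] | None = None
    phantom: PhantomParams = field(default_factory=PhantomParams)
    provider: str = "lightweight"  # or "detector"
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    head: HeadConfig = field(default_factory=HeadConfig)
    augmentation: AugmentationSpec = field(default_factory=AugmentationSpec)
    sequence_length: int = 5
    boundary: str = "replicate"
    k_folds: int = 4
    backbone_train: TrainConfig = field(default_factory=lambda: TrainConfig(lr=0.0001))
    head_train: TrainConfig = field(default_factory=lambda: TrainConfig(lr=0.005))
    version: str = "1"

    # -- (de)serialization --------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["detector"] = self.detector.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "phantom" in d and not isinstance(d["phantom"], PhantomParams):
            p = dict(d["phantom"])
            if "intensity_levels" in p and isinstance(p["intensity_levels"], dict):
                from .phantom import IntensityLevels

                p["intensity_levels"] = IntensityLevels(**p["intensity_levels"])
            for key in ("lumen_radius_range", "thrombus_thickness_range"):
                if key in p:
                    p[key] = tuple(p[key])
            d["phantom"] = PhantomParams(**p)
        if "detector" in d and not isinstance(d["detector"], DetectorConfig):
            d["detector"] = DetectorConfig.from_dict(d["detector"])
        if "head" in d and not isinstance(d["head"], HeadConfig):
            d["head"] = HeadConfig(**d["head"])
        if "augmentation" in d and not isinstance(d["augmentation"], AugmentationSpec):
            d["augmentation"] = AugmentationSpec(**d["augmentation"])
        for key in ("backbone_train", "head_train"):
            if key in d and not isinstance(d[key], TrainConfig):
                d[key] = TrainConfig(**d[key])
        if d.get("n_slices_range") is not None:
            d["n_slices_range"] = tuple(d["n_slices_range"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @property
    def out(self) -> Path:
        return Path(self.out_dir)


# ---------------------------------------------------------------------------
# generate
# ---------------------------------------------------------------------------

def run_generate(cfg: RunConfig) -> Path:
    """Write the phantom cohort; atomic (no partial cohort on error)."""
    cfg.phantom.validate()
    cohort = generate_cohort(
        cfg.n_studies, cfg.phantom, seed=derive_seed(cfg.seed, 0), n_slices_range=cfg.n_slices_range
    )
    cohort_dir = cfg.out / "cohort"
    tmp = Path(tempfile.mkdtemp(prefix="cohort-", dir=cfg.out if cfg.out.exists() else None))
    try:
        for study in cohort:
            write_study(study, tmp / study.study_id, format="nifti")
        manifest = {
            "study_ids": [s.study_id for s in cohort],
            "n_studies": cfg.n_studies,
            "seed": cfg.seed,
            "phantom": asdict(cfg.phantom),
        }
        (tmp / "manifest.json").write_text(json.dumps(manifest, indent=1))
    except Exception:
        shutil.rmtree(tmp, ignore_errors=True)
        raise
    if cohort_dir.exists():
        shutil.rmtree(cohort_dir)
    cohort_dir.parent.mkdir(parents=True, exist_ok=True)
    shutil.move(str(tmp), str(cohort_dir))
    log.info("generate: wrote %d studies to %s", len(cohort), cohort_dir)
    return cohort_dir


def load_cohort(cohort_dir: str | Path) -> list[PatientStudy]:
    cohort_dir = Path(cohort_dir)
    manifest = cohort_dir / "manifest.json"
    if not manifest.exists():
        raise FileNotFoundError(f"no cohort manifest at {manifest}")
    ids = json.loads(manifest.read_text())["study_ids"]
    return [load_study(cohort_dir / sid, format="nifti") for sid in ids]


# ---------------------------------------------------------------------------
# attention
# ---------------------------------------------------------------------------

def _new_provider(cfg: RunConfig, seed: int):
    if cfg.provider == "detector":
        return SingleInstanceDetector(cfg.detector, rng=np.random.default_rng(seed))
    if cfg.provider == "lightweight":
        return LightweightBackbone(rng=np.random.default_rng(seed))
    raise ValueError(f"unknown provider {cfg.provider!r}")


def _cache_maps(provider, studies, cache_dir: Path) -> dict[str, list[AttentionMap]]:
    """Compute or load cached per-study attention maps."""
    cache_dir.mkdir(parents=True, exist_ok=True)
    out: dict[str, list[AttentionMap]] = {}
    for study in studies:
        f = cache_dir / f"{study.study_id}.npz"
        if f.exists():
            log.info("attention: cache hit for %s", study.study_id)
            with np.load(f) as z:
                arrays = [z[f"map_{i:04d}"] for i in range(study.n_slices)]
            out[study.study_id] = [AttentionMap(a, provider_tag=provider.kind) for a in arrays]
            continue
        maps = [extract_attention_map(s, provider) for s in study.slices]
        np.savez(f, **{f"map_{i:04d}": m.values for i, m in enumerate(maps)})
        out[study.study_id] = maps
    return out


def run_attention(cfg: RunConfig) -> Path:
    """Train one provider on the whole cohort and cache all maps."""
    studies = [filter_slices_with_roi(s) for s in load_cohort(cfg.out / "cohort")]
    provider = _new_provider(cfg, derive_seed(cfg.seed, 1))
    provider, _ = train_backbone(provider, studies, cfg.backbone_train)
    save_model(provider, cfg.out / "checkpoints" / "full_backbone.npz")
    _cache_maps(provider, studies, cfg.out / "attention" / "full")
    return cfg.out / "attention" / "full"


# ---------------------------------------------------------------------------
# train (per-fold, patient-wise CV)
# ---------------------------------------------------------------------------

def _sequences_for(study, maps, cfg: RunConfig):
    seqs = build_sequences(study, maps, N=cfg.sequence_length, boundary=cfg.boundary)
    return [(seq, gt) for seq, gt in zip(seqs, study.gt_masks)]


def run_train(cfg: RunConfig) -> list[Path]:
    """Per fold: train backbone, cache maps, train head, checkpoint."""
    cohort_dir = cfg.out / "cohort"
    if not cohort_dir.exists():
        raise FileNotFoundError(f"missing cohort at {cohort_dir}; run generate first")
    studies = {s.study_id: filter_slices_with_roi(s) for s in load_cohort(cohort_dir)}
    folds = make_cv_folds(sorted(studies), k=cfg.k_folds, seed=derive_seed(cfg.seed, 2))
    (cfg.out / "folds.json").write_text(
        json.dumps([asdict(f) for f in folds], indent=1)
    )
    checkpoints = []
    for fold in folds:
        log.info("train: fold %d (%d train / %d test studies)", fold.fold_id, len(fold.train_ids), len(fold.test_ids))
        train_studies = [studies[sid] for sid in fold.train_ids]
        provider = _new_provider(cfg, derive_seed(cfg.seed, 3, fold.fold_id))
        backbone_cfg = replace(
            cfg.backbone_train, seed=derive_seed(cfg.seed, 4, fold.fold_id)
        )
        provider, backbone_trace = train_backbone(provider, train_studies, backbone_cfg)
        maps = _cache_maps(
            provider, studies.values(), cfg.out / "attention" / f"fold_{fold.fold_id}"
        )
        samples = []
        for s in train_studies:
            samples.extend(_sequences_for(s, maps[s.study_id], cfg))
        head = BiCLSTMHead(
            cfg.head, rng=np.random.default_rng(derive_seed(cfg.seed, 5, fold.fold_id))
        )
        head_cfg = replace(cfg.head_train, seed=derive_seed(cfg.seed, 6, fold.fold_id))
        augment = None
        if cfg.augmentation.enabled:
            spec = cfg.augmentation

            def augment(seq, gt, rng, _spec=spec):
                return augment_pair_sequence(seq, gt, _spec, rng)

        head, head_trace = train_head(head, samples, head_cfg, augment=augment)
        bpath = save_model(provider, cfg.out / "checkpoints" / f"fold_{fold.fold_id}_backbone.npz")
        hpath = save_model(head, cfg.out / "checkpoints" / f"fold_{fold.fold_id}_head.npz")
        traces = cfg.out / "traces"
        traces.mkdir(parents=True, exist_ok=True)
        (traces / f"fold_{fold.fold_id}.json").write_text(
            json.dumps({"backbone": backbone_trace, "head": head_trace})
        )
        checkpoints.extend([bpath, hpath])
    return checkpoints


# ---------------------------------------------------------------------------
# predict / evaluate / report
# ---------------------------------------------------------------------------

def run_predict(cfg: RunConfig, study_id: str, fold_id: int = 0) -> Path:
    """Segment one study with a fold's models; write a NIfTI mask volume."""
    import nibabel as nib

    head = load_model(cfg.out / "checkpoints" / f"fold_{fold_id}_head.npz")
    provider = load_model(cfg.out / "checkpoints" / f"fold_{fold_id}_backbone.npz")
    study = filter_slices_with_roi(load_study(cfg.out / "cohort" / study_id))
    maps = _cache_maps(provider, [study], cfg.out / "attention" / f"fold_{fold_id}")
    masks = []
    for seq, _ in _sequences_for(study, maps[study.study_id], cfg):
        _, mask = predict(head, seq)
        masks.append(mask)
    out_dir = cfg.out / "predictions"
    out_dir.mkdir(parents=True, exist_ok=True)
    vol = np.stack(masks, axis=-1).astype(np.uint8)
    path = out_dir / f"{study_id}_fold{fold_id}_pred.nii"
    nib.save(nib.Nifti1Image(vol, np.eye(4)), str(path))
    return path


def run_evaluate(cfg: RunConfig, gt_self_check: bool = False) -> Path:
    """Evaluate every study in the fold where it is a test item.

    ``gt_self_check`` scores the ground truth against itself (a protocol
    sanity mode: all overlaps 1, all errors 0).
    """
    folds_file = cfg.out / "folds.json"
    if not folds_file.exists():
        raise FileNotFoundError("no folds.json; run train first")
    folds = json.loads(folds_file.read_text())
    studies = {
        s.study_id: filter_slices_with_roi(s) for s in load_cohort(cfg.out / "cohort")
    }
    rows: list[dict] = []
    fold_reports: list[MetricsReport] = []
    for fold in folds:
        fid = fold["fold_id"]
        if not gt_self_check:
            head = load_model(cfg.out / "checkpoints" / f"fold_{fid}_head.npz")
            provider = load_model(cfg.out / "checkpoints" / f"fold_{fid}_backbone.npz")
        study_reports = []
        for sid in fold["test_ids"]:
            study = studies[sid]
            if gt_self_check:
                preds = list(study.gt_masks)
            else:
                maps = _cache_maps(provider, [study], cfg.out / "attention" / f"fold_{fid}")
                preds = [
                    predict(head, seq)[1]
                    for seq, _ in _sequences_for(study, maps[sid], cfg)
                ]
            slice_reports = []
            for pos, (pred, gt) in enumerate(zip(preds, study.gt_masks)):
                r = compute_metrics(pred, gt)
                slice_reports.append(r)
                rows.append(
                    dict(level="slice", fold=fid, study_id=sid,
                         slice_index=study.slice_indices[pos], n_items=1, **r.as_dict())
                )
            sr = aggregate(slice_reports, "study")
            study_reports.append(sr)
            rows.append(
                dict(level="study", fold=fid, study_id=sid, slice_index="", n_items=sr.n_items, **sr.as_dict())
            )
        fr = aggregate(study_reports, "fold")
        fold_reports.append(fr)
        rows.append(dict(level="fold", fold=fid, study_id="", slice_index="", n_items=fr.n_items, **fr.as_dict()))
    overall = aggregate(fold_reports, "overall")
    rows.append(dict(level="overall", fold="", study_id="", slice_index="", n_items=overall.n_items, **overall.as_dict()))

    eval_dir = cfg.out / "evaluation"
    eval_dir.mkdir(parents=True, exist_ok=True)
    csv_path = eval_dir / "metrics.csv"
    fieldnames = ["level", "fold", "study_id", "slice_index", "n_items", "TO", "Dice", "Jaccard", "FN", "FP"]
    with csv_path.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames)
        writer.writeheader()
        writer.writerows(rows)
    summary = {
        "overall": overall.as_dict(),
        "folds": [r.as_dict() for r in fold_reports],
        "n_studies": len(studies),
        "sequence_length": cfg.sequence_length,
        "provider": cfg.provider,
    }
    (eval_dir / "summary.json").write_text(json.dumps(summary, indent=1))
    log.info("evaluate: overall %s", {k: round(v, 4) for k, v in overall.as_dict().items()})
    return eval_dir


def run_report(cfg: RunConfig) -> str:
    """Human-readable five-metric table from the evaluation summary."""
    summary = json.loads((cfg.out / "evaluation" / "summary.json").read_text())
    lines = ["level    TO      Dice    Jaccard FN      FP"]
    for i, fold in enumerate(summary["folds"]):
        lines.append(
            f"fold {i}  " + " ".join(f"{fold[m]:.4f}" for m in ("TO", "Dice", "Jaccard", "FN", "FP"))
        )
    o = summary["overall"]
    lines.append("overall " + " ".join(f"{o[m]:.4f}" for m in ("TO", "Dice", "Jaccard", "FN", "FP")))
    return "\n".join(lines)
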