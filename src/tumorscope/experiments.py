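"""Experiment orchestration: stratified partitioning, the lambda sweep,
ablations and end-to-end pipeline runs.

Every number written to an output CSV is recomputable from saved artifacts
with the metrics module alone, and identical configuration plus seeds yield
bit-identical CSVs.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import metrics
from .datatypes import PhantomCase, PhantomConfig
from .detection import DetTrainConfig, TumorDetectionModel, _box_iou
from .phantom import generate_phantom_dataset
from .reconstruction import (ReconTrainConfig, TumorReconstructionModel,
                             VolumeGANSpec, tumor_sample_from_case)
from .segmentation import (LungSegmentationModel, RewardConfig, SegTrainConfig)

__all__ = [
    "Partition", "ExperimentConfig", "stratified_partition", "lambda_sweep",
    "run_pipeline", "paired_t", "PIPELINE_COLUMNS",
]

PIPELINE_COLUMNS = ["case_id", "seg_iou", "seg_hd", "det_iou", "det_hd",
                    "rec_hd", "rec_ed"]

SCHEMA_VERSION = 1


@dataclass
class Partition:
    """Disjoint folds of case ids whose union is the full case set."""

    folds: list[list[str]]
    strata: dict[str, str]

    def __post_init__(self):
        flat = [cid for fold in self.folds for cid in fold]
        if len(flat) != len(set(flat)):
            raise ValueError("folds overlap")

    def fold_of(self, case_id: str) -> int:
        for i, fold in enumerate(self.folds):
            if case_id in fold:
                return i
        raise KeyError(case_id)


def _stratum_key(case: PhantomCase, tercile_edges: np.ndarray) -> str:
    frac = float(np.mean([m.lung_fraction() for m in case.masks]))
    tercile = int(np.searchsorted(tercile_edges, frac, side="right"))
    return f"{'nodule' if case.has_nodule() else 'clear'}-t{tercile}"


def stratified_partition(cases: list[PhantomCase], n_folds: int,
                         seed: int = 0) -> Partition:
    """Deal cases into near-equal folds balanced over strata.

    The stratification key combines nodule presence with the lung-fraction
    tercile.  A single global dealing cursor keeps both per-stratum and
    overall fold sizes within one of each other.  Strata smaller than
    ``n_folds`` are flagged with a warning and assigned best-effort.
    """
    if n_folds < 2:
        raise ValueError("need at least two folds")
    if n_folds > len(cases):
        raise ValueError("more folds than cases")
    rng = np.random.default_rng(seed)
    fracs = [float(np.mean([m.lung_fraction() for m in c.masks]))
             for c in cases]
    edges = np.quantile(fracs, [1 / 3, 2 / 3])

    strata: dict[str, str] = {}
    groups: dict[str, list[str]] = {}
    for case in cases:
        key = _stratum_key(case, edges)
        strata[case.case_id] = key
        groups.setdefault(key, []).append(case.case_id)

    folds: list[list[str]] = [[] for _ in range(n_folds)]
    cursor = 0
    for key in sorted(groups):
        ids = sorted(groups[key])
        if len(ids) < n_folds:
            warnings.warn(
                f"stratum {key!r} has {len(ids)} case(s) < {n_folds} folds; "
                "assigning best-effort", stacklevel=2)
        rng.shuffle(ids)
        for cid in ids:
            folds[cursor % n_folds].append(cid)
            cursor += 1
    return Partition(folds=folds, strata=strata)


@dataclass
class ExperimentConfig:
    """Aggregate configuration for end-to-end runs (YAML-serialisable)."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    segmentation: SegTrainConfig = field(default_factory=SegTrainConfig)
    reward: RewardConfig = field(default_factory=RewardConfig)
    detection: DetTrainConfig = field(default_factory=DetTrainConfig)
    recon_spec: VolumeGANSpec = field(default_factory=VolumeGANSpec)
    recon_train: ReconTrainConfig = field(default_factory=ReconTrainConfig)
    n_cases: int = 10
    n_folds: int = 5
    seed: int = 0
    schema_version: int = SCHEMA_VERSION

    def to_yaml(self, path: str | Path) -> None:
        blob = {k: _plain(v) for k, v in asdict(self).items()}
        with open(path, "w") as fh:
            yaml.safe_dump(blob, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            blob = yaml.safe_load(fh) or {}
        version = blob.pop("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ValueError(f"unsupported config schema version {version}")
        kwargs = {}
        sections = {
            "phantom": PhantomConfig, "segmentation": SegTrainConfig,
            "reward": RewardConfig, "detection": DetTrainConfig,
            "recon_spec": VolumeGANSpec, "recon_train": ReconTrainConfig,
        }
        for key, typ in sections.items():
            if key in blob:
                section = blob.pop(key)
                section = {k: _tupleize(typ, k, v) for k, v in section.items()}
                kwargs[key] = typ(**section)
        kwargs.update(blob)
        return cls(**kwargs)


def _plain(v):
    if isinstance(v, dict):
        return {k: _plain(x) for k, x in v.items()}
    if isinstance(v, tuple):
        return list(v)
    return v


def _tupleize(typ, key, value):
    default = getattr(typ(), key, None) if key != "seed" else 0
    if isinstance(default, tuple) and isinstance(value, list):
        return tuple(value)
    return value


# --------------------------------------------------------------------------
# lambda sweep
# --------------------------------------------------------------------------

def lambda_sweep(cases: list[PhantomCase], lambdas, cfg: SegTrainConfig,
                 out_dir: str | Path | None = None) -> pd.DataFrame:
    """Train/evaluate the segmentation stage once per reward-shaping value.

    The sweep covers the open interval only: lam = 0 or 1 would erase the
    minority/majority asymmetry the reward table requires, so endpoints are
    excluded by construction.
    """
    rows = []
    for lam in lambdas:
        reward = RewardConfig(lam=float(lam))  # validates 0 < lam < 1
        res = LungSegmentationModel(cases, cfg, reward).fit(use_rl=True)
        last = res.history.iloc[-1]
        rows.append({"lam": float(lam), "mean_iou": float(last["val_iou"]),
                     "mean_hd": float(last["val_hd"])})
    table = pd.DataFrame(rows, columns=["lam", "mean_iou", "mean_hd"])
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "lambda_sweep.csv", index=False)
        _plot_sweep(table, out_dir / "lambda_sweep.png")
    return table


def _plot_sweep(table: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax1 = plt.subplots(figsize=(5, 3.2))
    ax1.plot(table["lam"], table["mean_iou"], "o-", label="IoU")
    ax1.set_xlabel("majority-reward scale lam")
    ax1.set_ylabel("validation IoU")
    ax2 = ax1.twinx()
    ax2.plot(table["lam"], table["mean_hd"], "s--", color="tab:red",
             label="HD")
    ax2.set_ylabel("validation HD")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# --------------------------------------------------------------------------
# end-to-end pipeline
# --------------------------------------------------------------------------

def run_pipeline(cases: list[PhantomCase], cfg: ExperimentConfig,
                 out_dir: str | Path | None = None) -> pd.DataFrame:
    """Train all three stages and score every case end to end.

    Per case: segmentation IoU/HD against the reference lung masks,
    detection box IoU/HD against the annotated boxes, and reconstruction
    HD/ED against the ground-truth tumor volume.  A failed stage marks the
    case's remaining columns NaN and the run continues.
    """
    if not cases:
        return pd.DataFrame(columns=PIPELINE_COLUMNS)

    seg_res = LungSegmentationModel(cases, cfg.segmentation, cfg.reward).fit()
    det_res = TumorDetectionModel(cases, cfg.detection).fit()
    rec_res = TumorReconstructionModel(cases, cfg.recon_spec,
                                       cfg.recon_train).fit()

    vol_dir = None
    if out_dir is not None:
        vol_dir = Path(out_dir) / "volumes"
        vol_dir.mkdir(parents=True, exist_ok=True)

    diag2 = float(np.hypot(*cases[0].slices[0].pixels.shape))
    rows = []
    for case in cases:
        row = {c: np.nan for c in PIPELINE_COLUMNS}
        row["case_id"] = case.case_id
        try:
            ious, hds = [], []
            for img, mask in zip(case.slices, case.masks):
                pred = seg_res.segment(img)
                ious.append(metrics.iou(pred, mask))
                if pred.labels.any() and mask.labels.any():
                    hds.append(metrics.hausdorff(np.argwhere(pred.labels),
                                                 np.argwhere(mask.labels)))
                else:
                    hds.append(diag2)
            row["seg_iou"] = float(np.mean(ious))
            row["seg_hd"] = float(np.mean(hds))

            det_ious, det_hds = [], []
            boxes_by_slice: dict[int, list] = {}
            for ann in case.annotations:
                boxes_by_slice.setdefault(ann.slice_index, []).append(ann.box)
            lung_slices = TumorDetectionModel.lung_masked_slices(case)
            for img in lung_slices:
                gt = boxes_by_slice.get(img.slice_index)
                if not gt:
                    continue
                preds = det_res.detect(img)
                if not preds:
                    det_ious.append(0.0)
                    det_hds.append(diag2)
                    continue
                best = max(preds, key=lambda p: max(
                    _box_iou(p.box, g) for g in gt))
                gbest = max(gt, key=lambda g: _box_iou(best.box, g))
                det_ious.append(_box_iou(best.box, gbest))
                det_hds.append(metrics.hausdorff(_corners(best.box),
                                                 _corners(gbest)))
            if det_ious:
                row["det_iou"] = float(np.mean(det_ious))
                row["det_hd"] = float(np.mean(det_hds))

            sample = tumor_sample_from_case(case)
            pred_vol = rec_res.reconstruct(sample.slices)
            if vol_dir is not None:
                from .io import write_volume
                write_volume(vol_dir / f"{case.case_id}.nii.gz", pred_vol)
            try:
                m = metrics.surface_metrics(pred_vol, sample.volume,
                                            cfg.recon_train.threshold)
                row["rec_hd"], row["rec_ed"] = m["hd"], m["ed"]
            except ValueError:
                diag3 = float(np.linalg.norm(
                    np.asarray(sample.volume.shape, dtype=float)))
                row["rec_hd"] = row["rec_ed"] = diag3
        except Exception as exc:  # a stage failure must not kill the run
            warnings.warn(f"case {case.case_id} failed: {exc}", stacklevel=2)
        rows.append(row)

    table = pd.DataFrame(rows, columns=PIPELINE_COLUMNS)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "pipeline_results.csv", index=False)
    return table


def _corners(box) -> np.ndarray:
    x0, y0, x1, y1 = box
    return np.array([[y0, x0], [y0, x1], [y1, x0], [y1, x1]], dtype=float)


def run_all(cfg: ExperimentConfig, out_dir: str | Path) -> pd.DataFrame:
    """Generate phantoms from config, run the pipeline, save the CSV."""
    cases = generate_phantom_dataset(cfg.phantom, cfg.n_cases, seed=cfg.seed)
    return run_pipeline(cases, cfg, out_dir=out_dir)


# --------------------------------------------------------------------------
# statistics
# --------------------------------------------------------------------------

def paired_t(values_a, values_b) -> tuple[float, float]:
    """Classical paired t-test with n-1 degrees of freedom."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-D sequences")
    if a.size < 2:
        raise ValueError("need at least two pairs")
    diffs = a - b
    if np.allclose(diffs.var(ddof=1), 0.0):
        raise ValueError("zero variance of differences: t is undefined")
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)
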