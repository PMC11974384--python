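"""Segmentation metrics, misprediction flagging, and the transfer experiment.

Evaluation is voxelwise over the *stitched* test volume (not per patch):
binarize the logits at probability 0.5 (logit 0; the boundary is assigned to
foreground), build the confusion counts, and report IoU along with accuracy,
positive predictive value and true positive rate.  Misprediction analysis
labels 26-connected components of the prediction and flags those whose
overlap fraction with the ground truth falls below a threshold (default
50%); flagged components are the candidates for red highlighting in
overlays.

The experiment grid trains, for every (pretraining task, target task,
fraction, replicate) cell, a scratch baseline and a fine-tuned transfer arm
under matched seeds and matched target subsets, and evaluates both on the
untouched target test volume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .model import NetworkSpec, ResUNet3d, WeightState, _DTYPE, build_network
from .preprocess import Patch, PatchSpec, stitch, tile
from .training import LossConfig, TrainConfig, fine_tune, sigmoid, train
from .volume_io import LabelGrid, VoxelGrid

__all__ = [
    "MetricsReport",
    "TaskData",
    "ExperimentPlan",
    "ExperimentResult",
    "binarize",
    "confusion",
    "misprediction_components",
    "predict_volume",
    "run_experiment",
    "summarize",
    "write_overlays",
]

log = logging.getLogger("vemseg")


@dataclass(frozen=True)
class MetricsReport:
    """Voxel confusion counts and the derived segmentation metrics."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def iou(self) -> float:
        d = self.tp + self.fp + self.fn
        return 1.0 if d == 0 else self.tp / d

    @property
    def ppv(self) -> float:
        d = self.tp + self.fp
        return 1.0 if d == 0 else self.tp / d

    @property
    def tpr(self) -> float:
        d = self.tp + self.fn
        return 1.0 if d == 0 else self.tp / d

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / (self.tp + self.fp + self.fn + self.tn)


def binarize(logits: np.ndarray | VoxelGrid, threshold: float = 0.5) -> LabelGrid:
    """Threshold sigmoid(logit) at ``threshold``; ties go to foreground."""
    vals = logits.values if isinstance(logits, VoxelGrid) else np.asarray(logits)
    vs = logits.voxel_size if isinstance(logits, VoxelGrid) else (1.0, 1.0, 1.0)
    mask = (sigmoid(vals) >= threshold).astype(np.uint8)
    return LabelGrid(values=mask, class_name="prediction", voxel_size=vs)


def _binary(arr) -> np.ndarray:
    vals = arr.values if isinstance(arr, (LabelGrid, VoxelGrid)) else np.asarray(arr)
    uniq = np.unique(vals)
    if not np.isin(uniq, (0, 1)).all():
        raise ValueError(f"expected a binary mask, found values {uniq[:10]}")
    return vals.astype(bool)


def confusion(pred, gt) -> MetricsReport:
    """Voxel confusion counts; the IoU of two empty masks is defined as 1."""
    p, g = _binary(pred), _binary(gt)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs gt {g.shape}")
    tp = int((p & g).sum())
    fp = int((p & ~g).sum())
    fn = int((~p & g).sum())
    tn = int(p.size - tp - fp - fn)
    return MetricsReport(tp=tp, fp=fp, fn=fn, tn=tn)


_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def misprediction_components(
    pred, gt, overlap_thr: float = 0.5
) -> tuple[np.ndarray, dict[int, float], list[int]]:
    """Score 26-connected prediction components by ground-truth overlap.

    Returns the labeled component grid, a mapping component id -> overlap
    fraction ``|component ∩ gt| / |component|``, and the list of component
    ids flagged as mispredictions (overlap strictly below ``overlap_thr``;
    a component at exactly the threshold is not flagged).
    """
    p, g = _binary(pred), _binary(gt)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs gt {g.shape}")
    comp, n = ndimage.label(p, structure=_STRUCT_26)
    scores: dict[int, float] = {}
    flagged: list[int] = []
    if n:
        sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=range(1, n + 1))
        overlaps = ndimage.sum_labels(g.astype(np.float64), comp, index=range(1, n + 1))
        for cid, (sz, ov) in enumerate(zip(sizes, overlaps), start=1):
            frac = float(ov / sz)
            scores[cid] = frac
            if frac < overlap_thr:
                flagged.append(cid)
    return comp, scores, flagged


# ---------------------------------------------------------------------------
# whole-volume inference


def predict_volume(
    weights: WeightState,
    volume: VoxelGrid,
    patch_spec: PatchSpec | None = None,
    batch_size: int = 4,
) -> VoxelGrid:
    """Tile (reflect-padded), run the network per patch, stitch, crop.

    Every voxel of the input is predicted; overlaps are averaged in logit
    space.  Output shape equals input shape.
    """
    spec = patch_spec or PatchSpec(
        patch_shape=weights.spec.input_patch, border_policy="reflect"
    )
    if spec.border_policy != "reflect":
        spec = replace(spec, border_policy="reflect")
    net = ResUNet3d(weights.spec)
    net.set_weights(weights)
    patches = tile(volume, spec)
    out: list[tuple[tuple[int, int, int], np.ndarray]] = []
    for i in range(0, len(patches), batch_size):
        chunk = patches[i : i + batch_size]
        x = np.stack([p.data for p in chunk]).astype(_DTYPE)
        logits = net.forward(x)
        for p, lg in zip(chunk, logits):
            out.append((p.origin, np.asarray(lg)))
    stitched = stitch(out, _padded_shape(volume.values.shape, spec), volume.voxel_size)
    z, y, x = volume.values.shape
    return VoxelGrid(values=stitched.values[:z, :y, :x], voxel_size=volume.voxel_size)


def _padded_shape(shape, spec: PatchSpec):
    from .preprocess import _padded_extent

    return tuple(
        _padded_extent(int(e), p, s) for e, p, s in zip(shape, spec.patch_shape, spec.stride)
    )


# ---------------------------------------------------------------------------
# the experiment grid


@dataclass
class TaskData:
    """Train patches and an untouched test volume for one segmentation task.

    Train and test must come from volumes with no shared provenance (for
    synthetic scenes: different seeds — the analogue of discarding a slice
    gap between train and test blocks of a real volume).
    """

    train_patches: list[np.ndarray]
    train_labels: list[np.ndarray]
    test_volume: VoxelGrid
    test_label: LabelGrid
    task_id: str = "task"


@dataclass
class ExperimentPlan:
    """The pretrain x target x fraction x replicate grid."""

    pretrain_tasks: list[str]
    target_tasks: list[str]
    fractions: tuple[float, ...] = (1.0, 0.75, 0.5, 0.25, 0.1)
    replicates: int = 3
    network: NetworkSpec | None = None
    train_cfg: TrainConfig = field(default_factory=TrainConfig)
    pretrain_cfg: TrainConfig | None = None  # None -> train_cfg
    loss_cfg: LossConfig = field(default_factory=LossConfig)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if any(not 0 < f <= 1 for f in self.fractions):
            raise ValueError("fractions must be in (0, 1]")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class ExperimentResult:
    """Long-form per-cell table; one row per completed (cell, arm)."""

    table: pd.DataFrame

    def to_csv(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(path, index=False)


_ROW_COLS = [
    "pretrain_task", "target_task", "fraction", "replicate", "arm",
    "iou", "accuracy", "ppv", "tpr", "epochs", "error",
]


def _stable_hash(text: str) -> int:
    import hashlib

    return int(hashlib.md5(text.encode()).hexdigest()[:8], 16) % 1000


def _cell_seed(master: int, *parts: int) -> int:
    # stable fan-out of the master seed; kept below 2**31
    h = np.random.SeedSequence(entropy=(int(master),) + tuple(int(p) for p in parts))
    return int(h.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _eval_weights(ws: WeightState, task: TaskData) -> MetricsReport:
    logits = predict_volume(ws, task.test_volume)
    pred = binarize(logits)
    return confusion(pred, task.test_label)


def run_experiment(plan: ExperimentPlan, datasets: Mapping[str, TaskData]) -> ExperimentResult:
    """Run every grid cell: scratch baseline vs fine-tuned transfer arm.

    Within a cell, both arms use the same seed and therefore see the identical
    target subset; replicates vary the initialization/pretraining seed.  One
    pretrained weight state is trained per (pretrain task, replicate) and
    reused across fractions.  A failing cell is recorded with an error marker
    and the run continues.
    """
    if plan.network is None:
        raise ValueError("ExperimentPlan.network must be set")
    spec = plan.network
    rows: list[dict] = []
    pretrained_cache: dict[tuple[str, int], WeightState] = {}

    base_pre_cfg = plan.pretrain_cfg or plan.train_cfg
    for pt in plan.pretrain_tasks:
        src = datasets[pt]
        for rep in range(plan.replicates):
            seed = _cell_seed(plan.master_seed, _stable_hash(pt), rep, 0)
            log.info("pretraining on %s (replicate %d)", pt, rep)
            init = build_network(spec, seed=seed)
            cfg = replace(base_pre_cfg, seed=seed)
            rec = train(init, src.train_patches, src.train_labels, cfg, plan.loss_cfg,
                        provenance=f"pretrained:{pt}")
            pretrained_cache[(pt, rep)] = rec.weights

    for pt in plan.pretrain_tasks:
        for tt in plan.target_tasks:
            tgt = datasets[tt]
            for frac in plan.fractions:
                for rep in range(plan.replicates):
                    seed = _cell_seed(plan.master_seed, _stable_hash(f"{pt}->{tt}"), rep, 1)
                    cfg = replace(plan.train_cfg, seed=seed)
                    for arm in ("baseline", "transfer"):
                        try:
                            if arm == "baseline":
                                start = build_network(spec, seed=seed)
                                start.provenance = "random-init"
                            else:
                                start = pretrained_cache[(pt, rep)]
                            rec = fine_tune(
                                start, tgt.train_patches, tgt.train_labels, frac,
                                cfg, plan.loss_cfg, seed=seed, task_id=tt,
                            )
                            rep_metrics = _eval_weights(rec.weights, tgt)
                            rows.append({
                                "pretrain_task": pt, "target_task": tt, "fraction": frac,
                                "replicate": rep, "arm": arm,
                                "iou": rep_metrics.iou, "accuracy": rep_metrics.accuracy,
                                "ppv": rep_metrics.ppv, "tpr": rep_metrics.tpr,
                                "epochs": rec.epochs_run, "error": "",
                            })
                            log.info(
                                "%s->%s frac=%.2f rep=%d %s: IoU=%.3f",
                                pt, tt, frac, rep, arm, rep_metrics.iou,
                            )
                        except Exception as exc:  # keep the grid running
                            log.exception("cell failed: %s->%s %.2f rep=%d %s", pt, tt, frac, rep, arm)
                            rows.append({
                                "pretrain_task": pt, "target_task": tt, "fraction": frac,
                                "replicate": rep, "arm": arm,
                                "iou": np.nan, "accuracy": np.nan, "ppv": np.nan, "tpr": np.nan,
                                "epochs": 0, "error": f"{type(exc).__name__}: {exc}",
                            })
    return ExperimentResult(table=pd.DataFrame(rows, columns=_ROW_COLS))


def summarize(result: ExperimentResult) -> pd.DataFrame:
    """Mean/std of each metric per (pair, fraction, arm) + transfer delta."""
    df = result.table
    if df.empty:
        raise ValueError("cannot summarize an empty experiment result")
    df = df[df["error"] == ""]
    keys = ["pretrain_task", "target_task", "fraction", "arm"]
    agg = df.groupby(keys)[["iou", "accuracy", "ppv", "tpr"]].agg(["mean", "std"])
    agg.columns = [f"{m}_{s}" for m, s in agg.columns]
    agg = agg.reset_index()
    agg[[c for c in agg.columns if c.endswith("_std")]] = agg[
        [c for c in agg.columns if c.endswith("_std")]
    ].fillna(0.0)
    piv = agg.pivot_table(
        index=["pretrain_task", "target_task", "fraction"], columns="arm", values="iou_mean"
    )
    if {"baseline", "transfer"} <= set(piv.columns):
        piv["transfer_delta"] = piv["transfer"] - piv["baseline"]
        agg = agg.merge(
            piv["transfer_delta"].reset_index(),
            on=["pretrain_task", "target_task", "fraction"],
            how="left",
        )
    return agg


def write_overlays(
    volume: VoxelGrid,
    pred: LabelGrid,
    gt: LabelGrid,
    out_dir: str | Path,
    overlap_thr: float = 0.5,
) -> list[Path]:
    """Per-slice RGB PNGs: grayscale image, prediction in red where flagged.

    Components of the prediction with ground-truth overlap below the
    threshold are drawn in saturated red; well-matched components in a
    softer red.
    """
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    comp, _scores, flagged = misprediction_components(pred, gt, overlap_thr)
    bad = np.isin(comp, flagged)
    good = (comp > 0) & ~bad
    vals = volume.values.astype(np.float64)
    vals = (vals - vals.min()) / max(np.ptp(vals), 1e-12)
    paths = []
    for zi in range(vals.shape[0]):
        gray = (vals[zi] * 255).astype(np.uint8)
        rgb = np.stack([gray, gray, gray], axis=-1)
        rgb[good[zi]] = (0.5 * rgb[good[zi]] + 0.5 * np.array([255, 64, 64])).astype(np.uint8)
        rgb[bad[zi]] = (255, 0, 0)
        p = out / f"slice_{zi:04d}.png"
        iio.imwrite(p, rgb)
        paths.append(p)
    return paths
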