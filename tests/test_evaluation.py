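import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as npst

import vemseg as v
from vemseg.evaluation import (
    ExperimentPlan,
    ExperimentResult,
    TaskData,
    binarize,
    confusion,
    misprediction_components,
    predict_volume,
    run_experiment,
    summarize,
    write_overlays,
)
from vemseg.model import NetworkSpec
from vemseg.training import TrainConfig
from vemseg.volume_io import LabelGrid, VoxelGrid

# ---------------------------------------------------------------------------
# binarize / confusion


def test_binarize_saturated_logits():
    assert (binarize(np.full((1, 2, 2), 10.0)).values == 1).all()
    assert (binarize(np.full((1, 2, 2), -10.0)).values == 0).all()


def test_binarize_zero_logit_goes_to_foreground():
    # sigmoid(0) = 0.5 exactly; the boundary is assigned to foreground
    assert binarize(np.zeros((1, 1, 1))).values[0, 0, 0] == 1


def test_confusion_perfect_and_disjoint():
    a = np.zeros((2, 3, 3), dtype=np.uint8)
    a[0, :2, :2] = 1
    assert confusion(a, a).iou == 1.0
    b = np.zeros_like(a)
    b[1, 2, 2] = 1
    assert confusion(a, b).iou == 0.0


def test_confusion_three_voxel_hand_case():
    # pred={v1,v2}, gt={v2,v3}: TP=1, FP=1, FN=1 -> IoU = 1/3
    pred = np.zeros((1, 1, 4), dtype=np.uint8)
    gt = np.zeros_like(pred)
    pred[0, 0, [0, 1]] = 1
    gt[0, 0, [1, 2]] = 1
    rep = confusion(pred, gt)
    assert (rep.tp, rep.fp, rep.fn) == (1, 1, 1)
    assert rep.iou == pytest.approx(1 / 3)


def test_confusion_empty_masks_define_iou_one():
    z = np.zeros((2, 2, 2), dtype=np.uint8)
    rep = confusion(z, z)
    assert rep.iou == 1.0 and rep.ppv == 1.0 and rep.tpr == 1.0 and rep.accuracy == 1.0


def test_confusion_shape_mismatch_and_nonbinary():
    with pytest.raises(ValueError, match="mismatch"):
        confusion(np.zeros((1, 2, 2), dtype=np.uint8), np.zeros((1, 2, 3), dtype=np.uint8))
    with pytest.raises(ValueError, match="binary"):
        confusion(np.full((1, 1, 1), 3), np.zeros((1, 1, 1), dtype=np.uint8))


def test_metrics_match_brute_force_set_oracle(rng):
    for _ in range(50):
        p = (rng.random((4, 4, 4)) > 0.6).astype(np.uint8)
        g = (rng.random((4, 4, 4)) > 0.6).astype(np.uint8)
        rep = confusion(p, g)
        P = {tuple(i) for i in np.argwhere(p)}
        G = {tuple(i) for i in np.argwhere(g)}
        tp = len(P & G)
        iou = tp / len(P | G) if P | G else 1.0
        ppv = tp / len(P) if P else 1.0
        tpr = tp / len(G) if G else 1.0
        assert rep.iou == pytest.approx(iou)
        assert rep.ppv == pytest.approx(ppv)
        assert rep.tpr == pytest.approx(tpr)
        assert rep.accuracy == pytest.approx((tp + len(set(map(tuple, np.argwhere((p == 0) & (g == 0)))))) / 64)


@settings(deadline=None, derandomize=True, max_examples=200)
@given(
    p=npst.arrays(np.uint8, (3, 5, 5), elements=st.integers(0, 1)),
    g=npst.arrays(np.uint8, (3, 5, 5), elements=st.integers(0, 1)),
)
def test_iou_bounded_by_ppv_and_tpr(p, g):
    rep = confusion(p, g)
    assert rep.iou <= min(rep.ppv, rep.tpr) + 1e-12
    assert 0.0 <= rep.accuracy <= 1.0


# ---------------------------------------------------------------------------
# misprediction components


def test_component_inside_gt_not_flagged():
    pred = np.zeros((3, 5, 5), dtype=np.uint8)
    pred[1, 1:3, 1:3] = 1
    gt = np.ones_like(pred)
    comp, scores, flagged = misprediction_components(pred, gt)
    assert scores[1] == 1.0 and flagged == []


def test_component_disjoint_from_gt_flagged():
    pred = np.zeros((3, 5, 5), dtype=np.uint8)
    pred[0, 0, 0] = 1
    gt = np.zeros_like(pred)
    gt[2, 4, 4] = 1
    _, scores, flagged = misprediction_components(pred, gt)
    assert scores[1] == 0.0 and flagged == [1]


def test_component_at_exactly_half_overlap_not_flagged():
    pred = np.zeros((1, 1, 4), dtype=np.uint8)
    pred[0, 0, :4] = 1  # one 4-voxel component
    gt = np.zeros_like(pred)
    gt[0, 0, :2] = 1  # overlap 2/4 = 0.5 exactly
    _, scores, flagged = misprediction_components(pred, gt, overlap_thr=0.5)
    assert scores[1] == 0.5 and flagged == []


def test_components_are_26_connected():
    pred = np.zeros((2, 2, 2), dtype=np.uint8)
    pred[0, 0, 0] = 1
    pred[1, 1, 1] = 1  # touching only across the body diagonal
    comp, scores, _ = misprediction_components(pred, np.zeros_like(pred))
    assert len(scores) == 1


# ---------------------------------------------------------------------------
# whole-volume inference


def test_predict_volume_shape_equals_input(tiny_spec):
    ws = v.build_network(tiny_spec, seed=0)
    vol = VoxelGrid(np.random.default_rng(0).normal(size=(3, 11, 13)))
    out = predict_volume(ws, vol)
    assert out.values.shape == (3, 11, 13)
    assert out.voxel_size == vol.voxel_size


# ---------------------------------------------------------------------------
# experiment grid


def _tiny_datasets(tiny_spec, tiny_task):
    patches, labels, test_img, test_lab = tiny_task
    td = TaskData(patches, labels, test_img, test_lab, task_id="t")
    return {"src": td, "tgt": td}


def _plan(tiny_spec, fractions, replicates, epochs=0):
    return ExperimentPlan(
        pretrain_tasks=["src"],
        target_tasks=["tgt"],
        fractions=fractions,
        replicates=replicates,
        network=tiny_spec,
        train_cfg=TrainConfig(max_epochs=epochs, seed=0),
        master_seed=1,
    )


def test_single_cell_yields_two_rows(tiny_spec, tiny_task):
    res = run_experiment(_plan(tiny_spec, (0.5,), 1), _tiny_datasets(tiny_spec, tiny_task))
    assert len(res.table) == 2
    assert set(res.table["arm"]) == {"baseline", "transfer"}
    assert (res.table["error"] == "").all()


def test_default_grid_has_thirty_rows(tiny_spec, tiny_task):
    res = run_experiment(
        _plan(tiny_spec, (1.0, 0.75, 0.5, 0.25, 0.1), 3), _tiny_datasets(tiny_spec, tiny_task)
    )
    assert len(res.table) == 30  # 5 fractions x 3 replicates x 2 arms


def test_experiment_reproducible_from_master_seed(tiny_spec, tiny_task):
    ds = _tiny_datasets(tiny_spec, tiny_task)
    a = run_experiment(_plan(tiny_spec, (0.5,), 2, epochs=1), ds)
    b = run_experiment(_plan(tiny_spec, (0.5,), 2, epochs=1), ds)
    pd.testing.assert_frame_equal(a.table, b.table)


def test_plan_validation():
    with pytest.raises(ValueError, match="fractions"):
        ExperimentPlan(["a"], ["b"], fractions=(0.0,))
    with pytest.raises(ValueError, match="replicates"):
        ExperimentPlan(["a"], ["b"], replicates=0)


# ---------------------------------------------------------------------------
# summaries


def _result_from_rows(rows):
    cols = ["pretrain_task", "target_task", "fraction", "replicate", "arm",
            "iou", "accuracy", "ppv", "tpr", "epochs", "error"]
    return ExperimentResult(pd.DataFrame(rows, columns=cols))


def test_summarize_single_row_mean_equals_value():
    res = _result_from_rows([("s", "t", 1.0, 0, "baseline", 0.8, 0.9, 0.85, 0.8, 5, "")])
    summ = summarize(res)
    assert summ.loc[0, "iou_mean"] == pytest.approx(0.8)
    assert summ.loc[0, "iou_std"] == 0.0


def test_summarize_three_replicates_hand_arithmetic():
    ious = (0.6, 0.7, 0.9)
    rows = [("s", "t", 0.1, r, "transfer", i, i, i, i, 5, "") for r, i in enumerate(ious)]
    summ = summarize(_result_from_rows(rows))
    assert summ.loc[0, "iou_mean"] == pytest.approx(sum(ious) / 3)
    assert summ.loc[0, "iou_std"] == pytest.approx(np.std(ious, ddof=1))


def test_summarize_equal_arms_have_zero_delta():
    rows = [
        ("s", "t", 0.5, 0, "baseline", 0.7, 0.7, 0.7, 0.7, 5, ""),
        ("s", "t", 0.5, 0, "transfer", 0.7, 0.7, 0.7, 0.7, 5, ""),
    ]
    summ = summarize(_result_from_rows(rows))
    assert (summ["transfer_delta"] == 0).all()


# ---------------------------------------------------------------------------
# overlays


def test_overlays_written_per_slice(tmp_path, rng):
    vol = VoxelGrid(rng.random((3, 8, 8)))
    pred = LabelGrid((rng.random((3, 8, 8)) > 0.5).astype(np.uint8))
    gt = LabelGrid((rng.random((3, 8, 8)) > 0.5).astype(np.uint8))
    paths = write_overlays(vol, pred, gt, tmp_path / "ov")
    assert len(paths) == 3
    assert all(p.exists() for p in paths)
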