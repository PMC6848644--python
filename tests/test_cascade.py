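import numpy as np
import pytest

from nigraseg.augment import AugmentSpec
from nigraseg.cascade import (
    CascadeModel,
    NetConfig,
    TrainConfig,
    assign_folds,
    build_cascade,
    compose_second_input,
    cross_validate,
    predict,
    train_cascade,
)
from nigraseg.evalstats import dice_masks
from nigraseg.imageio import Label, MaskSource
from nigraseg.phantom import PhantomParams, generate_cohort, generate_subject


def _tiny_cfg(**kw):
    base = dict(
        crop_size=32,
        epochs=1,
        alpha=1e-3,
        seed=0,
        input_scale=0.01,
        augment=AugmentSpec.identity(),
        train_slices="midbrain",
        folds=2,
    )
    base.update(kw)
    return TrainConfig(**base)


def _small_subjects(n_hc=2, n_pd=2, seed=5):
    params = PhantomParams(image_size=(64, 64), seed=seed, shift_px=2.0)
    _, subjects = generate_cohort(params, n_hc, n_pd)
    return subjects


def test_build_determinism_and_probability_normalization():
    a = build_cascade(NetConfig(depth=3, base_channels=4), seed=3)
    b = build_cascade(NetConfig(depth=3, base_channels=4), seed=3)
    for pa, pb in zip(a.net_midbrain.params, b.net_midbrain.params):
        np.testing.assert_array_equal(pa.value, pb.value)
    x = np.zeros((1, 1, 128, 128), dtype=np.float32)
    p = a.net_midbrain.predict_proba(x)
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-5)


def test_compose_second_input_contract():
    img = np.random.default_rng(0).normal(size=(2, 16, 16)).astype(np.float32)
    zero = np.zeros_like(img)
    x2 = compose_second_input(img, zero)
    assert x2.shape == (2, 2, 16, 16)
    np.testing.assert_array_equal(x2[:, 0], img)
    np.testing.assert_array_equal(x2[:, 1], 0.0)
    np.testing.assert_array_equal(x2, compose_second_input(img, zero))  # deterministic
    with pytest.raises(ValueError, match="geometry"):
        compose_second_input(img, zero[:, :8])


def test_zero_epochs_rejected():
    with pytest.raises(ValueError, match="epochs"):
        TrainConfig(epochs=0)


def test_crop_larger_than_image_rejected():
    subjects = _small_subjects(1, 1)
    with pytest.raises(ValueError, match="crop"):
        train_cascade(subjects, _tiny_cfg(crop_size=128), net_cfg=NetConfig(depth=2, base_channels=2))


def test_empty_training_set_rejected():
    with pytest.raises(ValueError, match="empty"):
        train_cascade([], _tiny_cfg())


def test_training_is_seed_reproducible():
    subjects = _small_subjects(1, 1)
    net = NetConfig(depth=2, base_channels=2)
    m1, t1 = train_cascade(subjects, _tiny_cfg(), net_cfg=net)
    m2, t2 = train_cascade(subjects, _tiny_cfg(), net_cfg=net)
    assert t1 == t2
    for pa, pb in zip(m1.net_midbrain.params, m2.net_midbrain.params):
        np.testing.assert_array_equal(pa.value, pb.value)


def test_disconnected_losses():
    """Training one net leaves the other's weights bit-identical."""
    subjects = _small_subjects(1, 1)
    net = NetConfig(depth=2, base_channels=2)
    model = build_cascade(net, seed=0)
    w_mb = [p.value.copy() for p in model.net_midbrain.params]
    w_sn = [p.value.copy() for p in model.net_snpc.params]

    model, _ = train_cascade(subjects, _tiny_cfg(), model=model, train_net1=False)
    for before, p in zip(w_mb, model.net_midbrain.params):
        np.testing.assert_array_equal(before, p.value)
    assert any(not np.array_equal(b, p.value) for b, p in zip(w_sn, model.net_snpc.params))

    model2 = build_cascade(net, seed=0)
    w_sn2 = [p.value.copy() for p in model2.net_snpc.params]
    model2, _ = train_cascade(subjects, _tiny_cfg(), model=model2, train_net2=False)
    for before, p in zip(w_sn2, model2.net_snpc.params):
        np.testing.assert_array_equal(before, p.value)


def test_predict_partition_containment_and_determinism():
    subjects = _small_subjects(1, 1)
    model = build_cascade(NetConfig(depth=2, base_channels=2), seed=1)
    img = subjects[0].image
    mask = predict(model, img)
    assert mask.source is MaskSource.NETWORK
    assert mask.shape == img.shape
    assert set(np.unique(mask.data)) <= {0, 1, 2}
    assert ((mask.data == Label.SNPC) <= (mask.data != Label.OUTSIDE)).all()
    mask2 = predict(model, img)
    np.testing.assert_array_equal(mask.data, mask2.data)


def test_predict_pads_non_divisible_geometry():
    params = PhantomParams(image_size=(70, 70), seed=2, shift_px=1.0)
    s = generate_subject(params, "HC", 4)
    model = build_cascade(NetConfig(depth=3, base_channels=2), seed=0)
    mask = predict(model, s.image)  # 70 % 4 != 0: reflect-pad then un-pad
    assert mask.shape == s.image.shape


def test_checkpoint_roundtrip(tmp_path):
    subjects = _small_subjects(1, 1)
    cfg = _tiny_cfg()
    model, _ = train_cascade(subjects, cfg, net_cfg=NetConfig(depth=2, base_channels=2))
    model.save(tmp_path / "cascade")
    back = CascadeModel.load(tmp_path / "cascade")
    img = subjects[0].image
    np.testing.assert_array_equal(predict(model, img).data, predict(back, img).data)
    assert back.train_config.input_scale == cfg.input_scale


def test_fold_assignment_stratified_and_deterministic():
    groups = ["HC"] * 8 + ["PD"] * 8
    folds = assign_folds(groups, 4, seed=9)
    for f in range(4):
        idx = np.flatnonzero(folds == f)
        assert len(idx) == 4
        assert sum(groups[i] == "HC" for i in idx) == 2  # 2 HC + 2 PD per fold
    np.testing.assert_array_equal(folds, assign_folds(groups, 4, seed=9))
    # every subject validated exactly once
    assert sorted(np.concatenate([np.flatnonzero(folds == f) for f in range(4)]).tolist()) == list(range(16))


def test_fold_assignment_rejects_small_group():
    with pytest.raises(ValueError, match="PD"):
        assign_folds(["HC"] * 8 + ["PD"] * 2, 4, seed=0)


def test_cross_validate_tiny_pipeline():
    subjects = _small_subjects(2, 2, seed=6)
    groups = [s.record.group for s in subjects]
    result = cross_validate(subjects, groups, _tiny_cfg(), net_cfg=NetConfig(depth=2, base_channels=2))
    report = result["report"]
    assert len(report["folds"]) == 2
    assert report["deployment_fold"] == 0
    assert result["model"].fold_id == 0
    assert sorted(report["fold_assignment"]) == [0, 0, 1, 1]
    for entry in report["folds"]:
        assert 0.0 <= entry["val_dice_midbrain"] <= 1.0


def test_overfit_single_noiseless_phantom():
    """300 iterations on one noiseless phantom: the cascade memorizes it.

    Verifies that optimization works end-to-end (midbrain Dice >= 0.95,
    SNpc Dice >= 0.8 on the training subject) and that both loss traces
    decrease in 50-iteration moving average.
    """
    params = PhantomParams(sigma_noise=0.0)
    s = generate_subject(params, "HC", 7)
    cfg = TrainConfig(
        crop_size=96,
        epochs=300,  # 3 samples, batch 2 -> one iteration per epoch
        alpha=1e-3,
        seed=0,
        input_scale=0.01,
        augment=None,
        train_slices="midbrain",
    )
    model, trace = train_cascade([s], cfg)
    assert len(trace["midbrain"]) == 300
    pred = predict(model, s.image)
    assert dice_masks(s.truth, pred, "midbrain") >= 0.95
    assert dice_masks(s.truth, pred, "snpc") >= 0.8
    for net in ("midbrain", "snpc"):
        losses = np.asarray(trace[net])
        windows = [losses[i : i + 50].mean() for i in range(0, 300, 50)]
        tol = 0.10 * windows[0]  # SGD fluctuation allowance
        assert all(b <= a + tol for a, b in zip(windows, windows[1:]))
        assert windows[-1] < 0.2 * windows[0]
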