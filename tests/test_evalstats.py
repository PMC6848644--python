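import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from nigraseg.evalstats import (
    delong_test,
    dice,
    dice_masks,
    dice_report,
    group_compare,
    rate_dsc,
    roc_auc,
    spearman_strength,
)
from nigraseg.imageio import Label, LabelMask


# ---------------------------------------------------------------------------
# Dice
# ---------------------------------------------------------------------------


def test_dice_examples():
    a = np.zeros((4, 4), bool)
    a[:2] = True
    assert dice(a, a) == 1.0
    b = np.zeros((4, 4), bool)
    b[3:] = True
    assert dice(a, b) == 0.0
    # |a|=4, |b|=6, |a&b|=3 -> 2*3/10
    a = np.zeros(10, bool)
    b = np.zeros(10, bool)
    a[:4] = True
    b[1:7] = True
    assert dice(a, b) == pytest.approx(0.6)


def test_dice_both_empty_is_one():
    z = np.zeros((3, 3), bool)
    assert dice(z, z) == 1.0


def test_dice_geometry_mismatch():
    with pytest.raises(ValueError):
        dice(np.zeros((2, 2), bool), np.zeros((3, 3), bool))


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.integers(0, 2**32 - 1))
def test_dice_symmetry_and_identity(seed):
    rng = np.random.default_rng(seed)
    a = rng.random((6, 6)) < 0.4
    b = rng.random((6, 6)) < 0.4
    assert dice(a, b) == dice(b, a)
    assert 0.0 <= dice(a, b) <= 1.0
    assert (dice(a, b) == 1.0) == np.array_equal(a, b)


def test_dice_masks_uses_truth_slice_pair():
    lab = np.zeros((4, 4, 4), dtype=np.uint8)
    lab[1:3, 1:3, 1:3] = Label.BACKGROUND
    lab[1, 1, 1] = Label.SNPC
    truth = LabelMask(lab)
    pred = LabelMask(lab.copy())
    assert dice_masks(truth, pred, "midbrain") == 1.0
    assert dice_masks(truth, pred, "snpc") == 1.0
    # a disagreement on a non-selected slice does not change the result
    lab2 = lab.copy()
    lab2[0, 0, 0] = Label.BACKGROUND
    assert dice_masks(truth, LabelMask(lab2), "midbrain", slice_pair=(1, 2)) == 1.0


@pytest.mark.parametrize(
    "dsc,category",
    [
        (0.0, "low"),
        (0.39, "low"),
        (0.40, "moderate"),
        (0.79, "moderate"),
        (0.80, "high"),
        (0.83, "high"),
        (1.0, "high"),
    ],
)
def test_rating_scale_band_edges(dsc, category):
    assert rate_dsc(dsc) == category


def test_rating_scale_total_on_grid():
    for v in np.linspace(0.0, 1.0, 201):
        assert rate_dsc(float(v)) in ("low", "moderate", "high")
    with pytest.raises(ValueError):
        rate_dsc(1.2)


def test_dice_report_mean_sd_category():
    rep = dice_report("snpc", [0.80, 0.86, 0.83])
    assert rep.mean == pytest.approx(0.83)
    assert rep.category == "high"


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


def test_auc_perfect_separation_low_is_positive():
    rep = roc_auc([1.0, 2.0, 3.0, 4.0], ["PD", "PD", "HC", "HC"], orientation="low_is_positive")
    assert rep.auc == 1.0
    assert rep.sensitivity == 1.0 and rep.specificity == 1.0
    # positivity rule is area <= cutoff; cutoff separates 2 from 3
    assert 2.0 <= rep.cutoff < 3.0


def test_auc_interleaved_is_three_quarters():
    rep = roc_auc([1.0, 3.0, 2.0, 4.0], ["PD", "PD", "HC", "HC"], orientation="low_is_positive")
    assert rep.auc == pytest.approx(0.75)


def test_auc_all_ties_is_half():
    rep = roc_auc([5.0] * 6, ["PD"] * 3 + ["HC"] * 3)
    assert rep.auc == pytest.approx(0.5)


def test_auc_single_class_rejected():
    with pytest.raises(ValueError):
        roc_auc([1.0, 2.0], ["HC", "HC"])


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.integers(0, 2**32 - 1))
def test_auc_agrees_with_sklearn_and_mann_whitney(seed):
    rng = np.random.default_rng(seed)
    n1, n0 = rng.integers(2, 10, 2)
    scores = np.concatenate([rng.integers(0, 6, n1), rng.integers(0, 6, n0)]).astype(float)
    labels = ["PD"] * n1 + ["HC"] * n0
    rep = roc_auc(scores, labels)
    y = np.array([1] * n1 + [0] * n0)
    assert rep.auc == pytest.approx(roc_auc_score(y, scores), abs=1e-12)
    u = sps.mannwhitneyu(scores[:n1], scores[n1:], alternative="two-sided").statistic
    assert rep.auc == pytest.approx(u / (n1 * n0), abs=1e-12)


def test_youden_cutoff_tie_breaks_to_higher_specificity():
    # J is maximal (=1) only at the separating threshold here; with ties the
    # implementation must prefer the lower false-positive rate
    scores = [1.0, 1.0, 3.0, 4.0]
    labels = ["PD", "PD", "HC", "HC"]
    rep = roc_auc(scores, labels, orientation="low_is_positive")
    assert rep.specificity == 1.0


# ---------------------------------------------------------------------------
# DeLong
# ---------------------------------------------------------------------------


def _paired_scores():
    rng = np.random.default_rng(5)
    y = np.array(["PD"] * 4 + ["HC"] * 4)
    a = np.array([0.9, 0.8, 0.6, 0.75, 0.4, 0.55, 0.3, 0.2])
    b = a + rng.normal(0, 0.15, a.size)
    return a, b, y


def test_delong_self_comparison():
    a, _, y = _paired_scores()
    res = delong_test(a, a, y)
    assert res.z == 0.0 and res.p == 1.0


def test_delong_antisymmetry():
    a, b, y = _paired_scores()
    r1 = delong_test(a, b, y)
    r2 = delong_test(b, a, y)
    assert r1.z == pytest.approx(-r2.z)
    assert r1.p == pytest.approx(r2.p)


def test_delong_matches_stratified_bootstrap():
    """On a small paired sample the DeLong p agrees with a stratified-bootstrap
    normal approximation of the AUC-difference distribution."""
    a, b, y = _paired_scores()
    res = delong_test(a, b, y)
    rng = np.random.default_rng(11)
    pos = np.flatnonzero(y == "PD")
    neg = np.flatnonzero(y == "HC")

    def auc(scores, p_idx, n_idx):
        x, z = scores[p_idx], scores[n_idx]
        return ((x[:, None] > z[None, :]) + 0.5 * (x[:, None] == z[None, :])).mean()

    diffs = []
    for _ in range(10_000):
        p_idx = rng.choice(pos, pos.size, replace=True)
        n_idx = rng.choice(neg, neg.size, replace=True)
        diffs.append(auc(a, p_idx, n_idx) - auc(b, p_idx, n_idx))
    diffs = np.asarray(diffs)
    observed = res.auc_a - res.auc_b
    z_boot = observed / diffs.std(ddof=1)
    p_boot = 2 * sps.norm.sf(abs(z_boot))
    assert res.p == pytest.approx(p_boot, abs=0.1)


def test_delong_unpaired_rejected():
    a, b, y = _paired_scores()
    with pytest.raises(ValueError):
        delong_test(a[:-1], b, y)


# ---------------------------------------------------------------------------
# Spearman and group tests
# ---------------------------------------------------------------------------


def test_spearman_concordant():
    r, p, cat = spearman_strength([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
    assert r == pytest.approx(1.0)
    assert cat == "very strong"


@pytest.mark.parametrize(
    "r,expected",
    [(0.1, "very weak"), (-0.32, "weak"), (0.5, "moderate"), (-0.65, "strong"), (0.9, "very strong")],
)
def test_spearman_strength_bands(r, expected):
    """The five-level scale applied to |r|; checked by constructing data whose
    Spearman correlation is close to the requested value."""
    rng = np.random.default_rng(42)
    n = 2000
    x = rng.normal(size=n)
    # Gaussian copula: Pearson rho_g gives Spearman 6/pi*asin(rho_g/2)
    rho_g = 2 * np.sin(np.pi * r / 6)
    y = rho_g * x + np.sqrt(1 - rho_g**2) * rng.normal(size=n)
    r_hat, _, cat = spearman_strength(x, y)
    assert r_hat == pytest.approx(r, abs=0.05)
    assert cat == expected


def test_spearman_constant_input_rejected():
    with pytest.raises(ValueError):
        spearman_strength([1, 1, 1], [1, 2, 3])


def test_t_identical_samples():
    stat, p = group_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], test="t")
    assert stat == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_mann_whitney_identical_distributions():
    a = [1.0, 2.0, 3.0, 4.0]
    stat, _ = group_compare(a, a, test="mann_whitney")
    assert stat == pytest.approx(len(a) * len(a) / 2)


def test_chi2_diagonal_table():
    stat, p = group_compare([[10, 0], [0, 10]], test="chi2")
    assert stat == pytest.approx(20.0)  # sum (O-E)^2/E with E=5 everywhere
    assert p < 0.001


def test_chi2_zero_margin_rejected():
    with pytest.raises(ValueError):
        group_compare([[0, 0], [5, 5]], test="chi2")
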