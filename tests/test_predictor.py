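"""KAN layer, losses, and the metric suite against independent references."""

import numpy as np
import pytest

from lmipredict._autodiff import Tensor
from lmipredict.predictor import (
    KanLayer,
    KanNetwork,
    bce_loss,
    bspline_basis,
    compute_metrics,
    kan_layer,
    make_knots,
    score_pairs,
    summarize_reports,
    total_loss,
)


# --------------------------------------------------------------- B-splines
def test_bspline_partition_of_unity(rng):
    knots = make_knots((-2, 2), 5, 3)
    x = rng.uniform(-1.99, 1.99, size=(50,))
    B, _ = bspline_basis(x, knots, 3)
    np.testing.assert_allclose(B.sum(axis=-1), 1.0, atol=1e-12)
    assert np.all(B >= 0)


def test_bspline_derivative_matches_central_difference(rng):
    knots = make_knots((-2, 2), 5, 3)
    x = rng.uniform(-1.9, 1.9, size=(20,))
    _, dB = bspline_basis(x, knots, 3)
    h = 1e-6
    Bp, _ = bspline_basis(x + h, knots, 3)
    Bm, _ = bspline_basis(x - h, knots, 3)
    np.testing.assert_allclose((Bp - Bm) / (2 * h), dB, atol=1e-6)


def test_make_knots_rejects_bad_grid():
    with pytest.raises(ValueError):
        make_knots((2, -2), 5, 3)
    with pytest.raises(ValueError):
        make_knots((-2, 2), 0, 3)


# --------------------------------------------------------------- KAN layer
def test_kan_layer_silu_only_at_origin(rng):
    layer = KanLayer(1, 1, np.random.default_rng(0), dtype=np.float64)
    layer.W_spline.data[:] = 0.0
    layer.W_base.data[:] = 1.0
    out = kan_layer(np.array([[0.0]]), layer)
    assert out.item() == pytest.approx(0.0, abs=1e-12)  # SiLU(0) = 0


def test_kan_layer_constant_spline_coefficients_give_constant(rng):
    # partition of unity: all coefficients c -> spline path outputs c
    layer = KanLayer(1, 1, np.random.default_rng(0), dtype=np.float64)
    layer.W_base.data[:] = 0.0
    c = 2.75
    layer.W_spline.data[:] = c
    x = np.linspace(-1.9, 1.9, 9).reshape(-1, 1)
    out = kan_layer(x, layer).data
    np.testing.assert_allclose(out, c, atol=1e-10)


def test_kan_layer_reduces_to_linear_in_silu(rng):
    layer = KanLayer(4, 3, np.random.default_rng(1), dtype=np.float64)
    layer.W_spline.data[:] = 0.0
    x = rng.standard_normal((6, 4))
    out = kan_layer(x, layer).data
    silu = x / (1 + np.exp(-x))
    np.testing.assert_allclose(out, silu @ layer.W_base.data, atol=1e-12)


def test_kan_layer_clamps_out_of_range_inputs(rng):
    layer = KanLayer(1, 1, np.random.default_rng(2), dtype=np.float64)
    far = kan_layer(np.array([[50.0]]), layer).data
    assert np.isfinite(far).all()


# ------------------------------------------------------------------- scores
def test_score_pairs_sigmoid_properties(rng):
    kan = KanNetwork(4, np.random.default_rng(0), hidden=3, dtype=np.float64)
    lnc = Tensor(rng.standard_normal((3, 2)))
    mir = Tensor(rng.standard_normal((2, 2)))
    pairs = np.array([[0, 0], [1, 1], [2, 0]])
    s = score_pairs(lnc, mir, pairs, kan).data
    assert s.shape == (3,) and np.all((s > 0) & (s < 1))


def test_zero_logit_scores_half(rng):
    kan = KanNetwork(2, np.random.default_rng(0), hidden=2, dtype=np.float64)
    for layer in kan.layers:
        layer.W_base.data[:] = 0.0
        layer.W_spline.data[:] = 0.0
    s = score_pairs(Tensor(np.ones((1, 1))), Tensor(np.ones((1, 1))),
                    np.array([[0, 0]]), kan).data
    assert s[0] == pytest.approx(0.5)
    assert (s > 0.5).astype(int)[0] == 0  # 0.5 itself is not called interacting


def test_sigmoid_monotone_in_logit():
    logits = np.linspace(-3, 3, 11)
    probs = 1 / (1 + np.exp(-logits))
    assert np.all(np.diff(probs) > 0)
    assert probs[logits > 0].min() > 0.5


# -------------------------------------------------------------------- losses
def test_bce_closed_forms():
    assert bce_loss(np.array([1.0, 0.0]), np.array([1 - 1e-9, 1e-9])).item() == pytest.approx(0.0, abs=1e-5)
    assert bce_loss(np.array([1.0]), np.array([0.5])).item() == pytest.approx(np.log(2), abs=1e-9)
    got = bce_loss(np.array([1.0, 1.0]), np.array([0.5, 0.25])).item()
    assert got == pytest.approx((np.log(2) + np.log(4)) / 2, abs=1e-9)


def test_bce_minimized_at_label_mean_for_constant_predictor():
    y = np.array([1.0, 1.0, 0.0, 1.0, 0.0])
    grid = np.linspace(0.01, 0.99, 197)
    losses = [bce_loss(y, np.full_like(y, p)).item() for p in grid]
    assert grid[int(np.argmin(losses))] == pytest.approx(y.mean(), abs=0.01)


def test_bce_rejects_length_mismatch():
    with pytest.raises(ValueError):
        bce_loss(np.array([1.0]), np.array([0.5, 0.5]))


def test_total_loss_is_unweighted_sum():
    assert total_loss(0.0, 0.7) == pytest.approx(0.7)
    assert total_loss(0.3, 0.7) == pytest.approx(1.0)
    assert total_loss(Tensor(np.asarray(0.2)), Tensor(np.asarray(0.5))).item() == pytest.approx(0.7)


# ------------------------------------------------------------------- metrics
def _rank_auc(y, s):
    """Mann-Whitney AUC with rank-averaged ties (independent reference)."""
    from scipy.stats import rankdata

    r = rankdata(s)
    n1 = y.sum()
    n0 = len(y) - n1
    return (r[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)


def _step_aupr(y, s):
    """Precision-recall step integration over unique score thresholds
    (independent reference; tied scores enter and leave together)."""
    thresholds = np.unique(s)[::-1]
    ap, prev_rec = 0.0, 0.0
    n_pos = y.sum()
    for t in thresholds:
        called = s >= t
        tp = int(np.sum(y[called]))
        prec = tp / called.sum()
        rec = tp / n_pos
        ap += (rec - prev_rec) * prec
        prev_rec = rec
    return ap


def test_metrics_perfect_separation():
    rep = compute_metrics(np.array([1, 1, 0, 0]), np.array([0.9, 0.8, 0.4, 0.2]))
    assert rep.auc == rep.aupr == rep.acc == 1.0


def test_metrics_confusion_table_arithmetic():
    # TP=3, FP=1, FN=1, TN=5
    y = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
    s = np.array([0.9, 0.8, 0.7, 0.2, 0.6, 0.1, 0.1, 0.1, 0.1, 0.1])
    rep = compute_metrics(y, s)
    assert (rep.tp, rep.fp, rep.fn, rep.tn) == (3, 1, 1, 5)
    assert rep.precision == pytest.approx(0.75)
    assert rep.recall == pytest.approx(0.75)
    assert rep.acc == pytest.approx(0.8)
    assert rep.f1 == pytest.approx(0.75)


def test_metrics_null_scores_give_half_auc(rng):
    y = (rng.random(10_000) < 0.5).astype(int)
    s = rng.random(10_000)
    rep = compute_metrics(y, s)
    assert rep.auc == pytest.approx(0.5, abs=0.02)


def test_metrics_match_independent_references(rng):
    for _ in range(100):
        n = int(rng.integers(10, 60))
        y = (rng.random(n) < 0.4).astype(int)
        if y.sum() in (0, n):
            continue
        s = np.round(rng.random(n), 2)  # rounding forces ties
        rep = compute_metrics(y, s)
        assert rep.auc == pytest.approx(_rank_auc(y, s), abs=1e-6)
        assert rep.aupr == pytest.approx(_step_aupr(y, s), abs=1e-6)


def test_auc_invariant_under_monotone_transform(rng):
    y = (rng.random(200) < 0.3).astype(int)
    s = rng.random(200)
    if y.sum() in (0, 200):
        y[:3] = [0, 1, 1]
    base = compute_metrics(y, s).auc
    for f in (lambda x: 3 * x + 1, np.exp, lambda x: x ** 3):
        assert compute_metrics(y, f(s)).auc == pytest.approx(base, abs=1e-12)


def test_metrics_single_class_raises():
    with pytest.raises(ValueError, match="single class"):
        compute_metrics(np.ones(4, dtype=int), np.array([0.1, 0.9, 0.5, 0.6]))


def test_summarize_reports_mean_and_std():
    r1 = compute_metrics(np.array([1, 0]), np.array([0.9, 0.1]))
    r2 = compute_metrics(np.array([1, 0]), np.array([0.1, 0.9]))
    summary = summarize_reports([r1, r2])
    assert summary["auc_mean"] == pytest.approx(0.5)
    assert summary["auc_std"] == pytest.approx(0.5)
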