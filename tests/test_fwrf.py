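"""Unit tests for the fwRF encoding-model building blocks."""

import numpy as np
import pytest
from scipy import signal as ssig
from scipy import stats as sps

import neurostim as ns
from neurostim import fwrf
from neurostim import synthetic_data as sd

from conftest import gt_encoding_model


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------

class TestFeatureExtraction:
    def test_deterministic_and_shaped(self, bank32, small_pool):
        im = small_pool.stimuli[0]
        a = ns.extract_features(im, bank32)
        b = ns.extract_features(im, bank32)
        for la, lb, shape in zip(a.levels, b.levels, bank32.layer_shapes):
            assert la.shape == shape
            np.testing.assert_array_equal(la, lb)
        assert (a.levels[0] >= 0).all()     # rectified

    def test_deepnet_scale_shapes_declared(self):
        bank = ns.deepnet_scale_bank()
        assert bank.layer_shapes == ((256, 27, 27), (896, 13, 13),
                                     (1536, 1, 1))
        with pytest.raises(ValueError, match="declaration"):
            ns.extract_features(np.zeros((227, 227)), bank)

    def test_impulse_matches_direct_convolution(self):
        # one linear (unrectified) filter, full-resolution map
        bank = ns.FeatureBank(
            bank_id="toy", layers=(ns.LayerSpec(1, 16, 5),),
            image_side=16, rectify=False, seed=3)
        img = np.zeros((16, 16))
        img[5, 9] = 1.0
        out = ns.extract_features(img, bank).levels[0][0]
        ref = ssig.convolve2d(img, bank.filters()[0], mode="same")
        np.testing.assert_allclose(out, ref, atol=1e-5)

    def test_wrong_image_size_rejected(self, bank32):
        with pytest.raises(ValueError, match="expected pixels"):
            fwrf._extract_batch(np.zeros((1, 16, 16)), bank32)


class TestChannelSelection:
    def test_matches_bruteforce_scores_and_sort(self, bank32, small_pool):
        K = 5
        got = ns.select_feature_maps(small_pool.stimuli, bank32, K)
        # independent recomputation: per-image spatial variance, averaged
        px = np.asarray([s.pixels for s in small_pool.stimuli])
        levels = fwrf._extract_batch(px, bank32)
        expected = []
        offset = 0
        for lv in levels:
            scores = np.array([
                np.mean([m.var() for m in lv[:, c]])
                for c in range(lv.shape[1])])
            if lv.shape[1] <= K:
                keep = np.arange(lv.shape[1])
            else:
                order = sorted(range(lv.shape[1]),
                               key=lambda c: (-scores[c], c))[:K]
                keep = np.sort(order)
            expected.extend(offset + keep)
            offset += lv.shape[1]
        np.testing.assert_array_equal(got, expected)

    def test_constant_channel_scores_zero_and_dropped(self, small_pool):
        # global (1x1) channels have zero spatial variance by construction
        bank = ns.default_bank(0, image_side=32)
        levels = fwrf._extract_batch(
            np.asarray([s.pixels for s in small_pool.stimuli]), bank)
        scores = fwrf._channel_scores(levels, "spatial")
        assert np.allclose(scores[bank.level_slices[2]], 0.0)

    def test_empty_pool_rejected(self, bank32):
        with pytest.raises(ValueError, match="empty"):
            ns.select_feature_maps([], bank32, 4)


# ---------------------------------------------------------------------------
# Gaussian pooling
# ---------------------------------------------------------------------------

class TestPooling:
    @pytest.mark.parametrize("side", [1, 3, 8, 16])
    @pytest.mark.parametrize("field", [
        ns.PoolingField((0.0, 0.0), 0.04),
        ns.PoolingField((2.8, -2.8), 0.4),
        ns.PoolingField((-4.0, 4.0), 0.1),
    ])
    def test_weights_nonnegative_sum_to_one(self, side, field):
        w = ns.pooling_weights(side, field)
        assert (w >= 0).all()
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_uniform_map_pools_to_its_value(self):
        stack = ns.FeatureMapStack((np.full((2, 8, 8), 3.25),))
        out = ns.pool_features(stack, ns.PoolingField((1.0, -2.0), 0.2))
        np.testing.assert_allclose(out, [3.25, 3.25])

    def test_tiny_radius_is_delta_at_nearest_cell(self):
        side = 8
        rng = np.random.default_rng(0)
        m = rng.random((1, side, side))
        # cell centers: x = -4.2 + 1.05*(j+0.5); pick cell (i=2, j=5)
        x = -4.2 + 1.05 * 5.5
        y = 4.2 - 1.05 * 2.5
        out = ns.pool_features(ns.FeatureMapStack((m,)),
                               ns.PoolingField((x, y), 0.005))
        assert out[0] == pytest.approx(m[0, 2, 5], abs=1e-9)

    def test_hand_summed_3x3(self):
        field = ns.PoolingField((0.0, 1.4), 0.2)
        m = np.arange(9, dtype=float).reshape(1, 3, 3)
        # manual: evaluate the Gaussian at the nine cell centers
        step = 8.4 / 3
        sig = 0.2 * 8.4
        acc = wsum = 0.0
        for i in range(3):
            for j in range(3):
                cx = -4.2 + step * (j + 0.5)
                cy = 4.2 - step * (i + 0.5)
                w = np.exp(-((cx - 0.0)**2 + (cy - 1.4)**2) / (2 * sig**2))
                wsum += w
                acc += w * m[0, i, j]
        out = ns.pool_features(ns.FeatureMapStack((m,)), field)
        assert out[0] == pytest.approx(acc / wsum, rel=1e-12)

    def test_pooled_value_within_map_range(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            m = rng.normal(size=(1, 8, 8))
            f = ns.PoolingField(tuple(rng.uniform(-4, 4, 2)),
                                rng.uniform(0.04, 0.4))
            v = ns.pool_features(ns.FeatureMapStack((m,)), f)[0]
            assert m.min() - 1e-12 <= v <= m.max() + 1e-12

    def test_one_by_one_passthrough(self):
        stack = ns.FeatureMapStack((np.array([[[7.5]], [[-2.0]]]),))
        out = ns.pool_features(stack, ns.PoolingField((3.0, 3.0), 0.04))
        np.testing.assert_allclose(out, [7.5, -2.0])


# ---------------------------------------------------------------------------
# hyperparameter grid
# ---------------------------------------------------------------------------

class TestHyperGrid:
    def test_full_scale_defaults(self):
        g = ns.build_hypergrid()
        assert len(g.radii) == 8
        assert g.radii[0] == pytest.approx(0.04, rel=1e-12)
        assert g.radii[-1] == pytest.approx(0.4, rel=1e-12)
        assert len(g.lambdas) == 9
        assert g.lambdas[0] == pytest.approx(1e3, rel=1e-12)
        assert g.lambdas[-1] == pytest.approx(1e7, rel=1e-12)
        # 1.4 deg lattice anchored at the center of an 8.4 deg field
        assert len(g.centers) == 49
        xs = sorted({c[0] for c in g.centers})
        assert np.allclose(np.diff(xs), 1.4)
        assert g.centers == tuple(sorted(g.centers))

    def test_two_point_grids_hit_endpoints_exactly(self):
        g = ns.build_hypergrid(n_radii=2, r_min=0.1, r_max=0.3,
                               n_lambdas=2, lam_min=1.0, lam_max=10.0)
        assert g.radii == (0.1, 0.3)
        assert g.lambdas == (1.0, 10.0)

    def test_log_spacing(self):
        g = ns.build_hypergrid()
        ratios = np.diff(np.log(g.radii))
        assert np.allclose(ratios, ratios[0])


# ---------------------------------------------------------------------------
# ridge
# ---------------------------------------------------------------------------

class TestRidge:
    def test_zero_penalty_matches_ols(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 4))
        y = rng.normal(size=30)
        w, b = ns.fit_ridge(X, y, 0.0)
        coef = np.linalg.lstsq(np.column_stack([X, np.ones(30)]), y,
                               rcond=None)[0]
        np.testing.assert_allclose(w, coef[:4], atol=1e-9)
        assert b == pytest.approx(coef[4], abs=1e-9)

    def test_infinite_penalty_shrinks_to_mean(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        w, b = ns.fit_ridge(X, y, 1e12)
        assert np.abs(w).max() < 1e-9
        assert b == pytest.approx(y.mean(), abs=1e-6)

    def test_matrix_oracle_4x2(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0], [0.0, 0.0]])
        y = np.array([2.0, 1.0, 3.0, 0.0])
        lam = 1.0
        # independent closed form on the centered system
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        w_exp = np.linalg.inv(Xc.T @ Xc + lam * np.eye(2)) @ Xc.T @ yc
        b_exp = y.mean() - X.mean(axis=0) @ w_exp
        w, b = ns.fit_ridge(X, y, lam)
        np.testing.assert_allclose(w, w_exp, rtol=1e-12)
        assert b == pytest.approx(b_exp, rel=1e-12)

    def test_normal_equations_residual(self):
        rng = np.random.default_rng(2)
        for lam in (1e-3, 1.0, 1e3):
            X = rng.normal(size=(40, 6))
            y = rng.normal(size=40)
            w, b = ns.fit_ridge(X, y, lam)
            Xc = X - X.mean(axis=0)
            lhs = (Xc.T @ Xc + lam * np.eye(6)) @ w
            rhs = Xc.T @ (y - y.mean())
            assert np.linalg.norm(lhs - rhs) <= 1e-8 * np.linalg.norm(rhs)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            ns.fit_ridge(np.array([[np.nan]]), np.array([1.0]), 1.0)


# ---------------------------------------------------------------------------
# prediction, group model, gradients
# ---------------------------------------------------------------------------

class TestPredict:
    def test_zero_weights_predict_bias(self, bank32, small_pool):
        m = gt_encoding_model(bank32, np.zeros(32), (0, 0), 0.2, bias=1.75)
        for im in small_pool.stimuli[:3]:
            assert ns.predict(m, im) == pytest.approx(1.75)

    def test_unselected_channels_ignored(self, bank32):
        sel = np.array([1, 5, 20])
        m = ns.EncodingModel(bank_id=bank32.bank_id, selected_channels=sel,
                             field=ns.PoolingField((0, 0), 0.2),
                             weights=np.array([1.0, -2.0, 0.5]), bias=0.1,
                             bank=bank32)
        rng = np.random.default_rng(0)
        levels = [rng.random((1, c, s, s)) for c, s, _ in
                  ((16, 8, 0), (12, 4, 0), (4, 1, 0))]
        base = m.predict_from_levels(levels)[0]
        perturbed = [lv.copy() for lv in levels]
        perturbed[0][:, 0] += 100.0      # channel 0 is not selected
        perturbed[2][:, 2] -= 50.0       # global channel 30, not selected
        assert m.predict_from_levels(perturbed)[0] == pytest.approx(base)

    def test_hand_dot_product_two_channels(self, bank32, small_pool):
        sel = np.array([3, 17])
        w = np.array([0.5, -1.25])
        fld = ns.PoolingField((1.0, 0.5), 0.18)
        m = ns.EncodingModel(bank_id=bank32.bank_id, selected_channels=sel,
                             field=fld, weights=w, bias=0.4, bank=bank32)
        im = small_pool.stimuli[5]
        pooled = ns.pool_features(ns.extract_features(im, bank32), fld)
        expected = w @ pooled[sel] + 0.4
        assert ns.predict(m, im) == pytest.approx(expected, rel=1e-6)

    def test_unattached_bank_rejected(self, bank32):
        m = gt_encoding_model(bank32, np.zeros(32), (0, 0), 0.2)
        m.bank = None
        with pytest.raises(ValueError, match="not attached"):
            ns.predict(m, np.zeros((32, 32)))


class TestGroupModel:
    def _bias_model(self, bank, bias, region="R"):
        return gt_encoding_model(bank, np.zeros(bank.n_channels_total),
                                 (0, 0), 0.2, bias=bias, region=region)

    def test_mean_of_predictions(self, bank32):
        g = ns.make_group_model([self._bias_model(bank32, 1.0),
                                 self._bias_model(bank32, 3.0)])
        assert ns.predict(g, np.zeros((32, 32))) == pytest.approx(2.0)

    def test_identical_members_equal_single(self, bank32, gt_model,
                                            small_pool):
        g = ns.make_group_model([gt_model] * 4)
        im = small_pool.stimuli[1]
        assert ns.predict(g, im) == pytest.approx(ns.predict(gt_model, im))

    def test_mixed_regions_rejected(self, bank32):
        with pytest.raises(ValueError, match="mixed regions"):
            ns.make_group_model([self._bias_model(bank32, 0, "A"),
                                 self._bias_model(bank32, 0, "B")])


class TestPixelGradient:
    def test_directional_derivative(self, bank32, gt_model, small_pool):
        px = small_pool.stimuli[0].pixels
        _, grad = ns.predict_and_grad(gt_model, px[None])
        rng = np.random.default_rng(4)
        eps = 1e-3
        for _ in range(3):
            d = rng.standard_normal(px.shape)
            d /= np.linalg.norm(d)
            fd = (gt_model.predict_batch((px + eps * d)[None])[0]
                  - gt_model.predict_batch((px - eps * d)[None])[0]) / (2 * eps)
            an = float((grad[0] * d).sum())
            assert an == pytest.approx(fd, rel=2e-2, abs=1e-5)

    def test_forward_value_consistent(self, gt_model, small_pool):
        px = np.asarray([s.pixels for s in small_pool.stimuli[:4]])
        pred, _ = ns.predict_and_grad(gt_model, px)
        np.testing.assert_allclose(pred, gt_model.predict_batch(px),
                                   rtol=1e-10)


# ---------------------------------------------------------------------------
# grid search
# ---------------------------------------------------------------------------

def _toy_training_data(bank, seed=0, n_train=40, n_val=12):
    pool = sd.make_pool(1, n_train, n_val, 4, seed=seed, side=bank.image_side)
    rng = np.random.default_rng(seed + 1)
    spec = sd.VirtualSubjectSpec(
        "gt", rng.standard_normal(bank.n_channels_total), (0.7, -0.7), 0.12,
        noise_sd=0.0)
    table = sd.simulate_responses([spec], pool.stimuli, "R", 1, bank, seed=2)
    resp = table.set_index("image_id")["response"]
    tr, va = pool.unique, pool.shared
    return (tr, resp.loc[[s.image_id for s in tr]].to_numpy()), \
           (va, resp.loc[[s.image_id for s in va]].to_numpy()), spec


class TestGridSearch:
    def test_equals_bruteforce_oracle_small_grid(self, bank32):
        train, val, _ = _toy_training_data(bank32, seed=5)
        grid = ns.HyperGrid(centers=((-0.7, 0.7), (0.0, 0.0), (0.7, -0.7)),
                            radii=(0.08, 0.2), lambdas=(1e-4, 1e-1))
        model = ns.grid_search_fit(train, val, bank32, 32, grid)
        # independent exhaustive loop over all combinations
        tr_levels = fwrf._extract_batch(
            np.asarray([s.pixels for s in train[0]]), bank32)
        va_levels = fwrf._extract_batch(
            np.asarray([s.pixels for s in val[0]]), bank32)
        best = (-np.inf, None)
        for ir, rad in enumerate(grid.radii):
            for il, lam in enumerate(grid.lambdas):
                for ic, center in enumerate(grid.centers):
                    fld = ns.PoolingField(center, rad)
                    Xtr = fwrf._pool_batch(tr_levels, fld)
                    Xva = fwrf._pool_batch(va_levels, fld)
                    w, b = ns.fit_ridge(Xtr, train[1], lam)
                    r = sps.pearsonr(Xva @ w + b, val[1])[0]
                    if r > best[0]:
                        best = (r, (center, rad, lam))
        center, rad, lam = best[1]
        assert model.field.center == center
        assert model.field.radius == rad
        assert model.val_accuracy == pytest.approx(best[0], abs=1e-9)

    def test_validation_too_small_rejected(self, bank32):
        train, val, _ = _toy_training_data(bank32, seed=6)
        grid = ns.HyperGrid(centers=((0.0, 0.0),), radii=(0.1, 0.2),
                            lambdas=(1e-3, 1e-1))
        with pytest.raises(ValueError, match="at least 3"):
            ns.grid_search_fit(train, (val[0][:2], val[1][:2]), bank32, 32,
                               grid)

    def test_overlapping_train_val_rejected(self, bank32):
        train, val, _ = _toy_training_data(bank32, seed=7)
        with pytest.raises(ValueError, match="share image ids"):
            ns.grid_search_fit(train, train, bank32, 32,
                               ns.HyperGrid(((0.0, 0.0),), (0.1, 0.2),
                                            (1e-3, 1e-1)))


def test_noiseless_recovery_on_grid(bank32):
    """Ground truth placed on the grid is recovered exactly with r ~ 1."""
    grid = ns.desk_hypergrid()
    true_center = grid.centers[30]
    true_radius = grid.radii[4]
    pool = sd.make_pool(1, 50, 15, 4, seed=9, side=32)
    rng = np.random.default_rng(10)
    spec = sd.VirtualSubjectSpec("gt", rng.standard_normal(32), true_center,
                                 true_radius, noise_sd=0.0)
    table = sd.simulate_responses([spec], pool.stimuli, "R", 1, bank32,
                                  seed=3)
    resp = table.set_index("image_id")["response"]
    tr, va = pool.unique, pool.shared
    model = ns.grid_search_fit(
        (tr, resp.loc[[s.image_id for s in tr]].to_numpy()),
        (va, resp.loc[[s.image_id for s in va]].to_numpy()),
        bank32, 32, grid)
    assert model.field.center == true_center
    assert model.field.radius == true_radius
    assert model.val_accuracy >= 0.999


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def test_model_roundtrip(tmp_path, bank32, small_pool):
    rng = np.random.default_rng(8)
    m = ns.EncodingModel(
        bank_id=bank32.bank_id, selected_channels=np.array([0, 4, 9]),
        field=ns.PoolingField((1.4, -1.4), 0.12),
        weights=rng.normal(size=3), bias=0.3, region="FFA1",
        subject_id="base00", val_accuracy=0.91, bank=bank32)
    path = str(tmp_path / "m.h5")
    ns.save_encoding_model(m, path)
    loaded = ns.load_encoding_model(path)
    assert loaded.region == "FFA1" and loaded.subject_id == "base00"
    assert loaded.val_accuracy == pytest.approx(0.91)
    im = small_pool.stimuli[2]
    assert ns.predict(loaded, im) == pytest.approx(ns.predict(m, im))
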