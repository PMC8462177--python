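"""Split-sample protocol, TSS evaluation, ensemble logic and habitat accounting."""

import numpy as np
import pandas as pd
import pytest

from edelweiss.geodata import GridSpec, Raster
from edelweiss.sdm import (
    MemberModel,
    apply_masks,
    build_ensemble,
    fit_member,
    fit_sdm,
    habitat_summary,
    net_loss,
    permutation_importance,
    predict_map,
    response_curve,
    split_sample,
    tss,
    tss_from_confusion,
)


class TestSplitSample:
    def test_80_20_partition_sizes(self):
        y = np.r_[np.ones(20), np.zeros(80)]
        splits = split_sample(y, calib_frac=0.8, reps=10, seed=0)
        assert len(splits) == 11
        for calib, evl in splits[:-1]:
            assert len(calib) == 80 and len(evl) == 20
            assert set(calib) | set(evl) == set(range(100))
            assert not set(calib) & set(evl)
            # stratified: both classes in both parts
            assert y[calib].sum() == 16 and y[evl].sum() == 4

    def test_full_data_entry_last(self):
        y = np.r_[np.ones(5), np.zeros(15)]
        calib, evl = split_sample(y, reps=3, seed=0)[-1]
        assert len(calib) == 20 and len(evl) == 0

    def test_frac_one_means_empty_evaluation(self):
        y = np.r_[np.ones(5), np.zeros(15)]
        for calib, evl in split_sample(y, calib_frac=1.0, reps=2, seed=0):
            assert len(evl) == 0

    def test_seed_determinism(self):
        y = np.r_[np.ones(30), np.zeros(70)]
        s1 = split_sample(y, reps=5, seed=3)
        s2 = split_sample(y, reps=5, seed=3)
        s3 = split_sample(y, reps=5, seed=4)
        for (a1, b1), (a2, b2) in zip(s1, s2):
            np.testing.assert_array_equal(a1, a2)
            np.testing.assert_array_equal(b1, b2)
        assert any(
            not np.array_equal(a1, a3) for (a1, _), (a3, _) in zip(s1[:-1], s3[:-1])
        )

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="both classes"):
            split_sample(np.ones(10))


class TestTss:
    def test_perfect_ranking_scores_one(self):
        scores = np.r_[np.linspace(0.6, 1, 10), np.linspace(0, 0.4, 10)]
        labels = np.r_[np.ones(10), np.zeros(10)]
        t, thr = tss(scores, labels)
        assert t == pytest.approx(1.0)
        assert 0.4 < thr <= 0.6

    def test_hand_computed_confusion(self):
        # TP 45, FN 5, TN 40, FP 10 -> sens 0.9, spec 0.8, TSS 0.7
        assert tss_from_confusion(45, 5, 40, 10) == pytest.approx(0.7)
        # same confusion realized at threshold 0.5 by construction
        scores = np.r_[np.full(45, 0.9), np.full(5, 0.1), np.full(40, 0.1), np.full(10, 0.9)]
        labels = np.r_[np.ones(50), np.zeros(50)]
        t, _ = tss(scores, labels)
        assert t == pytest.approx(0.7)

    def test_no_skill_limit(self):
        rng = np.random.default_rng(0)
        n = 10_000
        scores = rng.uniform(size=n)
        labels = rng.integers(0, 2, n)
        t, _ = tss(scores, labels)
        assert abs(t) < 0.1

    def test_smallest_argmax_threshold(self):
        scores = np.array([0.1, 0.4, 0.6, 0.9])
        labels = np.array([0, 0, 1, 1])
        _, thr = tss(scores, labels)
        assert thr == pytest.approx(0.5)  # midpoint, smallest of the arg-max set

    def test_one_class_raises(self):
        with pytest.raises(ValueError, match="both classes"):
            tss(np.arange(4) / 4, np.ones(4))


class TestMembers:
    def test_unknown_learner_lists_registry(self):
        with pytest.raises(KeyError, match="glm"):
            fit_member("nope", np.zeros((4, 1)), np.array([0, 1, 0, 1]))

    def test_sre_member_scores_presences_inside(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 2))
        y = np.r_[np.ones(20), np.zeros(20)].astype(int)
        X[y == 0] += 10  # absences far outside
        model = fit_member("sre", X, y, q=1.0)
        assert (model.predict_prob(X[y == 1]) == 1.0).all()

    def test_logistic_separable_tss_one(self):
        rng = np.random.default_rng(2)
        x = np.r_[rng.normal(3, 0.3, 30), rng.normal(-3, 0.3, 30)]
        X = x[:, None]
        y = np.r_[np.ones(30), np.zeros(30)].astype(int)
        model = fit_member("glm", X, y)
        t, _ = tss(model.predict_prob(X), y)
        assert t == pytest.approx(1.0)

    def test_gbm_seed_determinism(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 3))
        y = (X[:, 0] > 0).astype(int)
        p1 = fit_member("gbm", X, y, seed=5).predict_prob(X)
        p2 = fit_member("gbm", X, y, seed=5).predict_prob(X)
        np.testing.assert_array_equal(p1, p2)


def _const_member(tss_val, value=0.5):
    class _C:
        def predict_prob(self, X):
            return np.full(len(X), value)

    return MemberModel("const", _C(), tss_val, 0.5, rep=0)


class TestEnsemble:
    def test_cutoff_is_strict_080(self):
        members = [_const_member(0.79), _const_member(0.81)]
        ens = build_ensemble(members, tss_min=0.80)
        assert len(ens.members) == 1 and ens.members[0].tss == 0.81

    def test_single_member_identity(self):
        m = _const_member(0.9, value=0.37)
        ens = build_ensemble([m], tss_min=0.8)
        np.testing.assert_allclose(ens.predict_prob(np.zeros((5, 1))), 0.37)

    def test_mean_of_two_members(self):
        ens = build_ensemble(
            [_const_member(0.9, 0.2), _const_member(0.95, 0.8)], tss_min=0.8
        )
        np.testing.assert_allclose(ens.predict_prob(np.zeros((3, 1))), 0.5)

    def test_no_qualifier_reports_best(self):
        with pytest.raises(ValueError, match="0.790"):
            build_ensemble([_const_member(0.79)], tss_min=0.80)

    def test_prediction_bounded_by_members(self, occ_dataset):
        data, _, preds = occ_dataset
        ens, _ = fit_sdm(data, preds, learners=["glm", "sre"], reps=3, seed=0, tss_min=0.5)
        X = data[preds].to_numpy()
        stack = np.column_stack([m.predict_prob(X) for m in ens.members])
        p = ens.predict_prob(X)
        assert np.all(p >= stack.min(axis=1) - 1e-12)
        assert np.all(p <= stack.max(axis=1) + 1e-12)


class TestFitSdm:
    def test_calibration_tss_nonnegative_and_truth_ranking(self, occ_dataset, truth, landscape):
        from edelweiss import synthetic
        from scipy.stats import spearmanr

        data, _, preds = occ_dataset
        ens, members = fit_sdm(data, preds, learners=["glm", "rf"], reps=5, seed=1)
        y = (data["label"] == "presence").to_numpy().astype(int)
        t, _ = tss(ens.predict_prob(data), y)
        assert t >= 0
        # cell-wise ranking against the generative occupancy surface
        p_map = predict_map(ens, {p: landscape[p] for p in preds})
        p_true = synthetic.true_occupancy(truth, landscape)
        ok = np.isfinite(p_map.values) & np.isfinite(p_true.values)
        assert ok.sum() >= 2500
        rho = spearmanr(p_map.values[ok], p_true.values[ok]).statistic
        assert rho > 0.7

    def test_presence_cells_score_higher(self, occ_dataset, landscape):
        data, _, preds = occ_dataset
        ens, _ = fit_sdm(data, preds, learners=["glm"], reps=3, seed=2)
        p_map = predict_map(ens, {p: landscape[p] for p in preds})
        pres = data[data["label"] == "presence"]
        absn = data[data["label"] == "pseudo_absence"]
        mean_pres = np.nanmean(p_map.values[pres["row"], pres["col"]])
        mean_abs = np.nanmean(p_map.values[absn["row"], absn["col"]])
        assert mean_pres > mean_abs


@pytest.fixture(scope="module")
def signal_ensemble():
    rng = np.random.default_rng(4)
    n = 400
    x1 = rng.normal(size=n)
    x2 = rng.normal(size=n)  # pure noise
    y = (x1 + 0.1 * rng.normal(size=n) > 0).astype(int)
    data = pd.DataFrame(
        {"x1": x1, "x2": x2, "label": np.where(y == 1, "presence", "pseudo_absence")}
    )
    ens, _ = fit_sdm(data, ["x1", "x2"], learners=["glm"], reps=3, seed=0, tss_min=0.5)
    return ens, data


class TestInterpretation:
    def test_unused_predictor_near_zero(self, signal_ensemble):
        ens, data = signal_ensemble
        assert permutation_importance(ens, data, "x2", n_perm=5, seed=0) < 0.05

    def test_informative_predictor_dominates(self, signal_ensemble):
        ens, data = signal_ensemble
        i1 = permutation_importance(ens, data, "x1", n_perm=5, seed=0)
        i2 = permutation_importance(ens, data, "x2", n_perm=5, seed=0)
        assert i1 > 0.5 and i1 > i2

    def test_seed_determinism(self, signal_ensemble):
        ens, data = signal_ensemble
        a = permutation_importance(ens, data, "x1", n_perm=5, seed=7)
        b = permutation_importance(ens, data, "x1", n_perm=5, seed=7)
        assert a == b

    def test_unknown_predictor_raises(self, signal_ensemble):
        ens, data = signal_ensemble
        with pytest.raises(KeyError):
            permutation_importance(ens, data, "zz", seed=0)

    def test_response_curve_monotone_and_bounded(self, signal_ensemble):
        from scipy.stats import spearmanr

        ens, data = signal_ensemble
        grid = np.linspace(data["x1"].min(), data["x1"].max(), 25)
        curve = response_curve(ens, data, "x1", grid)
        assert ((curve["prediction"] >= 0) & (curve["prediction"] <= 1)).all()
        rho = spearmanr(curve["x1"], curve["prediction"]).statistic
        assert rho > 0.9

    def test_constant_ensemble_flat_curve(self):
        ens = build_ensemble([_const_member(0.9, 0.4)], tss_min=0.8, predictors=["a"],
                             training_means={"a": 0.0})
        curve = response_curve(ens, pd.DataFrame({"a": [0.0, 1.0]}), "a", np.linspace(-1, 1, 5))
        assert np.allclose(curve["prediction"], 0.4)


class TestMaps:
    def _ensemble(self):
        return build_ensemble([_const_member(0.9, 0.6)], tss_min=0.8, predictors=["a"],
                              training_means={"a": 0.0})

    def test_constant_inputs_constant_map(self, small_spec):
        ens = self._ensemble()
        r = Raster(small_spec, np.full(small_spec.shape, 1.0), "a")
        out = predict_map(ens, {"a": r})
        assert np.allclose(out.values, 0.6)

    def test_nodata_propagates(self, small_spec):
        ens = self._ensemble()
        z = np.ones(small_spec.shape)
        z[2, 3] = np.nan
        out = predict_map(ens, {"a": Raster(small_spec, z, "a")})
        assert np.isnan(out.values[2, 3])
        assert np.isfinite(np.delete(out.values.ravel(), 2 * 6 + 3)).all()

    def test_misaligned_rasters_raise(self, small_spec):
        ens = build_ensemble([_const_member(0.9)], tss_min=0.8, predictors=["a", "b"])
        other = GridSpec(4, 4, 0, 40, 10)
        with pytest.raises(ValueError, match="aligned"):
            predict_map(
                ens,
                {"a": Raster(small_spec, np.ones(small_spec.shape)),
                 "b": Raster(other, np.ones((4, 4)))},
            )


class TestMasksAndHabitat:
    def test_permissive_masks_identity(self, small_spec):
        prob = Raster(small_spec, np.full(small_spec.shape, 0.7))
        ones = Raster(small_spec, np.ones(small_spec.shape))
        out, removed = apply_masks(prob, ones, ones, Raster(small_spec, np.full(small_spec.shape, 1000.0)))
        np.testing.assert_allclose(out.values, prob.values)
        assert all(v == 0 for v in removed.values())

    def test_altitude_just_below_394_all_removed(self, small_spec):
        prob = Raster(small_spec, np.full(small_spec.shape, 0.7))
        alt = Raster(small_spec, np.full(small_spec.shape, 393.9))
        out, removed = apply_masks(prob, altitude=alt)
        assert np.isnan(out.values).all()
        assert removed["altitude"] == small_spec.n_rows * small_spec.n_cols

    def test_altitude_394_exactly_kept(self, small_spec):
        prob = Raster(small_spec, np.full(small_spec.shape, 0.7))
        alt = Raster(small_spec, np.full(small_spec.shape, 394.0))
        out, _ = apply_masks(prob, altitude=alt)
        assert np.isfinite(out.values).all()

    def test_substrate_half_grid(self, small_spec):
        prob = Raster(small_spec, np.full(small_spec.shape, 0.7))
        m = np.ones(small_spec.shape)
        m[:, :3] = 0
        out, removed = apply_masks(prob, substrate_mask=Raster(small_spec, m))
        assert removed["substrate"] == 15
        assert np.isnan(out.values[:, :3]).all() and np.isfinite(out.values[:, 3:]).all()

    def test_idempotent_and_order_independent(self, small_spec):
        rng = np.random.default_rng(8)
        prob = Raster(small_spec, rng.uniform(0, 1, small_spec.shape))
        sub = Raster(small_spec, (rng.uniform(size=small_spec.shape) > 0.3).astype(float))
        lc = Raster(small_spec, (rng.uniform(size=small_spec.shape) > 0.2).astype(float))
        alt = Raster(small_spec, rng.uniform(300, 500, small_spec.shape))
        once, _ = apply_masks(prob, sub, lc, alt)
        twice, _ = apply_masks(once, sub, lc, alt)
        np.testing.assert_array_equal(once.values, twice.values)
        # order across masks: apply one then the other vs both at once
        a, _ = apply_masks(prob, substrate_mask=sub)
        ab, _ = apply_masks(a, landcover_mask=lc)
        both, _ = apply_masks(prob, substrate_mask=sub, landcover_mask=lc)
        np.testing.assert_array_equal(ab.values, both.values)

    def test_habitat_strict_inequality_at_threshold(self, small_spec):
        prob = Raster(small_spec, np.full(small_spec.shape, 0.5))
        assert habitat_summary(prob, p_min=0.5).n_cells == 0

    def test_habitat_count_and_area(self):
        spec = GridSpec(10, 10, 0, 100, 10)
        vals = np.full((10, 10), 0.2)
        vals.ravel()[:65] = 0.9
        summ = habitat_summary(Raster(spec, vals), p_min=0.5, cell_area_km2=2.0)
        assert summ.n_cells == 65
        assert summ.area_km2 == 130.0

    def test_habitat_matches_loop_oracle(self, random_raster):
        prob = random_raster.copy_with(random_raster.values / 100.0)
        prob.values[1, 1] = np.nan
        summ = habitat_summary(prob, p_min=0.5)
        count = sum(
            1
            for r in range(prob.spec.n_rows)
            for c in range(prob.spec.n_cols)
            if np.isfinite(prob.values[r, c]) and prob.values[r, c] > 0.5
        )
        assert summ.n_cells == count

    def test_net_loss_arithmetic(self, small_spec):
        mk = lambda n: habitat_summary(
            Raster(small_spec, np.where(np.arange(30).reshape(5, 6) < n, 0.9, 0.1)), p_min=0.5
        )
        assert net_loss(mk(20), mk(13)) == pytest.approx(100 * 7 / 20)
        assert net_loss(mk(10), mk(10)) == 0.0
        assert net_loss(mk(10), mk(15)) == pytest.approx(-50.0)
        with pytest.raises(ValueError, match="empty"):
            net_loss(mk(0), mk(5))
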