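import numpy as np
import pytest

from sml.chemdata import Dataset
from sml.classify import ClassLabel
from sml.krr import HyperGrid
from sml.protocol import (
    DeltaSpec,
    LearningCurve,
    SplitSpec,
    delta_predict,
    delta_train,
    fit_loglog,
    make_splits,
    run_learning_curve,
    run_sml_comparison,
    scatter_table,
)
from sml.synthetic import GeneratorParams, make_benchmark

SIZES = (8, 16, 32)


def _spec(**kw):
    base = dict(train_sizes=SIZES, test_size_per_class=30, repetitions=3, seed=11)
    base.update(kw)
    return SplitSpec(**base)


class TestSplits:
    def test_disjoint_and_nested(self, small_bench):
        b = small_bench
        splits = make_splits(b.dataset.ids, _spec(), b.class_map)
        assert len(splits) == 3
        for split in splits:
            test_all = {i for ids in split.test.values() for i in ids}
            for n in SIZES:
                assert not test_all & set(split.generic[n])
                for c in split.selected:
                    assert not test_all & set(split.selected[c][n])
                    assert all(b.class_map[i] == c for i in split.selected[c][n])
            for small, large in zip(SIZES, SIZES[1:]):
                assert set(split.generic[small]) <= set(split.generic[large])
                for c in split.selected:
                    assert set(split.selected[c][small]) <= set(split.selected[c][large])

    def test_same_seed_identical(self, small_bench):
        b = small_bench
        s1 = make_splits(b.dataset.ids, _spec(), b.class_map)
        s2 = make_splits(b.dataset.ids, _spec(), b.class_map)
        assert s1[0].generic == s2[0].generic
        assert s1[-1].test == s2[-1].test

    def test_capacity_error_names_class(self, small_bench):
        b = small_bench
        with pytest.raises(ValueError, match="class I"):
            make_splits(b.dataset.ids, _spec(train_sizes=(1000,)), b.class_map)

    def test_sizes_must_increase(self):
        with pytest.raises(ValueError):
            SplitSpec(train_sizes=(32, 16))


class TestLearningCurve:
    def test_generic_curve_decreases(self, small_bench):
        b = small_bench
        splits = make_splits(b.dataset.ids, _spec(), b.class_map)
        curve = run_learning_curve(b.dataset, None, splits, ("gap", "target"),
                                   representations=b.X)
        assert curve.sizes == list(SIZES)
        # consistency: within one sd, MAE does not grow with training size
        for i in range(len(SIZES) - 1):
            assert curve.mae_mean[i + 1] <= curve.mae_mean[i] + curve.mae_sd[i]

    def test_single_size(self, small_bench):
        b = small_bench
        splits = make_splits(b.dataset.ids, _spec(train_sizes=(16,)), b.class_map)
        curve = run_learning_curve(b.dataset, None, splits, ("gap", "target"),
                                   representations=b.X)
        assert len(curve.mae_mean) == 1

    def test_determinism(self, small_bench):
        b = small_bench
        splits = make_splits(b.dataset.ids, _spec(), b.class_map)
        c1 = run_learning_curve(b.dataset, None, splits, ("gap", "target"),
                                representations=b.X)
        c2 = run_learning_curve(b.dataset, None, splits, ("gap", "target"),
                                representations=b.X)
        assert np.allclose(c1.mae_mean, c2.mae_mean, atol=1e-10)

    def test_negative_mae_rejected(self):
        with pytest.raises(ValueError):
            LearningCurve(sizes=[8], mae_mean=[-0.1], mae_sd=[0.0])


class TestSmlComparison:
    def test_selected_beats_generic_per_class(self, small_bench):
        b = small_bench
        pairs = run_sml_comparison(b.dataset, None, _spec(), ("gap", "target"),
                                   class_map=b.class_map, representations=b.X)
        assert set(pairs) == set(ClassLabel)
        for c, (generic, selected) in pairs.items():
            assert generic.selection == "generic" and selected.selection == "selected"
            assert np.mean(selected.mae_mean) < np.mean(generic.mae_mean)

    def test_identical_test_sets_feed_both_models(self, small_bench):
        b = small_bench
        splits = make_splits(b.dataset.ids, _spec(), b.class_map)
        # the protocol contract is in the split itself: one test set per
        # (repetition, class), shared by construction between modes
        for split in splits:
            for c, ids in split.test.items():
                assert len(ids) == 30
                assert len(set(ids)) == 30

    def test_single_class_pool_no_advantage(self):
        """With one class, generic and selected draw from the same pool, so
        their paired MAE difference is statistically indistinguishable."""
        b = make_benchmark(GeneratorParams(n_per_class=(150, 1, 1), seed=23))
        keep = [m.id for m in b.dataset.molecules if b.class_map[m.id] is ClassLabel.I_SATURATED]
        mols = [b.dataset.molecule(i) for i in keep]
        sub = Dataset(
            molecules=mols,
            records={k: r for k, r in b.dataset.records.items() if k[0] in set(keep)},
        )
        pos = {mid: i for i, mid in enumerate(b.dataset.ids)}
        X = b.X[[pos[i] for i in keep]]
        spec = SplitSpec(train_sizes=(16, 32), test_size_per_class=40,
                         repetitions=6, seed=5)
        pairs = run_sml_comparison(sub, None, spec, ("gap", "target"),
                                   class_map={i: ClassLabel.I_SATURATED for i in keep},
                                   representations=X)
        generic, selected = pairs[ClassLabel.I_SATURATED]
        for g, s, sd in zip(generic.mae_mean, selected.mae_mean, generic.mae_sd):
            assert abs(g - s) <= 2 * max(sd, 1e-6)


class TestDelta:
    def test_identical_levels_give_zero_correction(self, small_bench):
        b = small_bench
        ds = b.dataset
        ids = ds.ids[:40]
        # clone the target level under a new name
        from sml.chemdata import PropertyRecord
        for mid in ds.ids:
            r = ds.record(mid, "target")
            ds.add_record(PropertyRecord(mid, "copy", homo=r.homo, lumo=r.lumo, gap=r.gap))
        model = delta_train(ds, None, ids, DeltaSpec("copy", "target"), 64.0,
                            representations=b.X)
        assert np.allclose(model.alpha, 0.0)
        te = np.arange(50, 90)
        est = delta_predict(model, b.X[te],
                            ds.values("gap", "copy", [ds.ids[i] for i in te]))
        ref = ds.values("gap", "target", [ds.ids[i] for i in te])
        assert np.max(np.abs(est - ref)) <= 1e-10

    def test_constant_offset_learned(self, small_bench):
        b = small_bench
        p = GeneratorParams(n_per_class=(100, 100, 100), baseline_noise_sd=0.0, seed=11)
        from sml.chemdata import PropertyRecord
        from sml.synthetic import gen_two_level
        ds = b.dataset
        targets = [ds.record(mid, "target") for mid in ds.ids]
        for rec in gen_two_level(targets, p, level="shifted"):
            ds.add_record(rec)
        grid = HyperGrid(sigmas=tuple(float(4**k) for k in range(2, 14)))
        train = ds.ids[::9][:32]
        model = delta_train(ds, None, train, DeltaSpec("shifted", "target"), grid,
                            representations=b.X)
        te = np.arange(0, 290, 3)
        te_ids = [ds.ids[i] for i in te]
        est = delta_predict(model, b.X[te], ds.values("gap", "shifted", te_ids))
        ref = ds.values("gap", "target", te_ids)
        assert np.mean(np.abs(est - ref)) < 1e-4

    def test_correlated_baseline_beats_direct(self, small_bench):
        from sml.krr import krr_predict, krr_train, select_sigma
        b = small_bench
        ds = b.dataset
        grid = HyperGrid(sigmas=tuple(float(4**k) for k in range(2, 14)))
        gt = ds.values("gap", "target")
        assert np.corrcoef(gt, ds.values("gap", "baseline"))[0, 1] > 0.99
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(ds.ids))
        te = perm[64:214]
        te_ids = [ds.ids[i] for i in te]
        for n in (16, 32, 64):
            tr = perm[:n]
            tr_ids = [ds.ids[i] for i in tr]
            model = delta_train(ds, None, tr_ids, DeltaSpec("baseline", "target"),
                                grid, representations=b.X)
            est = delta_predict(model, b.X[te], ds.values("gap", "baseline", te_ids))
            delta_mae = np.mean(np.abs(est - gt[te]))
            sigma = select_sigma(b.X[tr], gt[tr], grid)
            direct = krr_predict(krr_train(b.X[tr], gt[tr], sigma), b.X[te])
            direct_mae = np.mean(np.abs(direct - gt[te]))
            assert delta_mae < direct_mae

    def test_missing_level_error(self, small_bench):
        b = small_bench
        with pytest.raises(ValueError, match="ZINDO"):
            delta_train(b.dataset, None, b.dataset.ids[:8],
                        DeltaSpec("ZINDO", "target"), 16.0, representations=b.X)


class TestLogLogFit:
    def test_exact_power_law(self):
        sizes = [16, 32, 64, 128]
        curve = LearningCurve(sizes=sizes,
                              mae_mean=[2.0 * n**-0.3 for n in sizes],
                              mae_sd=[0.0] * 4)
        offset, slope = fit_loglog(curve)
        assert slope == pytest.approx(-0.3, abs=1e-12)
        assert offset == pytest.approx(np.log10(2.0), abs=1e-12)

    def test_two_points_interpolate(self):
        curve = LearningCurve(sizes=[10, 100], mae_mean=[1.0, 0.1], mae_sd=[0, 0])
        offset, slope = fit_loglog(curve)
        assert slope == pytest.approx(-1.0)
        assert offset == pytest.approx(1.0)

    def test_recovers_slope_under_noise(self):
        rng = np.random.default_rng(12)
        sizes = [16, 32, 64, 128, 256, 512]
        slopes = []
        for _ in range(10):
            mae = 1.5 * np.asarray(sizes, float) ** -0.4 * np.exp(rng.normal(0, 0.02, 6))
            curve = LearningCurve(sizes=sizes, mae_mean=list(mae), mae_sd=[0.0] * 6)
            slopes.append(fit_loglog(curve)[1])
        assert np.mean(slopes) == pytest.approx(-0.4, abs=0.05)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            fit_loglog(LearningCurve(sizes=[8], mae_mean=[0.5], mae_sd=[0.0]))
        curve = LearningCurve(sizes=[8, 16], mae_mean=[0.5, 0.0], mae_sd=[0, 0])
        with pytest.raises(ValueError):
            fit_loglog(curve)


class TestScatterTable:
    def test_outlier_flagging(self):
        ids = [f"m{i}" for i in range(10)]
        cmap = {i: ClassLabel.I_SATURATED for i in ids}
        y_ref = np.zeros(10)
        y_pred = np.full(10, 0.1)
        y_pred[0] = 5.0  # gross outlier
        df = scatter_table(ids, y_ref, y_pred, cmap, "generic")
        assert bool(df.outlier[0]) is True
        assert df.outlier[1:].sum() == 0
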