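"""Data-model behaviour: normalisation, splits, subsampling, standardisation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from enoseda.datamodel import (
    ENoseMeasurement,
    LabeledDataset,
    SplitSpec,
    apply_standardizer,
    day_wise_split,
    fit_standardizer,
    instance_normalize,
    read_csv,
    read_hdf5,
    stratified_subsample,
    stratified_validation_split,
    write_csv,
    write_hdf5,
    write_split_manifest,
    read_split_manifest,
)
from conftest import make_dataset


def _measurement(values, label=0, day=1, domain="target", sid="m0"):
    return ENoseMeasurement(values, sid, label, domain, day)


class TestENoseMeasurement:
    def test_shape_enforced(self):
        with pytest.raises(ValueError, match="shape"):
            _measurement(np.zeros((10, 100)))

    def test_nonfinite_rejected(self):
        bad = np.zeros((10, 120))
        bad[3, 7] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            _measurement(bad)


class TestInstanceNormalize:
    def test_rows_become_zero_mean_unit_std(self):
        rng = np.random.default_rng(0)
        m = _measurement(rng.standard_normal((10, 120)) * 5 + 3)
        out = instance_normalize(m)
        np.testing.assert_allclose(out.values.mean(axis=1), 0, atol=1e-6)
        np.testing.assert_allclose(out.values.std(axis=1), 1, atol=1e-6)
        assert out.sample_id == m.sample_id and out.day == m.day

    def test_constant_channel_maps_to_zeros(self):
        values = np.ones((10, 120))
        values[2] = 5.0
        out = instance_normalize(_measurement(values))
        np.testing.assert_array_equal(out.values[2], np.zeros(120))

    def test_arithmetic_ramp_value(self):
        # channel t = 1..120: population std = sqrt((120^2 - 1)/12) = 34.63983,
        # so the final entry maps to (120 - 60.5)/34.63983 = 1.717677
        values = np.tile(np.arange(1.0, 121.0), (10, 1))
        out = instance_normalize(_measurement(values))
        std = np.sqrt((120.0**2 - 1.0) / 12.0)
        assert std == pytest.approx(34.639813, abs=1e-5)
        assert out.values[0, -1] == pytest.approx(59.5 / std, abs=1e-9)
        assert out.values[0, -1] == pytest.approx(1.717677, abs=1e-6)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        m = _measurement(rng.standard_normal((10, 120)) * rng.uniform(0.5, 10))
        once = instance_normalize(m)
        twice = instance_normalize(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-6)


class TestDayWiseSplit:
    @pytest.mark.parametrize("n_classes,expect_train,expect_test", [
        (6, 288, 72),   # 6 classes x 6/day x 10 days
        (8, 384, 96),   # 8 classes x 6/day x 10 days
    ])
    def test_target_preset_counts(self, n_classes, expect_train, expect_test):
        ds = make_dataset(n_classes=n_classes, per_class_per_day=6, n_days=10)
        spec = SplitSpec(set(range(1, 9)), {9, 10})
        train, test = day_wise_split(ds, spec)
        assert (len(train), len(test)) == (expect_train, expect_test)
        assert set(train.days) <= set(range(1, 9))
        assert set(test.days) == {9, 10}

    def test_empty_test_days_allowed(self):
        ds = make_dataset(n_days=2)
        train, test = day_wise_split(ds, SplitSpec({1, 2}, set()))
        assert len(train) == len(ds) and len(test) == 0

    def test_unassigned_day_errors_with_day_named(self):
        ds = make_dataset(n_days=3)
        with pytest.raises(ValueError, match="day 3"):
            day_wise_split(ds, SplitSpec({1}, {2}))

    def test_overlapping_day_sets_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            SplitSpec({1, 2}, {2, 3})


class TestStratifiedValidationSplit:
    def test_oolong_like_counts(self):
        # 288 samples, 48 per class over 6 classes, frac 0.2 -> 58 val / 230 fit
        ds = make_dataset(n_classes=6, per_class_per_day=6, n_days=8)
        fit, val = stratified_validation_split(ds, 0.2, seed=7)
        assert (len(fit), len(val)) == (230, 58)
        assert set(val.class_counts().values()) <= {9, 10}

    def test_half_split_of_two_per_class(self):
        ds = make_dataset(n_classes=4, per_class_per_day=2, n_days=1)
        fit, val = stratified_validation_split(ds, 0.5, seed=0)
        assert all(v == 1 for v in val.class_counts().values())

    def test_deterministic_and_disjoint(self):
        ds = make_dataset(n_classes=3, per_class_per_day=5, n_days=2)
        a = stratified_validation_split(ds, 0.25, seed=3)
        b = stratified_validation_split(ds, 0.25, seed=3)
        assert a[1].sample_ids == b[1].sample_ids
        assert not set(a[0].sample_ids) & set(a[1].sample_ids)
        assert sorted(a[0].sample_ids + a[1].sample_ids) == sorted(ds.sample_ids)

    @pytest.mark.parametrize("frac", [0.0, 1.0, -0.2])
    def test_invalid_fraction(self, frac):
        ds = make_dataset()
        with pytest.raises(ValueError):
            stratified_validation_split(ds, frac, seed=0)

    def test_single_sample_class_errors(self):
        m = [ENoseMeasurement(np.zeros((10, 120)), f"s{i}", i % 2, "target", 1)
             for i in range(3)]
        ds = LabeledDataset(m, ["a", "b"])
        with pytest.raises(ValueError, match="class"):
            stratified_validation_split(ds, 0.5, seed=0)


class TestStratifiedSubsample:
    # every Labeled-count cell of the label-efficiency design
    @pytest.mark.parametrize("n_classes,per_day,n_days,ratio,expected", [
        (6, 6, 8, 0.8, 230), (6, 6, 8, 0.6, 173),
        (6, 6, 8, 0.4, 115), (6, 6, 8, 0.2, 58),
        (8, 6, 8, 0.8, 307), (8, 6, 8, 0.6, 230),
        (8, 6, 8, 0.4, 154), (8, 6, 8, 0.2, 77),
    ])
    def test_retained_totals_match_round_half_up(self, n_classes, per_day,
                                                 n_days, ratio, expected):
        ds = make_dataset(n_classes=n_classes, per_class_per_day=per_day,
                          n_days=n_days)
        sub = stratified_subsample(ds, ratio, seed=0)
        assert len(sub) == expected
        counts = list(sub.class_counts().values())
        assert max(counts) - min(counts) <= 1

    def test_ratio_one_is_identity(self):
        ds = make_dataset()
        assert stratified_subsample(ds, 1.0, seed=5).sample_ids == ds.sample_ids

    def test_deterministic(self):
        ds = make_dataset(n_classes=5, per_class_per_day=7, n_days=2)
        a = stratified_subsample(ds, 0.6, seed=11)
        b = stratified_subsample(ds, 0.6, seed=11)
        assert a.sample_ids == b.sample_ids

    @pytest.mark.parametrize("ratio", [0.0, 1.5, -0.1])
    def test_invalid_ratio(self, ratio):
        with pytest.raises(ValueError):
            stratified_subsample(make_dataset(), ratio, seed=0)


class TestStandardizer:
    def test_hand_arithmetic(self):
        s = fit_standardizer(np.array([[0.0], [2.0]]))
        assert s.per_feature_mean[0] == 1.0 and s.per_feature_std[0] == 1.0
        np.testing.assert_allclose(apply_standardizer(s, np.array([[4.0]])), [[3.0]])

    def test_fit_set_becomes_zero_mean_unit_std(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((50, 7)) * 4 + 2
        s = fit_standardizer(x)
        z = apply_standardizer(s, x)
        np.testing.assert_allclose(z.mean(axis=0), 0, atol=1e-6)
        np.testing.assert_allclose(z.std(axis=0), 1, atol=1e-6)

    def test_constant_column_floored_to_zero(self):
        x = np.column_stack([np.ones(10), np.arange(10.0)])
        z = apply_standardizer(fit_standardizer(x), x)
        np.testing.assert_array_equal(z[:, 0], np.zeros(10))

    def test_feature_count_mismatch(self):
        s = fit_standardizer(np.zeros((3, 4)))
        with pytest.raises(ValueError, match="feature count"):
            apply_standardizer(s, np.zeros((3, 5)))


class TestNoLeakage:
    def test_val_split_never_contains_test_days(self):
        ds = make_dataset(n_classes=4, per_class_per_day=6, n_days=10)
        spec = SplitSpec(set(range(1, 9)), {9, 10})
        train, test = day_wise_split(ds, spec)
        fit, val = stratified_validation_split(train, 0.2, seed=0)
        test_ids = set(test.sample_ids)
        assert not test_ids & set(fit.sample_ids)
        assert not test_ids & set(val.sample_ids)
        assert not set(fit.days) & spec.test_days
        assert not set(val.days) & spec.test_days


class TestIO:
    def test_csv_roundtrip(self, tmp_path, small_dataset):
        path = tmp_path / "ds.csv"
        write_csv(small_dataset, path)
        back = read_csv(path)
        assert len(back) == len(small_dataset)
        np.testing.assert_allclose(back.to_array(), small_dataset.to_array())
        assert back.labels.tolist() == small_dataset.labels.tolist()

    def test_hdf5_roundtrip(self, tmp_path, small_dataset):
        path = tmp_path / "ds.h5"
        write_hdf5(small_dataset, path)
        back = read_hdf5(path)
        np.testing.assert_array_equal(back.to_array(), small_dataset.to_array())
        assert back.sample_ids == small_dataset.sample_ids
        assert back.days.tolist() == small_dataset.days.tolist()

    def test_split_manifest_roundtrip(self, tmp_path, small_dataset):
        spec = SplitSpec({1}, {2}, seed=9)
        train, test = day_wise_split(small_dataset, spec)
        path = tmp_path / "split.json"
        write_split_manifest(path, spec, {"train": train, "test": test})
        manifest = read_split_manifest(path)
        assert manifest["spec"]["seed"] == 9
        assert manifest["partitions"]["train"] == train.sample_ids
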