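"""Data model, file round-trips and preprocessing."""

import numpy as np
import pytest

from phasegan.spectra import (ImbalanceSpec, MinMaxNormalizer, Spectrum,
                              SpectralDataset, make_imbalanced_split,
                              most_square_grid, normalize_minmax, read_spectra,
                              resample_length, to_sequence_index, write_spectra)


class TestIO:
    def test_direct_readback(self, tmp_path, random_dataset):
        ds = random_dataset(n=2, length=4)
        path = tmp_path / "two.csv"
        write_spectra(ds, path)
        back = read_spectra(path)
        assert len(back) == 2 and back.length == 4
        assert back.classes == ["solution", "gel"]
        np.testing.assert_array_equal(back.values, ds.values)

    @pytest.mark.parametrize("seed", range(10))
    def test_round_trip_full_precision(self, tmp_path, random_dataset, seed):
        ds = random_dataset(n=7, length=9, seed=seed, with_meta=True)
        path = tmp_path / "rt.csv"
        write_spectra(ds, path)
        back = read_spectra(path)
        np.testing.assert_array_equal(back.values, ds.values)
        assert back.labels == ds.labels
        assert back.spectra[3].meta["well"] == 3

    def test_write_read_write_idempotent(self, tmp_path, random_dataset):
        ds = random_dataset(n=288, length=16, seed=5)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_spectra(ds, p1)
        write_spectra(read_spectra(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(ValueError, match="no spectra"):
            read_spectra(path)

    def test_malformed_row_names_location(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("id,label,v1,v2\n0,gel,1.0,2.0\n1,sol,oops,3.0\n")
        with pytest.raises(ValueError, match="row 3"):
            read_spectra(path)

    def test_inconsistent_lengths_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            SpectralDataset([Spectrum([1.0, 2.0], "a"), Spectrum([1.0], "a")])


class TestSequenceIndex:
    def test_values_unchanged_and_range_recorded(self):
        freqs = np.linspace(26013.75, 37000.0, 50)
        vals = np.sin(np.linspace(0, 3, 50))
        s = to_sequence_index(vals, freqs, label="gel")
        np.testing.assert_array_equal(s.values, vals)
        assert s.meta["freq_min_hz"] == 26013.75
        assert s.meta["freq_max_hz"] == 37000.0

    def test_distinct_ranges_same_axis(self):
        v = np.arange(5.0)
        a = to_sequence_index(v, np.linspace(26013.75, 37000, 5))
        b = to_sequence_index(v, np.linspace(31012.5, 41000, 5))
        np.testing.assert_array_equal(a.values, b.values)

    def test_non_monotone_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            to_sequence_index([1.0, 2.0, 3.0], [1.0, 3.0, 2.0])


class TestNormalize:
    def test_affine_endpoints(self, random_dataset):
        ds = SpectralDataset([Spectrum([0.0, 5.0], "a"), Spectrum([10.0, 5.0], "a")])
        out, norm = normalize_minmax(ds, -1.0, 1.0)
        v = out.values
        assert v.min() == -1.0 and v.max() == 1.0
        assert v[0, 1] == 0.0  # midpoint 5 -> 0

    def test_identity_when_already_scaled(self):
        ds = SpectralDataset([Spectrum([-1.0, 0.2], "a"), Spectrum([1.0, 0.0], "a")])
        out, _ = normalize_minmax(ds, -1.0, 1.0)
        np.testing.assert_allclose(out.values, ds.values)

    @pytest.mark.parametrize("seed", range(5))
    def test_inversion(self, random_dataset, seed):
        ds = random_dataset(n=6, length=8, seed=seed)
        out, norm = normalize_minmax(ds)
        back = norm.invert(out)
        np.testing.assert_allclose(back.values, ds.values, atol=1e-10)
        assert out.values.min() >= -1.0 and out.values.max() <= 1.0

    def test_constant_dataset_maps_to_midpoint(self):
        ds = SpectralDataset([Spectrum([3.0, 3.0], "a")])
        out, _ = normalize_minmax(ds, -1.0, 1.0)
        np.testing.assert_array_equal(out.values, 0.0)

    def test_train_constants_apply_to_test(self, random_dataset):
        train = random_dataset(n=6, seed=1)
        test = random_dataset(n=4, seed=2)
        _, norm = normalize_minmax(train)
        scaled = norm.transform(test)
        # test values may exceed [-1, 1]; the map is the training map
        expected = -1 + (test.values - norm.data_min) * 2 / (norm.data_max - norm.data_min)
        np.testing.assert_allclose(scaled.values, expected)


class TestResample:
    def test_identity_same_length(self):
        s = Spectrum(np.random.default_rng(0).normal(size=30), "a")
        out = resample_length(s, 30)
        np.testing.assert_array_equal(out.values, s.values)

    def test_endpoint_preservation(self):
        out = resample_length(Spectrum([0.0, 1.0, 2.0, 3.0], "a"), 2)
        np.testing.assert_array_equal(out.values, [0.0, 3.0])

    def test_down_up_reconstruction_matches_oracle_bound(self):
        # smooth spectrum: bound |f - interp| <= h^2/8 * max|f''|
        n, m = 200, 50
        t = np.linspace(0, 1, n)
        f = np.sin(2 * np.pi * t) + 0.5 * np.cos(5 * t)
        s = Spectrum(f, "a")
        back = resample_length(resample_length(s, m), n)
        h = 1.0 / (m - 1)
        fpp_max = np.abs((2 * np.pi) ** 2 + 0.5 * 25)
        assert np.max(np.abs(back.values - f)) <= 2 * (h ** 2 / 8) * fpp_max

        # independent piecewise-linear oracle for the downsampling step
        down = resample_length(s, m)
        x_new = np.linspace(0, 1, m)
        for j, x in enumerate(x_new):
            i = min(int(x * (n - 1)), n - 2)
            w = x * (n - 1) - i
            assert down.values[j] == pytest.approx(f[i] * (1 - w) + f[i + 1] * w)

    def test_too_short_target_rejected(self):
        with pytest.raises(ValueError):
            resample_length(Spectrum([1.0, 2.0], "a"), 1)


def _case_study_dataset(n_majority, n_minority, majority="solution", minority="gel",
                        length=6, seed=0):
    rng = np.random.default_rng(seed)
    spectra = [Spectrum(rng.normal(size=length), majority) for _ in range(n_majority)]
    spectra += [Spectrum(rng.normal(size=length), minority) for _ in range(n_minority)]
    return SpectralDataset(spectra, [majority, minority])


class TestImbalancedSplit:
    @pytest.mark.parametrize("maj_n,min_n,ratio", [
        (150, 2, 0.013), (150, 4, 0.027), (150, 6, 0.040),   # thermogelling design
        (120, 3, 0.025), (120, 6, 0.050), (120, 10, 0.083),  # supramolecular design
    ])
    def test_design_table_ratios(self, maj_n, min_n, ratio):
        ds = _case_study_dataset(maj_n + 31, min_n + 50)
        spec = ImbalanceSpec("solution", "gel", maj_n, min_n)
        _train, _test, realized = make_imbalanced_split(ds, spec, seed=0)
        assert realized.ratio_display == ratio
        assert realized.balanced_ratio == pytest.approx(min_n / maj_n)

    def test_balanced_case(self):
        ds = _case_study_dataset(8, 8)
        spec = ImbalanceSpec("solution", "gel", 5, 5)
        train, test, realized = make_imbalanced_split(ds, spec, seed=3)
        assert realized.balanced_ratio == 1.0 and len(train) == 10

    @pytest.mark.parametrize("seed", range(50))
    def test_disjoint_and_exhaustive(self, seed):
        ds = _case_study_dataset(20, 9)
        spec = ImbalanceSpec("solution", "gel", 12, 4)
        train, test, _ = make_imbalanced_split(ds, spec, seed)
        assert len(train) + len(test) == len(ds)
        assert len(train) == 16
        ids = lambda d: {id(s) for s in d.spectra}
        assert not (ids(train) & ids(test))
        assert train.class_counts() == {"solution": 12, "gel": 4}

    def test_determinism(self):
        ds = _case_study_dataset(30, 10)
        spec = ImbalanceSpec("solution", "gel", 20, 5)
        a = make_imbalanced_split(ds, spec, 7)
        b = make_imbalanced_split(ds, spec, 7)
        np.testing.assert_array_equal(a[0].values, b[0].values)
        np.testing.assert_array_equal(a[1].values, b[1].values)

    def test_insufficient_class_named(self):
        ds = _case_study_dataset(10, 3)
        with pytest.raises(ValueError, match="gel"):
            make_imbalanced_split(ds, ImbalanceSpec("solution", "gel", 5, 4), 0)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            ImbalanceSpec("a", "b", 4, 5)  # minority above majority
        with pytest.raises(ValueError):
            ImbalanceSpec("a", "b", 0, 0)


def test_most_square_grid():
    assert most_square_grid(800) == (25, 32)
    assert most_square_grid(200) == (10, 20)
    assert most_square_grid(128) == (8, 16)
    assert most_square_grid(13) == (1, 13)
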