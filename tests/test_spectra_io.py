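import json

import numpy as np
import pandas as pd
import pytest

from freezenir.spectra_io import (
    SpectraSet,
    read_jcamp,
    read_spectra_csv,
    resample,
    split_calibration_validation,
    write_spectra_csv,
    write_split,
)


class TestCsvRoundTrip:
    def test_roundtrip_identity(self, small_set, tmp_path):
        path = tmp_path / "s.csv"
        write_spectra_csv(small_set, path)
        back = read_spectra_csv(path)
        assert back.sample_ids == small_set.sample_ids
        assert back.labels == small_set.labels
        assert np.max(np.abs(back.absorbance - small_set.absorbance)) < 1e-9
        assert np.max(np.abs(back.wavelengths - small_set.wavelengths)) < 1e-9
        pd.testing.assert_frame_equal(
            back.meta, small_set.meta, check_dtype=False
        )

    def test_empty_set_roundtrip(self, tmp_path):
        empty = SpectraSet(
            wavelengths=np.array([900.0, 1000.0]),
            absorbance=np.empty((0, 2)),
            sample_ids=[],
            labels=[],
        )
        path = tmp_path / "empty.csv"
        write_spectra_csv(empty, path)
        back = read_spectra_csv(path)
        assert back.n_samples == 0
        assert back.n_channels == 2

    def test_shuffled_wavelength_columns_sorted(self, tmp_path):
        # hand-built file with columns out of order; oracle = manual sort
        path = tmp_path / "shuffled.csv"
        path.write_text(
            "id,label,1700,900,1300\n"
            "a,fresh,3.0,1.0,2.0\n"
            "b,frozen1,6.0,4.0,5.0\n"
        )
        data = read_spectra_csv(path)
        assert list(data.wavelengths) == [900.0, 1300.0, 1700.0]
        assert data.absorbance.tolist() == [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]]

    def test_duplicate_id_error_names_offender(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text("id,label,900\nS1,fresh,1.0\nS1,fresh,2.0\n")
        with pytest.raises(ValueError, match="S1"):
            read_spectra_csv(path)

    def test_nan_error_names_row_and_column(self, tmp_path):
        path = tmp_path / "nan.csv"
        path.write_text("id,label,900,1000\nS1,fresh,1.0,2.0\nS2,fresh,,2.0\n")
        with pytest.raises(ValueError, match="S2") as err:
            read_spectra_csv(path)
        assert "900" in str(err.value)

    def test_non_numeric_wavelength_header_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("id,label,900,badcol\nS1,fresh,1.0,2.0\n")
        with pytest.raises(ValueError, match="badcol"):
            read_spectra_csv(path)

    def test_reflectance_converted_to_absorbance(self, tmp_path):
        path = tmp_path / "refl.csv"
        path.write_text("id,label,900,1000\nS1,fresh,0.5,0.1\n")
        data = read_spectra_csv(path, reflectance=True)
        assert np.allclose(data.absorbance, np.log10(1 / np.array([[0.5, 0.1]])))


class TestValidation:
    def test_decreasing_wavelengths_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            SpectraSet(np.array([1000.0, 900.0]), np.ones((1, 2)), ["a"])

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="thawed"):
            SpectraSet(
                np.array([900.0, 1000.0]), np.ones((1, 2)), ["a"], labels=["thawed"]
            )

    def test_nonfinite_absorbance_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            SpectraSet(
                np.array([900.0, 1000.0]), np.array([[1.0, np.inf]]), ["a"]
            )


class TestSplit:
    @pytest.fixture
    def labeled_set(self, rng):
        wl = np.linspace(900, 1700, 6)
        n = 30
        labels = ["fresh"] * 12 + ["frozen1"] * 10 + ["frozen2"] * 8
        return SpectraSet(
            wavelengths=wl,
            absorbance=rng.standard_normal((n, 6)),
            sample_ids=[f"S{i}" for i in range(n)],
            labels=labels,
        )

    @pytest.mark.parametrize("seed", range(50))
    def test_split_is_partition(self, labeled_set, seed):
        res = split_calibration_validation(labeled_set, 2 / 3, seed)
        cal, val = set(res.calibration.sample_ids), set(res.validation.sample_ids)
        assert cal.isdisjoint(val)
        assert cal | val == set(labeled_set.sample_ids)

    def test_stratification_within_one_sample(self, labeled_set):
        res = split_calibration_validation(labeled_set, 2 / 3, seed=5)
        labels = np.asarray(labeled_set.labels)
        cal_labels = np.asarray(res.calibration.labels)
        for cls, size in (("fresh", 12), ("frozen1", 10), ("frozen2", 8)):
            got = int((cal_labels == cls).sum())
            assert abs(got - 2 / 3 * size) < 1.0

    def test_deterministic_for_fixed_seed(self, labeled_set):
        a = split_calibration_validation(labeled_set, 0.5, seed=9)
        b = split_calibration_validation(labeled_set, 0.5, seed=9)
        assert a.calibration.sample_ids == b.calibration.sample_ids
        assert a.validation.sample_ids == b.validation.sample_ids

    def test_published_experiment_shaped_split_sizes(self, rng):
        # class sizes of the published dorsal experiment (187/124/98 = 409);
        # its calibration partition held 283 samples overall
        sizes = {"fresh": 187, "frozen1": 124, "frozen2": 98}
        labels = sum(([c] * n for c, n in sizes.items()), [])
        data = SpectraSet(
            wavelengths=np.linspace(900, 1700, 4),
            absorbance=rng.standard_normal((409, 4)),
            sample_ids=[f"S{i}" for i in range(409)],
            labels=labels,
        )
        res = split_calibration_validation(data, 283 / 409, seed=1)
        assert abs(res.calibration.n_samples - 283) <= 2
        assert res.calibration.n_samples + res.validation.n_samples == 409

    def test_group_key_keeps_fish_together(self, small_set):
        res = split_calibration_validation(
            small_set, 0.5, seed=0, group_key="fish_id"
        )
        for part in (res.calibration, res.validation):
            ids = set(part.meta["fish_id"]) if part.n_samples else set()
            for fid in ids:
                total = (small_set.meta["fish_id"] == fid).sum()
                assert (part.meta["fish_id"] == fid).sum() == total

    def test_oversized_group_warns(self, rng):
        meta = pd.DataFrame({"fish_id": ["big"] * 4})
        data = SpectraSet(
            wavelengths=np.linspace(900, 1700, 4),
            absorbance=rng.standard_normal((4, 4)),
            sample_ids=list("abcd"),
            labels=["fresh"] * 4,
            meta=meta,
        )
        with pytest.warns(UserWarning, match="group larger"):
            split_calibration_validation(data, 0.5, seed=0, group_key="fish_id")

    def test_unlabeled_sample_rejected(self, rng):
        data = SpectraSet(
            wavelengths=np.linspace(900, 1700, 4),
            absorbance=rng.standard_normal((3, 4)),
            sample_ids=list("abc"),
        )
        with pytest.raises(ValueError, match="labeled"):
            split_calibration_validation(data, 0.5, seed=0)

    def test_manifest_written(self, labeled_set, tmp_path):
        res = split_calibration_validation(labeled_set, 2 / 3, seed=3)
        write_split(res, tmp_path)
        manifest = json.loads((tmp_path / "spectra_split.json").read_text())
        assert manifest["seed"] == 3
        assert manifest["counts"]["calibration"]["total"] == res.calibration.n_samples


class TestResample:
    def test_linear_interpolation_matches_numpy(self, small_set):
        grid = np.linspace(950, 1650, 7)
        out = resample(small_set, grid)
        expected = np.vstack(
            [
                np.interp(grid, small_set.wavelengths, row)
                for row in small_set.absorbance
            ]
        )
        assert np.allclose(out.absorbance, expected)

    def test_extrapolation_rejected(self, small_set):
        with pytest.raises(ValueError, match="beyond"):
            resample(small_set, np.array([800.0, 1000.0]))


class TestJcamp:
    def test_minimal_xydata_parsed(self, tmp_path):
        path = tmp_path / "s.jdx"
        path.write_text(
            "##TITLE=test spectrum\n"
            "##JCAMP-DX=4.24\n"
            "##XUNITS=NANOMETERS\n"
            "##YUNITS=ABSORBANCE\n"
            "##FIRSTX=900\n"
            "##LASTX=903\n"
            "##NPOINTS=4\n"
            "##YFACTOR=0.5\n"
            "##XYDATA=(X++(Y..Y))\n"
            "900 2.0 4.0\n"
            "902 6.0 8.0\n"
            "##END=\n"
        )
        x, y = read_jcamp(path)
        assert np.allclose(x, [900, 901, 902, 903])
        assert np.allclose(y, [1.0, 2.0, 3.0, 4.0])

    def test_npoints_mismatch_rejected(self, tmp_path):
        path = tmp_path / "bad.jdx"
        path.write_text(
            "##TITLE=t\n##FIRSTX=900\n##LASTX=901\n##NPOINTS=5\n"
            "##XYDATA=(X++(Y..Y))\n900 1.0 2.0\n##END=\n"
        )
        with pytest.raises(ValueError, match="NPOINTS"):
            read_jcamp(path)
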