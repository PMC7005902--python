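import json

import numpy as np
import pytest

from emrestore.core import AlgorithmSpec, ImageVolume
from emrestore.workflow import (
    AcquisitionPlan,
    RoiSpec,
    RunRecord,
    acquisition_time,
    apply_algorithm,
    apply_to_stack,
    export_png,
    preview_roi,
    read_volume,
    rerun_from_record,
    write_volume,
)

GAUSS = AlgorithmSpec("gaussian", {"sigma_g": 1.0})
BILAT = AlgorithmSpec("bilateral", {"sigma_sp": 2.0, "sigma_int": 0.15})
NLM = AlgorithmSpec("nlm", {"h": 0.3, "B": 1, "W": 2})


class TestTiffIO:
    def test_float_roundtrip_bit_identical(self, tmp_path, rng):
        data = rng.random((3, 32, 32)).astype(np.float32).astype(np.float64)
        vol = ImageVolume(data)
        path = tmp_path / "v.tif"
        write_volume(vol, path)
        back, _ = read_volume(path)
        assert np.array_equal(back.data, data)

    def test_runrecord_survives_description_tag(self, tmp_path, rng):
        vol = ImageVolume(rng.random((2, 16, 16)))
        record = RunRecord(spec=GAUSS.to_dict(), sigma_hat=0.05, slice_range=(0, 1))
        path = tmp_path / "v.tif"
        write_volume(vol, path, record)
        _, back = read_volume(path)
        assert back.spec == GAUSS.to_dict()
        assert back.sigma_hat == 0.05
        assert back.slice_range == (0, 1)

    def test_16bit_input_normalized(self, tmp_path):
        import tifffile

        raw = np.array([[0, 32768, 65535]], dtype=np.uint16)
        path = tmp_path / "u16.tif"
        tifffile.imwrite(path, raw)
        vol, _ = read_volume(path)
        np.testing.assert_allclose(vol.data[0, 0], [0.0, 32768 / 65535, 1.0])
        assert vol.source_dtype == "uint16"

    def test_rgb_rejected(self, tmp_path):
        import tifffile

        path = tmp_path / "rgb.tif"
        tifffile.imwrite(path, np.zeros((8, 8, 3), dtype=np.uint8), photometric="rgb")
        with pytest.raises(ValueError):
            read_volume(path)

    def test_png_export_is_8bit(self, tmp_path, rng):
        import imageio.v3 as iio

        path = tmp_path / "s.png"
        export_png(rng.random((16, 16)) * 1.4 - 0.2, path, clip=True)
        img = iio.imread(path)
        assert img.dtype == np.uint8


class TestPreview:
    @pytest.mark.parametrize("spec,margin", [(GAUSS, 3), (BILAT, 7), (NLM, 3)])
    def test_crop_equivalence_with_sufficient_margin(self, noisy_membranes, spec, margin):
        roi = RoiSpec(z=0, y0=64, y1=128, x0=32, x1=96, margin=margin)
        patch = preview_roi(noisy_membranes, roi, spec)
        full = apply_algorithm(noisy_membranes.data[0], spec)
        np.testing.assert_allclose(patch, full[64:128, 32:96], atol=1e-10)

    def test_full_slice_roi_equals_full_run(self, noisy_membranes):
        _, ny, nx = noisy_membranes.shape
        roi = RoiSpec(z=0, y0=0, y1=ny, x0=0, x1=nx, margin=3)
        patch = preview_roi(noisy_membranes, roi, GAUSS)
        np.testing.assert_allclose(patch, apply_algorithm(noisy_membranes.data[0], GAUSS))

    def test_zero_margin_differs_only_near_border(self, noisy_membranes):
        roi = RoiSpec(z=0, y0=64, y1=128, x0=32, x1=96, margin=0)
        with pytest.warns(RuntimeWarning, match="influence radius"):
            patch = preview_roi(noisy_membranes, roi, GAUSS)
        full = apply_algorithm(noisy_membranes.data[0], GAUSS)[64:128, 32:96]
        diff = np.abs(patch - full)
        r = 3  # gaussian influence radius
        assert np.abs(diff[r:-r, r:-r]).max() < 1e-12
        assert diff.max() > 0

    def test_invalid_roi_rejected(self, noisy_membranes):
        with pytest.raises(ValueError):
            RoiSpec(z=0, y0=10, y1=10, x0=0, x1=5)
        with pytest.raises(ValueError):
            RoiSpec(z=99, y0=0, y1=8, x0=0, x1=8).validate_against(noisy_membranes)


class TestApplyToStack:
    def test_each_slice_equals_single_slice_call(self, rng):
        vol = ImageVolume(rng.random((3, 32, 32)))
        out, _ = apply_to_stack(vol, GAUSS)
        for z in range(3):
            np.testing.assert_array_equal(out.data[z], apply_algorithm(vol.data[z], GAUSS))

    def test_out_of_range_slices_untouched(self, rng):
        vol = ImageVolume(rng.random((3, 32, 32)))
        out, record = apply_to_stack(vol, GAUSS, slice_range=(1, 1))
        assert np.array_equal(out.data[0], vol.data[0])
        assert np.array_equal(out.data[2], vol.data[2])
        assert not np.array_equal(out.data[1], vol.data[1])
        assert record.slice_range == (1, 1)

    def test_input_never_mutated(self, rng):
        data = rng.random((2, 32, 32))
        vol = ImageVolume(data.copy())
        apply_to_stack(vol, GAUSS)
        assert np.array_equal(vol.data, data)

    def test_z_permutation_equivariance(self, rng):
        vol = ImageVolume(rng.random((4, 24, 24)))
        perm = [2, 0, 3, 1]
        out_a, _ = apply_to_stack(vol, GAUSS)
        out_b, _ = apply_to_stack(ImageVolume(vol.data[perm]), GAUSS)
        assert np.array_equal(out_a.data[perm], out_b.data)

    def test_metadata_roundtrip_allows_bit_exact_rerun(self, tmp_path, rng):
        vol = ImageVolume(rng.random((2, 32, 32)))
        out, record = apply_to_stack(vol, NLM)
        path = tmp_path / "denoised.tif"
        write_volume(out, path, record)
        _, record_back = read_volume(path)
        rerun = rerun_from_record(vol, record_back)
        # float32 on disk: compare the persisted output against the re-run
        assert np.array_equal(
            out.data.astype(np.float32), rerun.data.astype(np.float32)
        )

    def test_checksum_mismatch_rejected(self, rng):
        vol = ImageVolume(rng.random((2, 16, 16)))
        _, record = apply_to_stack(vol, GAUSS)
        other = ImageVolume(rng.random((2, 16, 16)))
        with pytest.raises(ValueError, match="checksum"):
            rerun_from_record(other, record)


class TestAcquisitionTime:
    def test_printed_4us_example(self):
        plan = AcquisitionPlan(500, 1e8, 4.0, 18.0, 499)
        assert round(acquisition_time(plan)) == 58

    def test_printed_1us_example(self):
        plan = AcquisitionPlan(500, 1e8, 1.0, 18.0, 499)
        assert round(acquisition_time(plan)) == 16

    def test_speedup_factor(self):
        t4 = acquisition_time(AcquisitionPlan(500, 1e8, 4.0, 18.0, 499))
        t1 = acquisition_time(AcquisitionPlan(500, 1e8, 1.0, 18.0, 499))
        assert round(t4 / t1, 1) == 3.5

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            AcquisitionPlan(-1, 1e8, 4.0)


def test_runrecord_json_roundtrip():
    rec = RunRecord(spec=NLM.to_dict(), sigma_hat=0.1, blur_hat=0.2, slice_range=(0, 4))
    back = RunRecord.from_json(rec.to_json())
    assert back == rec
    assert json.loads(rec.to_json())  # valid JSON document
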