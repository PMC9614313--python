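"""Data model, I/O round-trips and warping contracts."""

import numpy as np
import pytest

from pqctseg.core_raster import (
    AffineTransform,
    DisplacementField,
    LabelMap2D,
    Raster2D,
    compose_affine_field,
    compose_fields,
    invert_field,
    read_image,
    read_labels,
    warp_image,
    warp_labels,
    write_image,
    write_labels,
)
from pqctseg.phantom import random_smooth_deformation


class TestIO:
    @pytest.mark.parametrize("suffix", [".nii.gz", ".png"])
    def test_image_round_trip(self, phantom64, tmp_path, suffix):
        img, _ = phantom64
        path = tmp_path / f"img{suffix}"
        write_image(img, path)
        back = read_image(path)
        assert back.spacing == pytest.approx(img.spacing)
        assert back.origin == pytest.approx(img.origin)
        # PNG quantizes to 16 bits over the value range
        tol = 1e-4 if suffix != ".png" else (np.ptp(img.values) / 65535.0)
        assert np.allclose(back.values, img.values, atol=tol + 1e-6)

    @pytest.mark.parametrize("suffix", [".nii.gz", ".png"])
    def test_labels_round_trip(self, phantom64, tmp_path, suffix):
        _, lab = phantom64
        path = tmp_path / f"lab{suffix}"
        write_labels(lab, path)
        back = read_labels(path)
        assert np.array_equal(back.labels, lab.labels)

    def test_png_without_sidecar_rejected(self, phantom64, tmp_path):
        img, _ = phantom64
        path = tmp_path / "img.png"
        write_image(img, path)
        (tmp_path / "img.json").unlink()
        with pytest.raises(ValueError, match="spacing metadata required"):
            read_image(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_image(tmp_path / "nope.nii.gz")

    def test_unknown_format(self, tmp_path):
        from pqctseg.core_raster import _infer_format
        with pytest.raises(ValueError, match="format"):
            _infer_format(tmp_path / "x.tiff", None)

    def test_nifti_spacing_preserved(self, tmp_path):
        img = Raster2D(np.random.default_rng(0).random((16, 16)), spacing=0.5)
        path = tmp_path / "s.nii.gz"
        write_image(img, path)
        assert read_image(path).spacing == pytest.approx(0.5)


class TestTypes:
    def test_invalid_label_codes_rejected(self):
        with pytest.raises(ValueError, match="invalid label"):
            LabelMap2D(np.full((8, 8), 7))

    def test_singular_affine_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            AffineTransform(np.zeros((2, 2)), np.zeros(2))

    def test_affine_compose_inverse(self):
        rng = np.random.default_rng(3)
        a = AffineTransform(np.eye(2) + 0.1 * rng.random((2, 2)), rng.random(2))
        comp = a.compose(a.inverse())
        assert np.allclose(comp.matrix, np.eye(2))
        assert np.allclose(comp.translation, 0.0)

    def test_tiny_grid_rejected(self):
        with pytest.raises(ValueError, match="8x8"):
            Raster2D(np.zeros((4, 4)))


class TestWarp:
    def test_identity_is_exact(self, phantom64):
        img, lab = phantom64
        assert np.array_equal(warp_image(img, AffineTransform.identity()).values,
                              img.values)
        assert np.array_equal(warp_labels(lab, AffineTransform.identity()).labels,
                              lab.labels)

    def test_integer_pixel_translation(self, phantom64):
        img, lab = phantom64
        # Pull-back: sampling source at x + 2 px shifts content 2 columns left.
        tr = AffineTransform(np.eye(2), [2 * img.spacing, 0.0])
        out = warp_image(img, tr)
        assert np.allclose(out.values[:, :-2], img.values[:, 2:], atol=1e-5)
        assert np.all(out.values[:, -2:] == 0.0)
        out_lab = warp_labels(lab, tr)
        assert np.array_equal(out_lab.labels[:, :-2], lab.labels[:, 2:])
        assert np.all(out_lab.labels[:, -2:] == 0)

    def test_warp_then_inverse_recovers_interior(self, phantom64):
        img, _ = phantom64
        fld = random_smooth_deformation(img.shape, img.spacing, seed=4,
                                        amplitude=2.0, scale=10.0)
        round_trip = warp_image(warp_image(img, fld), fld.inverse)
        interior = np.s_[8:-8, 8:-8]
        err = np.abs(round_trip.values[interior] - img.values[interior])
        # linear interpolation tolerance on a noisy image
        assert np.median(err) < 10.0

    def test_labels_never_invent_codes(self, phantom64):
        _, lab = phantom64
        fld = random_smooth_deformation(lab.shape, lab.spacing, seed=9,
                                        amplitude=3.0, scale=8.0)
        out = warp_labels(lab, fld)
        assert out.present_tissues() <= lab.present_tissues() | {0}

    def test_field_grid_mismatch(self, phantom64):
        img, _ = phantom64
        bad = DisplacementField.zeros((32, 32), img.spacing)
        with pytest.raises(ValueError, match="match"):
            warp_image(img, bad)


class TestCompose:
    def test_affine_field_composition_matches_two_pass(self, phantom64):
        img, lab = phantom64
        mu = AffineTransform(np.eye(2) * 1.02, [1.0, -0.5])
        fld = random_smooth_deformation(img.shape, img.spacing, seed=5,
                                        amplitude=1.5, scale=12.0)
        one_pass = warp_image(img, compose_affine_field(mu, fld))
        two_pass = warp_image(warp_image(img, mu), fld)
        interior = np.s_[6:-6, 6:-6]
        # two-pass interpolates twice; agree to interpolation tolerance
        assert np.median(np.abs(one_pass.values[interior]
                                - two_pass.values[interior])) < 5.0

    def test_field_nifti_round_trip(self, tmp_path):
        from pqctseg.core_raster import read_field, write_field
        fld = random_smooth_deformation((32, 32), 0.5, seed=2,
                                        amplitude=2.0, scale=8.0)
        path = tmp_path / "field.nii.gz"
        write_field(fld, path)
        back = read_field(path)
        assert back.spacing == pytest.approx(fld.spacing)
        assert np.allclose(back.displacement, fld.displacement, atol=1e-6)

    def test_invert_field_fixed_point(self):
        fld = random_smooth_deformation((48, 48), 0.5, seed=6,
                                        amplitude=2.0, scale=10.0)
        inv = invert_field(fld)
        residual = compose_fields(fld, inv).magnitude() / fld.spacing
        assert residual.mean() < 0.1
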