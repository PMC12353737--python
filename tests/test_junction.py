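"""Unit and oracle tests for the junction-core operations."""

import dataclasses

import numpy as np
import pytest

from gwjtv import (
    DegenerateSegmentationError,
    SegmentationSet,
    Volume3D,
    binarize_junction,
    box_blur_125,
    compute_thresholds,
    gaussian_smooth_fwhm,
    junction_volume,
    make_phantom,
    process_subject,
    shell_volume_mm3,
    tissue_totals,
)
from gwjtv.junction import FWHM_TO_SIGMA


def _toy_seg(si, gm, wm, csf=None):
    si = np.asarray(si, dtype=float)
    csf = np.zeros_like(si) if csf is None else np.asarray(csf, dtype=float)
    return SegmentationSet(
        t1=Volume3D(si),
        gm_pv=Volume3D(np.asarray(gm, dtype=float)),
        wm_pv=Volume3D(np.asarray(wm, dtype=float)),
        csf_pv=Volume3D(csf),
    )


class TestThresholds:
    def test_zero_variance_tissues(self):
        """Uniform GM=100 / WM=200 intensities give zero 2SD and band [100, 200]."""
        si = np.zeros((4, 4, 4))
        gm = np.zeros_like(si)
        wm = np.zeros_like(si)
        gm[:2], si[:2] = 1.0, 100.0
        wm[2:], si[2:] = 1.0, 200.0
        thr = compute_thresholds(_toy_seg(si, gm, wm))
        assert thr.si_gm50_mean == 100.0 and thr.si_gm50_2sd == 0.0
        assert thr.bt_lower == 100.0 and thr.bt_upper == 200.0

    def test_hand_computed_sample_sd(self):
        """GM voxels {98,100,102}: sample SD 2, so 2SD=4 and bt_lower=102."""
        si = np.zeros((3, 3, 3))
        gm = np.zeros_like(si)
        wm = np.zeros_like(si)
        si[0, 0, :] = [98.0, 100.0, 102.0]
        gm[0, 0, :] = 1.0
        si[2, 2, :2], wm[2, 2, :2] = 200.0, 1.0
        thr = compute_thresholds(_toy_seg(si, gm, wm))
        assert thr.si_gm50_mean == pytest.approx(100.0)
        assert thr.si_gm50_2sd == pytest.approx(4.0)
        assert thr.bt_lower == pytest.approx(102.0)
        assert thr.n_gm50 == 3 and thr.n_wm50 == 2

    def test_affine_equivariance_of_si_fields(self, noisy_seg):
        """SI -> 2*SI+10 maps means to 2m+10, 2SDs to 2*2SD, thresholds alike."""
        thr = compute_thresholds(noisy_seg)
        seg2 = SegmentationSet(
            t1=noisy_seg.t1.with_values(2.0 * noisy_seg.t1.values + 10.0),
            gm_pv=noisy_seg.gm_pv,
            wm_pv=noisy_seg.wm_pv,
            csf_pv=noisy_seg.csf_pv,
        )
        thr2 = compute_thresholds(seg2)
        assert thr2.si_gm50_mean == pytest.approx(2 * thr.si_gm50_mean + 10)
        assert thr2.si_wm50_2sd == pytest.approx(2 * thr.si_wm50_2sd)
        assert thr2.bt_lower == pytest.approx(2 * thr.bt_lower + 10)
        assert thr2.bt_upper == pytest.approx(2 * thr.bt_upper + 10)

    def test_degenerate_segmentation_rejected(self):
        si = np.full((3, 3, 3), 100.0)
        gm = np.zeros_like(si)
        gm[0, 0, 0] = 1.0  # only one majority-GM voxel
        wm = np.zeros_like(si)
        wm[1] = 1.0
        with pytest.raises(DegenerateSegmentationError):
            compute_thresholds(_toy_seg(si, gm, wm))


class TestBinarize:
    def test_junction_is_the_transition_shell(self, small_seg):
        """On a noiseless phantom the 1-voxels are exactly the voxels whose SI
        lies in the threshold band and that are majority brain tissue
        (independent per-voxel check of both conditions)."""
        thr = compute_thresholds(small_seg)
        binary = binarize_junction(small_seg, thr)
        si = small_seg.t1.values
        expected = (
            (si >= thr.bt_lower)
            & (si <= thr.bt_upper)
            & (small_seg.gm_pv.values + small_seg.wm_pv.values >= 0.5)
        )
        assert np.array_equal(binary.values.astype(bool), expected)
        assert binary.values.sum() > 0

    def test_si_below_band_gives_empty_map(self, small_seg):
        thr = compute_thresholds(small_seg)
        low = SegmentationSet(
            t1=small_seg.t1.with_values(
                np.full(small_seg.shape, thr.bt_lower - 1.0)
            ),
            gm_pv=small_seg.gm_pv,
            wm_pv=small_seg.wm_pv,
            csf_pv=small_seg.csf_pv,
        )
        assert binarize_junction(low, thr).values.sum() == 0

    def test_inverted_band_warns_and_zeroes(self, small_seg, caplog):
        thr = compute_thresholds(small_seg)
        bad = dataclasses.replace(
            thr,
            si_gm50_mean=thr.si_wm50_mean,
            si_wm50_mean=thr.si_gm50_mean,
            bt_lower=thr.si_wm50_mean + 0.5 * thr.si_gm50_2sd,
            bt_upper=thr.si_gm50_mean - 0.5 * thr.si_wm50_2sd,
        )
        with caplog.at_level("WARNING", logger="gwjtv"):
            out = binarize_junction(small_seg, bad)
        assert out.values.sum() == 0
        assert any("all-zero" in r.message for r in caplog.records)

    @pytest.mark.parametrize("a,b", [(2.0, 10.0), (0.5, -3.0), (7.3, 0.0)])
    def test_intensity_affine_invariance(self, noisy_seg, a, b):
        """The binary map of a*SI+b (a>0) is identical to that of SI."""
        ref = binarize_junction(noisy_seg, compute_thresholds(noisy_seg))
        seg2 = SegmentationSet(
            t1=noisy_seg.t1.with_values(a * noisy_seg.t1.values + b),
            gm_pv=noisy_seg.gm_pv,
            wm_pv=noisy_seg.wm_pv,
            csf_pv=noisy_seg.csf_pv,
        )
        out = binarize_junction(seg2, compute_thresholds(seg2))
        assert np.array_equal(ref.values, out.values)


def brute_force_box_blur(vals):
    """Direct 125-term convolution with zero padding (independent oracle)."""
    out = np.zeros_like(vals, dtype=float)
    nx, ny, nz = vals.shape
    for dx in range(-2, 3):
        for dy in range(-2, 3):
            for dz in range(-2, 3):
                shifted = np.zeros_like(vals, dtype=float)
                xs = slice(max(0, dx), min(nx, nx + dx))
                xd = slice(max(0, -dx), min(nx, nx - dx))
                ys = slice(max(0, dy), min(ny, ny + dy))
                yd = slice(max(0, -dy), min(ny, ny - dy))
                zs = slice(max(0, dz), min(nz, nz + dz))
                zd = slice(max(0, -dz), min(nz, nz - dz))
                shifted[xd, yd, zd] = vals[xs, ys, zs]
                out += shifted
    return out / 125.0


class TestBoxBlur:
    def test_all_zero_input(self):
        out = box_blur_125(Volume3D(np.zeros((6, 6, 6))))
        assert not out.values.any()

    def test_impulse_response(self):
        """An interior 1-voxel spreads to 125 voxels of 1/125; sum conserved."""
        vals = np.zeros((9, 9, 9))
        vals[4, 4, 4] = 1.0
        out = box_blur_125(Volume3D(vals)).values
        assert np.count_nonzero(out) == 125
        assert out[4, 4, 4] == pytest.approx(1 / 125)
        assert out.sum() == pytest.approx(1.0)

    def test_matches_brute_force_convolution(self, rng):
        vals = (rng.random((32, 32, 32)) < 0.2).astype(float)
        out = box_blur_125(Volume3D(vals)).values
        assert np.allclose(out, brute_force_box_blur(vals), atol=1e-12)

    def test_short_axis_rejected(self):
        with pytest.raises(ValueError, match=">=5"):
            box_blur_125(Volume3D(np.zeros((4, 8, 8))))

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            box_blur_125(Volume3D(np.full((6, 6, 6), 0.5)))


class TestGaussianSmooth:
    def test_sigma_closed_form(self):
        assert 8.0 * FWHM_TO_SIGMA == pytest.approx(3.39728, abs=1e-5)

    def test_delta_profile_matches_sampled_gaussian(self):
        """Smoothing a delta reproduces the separable sampled Gaussian."""
        vals = np.zeros((33, 33, 33))
        vals[16, 16, 16] = 1.0
        out = gaussian_smooth_fwhm(Volume3D(vals), 8.0).values
        sigma = 8.0 * FWHM_TO_SIGMA
        x = np.arange(33) - 16.0
        radius = int(4.0 * sigma + 0.5)
        g = np.exp(-(x**2) / (2 * sigma**2))
        g[np.abs(x) > radius] = 0.0
        g /= g.sum()
        expected = g[:, None, None] * g[None, :, None] * g[None, None, :]
        center = expected[16, 16, 16]
        assert out[16, 16, 16] == pytest.approx(center, rel=1e-6)
        assert np.allclose(out, expected, atol=1e-9)

    def test_interior_support_conserves_sum(self):
        vals = np.zeros((40, 40, 40))
        vals[18:22, 18:22, 18:22] = 1.0
        out = gaussian_smooth_fwhm(Volume3D(vals), 4.0).values
        assert out.sum() == pytest.approx(vals.sum(), rel=1e-6)

    def test_bad_fwhm_rejected(self):
        with pytest.raises(ValueError):
            gaussian_smooth_fwhm(Volume3D(np.zeros((8, 8, 8))), 0.0)


class TestVolumes:
    def test_single_voxel_unit_conversion(self):
        seg = _toy_seg(
            np.full((1, 1, 1), 100.0),
            np.ones((1, 1, 1)),
            np.zeros((1, 1, 1)),
        )
        gmv, wmv, csf, tiv = tissue_totals(seg)
        assert gmv == pytest.approx(0.001)  # 1 mm^3 = 0.001 mL
        assert tiv == pytest.approx(gmv + wmv + csf)

    def test_totals_match_analytic_sphere_shells(self, small_spec, small_seg):
        """Partial-volume sums agree with the closed-form volume of a
        logistic-blended sphere: integrating 4*pi*r^2 * sigmoid((R-r)/s)
        gives (4/3)*pi*R^3 * (1 + pi^2 s^2 / R^2) up to exponentially small
        terms, s being the logistic scale of the boundary."""
        from gwjtv.phantom import _LOGISTIC_5_95

        gmv, wmv, csf, tiv = tissue_totals(small_seg)

        def vol(radius, width):
            s = width / _LOGISTIC_5_95
            return (4 / 3 * np.pi * radius**3 / 1000.0
                    * (1 + np.pi**2 * s**2 / radius**2))

        v_wm = vol(small_spec.wm_radius_mm, small_spec.transition_width_mm)
        v_brain = vol(small_spec.gm_radius_mm, small_spec.outer_transition_mm)
        v_head = vol(small_spec.csf_radius_mm, small_spec.outer_transition_mm)
        assert wmv == pytest.approx(v_wm, rel=0.005)
        assert gmv == pytest.approx(v_brain - v_wm, rel=0.005)
        assert csf == pytest.approx(v_head - v_brain, rel=0.005)
        assert tiv == pytest.approx(v_head, rel=0.005)

    def test_junction_volume_units_and_normalization(self):
        # blurred map summing to 12000 at 1 mm^3 voxels -> 12 mL
        blurred = Volume3D(np.full((30, 30, 30), 12000.0 / 27000.0))
        total, frac = junction_volume(blurred, tiv=1500.0, tiv_mode="fraction")
        assert total == pytest.approx(12.0)  # 12000 mm^3 -> 12 mL
        assert np.allclose(frac.values, blurred.values / 1500.0)
        _, scaled = junction_volume(blurred, tiv=1500.0, tiv_mode="scaled",
                                    tiv_ref=1500.0)
        assert np.allclose(scaled.values, blurred.values)

    def test_all_zero_blurred_map(self):
        total, _ = junction_volume(Volume3D(np.zeros((5, 5, 5))), tiv=1000.0)
        assert total == 0.0

    def test_nonpositive_tiv_rejected(self):
        with pytest.raises(ValueError):
            junction_volume(Volume3D(np.zeros((5, 5, 5))), tiv=0.0)


class TestEndToEnd:
    def test_gwjtv_monotone_in_transition_width(self, small_spec):
        """Wider GM/WM transitions produce strictly larger junction volumes."""
        totals = []
        for width in (1.0, 2.0, 3.0):
            seg = make_phantom(
                dataclasses.replace(small_spec, transition_width_mm=width)
            )
            totals.append(process_subject(seg).gwjtv_total)
        assert totals[0] < totals[1] < totals[2]

    def test_gwjtv_ordering_matches_analytic_shell_ratio(self, small_spec):
        """gwJTV/TIV falls when the brain is scaled up at fixed junction width,
        in step with the analytic shell/sphere volume ratio."""
        big = dataclasses.replace(
            small_spec,
            grid_shape=(96, 96, 96),
            csf_radius_mm=40.0,
            gm_radius_mm=32.0,
            wm_radius_mm=20.0,
        )
        res_s = process_subject(make_phantom(small_spec))
        res_b = process_subject(make_phantom(big))
        assert res_b.gwjtv_total / res_b.tiv < res_s.gwjtv_total / res_s.tiv
        # analytic ordering: shell area ~ R^2 vs sphere ~ R^3
        ratio = lambda spec: shell_volume_mm3(
            spec, spec.transition_width_mm, octant_only=False
        ) / (4 / 3 * np.pi * spec.csf_radius_mm**3)
        assert ratio(big) < ratio(small_spec)

    def test_bitwise_determinism(self, noisy_seg):
        a = process_subject(noisy_seg)
        b = process_subject(noisy_seg)
        assert np.array_equal(a.gwjtv_map.values, b.gwjtv_map.values)
        assert a.gwjtv_total == b.gwjtv_total

    def test_tiv_closure_and_nonnegative_maps(self, noisy_seg):
        res = process_subject(noisy_seg)
        assert res.tiv == pytest.approx(
            res.gmv_total + res.wmv_total + res.csf_total, rel=1e-9
        )
        assert res.gwjtv_map.values.min() >= 0
        assert res.gmv_map.values.min() >= 0
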