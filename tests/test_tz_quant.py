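"""2D quantification operators against arithmetic / closed-form oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tzpheno import (
    IntensityProfile,
    PlaneImage,
    PointSet,
    Polyline,
    SceneGroundTruth,
    VolumeStack,
    asymmetry_index,
    bb_span,
    competition_index,
    extract_line_profile,
    fwhm_length,
    integrated_box_intensity,
    leakage_intensity,
    max_projection,
    mean_axial_distribution,
    normalize_to_group,
    simulate_phasmid_scene,
    trace_length,
)
from tzpheno.images import AnnotationError

PX = 0.08  # wide-field pixel size


def profile_from(values, step_um=PX):
    values = np.asarray(values, dtype=float)
    return IntensityProfile(np.arange(len(values)) * step_um, values)


class TestLineProfile:
    def test_constant_image_gives_constant_profile(self):
        img = PlaneImage(np.full((30, 40), 7.5), PX)
        prof = extract_line_profile(img, Polyline([[2, 15], [35, 15]]))
        assert np.allclose(prof.values, 7.5)
        assert prof.positions_um[0] == 0.0
        assert prof.step_um == pytest.approx(PX)

    def test_twenty_pixel_scan_spans_1_6_um(self):
        img = PlaneImage(np.zeros((10, 40)) + 1, PX)
        prof = extract_line_profile(img, Polyline([[3, 5], [33, 5]]), length_um=1.6)
        assert len(prof) == 21  # 20 one-pixel steps
        assert prof.positions_um[-1] == pytest.approx(1.6)

    def test_bilinear_interpolation_matches_bruteforce_oracle(self, rng):
        img = PlaneImage(rng.uniform(0, 100, size=(25, 25)), PX)
        line = Polyline([[3.3, 7.7], [20.1, 13.2]])
        prof = extract_line_profile(img, line)
        pts = line.sample(np.arange(0.0, line.arc_length_px(), 1.0))
        for k, (x, y) in enumerate(pts[: len(prof)]):
            x0, y0 = int(np.floor(x)), int(np.floor(y))
            fx, fy = x - x0, y - y0
            p = img.pixels
            oracle = (
                p[y0, x0] * (1 - fx) * (1 - fy)
                + p[y0, x0 + 1] * fx * (1 - fy)
                + p[y0 + 1, x0] * (1 - fx) * fy
                + p[y0 + 1, x0 + 1] * fx * fy
            )
            assert prof.values[k] == pytest.approx(oracle, rel=1e-9)

    def test_profile_on_noiseless_scene_matches_simulated_field(
        self, noiseless_widefield_scene
    ):
        scene = noiseless_widefield_scene
        img = scene.channels["tz"]
        prof = extract_line_profile(img, scene.info["profile_lines"][0])
        # the sampled row itself is the reference field (1 px width line)
        row = int(round(scene.info["cilium_y_um"][0] / PX - 0.5))
        x_px = scene.info["profile_lines"][0].points[0][0]
        cols = (np.arange(len(prof)) + x_px + 0.5).astype(int) - 0  # fractional start
        rms = np.sqrt(np.mean((prof.values - np.interp(
            np.arange(len(prof)) + x_px, np.arange(img.shape[1]), img.pixels[row]
        )) ** 2))
        assert rms <= 0.01 * prof.values.max()

    def test_line_leaving_image_raises_with_position(self):
        img = PlaneImage(np.ones((10, 10)), PX)
        with pytest.raises(AnnotationError, match="arc position"):
            extract_line_profile(img, Polyline([[5, 5], [50, 5]]))


class TestFWHM:
    def test_top_hat_width_recovered(self):
        pos = np.arange(0, 2.0, PX)
        vals = np.where((pos >= 0.4) & (pos <= 1.2), 1.0, 0.0)
        prof = IntensityProfile(pos, vals)
        assert fwhm_length(prof, baseline=0.0) == pytest.approx(0.8, abs=PX + 1e-9)

    def test_gaussian_fwhm_closed_form(self):
        sigma = 0.34
        pos = np.arange(0, 4.0, 0.02)
        vals = np.exp(-((pos - 2.0) ** 2) / (2 * sigma ** 2))
        expected = 2 * np.sqrt(2 * np.log(2)) * sigma  # 0.8006
        assert fwhm_length(IntensityProfile(pos, vals), baseline=0.0) == pytest.approx(
            expected, rel=0.01
        )

    @given(scale=st.floats(0.1, 1000))
    def test_scale_invariance(self, scale):
        pos = np.arange(0, 2.0, PX)
        vals = np.exp(-((pos - 1.0) ** 2) / (2 * 0.2 ** 2)) + 0.5
        f1 = fwhm_length(IntensityProfile(pos, vals))
        f2 = fwhm_length(IntensityProfile(pos, vals * scale))
        assert f1 == pytest.approx(f2, rel=1e-9)

    def test_no_signal_above_baseline_raises(self):
        prof = profile_from(np.full(10, 3.0))
        with pytest.raises(ValueError, match="no signal above baseline"):
            fwhm_length(prof, baseline=3.0)

    def test_truncated_signal_raises(self):
        pos = np.arange(0, 1.0, PX)
        vals = np.linspace(1.0, 0.0, len(pos))  # starts at its max
        with pytest.raises(ValueError, match="truncated"):
            fwhm_length(IntensityProfile(pos, vals), baseline=0.0)

    def test_interior_dips_below_half_max_are_spanned(self):
        # modulated plateau: outermost crossings define the length even
        # when an interior trough falls below half max
        pos = np.arange(0, 2.0, 0.01)
        vals = np.where((pos >= 0.5) & (pos <= 1.5), 1.0, 0.0)
        vals[(pos >= 0.9) & (pos <= 1.1)] = 0.2
        f = fwhm_length(IntensityProfile(pos, vals), baseline=0.0)
        assert f == pytest.approx(1.0, abs=0.02)


class TestBoxIntensity:
    def test_uniform_image_exactly_zero(self):
        img = PlaneImage(np.full((60, 60), 13.0), PX)
        assert integrated_box_intensity(img, (30, 30)) == pytest.approx(0.0, abs=1e-9)

    def test_linear_gradient_exactly_zero(self):
        yy, xx = np.mgrid[0:60, 0:60]
        img = PlaneImage(5.0 + 0.3 * xx + 0.7 * yy, PX)
        assert integrated_box_intensity(img, (30, 30)) == pytest.approx(0.0, abs=1e-6)

    def test_confined_signal_on_background_recovered_exactly(self, rng):
        b = 11.0
        pix = np.full((60, 60), b)
        sig = rng.uniform(0, 50, size=(20, 20))
        pix[20:40, 20:40] += sig
        img = PlaneImage(pix, PX)
        assert integrated_box_intensity(img, (30, 30)) == pytest.approx(
            sig.sum(), rel=1e-12
        )

    def test_ring_pixel_count_is_164_for_default_boxes(self):
        assert 42 ** 2 - 40 ** 2 == 164

    def test_linearity_in_added_signal(self, rng):
        base = rng.uniform(0, 30, size=(60, 60))
        add = np.zeros((60, 60))
        add[25:35, 25:35] = 4.0
        i0 = integrated_box_intensity(PlaneImage(base, PX), (30, 30))
        i1 = integrated_box_intensity(PlaneImage(base + add, PX), (30, 30))
        assert i1 - i0 == pytest.approx(add.sum(), rel=1e-9)

    def test_out_of_bounds_box_raises(self):
        img = PlaneImage(np.ones((30, 30)), PX)
        with pytest.raises(AnnotationError, match="box out of bounds"):
            integrated_box_intensity(img, (10, 10))


class TestNormalisationAndCompetition:
    def test_reference_normalised_to_itself_has_unit_mean(self, rng):
        ref = rng.uniform(10, 50, size=30)
        assert normalize_to_group(ref, ref).mean() == pytest.approx(1.0)

    def test_half_reference_is_fifty_percent(self):
        ref = [10.0, 20.0, 30.0]
        out = normalize_to_group([10.0], ref, percentage=True)
        assert out[0] == pytest.approx(50.0)

    def test_competition_index_identical_samples_is_100(self, rng):
        vals = rng.uniform(5, 50, size=40)
        assert competition_index(vals, vals) == pytest.approx(100.0, abs=1e-9)

    def test_competition_index_zero_het(self):
        assert competition_index([0.0, 0.0], [10.0, 20.0]) == 0.0

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            normalize_to_group([1.0], [0.0, 0.0])

    def test_median_centering_option(self):
        ref = [1.0, 1.0, 10.0]
        out = normalize_to_group([1.0], ref, center="median")
        assert out[0] == pytest.approx(1.0)


class TestAxialDistribution:
    def test_identical_profiles_mean_equals_profile(self):
        pos = np.arange(0, 2.0, PX)
        vals = np.exp(-((pos - 1.0) ** 2) / (2 * 0.2 ** 2))
        profs = [IntensityProfile(pos, vals)] * 5
        dist = mean_axial_distribution(profs)
        assert np.allclose(dist.sd, 0.0)
        assert dist.mean.max() == pytest.approx(vals.max(), rel=1e-6)

    def test_mirror_profiles_average_to_symmetry(self):
        pos = np.arange(0, 3.0, 0.02)
        w = 1.0
        tri_fall = np.clip(1 - (pos - 1.0) / w, 0, 1) * ((pos >= 1.0) & (pos <= 2.0))
        tri_rise = tri_fall[::-1].copy()
        p1 = IntensityProfile(pos, tri_fall)
        p2 = IntensityProfile(pos, tri_rise)
        idx1 = asymmetry_index(p1)
        idx2 = asymmetry_index(p2)
        assert (idx1 + idx2) / 2 == pytest.approx(0.5, abs=0.02)
        dist = mean_axial_distribution([p1, p2])
        mean_prof = IntensityProfile(dist.positions_um, dist.mean)
        assert asymmetry_index(mean_prof) == pytest.approx(0.5, abs=0.06)

    def test_self_normalised_group_peaks_at_one(self):
        pos = np.arange(0, 2.0, PX)
        profs = [
            IntensityProfile(pos, 3 * np.exp(-((pos - 1.0) ** 2) / 0.08))
            for _ in range(4)
        ]
        dist = mean_axial_distribution(profs, reference_profiles=profs)
        assert dist.mean.max() == pytest.approx(1.0, rel=1e-9)

    def test_mixed_sampling_steps_rejected(self):
        a = profile_from(np.r_[0, 1, 2, 1, 0], step_um=0.08)
        b = profile_from(np.r_[0, 1, 2, 1, 0], step_um=0.05)
        with pytest.raises(ValueError, match="mixed sampling steps"):
            mean_axial_distribution([a, b])


class TestAsymmetryIndex:
    def test_symmetric_profiles_are_half(self):
        pos = np.linspace(0, 2.0, 201)  # symmetric about the peak at 1.0
        gauss = np.exp(-((pos - 1.0) ** 2) / (2 * 0.15 ** 2))
        assert asymmetry_index(IntensityProfile(pos, gauss)) == pytest.approx(0.5, abs=0.01)
        tophat = ((pos >= 0.6) & (pos <= 1.4)).astype(float)
        assert asymmetry_index(IntensityProfile(pos, tophat)) == pytest.approx(0.5, abs=0.02)

    def test_right_triangle_closed_form(self):
        # proximal half of a falling right triangle holds 3/4 of its area
        pos = np.arange(0, 3.0, 0.02)
        w = 1.0
        vals = np.clip(1 - (pos - 1.0) / w, 0, 1) * ((pos >= 1.0) & (pos <= 2.0))
        assert asymmetry_index(IntensityProfile(pos, vals)) == pytest.approx(0.75, rel=0.02)

    def test_mass_in_proximal_quarter_scores_high(self):
        pos = np.arange(0, 2.0, 0.01)
        vals = np.zeros_like(pos)
        block = (pos >= 0.50) & (pos <= 0.58)
        vals[block] = 1.0
        vals[(pos > 0.58) & (pos <= 1.0)] = 0.02  # thin tail defines the window
        assert asymmetry_index(IntensityProfile(pos, vals)) > 0.9

    def test_simulated_uniform_tz_is_symmetric_and_decay_increases_index(self):
        indices = []
        for decay in (None, 2.0, 1.0, 0.5):
            truth = SceneGroundTruth.widefield(
                seed=5, asymmetry_decay_um=decay, shot_noise=False, read_noise_sd=0.0
            )
            scene = simulate_phasmid_scene(truth)
            prof = extract_line_profile(
                scene.channels["tz"], scene.info["profile_lines"][0]
            )
            indices.append(asymmetry_index(prof))
        assert indices[0] == pytest.approx(0.5, abs=0.03)
        assert indices[0] < indices[1] < indices[2] < indices[3]


class TestGeometryHelpers:
    def test_straight_trace_length(self):
        assert trace_length(Polyline([[0, 0], [100, 0]]), PX) == pytest.approx(8.0)

    def test_right_angle_is_path_length_not_chord(self):
        line = Polyline([[0, 0], [30, 0], [30, 30]])
        assert trace_length(line, 1.0) == pytest.approx(60.0)

    def test_polygonal_circle_circumference(self):
        theta = np.linspace(0, 2 * np.pi, 65)
        pts = np.column_stack([50 * np.cos(theta), 50 * np.sin(theta)])
        assert trace_length(Polyline(pts), 1.0) == pytest.approx(
            2 * np.pi * 50, rel=0.005
        )

    def test_max_projection_dominates_slices(self, rng):
        vox = rng.uniform(0, 10, size=(5, 12, 14))
        stack = VolumeStack(vox, PX, 0.2)
        proj = max_projection(stack)
        assert np.all(proj.pixels[None, :, :] >= vox - 1e-12)
        single = VolumeStack(vox[:1], PX, 0.2)
        assert np.array_equal(max_projection(single).pixels, vox[0])

    def test_bb_span_single_and_pair(self):
        assert bb_span(PointSet([[5, 5]]), PX) == 0.0
        assert bb_span(PointSet([[0, 3], [25, 3]]), PX) == pytest.approx(2.0)

    def test_bb_span_matches_projection_oracle(self, rng):
        pts = rng.uniform(0, 100, size=(20, 2))
        axis = np.array([1.0, 2.0]) / np.sqrt(5)
        proj = pts @ axis
        expected = (proj.max() - proj.min()) * PX
        assert bb_span(PointSet(pts, axis), PX) == pytest.approx(expected)


class TestLeakage:
    def _scene(self, amplitude):
        truth = SceneGroundTruth.widefield(
            seed=4, leakage_amplitude=amplitude, shot_noise=False, read_noise_sd=0.0
        )
        return simulate_phasmid_scene(truth)

    def test_constant_channel_is_zero(self):
        img = PlaneImage(np.full((40, 120), 9.0), PX)
        line = Polyline([[5, 20], [100, 20]])
        assert leakage_intensity(img, line) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_leakage_recovered_and_linear(self):
        scene = self._scene(10.0)
        line = scene.info["axis_lines"][0]
        v1 = leakage_intensity(scene.channels["leakage"], line, window_um=(2.0, 4.0))
        scene2 = self._scene(20.0)
        v2 = leakage_intensity(scene2.channels["leakage"], line, window_um=(2.0, 4.0))
        assert v1 > 0
        assert v2 / v1 == pytest.approx(2.0, rel=0.01)
        # point convention reads the same plateau as the interval convention
        vp = leakage_intensity(scene.channels["leakage"], line, window_um=(4.0, 4.0))
        assert vp == pytest.approx(v1, rel=0.02)

    def test_disjoint_support_reads_zero(self):
        # signal confined near the base, read-out window beyond it
        pix = np.full((40, 120), 2.0)
        pix[19:22, 10:22] += 50.0  # within ~1 um of the trace start
        img = PlaneImage(pix, PX)
        line = Polyline([[10, 20], [110, 20]])
        val = leakage_intensity(img, line, window_um=(2.0, 4.0))
        assert val == pytest.approx(0.0, abs=1e-6)

    def test_short_trace_rejected(self):
        img = PlaneImage(np.ones((40, 120)), PX)
        line = Polyline([[10, 20], [40, 20]])  # 2.4 um long
        with pytest.raises(AnnotationError, match="too short"):
            leakage_intensity(img, line, window_um=(2.0, 4.0))
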