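"""Effect sizes, midpoint comparator, thickness and curvature measures."""

import numpy as np
import pytest
from hypothesis import given, assume, settings
from hypothesis import strategies as st

from adiposeat import roi, synthetic as syn
from adiposeat.core import (
    ITLandmark,
    ParameterError,
    RegionIntensities,
    RegionError,
    SegmentationSet,
    UndefinedStatisticError,
)
from adiposeat.metrics import (
    bulk_tissue_thickness,
    compute_adipose_metrics,
    effect_size,
    midpoint_imat_fraction,
    sagittal_radius_of_curvature,
    taubin_circle_fit,
)

from ._oracles import oracle_effect_size


def _region(name, values):
    values = np.asarray(values, dtype=float)
    coords = np.column_stack([np.zeros(values.size, int),
                              np.arange(values.size)])
    return RegionIntensities(name, values, coords)


class TestEffectSize:
    def test_hand_computed_value(self):
        # means 4 and 2, both variances 1 -> pooled SD 1 -> d = 2
        assert effect_size(_region("a", [3, 4, 5]), _region("b", [1, 2, 3])) == (
            pytest.approx(2.0, abs=1e-12)
        )

    def test_equal_means_give_zero(self):
        assert effect_size(
            _region("a", [1.0, 3.0]), _region("b", [0.0, 4.0])
        ) == pytest.approx(0.0, abs=1e-12)

    def test_matches_longhand_oracle(self, rng):
        a = _region("a", rng.normal(10, 2, 35))
        b = _region("b", rng.normal(8, 3, 28))
        assert effect_size(a, b) == pytest.approx(
            oracle_effect_size(a.values, b.values), abs=1e-12
        )

    _samples = st.lists(
        st.floats(min_value=-1e4, max_value=1e4,
                  allow_nan=False, allow_infinity=False),
        min_size=2, max_size=25,
    )

    @settings(max_examples=60, deadline=None)
    @given(_samples, _samples)
    def test_antisymmetry(self, a, b):
        ra, rb = _region("a", a), _region("b", b)
        assume(float(np.std(ra.values) + np.std(rb.values)) > 1e-6)
        assert effect_size(ra, rb) == pytest.approx(
            -effect_size(rb, ra), abs=1e-9
        )

    @settings(max_examples=60, deadline=None)
    @given(_samples, _samples,
           st.floats(min_value=0.1, max_value=50),
           st.floats(min_value=-1e3, max_value=1e3))
    def test_affine_intensity_invariance(self, a, b, scale, shift):
        ra, rb = _region("a", a), _region("b", b)
        assume(float(np.std(ra.values) + np.std(rb.values)) > 1e-3)
        d0 = effect_size(ra, rb)
        d1 = effect_size(
            _region("a", scale * ra.values + shift),
            _region("b", scale * rb.values + shift),
        )
        assert d1 == pytest.approx(d0, rel=1e-9, abs=1e-12)

    def test_singleton_region_rejected(self):
        with pytest.raises(ParameterError):
            effect_size(_region("a", [1.0]), _region("b", [1.0, 2.0]))

    def test_zero_pooled_sd_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            effect_size(_region("a", [2.0, 2.0]), _region("b", [1.0, 1.0]))

    def test_negative_generative_contrast_measures_negative(self):
        params = syn.SubjectParams(subqf_contrast=-0.69, noise_sd=0.0, seed=6)
        _, _, truth = syn.generate_subject_slice(params)
        u = truth.regions["under"]
        s = truth.regions["surrounding"]
        img = truth.pre_gradient_image
        d = effect_size(
            _region("surrounding", img[s[:, 0], s[:, 1]]),
            _region("under", img[u[:, 0], u[:, 1]]),
        )
        assert d == pytest.approx(-0.69, abs=1e-10)

    def test_compute_adipose_metrics_bundles_region_stats(self, rng):
        regs = {
            n: _region(n, rng.normal(m, 10, 50))
            for n, m in (("under", 1707), ("surrounding", 2022),
                         ("ref", 1517), ("glut", 1324))
        }
        out = compute_adipose_metrics(
            regs["under"], regs["surrounding"], regs["ref"], regs["glut"]
        )
        row = out.to_row()
        assert row["subqf_effect_size"] == pytest.approx(
            effect_size(regs["surrounding"], regs["under"]))
        assert row["under_n"] == 50
        assert row["glut_mean"] == pytest.approx(regs["glut"].mean)


class TestMidpoint:
    def test_lean_muscle_near_zero(self, rng):
        ref = _region("ref", rng.normal(2000, 80, 500))
        glut = _region("glut", rng.normal(1324, 80, 2000))
        res = midpoint_imat_fraction(ref, glut)
        assert not res.degenerate
        assert res.fraction < 0.02
        # threshold sits between muscle mode and adipose mean
        assert 1324 < res.threshold < 2000

    def test_recovers_mixture_fraction(self, rng):
        # 30% adipose-like voxels among muscle, well-separated modes
        ref = _region("ref", rng.normal(2000, 80, 500))
        g = rng.normal(1324, 80, 2000)
        g[:600] = rng.normal(2022, 80, 600)
        res = midpoint_imat_fraction(ref, _region("glut", g))
        assert not res.degenerate
        assert res.fraction == pytest.approx(0.30, abs=0.05)

    def test_fully_infiltrated_is_flagged_degenerate(self, rng):
        ref = _region("ref", rng.normal(1517, 150, 500))
        glut = _region("glut", rng.normal(2022, 150, 2000))
        res = midpoint_imat_fraction(ref, glut)
        assert res.degenerate
        assert res.fraction > 0.9

    def test_tracks_generative_fraction_monotonically(self):
        base_int = {"fat": 2022.0, "posterior_fat": 2000.0, "muscle": 1324.0,
                    "bone": 400.0, "background": 80.0}
        fractions, effects = [], []
        for imat in (0.05, 0.20, 0.35):
            params = syn.SubjectParams(
                imat_fraction=imat, texture_sd=80.0, noise_sd=0.0,
                base_intensities=dict(base_int), seed=13,
            )
            image, seg, _ = syn.generate_subject_slice(params)
            lm = roi.find_it_peak(seg.ischium, seg.spacing_mm)
            ref, glut = roi.extract_imat_regions(image, seg, lm)
            res = midpoint_imat_fraction(ref, glut)
            assert not res.degenerate
            fractions.append(res.fraction)
            effects.append(effect_size(ref, glut))
        assert fractions[0] < fractions[1] < fractions[2]
        # more infiltration -> brighter muscle -> smaller IMAT effect size
        assert effects[0] > effects[1] > effects[2]

    def test_tiny_regions_rejected(self):
        with pytest.raises(ParameterError):
            midpoint_imat_fraction(_region("ref", [1.0]), _region("g", [1, 2]))


def _thickness_fixture(depths, skin_row=70, window_cols=range(45, 56)):
    """Bone block whose per-column bottom sits `depths[i]` above skin_row."""
    shape = (100, 100)
    ischium = np.zeros(shape, dtype=bool)
    subqf = np.zeros(shape, dtype=bool)
    for c, d in zip(window_cols, depths):
        bottom = skin_row - d
        ischium[bottom - 5 : bottom + 1, c] = True
        subqf[bottom + 1 : skin_row + 1, c] = True
    seg = SegmentationSet(
        ischium=ischium, gluteus=np.zeros(shape, bool), subqf=subqf,
        spacing_mm=(1.0, 1.0),
    )
    lm = ITLandmark(row=skin_row - min(depths), col=50,
                    height_mm=float(99 - (skin_row - min(depths))), ap_mm=50.0)
    return seg, lm


class TestThickness:
    def test_uniform_slab(self):
        seg, lm = _thickness_fixture([15] * 11)
        assert bulk_tissue_thickness(seg, lm, window_mm=10.0) == pytest.approx(
            15.0, abs=1e-12
        )

    def test_linear_profile_averages_to_midpoint(self):
        # depths 10..20 over the 11 columns of a 10-mm window -> mean 15
        seg, lm = _thickness_fixture(list(range(10, 21)))
        assert bulk_tissue_thickness(seg, lm, window_mm=10.0) == pytest.approx(
            15.0, abs=1e-12
        )

    def test_window_excludes_far_columns(self):
        # a huge outlier outside the window must not change the mean
        seg, lm = _thickness_fixture([15] * 11)
        seg.ischium[20:26, 90] = True
        seg.subqf[26:80, 90] = True
        assert bulk_tissue_thickness(seg, lm, window_mm=10.0) == pytest.approx(
            15.0, abs=1e-12
        )

    def test_matches_generator_ground_truth(self, noiseless_subject):
        _, seg, truth = noiseless_subject
        val = bulk_tissue_thickness(seg, truth.landmark, window_mm=50.0)
        assert val == pytest.approx(truth.achieved["bulk_thickness_mm"], abs=1e-9)
        # nominal target is met to within skin-row rounding
        assert val == pytest.approx(truth.params.tissue_thickness_mm, abs=0.5)

    def test_empty_window_raises(self):
        seg, _ = _thickness_fixture([15] * 11)
        far = ITLandmark(row=10, col=5, height_mm=89.0, ap_mm=5.0)
        with pytest.raises(RegionError):
            bulk_tissue_thickness(seg, far, window_mm=4.0)

    def test_nonpositive_window_rejected(self):
        seg, lm = _thickness_fixture([15] * 11)
        with pytest.raises(ParameterError):
            bulk_tissue_thickness(seg, lm, window_mm=0.0)


def _arc(radius, center, angles):
    return np.column_stack(
        [center[0] + radius * np.cos(angles), center[1] + radius * np.sin(angles)]
    )


class TestCurvature:
    def test_exact_on_noiseless_circle(self):
        pts = _arc(50.0, (10.0, -5.0), np.linspace(0.2, 2.8, 30))
        res = taubin_circle_fit(pts)
        assert not res.degenerate
        assert res.radius_mm == pytest.approx(50.0, abs=1e-6)
        assert res.center_mm[0] == pytest.approx(10.0, abs=1e-6)
        assert res.center_mm[1] == pytest.approx(-5.0, abs=1e-6)

    def test_unbiased_under_small_jitter(self):
        radii = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            angles = np.linspace(-np.pi / 2 - 0.35, -np.pi / 2 + 0.35, 51)
            pts = _arc(80.0, (0.0, 80.0), angles)
            pts += rng.normal(0.0, 0.3, size=pts.shape)
            radii.append(taubin_circle_fit(pts).radius_mm)
        assert float(np.mean(radii)) == pytest.approx(80.0, abs=2.0)

    def test_scale_equivariance(self, rng):
        pts = _arc(64.0, (3.0, 7.0), np.linspace(0.1, 1.9, 25))
        pts += rng.normal(0.0, 0.2, size=pts.shape)
        r1 = taubin_circle_fit(pts).radius_mm
        r3 = taubin_circle_fit(3.0 * pts).radius_mm
        assert r3 == pytest.approx(3.0 * r1, rel=1e-9)

    def test_collinear_points_degenerate(self):
        pts = np.column_stack([np.arange(10.0), 2.0 * np.arange(10.0) + 1.0])
        res = taubin_circle_fit(pts)
        assert res.degenerate
        assert np.isinf(res.radius_mm)

    def test_too_few_points_rejected(self):
        with pytest.raises(ParameterError):
            taubin_circle_fit(np.array([[0.0, 0.0], [1.0, 1.0]]))

    @pytest.mark.parametrize("radius", [60.0, 83.7, 110.0])
    def test_mask_contour_radius_within_quantization(self, radius):
        # 1-mm rasterization of a shallow arc carries a known upward bias of
        # about 10%; the measured radius must stay within 20% of truth
        params = syn.SubjectParams(it_radius_mm=radius, noise_sd=0.0, seed=2)
        _, seg, truth = syn.generate_subject_slice(params)
        contour = roi.inferior_bone_contour(seg)
        res = sagittal_radius_of_curvature(contour, truth.landmark)
        assert not res.degenerate
        assert abs(res.radius_mm - radius) / radius < 0.20

    def test_window_restricts_contour(self, noiseless_subject):
        _, seg, truth = noiseless_subject
        contour = roi.inferior_bone_contour(seg)
        with pytest.raises(ParameterError):
            sagittal_radius_of_curvature(contour, truth.landmark, window_mm=0.5)
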