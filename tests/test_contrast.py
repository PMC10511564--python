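import numpy as np
import pytest

from irllc import (
    LABELS,
    AcquisitionSpec,
    CohortConfig,
    IRModel,
    build_cohort_table,
    cohort_frame,
    ir_magnitude,
    llc,
    measure_si,
    place_rois,
    sample_cohort,
    simulate_cohort_images,
)
from irllc.errors import CompletenessError, LesionTooSmallError, UndefinedContrastError


def _disc_label_map(shape, center, r_lesion, r_necrosis=None):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    label = np.ones(shape, dtype=np.int16)  # parenchyma everywhere
    label[d2 <= r_lesion**2] = LABELS["lesion"]
    if r_necrosis is not None:
        label[d2 <= r_necrosis**2] = LABELS["necrosis"]
    return label


def _exhaustive_largest_disc(eligible):
    """Oracle: try every center and integer radius with a 1-px margin."""
    best = (-1, None)
    rows, cols = eligible.shape
    rr, cc = np.indices(eligible.shape)
    for r0 in range(rows):
        for c0 in range(cols):
            if not eligible[r0, c0]:
                continue
            r = 0
            while True:
                disc = (rr - r0) ** 2 + (cc - c0) ** 2 <= (r + 1) ** 2
                if not eligible[disc].all() or not disc[max(r0 - r - 1, 0), c0]:
                    break
                r += 1
            if r > best[0]:
                best = (r, (r0, c0))
    return best


class TestPlaceROIs:
    def test_solid_lesion_gives_one_pixel_margin_disc(self):
        label = _disc_label_map((64, 64), (32, 32), 12.0)
        lesion_roi, par_roi = place_rois(label, "L1")
        assert lesion_roi.center == (32, 32)
        assert lesion_roi.radius_px == 11
        assert par_roi.radius_px == 11

    def test_annulus_matches_exhaustive_oracle(self):
        label = _disc_label_map((64, 64), (32, 32), 12.0, r_necrosis=8.0)
        lesion_roi, _ = place_rois(label, "L1")
        eligible = label == LABELS["lesion"]
        r_oracle, _ = _exhaustive_largest_disc(eligible)
        assert lesion_roi.radius_px >= 1
        assert abs(lesion_roi.radius_px - r_oracle) <= 1
        # ROI avoids the necrotic core entirely
        assert np.all(label[lesion_roi.rows, lesion_roi.cols] == LABELS["lesion"])

    def test_rois_stay_in_their_compartments(self, small_phantom):
        lesion_roi, par_roi = place_rois(small_phantom.label_map, "L1")
        lm = small_phantom.label_map
        assert np.all(lm[lesion_roi.rows, lesion_roi.cols] == LABELS["lesion"])
        assert np.all(lm[par_roi.rows, par_roi.cols] == LABELS["parenchyma"])

    def test_tiny_lesion_rejected(self):
        label = np.ones((32, 32), dtype=np.int16)
        label[10, 10:13] = LABELS["lesion"]  # 3 pixels < min_area 5
        with pytest.raises(LesionTooSmallError):
            place_rois(label, "L1")

    def test_placement_deterministic(self, small_phantom):
        a = place_rois(small_phantom.label_map, "L1")
        b = place_rois(small_phantom.label_map, "L1")
        assert a[0].center == b[0].center and a[1].center == b[1].center


class TestMeasureSI:
    def test_constant_image(self):
        label = _disc_label_map((32, 32), (16, 16), 8.0)
        roi, _ = place_rois(label, "L1")
        assert measure_si(np.full((32, 32), 7.0), roi) == 7.0

    def test_two_value_mean(self):
        from irllc.contrast import ROISample

        roi = ROISample("x", "lesion", (0, 0), 0, np.array([0, 0]), np.array([0, 1]))
        img = np.array([[0.0, 10.0]])
        assert measure_si(img, roi) == 5.0

    def test_out_of_bounds_rejected(self):
        from irllc.contrast import ROISample

        roi = ROISample("x", "lesion", (0, 0), 0, np.array([5]), np.array([0]))
        with pytest.raises(ValueError):
            measure_si(np.zeros((2, 2)), roi)


class TestLLC:
    @pytest.mark.parametrize(
        "liver, lesion, expected", [(100.0, 70.0, 0.3), (5.0, 5.0, 0.0), (50.0, 100.0, 1.0)]
    )
    def test_formula(self, liver, lesion, expected):
        assert llc(liver, lesion) == pytest.approx(expected, rel=1e-12)

    def test_scale_invariance(self):
        assert llc(100.0, 70.0) == llc(370.0, 259.0)

    def test_zero_liver_signal_undefined(self):
        with pytest.raises(UndefinedContrastError):
            llc(0.0, 1.0)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            llc(-1.0, 1.0)
        with pytest.raises(ValueError):
            llc(1.0, -1.0)


@pytest.fixture(scope="module")
def small_cohort_images():
    mix = {"CRC": 3, "HCC": 2, "melanoma": 1}
    cfg = CohortConfig(n_lesions=6, entity_mix=mix, patient_mix=None, seed=21)
    lesions = sample_cohort(cfg)
    acq = AcquisitionSpec(noise_sigma=0.0)
    return lesions, simulate_cohort_images(lesions, acq, master_seed=21), acq


class TestCohortTable:
    def test_cardinality_one_record_per_lesion_condition(self, small_cohort_images):
        lesions, images, _ = small_cohort_images
        table = build_cohort_table(images, covariates=cohort_frame(lesions))
        assert len(table) == 6 * 9  # 8 TIs + comparator
        assert table.groupby(["lesion_id", "condition"]).size().eq(1).all()

    def test_noise_free_llc_matches_closed_form(self, small_cohort_images):
        lesions, images, acq = small_cohort_images
        table = build_cohort_table(images, covariates=cohort_frame(lesions))
        for lesion in lesions:
            liver = IRModel(1.0, acq.b_over_a, lesion.t1_liver_ms / acq.kappa)
            les = IRModel(1.0, acq.b_over_a, lesion.t1_lesion_ms / acq.kappa)
            sub = table[table["lesion_id"] == lesion.lesion_id]
            for ti in acq.ti_list_ms:
                s_liv = ir_magnitude(ti, liver)
                s_les = ir_magnitude(ti, les)
                got = sub.loc[sub["condition"] == f"TI{int(ti)}", "llc"].item()
                assert got == pytest.approx(abs(s_liv - s_les) / s_liv, rel=1e-9)

    def test_global_scaling_leaves_table_unchanged(self, small_cohort_images):
        lesions, images, _ = small_cohort_images
        table = build_cohort_table(images)
        scaled = {
            lid: (
                type(series)(
                    data=series.data * 3.7,
                    ti_list_ms=series.ti_list_ms,
                    vibe=None if series.vibe is None else series.vibe * 3.7,
                    seed=series.seed,
                    meta=series.meta,
                ),
                label,
            )
            for lid, (series, label) in images.items()
        }
        table2 = build_cohort_table(scaled)
        assert np.allclose(table["llc"], table2["llc"], rtol=1e-12, equal_nan=True)

    def test_monotone_contrast_decay_beyond_lesion_null(self, small_cohort_images):
        """Noise-free per-lesion LLC falls strictly across the late TIs."""
        lesions, images, _ = small_cohort_images
        table = build_cohort_table(images, covariates=cohort_frame(lesions))
        late = ["TI946", "TI1025", "TI1343", "TI1743"]
        checked = 0
        for lesion in lesions:
            # the decay property applies to TIs beyond the lesion's null point
            if (lesion.t1_lesion_ms / 1.4) * np.log(2) >= 946:
                continue
            sub = table[table["lesion_id"] == lesion.lesion_id]
            vals = [sub.loc[sub["condition"] == c, "llc"].item() for c in late]
            assert all(a > b for a, b in zip(vals, vals[1:])), lesion.lesion_id
            checked += 1
        assert checked > 0

    def test_missing_condition_raises(self, small_cohort_images):
        _, images, _ = small_cohort_images
        with pytest.raises(CompletenessError):
            build_cohort_table(images, conditions=["TI148", "TI9999"])
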