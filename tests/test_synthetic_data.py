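"""Generators: determinism, truth consistency, class invariants."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from nigraquant.synthetic_data import (
    ClinicalCorpusParams,
    CohortSimParams,
    DabFixtureSpec,
    DabObject,
    HistologyFixtureParams,
    generate_clinical_corpus,
    generate_cohort,
    generate_dab_fixture,
    generate_histology_fixture,
    make_blob_mask,
    make_thread_mask,
    random_dab_spec,
)
from nigraquant.imaging_io import RoiPolygon


class TestHistologyFixture:
    def test_empty_fixture_is_pure_background(self):
        params = HistologyFixtureParams(
            image_width_px=200, image_height_px=200,
            n_pigmented=0, n_non_pigmented=0, pigment_clutter_density=0.0, seed=0,
        )
        image, _, truth = generate_histology_fixture(params)
        assert truth == []
        # Noisy background only: everything stays near the background color.
        assert np.all(np.abs(image.pixels.astype(int) - [228, 208, 216]) < 25)

    def test_same_seed_byte_identical(self):
        params = HistologyFixtureParams(
            image_width_px=300, image_height_px=300,
            n_pigmented=3, n_non_pigmented=2, seed=42,
        )
        img1, _, truth1 = generate_histology_fixture(params)
        img2, _, truth2 = generate_histology_fixture(params)
        assert np.array_equal(img1.pixels, img2.pixels)
        assert truth1 == truth2

    def test_requested_counts_appear_in_truth(self):
        """20 pigmented neurons on a ~2 mm² ROI -> exactly 20 truth entries
        with a pigmented label, counted independently of the generator."""
        params = HistologyFixtureParams(
            image_width_px=2853, image_height_px=2853,
            n_pigmented=20, n_non_pigmented=7, seed=9,
        )
        _, roi, truth = generate_histology_fixture(params)
        assert roi.area_mm2(params.microns_per_pixel) == pytest.approx(2.0, rel=0.01)
        n_pig = sum(1 for t in truth if t.label.startswith("pigmented"))
        n_non = sum(1 for t in truth if t.label.startswith("non_pigmented"))
        assert (n_pig, n_non) == (20, 7)

    def test_truth_boxes_inside_image_and_roi_bounds(self, small_histology):
        params, image, roi, truth = small_histology
        for t in truth:
            x, y, w, h = t.bbox
            assert w > 0 and h > 0
            assert 0 <= x and x + w <= image.width
            assert 0 <= y and y + h <= image.height

    def test_nucleolus_fraction_extremes(self):
        for frac, suffix in ((1.0, "nucleolus"), (0.0, "no_nucleolus")):
            params = HistologyFixtureParams(
                image_width_px=500, image_height_px=500,
                n_pigmented=4, n_non_pigmented=3,
                nucleolus_fraction=frac, seed=2,
            )
            _, _, truth = generate_histology_fixture(params)
            assert all(t.label.endswith(suffix) for t in truth)

    def test_overfull_image_rejected(self):
        params = HistologyFixtureParams(
            image_width_px=120, image_height_px=120,
            n_pigmented=200, n_non_pigmented=0, seed=0,
        )
        with pytest.raises(ValueError, match="capacity"):
            generate_histology_fixture(params)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            HistologyFixtureParams(image_width_px=0)
        with pytest.raises(ValueError):
            HistologyFixtureParams(nucleolus_fraction=1.5)
        with pytest.raises(ValueError):
            HistologyFixtureParams(n_pigmented=-1)


class TestDabFixture:
    def _roi(self, side=100):
        return RoiPolygon(vertices=((2, 2), (side - 2, 2), (side - 2, side - 2), (2, side - 2)))

    def test_empty_spec_zero_percent(self):
        spec = DabFixtureSpec(
            objects=(), roi=self._roi(), microns_per_pixel=0.5, map_shape=(100, 100)
        )
        od, expected = generate_dab_fixture(spec)
        assert expected == 0.0
        assert od.values.max() == 0.0

    def test_single_tangle_percent_by_pixel_count(self, rng):
        """One 100 µm² tangle in a 10,000 µm² ROI -> 1.0% by pixel count."""
        mpp = 1.0
        roi = RoiPolygon(vertices=((0, 0), (100, 0), (100, 100), (0, 100)))
        mask = make_blob_mask(100, rng)  # 100 px = 100 um² at 1 um/px
        spec = DabFixtureSpec(
            objects=(DabObject(mask=mask, origin=(30, 30), od_value=0.9, kind="tangle"),),
            roi=roi, microns_per_pixel=mpp, map_shape=(100, 100),
        )
        _, expected = generate_dab_fixture(spec)
        # ROI rasterizes to 100x100 px with pixel-center containment.
        assert expected == pytest.approx(1.0, abs=0.02)

    def test_pigment_contributes_zero_expected_area(self, rng):
        mask = make_blob_mask(300, rng)  # 75 um² at 0.5 um/px -> pigment-sized
        spec = DabFixtureSpec(
            objects=(DabObject(mask=mask, origin=(40, 40), od_value=0.5, kind="pigment"),),
            roi=self._roi(), microns_per_pixel=0.5, map_shape=(100, 100),
        )
        od, expected = generate_dab_fixture(spec)
        assert expected == 0.0
        assert od.values.max() == 0.5

    def test_kind_invariants_enforced(self, rng):
        roi = self._roi()
        big = make_blob_mask(300, rng)  # 75 um² at 0.5 um/px
        small = make_blob_mask(40, rng)  # 10 um²
        cases = [
            (big, 0.5, "thread"),  # thread too large
            (small, 0.9, "thread"),  # thread too dark
            (big, 0.5, "tangle"),  # tangle too faint
            (small, 0.5, "pigment"),  # pigment too small
            (big, 0.9, "pigment"),  # pigment too dark
        ]
        for mask, od, kind in cases:
            with pytest.raises(ValueError):
                DabFixtureSpec(
                    objects=(DabObject(mask=mask, origin=(30, 30), od_value=od, kind=kind),),
                    roi=roi, microns_per_pixel=0.5, map_shape=(100, 100),
                )

    def test_overlapping_objects_rejected(self, rng):
        mask = make_blob_mask(40, rng)
        objs = (
            DabObject(mask=mask, origin=(30, 30), od_value=0.5, kind="thread"),
            DabObject(mask=mask, origin=(31, 30), od_value=0.6, kind="thread"),
        )
        with pytest.raises(ValueError, match="overlap"):
            DabFixtureSpec(objects=objs, roi=self._roi(), microns_per_pixel=0.5,
                           map_shape=(100, 100))

    def test_object_outside_roi_rejected(self, rng):
        mask = make_blob_mask(40, rng)
        with pytest.raises(ValueError, match="ROI|map"):
            DabFixtureSpec(
                objects=(DabObject(mask=mask, origin=(97, 50), od_value=0.5, kind="thread"),),
                roi=self._roi(), microns_per_pixel=0.5, map_shape=(100, 100),
            )

    def test_shape_helpers_hit_exact_pixel_counts(self, rng):
        for n in (1, 7, 40, 160, 333):
            assert make_blob_mask(n, rng).sum() == n
            assert make_thread_mask(n, rng).sum() == n

    def test_random_specs_are_valid_and_deterministic(self):
        s1 = random_dab_spec(np.random.default_rng(11))
        s2 = random_dab_spec(np.random.default_rng(11))
        _, e1 = generate_dab_fixture(s1)
        _, e2 = generate_dab_fixture(s2)
        assert e1 == e2
        kinds = {o.kind for o in s1.objects}
        assert kinds <= {"thread", "tangle", "pigment"}


class TestClinicalCorpus:
    def test_forced_negation_yields_absent_truth(self):
        params = ClinicalCorpusParams(
            n_patients=5, p_affirmed=0.0, p_negated=1.0, p_indeterminate=0.0, seed=1
        )
        corpus = generate_clinical_corpus(params)
        assert (corpus.excerpt_truth["call"] == 0).all()
        symptom_cols = [c for c in corpus.patient_truth.columns if c != "parkinsonism"]
        assert (corpus.patient_truth[symptom_cols] == "absent").all().all()

    def test_no_mentions_gives_all_na(self):
        params = ClinicalCorpusParams(
            n_patients=1, p_affirmed=0.0, p_negated=0.0, p_indeterminate=0.0, seed=1
        )
        corpus = generate_clinical_corpus(params)
        assert corpus.excerpt_truth.empty
        assert (corpus.patient_truth.iloc[0] == "NA").all()

    def test_deterministic_and_counts_match_planted(self, small_corpus):
        params, corpus = small_corpus
        again = generate_clinical_corpus(params)
        assert corpus.documents == again.documents
        pd.testing.assert_frame_equal(corpus.excerpt_truth, again.excerpt_truth)
        # One planted mention row per mention sentence in the documents.
        n_mentions = sum(
            1
            for text in corpus.documents.values()
            for line in text.split("\n")
            if any(
                key in line
                for key in ("was noted", "exhibited", "revealed", "No ", "denies",
                            "Negative for", "could not be assessed", "Possible",
                            "Family history")
            )
        )
        assert len(corpus.excerpt_truth) == n_mentions

    def test_empty_dictionary_rejected(self):
        from nigraquant.record_abstraction import SymptomDictionary

        with pytest.raises(ValueError):
            SymptomDictionary(entries={})


class TestCohortSimulator:
    def test_null_shift_same_distribution(self):
        p1 = CohortSimParams(n_cases=4000, group_shift=1.0, missingness=0.0, seed=7)
        cohort = generate_cohort(p1)
        x = cohort.loc[cohort.parkinsonism == "present", "neuron_density"]
        y = cohort.loc[cohort.parkinsonism == "absent", "neuron_density"]
        assert abs(np.median(x) - np.median(y)) / np.median(y) < 0.05

    def test_zero_prevalence_no_cases(self):
        cohort = generate_cohort(CohortSimParams(n_cases=50, prevalence_parkinsonism=0.0, seed=1))
        assert (cohort.parkinsonism == "absent").all()

    def test_planted_median_ratio_recovered_at_large_n(self):
        """n=10,000 with shift 0.83 -> empirical median ratio ~0.83."""
        cohort = generate_cohort(
            CohortSimParams(n_cases=10_000, prevalence_parkinsonism=0.5,
                            group_shift=0.83, seed=3)
        )
        x = cohort.loc[cohort.parkinsonism == "present", "neuron_density"].median()
        y = cohort.loc[cohort.parkinsonism == "absent", "neuron_density"].median()
        assert x / y == pytest.approx(0.83, abs=0.02)

    def test_symptoms_consistent_with_flag(self):
        cohort = generate_cohort(CohortSimParams(n_cases=300, missingness=0.0, seed=2))
        pdm = cohort.parkinsonism == "present"
        assert (cohort.loc[pdm, "bradykinesia"] == "present").all()
        assert (
            (cohort.loc[pdm, "rigidity"] == "present")
            | (cohort.loc[pdm, "rest_tremor"] == "present")
        ).all()

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            CohortSimParams(group_shift=0.0)
        with pytest.raises(ValueError):
            CohortSimParams(prevalence_parkinsonism=1.5)
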