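"""Synthetic cohort / image / embedding generator contracts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ngtlife as ng
from ngtlife.errors import ConfigurationError, EmptyCohortError
from ngtlife.synth import tip_region

PAPER_COUNTS = {"satisfactory": 4100, "malpositioned": 2500, "bronchial": 481}


class TestGenerateManifest:
    def test_empty_cohort(self):
        df = ng.generate_manifest(ng.SynthConfig(n_images=0))
        assert len(df) == 0 and "record_id" in df.columns

    def test_degenerate_prior_gives_single_class(self):
        df = ng.generate_manifest(
            ng.SynthConfig(n_images=50, class_priors=(1.0, 0.0, 0.0), seed=3)
        )
        assert (df["label"] == "satisfactory").all()

    def test_invalid_priors_rejected(self):
        with pytest.raises(ConfigurationError):
            ng.generate_manifest(ng.SynthConfig(class_priors=(0.5, 0.5, 0.5)))

    def test_archive_prevalence_counts_within_3_binomial_sd(self):
        # source archive: 4100 / 2500 / 481 of 7081
        n = 7081
        cfg = ng.SynthConfig(n_images=n, seed=11)
        counts = ng.generate_manifest(cfg)["label"].value_counts()
        for cls, expect in PAPER_COUNTS.items():
            p = expect / n
            sd = np.sqrt(n * p * (1 - p))
            assert abs(counts[cls] - expect) <= 3 * sd

    def test_deterministic_given_seed(self):
        cfg = ng.SynthConfig(n_images=80, seed=5)
        pd.testing.assert_frame_equal(ng.generate_manifest(cfg), ng.generate_manifest(cfg))

    def test_schema_and_record_content(self, small_manifest):
        from ngtlife.io import MANIFEST_COLUMNS

        df = small_manifest
        assert list(df.columns) == MANIFEST_COLUMNS
        assert set(df["view"]) <= {"AP", "PA"}
        assert set(df["sex"]) <= {"M", "F"}
        # report text carries the retention keywords
        assert df["report_text"].str.contains("tube", case=False).all()
        # ISO dates, age derivable and adult-dominated
        age = (pd.to_datetime(df["study_date"]) - pd.to_datetime(df["birth_date"])).dt.days
        assert (age > 0).all()

    def test_patients_reused_across_records(self):
        df = ng.generate_manifest(ng.SynthConfig(n_images=300, seed=2))
        assert df["patient_id"].nunique() < len(df)
        # patient attributes constant within patient
        per = df.groupby("patient_id")[["sex", "birth_date"]].nunique()
        assert (per <= 1).all().all()


class TestRenderImage:
    CFG = ng.SynthConfig(n_images=10, seed=4, noise_sd=0.0)

    def test_deterministic_bit_identical(self, small_manifest):
        rec = small_manifest.iloc[0]
        a = ng.render_image(rec, self.CFG).pixels
        b = ng.render_image(rec, self.CFG).pixels
        assert np.array_equal(a, b)

    @pytest.mark.parametrize("label", ng.CLASSES)
    def test_tip_inside_declared_region(self, label):
        rec = {"record_id": "R000009", "label": label, "manufacturer": "Systemix",
               "department": "A&E", "birth_date": "1950-01-01", "study_date": "2015-01-01"}
        im = ng.render_image(rec, self.CFG)
        r0, r1, c0, c1 = tip_region(label, self.CFG.image_size)
        assert r0 <= im.tip_xy[0] < r1 and c0 <= im.tip_xy[1] < c1

    def test_unknown_label_raises(self):
        rec = {"record_id": "R000001", "label": "esophageal", "manufacturer": "x",
               "department": "A&E", "birth_date": "1950-01-01", "study_date": "2015-01-01"}
        with pytest.raises(ValueError):
            ng.render_image(rec, self.CFG)

    def test_manufacturer_offset_shifts_mean_intensity(self):
        cfg = ng.SynthConfig(
            n_images=1, seed=9, noise_sd=30.0,
            manufacturer_levels=(("A", 0.0), ("B", 200.0)),
        )
        base = {"record_id": "R000003", "label": "satisfactory", "department": "A&E",
                "birth_date": "1950-01-01", "study_date": "2015-01-01"}
        im_a = ng.render_image({**base, "manufacturer": "A"}, cfg).pixels.astype(float)
        im_b = ng.render_image({**base, "manufacturer": "B"}, cfg).pixels.astype(float)
        tol = 3 * cfg.noise_sd / cfg.image_size + 1.0  # sampling + quantization
        assert abs((im_b - im_a).mean() - 200.0) <= tol

    def test_pixels_within_16bit_range(self, small_manifest):
        im = ng.render_image(small_manifest.iloc[3], ng.SynthConfig(seed=1))
        assert im.pixels.dtype == np.uint16


class TestSynthEmbeddings:
    def test_zero_noise_rows_equal_centers(self):
        centers = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        es = ng.synth_embeddings([4, 3, 2], centers, noise_sd=0.0, seed=0)
        for i, cls in enumerate(ng.CLASSES):
            assert np.allclose(es.X[es.labels == cls], centers[i])

    def test_output_dimension_matches_centers(self):
        es = ng.synth_embeddings([5, 5, 5], np.zeros((3, 7)), noise_sd=1.0, seed=0)
        assert es.X.shape == (15, 7)

    def test_mismatched_dimensions_raise(self):
        with pytest.raises(ValueError):
            ng.synth_embeddings([5, 5], np.zeros((3, 4)))
        with pytest.raises(ValueError):
            ng.synth_embeddings([5, 5, 5], np.zeros((3, 4)),
                                tag_effects={"t": np.zeros(3)})

    def test_seeded_reproducibility(self):
        a = ng.synth_embeddings([10, 10, 10], np.eye(3), noise_sd=1.0, seed=42)
        b = ng.synth_embeddings([10, 10, 10], np.eye(3), noise_sd=1.0, seed=42)
        assert np.array_equal(a.X, b.X)


class TestApplyDrift:
    def _embeddings(self, n=300, seed=0):
        return ng.synth_embeddings([n, 0, 0], np.zeros((3, 2)), noise_sd=1.0, seed=seed)

    def test_zero_mean_shift_is_identity(self):
        es = self._embeddings()
        out = ng.apply_drift(es, ng.DriftSpec("mean_shift", 0.0))
        assert np.allclose(out.X, es.X)

    def test_mean_shift_moves_means_by_sd_units(self):
        es = self._embeddings(n=2000)
        out = ng.apply_drift(es, ng.DriftSpec("mean_shift", 5.0))
        sd = es.X.std(axis=0)
        diff = out.X.mean(axis=0) - es.X.mean(axis=0)
        assert np.allclose(diff, 5.0 * sd, rtol=1e-9)

    def test_input_never_mutated_and_provenance_recorded(self, small_manifest):
        before = small_manifest.copy()
        out = ng.apply_drift(small_manifest, ng.DriftSpec("manufacturer_swap"))
        pd.testing.assert_frame_equal(small_manifest, before)
        # the whole candidate cohort now comes from one (initially rarest) system
        assert out["manufacturer"].nunique() == 1
        assert out["manufacturer"].iloc[0] == (
            small_manifest["manufacturer"].value_counts().index[-1]
        )
        assert any("manufacturer_swap" in p for p in out.attrs["provenance"])

    def test_disjoint_age_band_raises_empty_cohort(self):
        df = ng.generate_manifest(ng.SynthConfig(n_images=40, seed=8,
                                                 age_distribution=(69.0, 3.0, 62.0)))
        band = ng.apply_drift(df, ng.DriftSpec("age_band", (62.0, 76.0)))
        assert len(band) > 0
        with pytest.raises(EmptyCohortError):
            ng.apply_drift(band, ng.DriftSpec("age_band", (16.0, 62.0)))

    def test_injected_shift_is_ks_detectable(self):
        # 3-SD mean shift must reject at alpha=0.01 with 200 points per side
        es = self._embeddings(n=200, seed=3)
        out = ng.apply_drift(es, ng.DriftSpec("mean_shift", 3.0))
        _, p = ng.ks_2sample(es.X[:, 0], out.X[:, 0])
        assert p < 0.01
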