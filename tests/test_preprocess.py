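"""Preprocessing tests: rendering, state identification, pixel operations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tetcad import STATES
from tetcad import pdfio
from tetcad.preprocess import (
    BinarizationSpec,
    CropRect,
    MissingStateError,
    SidecarTextExtractor,
    binarize,
    crop_region,
    default_config,
    identify_state_pages,
    load_config,
    match_state_keyword,
    normalize_text,
    preprocess_report,
    render_report,
    to_grayscale,
    StatePageImage,
)


class TestNormalizeAndMatch:
    @pytest.mark.parametrize("raw,expected", [
        ("PRE-TEST  Stage 1!", "preteststage1"),
        ("", ""),
        ("Recovery 01:30", "recovery0130"),
    ])
    def test_normalize_examples(self, raw, expected):
        assert normalize_text(raw) == expected

    @given(st.text(max_size=80))
    @settings(max_examples=200, deadline=None)
    def test_normalized_text_is_lowercase_alphanumeric_and_idempotent(self, raw):
        out = normalize_text(raw)
        assert all(c.islower() or c.isdigit() for c in out)
        assert normalize_text(out) == out

    @pytest.mark.parametrize("text,expected", [
        ("preteststage1", "pretest"),
        ("xyz123", None),
        ("recoverythenpretest", "pretest"),  # priority order wins
        ("duringexercise", "exercise"),
    ])
    def test_keyword_match(self, text, expected):
        assert match_state_keyword(text) == expected


class TestIdentifyStates:
    def _pages(self, texts):
        pages = [StatePageImage(np.zeros((4, 4), np.uint8), source_page_index=i)
                 for i in range(len(texts))]
        return pages, SidecarTextExtractor(texts)

    def test_in_order_pages(self):
        pages, ext = self._pages(["Pretest", "Exercise", "Recovery"])
        assert identify_state_pages(pages, ext) == {
            "pretest": 0, "exercise": 1, "recovery": 2}

    def test_shuffled_pages(self):
        pages, ext = self._pages(["Recovery", "Pretest", "Exercise"])
        assert identify_state_pages(pages, ext) == {
            "pretest": 1, "exercise": 2, "recovery": 0}

    def test_missing_state_is_named(self):
        pages, ext = self._pages(["Pretest", "Recovery"])
        with pytest.raises(MissingStateError, match="exercise"):
            identify_state_pages(pages, ext)


class TestPixelOps:
    def test_crop_full_image_is_identity(self, rng):
        img = rng.integers(0, 256, (8, 10), dtype=np.uint8)
        np.testing.assert_array_equal(
            crop_region(img, CropRect(0, 0, 10, 8)), img)

    def test_crop_matches_index_arithmetic(self):
        ramp = np.arange(16, dtype=np.uint8).reshape(4, 4)
        out = crop_region(ramp, CropRect(1, 1, 2, 2))
        np.testing.assert_array_equal(out, ramp[1:3, 1:3])

    def test_crop_out_of_bounds_raises(self):
        img = np.zeros((4, 4), np.uint8)
        with pytest.raises(ValueError, match="bounds"):
            crop_region(img, CropRect(1, 0, 4, 4))

    @pytest.mark.parametrize("pixel,expected", [
        ((255, 255, 255), 255),
        ((255, 0, 0), 76),       # round(0.299 * 255)
        ((0, 255, 0), 150),      # round(0.587 * 255)
    ])
    def test_grayscale_weights(self, pixel, expected):
        img = np.array([[pixel]], dtype=np.uint8)
        assert to_grayscale(img)[0, 0] == expected

    def test_grayscale_passthrough(self, rng):
        gray = rng.integers(0, 256, (5, 5), dtype=np.uint8)
        assert to_grayscale(gray) is gray

    def test_binarize_elementwise(self):
        img = np.array([[10, 200], [120, 90]], dtype=np.uint8)
        out = binarize(img, BinarizationSpec(threshold=128))
        np.testing.assert_array_equal(out, [[0, 255], [0, 0]])

    def test_binarize_uniform_above_threshold(self):
        out = binarize(np.full((3, 3), 200, np.uint8), BinarizationSpec(threshold=128))
        assert (out == 255).all()

    def test_binarize_polarity_flag_inverts(self):
        img = np.array([[10, 200]], dtype=np.uint8)
        flipped = binarize(img, BinarizationSpec(128, "trace_light_on_black"))
        np.testing.assert_array_equal(flipped, [[255, 0]])

    def test_binarize_threshold_validated(self):
        with pytest.raises(ValueError):
            BinarizationSpec(threshold=300)

    @given(st.integers(1, 254))
    @settings(max_examples=50, deadline=None)
    def test_binarize_idempotent(self, threshold):
        rng = np.random.default_rng(threshold)
        img = rng.integers(0, 256, (6, 6), dtype=np.uint8)
        spec = BinarizationSpec(threshold=threshold)
        once = binarize(img, spec)
        np.testing.assert_array_equal(binarize(once, spec), once)

    def test_crop_grayscale_commute(self, rng):
        img = rng.integers(0, 256, (10, 12, 3), dtype=np.uint8)
        rect = CropRect(2, 3, 5, 4)
        np.testing.assert_array_equal(
            to_grayscale(crop_region(img, rect)),
            crop_region(to_grayscale(img), rect),
        )


class TestRenderReport:
    def test_pass_through_at_target_size(self, rng):
        arr = rng.integers(0, 256, (640, 1080), dtype=np.uint8)
        pages = render_report([arr])
        np.testing.assert_array_equal(pages[0].pixels, arr)
        assert pages[0].state is None

    def test_downsampling_matches_block_mean(self):
        # 2x downsample with the box kernel equals the 2x2 block mean
        rng = np.random.default_rng(0)
        src = rng.integers(0, 256, (16, 16), dtype=np.uint8)
        pages = render_report([src], target_size=(8, 8))
        expected = src.reshape(8, 2, 8, 2).mean(axis=(1, 3))
        np.testing.assert_allclose(pages[0].pixels, np.round(expected), atol=1)

    def test_empty_document_rejected(self):
        with pytest.raises(ValueError, match="pages"):
            render_report([])

    def test_pdf_round_trip(self, tmp_path, rng):
        arrays = [rng.integers(0, 256, (64, 108), dtype=np.uint8) for _ in range(3)]
        path = tmp_path / "report.pdf"
        pdfio.write_pdf(arrays, path)
        pages = render_report(path, target_size=(108, 64))
        assert len(pages) == 3
        for src, page in zip(arrays, pages):
            np.testing.assert_array_equal(page.pixels, src)

    def test_pdf_rgb_round_trip(self, tmp_path, rng):
        arr = rng.integers(0, 256, (32, 48, 3), dtype=np.uint8)
        path = tmp_path / "one.pdf"
        pdfio.write_pdf([arr], path)
        np.testing.assert_array_equal(pdfio.read_pdf(path)[0], arr)

    def test_non_pdf_rejected(self, tmp_path):
        bad = tmp_path / "fake.pdf"
        bad.write_bytes(b"not a pdf at all")
        with pytest.raises(ValueError, match="not a PDF"):
            pdfio.read_pdf(bad)


class TestFullPipeline:
    def test_synthetic_reports_come_out_ordered_and_binary(self, cohort_dir, small_cohort):
        _, patients, _ = small_cohort
        pdir = cohort_dir / patients[0].patient_id
        extractor = SidecarTextExtractor.from_patient_dir(pdir)
        pages = preprocess_report(pdir, extractor)
        assert [p.state for p in pages] == list(STATES)
        cfg = default_config()
        for page in pages:
            assert page.pixels.shape == (cfg.crop.height, cfg.crop.width)
            assert set(np.unique(page.pixels)) <= {0, 255}

    def test_state_identification_matches_sidecar_truth(self, cohort_dir, small_cohort):
        import json

        _, patients, _ = small_cohort
        for patient in patients:
            pdir = cohort_dir / patient.patient_id
            truth = json.loads((pdir / "truth.json").read_text())
            extractor = SidecarTextExtractor.from_patient_dir(pdir)
            pages = render_report(pdir)
            mapping = identify_state_pages(pages, extractor)
            files = sorted(truth["pages"])
            for state, idx in mapping.items():
                assert truth["pages"][files[idx]] == state

    def test_missing_page_raises_missing_state(self, small_cohort):
        _, patients, _ = small_cohort
        patient = patients[0]
        arrays = [patient.pages["pretest"], patient.pages["recovery"]]
        extractor = SidecarTextExtractor(["pretest", "recovery"])
        with pytest.raises(MissingStateError, match="exercise"):
            preprocess_report(arrays, extractor)

    def test_yaml_config_round_trip(self, tmp_path):
        cfg_file = tmp_path / "prep.yaml"
        cfg_file.write_text(
            "target_size: [540, 320]\n"
            "crop: {left: 0, top: 20, width: 540, height: 300}\n"
            "threshold: 100\n"
        )
        cfg = load_config(cfg_file)
        assert cfg.target_size == (540, 320)
        assert cfg.crop == CropRect(0, 20, 540, 300)
        assert cfg.binarization.threshold == 100
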