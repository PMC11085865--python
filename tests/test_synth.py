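"""Generator tests: waveform shape, page rendering, cohort bookkeeping."""

import numpy as np
import pytest

from tetcad import STATES
from tetcad.preprocess import BinarizationSpec, binarize
from tetcad.synth import (
    AGE_BIN_PROBABILITIES,
    SyntheticCohortConfig,
    WaveformParams,
    draw_demographics,
    generate_cohort,
    patient_waveform_params,
    render_state_page,
    st_sample_mask,
    synth_trace,
    trace_mask,
)


class TestWaveform:
    def test_exactly_periodic_at_integer_rate(self):
        # one beat per second at 250 Hz: the period is exactly 250 samples
        params = WaveformParams(heart_rate_bpm=60, sampling_rate=250, duration_s=2.0)
        trace = synth_trace(params)
        assert len(trace) == 500
        np.testing.assert_array_equal(trace[:250], trace[250:])

    def test_st_offset_touches_only_st_samples(self):
        base = WaveformParams(heart_rate_bpm=60)
        shifted = WaveformParams(heart_rate_bpm=60, st_offset=-0.2)
        t0, t1 = synth_trace(base), synth_trace(shifted)
        mask = st_sample_mask(base)
        assert mask.any() and not mask.all()
        assert np.any(t0[mask] != t1[mask])
        np.testing.assert_array_equal(t0[~mask], t1[~mask])

    def test_noise_magnitude_matches_halfnormal_mean(self):
        # |N(0, s)| has mean s*sqrt(2/pi); the empirical mean absolute
        # deviation from the clean trace must sit within 3 s/sqrt(n)
        sd = 0.05
        clean = synth_trace(WaveformParams(heart_rate_bpm=70, duration_s=8.0))
        noisy = synth_trace(
            WaveformParams(heart_rate_bpm=70, duration_s=8.0, noise_sd=sd),
            rng=np.random.default_rng(7),
        )
        n = len(clean)
        mad = np.abs(noisy - clean).mean()
        expected = sd * np.sqrt(2.0 / np.pi)
        assert abs(mad - expected) < 3.0 * sd / np.sqrt(n)

    @pytest.mark.parametrize("bad", [
        dict(heart_rate_bpm=0),
        dict(heart_rate_bpm=-50),
        dict(heart_rate_bpm=60, sampling_rate=0),
        dict(heart_rate_bpm=60, noise_sd=-0.1),
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            WaveformParams(**bad)

    def test_noise_requires_rng(self):
        with pytest.raises(ValueError, match="rng"):
            synth_trace(WaveformParams(heart_rate_bpm=60, noise_sd=0.1))


class TestPageRendering:
    def test_default_page_resolution(self):
        page = render_state_page([np.zeros(100)] * 12, "pretest")
        assert page.shape == (640, 1080)  # 1080 x 640 as (H, W)

    def test_blank_traces_draw_horizontal_lines_and_grid(self):
        page = render_state_page([np.zeros(100)] * 12, "exercise")
        mask = trace_mask([np.zeros(100)] * 12)
        # every trace pixel is dark, and grid pixels exist outside traces
        assert (page[mask] == 0).all()
        assert (page == 220).sum() > 1000

    def test_trace_count_must_be_twelve(self):
        with pytest.raises(ValueError, match="12"):
            render_state_page([np.zeros(100)] * 11, "pretest")

    def test_binarization_keeps_traces_and_removes_grid(self):
        traces = [synth_trace(WaveformParams(heart_rate_bpm=70 + i)) for i in range(12)]
        page = render_state_page(traces, "recovery")
        mask = trace_mask(traces)
        binary = binarize(page, BinarizationSpec(threshold=128))
        assert (binary[mask] == 0).mean() >= 0.99
        grid = (page == 220) & ~mask
        assert (binary[grid] == 255).all()


class TestCohort:
    def test_reference_prevalence_gives_exact_label_counts(self):
        cfg = SyntheticCohortConfig(n_patients=416, prevalence=192 / 416, seed=0)
        labels = []
        from tetcad.synth import _labels
        labels = _labels(cfg)
        assert labels.sum() == 192 and (~labels).sum() == 224

    def test_zero_prevalence_is_all_negative(self):
        cfg = SyntheticCohortConfig(n_patients=10, prevalence=0.0, seed=1,
                                    page_size=(216, 128))
        patients, metadata = generate_cohort(cfg)
        assert set(metadata["label"]) == {"non-CAD"}
        for p in patients:
            assert all(w.st_offset == 0 for w in p.params.values())

    def test_age_bins_match_multinomial_expectation(self):
        cfg = SyntheticCohortConfig(n_patients=5, seed=0)
        from tetcad.evaluate import age_bin
        from tetcad.synth import _rng
        n = 1000
        counts = np.zeros(5)
        order = ("<=40", "(40,50]", "(50,60]", "(60,70]", ">70")
        for i in range(n):
            _, age = draw_demographics(cfg, _rng(0, 9, i))
            counts[order.index(age_bin(age))] += 1
        p = np.asarray(AGE_BIN_PROBABILITIES)
        sd = np.sqrt(n * p * (1 - p))
        assert (np.abs(counts - n * p) <= 4 * sd).all()

    def test_generation_is_deterministic(self):
        cfg = SyntheticCohortConfig(n_patients=3, seed=11, page_size=(216, 128))
        p1, m1 = generate_cohort(cfg)
        p2, m2 = generate_cohort(cfg)
        assert m1.equals(m2)
        for a, b in zip(p1, p2):
            for state in STATES:
                np.testing.assert_array_equal(a.pages[state], b.pages[state])

    def test_heart_rate_ordering_invariant(self, small_cohort):
        _, patients, _ = small_cohort
        for p in patients:
            assert p.params["exercise"].heart_rate_bpm > p.params["pretest"].heart_rate_bpm

    def test_invalid_prevalence_rejected(self):
        with pytest.raises(ValueError, match="prevalence"):
            SyntheticCohortConfig(n_patients=10, prevalence=1.5)


class TestInterStateOnlyMode:
    def test_pretest_pages_identical_across_classes_with_matched_params(self):
        cfg = SyntheticCohortConfig(n_patients=2, seed=0, noise_sd=0.0,
                                    inter_state_only=True)
        params_cad = patient_waveform_params(cfg, np.random.default_rng(5), True)
        params_non = patient_waveform_params(cfg, np.random.default_rng(5), False)
        from tetcad.synth import state_traces
        page = {
            lab: {
                s: render_state_page(state_traces(prm[s]), s)
                for s in ("pretest", "exercise")
            }
            for lab, prm in (("cad", params_cad), ("non", params_non))
        }
        np.testing.assert_array_equal(page["cad"]["pretest"], page["non"]["pretest"])
        assert np.any(page["cad"]["exercise"] != page["non"]["exercise"])
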