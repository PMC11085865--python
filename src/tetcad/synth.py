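"""Synthetic simplified TET report generator.

Emulates the statistical structure the multi-state network is designed to
exploit: each patient contributes three 12-lead ECG report pages (pretest,
exercise, recovery) on a light grid background with the state keyword
printed in a banner, plus a labels/metadata table.  The class signal is
carried by state-dependent waveform changes for CAD patients --
exercise-induced ST-segment depression and T-wave inversion --
superimposed on class-independent per-lead nuisances (resting ST level,
non-specific resting T inversion) shared across the three states.  A
single state in isolation is therefore only weakly informative and the
discriminative clue is the *change* relative to the patient's own
pretest, as in real treadmill-test interpretation.

The quasi-ECG waveform is a sum of Gaussian bumps (P and T waves), a
triangular QRS complex and a piecewise-constant ST level; each lead tile
shows a fixed number of representative beats (median-beat style layout),
so the three states stay phase-aligned on the page.  It is not a
physiologically faithful ECG; it is a controllable stand-in whose class
effects can be isolated exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

from . import LEAD_NAMES, STATES
from . import defaults

__all__ = [
    "WaveformParams", "SyntheticCohortConfig", "SyntheticPatient",
    "synth_trace", "state_traces", "st_sample_mask", "render_state_page",
    "trace_mask", "draw_demographics", "patient_waveform_params",
    "generate_cohort", "iter_cohort", "write_cohort",
    "GENDER_PROPORTIONS", "AGE_BIN_PROBABILITIES", "AGE_BIN_RANGES",
    "ST_EFFECT", "T_WAVE_EFFECT", "DEFAULT_PREVALENCE", "BEATS_PER_PAGE",
]

# Demographic defaults normalized from the 416-patient cohort the generator
# emulates: 299 male / 117 female; age bins {<=40, (40,50], (50,60], (60,70],
# >70} with reported counts 16 / 39 / 119 / 118 / 4 (normalized by their sum).
GENDER_PROPORTIONS = (299 / 416, 117 / 416)  # (male, female)
_AGE_COUNTS = (16, 39, 119, 118, 4)
AGE_BIN_PROBABILITIES = tuple(c / sum(_AGE_COUNTS) for c in _AGE_COUNTS)
AGE_BIN_RANGES = ((18, 40), (41, 50), (51, 60), (61, 70), (71, 85))
DEFAULT_PREVALENCE = 192 / 416  # obstructive-CAD fraction

# Class effect: additional ST shift (trace units) per state for CAD patients.
# Exercise-induced depression, partially persisting into recovery, with a
# mild resting component; the "inter-state-only" mode zeroes the pretest
# component so the signal is purely cross-state.
ST_EFFECT = {"pretest": -0.05, "exercise": -0.15, "recovery": -0.1}

# Each lead tile shows this many representative beats regardless of heart
# rate (median-beat style layout, as on clinical report pages); the states
# therefore stay phase-aligned on the page while the exercise heart rate
# still exceeds the pretest one.
BEATS_PER_PAGE = 3

# Second component of the class effect: exercise-induced T-wave inversion
# (flattening persisting into recovery), expressed as a multiplier on the
# patient's resting T-wave scale.  1.0 means unchanged.
T_WAVE_EFFECT = {"pretest": 1.0, "exercise": -1.0, "recovery": -1.0}

# Per-lead resting ST baseline (both classes), drawn uniformly from this
# interval independently for each lead and shared across the three states;
# its spread exceeds the class effect so single-state marginals overlap
# between classes, and the lead-wise variation means only within-lead
# cross-state comparison cancels it.
BASELINE_ST_RANGE = (-0.35, 0.35)

# Probability that a lead shows non-specific resting T-wave inversion
# (both classes), independently per lead and carried through every state.
# At 0.5 the single-state T polarity of a lead carries no label
# information at all; the diagnostic clue is the change of polarity
# relative to the same lead's pretest.
BASELINE_T_INVERTED_PROB = 0.5

# Relative trace amplitude per lead, loosely shaped like a standard report.
LEAD_AMPLITUDE = (1.0, 1.1, 0.9, 0.8, 0.85, 0.95, 0.7, 0.9, 1.05, 1.1, 1.0, 0.95)


@dataclass
class WaveformParams:
    """Waveform parameters for one patient in one state.

    ``st_offset`` is the CAD class effect (0 for non-CAD patients in every
    state); ``baseline_st`` is a class-independent nuisance resting ST
    level.  ``amplitude_scale``, ``baseline_st`` and ``t_wave_scale`` may
    each be a scalar or a per-lead array of 12 (negative ``t_wave_scale``
    renders an inverted T wave).
    """

    heart_rate_bpm: float
    amplitude_scale: float | np.ndarray = 1.0
    baseline_st: float = 0.0
    st_offset: float = 0.0
    t_wave_scale: float = 1.0
    noise_sd: float = 0.0
    sampling_rate: float = 250.0
    duration_s: float = 2.0

    def __post_init__(self) -> None:
        if self.heart_rate_bpm <= 0:
            raise ValueError(f"heart rate must be positive, got {self.heart_rate_bpm}")
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.sampling_rate}")
        if self.duration_s <= 0:
            raise ValueError(f"duration must be positive, got {self.duration_s}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be non-negative, got {self.noise_sd}")
        if np.any(np.asarray(self.amplitude_scale) <= 0):
            raise ValueError("amplitude_scale must be positive")


# Beat morphology in beat-phase units (phase in [0, 1) within each beat).
_P_CENTER, _P_WIDTH, _P_AMPL = 0.16, 0.025, 0.12
_Q_CENTER, _Q_WIDTH, _Q_AMPL = 0.27, 0.015, -0.12
_R_CENTER, _R_WIDTH, _R_AMPL = 0.30, 0.020, 1.00
_S_CENTER, _S_WIDTH, _S_AMPL = 0.33, 0.015, -0.20
ST_PHASE_WINDOW = (0.36, 0.50)
_T_CENTER, _T_WIDTH, _T_AMPL = 0.60, 0.055, 0.45


def _triangle(phase: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.clip(1.0 - np.abs(phase - center) / width, 0.0, None)


def st_sample_mask(params: WaveformParams) -> np.ndarray:
    """Boolean mask of the samples lying in the ST phase window."""
    phase = _beat_phase(params)
    lo, hi = ST_PHASE_WINDOW
    return (phase > lo) & (phase <= hi)


def _beat_phase(params: WaveformParams) -> np.ndarray:
    n = int(round(params.duration_s * params.sampling_rate))
    # remainder before the division keeps the phase exactly periodic when
    # k * heart_rate lands on exact floats (e.g. integer heart rates)
    num = np.arange(n, dtype=np.float64) * params.heart_rate_bpm
    return np.remainder(num, 60.0 * params.sampling_rate) / (60.0 * params.sampling_rate)


def _lead_value(value, lead: int) -> float:
    arr = np.asarray(value, dtype=float).ravel()
    if arr.size == 1:
        return float(arr[0])
    if arr.size != 12:
        raise ValueError(f"per-lead parameter must have 12 entries, got {arr.size}")
    return float(arr[lead])


def synth_trace(
    params: WaveformParams,
    rng: np.random.Generator | None = None,
    lead: int = 0,
) -> np.ndarray:
    """Synthesize one lead's quasi-periodic ECG trace.

    The trace is P bump + triangular QRS + ST level (baseline_st +
    st_offset, confined to the ST phase window) + T bump, scaled by the
    lead amplitude, with optional additive Gaussian noise drawn from *rng*.
    """
    n = int(round(params.duration_s * params.sampling_rate))
    if n < 60.0 / params.heart_rate_bpm * params.sampling_rate:
        raise ValueError("duration must cover at least one beat period")
    phase = _beat_phase(params)
    trace = _P_AMPL * np.exp(-(((phase - _P_CENTER) / _P_WIDTH) ** 2))
    trace += _Q_AMPL * _triangle(phase, _Q_CENTER, _Q_WIDTH)
    trace += _R_AMPL * _triangle(phase, _R_CENTER, _R_WIDTH)
    trace += _S_AMPL * _triangle(phase, _S_CENTER, _S_WIDTH)
    t_scale = _lead_value(params.t_wave_scale, lead)
    trace += t_scale * _T_AMPL * np.exp(-(((phase - _T_CENTER) / _T_WIDTH) ** 2))
    lo, hi = ST_PHASE_WINDOW
    st_level = _lead_value(params.baseline_st, lead) + params.st_offset
    trace[(phase > lo) & (phase <= hi)] += st_level
    trace = _lead_value(params.amplitude_scale, lead) * trace
    if params.noise_sd > 0:
        if rng is None:
            raise ValueError("noise_sd > 0 requires an rng for reproducibility")
        trace = trace + rng.normal(0.0, params.noise_sd, size=n)
    return trace


def state_traces(params: WaveformParams, rng: np.random.Generator | None = None) -> np.ndarray:
    """All 12 lead traces for one state as a (12, n) array."""
    return np.stack([synth_trace(params, rng=rng, lead=g) for g in range(12)])


# ---------------------------------------------------------------------------
# page rendering


def _tile_bounds(extent: int, parts: int) -> list[tuple[int, int]]:
    edges = [round(i * extent / parts) for i in range(parts + 1)]
    return [(edges[i], edges[i + 1]) for i in range(parts)]


def _trace_polyline(trace, rect, gain: float, margin: int = 6):
    left, top, right, bottom = rect
    n = len(trace)
    xs = left + margin + (right - left - 2 * margin - 1) * np.arange(n) / max(n - 1, 1)
    cy = (top + bottom) / 2.0
    ys = np.clip(cy - gain * np.asarray(trace), top + 1, bottom - 2)
    return list(zip(xs.tolist(), ys.tolist()))


def _draw_traces(draw: ImageDraw.ImageDraw, traces, page_size, lead_layout,
                 banner_height: int, gain: float, fill: int) -> None:
    width, height = page_size
    rows, cols = lead_layout
    row_bounds = _tile_bounds(height - banner_height, rows)
    col_bounds = _tile_bounds(width, cols)
    for g, trace in enumerate(traces):
        r, c = divmod(g, cols)
        top = banner_height + row_bounds[r][0]
        bottom = banner_height + row_bounds[r][1]
        left, right = col_bounds[c]
        draw.line(_trace_polyline(trace, (left, top, right, bottom), gain),
                  fill=fill, width=1)


def render_state_page(
    traces,
    state: str,
    page_size: tuple[int, int] = defaults.PAGE_SIZE,
    lead_layout: tuple[int, int] = defaults.LEAD_GRID,
    banner_height: int = defaults.BANNER_HEIGHT,
    grid_step: int = defaults.GRID_STEP,
    grid_value: int = defaults.GRID_VALUE,
    gain: float = 30.0,
) -> np.ndarray:
    """Render 12 lead traces as one grayscale report page.

    The page carries a light grid background below a banner in which the
    state keyword is printed; traces are dark (0) polylines laid out on the
    ``lead_layout`` grid of tiles.  Returns a (height, width) uint8 array.
    """
    if state not in STATES:
        raise ValueError(f"unknown state {state!r}")
    traces = list(traces)
    if len(traces) != 12:
        raise ValueError(f"expected exactly 12 lead traces, got {len(traces)}")
    if page_size[0] <= 0 or page_size[1] <= 0:
        raise ValueError(f"page size must be positive, got {page_size}")
    width, height = page_size
    img = Image.new("L", (width, height), 255)
    draw = ImageDraw.Draw(img)
    for x in range(0, width, grid_step):
        draw.line([(x, banner_height), (x, height - 1)], fill=grid_value)
    for y in range(banner_height, height, grid_step):
        draw.line([(0, y), (width - 1, y)], fill=grid_value)
    draw.text((12, max(banner_height // 2 - 6, 2)),
              f"{state.capitalize()} 12-lead ECG", fill=0)
    _draw_traces(draw, traces, page_size, lead_layout, banner_height, gain, fill=0)
    return np.asarray(img)


def trace_mask(
    traces,
    page_size: tuple[int, int] = defaults.PAGE_SIZE,
    lead_layout: tuple[int, int] = defaults.LEAD_GRID,
    banner_height: int = defaults.BANNER_HEIGHT,
    gain: float = 30.0,
) -> np.ndarray:
    """Boolean mask of the pixels the trace polylines rasterize to.

    Uses the identical polyline routine as :func:`render_state_page`, so
    the mask is the ground truth for trace-pixel bookkeeping.
    """
    width, height = page_size
    img = Image.new("L", (width, height), 0)
    draw = ImageDraw.Draw(img)
    _draw_traces(draw, list(traces), page_size, lead_layout, banner_height, gain, fill=255)
    return np.asarray(img) > 0


# ---------------------------------------------------------------------------
# cohort generation


@dataclass
class SyntheticCohortConfig:
    """Cohort-level parameters for the generator."""

    n_patients: int = 416
    prevalence: float = DEFAULT_PREVALENCE
    seed: int = 0
    gender_proportions: tuple[float, float] = GENDER_PROPORTIONS
    age_bin_probabilities: tuple[float, ...] = AGE_BIN_PROBABILITIES
    page_size: tuple[int, int] = defaults.PAGE_SIZE
    lead_layout: tuple[int, int] = defaults.LEAD_GRID
    noise_sd: float = 0.02
    inter_state_only: bool = False

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError(f"n_patients must be >= 2, got {self.n_patients}")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError(f"prevalence must be in [0, 1], got {self.prevalence}")
        if abs(sum(self.gender_proportions) - 1.0) > 1e-9:
            raise ValueError("gender proportions must sum to 1")
        if len(self.age_bin_probabilities) != 5 or abs(sum(self.age_bin_probabilities) - 1.0) > 1e-9:
            raise ValueError("age_bin_probabilities must be 5 values summing to 1")
        rows, cols = self.lead_layout
        if rows * cols != 12:
            raise ValueError(f"lead layout must tile 12 leads, got {rows}x{cols}")


@dataclass
class SyntheticPatient:
    """One generated patient: label, demographics, per-state params and pages."""

    patient_id: str
    label: str  # "CAD" | "non-CAD"
    gender: str  # "male" | "female"
    age: int
    params: dict[str, WaveformParams] = field(repr=False)
    pages: dict[str, np.ndarray] = field(repr=False)

    def __post_init__(self) -> None:
        if set(self.pages) != set(STATES):
            raise ValueError("patient must have exactly one page per state")
        has_effect = any(p.st_offset != 0 for p in self.params.values())
        if has_effect != (self.label == "CAD"):
            raise ValueError("label inconsistent with st_offset class effect")


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def _labels(cfg: SyntheticCohortConfig) -> np.ndarray:
    n_cad = int(round(cfg.n_patients * cfg.prevalence))
    labels = np.zeros(cfg.n_patients, dtype=bool)
    labels[:n_cad] = True
    return _rng(cfg.seed, 0).permutation(labels)


def patient_waveform_params(
    cfg: SyntheticCohortConfig,
    rng: np.random.Generator,
    is_cad: bool,
) -> dict[str, WaveformParams]:
    """Draw one patient's per-state waveform parameters.

    Heart rate rises from pretest to exercise and partially recovers; the
    per-patient ST baseline is shared across states; CAD patients add the
    state-dependent class effect (pretest effect zeroed in
    inter-state-only mode).
    """
    hr_pre = rng.normal(75.0, 5.0)
    hr_ex = max(rng.normal(140.0, 10.0), hr_pre + 10.0)
    hr_rec = float(np.clip(rng.normal(95.0, 8.0), hr_pre + 1.0, hr_ex - 1.0))
    hr = {"pretest": hr_pre, "exercise": hr_ex, "recovery": hr_rec}
    baseline = rng.uniform(*BASELINE_ST_RANGE, size=12)
    amp = np.asarray(LEAD_AMPLITUDE) * rng.uniform(0.9, 1.1)
    t_scale = rng.uniform(0.8, 1.2, size=12)
    t_scale[rng.random(12) < BASELINE_T_INVERTED_PROB] *= -1.0
    params = {}
    for state in STATES:
        st = ST_EFFECT[state] if is_cad else 0.0
        t_factor = T_WAVE_EFFECT[state] if is_cad else 1.0
        if cfg.inter_state_only and state == "pretest":
            st = 0.0
            t_factor = 1.0
        params[state] = WaveformParams(
            heart_rate_bpm=hr[state],
            amplitude_scale=amp,
            baseline_st=baseline,
            st_offset=st,
            t_wave_scale=t_scale * t_factor,
            noise_sd=cfg.noise_sd,
            duration_s=BEATS_PER_PAGE * 60.0 / hr[state],
        )
    return params


def draw_demographics(cfg: SyntheticCohortConfig, rng: np.random.Generator) -> tuple[str, int]:
    """Draw one patient's gender and age from the configured proportions."""
    gender = "male" if rng.random() < cfg.gender_proportions[0] else "female"
    age_bin = int(rng.choice(len(cfg.age_bin_probabilities), p=cfg.age_bin_probabilities))
    lo, hi = AGE_BIN_RANGES[age_bin]
    return gender, int(rng.integers(lo, hi + 1))


def iter_cohort(cfg: SyntheticCohortConfig) -> Iterator[SyntheticPatient]:
    """Yield patients one at a time (memory-friendly for large cohorts).

    Each patient has an independent random stream derived from the cohort
    seed and the patient index, so generation is reproducible patient by
    patient and bit-identical across runs.
    """
    labels = _labels(cfg)
    for i in range(cfg.n_patients):
        rng = _rng(cfg.seed, 1, i)
        is_cad = bool(labels[i])
        gender, age = draw_demographics(cfg, rng)
        params = patient_waveform_params(cfg, rng, is_cad)
        pages = {}
        for state in STATES:
            traces = state_traces(params[state], rng=rng)
            pages[state] = render_state_page(
                traces, state, page_size=cfg.page_size, lead_layout=cfg.lead_layout
            )
        yield SyntheticPatient(
            patient_id=f"p{i:04d}",
            label="CAD" if is_cad else "non-CAD",
            gender=gender,
            age=age,
            params=params,
            pages=pages,
        )


def generate_cohort(cfg: SyntheticCohortConfig) -> tuple[list[SyntheticPatient], pd.DataFrame]:
    """Generate the full cohort and its metadata table.

    Exactly ``round(n_patients * prevalence)`` patients carry the CAD
    label; gender and age follow the configured proportions.
    """
    patients = list(iter_cohort(cfg))
    metadata = pd.DataFrame(
        {
            "id": [p.patient_id for p in patients],
            "label": [p.label for p in patients],
            "gender": [p.gender for p in patients],
            "age": [p.age for p in patients],
        }
    )
    return patients, metadata


def write_cohort(patients, metadata: pd.DataFrame, outdir: str | Path) -> Path:
    """Write a cohort to disk: per-patient page PNGs + truth.json sidecars
    and a cohort-level metadata.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for patient in patients:
        pdir = outdir / patient.patient_id
        pdir.mkdir(exist_ok=True)
        truth_pages = {}
        for state in STATES:
            name = f"{patient.patient_id}_{state}.png"
            Image.fromarray(patient.pages[state]).save(pdir / name)
            truth_pages[name] = state
        (pdir / "truth.json").write_text(json.dumps(
            {"patient_id": patient.patient_id, "label": patient.label,
             "pages": truth_pages}, indent=1))
    metadata.to_csv(outdir / "metadata.csv", index=False)
    return outdir
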