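"""Synthetic mesoscale-imaging sessions with known ground truth.

Everything the analysis pipeline consumes can be generated here: spontaneous
movies with planted sensory-motif events riding on band-limited background
activity and exponential dye bleaching; stimulus-locked evoked sessions in
which trial amplitude depends linearly on the pre-stimulus motif correlation
through a per-subject random intercept; interval-stimulation sessions whose
trial-to-trial variability shrinks as the conditioning interval widens; and
summary-level cohorts linking motif frequency to evoked variability.

Each generator returns the stimuli/movies plus a :class:`GroundTruth` record,
and is fully reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .io_core import MODALITIES, Movie, hemisphere_masks

# Modality loci as (row, col) fractions of the field, all in the left
# hemisphere (col < 0.5) and mutually >= 15 px apart at the default 64 x 64
# field.  The spatial arrangement loosely follows the somatotopy of dorsal
# cortex (forelimb anterior, hindlimb posterior, barrel lateral) but is a
# desk-scale stand-in, not an atlas registration.
LOCI_FRACTION: dict[str, tuple[float, float]] = {
    "forelimb": (0.20, 0.125),
    "hindlimb": (0.78, 0.155),
    "whisker": (0.47, 0.40),
}

# Per-modality drift direction of the blob centroid (unit vectors), chosen
# divergent so propagating blobs never converge on a common locus; the
# planted motifs propagate as well as spread, as evoked waves do.
DRIFT_DIRECTION: dict[str, tuple[float, float]] = {
    "forelimb": (0.0, 1.0),
    "hindlimb": (0.5, 0.87),
    "whisker": (-0.87, 0.5),
}

DEFAULT_FRAME_RATE_HZ = 150.0
DEFAULT_F0 = 100.0  # arbitrary raw-fluorescence baseline (camera counts)


@dataclass
class GroundTruth:
    """What was planted, for validating detection and model recovery."""

    planted_events: list[dict] = dc_field(default_factory=list)
    evoked_slope_beta: float = 0.0
    subject_effects: dict[str, float] = dc_field(default_factory=dict)
    bleach_tau_frames: float = np.inf
    extra: dict = dc_field(default_factory=dict)


def modality_locus(modality: str, field: tuple[int, int]) -> tuple[int, int]:
    """Pixel coordinates of a modality's response locus for a given field."""
    if modality not in LOCI_FRACTION:
        raise ValueError(f"unknown modality {modality!r}")
    fr, fc = LOCI_FRACTION[modality]
    return int(round(fr * field[0])), int(round(fc * field[1]))


def make_motif_kernel(modality: str, shape: tuple[int, int] = (64, 64),
                      duration_frames: int = 10, seed: int | None = None) -> np.ndarray:
    """A localized depolarization blob that rises, spreads and propagates.

    Frame 0 is a compact Gaussian peaked at the modality locus; over frames
    the width grows monotonically, the centroid drifts along a modality-
    specific direction, and the amplitude envelope ramps up over ~3 frames
    then decays.  The kernel is non-negative with unit peak.  ``seed`` is
    accepted for interface uniformity; the kernel is deterministic.
    """
    if duration_frames < 2:
        raise ValueError("duration_frames must be >= 2")
    rows, cols = shape
    if min(rows, cols) < 8:
        raise ValueError(f"field {shape} too small to hold a motif kernel")
    r0, c0 = modality_locus(modality, shape)
    dr, dc = DRIFT_DIRECTION[modality]
    scale = min(rows, cols)
    sigma0 = 0.040 * scale          # initial blob width (px)
    growth = 0.25                   # relative width growth per frame
    drift_px = 0.040 * scale        # centroid drift per frame (px)
    rr, cc = np.mgrid[0:rows, 0:cols].astype(np.float64)
    kernel = np.empty((duration_frames, rows, cols), dtype=np.float64)
    # Fixed fine-grained multiplicative texture (patchwork micro-domains within
    # the depolarized area), deterministic per modality and field.  It gives
    # the pattern many effective spatial degrees of freedom, so a random
    # pattern with the same second-order structure correlates with it only
    # weakly — a property real motifs have and a pure Gaussian blob lacks.
    tex_rng = np.random.default_rng(
        10_007 + 13 * MODALITIES.index(modality) + rows * 131 + cols)
    texture = 1.0 + 0.6 * (2.0 * tex_rng.random((rows, cols)) - 1.0)
    texture[r0, c0] = 1.6  # the locus stays the argmax of frame 0
    for j in range(duration_frames):
        sigma = sigma0 * (1.0 + growth * j)
        center_r = r0 + drift_px * j * dr
        center_c = c0 + drift_px * j * dc
        # cubic 3-frame rise then exponential decay: successive frames
        # differ enough that the sliding correlation localizes the onset
        env = min((j + 1) / 3.0, 1.0) ** 3 * np.exp(-max(0, j - 3) / 4.0)
        kernel[j] = env * texture * np.exp(-(((rr - center_r) ** 2 + (cc - center_c) ** 2)
                                             / (2.0 * sigma ** 2)))
    return kernel / kernel.max()


def _band_limited_background(n_frames: int, field: tuple[int, int], sd_pct: float,
                             band: tuple[float, float], frame_rate_hz: float,
                             rng: np.random.Generator, n_modes: int = 16) -> np.ndarray:
    """Low-rank spatially smooth, temporally band-limited background (percent).

    K smooth random spatial modes weighted by band-limited temporal
    coefficients: a cheap stand-in for the slow, spatially coherent
    depolarization waves that dominate anaesthetized cortex.
    """
    if sd_pct <= 0:
        return np.zeros((n_frames, *field), dtype=np.float64)
    rows, cols = field
    modes = rng.standard_normal((n_modes, rows, cols))
    modes = np.stack([ndimage.gaussian_filter(m, sigma=0.30 * min(rows, cols)) for m in modes])
    modes /= np.sqrt((modes ** 2).mean(axis=(1, 2), keepdims=True))
    coefs = rng.standard_normal((n_frames, n_modes))
    sos = signal.cheby1(4, 0.1, list(band), btype="bandpass", fs=frame_rate_hz, output="sos")
    coefs = signal.sosfiltfilt(sos, coefs, axis=0)
    bg = coefs @ modes.reshape(n_modes, -1)
    bg *= sd_pct / bg.std()
    return bg.reshape(n_frames, rows, cols)


def _poisson_onsets(rate: float, lo: int, hi: int, duration: int,
                    rng: np.random.Generator) -> list[int]:
    """Homogeneous-Poisson event onsets in [lo, hi), rejecting same-track overlap."""
    span = hi - lo
    if span <= 0:
        return []
    n = rng.poisson(rate * span)
    onsets: list[int] = []
    for _ in range(n):
        for _attempt in range(200):
            t = int(rng.integers(lo, hi))
            if all(abs(t - o) >= duration for o in onsets):
                onsets.append(t)
                break
    return sorted(onsets)


def simulate_spontaneous(n_frames: int = 10_001, field: tuple[int, int] = (64, 64),
                         event_rate_per_modality: float = 1.0e-3,
                         amplitude_pct: float = 0.4, noise_sd_pct: float = 0.05,
                         background_sd_pct: float = 0.002,
                         bleach_tau_frames: float = 30_000.0,
                         band_limits: tuple[float, float] = (0.5, 6.0),
                         duration_frames: int = 10,
                         frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ,
                         modalities: tuple[str, ...] = MODALITIES,
                         seed: int | None = None) -> tuple[Movie, GroundTruth]:
    """A raw-fluorescence spontaneous epoch with planted motif events.

    The percent-signal layer is ``background + sum(planted kernels) + white
    noise``; the raw movie is ``F0 * exp(-t/tau) * (1 + signal/100)``.  Event
    times are homogeneous Poisson per modality with same-modality overlap
    rejected.  Defaults give ~10 events per modality per 10,001 frames at
    0.4% peak amplitude over 0.05% white noise — comfortably detectable, by
    design rather than biological calibration.
    """
    rng = np.random.default_rng(seed)
    expected_overlap = event_rate_per_modality * duration_frames
    if expected_overlap >= 0.05:
        raise ValueError("event rate too high: same-modality overlap would exceed 5%")

    pct = _band_limited_background(n_frames, field, background_sd_pct, band_limits,
                                   frame_rate_hz, rng)
    truth = GroundTruth(bleach_tau_frames=bleach_tau_frames)
    margin = 50
    for modality in modalities:
        kernel = make_motif_kernel(modality, field, duration_frames)
        onsets = _poisson_onsets(event_rate_per_modality, margin,
                                 n_frames - duration_frames - margin,
                                 2 * duration_frames, rng)
        for onset in onsets:
            pct[onset:onset + duration_frames] += amplitude_pct * kernel
            truth.planted_events.append({
                "modality": modality, "onset_frame": int(onset),
                "duration_frames": int(duration_frames),
                "peak_amplitude_pct": float(amplitude_pct),
            })
    if noise_sd_pct > 0:
        pct += rng.normal(0.0, noise_sd_pct, size=pct.shape)

    t = np.arange(n_frames, dtype=np.float64)
    bleach = np.exp(-t / bleach_tau_frames)[:, None, None]
    raw = DEFAULT_F0 * bleach * (1.0 + pct / 100.0)
    if np.any(raw <= 0):
        raise ValueError("parameters produced non-positive raw fluorescence")
    truth.planted_events.sort(key=lambda e: e["onset_frame"])
    movie = Movie(raw.astype(np.float32), frame_rate_hz=frame_rate_hz, is_dff=False)
    return movie, truth


def template_from_kernel(modality: str, field: tuple[int, int] = (64, 64),
                         amplitude_pct: float = 0.4):
    """An idealized (noise-free) sensory template: kernel frames [0, 5).

    Hemisphere-restricted and flattened exactly as templates extracted from
    evoked data are; used when ground-truth templates are preferable to
    estimated ones (recovery tests, surrogate nulls).
    """
    from .evoked import SensoryTemplate

    kernel = make_motif_kernel(modality, field, duration_frames=5)
    hemi = hemisphere_masks(field)
    locus = modality_locus(modality, field)
    side = "left" if locus[1] < field[1] // 2 else "right"
    mask = hemi[side]
    frames = amplitude_pct * kernel
    return SensoryTemplate(
        modality=modality, frames=frames, hemisphere=side, mask=mask,
        flat=frames[:, mask].ravel(), onset_frame=0, source_subject="ground_truth")


@dataclass
class EvokedSession:
    """Movies and metadata for one simulated multi-subject evoked session."""

    trial_movies: dict   # (subject_id, modality) -> list[Movie], stimulus trials
    blank_movies: dict   # subject_id -> list[Movie], stimulus-free trials
    trial_table: pd.DataFrame
    truth: GroundTruth
    stimulus_frame: int
    modalities: tuple[str, ...]
    subjects: tuple[str, ...]


def simulate_evoked_session(n_subjects: int = 10, n_trials_per_modality: int = 10,
                            n_blank_trials: int = 5, beta: float = 0.5,
                            sigma_trial: float = 0.05, subject_sd: float = 0.2,
                            mean_amplitude_pct: float = 1.0,
                            baseline_motif_prob: float = 0.7,
                            baseline_motif_max_pct: float = 0.5,
                            noise_sd_pct: float = 0.05,
                            background_sd_pct: float = 0.002,
                            field: tuple[int, int] = (32, 32),
                            modalities: tuple[str, ...] = MODALITIES,
                            bleach_tau_frames: float = 3_000.0,
                            frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ,
                            seed: int | None = None) -> EvokedSession:
    """Stimulus-locked trials whose amplitude follows a random-intercept model.

    Each trial movie holds a >= 200 ms pre-stimulus baseline (optionally with
    a planted same-modality motif of random amplitude) followed by a
    stimulus-locked response kernel.  The response amplitude is::

        amplitude = mean + subject_intercept + beta * baseline_max_r + noise

    where ``baseline_max_r`` is the maximal template correlation actually
    measured in the trial's 200 ms baseline, so the analysis chain can
    recover ``beta`` without errors-in-variables attenuation.  Raw movies
    include bleaching; ``n_blank_trials`` stimulus-free trials per subject
    support the blank-normalization correction.
    """
    from .motifs import correlation_trace

    if n_blank_trials < 1:
        raise ValueError("need >= 1 blank trial for bleaching correction")
    if n_trials_per_modality < 2:
        raise ValueError("need >= 2 stimulus trials per modality")
    baseline_frames = int(round(0.200 * frame_rate_hz))  # 200 ms
    stimulus_frame = baseline_frames + 5
    n_frames = stimulus_frame + 15
    if baseline_frames < 5:
        raise ValueError("frame rate too low: 200 ms baseline holds < 5 frames")

    rng = np.random.default_rng(seed)
    truth = GroundTruth(evoked_slope_beta=beta, bleach_tau_frames=bleach_tau_frames)
    subjects = tuple(f"m{i:02d}" for i in range(n_subjects))
    for s in subjects:
        truth.subject_effects[s] = float(rng.normal(0.0, subject_sd))

    templates = {m: template_from_kernel(m, field) for m in modalities}
    resp_kernels = {m: make_motif_kernel(m, field, duration_frames=10) for m in modalities}
    # Scale factor mapping desired 5x5-ROI peak amplitude to kernel multiplier.
    roi_gain = {}
    for m in modalities:
        kern = resp_kernels[m]
        peak_frame = int(np.argmax(kern.max(axis=(1, 2))))
        r0, c0 = np.unravel_index(np.argmax(kern[peak_frame]), field)
        r0 = np.clip(r0, 2, field[0] - 3)
        c0 = np.clip(c0, 2, field[1] - 3)
        roi_gain[m] = float(kern[peak_frame, r0 - 2:r0 + 3, c0 - 2:c0 + 3].mean())

    t = np.arange(n_frames, dtype=np.float64)
    bleach = np.exp(-t / bleach_tau_frames)[:, None, None]

    def raw_from_pct(pct: np.ndarray) -> Movie:
        raw = DEFAULT_F0 * bleach * (1.0 + pct / 100.0)
        return Movie(raw.astype(np.float32), frame_rate_hz=frame_rate_hz, is_dff=False)

    trial_movies: dict = {}
    blank_movies: dict = {}
    rows = []
    for subject in subjects:
        blank_movies[subject] = []
        for b in range(n_blank_trials):
            pct = _band_limited_background(n_frames, field, background_sd_pct,
                                           (0.5, 6.0), frame_rate_hz, rng)
            pct += rng.normal(0.0, noise_sd_pct, size=pct.shape)
            blank_movies[subject].append(raw_from_pct(pct))
            rows.append({"subject_id": subject, "modality": "forelimb",
                         "stimulus_frame": stimulus_frame, "is_stimulus_free": True,
                         "group_label": "synthetic"})
        for modality in modalities:
            template = templates[modality]
            kernel5 = make_motif_kernel(modality, field, duration_frames=5)
            trial_movies[(subject, modality)] = []
            for _ in range(n_trials_per_modality):
                pct = _band_limited_background(n_frames, field, background_sd_pct,
                                               (0.5, 6.0), frame_rate_hz, rng)
                pct += rng.normal(0.0, noise_sd_pct, size=pct.shape)
                base_amp = 0.0
                if rng.random() < baseline_motif_prob:
                    base_amp = float(rng.uniform(0.1, baseline_motif_max_pct))
                    onset = int(rng.integers(2, stimulus_frame - 7))
                    pct[onset:onset + 5] += base_amp * kernel5
                # measure the baseline correlation the analysis will see
                base = Movie(pct[stimulus_frame - baseline_frames:stimulus_frame],
                             frame_rate_hz=frame_rate_hz, is_dff=True)
                r_base = float(np.max(correlation_trace(base, template).values))
                amp = (mean_amplitude_pct + truth.subject_effects[subject]
                       + beta * r_base + rng.normal(0.0, sigma_trial))
                amp = max(amp, 0.05)
                pct[stimulus_frame + 1:stimulus_frame + 11] += \
                    (amp / roi_gain[modality]) * resp_kernels[modality]
                trial_movies[(subject, modality)].append(raw_from_pct(pct))
                rows.append({"subject_id": subject, "modality": modality,
                             "stimulus_frame": stimulus_frame,
                             "is_stimulus_free": False, "group_label": "synthetic"})
                truth.extra.setdefault("trial_truth", []).append({
                    "subject_id": subject, "modality": modality,
                    "baseline_max_r": r_base, "baseline_motif_amp_pct": base_amp,
                    "true_amplitude_pct": float(amp)})
    table = pd.DataFrame(rows)
    return EvokedSession(trial_movies=trial_movies, blank_movies=blank_movies,
                         trial_table=table, truth=truth, stimulus_frame=stimulus_frame,
                         modalities=tuple(modalities), subjects=subjects)


def default_variability_curve(interval_ms: np.ndarray | float) -> np.ndarray:
    """Trial-to-trial SD vs conditioning interval: high when the interval is
    short (residual regional depolarization), relaxing to a floor by ~2 s."""
    interval_ms = np.asarray(interval_ms, dtype=float)
    return 0.06 + 0.22 * np.exp(-interval_ms / 900.0)


def simulate_interval_session(intervals_ms: tuple[float, ...] = (250, 500, 1000, 1500,
                                                                 2000, 5000, 7500),
                              n_trials: int = 30, n_subjects: int = 4,
                              mean_amplitude: float = 1.0,
                              variability_curve=None,
                              seed: int | None = None) -> tuple[pd.DataFrame, GroundTruth]:
    """Amplitudes for a conditioning-interval experiment (30 trials/interval).

    For each subject and interval, ``n_trials`` amplitudes are drawn from a
    normal with SD given by ``variability_curve(interval)`` (monotone
    decreasing by default).  Returns a long-format table with columns
    subject_id, interval_ms, trial, amplitude.
    """
    if len(intervals_ms) == 0 or any(i <= 0 for i in intervals_ms):
        raise ValueError("intervals_ms must be non-empty and positive")
    curve = variability_curve or default_variability_curve
    sds = np.asarray(curve(np.asarray(intervals_ms, dtype=float)), dtype=float)
    if np.any(sds < 0):
        raise ValueError("variability curve produced a negative SD")
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        subject = f"m{s:02d}"
        for interval, sd in zip(intervals_ms, sds):
            amps = rng.normal(mean_amplitude, sd, size=n_trials)
            for k, a in enumerate(amps):
                rows.append({"subject_id": subject, "interval_ms": float(interval),
                             "trial": k, "amplitude": float(a)})
    truth = GroundTruth(extra={"interval_sds": dict(zip(map(float, intervals_ms),
                                                        map(float, sds)))})
    return pd.DataFrame(rows), truth


def simulate_cohort(n_subjects: int = 90, slope: float = 0.005, intercept: float = 0.03,
                    freq_range: tuple[float, float] = (0.5, 10.0), n_trials: int = 10,
                    mean_amplitude: float = 1.0,
                    seed: int | None = None) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """A summary-level cohort where evoked variability tracks motif frequency.

    Subject ``i`` has motif frequency ``f_i ~ U(freq_range)`` (events per
    10,000 frames) and trial amplitudes ``N(mean, intercept + slope * f_i)``.
    Returns (trials, subject table, truth); regressing the per-subject sample
    SD on frequency recovers ``slope``.
    """
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(*freq_range, size=n_subjects)
    trial_rows, subj_rows = [], []
    for i, f in enumerate(freqs):
        subject = f"m{i:03d}"
        sd = intercept + slope * f
        amps = rng.normal(mean_amplitude, sd, size=n_trials)
        subj_rows.append({"subject_id": subject, "motif_frequency_per_10k": float(f),
                          "true_sd": float(sd)})
        for k, a in enumerate(amps):
            trial_rows.append({"subject_id": subject, "trial": k, "amplitude": float(a)})
    truth = GroundTruth(extra={"sd_slope": slope, "sd_intercept": intercept})
    return pd.DataFrame(trial_rows), pd.DataFrame(subj_rows), truth
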