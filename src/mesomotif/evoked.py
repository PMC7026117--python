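"""Sensory-evoked response quantification and template extraction.

An evoked response is summarized by the mean dF/F0 within a 5 x 5 pixel
region of interest centred on the maximally responsive pixel, with the peak
taken in the first ten post-stimulus frames.  The sensory template is the
five-frame initial segment of the (averaged) evoked response, restricted to
the hemisphere containing the primary response and flattened to a 1-D vector
for correlation against spontaneous activity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_core import Movie, hemisphere_masks

POST_STIM_FRAMES = 10   # peak search window after the stimulus
TEMPLATE_FRAMES = 5
BASELINE_MS = 200.0
ROI_HALF = 2            # 5 x 5 ROI


@dataclass
class EvokedResponse:
    modality: str | None
    roi_center: tuple[int, int]
    roi_trace: np.ndarray       # mean dF/F0 (percent) over the ROI, per frame
    peak_amplitude: float
    peak_frame: int             # absolute frame index of the in-window peak


@dataclass
class SensoryTemplate:
    """Five-frame, hemisphere-restricted evoked segment used for matching.

    ``frames`` keeps the full rasters (zero outside the hemisphere is not
    required; ``mask`` says which pixels enter ``flat``).  ``flat`` is the
    concatenation over frames of the in-mask pixels, the vector actually
    correlated against spontaneous windows.
    """

    modality: str | None
    frames: np.ndarray          # (5, rows, cols)
    hemisphere: str             # "left" | "right"
    mask: np.ndarray            # boolean (rows, cols), the hemisphere mask used
    flat: np.ndarray
    onset_frame: int
    source_subject: str | None = None

    def __post_init__(self) -> None:
        if self.frames.shape[0] != TEMPLATE_FRAMES:
            raise ValueError(f"template must have exactly {TEMPLATE_FRAMES} frames")
        if self.flat.shape[0] != TEMPLATE_FRAMES * int(self.mask.sum()):
            raise ValueError("flat vector length != 5 * in-mask pixel count")
        if not np.linalg.norm(self.flat) > 0:
            raise ValueError("template is identically zero")


def _clip_roi_center(center: tuple[int, int], shape: tuple[int, int]) -> tuple[int, int]:
    r = int(np.clip(center[0], ROI_HALF, shape[0] - ROI_HALF - 1))
    c = int(np.clip(center[1], ROI_HALF, shape[1] - ROI_HALF - 1))
    return r, c


def roi_trace(data: np.ndarray, center: tuple[int, int]) -> np.ndarray:
    """Per-frame mean over the 5 x 5 ROI centred at ``center``."""
    r, c = center
    return data[:, r - ROI_HALF:r + ROI_HALF + 1, c - ROI_HALF:c + ROI_HALF + 1].mean(axis=(1, 2))


def evoked_response(trial_movie: Movie, stimulus_frame: int,
                    modality: str | None = None, smooth: bool = True) -> EvokedResponse:
    """Locate the maximally responsive pixel and summarize the 5 x 5 ROI.

    The search covers post-stimulus frames ``[stimulus_frame, +10)`` of the
    (bleach-corrected) dF/F0 movie.  By default the peak frame is smoothed
    with a 3 x 3 mean before the argmax so a single noisy pixel cannot win;
    ``smooth=False`` gives the raw argmax.  An ROI that would cross the image
    or mask boundary is shifted inward with a warning.
    """
    data = np.asarray(trial_movie.data, dtype=np.float64)
    if data.shape[0] < stimulus_frame + POST_STIM_FRAMES:
        raise ValueError(f"need >= {POST_STIM_FRAMES} frames after the stimulus")
    window = data[stimulus_frame:stimulus_frame + POST_STIM_FRAMES]
    search = ndimage.uniform_filter(window, size=(1, 3, 3)) if smooth else window
    if trial_movie.mask is not None:
        search = np.where(trial_movie.mask[None], search, -np.inf)
    flat_idx = int(np.argmax(search))
    t_rel, r, c = np.unravel_index(flat_idx, window.shape)
    if search.max() <= 0:
        warnings.warn("no positive post-stimulus response; ROI centre is degenerate")
    center = (int(r), int(c))
    clipped = _clip_roi_center(center, data.shape[1:])
    if clipped != center:
        warnings.warn(f"ROI at {center} crosses the image boundary; shifted to {clipped}")
    trace = roi_trace(data, clipped)
    post = trace[stimulus_frame:stimulus_frame + POST_STIM_FRAMES]
    peak_rel = int(np.argmax(post))
    return EvokedResponse(modality=modality, roi_center=clipped, roi_trace=trace,
                          peak_amplitude=float(post[peak_rel]),
                          peak_frame=stimulus_frame + peak_rel)


def average_evoked(trials: list[Movie], stimulus_frames: list[int]) -> Movie:
    """Stimulus-aligned frame-wise mean of >= 2 trials.

    Trials are aligned on their stimulus frames and cropped to the common
    extent before averaging.
    """
    if len(trials) < 2:
        raise ValueError("need >= 2 trials to average")
    shapes = {t.data.shape[1:] for t in trials}
    if len(shapes) > 1:
        raise ValueError(f"misaligned trial shapes: {shapes}")
    pre = min(stimulus_frames)
    post = min(t.n_frames - s for t, s in zip(trials, stimulus_frames))
    stacked = np.stack([np.asarray(t.data[s - pre:s + post], dtype=np.float64)
                        for t, s in zip(trials, stimulus_frames)])
    return Movie(stacked.mean(axis=0), frame_rate_hz=trials[0].frame_rate_hz,
                 is_dff=trials[0].is_dff, mask=trials[0].mask)


def detect_onset(trace: np.ndarray, stimulus_frame: int, frame_rate_hz: float,
                 n_sd: float = 2.0) -> int:
    """First post-stimulus frame whose ROI value exceeds baseline mean + n_sd * SD.

    The baseline is the 200 ms preceding the stimulus.  Raises if no frame in
    the first ten post-stimulus frames crosses.
    """
    n_base = int(round(BASELINE_MS / 1000.0 * frame_rate_hz))
    lo = max(0, stimulus_frame - n_base)
    base = trace[lo:stimulus_frame]
    if base.size < 3:
        raise ValueError("baseline too short for onset detection")
    thr = base.mean() + n_sd * base.std(ddof=1)
    post = trace[stimulus_frame:stimulus_frame + POST_STIM_FRAMES]
    above = np.nonzero(post > thr)[0]
    if above.size == 0:
        raise ValueError("no response onset within the first ten post-stimulus frames")
    return stimulus_frame + int(above[0])


def extract_template(mean_evoked: Movie, stimulus_frame: int,
                     modality: str | None = None,
                     hemi_masks: dict[str, np.ndarray] | None = None,
                     source_subject: str | None = None,
                     onset_n_sd: float = 2.0) -> SensoryTemplate:
    """Five-frame initial segment of the evoked response, hemisphere-restricted.

    The hemisphere is the side containing the maximally responsive pixel
    (midline split unless ``hemi_masks`` is supplied); onset is the first
    post-stimulus frame whose ROI value exceeds the 200 ms-baseline mean +
    ``onset_n_sd`` SD; frames ``[onset, onset+5)`` restricted to that
    hemisphere populate the flat vector.
    """
    resp = evoked_response(mean_evoked, stimulus_frame, modality=modality)
    onset = detect_onset(resp.roi_trace, stimulus_frame, mean_evoked.frame_rate_hz,
                         n_sd=onset_n_sd)
    if onset + TEMPLATE_FRAMES > mean_evoked.n_frames:
        raise ValueError("movie ends before the five-frame template window")
    masks = hemi_masks or hemisphere_masks(mean_evoked.frame_shape, mean_evoked.mask)
    side = "left" if masks["left"][resp.roi_center] else "right"
    mask = masks[side]
    frames = np.asarray(mean_evoked.data[onset:onset + TEMPLATE_FRAMES], dtype=np.float64)
    return SensoryTemplate(modality=modality, frames=frames, hemisphere=side,
                           mask=mask, flat=frames[:, mask].ravel(),
                           onset_frame=onset, source_subject=source_subject)
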