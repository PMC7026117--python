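"""Template correlation, threshold calibration, and motif-event detection.

Spontaneous activity is scanned with a five-frame sensory template: each
index frame t yields the Pearson correlation between the template's flat
vector and the flattened in-mask window [t, t+5).  The detection threshold
is mean + 1.5 SD of the correlation trace, a value at which the concordance
between template and matches plateaus; a motif event is a maximal run of at
least five consecutive supra-threshold frames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .evoked import TEMPLATE_FRAMES, SensoryTemplate
from .io_core import MODALITIES, Movie

#: Binarization fraction for template first frames.
TEMPLATE_BINARIZE_FRACTION = 0.4
#: Match-frame binarization fractions; spontaneous matches peak lower than
#: evoked responses, so they need higher relative cuts.
MATCH_BINARIZE_FRACTION = {"whisker": 0.5, "forelimb": 0.6, "hindlimb": 0.7}

DEFAULT_K = 1.5          # threshold multiplier: mean + 1.5 SD
MIN_RUN = 5              # minimum supra-threshold run length (frames)


@dataclass
class CorrelationTrace:
    """Per-index-frame Pearson correlation against one template."""

    values: np.ndarray
    mu: float
    sigma: float
    template_id: str | None = None

    def threshold(self, k: float = DEFAULT_K) -> float:
        return self.mu + k * self.sigma


@dataclass
class MotifEvent:
    modality: str | None
    onset_frame: int
    duration_frames: int
    peak_r: float
    peak_frame: int


@dataclass
class ConcordanceCurve:
    k_values: np.ndarray
    concordance: np.ndarray
    plateau_k: float
    n_matches: np.ndarray = dc_field(default_factory=lambda: np.array([]))


def sliding_pearson(F: np.ndarray, T: np.ndarray, warn: bool = True) -> np.ndarray:
    """Pearson r between T (p x 5 template frames) and each 5-frame window of
    F (n x p masked movie frames).  Zero-variance windows yield r = 0."""
    n, p = F.shape
    m = TEMPLATE_FRAMES * p
    y = T.T.ravel()
    y_sum, y_sumsq = y.sum(), (y ** 2).sum()
    y_var = y_sumsq - y_sum ** 2 / m
    if y_var <= 0:
        raise ValueError("template has zero variance")
    P = F @ T                                   # per-frame dots with template frames
    s1 = F.sum(axis=1)
    s2 = (F ** 2).sum(axis=1)
    n_win = n - TEMPLATE_FRAMES + 1
    cross = np.zeros(n_win)
    win_s1 = np.zeros(n_win)
    win_s2 = np.zeros(n_win)
    for k in range(TEMPLATE_FRAMES):
        cross += P[k:k + n_win, k]
        win_s1 += s1[k:k + n_win]
        win_s2 += s2[k:k + n_win]
    x_var = win_s2 - win_s1 ** 2 / m
    cov = cross - win_s1 * y_sum / m
    values = np.zeros(n_win)
    ok = x_var > 1e-300 * m
    if warn and not ok.all():
        warnings.warn(f"{int((~ok).sum())} zero-variance windows set to r = 0")
    values[ok] = cov[ok] / np.sqrt(x_var[ok] * y_var)
    return np.clip(values, -1.0, 1.0)


def correlation_trace(spont_movie: Movie, template: SensoryTemplate) -> CorrelationTrace:
    """Pearson r of the template against every five-frame spontaneous window.

    ``values[t]`` correlates ``template.flat`` with the flattened in-mask
    pixels of frames ``[t, t+5)``; length is ``n_frames - 4``.  Zero-variance
    windows yield r = 0 with a warning.  Computed with a blocked matrix
    product so 50,000-frame epochs stay fast.
    """
    if spont_movie.frame_shape != template.mask.shape:
        raise ValueError(f"movie frame shape {spont_movie.frame_shape} != "
                         f"template mask shape {template.mask.shape}")
    if not spont_movie.is_dff:
        raise ValueError("correlation_trace expects a dF/F0 movie")
    if spont_movie.n_frames < TEMPLATE_FRAMES:
        raise ValueError("movie shorter than the template window")
    mask = template.mask
    F = np.asarray(spont_movie.data[:, mask], dtype=np.float64)      # (n, p)
    T = np.asarray(template.frames[:, mask], dtype=np.float64).T     # (p, 5)
    values = sliding_pearson(F, T)
    return CorrelationTrace(values=values, mu=float(values.mean()),
                            sigma=float(values.std(ddof=0)),
                            template_id=template.modality)


def binarize_frame(frame: np.ndarray, fraction_of_max: float) -> np.ndarray:
    """Pixels at or above ``fraction_of_max`` of the frame's maximum."""
    frame = np.asarray(frame, dtype=np.float64)
    peak = frame.max()
    if peak <= 0:
        raise ValueError("frame has no positive maximum to binarize against")
    return frame >= fraction_of_max * peak


def concordance(template_frame0: np.ndarray, match_frame0: np.ndarray,
                modality: str, metric: str = "jaccard") -> float:
    """Overlap of the binarized template and match first frames.

    The template is cut at 0.4 of its maximum, the match at the modality-
    specific fraction (whisker 0.5, forelimb 0.6, hindlimb 0.7).  Default
    metric is the Jaccard index |A∩B| / |A∪B|; Dice is available.
    """
    if template_frame0.shape != match_frame0.shape:
        raise ValueError("template and match frames differ in shape")
    if modality not in MATCH_BINARIZE_FRACTION:
        raise ValueError(f"unknown modality {modality!r}")
    a = binarize_frame(template_frame0, TEMPLATE_BINARIZE_FRACTION)
    b = binarize_frame(match_frame0, MATCH_BINARIZE_FRACTION[modality])
    union = np.logical_or(a, b).sum()
    inter = np.logical_and(a, b).sum()
    if union == 0:
        raise ValueError("both binarized frames are empty")
    if metric == "jaccard":
        return float(inter / union)
    if metric == "dice":
        return float(2 * inter / (a.sum() + b.sum()))
    raise ValueError(f"unknown concordance metric {metric!r}")


def _runs_above(values: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    """Maximal runs of strictly supra-threshold values as (start, length)."""
    above = values > threshold
    if not above.any():
        return []
    padded = np.diff(np.concatenate(([0], above.view(np.int8), [0])))
    starts = np.nonzero(padded == 1)[0]
    ends = np.nonzero(padded == -1)[0]
    return [(int(s), int(e - s)) for s, e in zip(starts, ends)]


def detect_events(trace: CorrelationTrace, threshold: float,
                  min_run: int = MIN_RUN) -> list[MotifEvent]:
    """Maximal runs of > threshold correlations lasting >= ``min_run`` frames.

    Shorter runs are discarded, runs are never merged across sub-threshold
    gaps, and events are disjoint by construction.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    events = []
    for start, length in _runs_above(trace.values, threshold):
        if length < min_run:
            continue
        seg = trace.values[start:start + length]
        peak = int(np.argmax(seg))
        events.append(MotifEvent(modality=trace.template_id, onset_frame=start,
                                 duration_frames=length, peak_r=float(seg[peak]),
                                 peak_frame=start + peak))
    return events


def calibrate_threshold(trace: CorrelationTrace, spont_movie: Movie,
                        template: SensoryTemplate,
                        k_grid: np.ndarray | None = None,
                        plateau_rel_gain: float = 0.01,
                        k_default: float = DEFAULT_K,
                        metric: str = "jaccard",
                        match_frame_offset: int = 2) -> tuple[ConcordanceCurve, float]:
    """Concordance sweep over threshold multipliers and the resulting threshold.

    For each k, matches are the runs crossing mu + k*sigma; the curve is the
    mean template/match concordance of the matches' first frames.  Because
    index t labels the left-aligned window [t, t+5), the frame carrying the
    visible onset of a matched motif is the window's central frame, so the
    "first frame of the match" is taken ``match_frame_offset`` frames after
    the crossing index (0 gives the literal crossing frame, which for a
    sliding correlation leads the visible pattern).  The plateau is the
    smallest k after which every remaining per-step relative gain stays below
    ``plateau_rel_gain``.  The returned threshold is
    ``mu + max(plateau_k, k_default) * sigma``, so the sweep diagnoses but
    never lowers the conventional mean + 1.5 SD rule.
    """
    if k_grid is None:
        k_grid = np.arange(0.0, 3.0 + 1e-9, 0.05)
    k_grid = np.asarray(k_grid, dtype=float)
    if k_grid.ndim != 1 or k_grid.size == 0 or np.any(np.diff(k_grid) <= 0):
        raise ValueError("k_grid must be non-empty and strictly increasing")
    modality = template.modality or "forelimb"
    data = np.asarray(spont_movie.data, dtype=np.float64)
    scores = np.full(k_grid.size, np.nan)
    n_matches = np.zeros(k_grid.size, dtype=int)
    for i, k in enumerate(k_grid):
        runs = _runs_above(trace.values, trace.mu + k * trace.sigma)
        vals = []
        for start, _length in runs:
            frame = data[min(start + match_frame_offset, len(data) - 1)]
            if frame.max() <= 0:
                continue
            vals.append(concordance(template.frames[0], frame, modality, metric=metric))
        n_matches[i] = len(vals)
        if vals:
            scores[i] = float(np.mean(vals))
    if n_matches[0] == 0:
        raise ValueError("no matches at the smallest k; trace is degenerate")
    # forward-fill so plateau detection tolerates empty high-k bins
    filled = pd.Series(scores).ffill().to_numpy()
    plateau_k = float(k_grid[-1])
    gains = np.abs(np.diff(filled)) / np.maximum(np.abs(filled[:-1]), 1e-12)
    for i in range(k_grid.size - 1):
        if np.all(gains[i:] < plateau_rel_gain):
            plateau_k = float(k_grid[i])
            break
    curve = ConcordanceCurve(k_values=k_grid, concordance=filled,
                             plateau_k=plateau_k, n_matches=n_matches)
    threshold = trace.mu + max(plateau_k, k_default) * trace.sigma
    return curve, threshold


def motif_frequency(events: list[MotifEvent], n_frames: int) -> float:
    """Events per 10,000 index frames (n_frames - 4 correlation windows)."""
    if n_frames < TEMPLATE_FRAMES:
        raise ValueError("n_frames must be >= 5")
    return len(events) / (n_frames - TEMPLATE_FRAMES + 1) * 10_000.0


def most_represented_motif(per_modality_frequencies: dict[str, float]) -> tuple[str, float]:
    """Modality with the highest motif frequency; ties break in canonical
    order (forelimb < hindlimb < whisker)."""
    if not per_modality_frequencies:
        raise ValueError("no modalities given")
    order = {m: i for i, m in enumerate(MODALITIES)}
    best = min(per_modality_frequencies,
               key=lambda m: (-per_modality_frequencies[m], order.get(m, len(order))))
    return best, per_modality_frequencies[best]


def modality_icc(frequency_table: pd.DataFrame) -> tuple[float, float]:
    """One-way random-effects ICC(1,1) of motif frequencies across modalities.

    ``frequency_table`` is subjects x modality columns.  A low ICC means
    motif upregulation is idiosyncratic per animal rather than uniform.
    Returns (ICC, F-test p); zero between-subject variance yields ICC <= 0.
    """
    import pingouin as pg

    if frequency_table.shape[0] < 3 or frequency_table.shape[1] < 2:
        raise ValueError("need >= 3 subjects and >= 2 modality columns")
    long = frequency_table.reset_index(names="subject").melt(
        id_vars="subject", var_name="modality", value_name="frequency")
    res = pg.intraclass_corr(data=long, targets="subject", raters="modality",
                             ratings="frequency")
    row = res[res["Type"].isin(["ICC1", "ICC(1,1)"])].iloc[0]
    return float(row["ICC"]), float(row["pval"])
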