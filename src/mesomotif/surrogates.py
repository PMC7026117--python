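"""Fourier-domain null ("shuffled") templates and movies.

The null model randomizes the spatial phase of each frame in the 2-D Fourier
domain while preserving its amplitude spectrum exactly — hence also the
frame's mean, variance and spatial autocorrelation (first- and second-order
structure).  An optional rank-remap additionally makes the surrogate's
grey-value histogram identical to the original's, at the cost of an only
approximate spectrum.  Correlating sensory templates against such surrogates
(or surrogate templates against real movies) yields the null distribution of
motif-match counts; a real count outside the null's empirical confidence
interval indicates genuine sensory-patterned structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evoked import SensoryTemplate, TEMPLATE_FRAMES
from .io_core import Movie
from .motifs import (CorrelationTrace, correlation_trace, detect_events,
                     sliding_pearson, MIN_RUN, DEFAULT_K)

#: Refuse whole-movie shuffling above this many pixels x frames without
#: explicit override (memory guard for carelessly large inputs).
FRAME_BUDGET = 600_000_000


@dataclass
class SurrogateSet:
    """Bookkeeping for one batch of surrogates and the null CI they imply."""

    n_surrogates: int
    seed: int | None
    mode: str                       # "template" | "movie"
    match_counts: np.ndarray
    null_ci: tuple[float, float]
    coverage: float


def _random_phase_field(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Unit-modulus Hermitian phase field with DC factor 1.

    Taking the phase of the FFT of real white noise guarantees conjugate
    symmetry (so the surrogate is real) including the self-conjugate
    DC/Nyquist bins; the DC factor is then forced to 1 so the frame mean is
    preserved exactly.
    """
    noise = rng.standard_normal(shape)
    spec = np.fft.fft2(noise)
    mag = np.abs(spec)
    mag[mag == 0] = 1.0
    phase = spec / mag
    phase[0, 0] = 1.0
    return phase


def shuffle_frame(frame: np.ndarray, rng: np.random.Generator | int | None = None,
                  histogram_match: bool = False, mode: str = "phase") -> np.ndarray:
    """Phase-randomized surrogate of one frame.

    ``mode="phase"`` multiplies the frame's 2-D spectrum by a unit-modulus
    random-phase field: the amplitude spectrum is preserved exactly.
    ``mode="literal"`` multiplies by the full spectrum of random grey values
    instead (changing the amplitude spectrum; kept for comparison only).
    With ``histogram_match`` the result is rank-remapped onto the original
    frame's sorted values, making the grey-value histogram identical.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite values")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    spec = np.fft.fft2(frame)
    if mode == "phase":
        spec = spec * _random_phase_field(frame.shape, rng)
    elif mode == "literal":
        spec = spec * np.fft.fft2(rng.standard_normal(frame.shape))
    else:
        raise ValueError(f"unknown shuffle mode {mode!r}")
    out = np.fft.ifft2(spec).real
    if histogram_match:
        ranks = np.argsort(np.argsort(out, axis=None))
        out = np.sort(frame, axis=None)[ranks].reshape(frame.shape)
    return out


def shuffle_template(template: SensoryTemplate,
                     rng: np.random.Generator | int | None = None,
                     histogram_match: bool = False,
                     mode: str = "phase",
                     shared_phase: bool = True) -> SensoryTemplate:
    """Null template: the five frames phase-shuffled in the spatial domain.

    By default one random phase field is shared by all five frames.  This
    preserves not only each frame's amplitude spectrum but the whole
    inter-frame Gram matrix (<f_i, f_j> is invariant under a common
    unit-modulus phase multiplication, by Parseval), so the null template's
    correlation trace has the same temporal autocorrelation as the real
    one — a requirement for run-length match counts to be exchangeable under
    the null.  ``shared_phase=False`` draws a fresh phase field per frame,
    which whitens the null trace and is kept for comparison.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if mode == "phase" and shared_phase:
        phase = _random_phase_field(template.frames.shape[1:], rng)
        frames = np.stack([np.fft.ifft2(np.fft.fft2(f) * phase).real
                           for f in template.frames])
        if histogram_match:
            for i, f in enumerate(template.frames):
                ranks = np.argsort(np.argsort(frames[i], axis=None))
                frames[i] = np.sort(np.asarray(f, dtype=np.float64),
                                    axis=None)[ranks].reshape(f.shape)
    else:
        frames = np.stack([shuffle_frame(f, rng, histogram_match=histogram_match,
                                         mode=mode)
                           for f in template.frames])
    return SensoryTemplate(modality=template.modality, frames=frames,
                           hemisphere=template.hemisphere, mask=template.mask,
                           flat=frames[:, template.mask].ravel(),
                           onset_frame=template.onset_frame,
                           source_subject=template.source_subject)


def shuffle_movie(movie: Movie, n_shuffles: int,
                  seed: int | None = None, histogram_match: bool = False,
                  mode: str = "phase", frame_budget: int = FRAME_BUDGET) -> list[Movie]:
    """Null movies: every frame spatially phase-shuffled, frame order intact.

    The transform is 2-D (spatial only) so the temporal sequence of frames is
    untouched; only the within-frame spatial organization is destroyed.
    """
    if not movie.is_dff:
        raise ValueError("shuffle_movie expects a dF/F0 movie")
    total = n_shuffles * movie.data.size
    if total > frame_budget:
        raise MemoryError(
            f"{n_shuffles} surrogates of a {movie.data.shape} movie exceed the "
            f"frame budget ({total} > {frame_budget}); shuffle in batches")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_shuffles):
        if mode == "phase" and not histogram_match:
            # vectorized path: fresh Hermitian phase field per frame
            spec = np.fft.fft2(np.asarray(movie.data, dtype=np.float64), axes=(-2, -1))
            wspec = np.fft.fft2(rng.standard_normal(movie.data.shape), axes=(-2, -1))
            mag = np.abs(wspec)
            mag[mag == 0] = 1.0
            phase = wspec / mag
            phase[:, 0, 0] = 1.0
            frames = np.fft.ifft2(spec * phase, axes=(-2, -1)).real
        else:
            frames = np.stack([shuffle_frame(f, rng, histogram_match=histogram_match,
                                             mode=mode)
                               for f in movie.data])
        out.append(Movie(frames, frame_rate_hz=movie.frame_rate_hz, is_dff=True,
                         mask=movie.mask))
    return out


def null_match_ci(match_counts: np.ndarray, coverage: float = 0.99) -> tuple[float, float]:
    """Empirical percentile interval of surrogate match counts.

    Linear-interpolation percentiles at (1-coverage)/2 and 1-(1-coverage)/2.
    Requires enough surrogates that the tails are populated
    (n >= 1 / (1 - coverage)); coverage 0 degenerates to the median.
    """
    counts = np.asarray(match_counts, dtype=np.float64)
    if counts.size == 0:
        raise ValueError("no surrogate counts given")
    if not 0 <= coverage < 1:
        raise ValueError("coverage must be in [0, 1)")
    if coverage > 0 and counts.size < 1.0 / (1.0 - coverage):
        raise ValueError(
            f"{counts.size} surrogates are too few for {coverage:.0%} coverage")
    alpha = (1.0 - coverage) / 2.0
    lo, hi = np.percentile(counts, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


def surrogate_match_counts(spont_movie: Movie, template: SensoryTemplate,
                           n_surrogates: int, threshold: float | None = None,
                           k_threshold: float = DEFAULT_K,
                           min_run: int = MIN_RUN, seed: int | None = None,
                           mode: str = "template") -> np.ndarray:
    """Motif-match counts under the null, via surrogate templates or movies.

    ``mode="template"`` correlates phase-shuffled templates against the real
    movie (the 1000-surrogate design); ``mode="movie"`` correlates the real
    template against phase-shuffled movies.  Every surrogate trace is held to
    the same absolute match criterion as the experimental data: ``threshold``
    defaults to mean + k*SD of the real template's correlation trace.  (A
    per-surrogate threshold would hand the null a lower bar whenever genuine
    matches inflate the real trace's SD.)
    """
    rng = np.random.default_rng(seed)
    if threshold is None:
        real = correlation_trace(spont_movie, template)
        threshold = real.threshold(k_threshold)
    counts = np.empty(n_surrogates, dtype=np.int64)
    if mode == "template":
        # Batch all surrogate templates into one matrix product per movie.
        mask = template.mask
        F = np.asarray(spont_movie.data[:, mask], dtype=np.float64)
        p = int(mask.sum())
        m = TEMPLATE_FRAMES * p
        n = F.shape[0]
        n_win = n - TEMPLATE_FRAMES + 1
        s1 = F.sum(axis=1)
        s2 = (F ** 2).sum(axis=1)
        win_s1 = np.zeros(n_win)
        win_s2 = np.zeros(n_win)
        for k in range(TEMPLATE_FRAMES):
            win_s1 += s1[k:k + n_win]
            win_s2 += s2[k:k + n_win]
        x_var = np.maximum(win_s2 - win_s1 ** 2 / m, 0.0)
        T_all = np.empty((p, TEMPLATE_FRAMES * n_surrogates))
        y_sum = np.empty(n_surrogates)
        y_var = np.empty(n_surrogates)
        for i in range(n_surrogates):
            surr = shuffle_template(template, rng)
            Ts = np.asarray(surr.frames[:, mask], dtype=np.float64)
            T_all[:, i * TEMPLATE_FRAMES:(i + 1) * TEMPLATE_FRAMES] = Ts.T
            y_sum[i] = Ts.sum()
            y_var[i] = (Ts ** 2).sum() - y_sum[i] ** 2 / m
        P = F @ T_all
        for i in range(n_surrogates):
            cross = np.zeros(n_win)
            for k in range(TEMPLATE_FRAMES):
                cross += P[k:k + n_win, i * TEMPLATE_FRAMES + k]
            cov = cross - win_s1 * y_sum[i] / m
            denom = np.sqrt(x_var * y_var[i])
            values = np.divide(cov, denom, out=np.zeros(n_win), where=denom > 0)
            values = np.clip(values, -1.0, 1.0)
            trace = CorrelationTrace(values=values, mu=float(values.mean()),
                                     sigma=float(values.std(ddof=0)),
                                     template_id=template.modality)
            counts[i] = len(detect_events(trace, threshold, min_run=min_run))
        return counts
    if mode == "movie":
        # Fast path: cache the movie's spatial spectrum once, then per
        # surrogate draw a fresh Hermitian phase field via a real FFT of
        # white noise (rfft2 keeps only the non-redundant half-spectrum, so
        # conjugate symmetry — hence a real surrogate — is automatic).
        shape = spont_movie.data.shape
        rspec = np.fft.rfft2(np.asarray(spont_movie.data, dtype=np.float64),
                             axes=(-2, -1))
        mask = template.mask
        T = np.asarray(template.frames[:, mask], dtype=np.float64).T
        for i in range(n_surrogates):
            wspec = np.fft.rfft2(rng.standard_normal(shape), axes=(-2, -1))
            wmag = np.abs(wspec)
            wmag[wmag == 0] = 1.0
            phase = wspec / wmag
            phase[:, 0, 0] = 1.0
            frames = np.fft.irfft2(rspec * phase, s=shape[1:], axes=(-2, -1))
            values = sliding_pearson(frames[:, mask], T, warn=False)
            trace = CorrelationTrace(values=values, mu=float(values.mean()),
                                     sigma=float(values.std(ddof=0)),
                                     template_id=template.modality)
            counts[i] = len(detect_events(trace, threshold, min_run=min_run))
        return counts
    raise ValueError(f"unknown surrogate mode {mode!r}")


def compare_distributions(real_values: np.ndarray,
                          null_values: np.ndarray | list[np.ndarray]) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test: real vs pooled null correlations."""
    from scipy import stats

    real = np.asarray(real_values, dtype=np.float64).ravel()
    if isinstance(null_values, (list, tuple)):
        null = np.concatenate([np.asarray(v, dtype=np.float64).ravel() for v in null_values])
    else:
        null = np.asarray(null_values, dtype=np.float64).ravel()
    if real.size == 0 or null.size == 0:
        raise ValueError("empty sample passed to the KS comparison")
    res = stats.ks_2samp(real, null)
    return float(res.statistic), float(res.pvalue)
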