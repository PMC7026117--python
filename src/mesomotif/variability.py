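"""Trial-to-trial evoked variability and its relation to spontaneous motifs.

Per-trial amplitudes (5 x 5-ROI peak within ten post-stimulus frames,
corrected for the mean signal in the three frames preceding response onset)
are summarized per subject as a sample SD, related to spontaneous motif
frequency by ordinary least squares, and related to the pre-stimulus
maximal template correlation by a linear mixed model with a per-subject
random intercept (Wilkinson form: amplitude ~ baseline_max_r + (1 | subject)).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .evoked import POST_STIM_FRAMES, detect_onset, roi_trace
from .io_core import Movie
from .motifs import correlation_trace

BASELINE_MS = 200.0
ONSET_CORRECTION_FRAMES = 3   # ~20 ms at 150 Hz


def trial_amplitude(trial_movie: Movie, roi_center: tuple[int, int],
                    stimulus_frame: int) -> tuple[float, float]:
    """Peak ROI amplitude and its pre-onset baseline-corrected value.

    Amplitude is the maximum of the 5 x 5-ROI trace over post-stimulus frames
    [0, 10).  The corrected amplitude subtracts the mean ROI value of the
    three frames preceding the detected response onset (falling back to the
    stimulus frame when no onset crossing is found), preventing additive
    carry-over of spontaneous fluctuations into the response measure.
    """
    data = np.asarray(trial_movie.data, dtype=np.float64)
    if data.shape[0] < stimulus_frame + POST_STIM_FRAMES:
        raise ValueError("need >= 10 frames after the stimulus")
    trace = roi_trace(data, roi_center)
    post = trace[stimulus_frame:stimulus_frame + POST_STIM_FRAMES]
    amplitude = float(post.max())
    try:
        onset = detect_onset(trace, stimulus_frame, trial_movie.frame_rate_hz)
    except ValueError:
        onset = stimulus_frame
    lo = onset - ONSET_CORRECTION_FRAMES
    if lo < 0:
        raise ValueError("need >= 3 frames before the response onset")
    corrected = amplitude - float(trace[lo:onset].mean())
    return amplitude, corrected


def baseline_max_correlation(trial_movie: Movie, template, stimulus_frame: int,
                             baseline_ms: float = BASELINE_MS) -> float:
    """Maximal template correlation among windows inside the pre-stimulus baseline.

    Only windows lying entirely within ``[stimulus_frame - n_base,
    stimulus_frame)`` contribute; no post-stimulus frame can leak in.
    """
    n_base = int(round(baseline_ms / 1000.0 * trial_movie.frame_rate_hz))
    if n_base < 5:
        raise ValueError("baseline holds fewer than 5 frames")
    lo = stimulus_frame - n_base
    if lo < 0:
        raise ValueError("movie starts after the requested baseline")
    segment = Movie(np.asarray(trial_movie.data[lo:stimulus_frame], dtype=np.float64),
                    frame_rate_hz=trial_movie.frame_rate_hz, is_dff=True,
                    mask=trial_movie.mask)
    trace = correlation_trace(segment, template)
    return float(trace.values.max())


def evoked_sd(amplitudes: np.ndarray) -> float:
    """Sample SD (n-1 denominator) of baseline-corrected trial amplitudes."""
    amplitudes = np.asarray(amplitudes, dtype=np.float64)
    if amplitudes.size < 2:
        raise ValueError("need >= 2 trials for a standard deviation")
    return float(amplitudes.std(ddof=1))


def tukey_exclude(values: np.ndarray, mode: str = "fences",
                  fixed_cutoff: float | None = None,
                  two_sided: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Outlier exclusion by Tukey's fences or a fixed upper cutoff.

    ``fences`` flags values above Q3 + 1.5 IQR (upper fence only by default,
    since excess variability is one-sided; ``two_sided`` adds the lower
    fence).  ``fixed`` flags values above ``fixed_cutoff``.  Returns
    (kept values, excluded indices).
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("empty input")
    if mode == "fences":
        if values.size < 4:
            raise ValueError("need >= 4 values for quartile fences")
        q1, q3 = np.percentile(values, [25, 75])
        iqr = q3 - q1
        bad = values > q3 + 1.5 * iqr
        if two_sided:
            bad |= values < q1 - 1.5 * iqr
    elif mode == "fixed":
        if fixed_cutoff is None:
            raise ValueError("fixed mode requires fixed_cutoff")
        bad = values > fixed_cutoff
    else:
        raise ValueError(f"unknown exclusion mode {mode!r}")
    excluded = np.nonzero(bad)[0]
    return values[~bad], excluded


def regress(y: np.ndarray, x: np.ndarray) -> dict:
    """Ordinary least squares of y on x with the F-test on the slope.

    Returns slope, intercept, F, df (1, n-2), p, and R^2.
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need >= 3 paired finite observations")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return {
        "slope": float(model.params[1]), "intercept": float(model.params[0]),
        "F": float(model.fvalue), "df": (int(model.df_model), int(model.df_resid)),
        "p": float(model.f_pvalue), "r_squared": float(model.rsquared),
        "slope_ci": tuple(float(v) for v in model.conf_int()[1]),
    }


def fit_random_intercept(trials: pd.DataFrame,
                         response: str = "baseline_corrected_amplitude",
                         predictor: str = "baseline_max_r",
                         group: str = "subject_id") -> dict:
    """Linear mixed model: response ~ predictor + (1 | subject), fitted by ML.

    Maximum likelihood (not REML) so nested model comparisons across
    simulations are valid.  The fixed-effect slope is returned with a Wald
    95% CI and a t statistic referred to df = n_obs - 2, the residual-like
    convention documented in the methods note.  Singular (boundary) fits are
    reported with a warning rather than raised.
    """
    import scipy.stats
    import statsmodels.formula.api as smf

    if trials[group].nunique() < 3:
        raise ValueError("need >= 3 subjects for a random-intercept model")
    if trials.groupby(group).size().min() < 2:
        raise ValueError("need >= 2 trials per subject")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(f"{response} ~ {predictor}", data=trials, groups=trials[group])
        fit = model.fit(reml=False)
    slope = float(fit.fe_params[predictor])
    se = float(fit.bse_fe[predictor])
    df = len(trials) - 2
    tval = slope / se if se > 0 else np.inf
    p = float(2 * scipy.stats.t.sf(abs(tval), df))
    tcrit = scipy.stats.t.ppf(0.975, df)
    out = {
        "slope": slope, "se": se, "t": float(tval), "df": int(df), "p": p,
        "ci_low": slope - tcrit * se, "ci_high": slope + tcrit * se,
        "subject_var": float(fit.cov_re.iloc[0, 0]),
        "converged": bool(fit.converged),
    }
    if out["subject_var"] <= 1e-10:
        warnings.warn("random-intercept variance at boundary (singular fit)")
    return out


def interval_variability(amplitudes: pd.DataFrame) -> tuple[pd.DataFrame, float, float]:
    """Per-interval SDs and a one-way repeated-measures ANOVA across intervals.

    ``amplitudes`` is long-format with columns subject_id, interval_ms,
    amplitude; the design must be balanced (same trial count per interval).
    Returns (per subject x interval SD table, F, p).
    """
    import pingouin as pg

    counts = amplitudes.groupby(["subject_id", "interval_ms"]).size()
    if counts.nunique() != 1:
        raise ValueError("unbalanced design: unequal trial counts per interval")
    if amplitudes["interval_ms"].nunique() < 2:
        raise ValueError("need >= 2 intervals")
    sds = (amplitudes.groupby(["subject_id", "interval_ms"])["amplitude"]
           .std(ddof=1).reset_index(name="sd"))
    if np.ptp(sds["sd"].to_numpy()) < 1e-12:   # degenerate: no variability anywhere
        return sds, 0.0, 1.0
    aov = pg.rm_anova(data=sds, dv="sd", within="interval_ms", subject="subject_id")
    pcol = "p_unc" if "p_unc" in aov.columns else "p-unc"
    return sds, float(aov["F"].iloc[0]), float(aov[pcol].iloc[0])


# ---------------------------------------------------------------------------
# Session-level assembly used by the pipeline driver
# ---------------------------------------------------------------------------

def build_trial_records(session, templates: dict) -> pd.DataFrame:
    """TrialRecord table for a simulated evoked session.

    For each stimulus trial: bleach-correct against the subject's blank
    trials, measure amplitude at the template's ROI, and the maximal
    template correlation in the 200 ms baseline.
    """
    from .evoked import evoked_response
    from .preprocess import bleach_correct_trial

    rows = []
    for subject in session.subjects:
        blanks = session.blank_movies[subject]
        for modality in session.modalities:
            template = templates[modality]
            for i, trial in enumerate(session.trial_movies[(subject, modality)]):
                corrected_movie = bleach_correct_trial(trial, blanks)
                resp = evoked_response(corrected_movie, session.stimulus_frame,
                                       modality=modality)
                amp, amp_corr = trial_amplitude(corrected_movie, resp.roi_center,
                                                session.stimulus_frame)
                r = baseline_max_correlation(corrected_movie, template,
                                             session.stimulus_frame)
                rows.append({
                    "subject_id": subject, "modality": modality, "trial": i,
                    "amplitude": amp, "baseline_corrected_amplitude": amp_corr,
                    "baseline_max_r": r, "group_label": "synthetic",
                })
    return pd.DataFrame(rows)


def subject_summaries(trials: pd.DataFrame,
                      frequencies: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per subject x modality evoked SD, optional motif frequency, outlier flag."""
    rows = []
    for (subject, modality), grp in trials.groupby(["subject_id", "modality"]):
        rows.append({"subject_id": subject, "modality": modality,
                     "evoked_sd": evoked_sd(grp["baseline_corrected_amplitude"].to_numpy()),
                     "n_trials": len(grp)})
    summary = pd.DataFrame(rows)
    if frequencies is not None:
        summary = summary.merge(frequencies, on="modality", how="left")
    summary["outlier_flag"] = False
    for modality, grp in summary.groupby("modality"):
        if len(grp) >= 4:
            _, excluded = tukey_exclude(grp["evoked_sd"].to_numpy())
            summary.loc[grp.index[excluded], "outlier_flag"] = True
    return summary
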