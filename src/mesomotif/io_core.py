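"""Movie/trial-table I/O, result serialization, configuration and the pipeline driver.

Movies are 3-D stacks (frames x rows x cols) stored either as multi-page TIFF
(data only, metadata in a YAML sidecar) or HDF5 (data plus ``frame_rate_hz`` /
``is_dff`` attributes).  Result tables are RFC-4180 CSV with a JSON manifest
recording row counts and a hash of the configuration that produced them.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("mesomotif")

#: Default acquisition rate: 6.67 ms per frame.
DEFAULT_FRAME_RATE_HZ = 150.0

#: Sensory modalities, in canonical (tie-break) order.
MODALITIES = ("forelimb", "hindlimb", "whisker")

TRIAL_COLUMNS = ("subject_id", "modality", "stimulus_frame", "is_stimulus_free", "group_label")


def configure_logging(level: int = logging.INFO) -> None:
    """Attach a stderr handler to the package logger (idempotent)."""
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(level)


def log_stage(stage: str, **params) -> None:
    """Log one pipeline stage with its parameter echo."""
    echo = ", ".join(f"{k}={v!r}" for k, v in sorted(params.items()))
    logger.info("stage=%s %s", stage, echo)


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass
class Movie:
    """A time-ordered raster stack.

    Parameters
    ----------
    data
        Array of shape ``(n_frames, rows, cols)``; raw fluorescence counts or
        dF/F0 in percent depending on ``is_dff``.
    frame_rate_hz
        Acquisition rate in Hz (default 150).
    is_dff
        True once the stack has been normalized to percent dF/F0.
    mask
        Optional boolean raster ``(rows, cols)``; pixels outside it are
        ignored by downstream analysis.
    """

    data: np.ndarray
    frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ
    is_dff: bool = False
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"movie data must be 3-D (frames, rows, cols), got ndim={self.data.ndim}")
        if self.data.shape[0] < 1:
            raise ValueError("movie must contain at least one frame")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("movie contains non-finite values")
        if not self.frame_rate_hz > 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape[1:]:
                raise ValueError(
                    f"mask shape {self.mask.shape} != frame shape {self.data.shape[1:]}"
                )

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]


def hemisphere_masks(frame_shape: tuple[int, int],
                     base_mask: np.ndarray | None = None) -> dict[str, np.ndarray]:
    """Left/right hemisphere rasters from a vertical midline split.

    Columns ``[0, cols//2)`` are "left".  A user-supplied craniotomy mask, when
    given, is intersected with each side.
    """
    rows, cols = frame_shape
    left = np.zeros((rows, cols), dtype=bool)
    left[:, : cols // 2] = True
    right = ~left
    if base_mask is not None:
        base_mask = np.asarray(base_mask, dtype=bool)
        left = left & base_mask
        right = right & base_mask
    return {"left": left, "right": right}


# ---------------------------------------------------------------------------
# Movie containers
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def write_movie(movie: Movie, path: str | Path, format: str | None = None) -> Path:
    """Write a movie as multi-page TIFF (+ YAML sidecar) or HDF5.

    The format is inferred from the suffix when not given.  TIFF holds data
    only; ``frame_rate_hz`` and ``is_dff`` go to ``<name>.tif.yaml``.  HDF5
    stores them as attributes of the ``movie`` dataset, and the mask (if any)
    as a ``mask`` dataset.
    """
    import tifffile

    path = Path(path)
    fmt = format or ("hdf5" if path.suffix.lower() in {".h5", ".hdf5"} else "tiff")
    if fmt == "tiff":
        tifffile.imwrite(path, movie.data)
        meta = {"frame_rate_hz": float(movie.frame_rate_hz), "is_dff": bool(movie.is_dff)}
        _sidecar_path(path).write_text(yaml.safe_dump(meta))
    elif fmt == "hdf5":
        import h5py

        with h5py.File(path, "w") as f:
            dset = f.create_dataset("movie", data=movie.data)
            dset.attrs["frame_rate_hz"] = float(movie.frame_rate_hz)
            dset.attrs["is_dff"] = bool(movie.is_dff)
            if movie.mask is not None:
                f.create_dataset("mask", data=movie.mask.astype(np.uint8))
    else:
        raise ValueError(f"unknown movie format {fmt!r}")
    return path


def read_movie(path: str | Path, format: str | None = None) -> Movie:
    """Read a movie from multi-page TIFF or HDF5.

    For TIFF, metadata come from the YAML sidecar when present, else defaults
    (150 Hz, raw fluorescence).
    """
    import tifffile

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("hdf5" if path.suffix.lower() in {".h5", ".hdf5"} else "tiff")
    if fmt == "tiff":
        data = tifffile.imread(path)
        if data.ndim == 2:  # single-page file
            data = data[None]
        if data.ndim != 3:
            raise ValueError(f"TIFF at {path} does not decode to a 3-D stack (ndim={data.ndim})")
        meta: dict = {}
        side = _sidecar_path(path)
        if side.exists():
            meta = yaml.safe_load(side.read_text()) or {}
        return Movie(
            data,
            frame_rate_hz=float(meta.get("frame_rate_hz", DEFAULT_FRAME_RATE_HZ)),
            is_dff=bool(meta.get("is_dff", False)),
        )
    if fmt == "hdf5":
        import h5py

        with h5py.File(path, "r") as f:
            if "movie" not in f:
                raise ValueError(f"HDF5 file {path} lacks a 'movie' dataset")
            dset = f["movie"]
            data = dset[()]
            if data.ndim != 3:
                raise ValueError(f"HDF5 movie at {path} is not 3-D (ndim={data.ndim})")
            mask = f["mask"][()].astype(bool) if "mask" in f else None
            return Movie(
                data,
                frame_rate_hz=float(dset.attrs.get("frame_rate_hz", DEFAULT_FRAME_RATE_HZ)),
                is_dff=bool(dset.attrs.get("is_dff", False)),
                mask=mask,
            )
    raise ValueError(f"unknown movie format {format!r}")


# ---------------------------------------------------------------------------
# Trial tables
# ---------------------------------------------------------------------------

def validate_trial_table(table: pd.DataFrame, n_frames: int | None = None) -> pd.DataFrame:
    """Check the trial-table schema and invariants; return the table."""
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    bad = set(table["modality"]) - set(MODALITIES)
    if bad:
        raise ValueError(f"unknown modalities in trial table: {sorted(bad)}")
    if n_frames is not None:
        out = (table["stimulus_frame"] < 0) | (table["stimulus_frame"] >= n_frames)
        if out.any():
            raise ValueError("stimulus_frame out of movie bounds")
    stim = table[~table["is_stimulus_free"].astype(bool)]
    for (subj, mod), grp in stim.groupby(["subject_id", "modality"]):
        if len(grp) < 1:  # pragma: no cover - groupby only yields non-empty groups
            raise ValueError(f"no stimulus trials for {subj}/{mod}")
    return table


def read_trial_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    return validate_trial_table(table)


def write_trial_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    validate_trial_table(table).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Results and configuration
# ---------------------------------------------------------------------------

def config_hash(config: Mapping | None) -> str:
    """Stable SHA-256 of a configuration mapping (sorted-key JSON)."""
    payload = json.dumps(config or {}, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()


def write_results(tables: Mapping[str, pd.DataFrame], out_dir: str | Path,
                  config: Mapping | None = None) -> dict:
    """Write each table as CSV plus a JSON manifest.

    The manifest maps table name -> {path, row_count} and records the config
    hash so any number in a result table can be traced to a configuration.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config_hash(config), "tables": {}}
    for name, table in tables.items():
        path = out_dir / f"{name}.csv"
        table.to_csv(path, index=False, float_format="%.10g")
        manifest["tables"][name] = {"path": path.name, "row_count": int(len(table))}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


DEFAULT_CONFIG: dict = {
    "simulate": {
        "n_frames": 3000,
        "field": [32, 32],
        "event_rate_per_modality": 1.0e-3,
        "amplitude_pct": 0.4,
        "noise_sd_pct": 0.05,
        "n_subjects": 3,
        "n_trials_per_modality": 5,
        "n_blank_trials": 2,
        "beta": 0.5,
    },
    "preprocess": {"band_low_hz": 0.5, "band_high_hz": 6.0, "filter_order": 4,
                   "passband_ripple_db": 0.1, "apply_bandpass": True},
    "detect": {"k_threshold": 1.5, "min_run": 5},
    "surrogate": {"n_surrogates": 50, "coverage": 0.95},
}


def _merge(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for key, val in override.items():
        if isinstance(val, Mapping) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def load_config(path: str | Path | None = None, overrides: Mapping | None = None) -> dict:
    """Merge a YAML config file (and/or an override mapping) over the defaults."""
    config = dict(DEFAULT_CONFIG)
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, Mapping):
            raise ValueError(f"config at {path} is not a mapping")
        config = _merge(config, loaded)
    if overrides:
        config = _merge(config, overrides)
    return config


def run_pipeline(config: Mapping, seed: int, out_dir: str | Path) -> dict:
    """Run the full analysis chain on a synthetic session and write result tables.

    Stages (in acquisition order): simulate spontaneous + evoked movies;
    dF/F0 + bandpass; per-modality sensory templates from the evoked trials;
    template correlation, threshold, event detection; surrogate-template null;
    trial-level variability statistics and the random-intercept model.
    Deterministic for fixed ``(config, seed)``.
    """
    from . import evoked as evoked_mod
    from . import motifs as motifs_mod
    from . import preprocess as pre
    from . import surrogates as surr
    from . import synthetic
    from . import variability as vari

    for key in ("simulate", "preprocess", "detect", "surrogate"):
        if key not in config:
            raise KeyError(f"config missing required section {key!r}")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    sim_cfg = config["simulate"]
    field = tuple(sim_cfg.get("field", (32, 32)))

    log_stage("simulate", seed=seed, **{k: v for k, v in sim_cfg.items()})
    spont, truth = synthetic.simulate_spontaneous(
        n_frames=sim_cfg.get("n_frames", 3000),
        field=field,
        event_rate_per_modality=sim_cfg.get("event_rate_per_modality", 1.0e-3),
        amplitude_pct=sim_cfg.get("amplitude_pct", 0.4),
        noise_sd_pct=sim_cfg.get("noise_sd_pct", 0.05),
        seed=int(rng.integers(2**31 - 1)),
    )
    session = synthetic.simulate_evoked_session(
        n_subjects=sim_cfg.get("n_subjects", 3),
        n_trials_per_modality=sim_cfg.get("n_trials_per_modality", 5),
        n_blank_trials=sim_cfg.get("n_blank_trials", 2),
        beta=sim_cfg.get("beta", 0.5),
        field=field,
        modalities=tuple(sim_cfg.get("modalities", MODALITIES)),
        seed=int(rng.integers(2**31 - 1)),
    )

    pre_cfg = config["preprocess"]
    log_stage("preprocess", **pre_cfg)
    spont_dff = pre.dff(spont)
    if pre_cfg.get("apply_bandpass", True):
        spont_dff = pre.bandpass(
            spont_dff,
            band_low_hz=pre_cfg.get("band_low_hz", 0.5),
            band_high_hz=pre_cfg.get("band_high_hz", 6.0),
            filter_order=pre_cfg.get("filter_order", 4),
            passband_ripple_db=pre_cfg.get("passband_ripple_db", 0.1),
        )

    # Templates from the first subject's averaged, bleach-corrected evoked trials.
    log_stage("template", n_subjects=sim_cfg.get("n_subjects", 3))
    templates = {}
    subject0 = session.subjects[0]
    for modality in session.modalities:
        trials = session.trial_movies[(subject0, modality)]
        blanks = session.blank_movies[subject0]
        corrected = [pre.bleach_correct_trial(t, blanks) for t in trials]
        mean_evoked = evoked_mod.average_evoked(corrected, [session.stimulus_frame] * len(corrected))
        templates[modality] = evoked_mod.extract_template(
            mean_evoked, session.stimulus_frame, modality=modality)

    det_cfg = config["detect"]
    log_stage("detect", **det_cfg)
    event_rows, freq_rows = [], []
    traces = {}
    for modality, template in templates.items():
        trace = motifs_mod.correlation_trace(spont_dff, template)
        traces[modality] = trace
        threshold = trace.mu + det_cfg.get("k_threshold", 1.5) * trace.sigma
        events = motifs_mod.detect_events(trace, threshold, min_run=det_cfg.get("min_run", 5))
        for ev in events:
            event_rows.append({
                "modality": modality, "onset_frame": ev.onset_frame,
                "duration_frames": ev.duration_frames, "peak_r": ev.peak_r,
                "peak_frame": ev.peak_frame,
            })
        freq_rows.append({
            "modality": modality,
            "frequency_per_10k": motifs_mod.motif_frequency(events, spont_dff.n_frames),
            "threshold": threshold, "mu": trace.mu, "sigma": trace.sigma,
        })
    events_table = pd.DataFrame(event_rows, columns=[
        "modality", "onset_frame", "duration_frames", "peak_r", "peak_frame"])
    freq_table = pd.DataFrame(freq_rows)

    surr_cfg = config["surrogate"]
    log_stage("surrogate", **surr_cfg)
    surr_rows = []
    for modality, template in templates.items():
        trace = traces[modality]
        threshold = trace.mu + det_cfg.get("k_threshold", 1.5) * trace.sigma
        real_count = len(motifs_mod.detect_events(trace, threshold,
                                                  min_run=det_cfg.get("min_run", 5)))
        counts = surr.surrogate_match_counts(
            spont_dff, template, n_surrogates=surr_cfg.get("n_surrogates", 50),
            threshold=threshold, min_run=det_cfg.get("min_run", 5),
            seed=int(rng.integers(2**31 - 1)))
        lo, hi = surr.null_match_ci(counts, coverage=surr_cfg.get("coverage", 0.95))
        surr_rows.append({"modality": modality, "real_count": real_count,
                          "null_lower": lo, "null_upper": hi,
                          "n_surrogates": len(counts)})
    surr_table = pd.DataFrame(surr_rows)

    log_stage("variability")
    trial_table = vari.build_trial_records(session, templates)
    summary = vari.subject_summaries(trial_table)
    mm_rows = []
    if trial_table["subject_id"].nunique() >= 3:
        for modality in session.modalities:
            sub = trial_table[trial_table["modality"] == modality]
            fit = vari.fit_random_intercept(sub)
            mm_rows.append({"modality": modality, **fit})
    mm_table = pd.DataFrame(mm_rows)

    manifest = write_results(
        {"events": events_table, "frequencies": freq_table, "surrogates": surr_table,
         "trials": trial_table, "subject_summary": summary, "mixed_model": mm_table},
        out_dir, config={"seed": seed, **{k: config[k] for k in sorted(config)}})
    return manifest
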