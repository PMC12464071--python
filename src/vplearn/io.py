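"""File formats, configuration, and schema validation.

All interchange is plain CSV (RFC-4180 via pandas) plus YAML/JSON configs.
The trial-log schema carries one row per 2AFC trial; the eye-trace schema
one row per 1-ms gaze sample.  Config defaults reproduce the experiment's
constants (stimulus parameters, staircase rules, exclusion criterion, and
eye-analysis windows/thresholds).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from importlib import metadata

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TrialLogError",
    "TRIAL_LOG_COLUMNS",
    "read_trial_log",
    "write_trial_log",
    "read_eye_trace",
    "write_eye_trace",
    "read_markers",
    "default_config",
    "load_config",
    "save_config",
    "run_info",
    "location_distances",
]


class TrialLogError(ValueError):
    """Schema violation in a trial-log file, with the offending row."""


TRIAL_LOG_COLUMNS = (
    "subject_id",
    "randomization",
    "training_location",
    "session_type",
    "session_index",
    "block",
    "trial",
    "location",
    "reference_ori_deg",
    "offset_deg",
    "phase_deg",
    "contrast",
    "staircase_id",
    "response",
    "correct",
    "aborted",
)

_ENUMS = {
    "randomization": {"phase", "contrast"},
    "training_location": {"UVF", "LVF"},
    "session_type": {"pre", "train", "post"},
    "location": {"training", "C", "F", "C-transfer", "F-transfer"},
    "response": {"cw", "ccw"},
    "correct": {0, 1},
    "aborted": {0, 1},
}

_OPTIONAL = {"phase_deg"}


def read_trial_log(path) -> pd.DataFrame:
    """Read and validate a trial-log CSV.

    Hard errors (with the first offending CSV row number): unknown enum
    values, duplicate (subject, session, block, trial) keys, and a zero
    orientation offset on a scored (non-aborted) trial.  A missing optional
    ``phase_deg`` column (contrast-group files) is accepted with a warning.
    Aborted trials are retained, flagged by the ``aborted`` column.
    """
    df = pd.read_csv(path)
    missing = set(TRIAL_LOG_COLUMNS) - set(df.columns)
    if missing - _OPTIONAL:
        raise TrialLogError(f"missing required column(s): {sorted(missing - _OPTIONAL)}")
    if missing & _OPTIONAL:
        warnings.warn(f"optional column(s) missing: {sorted(missing & _OPTIONAL)}")
        for col in missing & _OPTIONAL:
            df[col] = np.nan

    for col, allowed in _ENUMS.items():
        bad = ~df[col].isin(allowed)
        if bad.any():
            row = int(df.index[bad][0]) + 2  # header + 1-based
            raise TrialLogError(
                f"unknown {col} value {df.loc[df.index[bad][0], col]!r} at CSV row {row}"
            )

    # natural trial key: block indices restart at each measured location
    key = ["subject_id", "session_type", "session_index", "location", "block", "trial"]
    dup = df.duplicated(subset=key)
    if dup.any():
        row = int(df.index[dup][0]) + 2
        raise TrialLogError(
            f"duplicate (subject, session, location, block, trial) at CSV row {row}"
        )

    zero = (df["aborted"] == 0) & (df["offset_deg"] == 0)
    if zero.any():
        row = int(df.index[zero][0]) + 2
        raise TrialLogError(f"offset_deg = 0 on a scored trial at CSV row {row}")

    per_subj = df.groupby("subject_id")[["randomization", "training_location"]].nunique()
    if (per_subj > 1).any().any():
        raise TrialLogError("a subject appears with more than one group assignment")
    return df


def write_trial_log(df: pd.DataFrame, path) -> None:
    cols = [c for c in TRIAL_LOG_COLUMNS if c in df.columns]
    df.to_csv(path, index=False, columns=cols)


def read_eye_trace(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"trial_id", "t_ms", "x_dva", "y_dva", "valid"}
    missing = required - set(df.columns)
    if missing:
        raise TrialLogError(f"eye trace missing column(s): {sorted(missing)}")
    df["valid"] = df["valid"].astype(bool)
    if "blink" in df.columns:
        df["blink"] = df["blink"].astype(bool)
    for _, g in df.groupby("trial_id", observed=True):
        dt = np.diff(g["t_ms"].to_numpy())
        if dt.size and not np.all(dt == 1):
            raise TrialLogError(
                f"trial {g['trial_id'].iloc[0]}: t_ms must increase in 1-ms steps"
            )
    return df


def write_eye_trace(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_markers(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"trial_id", "ref_onset_ms", "ref_offset_ms", "test_onset_ms", "test_offset_ms"}
    missing = required - set(df.columns)
    if missing:
        raise TrialLogError(f"markers missing column(s): {sorted(missing)}")
    return df


def default_config() -> dict:
    """All analysis constants, as one nested dict."""
    return {
        "stimulus": {
            "size_deg": 2.0,
            "sf_cpd": 2.5,
            "sigma_deg": 0.28,
            "background_lum": 52.42,
            "eccentricity_deg": 6.0,
            "reference_ori_deg": 45.0,
            "fixed_contrast": 0.45,
            "fixed_phase_deg": 0.0,
            "phase_range_deg": [0.0, 180.0],
            "contrast_range": [0.33, 0.66],
        },
        "staircase": {
            "start_levels_deg": [1.0, 3.0],
            "step_log10": 0.05,
            "n_down": 3,
            "n_up": 1,
            "max_trials": 200,
            "reversals_to_stop": 10,
            "discard_reversals": 4,
            "average_reversals": 6,
            "pool_staircases": False,
        },
        "analysis": {
            "exclusion_li": -0.20,
            "blocks_per_location": 3,
        },
        "eye": {
            "sampling_hz": 1000,
            "blink_pre_ms": 100,
            "blink_post_ms": 150,
            "segment_pre_ref_ms": 200,
            "segment_post_target_ms": 350,
            "velocity_sd_threshold": 6.0,
            "velocity_estimator": "median",
            "min_duration_ms": 6,
            "min_gap_ms": 10,
            "max_amplitude_dva": 1.0,
            "fixation_window_deg": 2.0,
        },
        "art": {"df_method": "stratified-satterthwaite"},
        # polar angles (deg, math convention) of the three locations on the
        # 6-deg iso-eccentric circle.  Configurable: the printed pairwise
        # distances (5.0 between adjacent locations, 11.5 training to
        # far-transfer) cannot all be realized on one circle, so the
        # defaults honor training--C-transfer = 5.0 and training--
        # F-transfer = 11.5 (far transfer in the opposite hemifield) and the
        # C--F distance is whatever the geometry implies; distances are
        # always recomputed from the configured angles.
        "locations": {
            "eccentricity_deg": 6.0,
            "polar_angles_deg": {
                "training": 100.0,
                "C-transfer": 149.25,
                "F-transfer": 246.9,
            },
        },
    }


def location_distances(config: dict | None = None) -> dict:
    """Chord distances (dva) between the configured stimulus locations."""
    cfg = (config or default_config())["locations"]
    ecc = cfg["eccentricity_deg"]
    ang = cfg["polar_angles_deg"]
    pts = {
        k: np.array([ecc * np.cos(np.deg2rad(a)), ecc * np.sin(np.deg2rad(a))])
        for k, a in ang.items()
    }
    names = list(pts)
    return {
        f"{a}--{b}": float(np.linalg.norm(pts[a] - pts[b]))
        for i, a in enumerate(names)
        for b in names[i + 1 :]
    }


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = default_config()

    def merge(base, over):
        for k, v in over.items():
            if isinstance(v, dict) and isinstance(base.get(k), dict):
                merge(base[k], v)
            else:
                base[k] = v

    merge(cfg, user)
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def run_info(config: dict, seed: int | None) -> dict:
    """Provenance block written next to every CLI artifact."""
    blob = json.dumps(config, sort_keys=True).encode()
    try:
        version = metadata.version("vplearn")
    except metadata.PackageNotFoundError:  # pragma: no cover
        version = "unknown"
    return {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
        "vplearn_version": version,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
    }
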