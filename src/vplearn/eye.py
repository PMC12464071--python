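"""Gaze preprocessing, microsaccade detection, and fixation statistics.

Traces are 1000-Hz gaze samples in degrees of visual angle (dva) relative to
screen center (x rightward, y upward), with a per-sample blink/track-loss
channel.  Blinks are excluded together with a 100-ms pre- and 150-ms
post-margin; trials are segmented from 200 ms before reference onset to
350 ms after test offset.

Microsaccades are detected per trial with a velocity-threshold algorithm:
2-D velocity from a 5-sample centered difference kernel, a candidate being a
run of samples whose velocity exceeds a 6-SD threshold for at least 6 ms.
Candidates closer than 10 ms are merged and events with amplitude >= 1 dva
are discarded.  The default threshold is the median-based elliptical
criterion of the canonical velocity-threshold algorithm (robust: the events
themselves cannot inflate it); ``estimator='mean'`` selects the literal
scalar reading (trial mean speed + 6 SD), which loses sensitivity when
events occupy a non-negligible fraction of the trial.  Detected amplitudes and peak velocities should obey
the linear "main sequence" relation, which :func:`main_sequence` quantifies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .psychstats import PearsonResult, pearson_r_test

__all__ = [
    "Microsaccade",
    "Segment",
    "mask_blinks",
    "segment_trials",
    "detect_microsaccades",
    "detect_microsaccades_df",
    "ms_rate",
    "ms_percentage",
    "fixation_variability",
    "main_sequence",
]

TRACE_COLUMNS = ("trial_id", "t_ms", "x_dva", "y_dva", "valid")


@dataclass(frozen=True)
class Microsaccade:
    """One ballistic fixational event."""

    trial_id: object
    onset_ms: int
    offset_ms: int
    amplitude_dva: float
    peak_velocity_dva_s: float

    def __post_init__(self) -> None:
        if self.offset_ms - self.onset_ms + 1 < 6:
            raise ValueError("microsaccade shorter than 6 ms")
        if not self.amplitude_dva < 1.0:
            raise ValueError("microsaccade amplitude must be < 1 dva")


@dataclass
class Segment:
    """One trial's analysis window with its event markers."""

    trial_id: object
    data: pd.DataFrame
    markers: dict
    has_blink: bool


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, end) inclusive index pairs."""
    if mask.size == 0:
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1))
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size - 1)
    return list(zip(starts, ends))


def mask_blinks(
    trace: pd.DataFrame, pre_ms: int = 100, post_ms: int = 150
) -> pd.DataFrame:
    """Invalidate samples within [blink_start - pre_ms, blink_end + post_ms].

    The raw blink channel is preserved in a ``blink`` column (created from
    ``~valid`` on first application), and ``valid`` is always rederived from
    it, so the operation is idempotent and overlapping margins merge into a
    single invalid run.
    """
    out = trace.copy()
    if "blink" not in out.columns:
        out["blink"] = ~out["valid"].astype(bool)
    new_valid = np.ones(len(out), dtype=bool)
    for _, idx in out.groupby("trial_id", sort=False, observed=True).indices.items():
        idx = np.sort(idx)
        t = out["t_ms"].to_numpy()[idx]
        blink = out["blink"].to_numpy()[idx]
        invalid = np.zeros(idx.size, dtype=bool)
        for s, e in _runs(blink):
            invalid |= (t >= t[s] - pre_ms) & (t <= t[e] + post_ms)
        new_valid[idx] = ~invalid
    out["valid"] = new_valid
    return out


def segment_trials(
    trace: pd.DataFrame,
    markers: pd.DataFrame,
    pre_ref_ms: int = 200,
    post_target_ms: int = 350,
) -> tuple[list[Segment], list]:
    """Cut per-trial analysis windows.

    The window runs from ``pre_ref_ms`` before reference onset to
    ``post_target_ms`` after test (target) offset.  Trials whose markers are
    missing are skipped with a warning; trials containing any blink sample in
    the window are flagged (they are excluded from valid-trial denominators).
    Returns ``(segments, skipped_trial_ids)``.
    """
    marker_cols = ("ref_onset_ms", "ref_offset_ms", "test_onset_ms", "test_offset_ms")
    mk = markers.set_index("trial_id")
    segments: list[Segment] = []
    skipped: list = []
    for trial_id, g in trace.groupby("trial_id", sort=False, observed=True):
        if trial_id not in mk.index or mk.loc[trial_id, list(marker_cols)].isna().any():
            warnings.warn(f"trial {trial_id}: missing event markers, skipped")
            skipped.append(trial_id)
            continue
        row = mk.loc[trial_id]
        lo = float(row["ref_onset_ms"]) - pre_ref_ms
        hi = float(row["test_offset_ms"]) + post_target_ms
        win = g[(g["t_ms"] >= lo) & (g["t_ms"] <= hi)]
        blink_col = win["blink"] if "blink" in win.columns else ~win["valid"].astype(bool)
        segments.append(
            Segment(
                trial_id=trial_id,
                data=win.reset_index(drop=True),
                markers=row.to_dict(),
                has_blink=bool(blink_col.any()),
            )
        )
    return segments, skipped


def _velocity(x: np.ndarray, y: np.ndarray, valid: np.ndarray, dt_s: float = 1e-3):
    """5-sample centered difference velocity; invalid where the kernel touches
    an invalid sample or the trace edge."""
    n = x.size
    vx = np.full(n, np.nan)
    vy = np.full(n, np.nan)
    if n >= 5:
        vx[2:-2] = (x[4:] + x[3:-1] - x[1:-3] - x[:-4]) / (6.0 * dt_s)
        vy[2:-2] = (y[4:] + y[3:-1] - y[1:-3] - y[:-4]) / (6.0 * dt_s)
    ok = np.zeros(n, dtype=bool)
    if n >= 5:
        v5 = np.ones(n, dtype=bool)
        for k in range(-2, 3):
            v5[2:-2] &= valid[2 + k : n - 2 + k]
        ok[2:-2] = v5[2:-2]
    return vx, vy, ok


def detect_microsaccades(
    segment: Segment | pd.DataFrame,
    threshold_sd: float = 6.0,
    min_duration_ms: int = 6,
    min_gap_ms: int = 10,
    max_amplitude_dva: float = 1.0,
    estimator: str = "median",
    amplitude: str = "range",
    gap_mode: str = "merge",
) -> list[Microsaccade]:
    """Velocity-threshold microsaccade detection on one trial.

    ``estimator='median'`` (default) uses the median-based per-component
    elliptical criterion; ``'mean'`` thresholds scalar speed at trial
    mean + 6 SD.
    ``amplitude='range'`` combines the per-axis positional ranges over the
    event (``'displacement'`` uses onset-to-offset displacement instead).
    Candidates closer than ``min_gap_ms`` are merged by default
    (``gap_mode='discard'`` drops the later one).  Traces with fewer than
    20 valid samples yield an empty list.
    """
    if estimator not in ("mean", "median"):
        raise ValueError("estimator must be 'mean' or 'median'")
    if amplitude not in ("range", "displacement"):
        raise ValueError("amplitude must be 'range' or 'displacement'")
    if gap_mode not in ("merge", "discard"):
        raise ValueError("gap_mode must be 'merge' or 'discard'")
    if isinstance(segment, Segment):
        data = segment.data
        trial_id = segment.trial_id
    else:
        data = segment
        trial_id = data["trial_id"].iloc[0] if "trial_id" in data.columns else None
    t = data["t_ms"].to_numpy(dtype=float)
    x = data["x_dva"].to_numpy(dtype=float)
    y = data["y_dva"].to_numpy(dtype=float)
    valid = data["valid"].to_numpy(dtype=bool)
    if valid.sum() < 20:
        return []

    vx, vy, vok = _velocity(x, y, valid)
    speed = np.hypot(vx, vy)
    if vok.sum() < 10:
        return []
    if estimator == "mean":
        mu = float(np.mean(speed[vok]))
        sd = float(np.std(speed[vok]))
        above = vok & (speed > mu + threshold_sd * sd)
    else:
        # median-based elliptical criterion per component
        crit = np.zeros_like(speed)
        for v in (vx, vy):
            med = np.median(v[vok])
            sigma = np.sqrt(max(np.median(v[vok] ** 2) - med**2, 1e-12))
            crit += (v / (threshold_sd * sigma)) ** 2
        above = vok & (crit > 1.0)

    cands = [(s, e) for s, e in _runs(above) if t[e] - t[s] + 1 >= min_duration_ms]
    # enforce the minimum inter-event gap
    merged: list[list[int]] = []
    for s, e in cands:
        if merged and t[s] - t[merged[-1][1]] < min_gap_ms:
            if gap_mode == "merge":
                merged[-1][1] = e
            # discard: keep the earlier event, drop this one
        else:
            merged.append([s, e])

    events: list[Microsaccade] = []
    for s, e in merged:
        sl = slice(s, e + 1)
        if amplitude == "range":
            amp = float(np.hypot(x[sl].max() - x[sl].min(), y[sl].max() - y[sl].min()))
        else:
            amp = float(np.hypot(x[e] - x[s], y[e] - y[s]))
        if amp >= max_amplitude_dva:
            continue
        events.append(
            Microsaccade(
                trial_id=trial_id,
                onset_ms=int(t[s]),
                offset_ms=int(t[e]),
                amplitude_dva=amp,
                peak_velocity_dva_s=float(np.nanmax(speed[sl])),
            )
        )
    return events


def detect_microsaccades_df(segments: list[Segment], **kwargs) -> pd.DataFrame:
    """Detect over a list of segments; returns one row per event."""
    rows = [
        {
            "trial_id": ev.trial_id,
            "onset_ms": ev.onset_ms,
            "offset_ms": ev.offset_ms,
            "amplitude_dva": ev.amplitude_dva,
            "peak_velocity_dva_s": ev.peak_velocity_dva_s,
        }
        for seg in segments
        for ev in detect_microsaccades(seg, **kwargs)
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "trial_id",
            "onset_ms",
            "offset_ms",
            "amplitude_dva",
            "peak_velocity_dva_s",
        ],
    )


def ms_rate(n_events_per_trial, trial_duration_ms) -> float:
    """Events per second: mean onset count per 1-ms bin across trials x 1000.

    ``trial_duration_ms`` may be a scalar (equal-length trials) or a
    per-trial sequence.
    """
    counts = np.asarray(n_events_per_trial, dtype=float)
    if counts.size == 0:
        raise ValueError("need at least one trial")
    durations = np.broadcast_to(
        np.asarray(trial_duration_ms, dtype=float), counts.shape
    )
    return float(counts.sum() / durations.sum() * 1000.0)


def ms_percentage(n_events: int, n_valid_trials: int) -> float:
    """Events per valid (blink-free) trial."""
    if n_valid_trials <= 0:
        raise ValueError("need at least one valid trial")
    return n_events / n_valid_trials


def fixation_variability(
    segments: list[Segment],
    fixation_point: tuple[float, float] = (0.0, 0.0),
    window: str = "both",
) -> float:
    """Across-trial SD of the mean gaze-to-fixation distance.

    Per trial, the mean Euclidean distance of valid samples to the fixation
    point is computed over the stimulus-presentation window: the reference
    window, the test window, or their union (default).  Returns the sample
    SD of the per-trial means.
    """
    if window not in ("both", "reference", "test"):
        raise ValueError("window must be 'both', 'reference' or 'test'")
    fx, fy = fixation_point
    means = []
    for seg in segments:
        t = seg.data["t_ms"].to_numpy(dtype=float)
        sel = np.zeros(t.size, dtype=bool)
        if window in ("both", "reference"):
            sel |= (t >= seg.markers["ref_onset_ms"]) & (
                t <= seg.markers["ref_offset_ms"]
            )
        if window in ("both", "test"):
            sel |= (t >= seg.markers["test_onset_ms"]) & (
                t <= seg.markers["test_offset_ms"]
            )
        sel &= seg.data["valid"].to_numpy(dtype=bool)
        if not sel.any():
            continue
        d = np.hypot(
            seg.data["x_dva"].to_numpy(dtype=float)[sel] - fx,
            seg.data["y_dva"].to_numpy(dtype=float)[sel] - fy,
        )
        means.append(float(d.mean()))
    if len(means) < 2:
        raise ValueError("need >= 2 trials with stimulus-window samples")
    return float(np.std(means, ddof=1))


def main_sequence(events) -> PearsonResult:
    """Amplitude / peak-velocity correlation of detected events."""
    if isinstance(events, pd.DataFrame):
        amp = events["amplitude_dva"].to_numpy(dtype=float)
        vel = events["peak_velocity_dva_s"].to_numpy(dtype=float)
    else:
        amp = np.array([e.amplitude_dva for e in events], dtype=float)
        vel = np.array([e.peak_velocity_dva_s for e in events], dtype=float)
    return pearson_r_test(amp, vel, sided="two")
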