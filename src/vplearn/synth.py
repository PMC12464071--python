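"""Synthetic observers, learning cohorts, and eye traces.

Everything the analysis pipeline consumes can be generated here with known
ground truth:

* :class:`ObserverModel` — a 2AFC observer whose probability of a correct
  response is ``0.5 + (0.5 - lapse) * W(|offset|)`` with a Weibull ``W``
  parameterized so that ``alpha_deg`` is exactly the 79.4%-correct point
  (the 3-down-1-up convergence level) regardless of lapse rate.
* :func:`simulate_cohort` — a full pre/post threshold experiment: per
  subject, pre-thresholds are drawn log-normally, transfer learning indices
  (LIs) come from a bivariate normal with a group-specific correlation, and
  every block is measured by actually running the interleaved staircases
  against the evolving observer.
* :func:`simulate_trace` — 1000-Hz gaze traces: random-walk drift plus
  white measurement noise, injected minimum-jerk microsaccades whose peak
  velocity follows a linear main sequence, and blink gaps in the validity
  channel, with a ground-truth event list.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .staircase import BlockConfig, block_threshold, run_block
from .stimulus import RandomizationScheme

__all__ = [
    "ObserverModel",
    "CohortSpec",
    "TraceSpec",
    "CohortResult",
    "observer_respond",
    "simulate_cohort",
    "simulate_null_table",
    "simulate_trace",
    "cohort_preset",
    "trace_preset",
]

LOCATIONS = ("training", "C-transfer", "F-transfer")
#: level at which a 3-down-1-up staircase converges
P_CONVERGENCE = 0.5 ** (1.0 / 3.0)


@dataclass(frozen=True)
class ObserverModel:
    """Weibull 2AFC observer; ``alpha_deg`` pins the 79.4%-correct offset."""

    alpha_deg: float
    beta: float = 2.0
    lapse: float = 0.0
    guess: float = 0.5

    def __post_init__(self) -> None:
        if self.alpha_deg <= 0:
            raise ValueError("alpha_deg must be positive")
        if not 0.0 <= self.lapse <= 0.1:
            raise ValueError("lapse must be in [0, 0.1]")
        if self.beta <= 0:
            raise ValueError("beta must be positive")

    def p_correct(self, offset_deg: float) -> float:
        """Probability of a correct response at a signed offset (sign-blind)."""
        x = abs(offset_deg)
        upper = 1.0 - self.guess - self.lapse
        # scale chosen so p(alpha) = 0.5^(1/3) exactly
        w_target = (P_CONVERGENCE - self.guess) / upper
        scale = self.alpha_deg / (-math.log1p(-w_target)) ** (1.0 / self.beta)
        w = 1.0 - math.exp(-((x / scale) ** self.beta))
        return self.guess + upper * w


def observer_respond(
    model: ObserverModel, offset_deg: float, rng: np.random.Generator
) -> bool:
    """One Bernoulli 2AFC response."""
    return bool(rng.random() < model.p_correct(offset_deg))


def make_observer(model: ObserverModel):
    """Closure with the :mod:`staircase` observer signature."""

    def respond(offset_deg: float, rng: np.random.Generator) -> bool:
        return observer_respond(model, offset_deg, rng)

    return respond


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one simulated cohort.

    Defaults are the experiment's conditions: post-exclusion group sizes of
    13 (phase) and 16 (contrast), mean threshold improvements in degrees at
    the training and far-transfer locations as reported for the human
    cohort, and transfer-LI correlations of 0.71 (phase) / 0.09 (contrast).
    The C-transfer improvement is not printed in the source results and is
    interpolated between the other two.  Improvements are converted to mean
    LIs by dividing by the expected pre-threshold.
    """

    n_phase: int = 13
    n_contrast: int = 16
    pre_median_deg: float = 3.0
    pre_log_sd: float = 0.15
    improvement_deg: dict = field(
        default_factory=lambda: {
            ("phase", "training"): 1.53,
            ("contrast", "training"): 1.40,
            ("phase", "C-transfer"): 1.55,
            ("contrast", "C-transfer"): 1.45,
            ("phase", "F-transfer"): 1.99,
            ("contrast", "F-transfer"): 1.31,
        }
    )
    li_sd_training: float = 0.10
    li_sd_transfer: float = 0.14
    transfer_rho: dict = field(
        default_factory=lambda: {"phase": 0.71, "contrast": 0.09}
    )
    observer_beta: float = 3.5
    observer_lapse: float = 0.02
    blocks_per_location: int = 3
    block_config: BlockConfig = BlockConfig()
    seed: int = 0

    def __post_init__(self) -> None:
        for rho in self.transfer_rho.values():
            if not -1.0 < rho < 1.0:
                raise ValueError("transfer rho must be in (-1, 1)")
        if self.pre_median_deg <= 0:
            raise ValueError("pre_median_deg must be positive")

    def mean_li(self, group: str, location: str) -> float:
        expected_pre = self.pre_median_deg * math.exp(self.pre_log_sd**2 / 2.0)
        return -self.improvement_deg[(group, location)] / expected_pre


@dataclass
class CohortResult:
    trials: pd.DataFrame | None
    blocks: pd.DataFrame
    truth: pd.DataFrame
    spec: CohortSpec


def _truncated(draw, lo: float, hi: float, rng, max_tries: int = 200):
    """Redraw until inside (lo, hi); warn-and-clip after bounded retries."""
    for _ in range(max_tries):
        v = draw(rng)
        if np.all((np.asarray(v) > lo) & (np.asarray(v) < hi)):
            return v
    import warnings

    warnings.warn("truncation retries exhausted; clipping draw")
    return np.clip(draw(rng), lo + 1e-6, hi - 1e-6)


def simulate_cohort(
    spec: CohortSpec,
    rng: np.random.Generator | None = None,
    keep_trials: bool = True,
    measure: str = "staircase",
    include_training: bool = False,
) -> CohortResult:
    """Simulate one cohort's pre/post threshold measurements.

    ``measure='staircase'`` runs every block through the interleaved
    staircase engine against the subject's observer; ``'direct'`` returns
    the true thresholds as block thresholds (a fast noise-free path for
    calibration studies).  ``include_training`` additionally simulates the
    four 1000-trial training sessions (five blocks each) with a smooth
    power-law threshold decay between pre and post, for learning-curve
    analyses.
    """
    if measure not in ("staircase", "direct"):
        raise ValueError("measure must be 'staircase' or 'direct'")
    if rng is None:
        rng = np.random.default_rng(spec.seed)

    groups = [("phase", spec.n_phase), ("contrast", spec.n_contrast)]
    subjects = []
    k = 0
    for gname, n in groups:
        for i in range(n):
            subjects.append(
                {
                    "subject": f"S{k:02d}",
                    "randomization": gname,
                    "training_location": "UVF" if i % 2 == 0 else "LVF",
                }
            )
            k += 1

    block_rows: list[dict] = []
    trial_rows: list[dict] = []
    truth_rows: list[dict] = []
    cfg = spec.block_config

    for sub in subjects:
        g = sub["randomization"]
        scheme = RandomizationScheme(kind=g)
        pre = {
            loc: spec.pre_median_deg * math.exp(spec.pre_log_sd * rng.standard_normal())
            for loc in LOCATIONS
        }
        li_train = _truncated(
            lambda r: spec.mean_li(g, "training") + spec.li_sd_training * r.standard_normal(),
            -0.95,
            0.5,
            rng,
        )
        rho = spec.transfer_rho[g]
        cov = spec.li_sd_transfer**2 * np.array([[1.0, rho], [rho, 1.0]])
        mean = [spec.mean_li(g, "C-transfer"), spec.mean_li(g, "F-transfer")]
        li_c, li_f = _truncated(
            lambda r: r.multivariate_normal(mean, cov, method="cholesky"),
            -0.95,
            0.5,
            rng,
        )
        li = {"training": float(li_train), "C-transfer": float(li_c), "F-transfer": float(li_f)}
        post = {loc: pre[loc] * (1.0 + li[loc]) for loc in LOCATIONS}
        truth_rows.append(
            {
                **sub,
                **{f"pre_{loc}": pre[loc] for loc in LOCATIONS},
                **{f"post_{loc}": post[loc] for loc in LOCATIONS},
                **{f"li_{loc}": li[loc] for loc in LOCATIONS},
            }
        )

        for time, thresholds in (("pre", pre), ("post", post)):
            session_index = 0 if time == "pre" else 5
            for loc in LOCATIONS:
                alpha = thresholds[loc]
                model = ObserverModel(
                    alpha_deg=alpha, beta=spec.observer_beta, lapse=spec.observer_lapse
                )
                obs = make_observer(model)
                for b in range(spec.blocks_per_location):
                    if measure == "direct":
                        est_thr, est_valid, n_rev = alpha, True, cfg.reversals_to_stop
                    else:
                        trials, states = run_block(
                            obs,
                            cfg,
                            scheme=scheme if keep_trials else None,
                            rng=rng,
                        )
                        est = block_threshold(states, cfg)
                        est_thr, est_valid, n_rev = (
                            est.threshold_deg,
                            est.valid,
                            est.n_reversals_used,
                        )
                        if keep_trials:
                            for tr in trials:
                                trial_rows.append(
                                    {
                                        "subject_id": sub["subject"],
                                        "randomization": g,
                                        "training_location": sub["training_location"],
                                        "session_type": time,
                                        "session_index": session_index,
                                        "block": b,
                                        "trial": tr["trial"],
                                        "location": loc,
                                        "reference_ori_deg": 45.0,
                                        "offset_deg": tr["offset_deg"],
                                        "phase_deg": tr["phase_deg"],
                                        "contrast": tr["contrast"],
                                        "staircase_id": tr["staircase_id"],
                                        "response": tr["response"],
                                        "correct": tr["correct"],
                                        "aborted": 0,
                                    }
                                )
                    block_rows.append(
                        {
                            "subject": sub["subject"],
                            "randomization": g,
                            "training_location": sub["training_location"],
                            "time": time,
                            "location": loc,
                            "block": b,
                            "threshold": est_thr,
                            "valid": est_valid,
                            "n_reversals_used": n_rev,
                        }
                    )

        if include_training:
            _simulate_training(sub, pre, post, spec, rng, block_rows, trial_rows, keep_trials)

    trials_df = pd.DataFrame(trial_rows) if keep_trials else None
    return CohortResult(
        trials=trials_df,
        blocks=pd.DataFrame(block_rows),
        truth=pd.DataFrame(truth_rows),
        spec=spec,
    )


def _simulate_training(sub, pre, post, spec, rng, block_rows, trial_rows, keep_trials):
    """Four 5-block training sessions with power-law threshold decay."""
    g = sub["randomization"]
    scheme = RandomizationScheme(kind=g)
    cfg = spec.block_config
    t0, t1 = pre["training"], post["training"]
    n_blocks = 20
    # alpha(b) = a * b^-beta + c through (1, t0) and (20, t1)
    beta_lc = 0.6
    c = max(t1 - 0.05 * (t0 - t1), 1e-3)
    a = (t0 - c) / 1.0
    for session in range(1, 5):
        for b in range(5):
            bi = (session - 1) * 5 + b + 1
            alpha = max(a * bi ** (-beta_lc) + c, 0.05)
            model = ObserverModel(
                alpha_deg=alpha, beta=spec.observer_beta, lapse=spec.observer_lapse
            )
            trials, states = run_block(
                make_observer(model), cfg, scheme=scheme if keep_trials else None, rng=rng
            )
            est = block_threshold(states, cfg)
            block_rows.append(
                {
                    "subject": sub["subject"],
                    "randomization": g,
                    "training_location": sub["training_location"],
                    "time": f"train{session}",
                    "location": "training",
                    "block": bi,
                    "threshold": est.threshold_deg,
                    "valid": est.valid,
                    "n_reversals_used": est.n_reversals_used,
                }
            )
            if keep_trials:
                for tr in trials:
                    trial_rows.append(
                        {
                            "subject_id": sub["subject"],
                            "randomization": g,
                            "training_location": sub["training_location"],
                            "session_type": "train",
                            "session_index": session,
                            "block": bi,
                            "trial": tr["trial"],
                            "location": "training",
                            "reference_ori_deg": 45.0,
                            "offset_deg": tr["offset_deg"],
                            "phase_deg": tr["phase_deg"],
                            "contrast": tr["contrast"],
                            "staircase_id": tr["staircase_id"],
                            "response": tr["response"],
                            "correct": tr["correct"],
                            "aborted": 0,
                        }
                    )


def simulate_null_table(
    n_subjects: int = 24,
    blocks: int = 1,
    subject_sd: float = 0.5,
    noise_sd: float = 1.0,
    baseline: float = 10.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """A no-effect cohort table with a true random subject intercept.

    Thresholds are normal around a positive ``baseline`` (additive subject
    intercept + residual noise, no fixed effects); subjects are assigned
    round-robin to the four between-subject groups.  Used for ART
    type-I-error calibration.
    """
    if rng is None:
        rng = np.random.default_rng()
    rows = []
    between = [("phase", "UVF"), ("phase", "LVF"), ("contrast", "UVF"), ("contrast", "LVF")]
    subj_eff = subject_sd * rng.standard_normal(n_subjects)
    for s in range(n_subjects):
        rnd, tl = between[s % 4]
        for time in ("pre", "post"):
            for loc in LOCATIONS:
                for b in range(blocks):
                    rows.append(
                        {
                            "subject": f"S{s:02d}",
                            "randomization": rnd,
                            "training_location": tl,
                            "time": time,
                            "location": loc,
                            "block": b,
                            "threshold": float(
                                baseline + subj_eff[s] + noise_sd * rng.standard_normal()
                            ),
                            "valid": True,
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# eye traces


@dataclass(frozen=True)
class TraceSpec:
    """Generative model of one session's 1000-Hz gaze traces.

    Drift is a 2-D random walk (``drift_step_sd`` dva per sample) plus white
    measurement noise (``noise_sd`` dva).  Microsaccade onsets are Poisson
    with ``ms_rate_hz``; amplitudes are log-normal truncated to
    ``amp_range``; peak velocity is ``main_seq_gain * amplitude`` times a
    (1 + noise) factor, and the displacement follows a minimum-jerk profile
    (duration = 1.875 * amplitude / peak velocity).  Blinks knock out the
    validity channel.
    """

    n_trials: int = 100
    duration_ms: int = 1800
    drift_step_sd: float = 0.001
    noise_sd: float = 0.005
    ms_rate_hz: float = 1.0
    amp_median_dva: float = 0.4
    amp_log_sd: float = 0.35
    amp_range: tuple[float, float] = (0.05, 0.95)
    main_seq_gain: float = 100.0
    main_seq_noise: float = 0.10
    blink_prob: float = 0.10
    blink_duration_ms: tuple[int, int] = (80, 200)
    ref_onset_ms: int = 400
    stim_duration_ms: int = 92
    isi_ms: int = 600
    seed: int = 0

    def __post_init__(self) -> None:
        if self.drift_step_sd < 0 or self.noise_sd < 0 or self.ms_rate_hz < 0:
            raise ValueError("SDs and rates must be nonnegative")
        lo, hi = self.amp_range
        if not 0 < lo < hi < 1.0:
            raise ValueError("amp_range must be inside (0, 1)")


def _min_jerk_profile(n: int) -> np.ndarray:
    tau = np.linspace(0.0, 1.0, n)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def simulate_trace(
    spec: TraceSpec, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate traces, event markers, and the ground-truth event list.

    Returns ``(trace, markers, truth)``: ``trace`` has columns
    ``trial_id, t_ms, x_dva, y_dva, valid``; ``markers`` carries the
    reference/test windows and fixation point; ``truth`` lists the injected
    microsaccades (onset, offset, amplitude, peak velocity).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.duration_ms
    ref_on = spec.ref_onset_ms
    ref_off = ref_on + spec.stim_duration_ms
    test_on = ref_off + spec.isi_ms
    test_off = test_on + spec.stim_duration_ms

    traces = []
    markers = []
    truth = []
    for trial in range(spec.n_trials):
        t = np.arange(n)
        x = np.cumsum(spec.drift_step_sd * rng.standard_normal(n))
        y = np.cumsum(spec.drift_step_sd * rng.standard_normal(n))
        valid = np.ones(n, dtype=bool)

        blink_iv = None
        if rng.random() < spec.blink_prob:
            dur = int(rng.integers(*spec.blink_duration_ms))
            start = int(rng.integers(50, n - dur - 50))
            valid[start : start + dur] = False
            blink_iv = (start, start + dur - 1)

        n_ms = rng.poisson(spec.ms_rate_hz * n / 1000.0)
        onsets: list[int] = []
        for _ in range(n_ms):
            for _try in range(50):
                amp = spec.amp_median_dva * math.exp(
                    spec.amp_log_sd * rng.standard_normal()
                )
                if not spec.amp_range[0] <= amp <= spec.amp_range[1]:
                    continue
                vpeak = spec.main_seq_gain * amp * (
                    1.0 + spec.main_seq_noise * rng.standard_normal()
                )
                if vpeak <= 0:
                    continue
                dur = int(round(1.875 * amp / vpeak * 1000.0))
                dur = max(dur, 8)
                onset = int(rng.integers(60, n - dur - 60))
                # keep events clear of each other and of any blink margin
                if any(abs(onset - o) < dur + 50 for o in onsets):
                    continue
                if blink_iv is not None and not (
                    onset + dur < blink_iv[0] - 160 or onset > blink_iv[1] + 210
                ):
                    continue
                theta = rng.uniform(0.0, 2.0 * np.pi)
                prof = amp * _min_jerk_profile(dur + 1)
                x[onset : onset + dur + 1] += np.cos(theta) * prof
                x[onset + dur + 1 :] += np.cos(theta) * amp
                y[onset : onset + dur + 1] += np.sin(theta) * prof
                y[onset + dur + 1 :] += np.sin(theta) * amp
                onsets.append(onset)
                truth.append(
                    {
                        "trial_id": trial,
                        "onset_ms": onset,
                        "offset_ms": onset + dur,
                        "amplitude_dva": amp,
                        "peak_velocity_dva_s": 1.875 * amp / (dur / 1000.0),
                    }
                )
                break

        x = x + spec.noise_sd * rng.standard_normal(n)
        y = y + spec.noise_sd * rng.standard_normal(n)
        traces.append(
            pd.DataFrame(
                {
                    "trial_id": trial,
                    "t_ms": t,
                    "x_dva": x,
                    "y_dva": y,
                    "valid": valid,
                }
            )
        )
        markers.append(
            {
                "trial_id": trial,
                "ref_onset_ms": ref_on,
                "ref_offset_ms": ref_off,
                "test_onset_ms": test_on,
                "test_offset_ms": test_off,
                "fix_x_dva": 0.0,
                "fix_y_dva": 0.0,
            }
        )
    truth_df = pd.DataFrame(
        truth,
        columns=["trial_id", "onset_ms", "offset_ms", "amplitude_dva", "peak_velocity_dva_s"],
    )
    return pd.concat(traces, ignore_index=True), pd.DataFrame(markers), truth_df


# ---------------------------------------------------------------------------
# presets


def cohort_preset(name: str, seed: int = 0) -> CohortSpec:
    """Named study conditions: ``paper-like``, ``null``, ``high-noise``."""
    if name == "paper-like":
        return CohortSpec(seed=seed)
    if name == "null":
        zero = {k: 0.0 for k in CohortSpec().improvement_deg}
        return CohortSpec(
            improvement_deg=zero,
            transfer_rho={"phase": 0.0, "contrast": 0.0},
            seed=seed,
        )
    if name == "high-noise":
        return CohortSpec(
            li_sd_training=0.24,
            li_sd_transfer=0.30,
            pre_log_sd=0.35,
            observer_lapse=0.05,
            seed=seed,
        )
    raise ValueError(f"unknown preset {name!r}")


def trace_preset(name: str, seed: int = 0) -> TraceSpec:
    """Named trace conditions: ``default``, ``null``, ``high-noise``."""
    if name in ("default", "paper-like"):
        return TraceSpec(seed=seed)
    if name == "null":
        return TraceSpec(ms_rate_hz=0.0, blink_prob=0.0, seed=seed)
    if name == "high-noise":
        return TraceSpec(noise_sd=0.02, drift_step_sd=0.002, seed=seed)
    raise ValueError(f"unknown preset {name!r}")
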