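"""Transformed up-down (3-down-1-up) staircase engine.

The orientation-offset level is multiplied by 10**(-step) after three
consecutive correct responses and by 10**(+step) after any error
(step = 0.05 log10 units).  This rule converges on the stimulus level at
which the probability of a correct response is 0.5**(1/3) ~ 0.794.

A block interleaves two staircases (starting at 1 and 3 deg offsets) by
seeded uniform random choice among the unfinished staircases; it ends when
every staircase has accumulated its target number of reversals or when the
block-wide trial cap is reached.  The block threshold discards the first
four reversals of each staircase and averages the following six; staircases
(and blocks) with too few reversals are flagged invalid rather than raised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .stimulus import GaborSpec, RandomizationScheme, sample_trial_stimulus

__all__ = [
    "StaircaseState",
    "BlockConfig",
    "ThresholdEstimate",
    "update_staircase",
    "run_block",
    "block_threshold",
    "replay_staircase",
]

# Observer contract: callable(signed offset in deg, rng) -> bool (correct?)
Observer = Callable[[float, np.random.Generator], bool]


@dataclass
class StaircaseState:
    """One transformed up-down track.

    ``history`` holds one ``(level, correct, moved)`` record per trial, where
    ``moved`` is ``'up'``, ``'down'`` or ``None``.  ``reversal_levels`` holds
    the level *at* each reversal-triggering trial (pre-move), with the trial
    index recorded alongside in ``reversal_trials`` so reversals can be pooled
    across interleaved staircases in time order.
    """

    level_deg: float
    step_log10: float = 0.05
    consecutive_correct: int = 0
    last_move: str = "none"  # none | down | up
    history: list = field(default_factory=list)
    reversal_levels: list = field(default_factory=list)
    reversal_trials: list = field(default_factory=list)
    n_trials: int = 0

    def __post_init__(self) -> None:
        if self.level_deg <= 0:
            raise ValueError("level_deg must be positive")
        if self.step_log10 <= 0:
            raise ValueError("step_log10 must be positive")


@dataclass(frozen=True)
class BlockConfig:
    start_levels_deg: tuple[float, ...] = (1.0, 3.0)
    step_log10: float = 0.05
    max_trials: int = 200
    reversals_to_stop: int = 10
    discard_reversals: int = 4
    average_reversals: int = 6
    pool_staircases: bool = False

    def __post_init__(self) -> None:
        if self.discard_reversals + self.average_reversals != self.reversals_to_stop:
            raise ValueError(
                "discard_reversals + average_reversals must equal reversals_to_stop"
            )
        if any(l <= 0 for l in self.start_levels_deg):
            raise ValueError("start levels must be positive")
        if self.max_trials < 1:
            raise ValueError("max_trials must be >= 1")


@dataclass(frozen=True)
class ThresholdEstimate:
    """Per-block threshold from reversal averaging."""

    threshold_deg: float  # nan when invalid
    n_reversals_used: int
    valid: bool
    source: str = ""

    def __post_init__(self) -> None:
        if self.valid and not self.threshold_deg > 0:
            raise ValueError("valid estimate requires a positive threshold")


def update_staircase(state: StaircaseState, correct: bool) -> StaircaseState:
    """Apply one trial outcome to ``state`` (mutates and returns it).

    An error multiplies the level by 10**step and resets the correct counter;
    the third consecutive correct response divides it by the same factor.  A
    reversal is logged when the move direction differs from the previous move.
    """
    level = state.level_deg
    moved = None
    if correct:
        cc = state.consecutive_correct + 1
        if cc >= 3:
            new_level = level * 10.0 ** (-state.step_log10)
            moved = "down"
            cc = 0
        else:
            new_level = level
    else:
        new_level = level * 10.0**state.step_log10
        moved = "up"
        cc = 0
    if moved is not None:
        if state.last_move in ("up", "down") and moved != state.last_move:
            state.reversal_levels.append(level)
            state.reversal_trials.append(state.n_trials)
        state.last_move = moved
    state.history.append((level, bool(correct), moved))
    state.level_deg = new_level
    state.consecutive_correct = cc
    state.n_trials += 1
    return state


def _finished(state: StaircaseState, config: BlockConfig) -> bool:
    return len(state.reversal_levels) >= config.reversals_to_stop


def run_block(
    observer: Observer,
    config: BlockConfig = BlockConfig(),
    scheme: RandomizationScheme | None = None,
    rng: np.random.Generator | None = None,
    base: GaborSpec | None = None,
) -> tuple[list[dict], list[StaircaseState]]:
    """Run one block of interleaved staircases against ``observer``.

    Each trial picks uniformly among unfinished staircases, draws a uniform
    random sign for the offset (clockwise vs counterclockwise of the 45 deg
    reference), optionally samples the task-irrelevant dimension via
    ``scheme``, and queries the observer with the signed offset.  Returns the
    trial records and the final per-staircase states.
    """
    if rng is None:
        rng = np.random.default_rng()
    if base is None:
        base = GaborSpec()
    states = [
        StaircaseState(level_deg=l, step_log10=config.step_log10)
        for l in config.start_levels_deg
    ]
    trials: list[dict] = []
    total = 0
    while total < config.max_trials:
        active = [i for i, s in enumerate(states) if not _finished(s, config)]
        if not active:
            break
        idx = active[int(rng.integers(len(active)))]
        st = states[idx]
        level = st.level_deg
        sign = 1 if rng.random() < 0.5 else -1
        if scheme is not None:
            stim = sample_trial_stimulus(scheme, base, rng)
        else:
            stim = base
        correct = observer(sign * level, rng)
        if not isinstance(correct, (bool, np.bool_)):
            raise TypeError(
                f"observer must return a boolean, got {type(correct).__name__}"
            )
        update_staircase(st, bool(correct))
        trials.append(
            {
                "trial": total,
                "staircase_id": idx,
                "level_deg": level,
                "offset_deg": sign * level,
                "phase_deg": stim.phase_deg,
                "contrast": stim.contrast,
                "response": "cw" if bool(correct) == (sign > 0) else "ccw",
                "correct": int(correct),
            }
        )
        total += 1
    return trials, states


def _staircase_threshold(
    reversals: Sequence[float], config: BlockConfig
) -> tuple[float, int, bool]:
    if len(reversals) < config.reversals_to_stop:
        return float("nan"), 0, False
    use = reversals[
        config.discard_reversals : config.discard_reversals + config.average_reversals
    ]
    return float(np.mean(use)), len(use), True


def block_threshold(
    states: Sequence[StaircaseState], config: BlockConfig = BlockConfig()
) -> ThresholdEstimate:
    """Reversal-averaged threshold of one block.

    Default: per staircase with >= ``reversals_to_stop`` reversals, average
    reversals 5..10 (extras beyond 10 are ignored so the estimator is
    identical across blocks); the block estimate is the mean of the valid
    per-staircase thresholds.  With ``pool_staircases`` the reversals of all
    staircases are merged in trial order before discarding/averaging.
    """
    if config.pool_staircases:
        pooled = sorted(
            (t, l)
            for s in states
            for t, l in zip(s.reversal_trials, s.reversal_levels)
        )
        thr, n_used, valid = _staircase_threshold([l for _, l in pooled], config)
        return ThresholdEstimate(thr, n_used, valid, source="pooled")
    per = [_staircase_threshold(s.reversal_levels, config) for s in states]
    valid_thresholds = [t for t, _, ok in per if ok]
    n_used = sum(n for _, n, ok in per if ok)
    if not valid_thresholds:
        return ThresholdEstimate(float("nan"), 0, False, source="per-staircase")
    return ThresholdEstimate(
        float(np.mean(valid_thresholds)), n_used, True, source="per-staircase"
    )


def replay_staircase(
    levels: Sequence[float], corrects: Sequence[int], step_log10: float = 0.05
) -> StaircaseState:
    """Reconstruct a staircase state from a logged (level, correct) sequence.

    Used to recompute reversals and thresholds from trial-log CSVs.  The
    logged levels are checked against the replayed track to catch corrupted
    or reordered logs.
    """
    if len(levels) != len(corrects) or len(levels) == 0:
        raise ValueError("levels and corrects must be equal-length and non-empty")
    state = StaircaseState(level_deg=float(levels[0]), step_log10=step_log10)
    for i, (lvl, cor) in enumerate(zip(levels, corrects)):
        if not np.isclose(state.level_deg, lvl, rtol=1e-6):
            raise ValueError(
                f"logged level {lvl} at trial {i} does not match replayed "
                f"level {state.level_deg:.6g}"
            )
        update_staircase(state, bool(cor))
    return state
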