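"""Deterministic construction of the task designs.

Four trial structures are covered:

* the Pavlovian conditioning task (80 trials; five fractal cues mapped
  one-to-one onto monetary reward values −2..+2 CHF, cue side randomized),
* the forced-choice learning check (each of the 10 unordered cue pairings
  presented 3 times, 30 trials),
* the in-lab Go/NoGo task (4 blocks × 200 trials; 120 Go + 80 NoGo per
  block, i.e. 60% Go),
* the gamified Go/NoGo training staircase: the reaction-time threshold
  (RTT) tightens by one difficulty level after every 6 successful trials.

All builders are pure functions of their seed: the same seed yields an
identical schedule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CS_VALUES_CHF",
    "RTT_TABLE_S",
    "RttState",
    "adaptive_rtt",
    "advance_rtt",
    "build_forced_choice_schedule",
    "build_gng_schedule",
    "build_pavlovian_schedule",
    "cs_value_map",
    "rtt_for_level",
]

#: Reward values (CHF) associated with the five conditioned stimuli.
CS_VALUES_CHF = (-2, -1, 0, 1, 2)

#: Training staircase: reaction-time threshold (s) per difficulty level 1..18.
RTT_TABLE_S = (1.1, 1.0, 0.9, 0.8, 0.725, 0.675, 0.625, 0.575, 0.55,
               0.525, 0.5, 0.475, 0.4525, 0.43, 0.407, 0.387, 0.36, 0.33)

MAX_LEVEL = len(RTT_TABLE_S)

#: Number of consecutive successful trials needed to advance one level.
SUCCESSES_PER_LEVEL = 6


def cs_value_map(seed: int) -> dict[str, int]:
    """Seed-deterministic bijection of the five cue identities onto CHF values."""
    rng = np.random.default_rng(seed)
    ids = [f"cs{i + 1}" for i in range(len(CS_VALUES_CHF))]
    values = rng.permutation(CS_VALUES_CHF)
    return {c: int(v) for c, v in zip(ids, values)}


def build_pavlovian_schedule(seed: int, n_trials: int = 80) -> pd.DataFrame:
    """Build the Pavlovian conditioning schedule.

    Each of the five cues appears equally often (n_trials must divide by 5);
    trial order is shuffled and the cue side is an independent fair coin per
    trial. Columns: ``trial_index, cs_id, cs_value, cs_side``.
    """
    if n_trials % len(CS_VALUES_CHF):
        raise ValueError("n_trials must be a multiple of the number of cues")
    rng = np.random.default_rng(seed)
    mapping = cs_value_map(seed)
    ids = np.repeat(list(mapping), n_trials // len(mapping))
    rng.shuffle(ids)
    sides = rng.choice(["left", "right"], size=n_trials)
    return pd.DataFrame({
        "trial_index": np.arange(n_trials),
        "cs_id": ids,
        "cs_value": [mapping[c] for c in ids],
        "cs_side": sides,
    })


def build_forced_choice_schedule(seed: int, cs_values: dict[str, int] | None = None,
                                 repetitions: int = 3) -> pd.DataFrame:
    """Build the forced-choice learning-check schedule.

    Every unordered pairing of distinct cues appears ``repetitions`` times
    (10 pairings × 3 = 30 trials); presentation order within a pair and the
    trial order are randomized by the seed. ``correct`` marks which of the
    two presented cues carries the higher reward value.
    """
    rng = np.random.default_rng(seed)
    if cs_values is None:
        cs_values = cs_value_map(seed)
    ids = list(cs_values)
    pairs = [(a, b) for i, a in enumerate(ids) for b in ids[i + 1:]]
    rows = []
    for a, b in pairs * repetitions:
        first, second = (a, b) if rng.random() < 0.5 else (b, a)
        correct = "first" if cs_values[first] > cs_values[second] else "second"
        rows.append((first, second, cs_values[first], cs_values[second], correct))
    order = rng.permutation(len(rows))
    df = pd.DataFrame(
        [rows[i] for i in order],
        columns=["first_cs", "second_cs", "first_value", "second_value", "correct"],
    )
    df.insert(0, "trial_index", np.arange(len(df)))
    return df


def build_gng_schedule(seed: int, blocks: int = 4, go_per_block: int = 120,
                       nogo_per_block: int = 80,
                       go_items: list[str] | None = None,
                       nogo_items: list[str] | None = None) -> pd.DataFrame:
    """Build the Go/NoGo schedule: ``blocks`` blocks with exact per-block counts.

    Items are cycled through their pool so presentations stay balanced, then
    the within-block order is shuffled. Defaults give the in-lab task
    (4 × 200 trials, 60% Go); ``go_per_block=7, nogo_per_block=3`` per ten
    trials reproduces the 70/30 training ratio.
    """
    if go_items is None:
        go_items = [f"go_item{i + 1}" for i in range(24)]
    if nogo_items is None:
        nogo_items = [f"nogo_item{i + 1}" for i in range(24)]
    if go_per_block > 0 and not go_items:
        raise ValueError("empty Go item pool")
    if nogo_per_block > 0 and not nogo_items:
        raise ValueError("empty NoGo item pool")
    rng = np.random.default_rng(seed)
    frames = []
    for b in range(1, blocks + 1):
        go = [("Go", go_items[i % len(go_items)]) for i in range(go_per_block)]
        nogo = [("NoGo", nogo_items[i % len(nogo_items)]) for i in range(nogo_per_block)]
        trials = go + nogo
        order = rng.permutation(len(trials))
        frames.append(pd.DataFrame(
            [(b, trials[i][0], trials[i][1]) for i in order],
            columns=["block", "trial_type", "item_id"],
        ))
    df = pd.concat(frames, ignore_index=True)
    df.insert(1, "trial_index", np.arange(len(df)))
    return df


def rtt_for_level(level: int) -> float:
    """Reaction-time threshold (s) at a training difficulty level (1..18)."""
    if not 1 <= level <= MAX_LEVEL:
        raise ValueError(f"level must be in 1..{MAX_LEVEL}, got {level}")
    return RTT_TABLE_S[level - 1]


@dataclass(frozen=True)
class RttState:
    """Staircase state of the gamified training."""

    level: int = 1
    consecutive_successes: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.level <= MAX_LEVEL:
            raise ValueError("level out of range")
        if self.consecutive_successes < 0:
            raise ValueError("negative success counter")

    @property
    def rtt_seconds(self) -> float:
        return rtt_for_level(self.level)


def advance_rtt(state: RttState, trial_success: bool) -> RttState:
    """Advance the training staircase by one trial.

    A success increments the counter; the sixth consecutive success raises
    the difficulty level (capped at 18) and resets the counter. A failure
    resets the counter and leaves the level unchanged.
    """
    if not trial_success:
        return RttState(state.level, 0)
    count = state.consecutive_successes + 1
    if count >= SUCCESSES_PER_LEVEL:
        return RttState(min(state.level + 1, MAX_LEVEL), 0)
    return RttState(state.level, count)


def adaptive_rtt(block_rts) -> float:
    """In-lab adaptive deadline: 1.10 × median of the current block's RTs (ms).

    The median of an even-length block is the midpoint of the central pair.
    """
    rts = np.asarray(block_rts, dtype=float)
    if rts.size == 0:
        raise ValueError("adaptive RTT needs at least one reaction time")
    return 1.10 * float(np.median(rts))
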