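"""Visual-detection task protocols.

The experiment this package analyses is a rapid serial picture-viewing task:
grayscale pictures of a few categories (spatial scenes, everyday objects,
faces) are shown for 300 ms every 1,100 ms in blocks of five, with a 3-s pause
between blocks.  A rare fourth category (fruits/vegetables) is the behavioural
target: the subject presses a key when one appears, and those trials are
excluded from the neural analysis.  Each unique picture is repeated a fixed
number of times in a pseudorandom order with no immediate repetition of the
same picture.

:func:`build_protocol` turns a :class:`ProtocolSpec` into an events table
(one row per stimulus presentation) suitable for the simulator and for the
epoching stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CategorySpec",
    "ProtocolSpec",
    "build_protocol",
    "default_protocol",
]


@dataclass(frozen=True)
class CategorySpec:
    """One stimulus category: ``n_unique`` pictures each shown ``n_repeats`` times."""

    name: str
    n_unique: int
    n_repeats: int

    def __post_init__(self) -> None:
        if self.n_unique < 1:
            raise ValueError(f"category {self.name!r}: n_unique must be >= 1")
        if self.n_repeats < 1:
            raise ValueError(f"category {self.name!r}: n_repeats must be >= 1")


@dataclass(frozen=True)
class ProtocolSpec:
    """Stimulation protocol parameters.

    Parameters
    ----------
    categories
        Stimulus categories.  The default study protocol has scenes, objects
        and faces (100 unique pictures, 2 repeats each) plus a fruit/vegetable
        target category (25 unique, 2 repeats), 650 presentations in total.
    target_category
        Name of the oddball category requiring a keypress, or ``None``.
    block_size
        Stimuli per block; blocks are separated by ``pause_duration``.
    soa
        Stimulus-onset asynchrony inside a block, seconds.
    stim_duration
        Picture display time, seconds.  Must be < ``soa``.
    pause_duration
        Extra rest between blocks, seconds.
    miss_rate, false_alarm_rate
        Behavioural error rates used when simulating keypresses on target and
        non-target trials.
    seed
        Seed for the pseudorandom stimulus order and simulated behaviour.
    """

    categories: tuple[CategorySpec, ...]
    target_category: str | None = None
    block_size: int = 5
    soa: float = 1.1
    stim_duration: float = 0.3
    pause_duration: float = 3.0
    miss_rate: float = 0.053
    false_alarm_rate: float = 0.008
    seed: int = 0

    def __post_init__(self) -> None:
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")
        if not (self.soa > self.stim_duration > 0):
            raise ValueError("require soa > stim_duration > 0")
        if self.target_category is not None and self.target_category not in {
            c.name for c in self.categories
        }:
            raise ValueError(f"target_category {self.target_category!r} not in categories")

    @property
    def n_events(self) -> int:
        return sum(c.n_unique * c.n_repeats for c in self.categories)


def default_protocol(seed: int = 0) -> ProtocolSpec:
    """The study protocol: 3 x (100 pictures x 2) plus a 25 x 2 target category."""
    return ProtocolSpec(
        categories=(
            CategorySpec("scene", 100, 2),
            CategorySpec("object", 100, 2),
            CategorySpec("face", 100, 2),
            CategorySpec("fruit", 25, 2),
        ),
        target_category="fruit",
        seed=seed,
    )


def _order_without_immediate_repeats(
    items: list[tuple[str, int]], rng: np.random.Generator
) -> list[tuple[str, int]]:
    """Pseudorandom order of ``items`` with no two equal items adjacent.

    Feasible iff the most frequent item occurs at most ceil(n/2) times.
    Random shuffles are repaired by swapping offending positions; a bounded
    number of repair sweeps keeps the procedure deterministic per rng state.
    """
    n = len(items)
    counts: dict[tuple[str, int], int] = {}
    for it in items:
        counts[it] = counts.get(it, 0) + 1
    if max(counts.values()) > (n + 1) // 2:
        raise ValueError(
            "no ordering without immediate repetition exists: one picture "
            f"accounts for {max(counts.values())} of {n} presentations"
        )
    seq = list(items)
    for _attempt in range(200):
        perm = rng.permutation(n)
        seq = [items[i] for i in perm]
        for _sweep in range(50):
            bad = [i for i in range(1, n) if seq[i] == seq[i - 1]]
            if not bad:
                return seq
            for i in bad:
                if seq[i] != seq[i - 1]:
                    continue
                choices = rng.permutation(n)
                for j in choices:
                    if j in (i, i - 1):
                        continue
                    # swapping seq[i] and seq[j] must not create new adjacencies
                    ok_j = (j == 0 or seq[j - 1] != seq[i]) and (
                        j == n - 1 or seq[j + 1] != seq[i]
                    )
                    ok_i = seq[j] != seq[i - 1] and (i == n - 1 or seq[j] != seq[i + 1])
                    if ok_i and ok_j and seq[j] != seq[i]:
                        seq[i], seq[j] = seq[j], seq[i]
                        break
    raise ValueError("could not construct an ordering without immediate repeats")


def build_protocol(spec: ProtocolSpec) -> pd.DataFrame:
    """Generate the events table for a protocol.

    Returns a DataFrame with one row per presentation and columns
    ``onset`` (s), ``duration`` (s), ``trial_type``, ``picture_id``,
    ``block`` (0-based), ``target`` (bool), ``response`` (bool, keypress) and
    ``rt`` (s, NaN when no keypress).  Onsets start at 0; inside a block the
    inter-onset interval is ``soa`` and each block boundary adds
    ``pause_duration``.
    """
    rng = np.random.default_rng(spec.seed)
    items: list[tuple[str, int]] = []
    for cat in spec.categories:
        for pic in range(cat.n_unique):
            items.extend([(cat.name, pic)] * cat.n_repeats)
    seq = _order_without_immediate_repeats(items, rng)

    n = len(seq)
    idx = np.arange(n)
    block = idx // spec.block_size
    onset = idx * spec.soa + block * spec.pause_duration
    trial_type = np.array([c for c, _ in seq])
    picture_id = np.array([f"{c}_{p:03d}" for c, p in seq])
    target = trial_type == spec.target_category if spec.target_category else np.zeros(n, bool)

    # simulated behaviour: hits on targets (lognormal RT ~ 540 ms median),
    # rare false alarms elsewhere
    response = np.zeros(n, bool)
    rt = np.full(n, np.nan)
    hit = target & (rng.random(n) >= spec.miss_rate)
    fa = ~target & (rng.random(n) < spec.false_alarm_rate)
    response = hit | fa
    rt[response] = rng.lognormal(mean=np.log(0.54), sigma=0.2, size=int(response.sum()))

    return pd.DataFrame(
        {
            "onset": onset,
            "duration": spec.stim_duration,
            "trial_type": trial_type,
            "picture_id": picture_id,
            "block": block,
            "target": target,
            "response": response,
            "rt": rt,
        }
    )
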