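"""Single-trial discriminability of the preferred category (ROC / AUC).

For a selective channel, how well does the single-trial BGA response at a
given latency separate the two categories?  The area under the ROC curve
(AUC) answers this across all magnitude thresholds at once: it equals the
probability that a random preferred-category trial exceeds a random
non-preferred trial, and is computed here from the Mann-Whitney rank-sum
statistic (ties credited 0.5).  The time course of the AUC over all
post-stimulus samples, and its maximum, summarise a channel's discriminative
power; channels responding more to scenes are evaluated for discriminating
scenes from objects, and vice versa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .envelope import EpochSet

__all__ = ["ROCProfile", "auc_mann_whitney", "auc_timecourse"]


@dataclass
class ROCProfile:
    """Per-sample AUC of one channel, preferred category as positive class."""

    auc: np.ndarray  # over post-stimulus samples
    times: np.ndarray  # s
    direction: str  # positive-class category
    max_auc: float
    t_max: float  # s

    @property
    def max_time_ms(self) -> float:
        return self.t_max * 1000.0


def auc_mann_whitney(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC = U / (n_pos * n_neg) with average ranks (ties count 0.5)."""
    pos = np.asarray(pos, float)
    neg = np.asarray(neg, float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes need at least one value")
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def auc_timecourse(
    epochs: EpochSet,
    channel: int,
    direction: str,
    other: str | None = None,
    pair: tuple[str, str] = ("scene", "object"),
) -> ROCProfile:
    """AUC at every post-stimulus sample for one channel.

    ``direction`` is the preferred (positive-class) category; ``other``
    defaults to the remaining member of ``pair``.  The single-trial response
    at a sample is the baseline-corrected % power change at that sample; no
    smoothing is applied and the maximum is taken over the full grid.
    """
    if other is None:
        if direction not in pair:
            raise ValueError(f"direction {direction!r} not in pair {pair}")
        other = pair[1] if direction == pair[0] else pair[0]
    tp = epochs.trials_of(direction, channel)
    tn = epochs.trials_of(other, channel)
    if tp.size == 0 or tn.size == 0:
        raise ValueError("no usable trials for one of the categories")
    post = epochs.post
    a = epochs.data[channel, tp][:, post]
    b = epochs.data[channel, tn][:, post]
    auc = np.array([auc_mann_whitney(a[:, t], b[:, t]) for t in range(a.shape[1])])
    i = int(np.argmax(auc))
    return ROCProfile(
        auc=auc,
        times=epochs.post_times,
        direction=direction,
        max_auc=float(auc[i]),
        t_max=float(epochs.post_times[i]),
    )
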