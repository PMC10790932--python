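"""Channel-wise paired turn vs. no-turn comparison in sensor space.

Per subject and channel, each intersection contributes a pair (mean HbR in
the turn window, mean HbR in the no-turn window). A paired t-test over
intersections and the paired Cohen's d = mean(diff)/SD(diff) quantify the
activation difference per channel. The sign convention is
diff = no_turn - turn, so a positive d means the turn window shows the
larger activation-related HbR decrease. Group maps average the per-subject
t statistics channel-wise and convert back to d (d = t / sqrt(n_pairs) in
the paired design), which attenuates idiosyncratic single-subject effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .features import EpochSet

__all__ = ["EffectMap", "paired_effect", "group_average"]


@dataclass
class EffectMap:
    t: np.ndarray  # per channel
    d: np.ndarray
    n_pairs: int
    channel_indices: np.ndarray
    p: np.ndarray | None = None

    @property
    def n_channels(self) -> int:
        return self.t.size


def paired_effect(epochs: EpochSet, reduction: str = "mean") -> EffectMap:
    """Channel-wise paired t and Cohen's d over intersections.

    ``reduction`` maps each 4-s window to one value per channel: ``mean``
    (default) or ``peak`` (sample of largest magnitude). Channels with zero
    within-pair variance get d = nan (flagged, not an error).
    """
    iids = np.unique(epochs.intersection_ids)
    if iids.size < 2:
        raise ValueError("need >= 2 intersections with both phases")
    if reduction == "mean":
        summary = epochs.samples.mean(axis=-1)  # epochs x channels
    elif reduction == "peak":
        idx = np.abs(epochs.samples).argmax(axis=-1)
        summary = np.take_along_axis(epochs.samples, idx[..., None], axis=-1)[..., 0]
    else:
        raise ValueError("reduction must be 'mean' or 'peak'")

    turn_rows, noturn_rows = [], []
    for iid in iids:
        sel = epochs.intersection_ids == iid
        lab = epochs.labels[sel]
        if not (np.any(lab == 1) and np.any(lab == 0)):
            continue  # incomplete pair (skipped epoch) excluded pairwise
        turn_rows.append(summary[sel][lab == 1][0])
        noturn_rows.append(summary[sel][lab == 0][0])
    turn = np.vstack(turn_rows)
    noturn = np.vstack(noturn_rows)
    if turn.shape[0] < 2:
        raise ValueError("need >= 2 complete turn/no-turn pairs")

    diff = noturn - turn  # positive = larger HbR decrease while turning
    mean = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    n = diff.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        # zero within-pair variance: an exactly null difference is d = 0;
        # a constant nonzero difference has no defined d (flagged as nan)
        d = np.where(sd > 0, mean / sd,
                     np.where(np.abs(mean) < 1e-300, 0.0, np.nan))
        t = d * np.sqrt(n)
    p = 2 * stats.t.sf(np.abs(t), df=n - 1)
    return EffectMap(t=t, d=d, n_pairs=n,
                     channel_indices=epochs.channel_indices, p=p)


def group_average(maps: list[EffectMap]) -> EffectMap:
    """Average subject maps channel-wise over their common channel frame.

    The group t is the mean of subject t values per channel and the group
    d is derived from it via d = t / sqrt(mean n_pairs); the plain mean of
    subject d values is numerically almost identical and can be recovered
    from the inputs.
    """
    if len(maps) < 2:
        raise ValueError("need >= 2 subject maps")
    common = maps[0].channel_indices
    for m in maps[1:]:
        common = np.intersect1d(common, m.channel_indices)
    if common.size == 0:
        raise ValueError("subject maps share no channels")

    t_stack = []
    for m in maps:
        pos = {ch: k for k, ch in enumerate(m.channel_indices)}
        t_stack.append(m.t[[pos[ch] for ch in common]])
    t_mean = np.mean(t_stack, axis=0)
    n_mean = float(np.mean([m.n_pairs for m in maps]))
    d_group = t_mean / np.sqrt(n_mean)
    return EffectMap(t=t_mean, d=d_group, n_pairs=int(round(n_mean)),
                     channel_indices=common)
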