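"""End-to-end trial-level repair workflows.

Two parallel pipelines take a corrupted :class:`~eegrepair.analysis.TrialSet`
(per-trial observed masks set) to a repaired one plus retention bookkeeping:

* completion: every trial epoch is treated as one block and regenerated by
  the low-rank model; lines that violate the completability assumption stay
  corrupted and count against the trial's retention;
* spline: any channel containing a corrupted value is marked bad for the
  whole trial and spherical-spline interpolated from the clean channels
  (the conventional spatial approach); trials with too few clean channels
  are left unrepaired.

Both end with the same 50%-corruption trial-rejection rule, so their
retention counts and downstream ERP/variability statistics are directly
comparable.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .analysis import TrialSet
from .pipeline import ArtifactRepair, RepairConfig, reject_trials
from .recording import Recording
from .spline import Montage, interpolate_bads

__all__ = ["repair_trials_completion", "repair_trials_spline"]


def repair_trials_completion(
    ts: TrialSet, rank: int = 12, trial_reject_frac: float = 0.50
) -> tuple[TrialSet, list[int]]:
    """Complete each trial epoch as a single low-rank block.

    Returns the repaired TrialSet restricted to retained trials and the
    retained trial indices.
    """
    if ts.masks is None:
        return ts, list(range(ts.n_trials))
    n_times = ts.data.shape[2]
    cfg = RepairConfig(block_size=n_times, rank=rank,
                       trial_reject_frac=trial_reject_frac)
    repaired = np.empty_like(ts.data)
    masks = np.empty_like(ts.masks)
    for k in range(ts.n_trials):
        rec = Recording(ts.data[k].copy(), fs=ts.fs, mask=ts.masks[k].copy())
        out = ArtifactRepair(rec, cfg).fit()
        repaired[k] = out.recording.data
        masks[k] = out.recording.mask
    kept = reject_trials(list(masks), trial_reject_frac)
    return (
        replace(ts, data=repaired[kept], masks=masks[kept]),
        kept,
    )


def repair_trials_spline(
    ts: TrialSet,
    montage: Montage,
    trial_reject_frac: float = 0.50,
    min_good: int = 4,
) -> tuple[TrialSet, list[int]]:
    """Spline-interpolate every channel containing corrupted values.

    Trials whose clean-channel count falls below ``min_good`` cannot be
    interpolated and keep their corrupted entries (counting against the
    retention rule).
    """
    if ts.masks is None:
        return ts, list(range(ts.n_trials))
    repaired = ts.data.copy()
    masks = ts.masks.copy()
    for k in range(ts.n_trials):
        bad_ch = np.flatnonzero(~ts.masks[k].all(axis=1))
        if bad_ch.size == 0:
            continue
        n_good = ts.data.shape[1] - bad_ch.size
        if n_good < min_good:
            continue  # irreparable: masks stay corrupted
        rec = Recording(ts.data[k].copy(), fs=ts.fs, mask=ts.masks[k].copy())
        out = interpolate_bads(rec, bad_ch, montage)
        repaired[k] = out.data
        masks[k] = out.mask
    kept = reject_trials(list(masks), trial_reject_frac)
    return (
        replace(ts, data=repaired[kept], masks=masks[kept]),
        kept,
    )
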