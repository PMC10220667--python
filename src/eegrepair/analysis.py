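"""Downstream validation metrics: ERPs and between-trial variability.

Event-related potentials are extracted after the standard preprocessing
chain — baseline correction, average reference, global-field-power (GFP)
normalization — by averaging a channel cluster across stimulus-aligned
trials, with per-timepoint SEM.  Between-trial "event-related variability"
(ERV) is the mean pairwise correlation distance between the across-channel
state vectors of different trials, averaged over a peristimulus window
(default 400-600 ms, around the P400 component); stimulus onset quenches
this variability, and the degree of quenching matures with age.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.stats

__all__ = [
    "TrialSet",
    "preprocess_trials",
    "erp",
    "grand_average",
    "between_trial_variability",
    "zscore_scores",
    "compare_groups",
    "window_contrast_f",
    "peak_latency",
]

_GFP_FLOOR = 1e-12


@dataclass
class TrialSet:
    """Stimulus-aligned epochs for one subject and condition.

    ``data`` has shape (n_trials, n_channels, n_times); ``times`` is the
    peristimulus axis in milliseconds with 0 at stimulus onset.
    """

    data: np.ndarray
    fs: float
    times: np.ndarray
    condition: str = ""
    subject: str = ""
    age_weeks: float = np.nan
    masks: np.ndarray | None = None  # same shape, True = observed

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x times")
        if self.times.size != self.data.shape[2]:
            raise ValueError("times length mismatch")
        if self.masks is not None:
            self.masks = np.asarray(self.masks, dtype=bool)
            if self.masks.shape != self.data.shape:
                raise ValueError("masks shape mismatch")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def window_indices(self, window_ms) -> np.ndarray:
        lo, hi = window_ms
        return np.flatnonzero((self.times >= lo) & (self.times <= hi))


def preprocess_trials(ts: TrialSet, baseline_window=(-100.0, 0.0)) -> TrialSet:
    """Baseline-correct, average-reference and GFP-normalize every trial.

    GFP at an instant is the across-channel standard deviation; dividing
    by it makes trials scale invariant.  Instants with (near) zero GFP are
    guarded by an epsilon floor.
    """
    idx = ts.window_indices(baseline_window)
    if idx.size == 0:
        raise ValueError("baseline window outside the epoch")
    data = ts.data.copy()
    data -= data[:, :, idx].mean(axis=2, keepdims=True)          # baseline
    data -= data.mean(axis=1, keepdims=True)                     # avg ref
    gfp = data.std(axis=1, keepdims=True)                        # 1 x T per trial
    data /= np.maximum(gfp, _GFP_FLOOR)
    return replace(ts, data=data)


def erp(ts: TrialSet, channel_cluster) -> tuple[np.ndarray, np.ndarray, int]:
    """Cluster-averaged, trial-averaged waveform with per-timepoint SEM."""
    cluster = np.asarray(channel_cluster, dtype=int)
    if cluster.size == 0:
        raise ValueError("empty channel cluster")
    if ts.n_trials < 2:
        raise ValueError("need at least 2 trials for an ERP")
    curves = ts.data[:, cluster, :].mean(axis=1)   # trials x times
    mean = curves.mean(axis=0)
    sem = curves.std(axis=0, ddof=1) / np.sqrt(ts.n_trials)
    return mean, sem, ts.n_trials


def grand_average(subject_curves) -> tuple[np.ndarray, np.ndarray, int]:
    """Across-subject mean and SEM of subject-level ERP curves."""
    curves = np.asarray(subject_curves, dtype=float)
    n = curves.shape[0]
    mean = curves.mean(axis=0)
    sem = curves.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    return mean, sem, n


def between_trial_variability(
    ts: TrialSet, window_ms=(400.0, 600.0)
) -> float:
    """Mean pairwise correlation distance between trials in a window.

    At each timepoint the trial state is the across-channel vector; the
    distance between two trials is 1 - Pearson r of their vectors,
    averaged over all unordered pairs and then over the window.  Pairs
    with a constant vector (undefined correlation) are skipped.
    """
    if ts.n_trials < 3:
        raise ValueError("need at least 3 trials")
    idx = ts.window_indices(window_ms)
    if idx.size == 0:
        raise ValueError("analysis window outside the epoch")
    x = ts.data[:, :, idx]                      # trials x channels x win
    xc = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(xc, axis=1)          # trials x win
    iu = np.triu_indices(ts.n_trials, k=1)
    per_time = []
    for t in range(idx.size):
        nv = norms[:, t]
        valid = nv >= _GFP_FLOOR
        v = np.where(valid[:, None], xc[:, :, t] / np.maximum(nv, _GFP_FLOOR)[:, None], 0.0)
        r = (v @ v.T)[iu]
        pair_ok = (valid[:, None] & valid[None, :])[iu]
        if pair_ok.any():
            per_time.append(np.mean(1.0 - r[pair_ok]))
    if not per_time:
        raise ValueError("all trial pairs degenerate in the window")
    return float(np.mean(per_time))


def zscore_scores(scores) -> np.ndarray:
    """Z-score subject-level scores across the analyzed cohort."""
    scores = np.asarray(scores, dtype=float)
    sd = scores.std(ddof=0)
    if sd == 0:
        return np.zeros_like(scores)
    return (scores - scores.mean()) / sd


def compare_groups(scores_a, scores_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test for equality of medians."""
    res = scipy.stats.ranksums(scores_a, scores_b)
    return float(res.statistic), float(res.pvalue)


def window_contrast_f(contrasts) -> tuple[float, float]:
    """One-sample F-test (squared t) that a per-subject window-mean
    contrast differs from zero; returns (F, p) with (1, n-1) dof."""
    c = np.asarray(contrasts, dtype=float)
    n = c.size
    if n < 2:
        raise ValueError("need at least 2 subjects")
    t = c.mean() / (c.std(ddof=1) / np.sqrt(n))
    f = t * t
    p = float(scipy.stats.f.sf(f, 1, n - 1))
    return float(f), p


def peak_latency(curve, times, window_ms=None) -> float:
    """Time (ms) of the maximum-|amplitude| point, optionally windowed."""
    curve = np.asarray(curve, dtype=float)
    times = np.asarray(times, dtype=float)
    if window_ms is not None:
        sel = (times >= window_ms[0]) & (times <= window_ms[1])
        curve, times = curve[sel], times[sel]
    return float(times[int(np.argmax(np.abs(curve)))])
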