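"""End-to-end repair of a continuous recording.

The pipeline marks artifactual entries with amplitude-based rules, rejects
hopeless channels and timepoints, splits the recording into short
nonoverlapping blocks, completes each block with the low-rank solver, and
reassembles the repaired recording.  Filtering is deliberately applied
*after* completion by default: a shared narrow-band (power line) component
raises spatiotemporal redundancy and thereby helps, not hurts, the low-rank
fit, while filtering a gap-ridden signal first smears gap edges into the
surrounding observed samples.

Artifact-marking rules (all thresholds configurable, defaults in muV):

* jump: a sample-to-sample difference above ``jump_threshold`` (250) marks
  the two flanking samples;
* drift: |fast moving average - slow moving average| above
  ``deviation_threshold`` (150), with 20 ms / 500 ms centered windows;
* outlier: |value - global mean| above ``sd_threshold`` (10) global SDs;
* any non-finite sample; plus user-supplied manual annotations.

Channels bad for more than 70% of samples, and timepoints bad on more than
75% of channels, are rejected outright and excluded from completion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import scipy.ndimage
import scipy.signal

from .exceptions import DataError, InfeasibleBlockError, SingularSystemError
from .optspace import MaskedMatrix, complete
from .recording import Recording

__all__ = [
    "RepairConfig",
    "RepairReport",
    "ArtifactRepair",
    "mark_artifacts",
    "reject_channels",
    "reject_timepoints",
    "epoch",
    "repair",
    "bandpass",
    "reject_trials",
]


@dataclass
class RepairConfig:
    """Hyperparameters of the repair pipeline.

    ``block_size`` is the completion-epoch length in samples (order of the
    channel count); ``rank`` the fixed low-rank dimension used for every
    block.  Thresholds assume microvolt data and scale linearly with the
    unit.
    """

    block_size: int = 120
    rank: int = 12
    jump_threshold: float = 250.0
    deviation_threshold: float = 150.0
    sd_threshold: float = 10.0
    fast_window_ms: float = 20.0
    slow_window_ms: float = 500.0
    channel_reject_frac: float = 0.70
    timepoint_reject_frac: float = 0.75
    trial_reject_frac: float = 0.50
    replace_observed: bool = True
    bandpass: tuple = (0.5, 20.0)
    degree_factor: float = 2.0
    max_iter: int = 200
    tol: float = 1e-6

    def __post_init__(self):
        for name in ("channel_reject_frac", "timepoint_reject_frac", "trial_reject_frac"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        for name in ("jump_threshold", "deviation_threshold", "sd_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.block_size < 2:
            raise ValueError("block_size must be >= 2")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RepairReport:
    """Per-block bookkeeping of a repair run."""

    config: dict
    blocks: list = field(default_factory=list)
    rejected_channels: list = field(default_factory=list)
    rejected_timepoints: list = field(default_factory=list)

    @property
    def n_irrecoverable(self) -> int:
        return sum(1 for b in self.blocks if b.get("skipped"))

    def summary(self) -> str:
        n = len(self.blocks)
        done = [b for b in self.blocks if not b.get("skipped")]
        lines = [
            "Recording repair results",
            "========================",
            f"blocks:               {n}",
            f"completed:            {len(done)}",
            f"irrecoverable blocks: {self.n_irrecoverable}",
            f"rejected channels:    {len(self.rejected_channels)}",
            f"rejected timepoints:  {len(self.rejected_timepoints)}",
        ]
        if done:
            sev = np.array([b["severity"] for b in done])
            it = np.array([b["iterations"] for b in done])
            lines.append(f"median severity:      {np.median(sev):.2f}%")
            lines.append(f"median iterations:    {np.median(it):.0f}")
        return "\n".join(lines)


def _moving_mean(x: np.ndarray, window: int) -> np.ndarray:
    window = max(1, int(window))
    return scipy.ndimage.uniform_filter1d(x, size=window, axis=-1, mode="nearest")


def mark_artifacts(
    rec: Recording,
    cfg: RepairConfig | None = None,
    manual_bad: np.ndarray | None = None,
) -> np.ndarray:
    """Return a boolean bad-entry matrix (True = artifact).

    Non-finite samples are marked bad rather than raising; manual
    annotations (same-shape boolean, True = bad) are OR-ed in.
    """
    cfg = cfg or RepairConfig()
    data = rec.data
    bad = ~np.isfinite(data)
    finite = np.where(bad, 0.0, data)

    # (a) sudden jumps: mark both flanking samples
    jumps = np.abs(np.diff(finite, axis=1)) > cfg.jump_threshold
    bad[:, :-1] |= jumps
    bad[:, 1:] |= jumps

    # (b) fast/slow moving-average deviation (transients vs. drifts)
    fast = _moving_mean(finite, round(cfg.fast_window_ms * rec.fs / 1000.0))
    slow = _moving_mean(finite, round(cfg.slow_window_ms * rec.fs / 1000.0))
    bad |= np.abs(fast - slow) > cfg.deviation_threshold

    # (c) global amplitude outliers
    ok = np.isfinite(data)
    mu = float(finite[ok].mean()) if ok.any() else 0.0
    sd = float(finite[ok].std()) if ok.any() else 0.0
    if sd > 0:
        bad |= np.abs(finite - mu) > cfg.sd_threshold * sd

    if manual_bad is not None:
        bad |= np.asarray(manual_bad, dtype=bool)
    return bad


def reject_channels(bad: np.ndarray, frac: float = 0.70) -> list[int]:
    """Channels whose bad fraction strictly exceeds ``frac``."""
    bad_frac = bad.mean(axis=1)
    return np.flatnonzero(bad_frac > frac).tolist()


def reject_timepoints(bad: np.ndarray, frac: float = 0.75) -> list[int]:
    """Timepoints bad on strictly more than ``frac`` of the channels."""
    bad_frac = bad.mean(axis=0)
    return np.flatnonzero(bad_frac > frac).tolist()


def epoch(rec: Recording, block_size: int) -> list[tuple[int, int, MaskedMatrix]]:
    """Split into consecutive nonoverlapping blocks of ``block_size``
    samples (final remainder kept as a shorter block); each item is
    ``(start, stop, MaskedMatrix)`` so reassembly is exact."""
    if block_size < 2:
        raise ValueError("block_size must be >= 2")
    out = []
    t = rec.n_samples
    for start in range(0, t, block_size):
        stop = min(start + block_size, t)
        out.append(
            (start, stop, MaskedMatrix(rec.data[:, start:stop].copy(),
                                       rec.mask[:, start:stop].copy()))
        )
    return out


def repair(rec: Recording, cfg: RepairConfig | None = None) -> tuple[Recording, RepairReport]:
    """Repair a recording blockwise; equivalent to
    ``ArtifactRepair(rec, cfg).fit()`` unpacked as a tuple."""
    res = ArtifactRepair(rec, cfg).fit()
    return res.recording, res.report


class ArtifactRepair:
    """Model-style front end for whole-recording repair.

    ``fit()`` marks nothing by itself: the recording's mask is taken as
    given (use :func:`mark_artifacts` / annotations first), rejected
    channels/timepoints are excluded, each block is completed at
    ``cfg.rank``, and blocks that violate the completability assumption
    are reported rather than aborting the run.
    """

    def __init__(self, rec: Recording, cfg: RepairConfig | None = None):
        self.rec = rec
        self.cfg = cfg or RepairConfig()

    def fit(self) -> "RepairResult":
        rec, cfg = self.rec, self.cfg
        out = rec.copy()
        report = RepairReport(
            config=cfg.to_dict(),
            rejected_channels=list(rec.rejected_channels),
            rejected_timepoints=list(rec.rejected_timepoints),
        )
        keep_ch = np.setdiff1d(np.arange(rec.n_channels), rec.rejected_channels)
        keep_t = np.ones(rec.n_samples, dtype=bool)
        keep_t[list(rec.rejected_timepoints)] = False

        blocks = epoch(rec, cfg.block_size)
        # merge a too-short remainder into the previous block: fewer than
        # 2*rank columns makes the core system fragile
        if len(blocks) >= 2 and (blocks[-1][1] - blocks[-1][0]) < 2 * cfg.rank:
            s0, _, _ = blocks[-2]
            _, s2, _ = blocks[-1]
            blocks = blocks[:-2] + [
                (s0, s2, MaskedMatrix(rec.data[:, s0:s2].copy(),
                                      rec.mask[:, s0:s2].copy()))
            ]

        for bi, (start, stop, blk) in enumerate(blocks):
            cols_keep = np.flatnonzero(keep_t[start:stop])
            record = {
                "index": bi,
                "start": start,
                "stop": stop,
                "severity": blk.severity(),
                "skipped": None,
                "infeasible_rows": [],
                "infeasible_cols": [],
            }
            sub = MaskedMatrix(
                blk.values[np.ix_(keep_ch, cols_keep)],
                blk.mask[np.ix_(keep_ch, cols_keep)],
            )
            # lines with no observed entry cannot be inferred: exclude them
            # from the fit and report them irrecoverable
            miss_r, miss_c = sub.missing_rows(), sub.missing_cols()
            record["infeasible_rows"] = [int(keep_ch[i]) for i in miss_r]
            record["infeasible_cols"] = [int(start + cols_keep[j]) for j in miss_c]
            fit_rows = np.setdiff1d(np.arange(sub.shape[0]), miss_r)
            fit_cols = np.setdiff1d(np.arange(sub.shape[1]), miss_c)
            r_eff = min(cfg.rank, fit_rows.size, fit_cols.size)
            if r_eff < 1 or fit_rows.size == 0 or fit_cols.size == 0:
                record["skipped"] = "no completable sub-block"
                report.blocks.append(record)
                continue
            core_blk = MaskedMatrix(
                sub.values[np.ix_(fit_rows, fit_cols)],
                sub.mask[np.ix_(fit_rows, fit_cols)],
            )
            try:
                res = complete(
                    core_blk,
                    r_eff,
                    max_iter=cfg.max_iter,
                    tol=cfg.tol,
                    degree_factor=cfg.degree_factor,
                )
            except (InfeasibleBlockError, SingularSystemError, DataError) as exc:
                record["skipped"] = str(exc)
                report.blocks.append(record)
                continue
            record.update(
                iterations=res.iterations,
                final_cost=res.final_cost,
                converged=res.converged,
            )
            abs_rows = keep_ch[fit_rows]
            abs_cols = start + cols_keep[fit_cols]
            target = out.data[np.ix_(abs_rows, abs_cols)]
            obs = core_blk.mask
            if cfg.replace_observed:
                target = res.completed
            else:
                target = np.where(obs, target, res.completed)
            out.data[np.ix_(abs_rows, abs_cols)] = target
            # filled entries are usable downstream
            newmask = out.mask[np.ix_(abs_rows, abs_cols)]
            newmask[:, :] = True
            out.mask[np.ix_(abs_rows, abs_cols)] = newmask
            report.blocks.append(record)
        return RepairResult(out, report)


@dataclass
class RepairResult:
    """Repaired recording plus the per-block report."""

    recording: Recording
    report: RepairReport

    def summary(self) -> str:
        return self.report.summary()


def bandpass(rec: Recording, low: float, high: float, order: int = 4) -> Recording:
    """Zero-phase band-pass (second-order sections) of every channel."""
    if not (0 < low < high < rec.fs / 2):
        raise ValueError(
            f"band ({low}, {high}) Hz invalid for fs = {rec.fs} Hz"
        )
    sos = scipy.signal.butter(order, [low, high], btype="bandpass",
                              fs=rec.fs, output="sos")
    out = rec.copy()
    out.data = scipy.signal.sosfiltfilt(sos, out.data, axis=1)
    return out


def reject_trials(trial_masks, frac: float = 0.50) -> list[int]:
    """Indices of trials kept: a trial is dropped when its corrupted
    fraction strictly exceeds ``frac`` (masks are True = observed)."""
    kept = []
    for i, m in enumerate(trial_masks):
        m = np.asarray(m, dtype=bool)
        if (1.0 - m.mean()) <= frac:
            kept.append(i)
    return kept
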