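"""Synthetic recordings, artifact masks and trial cohorts.

The generator realizes the statistical structure the repair method assumes
so that every stage is testable without any external dataset:

* multichannel signals that are exactly low rank before sensor noise —
  a random mixing matrix applied to latent sources that mix drifting-phase
  alpha/theta-band sinusoids with band-limited smoothed noise, optionally
  plus a common power-line component;
* bursty artifact masks — uniform speckle, single-channel bursts with
  geometric durations, and all-channel bursts — whose blockwise severity
  distribution is strongly right skewed, like real motion/blink artifacts;
* stimulus-locked trial cohorts with a lateralized evoked effect in a
  configurable window and a per-group between-trial variability level, so
  ERP contrasts and variability ("quenching") group differences have a
  known ground truth.

Everything is a pure function of ``(spec, seed)``; nothing reads files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.ndimage

from .analysis import TrialSet
from .recording import Recording

__all__ = [
    "GeneratorSpec",
    "SubjectData",
    "Cohort",
    "generate_recording",
    "generate_mask",
    "generate_cohort",
]


@dataclass
class GeneratorSpec:
    """Study conditions for the synthetic generator.

    Signal amplitudes are in microvolts; rates are per-sample
    probabilities; burst durations are geometric with the given means.
    """

    n_channels: int = 128
    n_samples: int = 15000
    fs: float = 250.0
    latent_rank: int = 8
    sine_band: tuple = (4.0, 12.0)          # Hz, oscillatory sources
    noise_bandwidth: tuple = (1.0, 8.0)     # Hz, smoothed-noise sources
    signal_sd: float = 20.0                 # muV, median channel SD
    sensor_noise_sd: float = 2.0            # muV
    line_amplitude: float = 0.0             # muV (0 = line noise off)
    line_freq: float = 50.0
    # artifact mask process
    uniform_rate: float = 1e-5
    channel_burst_rate: float = 1e-4
    channel_burst_mean: float = 100.0       # samples
    global_burst_rate: float = 4e-4
    global_burst_mean: float = 40.0
    # trial / cohort structure
    conditions: tuple = ("left", "right")
    epoch_ms: tuple = (-200.0, 800.0)
    effect_window_ms: tuple = (250.0, 450.0)
    effect_size: float = 2.0                # muV added for the first condition
    cluster_size: int = 8
    n_trials: int = 20
    trial_severity_spread: float = 1.2      # lognormal sigma of per-trial rates
    groups: dict = field(default_factory=lambda: {
        "young": {"n_subjects": 20, "erv_level": 0.15, "age_weeks": (5, 12)},
        "old": {"n_subjects": 20, "erv_level": 0.30, "age_weeks": (16, 24)},
    })
    artifact_amplitude: float = 400.0       # muV, injected artifact waveform

    def __post_init__(self):
        if self.latent_rank > self.n_channels:
            raise ValueError("latent_rank must be <= n_channels")
        for r in (self.uniform_rate, self.channel_burst_rate, self.global_burst_rate):
            if r < 0:
                raise ValueError("rates must be >= 0")


def _latent_sources(spec: GeneratorSpec, n_samples: int, rng) -> np.ndarray:
    """latent_rank x n_samples unit-SD sources: drifting-phase sinusoids
    plus band-limited smoothed noise."""
    r = spec.latent_rank
    t = np.arange(n_samples) / spec.fs
    src = np.empty((r, n_samples))
    n_sin = max(1, r // 2)
    for k in range(r):
        if k < n_sin:
            f = rng.uniform(*spec.sine_band)
            drift = np.cumsum(rng.normal(0.0, 0.05, n_samples))
            src[k] = np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi) + drift)
        else:
            bw = rng.uniform(*spec.noise_bandwidth)
            sigma = spec.fs / (2.0 * np.pi * bw)
            src[k] = scipy.ndimage.gaussian_filter1d(
                rng.normal(size=n_samples), sigma, mode="nearest"
            )
        sd = src[k].std()
        if sd > 0:
            src[k] /= sd
    return src


def generate_recording(spec: GeneratorSpec, seed: int) -> tuple[Recording, np.ndarray]:
    """Continuous recording plus its noiseless low-rank truth.

    ``data = mixing @ sources * scale + sensor noise (+ line noise)``; the
    noiseless part has numerical rank exactly ``latent_rank``.
    """
    rng = np.random.default_rng(seed)
    c, t = spec.n_channels, spec.n_samples
    mixing = rng.normal(size=(c, spec.latent_rank))
    truth = mixing @ _latent_sources(spec, t, rng)
    med_sd = np.median(truth.std(axis=1))
    if med_sd > 0:
        truth *= spec.signal_sd / med_sd
    data = truth + rng.normal(0.0, spec.sensor_noise_sd, size=(c, t))
    if spec.line_amplitude > 0:
        tt = np.arange(t) / spec.fs
        wave = np.sin(2 * np.pi * spec.line_freq * tt + rng.uniform(0, 2 * np.pi))
        gains = 1.0 + 0.2 * rng.normal(size=c)
        data = data + spec.line_amplitude * gains[:, None] * wave[None, :]
    return Recording(data, fs=spec.fs), truth


def _burst_starts(n: int, rate: float, rng) -> np.ndarray:
    if rate <= 0:
        return np.empty(0, dtype=int)
    return np.flatnonzero(rng.random(n) < rate)


def generate_mask(
    spec: GeneratorSpec, seed: int, n_samples: int | None = None
) -> np.ndarray:
    """Observed mask (True = usable): union of uniform speckle,
    single-channel geometric bursts and all-channel bursts."""
    rng = np.random.default_rng(seed)
    c = spec.n_channels
    t = n_samples if n_samples is not None else spec.n_samples
    bad = rng.random((c, t)) < spec.uniform_rate
    for ch in range(c):
        for s in _burst_starts(t, spec.channel_burst_rate, rng):
            d = rng.geometric(1.0 / spec.channel_burst_mean)
            bad[ch, s:s + d] = True
    for s in _burst_starts(t, spec.global_burst_rate, rng):
        d = rng.geometric(1.0 / spec.global_burst_mean)
        bad[:, s:s + d] = True
    return ~bad


@dataclass
class SubjectData:
    """One synthetic subject: corrupted trials, masks, and clean truth."""

    subject: str
    group: str
    age_weeks: float
    trials: dict            # condition -> TrialSet (corrupted values, masks set)
    truth: dict             # condition -> ndarray trials x channels x times
    erv_level: float


@dataclass
class Cohort:
    subjects: list

    def group(self, name: str) -> list:
        return [s for s in self.subjects if s.group == name]


def _evoked_template(spec: GeneratorSpec, times: np.ndarray, rng) -> np.ndarray:
    """Channels x times evoked response: an early bump on the cluster plus
    a weaker widespread component."""
    c = spec.n_channels
    cluster = np.arange(min(spec.cluster_size, c))
    topo = 0.15 * rng.normal(size=c)
    topo[cluster] += 1.0
    bump = np.exp(-0.5 * ((times - 180.0) / 60.0) ** 2)     # early component
    late = np.exp(-0.5 * ((times - 450.0) / 130.0) ** 2)    # broad P400-like wave
    wave = 3.0 * bump + 2.0 * late
    return topo[:, None] * wave[None, :]


def _effect_template(spec: GeneratorSpec, times: np.ndarray) -> np.ndarray:
    lo, hi = spec.effect_window_ms
    mid, width = 0.5 * (lo + hi), 0.25 * (hi - lo)
    c = spec.n_channels
    cluster = np.arange(min(spec.cluster_size, c))
    topo = np.zeros(c)
    topo[cluster] = 1.0
    wave = np.exp(-0.5 * ((times - mid) / width) ** 2)
    return topo[:, None] * wave[None, :]


def generate_cohort(spec: GeneratorSpec, seed: int) -> Cohort:
    """Two-condition, two-group trial cohort with known ground truth.

    The first condition carries an extra evoked component of
    ``effect_size`` muV in the effect window on the cluster channels.  The
    per-group ``erv_level`` sets the expected between-trial correlation
    distance in the effect window: trialwise low-rank background activity
    is scaled so that (background variance)/(total variance) across
    channels matches the level.  Corrupted entries get a large-amplitude
    artifact waveform and are flagged in the trial masks.
    """
    rng = np.random.default_rng(seed)
    n_t = int(round((spec.epoch_ms[1] - spec.epoch_ms[0]) / 1000.0 * spec.fs)) + 1
    times = spec.epoch_ms[0] + np.arange(n_t) * 1000.0 / spec.fs
    win = (times >= spec.effect_window_ms[0]) & (times <= spec.effect_window_ms[1])
    c = spec.n_channels
    subjects = []
    sid = 0
    for group, g in spec.groups.items():
        for _ in range(g["n_subjects"]):
            sid += 1
            age = rng.uniform(*g["age_weeks"])
            evoked = _evoked_template(spec, times, rng)
            effect = spec.effect_size * _effect_template(spec, times)
            # subject-level jitter keeps group means at the configured level
            erv = g["erv_level"] * np.exp(rng.normal(0.0, 0.08))
            trials_by_cond, truth_by_cond = {}, {}
            for ci, cond in enumerate(spec.conditions):
                signal = evoked + (effect if ci == 0 else 0.0)
                # per-timepoint across-channel variance of the shared signal
                vs_t = signal.var(axis=0)
                vs = float(np.mean(vs_t[win]))
                bg = np.empty((spec.n_trials, c, n_t))
                mixing = rng.normal(size=(c, spec.latent_rank))
                for k in range(spec.n_trials):
                    bg[k] = mixing @ _latent_sources(spec, n_t, rng)
                # stimulus-locked variability envelope: the trialwise
                # background tracks the evoked field strength so the
                # expected between-trial correlation distance equals the
                # configured level at every instant, not just on average
                vb_t = vs_t * erv / (1.0 - erv)
                bg_sd_t = bg.std(axis=(0, 1))
                scale_t = np.sqrt(vb_t) / np.maximum(bg_sd_t, 1e-12)
                bg *= scale_t[None, None, :]
                clean = signal[None, :, :] + bg
                clean = clean + rng.normal(0.0, 0.02 * np.sqrt(vs), clean.shape)
                masks = np.empty(clean.shape, dtype=bool)
                corrupted = clean.copy()
                for k in range(spec.n_trials):
                    # right-skewed per-trial artifact load: a lognormal
                    # multiplier on all mask rates (some trials are nearly
                    # clean, a few are heavily corrupted)
                    mult = rng.lognormal(0.0, spec.trial_severity_spread)
                    tspec = replace(
                        spec,
                        uniform_rate=min(1.0, spec.uniform_rate * mult),
                        channel_burst_rate=min(1.0, spec.channel_burst_rate * mult),
                        global_burst_rate=min(1.0, spec.global_burst_rate * mult),
                    )
                    m = generate_mask(tspec, int(rng.integers(2**31)), n_samples=n_t)
                    masks[k] = m
                    art = spec.artifact_amplitude * scipy.ndimage.gaussian_filter1d(
                        rng.normal(size=(c, n_t)), 5.0, axis=1, mode="nearest"
                    )
                    corrupted[k] = np.where(m, clean[k], art)
                trials_by_cond[cond] = TrialSet(
                    data=corrupted, fs=spec.fs, times=times, condition=cond,
                    subject=f"S{sid:03d}", age_weeks=age, masks=masks,
                )
                truth_by_cond[cond] = clean
            subjects.append(SubjectData(
                subject=f"S{sid:03d}", group=group, age_weeks=age,
                trials=trials_by_cond, truth=truth_by_cond, erv_level=erv,
            ))
    return Cohort(subjects)
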