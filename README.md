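# eegrepair

Blockwise low-rank matrix completion for repairing artifacts in
multichannel neural recordings (EEG, MEG, LFP).

Electrophysiology recordings — especially from infants, patients and other
"atypical" cohorts — are riddled with motion and blink artifacts.  The
usual remedy is to reject contaminated trials, which destroys statistical
power exactly where data are scarcest.  This package treats artifact
repair as a **matrix completion** problem: because neural activity unfolds
on low-dimensional manifolds, a short channels × time block `M` of a
recording is well approximated by a low-rank model, and entries marked as
corrupted can be inferred from the clean ones.

For each block the package minimizes, over pairs of orthonormal factors,
the observed-entry misfit

    F(X, Y) = min_S ‖ P_Ω(M) − P_Ω(X S Yᵀ) ‖_F

where `Ω` is the set of clean entries, `X ∈ R^{C×r}`, `Y ∈ R^{Tk×r}` have
orthonormal columns and `S` is an `r × r` core solved exactly at every
step.  Optimization follows the OptSpace recipe: trimming of
over-represented rows/columns, a rescaled truncated-SVD initialization,
then projected gradient descent with QR retraction and a backtracking
line search.  The completed block `X S Yᵀ` regenerates *every* entry, so
the repaired signal is a denoised low-rank rendering of the block.

Around that core the package provides, as both a library and a CLI:

* an end-to-end repair pipeline (`ArtifactRepair`): threshold-based
  artifact marking (250 μV jumps, 150 μV fast/slow deviation, 10 SD
  outliers), channel/timepoint rejection (70% / 75%), epoching,
  per-block completion and zero-phase band-pass filtering;
* surrogate-artifact benchmarking (`build_library`, `sweep`): real
  artifact masks are overlaid on clean blocks so reconstruction accuracy
  (Pearson r, relative Frobenius distance) is measurable against known
  ground truth, across block size × rank × severity grids with
  permutation chance levels;
* a spherical-spline interpolation comparator (the conventional spatial
  repair baseline);
* downstream analyses: ERP extraction (baseline correction, average
  reference, GFP normalization, cluster averages with SEM) and
  between-trial variability (mean pairwise correlation distance in a
  peristimulus window, rank-sum group comparison);
* a synthetic-data generator producing low-rank recordings, bursty
  right-skew-severity artifact masks, and stimulus-locked trial cohorts
  with known ground truth.

## Worked example

```python
import numpy as np
import eegrepair as er

# simulate a 32-channel minute of EEG-like data with bursty artifacts
spec = er.GeneratorSpec(n_channels=32, n_samples=15000)
rec, truth = er.generate_recording(spec, seed=7)
rec.mask = er.generate_mask(spec, seed=8)
print(f"corrupted: {100 * (1 - rec.mask.mean()):.1f}% of entries")

res = er.ArtifactRepair(rec, er.RepairConfig(block_size=120, rank=8)).fit()
print(res.summary())

hid = ~rec.mask
r = np.corrcoef(res.recording.data[hid], truth[hid])[0, 1]
print(f"hidden-entry correlation with ground truth: {r:.3f}")
```

prints

```
corrupted: 2.6% of entries
Recording repair results
========================
blocks:               125
completed:            125
irrecoverable blocks: 0
rejected channels:    0
rejected timepoints:  0
median severity:      0.65%
median iterations:    36
hidden-entry correlation with ground truth: 0.894
```

2.6% of all entries were artifact-masked (concentrated in single-channel
and all-channel bursts); every 120-sample block satisfied the
completability assumption, and the values the model filled in at the
masked locations correlate at r ≈ 0.89 with the ground-truth signal the
generator hid there.

The same run from a shell:

```bash
eegrepair synth recording --seed 7 --out rec.npz
eegrepair repair --input rec.npz --block-size 120 --rank 8 \
                 --output repaired.npz --report report.json
eegrepair benchmark --recording rec.npz --block-size 120 --n-boot 25 \
                    --seed 7 --out results/
```

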