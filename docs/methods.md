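# Methods

## The repair model

A continuous multichannel recording is a matrix `D` of `C` channels by `T`
samples (microvolts).  Artifact detection partitions each short epoch `M`
(a `C x Tk` block of `D`, `Tk` on the order of `C`) into observed entries
`Ω(M)` and corrupted entries, and the corrupted values are inferred under a
low-rank hypothesis: neural trajectories occupy a subspace of dimension
`r ≪ C`, so `M ≈ X S Yᵀ` with orthonormal `X (C x r)`, `Y (Tk x r)` and an
unconstrained `r x r` core `S`.  The fitted quantity is the observed-entry
misfit

    F(X, Y) = min_S ‖ P_Ω(M) − P_Ω(X S Yᵀ) ‖_F ,

minimized over the pair of subspaces; the completed block is the low-rank
model evaluated at *every* entry, so by default observed entries are also
replaced by their (denoised) model values.  Blocks are repaired
independently, which lets the local subspace follow slow state changes
along the recording.

Recovery is only possible when (1) the block is genuinely low rank,
(2) every row and column retains at least one observed entry, and
(3) corrupted entries are not too clustered.  Rows/columns violating (2)
are detected, excluded from the fit, and reported irrecoverable instead of
being guessed.

## Solver

* **Spectral initialization.** Rank-`r` truncated SVD of the zero-filled
  block after trimming rows/columns whose observed count exceeds twice the
  mean (over-represented lines distort the leading singular vectors), with
  singular values rescaled by `C·Tk/|Ω|` to undo the zero-filling bias.
  SVD signs are fixed (largest-magnitude entry of each left vector
  positive) for cross-platform reproducibility.
* **Core solve.** `S` is an exact linear least-squares problem in `r²`
  unknowns.  Small systems (`r ≤ 4`) go through dense normal equations;
  larger ones use conjugate gradients on the masked normal operator
  `S → Xᵀ P_Ω(X S Yᵀ) Y`, which is the identity at full observation and
  therefore well conditioned at the high observation densities typical of
  artifact masks; successive solves warm-start from the previous core,
  which changes little between line-search trials.  A dense fallback
  settles near-singular systems and diagnoses rank deficiency (too few
  observed entries), which is raised as an error carrying the block index.
* **Descent.** Projected steepest descent on `(X, Y)`: the Euclidean
  gradient of the squared misfit is projected onto the horizontal space
  `(I − XXᵀ)·`, the initial step is the Barzilai–Borwein spectral step,
  an Armijo backtracking line search guarantees decrease, and a QR
  retraction (positive-diagonal convention) restores orthonormality.  The
  first line-search trial re-solves the core exactly, so long
  valley-following steps are not rejected because of a stale core; halved
  steps reuse the current core and the core is re-solved on acceptance,
  which can only lower the cost further.  The recorded cost sequence is
  therefore nonincreasing by construction.
* **Stopping.** Relative cost decrease below `tol = 1e-6` for 10
  consecutive iterations (a single flat step after a large
  exact-line-search jump does not mean the subspace has stopped turning),
  an absolute floor of `1e-10·‖P_Ω(M)‖` for exact fits, or
  `max_iter = 200`.  Typical EEG-scale blocks (≤ 128 x 470) converge in
  well under a second.
* **Saddle escape.** The factored objective can have saddles and, for
  marginally sampled tiny blocks, spurious basins.  With `n_restarts > 0`
  (off by default), a stalled or converged-above-floor state is perturbed
  by a seeded jitter of the best factors (escalating scale) and descent
  resumes; only improvements over the incumbent are accepted or recorded,
  so the reported history stays monotone and determinism is preserved
  through `restart_seed`.  Recommended for blocks smaller than ~10 x 10.
* **Optional incoherence barrier.** A hinge penalty on factor row norms
  (threshold `3r/C` per row) is available but off by default, so the
  default cost is exactly `F` above.

## Repair pipeline

Artifact marking uses three amplitude rules with microvolt defaults:
sample-to-sample jumps above 250 (both flanking samples marked), a
fast-minus-slow moving-average deviation above 150 (20 ms / 500 ms
centered windows, separating transients from drifts at 250 Hz), and
global 10-SD outliers; non-finite samples are marked, and manual interval
annotations are OR-ed in.  Channels bad for more than 70% of samples and
timepoints bad on more than 75% of channels are rejected outright (strict
inequalities).  Blocks default to `Tk = 120` samples; a final remainder
shorter than `2r` columns is merged into the previous block to avoid
fragile core systems.  Band-pass filtering (zero-phase
second-order-section Butterworth, 0.5–20 Hz default) is applied *after*
completion: a shared power-line component only adds one coherent dimension
and increases cross-channel redundancy, whereas filtering a gap-ridden
signal first smears gap edges into neighboring observed samples.  Trials
with more than 50% corrupted entries (strict) are rejected; because repair
only clears corrupted entries, the retained set can only grow.

## Surrogate benchmarking

Uniform random masks misrepresent real artifacts, so benchmarking overlays
*observed* artifact masks on fully clean blocks.  A library of
nonoverlapping random chunks is drawn from a recording (pooling across
recordings mirrors pooling across subjects and is required at large block
sizes, where fully clean stretches are rare); bad-block severities are
split into five equiprobable classes by stable-ranked quintiles.  Each
bootstrap draw overlays a random bad mask on a random good block (both
with replacement), completes it, and scores Pearson correlation plus
relative Frobenius distance `‖truth − completed‖_F / ‖truth‖_F` over all,
observed and hidden entries (the normalization makes distances comparable
across blocks; it is recorded in the output metadata).  Draws whose mask
leaves a row or column fully hidden are resampled up to a cap and counted.
Chance levels are the 95th percentile of correlation (5th of distance)
against entry-permuted blocks.  Every cell's random stream derives from
the global seed plus the cell coordinates, so cells are independently
reproducible.

## Spherical-spline comparator

The baseline replaces an entire bad channel by a weighted sum of good
channels, with weights from the spherical-spline kernel
`g(cos γ) = (4π)⁻¹ Σₙ (2n+1)/(n(n+1))^m Pₙ(cos γ)` (stiffness `m = 4`,
7 Legendre terms, ridge `1e-5`), solved with the affine constraint so
constants interpolate exactly.  Electrode positions are projected onto the
unit sphere; a deterministic Fibonacci-lattice cap provides an idealized
high-density montage for tests.  The implementation agrees with the
reference implementation in MNE-Python to ~1e-11 at matched series
truncation (checked in the test suite).  Being purely spatial, the method
cannot exploit temporal structure — which is exactly the contrast the
benchmark quantifies.

## ERP and between-trial variability

Trials are baseline-corrected (per channel), average-referenced, and
normalized by global field power (the across-channel SD at each instant,
floored at 1e-12), making them scale invariant.  ERPs average a channel
cluster within trials, then across trials, with per-timepoint SEM;
subject curves aggregate into grand averages with across-subject SEM.
The window-contrast statistic is a one-sample F (squared t) on per-subject
window means, with the 250–450 ms contrast window and the 400–600 ms
variability window as configuration defaults.  Between-trial variability
is the mean pairwise `1 − Pearson r` between the across-channel state
vectors of different trials at each instant, averaged over pairs and over
the window; degenerate (constant) vectors are skipped.  Subject scores are
z-scored across the analyzed cohort before group comparison, and groups
are compared with the two-sided Wilcoxon rank-sum test.

## Synthetic study conditions

The generator realizes exactly the structure the method assumes and is the
test bed for every claim:

* **Signals.** `mixing (C x r) · sources (r x T)` plus sensor noise;
  sources mix 4–12 Hz drifting-phase sinusoids with 1–8 Hz smoothed noise,
  scaled to a 20 μV median channel SD with 2 μV sensor noise; an optional
  50 Hz common component with per-channel gains models power-line pickup.
  The noiseless part has numerical rank exactly `latent_rank` (default 8).
* **Masks.** Union of uniform speckle (rate 1e-5), single-channel bursts
  (rate 1e-4 per channel-sample, geometric durations of mean 100 samples)
  and all-channel bursts (rate 4e-4, mean 40).  These rates were chosen
  once so that, as in heavily artifacted infant recordings, blockwise
  severity is strongly right skewed, fully clean 120-sample blocks exist
  but are a minority, and the severest quantile reaches tens of percent.
* **Cohorts.** Each subject gets an evoked template (an early bump plus a
  broad late wave on a cluster of channels) and, for the first condition,
  an extra effect of configurable amplitude in the 250–450 ms window.
  Trialwise low-rank background activity is scaled with a stimulus-locked
  envelope such that the expected between-trial correlation distance
  equals the configured per-group level at every instant — i.e., the
  generator realizes a genuine variability-quenching profile, so a
  configured group ratio is recoverable by the analysis.  Per-trial
  artifact rates carry a lognormal multiplier (σ = 1.2), making trial
  corruption right skewed; corrupted entries are overwritten with
  large-amplitude smoothed noise and flagged in the trial masks.

What the generator does *not* emulate: volume-conduction-consistent
topographies tied to electrode geometry, 1/f spectra, nonstationary
oscillatory bursts (sleep spindles, movement rhythms), or artifact
waveforms with realistic morphology (only the masks matter to the method).
Passing tests therefore certify the algorithmic claims under the stated
low-rank + bursty-mask conditions, not clinical performance on any
particular real dataset.

## Test problem sizes

The acceptance suite runs at desk scale, chosen as the package's own
balance of statistical resolution and turnaround: exact recovery at the
full 128 x 120 block size over 100 seeds; severity curves from a
64-channel library (block size 120, rank 8, 50 bootstrap draws per class);
rank saturation from eight pooled 48-channel recordings at block size 470
with 30 draws per rank; the comparator on 50 surrogate 32-channel blocks;
the ERP pipeline on 16 subjects x 2 conditions x 20 trials of 24 channels;
and variability recovery on 20 subjects per group.  The benchmarking
module itself scales to the full grid (block sizes 20–470, ranks 4–20,
hundreds of bootstrap iterations) when given time.

## Known limitations

* Steepest descent with exact core response is linearly convergent; on
  ill-conditioned valleys it approaches the optimum slowly, and the
  default budget (200 iterations) can stop short of full subspace
  alignment for over-parameterized ranks.  Hidden-entry accuracy at
  `r` well above the true rank benefits from larger budgets.
* A fixed rank per recording is a practical compromise; per-block rank
  selection is left to the caller (both modes are exposed).
* Severity classes are recording-specific quantiles, so absolute severity
  ranges differ between datasets.
* The spline comparator assumes a spherical head and idealized positions;
  it is a baseline, not a validated clinical interpolator.
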