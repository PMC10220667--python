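"""Surrogate-artifact benchmarking.

Real artifact patterns carry bursty spatiotemporal structure that uniform
random masking does not; benchmarking therefore overlays *actual* artifact
masks (from "bad" blocks) onto fully observed "good" blocks, producing
surrogate corrupted blocks whose hidden ground truth is known.  A block
library is built by sampling nonoverlapping contiguous chunks of a
recording; bad blocks are binned into five equiprobable severity classes;
a bootstrapped sweep completes surrogates over a (block size, rank,
severity) grid and scores each reconstruction by Pearson correlation and
relative Frobenius distance over all / observed / hidden entries, with
permutation-based chance levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import EegRepairError, InfeasibleBlockError, SingularSystemError
from .optspace import MaskedMatrix, complete
from .recording import Recording

__all__ = [
    "ArtifactMask",
    "BlockLibrary",
    "BenchmarkResult",
    "build_library",
    "merge_libraries",
    "quantile_classes",
    "make_surrogate",
    "evaluate",
    "chance_level",
    "sweep",
]


@dataclass
class ArtifactMask:
    """Binary artifact pattern of a bad block (True = observed)."""

    pattern: np.ndarray
    severity_class: int | None = None

    def __post_init__(self):
        self.pattern = np.asarray(self.pattern, dtype=bool)

    @property
    def severity(self) -> float:
        return 100.0 * (self.pattern.size - self.pattern.sum()) / self.pattern.size


@dataclass
class BlockLibrary:
    """Good (fully observed) blocks and bad-block artifact masks for one
    block size, with severity quantile edges."""

    good: list = field(default_factory=list)
    bad: list = field(default_factory=list)
    block_size: int = 0
    quantile_edges: np.ndarray | None = None
    degenerate_classes: bool = False

    @property
    def severities(self) -> np.ndarray:
        return np.array([b.severity for b in self.bad])

    def bad_in_class(self, q: int) -> list:
        return [b for b in self.bad if b.severity_class == q]


def quantile_classes(severities, k: int = 5) -> tuple[np.ndarray, np.ndarray, bool]:
    """Split severities into ``k`` equiprobable classes (sizes differ by
    at most one; ties broken by stable order).

    Returns (labels in 1..k, k-1 class edges, degenerate flag); the flag is
    set when there are fewer than ``k`` distinct values.
    """
    sev = np.asarray(severities, dtype=float)
    if sev.size == 0:
        raise ValueError("empty severity list")
    order = np.argsort(sev, kind="stable")
    labels = np.empty(sev.size, dtype=int)
    labels[order] = np.arange(sev.size) * k // sev.size + 1
    edges = np.quantile(sev, np.arange(1, k) / k)
    degenerate = np.unique(sev).size < k
    return labels, edges, degenerate


def build_library(
    rec: Recording,
    block_size: int,
    target_size: int,
    seed: int,
    n_classes: int = 5,
) -> BlockLibrary:
    """Sample nonoverlapping contiguous chunks of width ``block_size`` at
    random until ``target_size`` blocks are collected or the recording is
    exhausted; label each good (no corrupted entry) or bad (mask kept as
    an artifact pattern with a severity class)."""
    rng = np.random.default_rng(seed)
    t = rec.n_samples
    starts = rng.permutation(t - block_size + 1)
    taken = np.zeros(t, dtype=bool)
    lib = BlockLibrary(block_size=block_size)
    for s in starts:
        if len(lib.good) + len(lib.bad) >= target_size:
            break
        if taken[s:s + block_size].any():
            continue
        taken[s:s + block_size] = True
        m = rec.mask[:, s:s + block_size]
        if m.all():
            lib.good.append(MaskedMatrix(rec.data[:, s:s + block_size].copy(),
                                         m.copy()))
        else:
            lib.bad.append(ArtifactMask(m.copy()))
    if not lib.good:
        import warnings

        warnings.warn("no fully observed blocks found; library has no good blocks")
    if lib.bad:
        labels, edges, degen = quantile_classes(lib.severities, n_classes)
        for b, lab in zip(lib.bad, labels):
            b.severity_class = int(lab)
        lib.quantile_edges = edges
        lib.degenerate_classes = degen
    return lib


def merge_libraries(libs, n_classes: int = 5) -> BlockLibrary:
    """Pool libraries of the same block size (e.g. one per subject) and
    reassign severity classes on the union."""
    sizes = {lib.block_size for lib in libs}
    if len(sizes) != 1:
        raise EegRepairError(f"cannot merge libraries of differing block sizes {sizes}")
    merged = BlockLibrary(block_size=sizes.pop())
    for lib in libs:
        merged.good.extend(lib.good)
        merged.bad.extend(lib.bad)
    if merged.bad:
        labels, edges, degen = quantile_classes(merged.severities, n_classes)
        for b, lab in zip(merged.bad, labels):
            b.severity_class = int(lab)
        merged.quantile_edges = edges
        merged.degenerate_classes = degen
    return merged


def make_surrogate(
    good: MaskedMatrix, mask: ArtifactMask
) -> tuple[MaskedMatrix, np.ndarray]:
    """Overlay an artifact pattern on a good block: the surrogate's values
    are zero where masked and the ground truth is kept for scoring."""
    if good.shape != mask.pattern.shape:
        raise EegRepairError(
            f"shape mismatch: block {good.shape} vs mask {mask.pattern.shape}"
        )
    pattern = mask.pattern
    surrogate = MaskedMatrix(np.where(pattern, good.values, 0.0), pattern.copy())
    return surrogate, good.values.copy()


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.size < 2:
        return np.nan
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def _rel_frob(a: np.ndarray, b: np.ndarray) -> float:
    denom = np.linalg.norm(a)
    if denom == 0:
        return np.nan
    return float(np.linalg.norm(a - b) / denom)


def evaluate(truth: np.ndarray, completed: np.ndarray, pattern: np.ndarray) -> dict:
    """Pearson correlation and relative Frobenius distance between truth
    and reconstruction over all, observed and hidden entries.  Undefined
    correlations (constant scope) are reported as NaN."""
    truth = np.asarray(truth, dtype=float)
    completed = np.asarray(completed, dtype=float)
    pattern = np.asarray(pattern, dtype=bool)
    if truth.shape != completed.shape or truth.shape != pattern.shape:
        raise EegRepairError("evaluate: shape mismatch")
    obs, hid = pattern, ~pattern
    return {
        "pearson_all": _pearson(truth.ravel(), completed.ravel()),
        "pearson_observed": _pearson(truth[obs], completed[obs]),
        "pearson_missing": _pearson(truth[hid], completed[hid]),
        "frobenius_all": _rel_frob(truth.ravel(), completed.ravel()),
        "frobenius_missing": _rel_frob(truth[hid], completed[hid]),
        "n_missing": int(hid.sum()),
    }


def chance_level(
    truth: np.ndarray, pattern: np.ndarray, n_perm: int = 200, seed: int = 0
) -> tuple[float, float]:
    """Permutation chance thresholds: the 95th percentile of correlations
    (and 5th percentile of relative Frobenius distances) between the block
    and entry-permuted versions of itself."""
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    flat = np.asarray(truth, dtype=float).ravel()
    corrs = np.empty(n_perm)
    dists = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(flat)
        corrs[i] = _pearson(flat, perm)
        dists[i] = _rel_frob(flat, perm)
    return float(np.nanpercentile(corrs, 95)), float(np.nanpercentile(dists, 5))


@dataclass
class BenchmarkResult:
    """Per-iteration metric records of a bootstrapped sweep."""

    records: pd.DataFrame
    chance: dict = field(default_factory=dict)  # Tk -> (C_chance, D_chance)
    n_resampled: int = 0
    metadata: dict = field(default_factory=dict)

    def medians(self, metric: str = "pearson_missing") -> pd.DataFrame:
        return (
            self.records.groupby(["block_size", "rank", "severity_class"])[metric]
            .median()
            .reset_index()
        )

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    def summary(self) -> str:
        med = self.records.median(numeric_only=True)
        lines = [
            "Benchmark sweep results",
            "=======================",
            f"iterations:            {len(self.records)}",
            f"resampled draws:       {self.n_resampled}",
            f"median pearson_all:    {med.get('pearson_all', np.nan):.4f}",
            f"median pearson_obs:    {med.get('pearson_observed', np.nan):.4f}",
            f"median pearson_miss:   {med.get('pearson_missing', np.nan):.4f}",
            f"median frobenius_all:  {med.get('frobenius_all', np.nan):.4f}",
            f"median frobenius_miss: {med.get('frobenius_missing', np.nan):.4f}",
        ]
        return "\n".join(lines)


def sweep(
    libraries,
    r_grid=(4, 8, 12, 16, 20),
    n_boot: int = 50,
    seed: int = 0,
    q_classes=(1, 2, 3, 4, 5),
    max_retries: int = 20,
    max_iter: int = 200,
    tol: float = 1e-6,
    compute_chance: bool = True,
) -> BenchmarkResult:
    """Bootstrapped (block size x severity x rank) sweep.

    ``libraries`` is a single :class:`BlockLibrary` or a dict keyed by
    block size.  For every cell, ``n_boot`` surrogates are drawn with
    replacement, completed and scored.  Draws whose overlaid mask leaves a
    row or column fully hidden are resampled up to ``max_retries`` times
    (the resample count is reported).  Each cell's random stream derives
    deterministically from ``seed`` and the cell coordinates, so cells are
    reproducible independently.
    """
    if isinstance(libraries, BlockLibrary):
        libraries = {libraries.block_size: libraries}
    rows = []
    n_resampled = 0
    chance = {}
    for tki, (tk, lib) in enumerate(sorted(libraries.items())):
        if compute_chance and lib.good:
            chance[tk] = chance_level(
                lib.good[0].values, lib.good[0].mask, seed=seed + 7919 * tki
            )
        for q in q_classes:
            bads = lib.bad_in_class(q)
            if not bads or not lib.good:
                continue
            for r in r_grid:
                rng = np.random.default_rng([seed, tki, int(q), int(r)])
                for it in range(n_boot):
                    rec_row = {
                        "block_size": tk, "severity_class": q,
                        "rank": r, "iteration": it,
                    }
                    done = False
                    for _ in range(max_retries):
                        good = lib.good[rng.integers(len(lib.good))]
                        amask = bads[rng.integers(len(bads))]
                        surrogate, truth = make_surrogate(good, amask)
                        if not surrogate.is_completable():
                            n_resampled += 1
                            continue
                        try:
                            res = complete(surrogate, min(r, *surrogate.shape),
                                           max_iter=max_iter, tol=tol)
                        except (InfeasibleBlockError, SingularSystemError):
                            n_resampled += 1
                            continue
                        rec_row.update(evaluate(truth, res.completed,
                                                surrogate.mask))
                        rec_row["severity"] = amask.severity
                        rec_row["iterations"] = res.iterations
                        rec_row["final_cost"] = res.final_cost
                        done = True
                        break
                    if done:
                        rows.append(rec_row)
    return BenchmarkResult(
        records=pd.DataFrame(rows),
        chance=chance,
        n_resampled=n_resampled,
        metadata={
            "seed": seed,
            "n_boot": n_boot,
            "r_grid": list(r_grid),
            "frobenius_normalization": "||truth||_F",
        },
    )
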