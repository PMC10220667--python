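"""Tests of the surrogate-artifact benchmarking machinery."""

import itertools

import numpy as np
import pytest
import scipy.stats

import eegrepair as er
from eegrepair import (
    ArtifactMask,
    MaskedMatrix,
    Recording,
    build_library,
    chance_level,
    evaluate,
    make_surrogate,
    merge_libraries,
    quantile_classes,
    sweep,
)

from conftest import random_low_rank


class TestQuantileClasses:
    def test_even_split(self):
        labels, edges, degen = quantile_classes(np.arange(1.0, 101.0))
        counts = np.bincount(labels)[1:]
        assert list(counts) == [20] * 5
        assert not degen

    def test_degenerate_flagged(self):
        labels, _, degen = quantile_classes([3.0, 3.0, 3.0, 3.0])
        assert degen

    def test_sizes_differ_by_at_most_one(self, rng):
        sev = rng.uniform(0, 50, size=103)
        labels, _, _ = quantile_classes(sev)
        counts = np.bincount(labels)[1:]
        assert counts.max() - counts.min() <= 1

    def test_classes_ordered_by_severity(self, rng):
        sev = rng.uniform(0, 50, size=60)
        labels, _, _ = quantile_classes(sev)
        for a, b in itertools.combinations(range(1, 6), 2):
            assert sev[labels == a].max() <= sev[labels == b].min() + 1e-12


class TestBuildLibrary:
    def test_clean_recording_all_good(self, rng):
        rec = Recording(rng.normal(size=(8, 1200)), fs=250.0)
        lib = build_library(rec, 120, 8, seed=0)
        assert len(lib.bad) == 0 and len(lib.good) > 0
        assert all(b.mask.all() for b in lib.good)

    def test_one_bad_entry_per_window(self, rng):
        c, tk = 8, 60
        rec = Recording(rng.normal(size=(c, 1200)), fs=250.0)
        rec.mask[0, ::tk] = False  # exactly one bad entry per Tk window
        lib = build_library(rec, tk, 10, seed=1)
        assert len(lib.good) == 0
        assert all(b.severity == pytest.approx(100.0 / (c * tk)) for b in lib.bad)

    def test_blocks_do_not_overlap(self, rng):
        rec = Recording(rng.normal(size=(4, 2000)), fs=250.0)
        lib = build_library(rec, 100, 50, seed=2)
        assert len(lib.good) + len(lib.bad) <= 20

    def test_bursty_severity_right_skewed(self):
        spec = er.GeneratorSpec(n_channels=32, n_samples=20000)
        rec, _ = er.generate_recording(spec, 5)
        rec.mask = er.generate_mask(spec, 6)
        lib = build_library(rec, 120, 160, seed=7)
        sev = lib.severities
        assert np.median(sev) < sev.mean()

    def test_merge_reassigns_classes(self, rng):
        recs = [Recording(rng.normal(size=(4, 800)), fs=250.0) for _ in range(2)]
        for rec in recs:
            bad = rng.random(rec.data.shape) < 0.02
            rec.mask = ~bad
        libs = [build_library(r, 80, 10, seed=i) for i, r in enumerate(recs)]
        merged = merge_libraries(libs)
        n_bad = len(merged.bad)
        assert n_bad == sum(len(l.bad) for l in libs)
        counts = np.bincount([b.severity_class for b in merged.bad])[1:]
        assert counts.max() - counts.min() <= 1


class TestMakeSurrogate:
    def test_all_ones_pattern_identity(self, rng):
        good = MaskedMatrix(rng.normal(size=(4, 5)), np.ones((4, 5), bool))
        sur, truth = make_surrogate(good, ArtifactMask(np.ones((4, 5), bool)))
        assert np.array_equal(sur.values, good.values)
        assert np.array_equal(truth, good.values)

    def test_all_zero_pattern_hides_everything(self, rng):
        good = MaskedMatrix(rng.normal(size=(4, 5)), np.ones((4, 5), bool))
        sur, _ = make_surrogate(good, ArtifactMask(np.zeros((4, 5), bool)))
        assert not sur.mask.any()
        assert np.array_equal(sur.values, np.zeros((4, 5)))

    def test_hand_3x3(self):
        vals = np.arange(9.0).reshape(3, 3)
        pattern = np.array([[1, 0, 1], [0, 1, 0], [1, 1, 1]], dtype=bool)
        good = MaskedMatrix(vals, np.ones((3, 3), bool))
        sur, truth = make_surrogate(good, ArtifactMask(pattern))
        assert np.array_equal(sur.values, vals * pattern)
        assert np.array_equal(sur.mask, pattern)

    def test_severity_conserved(self, rng):
        pattern = rng.random((6, 8)) > 0.3
        am = ArtifactMask(pattern)
        good = MaskedMatrix(rng.normal(size=(6, 8)), np.ones((6, 8), bool))
        sur, truth = make_surrogate(good, am)
        assert sur.severity() == pytest.approx(am.severity)
        ev = evaluate(truth, truth, pattern)
        assert ev["n_missing"] == int((~pattern).sum())

    def test_shape_mismatch_raises(self, rng):
        good = MaskedMatrix(rng.normal(size=(4, 5)), np.ones((4, 5), bool))
        with pytest.raises(er.EegRepairError):
            make_surrogate(good, ArtifactMask(np.ones((5, 4), bool)))


class TestEvaluate:
    def test_perfect_reconstruction(self, rng):
        truth = rng.normal(size=(5, 6))
        pattern = rng.random((5, 6)) > 0.3
        ev = evaluate(truth, truth.copy(), pattern)
        for scope in ("all", "observed", "missing"):
            assert ev[f"pearson_{scope}"] == pytest.approx(1.0)
        assert ev["frobenius_all"] == 0.0
        assert ev["frobenius_missing"] == 0.0

    def test_sign_flip(self, rng):
        truth = rng.normal(size=(5, 6))
        pattern = rng.random((5, 6)) > 0.3
        ev = evaluate(truth, -truth, pattern)
        assert ev["pearson_all"] == pytest.approx(-1.0)
        assert ev["frobenius_all"] == pytest.approx(2.0)

    def test_matches_textbook_formulas(self, rng):
        truth = rng.normal(size=(6, 7))
        completed = truth + rng.normal(size=(6, 7))
        pattern = rng.random((6, 7)) > 0.4
        ev = evaluate(truth, completed, pattern)
        hid = ~pattern
        r_ref = scipy.stats.pearsonr(truth[hid], completed[hid]).statistic
        d_ref = np.linalg.norm(truth[hid] - completed[hid]) / np.linalg.norm(truth[hid])
        assert ev["pearson_missing"] == pytest.approx(r_ref, abs=1e-12)
        assert ev["frobenius_missing"] == pytest.approx(d_ref, abs=1e-12)

    def test_constant_scope_reported_missing(self):
        truth = np.ones((3, 3))
        ev = evaluate(truth, truth * 2, np.ones((3, 3), bool))
        assert np.isnan(ev["pearson_all"])


class TestChanceLevel:
    def test_iid_block_near_zero(self, rng):
        truth = rng.normal(size=(40, 100))
        c, d = chance_level(truth, np.ones_like(truth, bool), n_perm=300, seed=0)
        assert abs(c) < 0.1
        assert d > 1.0  # permuted reconstructions are far in distance

    def test_reproducible(self, rng):
        truth = rng.normal(size=(10, 10))
        a = chance_level(truth, np.ones_like(truth, bool), n_perm=100, seed=5)
        b = chance_level(truth, np.ones_like(truth, bool), n_perm=100, seed=5)
        assert a == b

    def test_matches_exhaustive_on_tiny_block(self, rng):
        truth = rng.normal(size=(2, 3))
        flat = truth.ravel()
        corrs = [np.corrcoef(flat, np.array(p))[0, 1]
                 for p in itertools.permutations(flat)]
        exact = np.percentile(corrs, 95)
        c, _ = chance_level(truth, np.ones((2, 3), bool), n_perm=2000, seed=3)
        assert c == pytest.approx(exact, abs=0.1)


class TestSweep:
    @pytest.fixture(scope="class")
    def small_library(self):
        spec = er.GeneratorSpec(n_channels=16, n_samples=12000, latent_rank=4)
        rec, _ = er.generate_recording(spec, 31)
        rec.mask = er.generate_mask(spec, 32)
        return build_library(rec, 60, 150, seed=33)

    def test_result_shape_one_cell(self, small_library):
        res = sweep(small_library, r_grid=(4,), n_boot=2, seed=1,
                    q_classes=(1,), compute_chance=False)
        assert len(res.records) == 2
        assert set(res.records["rank"]) == {4}

    def test_seed_reproducibility(self, small_library):
        a = sweep(small_library, r_grid=(4,), n_boot=3, seed=9,
                  q_classes=(1, 3), compute_chance=False)
        b = sweep(small_library, r_grid=(4,), n_boot=3, seed=9,
                  q_classes=(1, 3), compute_chance=False)
        assert a.records.equals(b.records)

    def test_metrics_in_range(self, small_library):
        res = sweep(small_library, r_grid=(4,), n_boot=4, seed=2,
                    compute_chance=False)
        p = res.records["pearson_missing"].dropna()
        assert ((p >= -1) & (p <= 1)).all()
        assert (res.records["frobenius_missing"].dropna() >= 0).all()
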