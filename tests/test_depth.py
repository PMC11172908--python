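import numpy as np
import pytest

from cnvpopscan.cohort import GCBias, RegionSpec, plant_truth, simulate_depth
from cnvpopscan.depth import call_sample_cnvs, gc_correct, normalize_copy_number
from cnvpopscan.errors import ConfigurationError, InputError
from cnvpopscan.evaluate import call_recovery, gc_residual_correlation
from cnvpopscan.genome import make_windowed_genome
from cnvpopscan.matrix import CopyNumberMatrix, DepthMatrix


def cn_matrix_from_rows(rows, window_size=800):
    """A CopyNumberMatrix on a flat single-chromosome genome from raw rows."""
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    g = make_windowed_genome({"chr1": window_size * rows.shape[1]}, window_size)
    samples = [f"s{i}" for i in range(rows.shape[0])]
    return CopyNumberMatrix(samples=samples, cn=rows, genome=g)


class TestGcCorrect:
    def test_uniform_gc_is_identity(self):
        g = make_windowed_genome({"chr1": 8000})
        g.windows["gc"] = 0.5
        dm = DepthMatrix(["s0"], np.arange(10, dtype=float)[None, :] + 1, g)
        out = gc_correct(dm, g)
        np.testing.assert_allclose(out.values, dm.values)

    def test_two_bin_median_ratio(self):
        # bin medians 50 and 100, global median 75 -> factors 1.5 and 0.75
        g = make_windowed_genome({"chr1": 8000})
        g.windows["gc"] = [0.3] * 5 + [0.7] * 5
        row = np.array([40.0, 45, 50, 55, 60, 90, 95, 100, 105, 110])
        dm = DepthMatrix(["s0"], row[None, :], g)
        out = gc_correct(dm, g, n_bins=2)
        np.testing.assert_allclose(out.values[0, :5], row[:5] * 1.5)
        np.testing.assert_allclose(out.values[0, 5:], row[5:] * 0.75)

    def test_zero_median_bin_left_unchanged_with_warning(self):
        g = make_windowed_genome({"chr1": 8000})
        g.windows["gc"] = [0.3] * 5 + [0.7] * 5
        row = np.array([0.0, 0, 0, 0, 0, 90, 95, 100, 105, 110])
        dm = DepthMatrix(["s0"], row[None, :], g)
        with pytest.warns(UserWarning, match="zero median"):
            out = gc_correct(dm, g, n_bins=2)
        np.testing.assert_allclose(out.values[0, :5], row[:5])

    def test_removes_injected_quadratic_bias(self):
        g = make_windowed_genome({"chr1": 800 * 1500}, gc_profile_seed=2)
        truth = plant_truth(g, {"A": 5}, [], seed=0)
        dm = simulate_depth(g, truth, mean_coverage=60, gc_bias=GCBias(0.25, 1.5), seed=4)
        before = gc_residual_correlation(dm, g).abs()
        after = gc_residual_correlation(gc_correct(dm, g), g).abs()
        assert before.min() > 0.3
        assert after.max() < 0.1

    def test_empty_matrix_rejected(self):
        g = make_windowed_genome({"chr1": 8000})
        with pytest.raises(InputError):
            gc_correct(DepthMatrix([], np.zeros((0, 10)), g), g)


class TestNormalizeCopyNumber:
    def test_median_window_maps_to_two_and_double_to_four(self):
        g = make_windowed_genome({"chr1": 4000})
        dm = DepthMatrix(["s0"], np.array([[50.0, 50, 50, 50, 100]]), g)
        cn = normalize_copy_number(dm)
        assert cn.cn[0, 0] == pytest.approx(2.0)
        assert cn.cn[0, 4] == pytest.approx(4.0)

    def test_per_sample_median_cn_near_two(self, demo_state):
        cnmat = demo_state["cnmat"]
        unmasked = cnmat.genome.unmasked
        for row in cnmat.cn:
            assert 1.9 <= np.median(row[unmasked]) <= 2.1

    def test_scaling_invariance(self, flat_genome, rng):
        vals = rng.poisson(80, size=(2, flat_genome.n_windows)).astype(float) + 1
        dm1 = DepthMatrix(["a", "b"], vals, flat_genome)
        scaled = vals.copy()
        scaled[0] *= 7.3
        dm2 = DepthMatrix(["a", "b"], scaled, flat_genome)
        np.testing.assert_allclose(
            normalize_copy_number(dm1).cn, normalize_copy_number(dm2).cn
        )

    def test_planted_deletion_recovered_in_cn_units(self):
        g = make_windowed_genome({"chr1": 800 * 400}, gc_profile_seed=1)
        spec = RegionSpec("chr1", 8000, 40_000, "loss", {"A": 1.0}, carrier_cn=1)
        truth = plant_truth(g, {"A": 5}, [spec], seed=0)
        dm = simulate_depth(g, truth, mean_coverage=200, seed=5)
        cn = normalize_copy_number(gc_correct(dm, g))
        sl = g.window_range("chr1", 8000, 40_000)
        assert cn.cn[:, sl].mean() == pytest.approx(1.0, abs=0.2)

    def test_all_zero_sample_rejected_by_name(self, flat_genome):
        vals = np.ones((2, flat_genome.n_windows))
        vals[1] = 0.0
        dm = DepthMatrix(["good", "dead"], vals, flat_genome)
        with pytest.raises(InputError, match="dead"):
            normalize_copy_number(dm)


def brute_force_calls(row, loss_max, gain_min, min_windows, max_gap):
    """Independent oracle: enumerate seed runs directly on one cn row."""
    kinds = [
        "loss" if v <= loss_max else "gain" if v >= gain_min else None for v in row
    ]
    calls = []
    for kind in ("loss", "gain"):
        seeds = [i for i, k in enumerate(kinds) if k == kind]
        runs = []
        for i in seeds:
            if (
                runs
                and i - runs[-1][-1] - 1 <= max_gap
                and not any(
                    kinds[j] not in (None, kind) for j in range(runs[-1][-1] + 1, i)
                )
            ):
                runs[-1].append(i)
            else:
                runs.append([i])
        for run in runs:
            if len(run) >= min_windows:
                calls.append((kind, run[0], run[-1]))
    return sorted(calls, key=lambda c: c[1])


class TestCallSampleCnvs:
    def test_diploid_row_gives_no_calls(self):
        cnmat = cn_matrix_from_rows([[2.0] * 8])
        assert call_sample_cnvs(cnmat) == []

    def test_single_loss_run(self):
        cnmat = cn_matrix_from_rows([[2, 2, 0.9, 1.0, 1.1, 2, 2]])
        calls = call_sample_cnvs(cnmat, loss_max=1.5, min_windows=2, max_gap_windows=0)
        assert len(calls) == 1
        c = calls[0]
        assert (c.kind, c.start, c.end, c.n_windows) == ("loss", 2 * 800, 5 * 800, 3)
        assert c.mean_cn == pytest.approx(1.0)

    def test_gap_bridging_merges_gain_runs(self):
        row = [2, 3.2, 3.1, 2.2, 3.4, 3.0, 2]
        cnmat = cn_matrix_from_rows([row])
        merged = call_sample_cnvs(cnmat, max_gap_windows=1)
        assert len(merged) == 1 and merged[0].kind == "gain"
        assert (merged[0].start, merged[0].end) == (800, 6 * 800)
        split = call_sample_cnvs(cnmat, max_gap_windows=0)
        assert len(split) == 2

    def test_opposite_kind_seed_blocks_bridging(self):
        row = [3.0, 3.0, 1.0, 3.0, 3.0]
        cnmat = cn_matrix_from_rows([row])
        calls = call_sample_cnvs(cnmat, max_gap_windows=1, min_windows=2)
        gains = [c for c in calls if c.kind == "gain"]
        assert len(gains) == 2

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 40))
            row = rng.choice([0.5, 1.0, 1.8, 2.0, 2.2, 3.0, 4.0], size=n)
            min_windows = int(rng.integers(1, 4))
            max_gap = int(rng.integers(0, 3))
            cnmat = cn_matrix_from_rows([row])
            got = [
                (c.kind, c.start // 800, c.end // 800 - 1)
                for c in call_sample_cnvs(
                    cnmat, min_windows=min_windows, max_gap_windows=max_gap
                )
            ]
            expected = brute_force_calls(row, 1.5, 2.5, min_windows, max_gap)
            assert sorted(got) == sorted(expected)

    def test_calls_nonoverlapping_and_kind_consistent(self, demo_state):
        by_sample = {}
        for c in demo_state["calls"]:
            by_sample.setdefault((c.sample, c.chrom), []).append(c)
            assert (c.kind == "loss") == (c.mean_cn < 2)
            assert c.end > c.start and c.start % 800 == 0
        for calls in by_sample.values():
            calls.sort(key=lambda c: c.start)
            for a, b in zip(calls, calls[1:]):
                assert a.end <= b.start

    def test_recovery_of_planted_carrier_regions(self, demo_state):
        """At 50 reads/window, nearly all planted carrier regions of >= 3
        windows are recalled per sample with reciprocal overlap >= 0.8."""
        cr = call_recovery(demo_state["truth"], demo_state["calls"])
        assert cr["recovered"].mean() >= 0.95

    def test_threshold_validation(self):
        cnmat = cn_matrix_from_rows([[2.0] * 5])
        with pytest.raises(ConfigurationError):
            call_sample_cnvs(cnmat, loss_max=2.5)
        with pytest.raises(ConfigurationError):
            call_sample_cnvs(cnmat, gain_min=1.5)
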