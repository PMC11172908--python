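import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnvpopscan.cnvr import (
    CNVR,
    MergeConfig,
    allele_frequencies,
    build_cnvrs,
    candidate_windows,
    classify_cnvr,
    filter_cnvrs,
    genotype_cnvr,
    merge_to_cnvrs,
    silhouette_cn,
)
from cnvpopscan.errors import AnnotationError, ConfigurationError, InputError
from cnvpopscan.evaluate import carrier_freq_errors, match_truth_to_cnvrs
from cnvpopscan.genome import make_windowed_genome
from cnvpopscan.matrix import CopyNumberMatrix


def cn_matrix(rows, window_size=800, masked=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    g = make_windowed_genome({"chr1": window_size * rows.shape[1]}, window_size)
    if masked is not None:
        g.windows["masked"] = masked
        rows = rows.copy()
        rows[:, np.asarray(masked, dtype=bool)] = np.nan
    return CopyNumberMatrix([f"s{i}" for i in range(rows.shape[0])], rows, g)


class TestCandidateWindows:
    def test_all_diploid_no_flags(self):
        m = cn_matrix(np.full((10, 6), 2.0))
        assert not candidate_windows(m, MergeConfig()).any()

    def test_fraction_strictly_above_threshold(self):
        rows = np.full((50, 3), 2.0)
        rows[:3, 1] = 1.0   # 3/50 = 0.06 > 0.05 -> flagged
        rows[:2, 2] = 1.0   # 2/50 = 0.04       -> not flagged
        flags = candidate_windows(cn_matrix(rows), MergeConfig(min_variant_freq=0.05))
        assert flags.tolist() == [False, True, False]

    def test_masked_windows_never_flagged(self):
        rows = np.full((4, 5), 0.0)
        m = cn_matrix(rows, masked=[0, 0, 1, 0, 0])
        flags = candidate_windows(m, MergeConfig())
        assert flags.tolist() == [True, True, False, True, True]


class TestMergeToCnvrs:
    def test_single_run_spans_flagged_windows(self):
        rows = np.full((10, 8), 2.0)
        rows[:5, 2:5] = 1.0
        m = cn_matrix(rows)
        cfg = MergeConfig(min_variant_freq=0.2)
        flags = candidate_windows(m, cfg)
        assert merge_to_cnvrs(flags, m, cfg) == [("chr1", 2, 5)]

    def test_correlated_adjacent_runs_merge(self):
        rows = np.full((10, 9), 2.0)
        rows[:5, 1:3] = 1.0     # run 1
        rows[:5, 5:7] = 1.0     # run 2, same samples -> r = 1.0
        m = cn_matrix(rows)
        cfg = MergeConfig(min_variant_freq=0.2, max_gap_windows=0, corr_merge_gap_windows=3)
        out = merge_to_cnvrs(candidate_windows(m, cfg), m, cfg)
        assert out == [("chr1", 1, 7)]

    def test_anticorrelated_runs_do_not_merge(self):
        rows = np.full((10, 9), 2.0)
        rows[:5, 1:3] = 1.0
        rows[5:, 5:7] = 1.0     # complementary samples -> r = -1
        m = cn_matrix(rows)
        cfg = MergeConfig(min_variant_freq=0.2, max_gap_windows=0, corr_merge_gap_windows=3)
        out = merge_to_cnvrs(candidate_windows(m, cfg), m, cfg)
        assert out == [("chr1", 1, 3), ("chr1", 5, 7)]

    def test_distant_runs_never_correlation_merged(self):
        rows = np.full((10, 20), 2.0)
        rows[:5, 1:3] = 1.0
        rows[:5, 15:17] = 1.0
        m = cn_matrix(rows)
        cfg = MergeConfig(min_variant_freq=0.2, max_gap_windows=0, corr_merge_gap_windows=3)
        out = merge_to_cnvrs(candidate_windows(m, cfg), m, cfg)
        assert len(out) == 2


class TestGenotype:
    def test_median_and_rounding(self):
        m = cn_matrix([[1.1, 0.9, 1.0]])
        real, integer = genotype_cnvr(m, ("chr1", 0, 3))
        assert real["s0"] == pytest.approx(1.0) and integer["s0"] == 1

    def test_diploid(self):
        m = cn_matrix([[2.0, 2.0]])
        _, integer = genotype_cnvr(m, ("chr1", 0, 2))
        assert integer["s0"] == 2

    def test_half_away_from_zero_rounding(self):
        m = cn_matrix([[3.6, 3.4, 4.1]])
        real, integer = genotype_cnvr(m, ("chr1", 0, 3))
        assert real["s0"] == pytest.approx(3.6) and integer["s0"] == 4

    def test_fully_masked_interval_rejected(self):
        m = cn_matrix([[2.0, 2.0, 2.0]], masked=[0, 1, 1])
        with pytest.raises(AnnotationError):
            genotype_cnvr(m, ("chr1", 1, 3))


class TestAlleleFrequencies:
    def test_all_diploid(self):
        assert allele_frequencies({f"s{i}": 2 for i in range(7)}) == (0.0, 0.0)

    def test_allele_mode_counts_alleles(self):
        cns = {f"s{i}": 2 for i in range(10)}
        cns["s0"] = 0   # homozygous deletion = 2 loss alleles
        loss, gain = allele_frequencies(cns, mode="allele")
        assert loss == pytest.approx(2 / 20) and gain == 0.0

    def test_carrier_mode_counts_samples(self):
        cns = {f"s{i}": (3 if i < 10 else 2) for i in range(20)}
        loss, gain = allele_frequencies(cns, mode="carrier")
        assert gain == pytest.approx(0.5) and loss == 0.0

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            allele_frequencies({})


def independent_classification(loss_af, gain_af):
    """Separately coded Loss/Gain/Both predicate (oracle)."""
    is_loss = loss_af > 0.05 and loss_af <= 0.95 and gain_af <= 0.01
    is_gain = gain_af > 0.05 and gain_af < 0.95 and loss_af <= 0.01
    is_both = gain_af > 0.05 and gain_af < 0.95 and loss_af > 0.05 and loss_af <= 0.95
    if is_loss:
        return "loss"
    if is_gain:
        return "gain"
    if is_both:
        return "both"
    return "none"


class TestClassification:
    @pytest.mark.parametrize(
        "loss_af,gain_af,expected",
        [
            (0.50, 0.00, "loss"),
            (0.00, 0.50, "gain"),
            (0.20, 0.20, "both"),
            (0.05, 0.00, "none"),   # strict lower bound
            (0.95, 0.00, "loss"),   # inclusive upper bound for loss
            (0.00, 0.95, "none"),   # exclusive upper bound for gain
            (0.96, 0.00, "none"),
            (0.02, 0.02, "none"),
        ],
    )
    def test_examples(self, loss_af, gain_af, expected):
        assert classify_cnvr(loss_af, gain_af) == expected

    @given(
        st.floats(min_value=0, max_value=1, allow_nan=False),
        st.floats(min_value=0, max_value=1, allow_nan=False),
    )
    @settings(max_examples=300, derandomize=True)
    def test_matches_independent_predicate(self, loss_af, gain_af):
        assert classify_cnvr(loss_af, gain_af) == independent_classification(loss_af, gain_af)

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            classify_cnvr(-0.1, 0.5)


def brute_force_silhouette(reals, labels):
    """Textbook silhouette with singleton convention s(i)=0."""
    n = len(reals)
    scores = []
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            scores.append(0.0)
            continue
        a = np.mean([abs(reals[i] - reals[j]) for j in own])
        b = min(
            np.mean([abs(reals[i] - reals[j]) for j in range(n) if labels[j] == lab])
            for lab in set(labels)
            if lab != labels[i]
        )
        scores.append((b - a) / max(a, b) if max(a, b) > 0 else 0.0)
    return float(np.mean(scores))


class TestSilhouette:
    def test_two_clean_clusters(self):
        reals = {"a": 1.0, "b": 1.0, "c": 3.0, "d": 3.0}
        ints = {"a": 1, "b": 1, "c": 3, "d": 3}
        assert silhouette_cn(reals, ints) == pytest.approx(1.0)

    def test_single_cluster_degenerate_pass(self):
        reals = {"a": 1.9, "b": 2.0, "c": 2.1, "d": 2.2}
        ints = {k: 2 for k in reals}
        assert silhouette_cn(reals, ints) == 1.0

    def test_all_singletons_score_zero(self):
        reals = {"a": 0.9, "b": 2.0, "c": 3.1}
        ints = {"a": 1, "b": 2, "c": 3}
        assert silhouette_cn(reals, ints) == 0.0

    def test_matches_brute_force(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 20))
            reals = rng.uniform(0, 4, size=n)
            labels = np.array([max(0, int(np.floor(v + 0.5))) for v in reals])
            if len(set(labels)) in (1, n):
                continue
            got = silhouette_cn(
                {f"s{i}": reals[i] for i in range(n)},
                {f"s{i}": int(labels[i]) for i in range(n)},
            )
            assert got == pytest.approx(brute_force_silhouette(reals, labels), abs=1e-9)

    def test_needs_two_samples(self):
        with pytest.raises(InputError):
            silhouette_cn({"a": 2.0}, {"a": 2})


def make_cnvr(type_, length, silhouette=0.9):
    return CNVR(
        id=f"chr1:1-{length}",
        chrom="chr1",
        start=0,
        end=length,
        per_sample_cn_real={},
        per_sample_cn_int={},
        loss_af=0.5 if type_ in ("loss", "both") else 0.0,
        gain_af=0.5 if type_ in ("gain", "both") else 0.0,
        type=type_,
        silhouette=silhouette,
    )


class TestFilters:
    def test_length_caps_by_type(self):
        kept = filter_cnvrs(
            [
                make_cnvr("loss", 60_000),        # above the 50 kb deletion cap
                make_cnvr("loss", 50_000),
                make_cnvr("gain", 400_000),       # within the 500 kb duplication cap
                make_cnvr("both", 60_000),        # above the 50 kb complex cap
                make_cnvr("none", 10_000),
            ]
        )
        assert [(c.type, c.length) for c in kept] == [("loss", 50_000), ("gain", 400_000)]

    def test_silhouette_strictly_above(self):
        assert filter_cnvrs([make_cnvr("loss", 1000, silhouette=0.6)]) == []
        assert len(filter_cnvrs([make_cnvr("loss", 1000, silhouette=0.601)])) == 1


class TestBuildOnDemoCohort:
    def test_planted_regions_map_one_to_one(self, demo_state):
        truth, cnvrs = demo_state["truth"], demo_state["cnvrs"]
        matched = match_truth_to_cnvrs(truth, cnvrs, min_ro=0.8)
        hits = [c for c in matched.values() if c is not None]
        assert len(hits) >= 0.95 * len(truth.regions)
        assert len({c.id for c in hits}) == len(hits)  # one CNVR per region

    def test_carrier_frequencies_recovered(self, demo_state):
        errs = carrier_freq_errors(demo_state["truth"], demo_state["cnvrs"])
        assert errs["abs_error"].max() <= 0.1

    def test_every_retained_type_satisfies_its_predicate(self, demo_state):
        for c in demo_state["cnvrs"]:
            assert c.type == classify_cnvr(c.loss_af, c.gain_af)
            assert c.silhouette > 0.6
            assert c.length == c.end - c.start

    def test_deterministic_rebuild(self, demo_state):
        cnmat = demo_state["cnmat"]
        cfg = MergeConfig(min_variant_freq=0.18)
        a = build_cnvrs(cnmat, cfg)
        b = build_cnvrs(cnmat, cfg)
        assert [(c.id, c.type, c.loss_af, c.gain_af) for c in a] == [
            (c.id, c.type, c.loss_af, c.gain_af) for c in b
        ]


def test_merge_config_validation():
    with pytest.raises(ConfigurationError):
        MergeConfig(min_variant_freq=0.0)
    with pytest.raises(ConfigurationError):
        MergeConfig(corr_min=1.5)
    with pytest.raises(ConfigurationError):
        MergeConfig(max_gap_windows=-1)
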