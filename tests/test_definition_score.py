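"""Score engine vs brute-force oracle, binning determinism, and context analyses."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import cluster_regions, uniform_random_reads
from pistop.alphabet import STOP_CODONS, UNN
from pistop.definition_score import (
    ScoreConfig,
    bin_composition,
    bin_positions,
    compute_scores,
    correlate_five_three,
    motif_around,
    score_by_context,
)
from pistop.io_formats import Interval, IntervalSet, ReadRecord, SequenceSet
from pistop.synthetic_data import CleavageModel, simulate_phased_reads


def brute_force_scores(reads, region, config, end="five_prime"):
    """Literal re-implementation: for each x, sum f over i = x-10..x+20."""
    L = region.length
    f = [0.0] * L
    for r in reads:
        if r.contig != region.contig or r.strand != region.strand:
            continue
        g = r.five_prime if end == "five_prime" else r.downstream_of_three_prime
        if region.start <= g < region.end:
            off = g - region.start if region.strand == "+" else region.end - 1 - g
            f[off] += r.count
    rows = []
    for x in range(L):
        total = sum(
            f[i]
            for i in range(x - config.upstream_window, x + config.downstream_window + 1)
            if 0 <= i < L
        )
        s = f[x] / total if total > 0 else 0.0
        rows.append((f[x], total, s, total >= config.min_local_reads))
    return rows


def reads_from_offsets(contig, offsets_counts, strand="+", length=28, region_len=200):
    reads = []
    for off, n in offsets_counts.items():
        if strand == "+":
            start = off
            end = start + length
        else:
            end = region_len - off
            start = end - length
        reads.extend([ReadRecord(contig, start, end, strand, 1)] * n)
    return reads


class TestComputeScores:
    def test_isolated_peak_scores_one(self):
        region = Interval("c", 0, 200, "+", "r")
        reads = reads_from_offsets("c", {50: 120})
        scored = compute_scores(reads, [region], ScoreConfig())
        row = scored[scored["offset"] == 50].iloc[0]
        assert row["s"] == 1.0 and row["covered"]

    def test_zero_f_with_covered_window_scores_zero(self):
        region = Interval("c", 0, 200, "+", "r")
        reads = reads_from_offsets("c", {52: 150})
        scored = compute_scores(reads, [region], ScoreConfig())
        row = scored[scored["offset"] == 50].iloc[0]
        assert row["f"] == 0 and row["local_total"] == 150
        assert row["s"] == 0.0 and row["covered"]

    def test_hand_evaluated_window(self):
        # counts {x-1: 30, x: 60, x+5: 30} -> s(x) = 60/120
        region = Interval("c", 0, 200, "+", "r")
        reads = reads_from_offsets("c", {49: 30, 50: 60, 55: 30})
        scored = compute_scores(reads, [region], ScoreConfig())
        assert scored[scored["offset"] == 50].iloc[0]["s"] == pytest.approx(0.5)

    @pytest.mark.parametrize("strand", ["+", "-"])
    @pytest.mark.parametrize("end", ["five_prime", "downstream_of_three_prime"])
    def test_matches_brute_force_oracle(self, strand, end):
        rng = np.random.default_rng(42)
        region = Interval("c", 10, 190, strand, "r")
        reads = []
        for _ in range(300):
            start = int(rng.integers(0, 170))
            reads.append(ReadRecord("c", start, start + 28, strand, int(rng.integers(1, 5))))
        # include opposite-strand reads that must be ignored
        reads.append(ReadRecord("c", 50, 78, "-" if strand == "+" else "+", 99))
        config = ScoreConfig(min_local_reads=10)
        scored = compute_scores(reads, [region], config, end=end)
        oracle = brute_force_scores(reads, region, config, end=end)
        assert len(scored) == len(oracle)
        for row, (f, total, s, covered) in zip(scored.itertuples(), oracle):
            assert row.f == f
            assert row.local_total == total
            assert row.s == pytest.approx(s, rel=1e-12, abs=1e-15)
            assert row.covered == covered

    def test_f_totals_conserve_read_counts(self):
        region = Interval("c", 0, 200, "+", "r")
        reads = reads_from_offsets("c", {10: 7, 50: 3, 120: 11})
        scored = compute_scores(reads, [region], ScoreConfig())
        assert scored["f"].sum() == 21

    def test_short_region_flagged_truncated(self):
        region = Interval("c", 0, 25, "+", "tiny")
        with pytest.warns(UserWarning, match="truncated"):
            scored = compute_scores(
                [ReadRecord("c", 0, 20, "+")], [region], ScoreConfig()
            )
        assert scored["truncated"].all()

    def test_downstream_of_three_prime_counts_past_read_ends(self):
        region = Interval("c", 0, 200, "+", "r")
        reads = [ReadRecord("c", 10, 38, "+", 5)]
        scored = compute_scores(reads, [region], ScoreConfig(min_local_reads=1),
                                end="downstream_of_three_prime")
        assert scored[scored["offset"] == 38].iloc[0]["f"] == 5


class TestBinPositions:
    def _scored(self, s_values):
        n = len(s_values)
        return pd.DataFrame(
            {
                "contig": "c",
                "position": np.arange(n),
                "strand": "+",
                "region": "r",
                "offset": np.arange(n),
                "f": 0.0,
                "local_total": 100.0,
                "s": s_values,
                "covered": True,
                "truncated": False,
            }
        )

    def test_all_zero_scores_go_to_bin_zero(self):
        binned = bin_positions(self._scored([0.0] * 30))
        assert (binned["bin"] == 0).all()

    def test_forty_distinct_scores_make_bins_of_two(self):
        rng = np.random.default_rng(1)
        s = rng.uniform(0.01, 1.0, 40)
        binned = bin_positions(self._scored(s), ScoreConfig())
        sizes = binned[binned["bin"] > 0]["bin"].value_counts()
        assert sorted(sizes.unique()) == [2]
        assert set(sizes.index) == set(range(1, 21))

    def test_bins_ordered_by_score(self):
        rng = np.random.default_rng(2)
        s = np.concatenate([[0.0] * 10, rng.uniform(0.01, 1.0, 200)])
        binned = bin_positions(self._scored(s), ScoreConfig())
        means = binned[binned["bin"] > 0].groupby("bin")["s"].max().sort_index()
        assert means.is_monotonic_increasing
        assert (binned.loc[binned["s"] == 0, "bin"] == 0).all()

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        s = rng.uniform(0.0, 1.0, 100)
        df = self._scored(s)
        shuffled = df.sample(frac=1.0, random_state=7)
        a = bin_positions(df).sort_values("position")["bin"].to_numpy()
        b = bin_positions(shuffled).sort_values("position")["bin"].to_numpy()
        assert (a == b).all()

    def test_fewer_positions_than_bins_warns(self):
        with pytest.warns(UserWarning, match="fewer"):
            binned = bin_positions(self._scored([0.1, 0.2, 0.3]), ScoreConfig())
        assert set(binned["bin"]) == {1, 2, 3}

    def test_size_balance_with_heavy_ties(self):
        s = [0.5] * 37 + [0.9] * 3
        binned = bin_positions(self._scored(s), ScoreConfig())
        sizes = binned[binned["bin"] > 0]["bin"].value_counts()
        assert sizes.max() - sizes.min() <= 1  # equal sizes beat tie cohesion


@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=120), st.integers(0, 2**31 - 1))
@settings(max_examples=40, deadline=None, derandomize=True)
def test_bin_assignment_properties(scores, perm_seed):
    """Bin index is nondecreasing in s; bin 0 is exactly the zero-score set."""
    df = pd.DataFrame(
        {
            "contig": "c",
            "position": np.arange(len(scores)),
            "strand": "+",
            "region": "r",
            "offset": np.arange(len(scores)),
            "f": 0.0,
            "local_total": 100.0,
            "s": scores,
            "covered": True,
            "truncated": False,
        }
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        binned = bin_positions(df, ScoreConfig())
    assert ((binned["bin"] == 0) == (binned["s"] == 0.0)).all()
    ordered = binned[binned["bin"] > 0].sort_values(["s", "contig", "position"],
                                                    kind="mergesort")
    assert ordered["bin"].is_monotonic_increasing


@pytest.fixture(scope="module")
def unn_run(uniform_cluster):
    reads, _ = simulate_phased_reads(
        uniform_cluster, CleavageModel.uniform_u(), n_initiations=4000, seed=21
    )
    return compute_scores(reads, cluster_regions(uniform_cluster), ScoreConfig())


@pytest.fixture(scope="module")
def binned_run(uniform_cluster):
    model = CleavageModel(
        weights={**{k: 1.0 for k in UNN}, **{k: 6.0 for k in STOP_CODONS}},
        minus1_g_penalty=0.25,
    )
    reads, _ = simulate_phased_reads(uniform_cluster, model, n_initiations=4000, seed=24)
    scored = compute_scores(reads, cluster_regions(uniform_cluster), ScoreConfig())
    return bin_positions(scored, ScoreConfig())


class TestScoreByContext:
    def test_u_positions_outscore_other_bases(self, unn_run, uniform_cluster):
        ctx = score_by_context(unn_run, uniform_cluster, context="nucleotide")
        assert ctx.loc["T", "median"] > ctx.loc["A", "median"]
        assert ctx.loc["T", "median"] > ctx.loc["C", "median"]
        assert ctx.loc["T", "median"] > ctx.loc["G", "median"]

    def test_uniform_reads_show_no_context_signal(self, uniform_cluster):
        reads = uniform_random_reads(uniform_cluster, 60_000, 28, seed=22)
        scored = compute_scores(reads, cluster_regions(uniform_cluster),
                                ScoreConfig(min_local_reads=50))
        ctx = score_by_context(scored, uniform_cluster, context="nucleotide")
        spread = ctx["mean"].max() - ctx["mean"].min()
        assert spread < 0.2 * ctx["mean"].mean()

    def test_stop_weighted_run_elevates_stop_medians(self, uniform_cluster):
        model = CleavageModel(
            weights={**{k: 1.0 for k in UNN}, **{k: 4.0 for k in STOP_CODONS}}
        )
        reads, _ = simulate_phased_reads(uniform_cluster, model, n_initiations=4000, seed=23)
        scored = compute_scores(reads, cluster_regions(uniform_cluster), ScoreConfig())
        ctx = score_by_context(scored, uniform_cluster, context="trinucleotide")
        unn_ctx = ctx.loc[[k for k in UNN if k in ctx.index]]
        other = unn_ctx.drop(list(STOP_CODONS), errors="ignore")
        for stop in STOP_CODONS:
            assert unn_ctx.loc[stop, "median"] > other["median"].median()


class TestBinCompositionAndMotif:
    def test_bin_frequencies_sum_to_one(self, binned_run, uniform_cluster):
        tri, base = bin_composition(binned_run, uniform_cluster)
        assert np.allclose(tri.sum(axis=0), 1.0)
        assert np.allclose(base.sum(axis=0), 1.0)

    def test_stop_trinucleotides_peak_in_top_bin(self, binned_run, uniform_cluster):
        tri, _ = bin_composition(binned_run, uniform_cluster)
        stop_by_bin = tri.loc[list(STOP_CODONS)].sum(axis=0)
        assert stop_by_bin.idxmax() == 20

    def test_bin_zero_depleted_for_u(self, binned_run, uniform_cluster):
        _, base = bin_composition(binned_run, uniform_cluster)
        assert base.loc["T", 0] < base.loc["T", 20]

    def test_self_background_enrichment_is_one(self, binned_run, uniform_cluster):
        motif = motif_around(binned_run, uniform_cluster, bin_index=20, flank=5,
                             background="self")
        observed = motif.enrichment.to_numpy()
        assert np.allclose(observed[np.isfinite(observed)], 1.0)

    def test_minus1_g_depleted_in_top_bin(self, binned_run, uniform_cluster):
        motif = motif_around(binned_run, uniform_cluster, bin_index=20, flank=5)
        assert motif.enrichment.loc["G", -1] < 1.0

    def test_upstream_gc_bonus_enriches_gc(self, uniform_cluster):
        model = CleavageModel.uniform_u(upstream_gc_bonus=4.0)
        reads, _ = simulate_phased_reads(uniform_cluster, model, n_initiations=4000, seed=25)
        scored = compute_scores(reads, cluster_regions(uniform_cluster), ScoreConfig())
        binned = bin_positions(scored, ScoreConfig())
        motif = motif_around(binned, uniform_cluster, bin_index=20, flank=20)
        upstream = motif.enrichment.loc[["G", "C"], range(-18, -12)].mean().mean()
        assert upstream > 1.0


class TestCorrelateFiveThree:
    def test_identical_inputs_give_r_one(self, uniform_cluster):
        reads, _ = simulate_phased_reads(
            uniform_cluster, CleavageModel.uniform_u(), n_initiations=2000, seed=26
        )
        scored = compute_scores(reads, cluster_regions(uniform_cluster), ScoreConfig())
        result = correlate_five_three(scored, scored)
        assert result.r == pytest.approx(1.0)

    def test_phased_output_couples_five_and_three_scores(self, uniform_cluster):
        reads, _ = simulate_phased_reads(
            uniform_cluster, CleavageModel.uniform_u(), n_initiations=4000, seed=27,
            trimming="untrimmed",
        )
        regions = cluster_regions(uniform_cluster)
        s5 = compute_scores(reads, regions, ScoreConfig(), end="five_prime")
        s3 = compute_scores(reads, regions, ScoreConfig(),
                            end="downstream_of_three_prime")
        result = correlate_five_three(s5, s3)
        assert result.r > 0.8

    def test_too_few_shared_positions_flagged(self):
        empty = compute_scores([], IntervalSet([Interval("c", 0, 100, "+", "r")]),
                               ScoreConfig())
        result = correlate_five_three(empty, empty)
        assert not result.defined
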