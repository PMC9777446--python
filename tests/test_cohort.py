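import numpy as np
import pytest
from scipy import stats

from matcnv.calling import CNVCall
from matcnv.cohort import (chromosome_density, cluster_movs, compare_to_db,
                           mov_frequency_pct, reciprocal_overlap,
                           summarize_cohort)


def call(sample_id, chrom="chr6", start=168_340_000, end=168_580_000,
         ctype="gain"):
    return CNVCall(sample_id=sample_id, chrom=chrom, start_bp=start,
                   end_bp=end, type=ctype, length_bp=end - start,
                   deviation=1.0, z_score=9.0,
                   mean_ratio=1.5 if ctype == "gain" else 0.5)


def chi2_oracle(table):
    """Textbook Pearson chi-squared on an explicitly built 2x2 table."""
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    return float(((table - expected) ** 2 / expected).sum())


class TestClustering:
    def test_recurrent_identical_calls_form_one_mov(self):
        calls = [call(f"S{i}") for i in range(126)]
        (cl,) = cluster_movs(calls, cohort_size=6422)
        assert cl.is_mov
        assert cl.n_occurrences == 126
        assert cl.frequency_pct == 1.962
        assert (cl.start_bp, cl.end_bp) == (168_340_000, 168_580_000)

    def test_singleton_is_not_a_mov(self):
        (cl,) = cluster_movs([call("S1")], cohort_size=100)
        assert cl.n_occurrences == 1 and not cl.is_mov

    def test_overlap_threshold_controls_linking(self):
        # 60% reciprocal overlap: [0, 1000) vs [400, 1400)
        a = call("A", start=0, end=1_000_000)
        b = call("B", start=400_000, end=1_400_000)
        assert reciprocal_overlap((0, 1_000_000),
                                  (400_000, 1_400_000)) == pytest.approx(0.6)
        assert len(cluster_movs([a, b], 100,
                                min_reciprocal_overlap=0.75)) == 2
        assert len(cluster_movs([a, b], 100,
                                min_reciprocal_overlap=0.5)) == 1

    def test_gain_and_loss_never_merge(self):
        calls = [call("A"), call("B", ctype="loss")]
        clusters = cluster_movs(calls, 100)
        assert len(clusters) == 2
        assert {c.type for c in clusters} == {"gain", "loss"}

    def test_order_invariance(self):
        rng = np.random.default_rng(2)
        calls = [call(f"S{i}", start=s, end=s + 240_000)
                 for i, s in enumerate([0, 20_000, 40_000, 5_000_000,
                                        5_020_000])]
        ref = cluster_movs(calls, 100)
        for _ in range(5):
            perm = list(rng.permutation(len(calls)))
            got = cluster_movs([calls[i] for i in perm], 100)
            assert [(c.start_bp, c.end_bp, c.n_occurrences)
                    for c in got] == [(c.start_bp, c.end_bp,
                                       c.n_occurrences) for c in ref]

    def test_modal_interval_is_representative(self):
        calls = ([call(f"A{i}", start=100_000, end=340_000)
                  for i in range(3)]
                 + [call("B", start=120_000, end=340_000)])
        (cl,) = cluster_movs(calls, 100)
        assert (cl.start_bp, cl.end_bp) == (100_000, 340_000)

    def test_modal_tie_broken_leftmost_then_shortest(self):
        calls = [call("A", start=120_000, end=360_000),
                 call("B", start=100_000, end=360_000),
                 call("C", start=100_000, end=340_000)]
        (cl,) = cluster_movs(calls, 100)
        assert (cl.start_bp, cl.end_bp) == (100_000, 340_000)

    def test_occurrences_count_distinct_samples(self):
        calls = [call("A"), call("A"), call("B")]
        (cl,) = cluster_movs(calls, 100)
        assert cl.n_occurrences == 2

    def test_cluster_sizes_conserve_clustered_calls(self):
        rng = np.random.default_rng(3)
        calls = []
        for i in range(40):
            s = int(rng.integers(0, 50)) * 20_000
            calls.append(call(f"S{i}", start=s, end=s + 240_000))
        clusters = cluster_movs(calls, 1000)
        member_total = sum(len(c.member_sample_ids) for c in clusters)
        assert member_total == len({c.sample_id for c in calls})

    def test_zero_cohort_rejected(self):
        with pytest.raises(ValueError):
            cluster_movs([], cohort_size=0)


class TestFrequency:
    @pytest.mark.parametrize("n,expected", [
        (126, 1.962), (98, 1.526), (31, 0.483), (13, 0.202),
    ])
    def test_cohort_percentages(self, n, expected):
        assert mov_frequency_pct(n, 6422) == expected


class TestDbComparison:
    def test_identical_frequencies_give_null_result(self):
        res = compare_to_db(10, 1000, 1.0, 1000)
        assert res.chi2_stat == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_statistic_equals_contingency_oracle(self):
        cases = [(126, 6422, 1.4, 7624), (42, 6422, 0.23, 7624),
                 (12, 6422, 0.2, 11222), (98, 6422, 0.7, 11222)]
        for n, N, f, dbN in cases:
            res = compare_to_db(n, N, f, dbN)
            db_n = round(f / 100 * dbN)
            table = [[n, N - n], [db_n, dbN - db_n]]
            assert res.chi2_stat == pytest.approx(chi2_oracle(table),
                                                  abs=1e-10)
            assert res.p_value == pytest.approx(
                stats.chi2.sf(chi2_oracle(table), 1))

    def test_degenerate_zero_table_flagged(self):
        res = compare_to_db(0, 100, 0.0, 100)
        assert res.degenerate
        assert np.isnan(res.p_value)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            compare_to_db(5, 0, 1.0, 100)
        with pytest.raises(ValueError):
            compare_to_db(5, 100, 120.0, 100)
        with pytest.raises(ValueError):
            compare_to_db(101, 100, 1.0, 100)


class TestChromosomeDensity:
    def test_three_chromosome_closed_form(self):
        rows = chromosome_density({"1": 1, "2": 1, "3": 4},
                                  {"1": 10 ** 6, "2": 10 ** 6, "3": 10 ** 6})
        per_mb = [r.per_mb for r in rows]
        assert per_mb == [1.0, 1.0, 4.0]
        # z for the last = (4 - 2) / sqrt(3); p = Phi(1.1547...)
        z = (4 - 2) / np.sqrt(3)
        assert rows[2].p_value == pytest.approx(stats.norm.cdf(z))
        assert rows[0].p_value == pytest.approx(
            stats.norm.cdf((1 - 2) / np.sqrt(3)))

    def test_equal_densities_degenerate_to_half(self):
        with pytest.warns(UserWarning, match="identical density"):
            rows = chromosome_density(
                {"1": 5, "2": 5, "3": 5},
                {"1": 10 ** 6, "2": 10 ** 6, "3": 10 ** 6})
        assert all(r.p_value == 0.5 for r in rows)
        assert not any(r.significant for r in rows)

    def test_two_sided_option(self):
        rows = chromosome_density(
            {"1": 1, "2": 1, "3": 4},
            {"1": 10 ** 6, "2": 10 ** 6, "3": 10 ** 6}, two_sided=True)
        z = (4 - 2) / np.sqrt(3)
        assert rows[2].p_value == pytest.approx(2 * stats.norm.sf(z))

    def test_validation(self):
        with pytest.raises(ValueError, match="3 chromosomes"):
            chromosome_density({"1": 1, "2": 2}, {"1": 10, "2": 10})
        with pytest.raises(ValueError, match="positive"):
            chromosome_density({"1": 1, "2": 2, "3": 3},
                               {"1": 10, "2": 0, "3": 10})


class TestSummary:
    def test_empty_call_set(self):
        s = summarize_cohort([], [], cohort_size=10)
        assert (s.n_calls, s.n_distinct, s.n_mov) == (0, 0, 0)
        assert s.mov_table.empty

    def test_shared_call_plus_singleton(self):
        calls = ([call(f"S{i}") for i in range(3)]
                 + [call("S9", chrom="chr2", start=0, end=240_000)])
        clusters = cluster_movs(calls, cohort_size=50)
        s = summarize_cohort(clusters, calls, cohort_size=50)
        assert s.n_calls == 4
        assert s.n_distinct == 2
        assert s.n_mov == 1
        assert s.per_chromosome == {"chr6": 1, "chr2": 1}
        assert s.mov_table.iloc[0]["n"] == 3
        assert s.mov_table.iloc[0]["frequency_pct"] == 6.0

    def test_gain_loss_split(self):
        calls = [call("A"), call("B", ctype="loss", chrom="chr3")]
        clusters = cluster_movs(calls, 10)
        s = summarize_cohort(clusters, calls, 10)
        assert s.n_distinct_gain == 1 and s.n_distinct_loss == 1
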