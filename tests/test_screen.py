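"""Demultiplexing, exact count test, rank metric, BH, contrasts, hits."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from petite_dynamics import (
    BarcodeMaps,
    CountMatrix,
    ReadLayout,
    ScreenConfig,
    ValidationError,
    bh_adjust,
    demultiplex_counts,
    exact_count_test,
    rank_metric,
    run_contrast,
    select_hits,
)
from petite_dynamics import synthetic as syn
from petite_dynamics.screen import exact_count_test_nb


def exact_test_oracle(a, b, size_a, size_b):
    """Minimum-likelihood two-sided binomial p-value in exact rational
    arithmetic (independent of scipy)."""
    n = a + b
    if n == 0:
        return 1.0
    p0 = Fraction(size_a, size_a + size_b)
    q0 = 1 - p0
    pmf = [comb(n, k) * p0**k * q0 ** (n - k) for k in range(n + 1)]
    obs = pmf[a]
    return float(min(sum(x for x in pmf if x <= obs), 1))


class TestDemultiplex:
    LAYOUT = ReadLayout(index_offset=0, index_len=4, barcode_offset=6,
                        barcode_len=8, read_len=16)

    @pytest.fixture
    def maps(self):
        return BarcodeMaps(
            gene_map={"geneA": "ACGTACGT", "geneB": "TTTTCCCC"},
            index_map={"s1": "AAAA", "s2": "CCCC"},
            layout=self.LAYOUT,
        )

    def test_exact_match_counts_once(self, maps):
        read = "AAAA" + "GG" + "ACGTACGT" + "GG"
        counts, stats = demultiplex_counts([read], maps)
        assert counts.loc["geneA", "s1"] == 1
        assert counts.values.sum() == 1
        assert stats.counted == 1

    def test_single_substitution_in_barcode_discards(self, maps):
        read = "AAAA" + "GG" + "ACGTACGA" + "GG"  # last barcode base changed
        counts, stats = demultiplex_counts([read], maps)
        assert counts.values.sum() == 0
        assert stats.bad_barcode == 1

    def test_discard_reasons_partition_reads(self, maps):
        reads = [
            "AAAA" + "GG" + "ACGTACGT" + "GG",  # good
            "GGGG" + "GG" + "ACGTACGT" + "GG",  # bad index
            "AAAA" + "GG" + "AAAAAAAA" + "GG",  # bad barcode
            "GGGG" + "GG" + "AAAAAAAA" + "GG",  # both bad
            "AAAA",  # too short
        ]
        _, stats = demultiplex_counts(reads, maps)
        assert stats.total == 5
        assert (stats.bad_index, stats.bad_barcode, stats.bad_both,
                stats.too_short) == (1, 1, 1, 1)
        assert stats.counted + stats.discarded == stats.total

    def test_fastq_file_round_trip(self, maps, tmp_path):
        from petite_dynamics.io_utils import write_fastq

        reads = [("r1", "AAAA" + "GG" + "ACGTACGT" + "GG"),
                 ("r2", "CCCC" + "GG" + "TTTTCCCC" + "GG")]
        path = tmp_path / "reads.fastq"
        write_fastq(reads, path)
        counts, stats = demultiplex_counts(str(path), maps)
        assert counts.loc["geneA", "s1"] == 1
        assert counts.loc["geneB", "s2"] == 1
        assert stats.total == 2

    def test_duplicate_barcodes_rejected(self):
        with pytest.raises(ValidationError):
            BarcodeMaps(
                gene_map={"a": "ACGTACGT", "b": "ACGTACGT"},
                index_map={"s1": "AAAA"},
                layout=self.LAYOUT,
            )


class TestExactCountTest:
    def test_modal_outcome_has_p_one(self):
        p, l2 = exact_count_test(5, 5, 1000, 1000)
        assert p == pytest.approx(1.0)
        assert l2 == pytest.approx(0.0)

    def test_ten_versus_zero_enumeration(self):
        # all mass on {0, 10} at or below the observed point probability
        p, l2 = exact_count_test(10, 0, 1000, 1000)
        assert p == pytest.approx(2 / 1024, rel=1e-12)
        assert l2 > 0

    def test_swap_symmetry(self):
        p1, l1 = exact_count_test(17, 4, 900, 1100)
        p2, l2 = exact_count_test(4, 17, 1100, 900)
        assert p1 == pytest.approx(p2, rel=1e-12)
        assert l1 == pytest.approx(-l2, rel=1e-12)

    def test_zero_total_convention(self):
        assert exact_count_test(0, 0, 100, 100) == (1.0, 0.0)

    @pytest.mark.parametrize("size_a,size_b", [(1000, 1000), (1500, 500)])
    def test_matches_rational_oracle_small_totals(self, size_a, size_b):
        for n in range(0, 26):
            for a in range(n + 1):
                p, _ = exact_count_test(a, n - a, size_a, size_b)
                ref = exact_test_oracle(a, n - a, size_a, size_b)
                assert p == pytest.approx(ref, rel=1e-9), (a, n - a)

    def test_invariant_under_size_scaling(self):
        p1, l1 = exact_count_test(30, 12, 1000, 2000)
        p2, l2 = exact_count_test(30, 12, 5000, 10000)
        assert p1 == pytest.approx(p2, rel=1e-12)

    @given(
        a=st.integers(0, 200),
        b=st.integers(0, 200),
        sa=st.integers(1, 10**6),
        sb=st.integers(1, 10**6),
    )
    def test_p_value_in_unit_interval(self, a, b, sa, sb):
        p, _ = exact_count_test(a, b, sa, sb)
        assert 0 < p <= 1

    def test_nb_variant_reduces_to_binomial_and_is_more_conservative(self):
        p0, _ = exact_count_test_nb(40, 10, 1000, 1000, dispersion=0.0)
        pb, _ = exact_count_test(40, 10, 1000, 1000)
        assert p0 == pytest.approx(pb, rel=1e-12)
        p_disp, _ = exact_count_test_nb(40, 10, 1000, 1000, dispersion=0.5)
        assert p_disp > pb


class TestRankMetric:
    @pytest.mark.parametrize(
        "p,l2,expected",
        [
            (0.01, 1.0, 2.0),
            (0.001, -0.5, -3.0),
            (1.0, 2.0, 0.0),
            (1.0, -2.0, 0.0),
            (0.1, 0.0, 0.0),
        ],
    )
    def test_quoted_formula(self, p, l2, expected):
        assert rank_metric(p, l2) == pytest.approx(expected)

    def test_zero_p_floored(self):
        assert rank_metric(0.0, 1.0) == pytest.approx(300.0)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValidationError):
            rank_metric(1.5, 1.0)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.031])[0] == pytest.approx(0.031)

    def test_textbook_example(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_matches_step_up_oracle_on_random_vectors(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            m = int(rng.integers(1, 40))
            p = rng.uniform(1e-6, 1.0, size=m)
            out = bh_adjust(p)
            # independent step-up: min over j >= i of m * p_(j) / j
            order = np.argsort(p)
            sorted_p = p[order]
            adj = np.minimum.accumulate(
                (m * sorted_p / np.arange(1, m + 1))[::-1]
            )[::-1]
            ref = np.empty(m)
            ref[order] = np.minimum(adj, 1.0)
            assert np.allclose(out, ref, rtol=1e-12)

    def test_adjusted_at_least_raw_and_order_invariant(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(1e-4, 1, 25)
        out = bh_adjust(p)
        assert np.all(out >= p - 1e-15)
        perm = rng.permutation(25)
        assert np.allclose(bh_adjust(p[perm]), out[perm])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 0.0])
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.2])


def _matrix_from_counts(counts: pd.DataFrame, conditions: dict) -> CountMatrix:
    samples = pd.DataFrame(
        [(s, conditions[s], i + 1) for i, s in enumerate(counts.columns)],
        columns=["sample_id", "condition", "replicate"],
    ).set_index("sample_id")
    return CountMatrix(counts=counts, samples=samples)


class TestRunContrast:
    def test_identical_pooled_counts_are_null(self):
        genes = [f"g{i}" for i in range(5)]
        counts = pd.DataFrame(
            {"a1": [10, 20, 30, 40, 0], "b1": [10, 20, 30, 40, 0]}, index=genes
        )
        cm = _matrix_from_counts(counts, {"a1": "etbr", "b1": "control"})
        res = run_contrast(cm, ("etbr", "control"))
        assert (res["p_raw"] == 1.0).all()
        assert (res["rank_metric"] == 0.0).all()
        assert res.loc["g4", "low_evidence"]

    def test_spiked_genes_dominate_rank_metric(self):
        spikes = {f"g{i:04d}": {"etbr": 2.0 if i <= 5 else -2.0}
                  for i in range(1, 11)}
        cm = syn.generate_screen_counts(
            n_genes=400, n_reps=3, library_size=200_000,
            spike_effects=spikes, seed=17,
        )
        res = run_contrast(cm, ("etbr", "control"))
        top = res["rank_metric"].abs().nlargest(20)
        assert set(spikes) <= set(top.index)
        for g, eff in spikes.items():
            assert np.sign(res.loc[g, "rank_metric"]) == np.sign(eff["etbr"])

    def test_invariant_to_replicate_label_permutation(self):
        cm = syn.generate_screen_counts(n_genes=60, n_reps=3,
                                        library_size=30_000, seed=18)
        res1 = run_contrast(cm, ("etbr", "control"))
        perm = cm.counts.rename(
            columns={"etbr_r1": "etbr_r2", "etbr_r2": "etbr_r1"}
        )[cm.counts.columns]
        cm2 = CountMatrix(counts=perm, samples=cm.samples)
        res2 = run_contrast(cm2, ("etbr", "control"))
        pd.testing.assert_frame_equal(res1, res2)

    def test_missing_condition_rejected(self):
        cm = syn.generate_screen_counts(n_genes=10, library_size=1000, seed=1)
        with pytest.raises(ValidationError):
            run_contrast(cm, ("etbr", "outgrowth"))


class TestSelectHits:
    @pytest.fixture
    def toy(self):
        return pd.DataFrame(
            {
                "rank_metric": [3.0, -1.0, 5.0, 5.0, 0.5],
                "p_adj": [0.001, 0.5, 1e-5, 1e-5, 0.2],
            },
            index=pd.Index(["gB", "gC", "gE", "gA", "gD"], name="gene_id"),
        )

    def test_top_one_is_max_rank_with_lexicographic_ties(self, toy):
        # gA and gE tie at 5.0; gA wins lexicographically
        assert select_hits(toy, "top_k_adaptive", k=1) == ["gA"]

    def test_top_and_bottom_slices_disjoint(self):
        cm = syn.generate_screen_counts(n_genes=1000, n_reps=3,
                                        library_size=100_000, seed=19)
        res = run_contrast(cm, ("etbr", "control"))
        top = select_hits(res, "top_k_adaptive", k=147)
        bottom = select_hits(res, "bottom_k", k=45)
        assert len(top) == 147 and len(bottom) == 45
        assert not set(top) & set(bottom)

    def test_fdr_mode_on_null_table_nearly_empty(self):
        hit_fractions = []
        for seed in range(10):
            cm = syn.generate_screen_counts(n_genes=300, n_reps=3,
                                            library_size=60_000, seed=100 + seed)
            res = run_contrast(cm, ("etbr", "control"))
            hits = select_hits(res, "fdr", fdr=0.05)
            hit_fractions.append(len(hits) / len(res))
        assert np.mean(hit_fractions) <= 0.05

    def test_oversized_k_truncates_with_warning(self, toy):
        with pytest.warns(UserWarning, match="truncating"):
            hits = select_hits(toy, "top_k_adaptive", k=10)
        assert len(hits) == 5

    def test_empty_table_rejected(self):
        with pytest.raises(ValidationError):
            select_hits(pd.DataFrame(), "fdr")
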