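"""Counting, TPM, group sums, isoform fractions, and agreement reports."""

import numpy as np
import pandas as pd
import pytest

from exonproxy.genomic_model import GenomicInterval, Placement
from exonproxy.proxy_finder import IsoformGroup, ProxyRegion
from exonproxy.quantifier import (
    RegionOverlapError,
    count_overlaps,
    isoform_fraction,
    isoform_fraction_from_counts,
    proxy_agreement,
    read_table,
    sum_group_tpm,
    three_prime_capture_probability,
    tpm,
    write_table,
)


def place(start, end, name="r", sample="s1", seqname="chr17", strand="+"):
    return Placement(
        name=name, blocks=(GenomicInterval(seqname, start, end, strand),), sample=sample
    )


THRA2_PROXY = ProxyRegion(
    "THRA2", (GenomicInterval("chr17", 40_093_020, 40_093_867, "+"),)
)
THRA1_PROXY = ProxyRegion(
    "THRA1", (GenomicInterval("chr17", 40_089_334, 40_092_627, "+"),)
)


class TestCountOverlaps:
    def test_contained_read_counts_once(self):
        counts = count_overlaps([place(40_093_100, 40_093_190)], [THRA2_PROXY])
        assert counts.loc["THRA2", "s1"] == 1

    def test_single_base_overlap_counts(self):
        counts = count_overlaps(
            [place(40_092_930, 40_093_020)], [THRA2_PROXY]  # last base touches
        )
        assert counts.loc["THRA2", "s1"] == 1
        counts = count_overlaps([place(40_092_930, 40_093_019)], [THRA2_PROXY])
        assert counts.loc["THRA2", "s1"] == 0

    def test_spliced_read_counts_via_any_block(self):
        read = Placement(
            name="spliced",
            blocks=(
                GenomicInterval("chr17", 40_089_300, 40_089_333, "+"),
                GenomicInterval("chr17", 40_093_020, 40_093_076, "+"),
            ),
        )
        counts = count_overlaps([read], [THRA2_PROXY])
        assert counts.loc["THRA2", "sample1"] == 1

    def test_ambiguous_read_dropped(self):
        # a (pathological) placement spanning both proxies counts for neither
        read = Placement(
            name="amb",
            blocks=(
                GenomicInterval("chr17", 40_092_600, 40_092_627, "+"),
                GenomicInterval("chr17", 40_093_020, 40_093_060, "+"),
            ),
        )
        counts = count_overlaps([read], [THRA1_PROXY, THRA2_PROXY])
        assert counts.values.sum() == 0

    def test_overlapping_regions_rejected(self):
        bad = ProxyRegion("X", (GenomicInterval("chr17", 40_093_500, 40_094_000, "+"),))
        with pytest.raises(RegionOverlapError):
            count_overlaps([], [THRA2_PROXY, bad])

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(5)
        # 5 disjoint regions on [1, 100000]
        starts = np.sort(rng.choice(np.arange(1, 90_000, 2_000), size=5, replace=False))
        regions = [
            ProxyRegion(f"R{i}", (GenomicInterval("c", int(s), int(s) + 999, "+"),))
            for i, s in enumerate(starts)
        ]
        reads = [
            place(int(s), int(s) + 90, name=f"r{i}", seqname="c")
            for i, s in enumerate(rng.integers(1, 99_000, size=10_000))
        ]
        counts = count_overlaps(reads, regions)
        # brute-force oracle: per-read scan over region intervals
        brute = {r.group_name: 0 for r in regions}
        for rd in reads:
            hits = [
                r.group_name
                for r in regions
                if any(
                    b.overlap_length(iv) >= 1 for b in rd.blocks for iv in r.intervals
                )
            ]
            if len(hits) == 1:
                brute[hits[0]] += 1
        for r in regions:
            assert counts.loc[r.group_name, "s1"] == brute[r.group_name]

    def test_per_sample_columns(self):
        reads = [
            place(40_093_100, 40_093_190, sample="cellA"),
            place(40_093_100, 40_093_190, sample="cellB"),
            place(40_093_100, 40_093_190, sample="cellB"),
        ]
        counts = count_overlaps(reads, [THRA2_PROXY])
        assert counts.loc["THRA2", "cellA"] == 1
        assert counts.loc["THRA2", "cellB"] == 2


class TestTpm:
    def test_single_feature_is_one_million(self):
        counts = pd.DataFrame({"s": {"f": 7}})
        assert tpm(counts, {"f": 848}).loc["f", "s"] == pytest.approx(1e6)

    def test_equal_counts_lengths_L_and_2L(self):
        counts = pd.DataFrame({"s": {"a": 10, "b": 10}})
        out = tpm(counts, {"a": 100, "b": 200})
        assert out.loc["a", "s"] == pytest.approx(666_666.6667, rel=1e-6)
        assert out.loc["b", "s"] == pytest.approx(333_333.3333, rel=1e-6)

    def test_columns_sum_to_one_million(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(
            rng.integers(1, 1000, size=(6, 4)),
            index=list("abcdef"),
            columns=list("wxyz"),
        )
        lengths = {f: int(l) for f, l in zip("abcdef", rng.integers(100, 5000, 6))}
        out = tpm(counts, lengths)
        assert np.allclose(out.sum(axis=0), 1e6, rtol=1e-6)

    def test_zero_count_column_is_na(self):
        counts = pd.DataFrame({"s0": {"a": 0, "b": 0}, "s1": {"a": 1, "b": 1}})
        out = tpm(counts, {"a": 100, "b": 100})
        assert out["s0"].isna().all() and not out["s1"].isna().any()

    def test_bad_lengths_rejected(self):
        counts = pd.DataFrame({"s": {"a": 1}})
        with pytest.raises(ValueError):
            tpm(counts, {"a": 0})
        with pytest.raises(KeyError, match="a"):
            tpm(counts, {"b": 10})

    def test_shorter_proxy_length_inflates_tpm(self):
        """Same counts normalized by the 848 bp proxy length vs the full
        transcript length: against a fixed background, every proxy TPM is
        strictly larger — the expected length effect of proxy counting."""
        counts = pd.DataFrame({"s": {"THRA1": 120, "THRA2": 300, "background": 50_000}})
        proxy_lengths = {"THRA1": 3294, "THRA2": 848, "background": 2_000}
        transcript_lengths = {"THRA1": 5602, "THRA2": 2448, "background": 2_000}
        by_proxy = tpm(counts, proxy_lengths)
        by_transcript = tpm(counts, transcript_lengths)
        for g in ("THRA1", "THRA2"):
            assert by_proxy.loc[g, "s"] > by_transcript.loc[g, "s"]


class TestGroupSumsAndFractions:
    def test_group_sum_simple(self):
        table = pd.DataFrame({"s": {"t1": 10.0, "t2": 5.0}})
        groups = [IsoformGroup("G", frozenset({"t1", "t2"}))]
        assert sum_group_tpm(table, groups).loc["G", "s"] == 15.0

    def test_absent_member_counts_as_zero_with_warning(self, caplog):
        table = pd.DataFrame({"s": {"t1": 10.0}})
        groups = [IsoformGroup("G", frozenset({"t1", "missing"}))]
        with caplog.at_level("WARNING"):
            out = sum_group_tpm(table, groups)
        assert out.loc["G", "s"] == 10.0
        assert "missing" in caplog.text

    def test_group_sum_equals_membership_matrix_product(self):
        rng = np.random.default_rng(7)
        tx_ids = [f"t{i}" for i in range(12)]
        table = pd.DataFrame(
            rng.random((12, 5)) * 100, index=tx_ids, columns=[f"s{i}" for i in range(5)]
        )
        groups = [
            IsoformGroup("A", frozenset(tx_ids[:4])),
            IsoformGroup("B", frozenset(tx_ids[4:9])),
            IsoformGroup("C", frozenset(tx_ids[9:])),
        ]
        out = sum_group_tpm(table, groups)
        membership = np.zeros((3, 12))
        for gi, g in enumerate(groups):
            for ti, t in enumerate(tx_ids):
                membership[gi, ti] = t in g.transcript_ids
        expected = membership @ table.values
        assert np.allclose(out.values, expected)

    @pytest.mark.parametrize(
        "values, expected",
        [((50.0, 50.0), (0.5, 0.5)), ((20.0, 80.0), (0.2, 0.8))],
    )
    def test_fraction_closed_form(self, values, expected):
        table = pd.DataFrame({"s": {"G1": values[0], "G2": values[1]}})
        out = isoform_fraction(table)
        assert out.loc["G1", "s"] == pytest.approx(expected[0])
        assert out.loc["G2", "s"] == pytest.approx(expected[1])

    def test_zero_total_flagged_na(self):
        table = pd.DataFrame({"s": {"G1": 0.0, "G2": 0.0}})
        assert isoform_fraction(table)["s"].isna().all()

    def test_rescaling_invariance(self):
        rng = np.random.default_rng(9)
        table = pd.DataFrame(
            rng.random((3, 4)) + 0.1, index=list("abc"), columns=list("wxyz")
        )
        f1 = isoform_fraction(table)
        f2 = isoform_fraction(table * 37.5)
        assert np.allclose(f1.values, f2.values)

    def test_capture_corrected_count_fractions(self):
        counts = pd.DataFrame({"s": {"A": 800, "B": 440}})
        # B's proxy captures only half its molecules; correcting recovers parity
        out = isoform_fraction_from_counts(counts, {"A": 1.0, "B": 0.5})
        assert out.loc["B", "s"] == pytest.approx(880 / 1680)

    def test_capture_probability_limits(self):
        # proxy much longer than the bias scale: capture ~ 1
        assert three_prime_capture_probability(5_000, 10_000, 400) == pytest.approx(1.0, abs=1e-4)
        # short proxy: capture = truncated-exponential CDF at its length
        p = three_prime_capture_probability(848, 2448, 400, read_length=91)
        z = 1 - np.exp(-(2448 - 91) / 400)
        assert p == pytest.approx((1 - np.exp(-848 / 400)) / z)


class TestAgreement:
    def test_identical_tables_pass_with_zero_difference(self):
        f = pd.DataFrame({"s1": {"A": 0.3, "B": 0.7}, "s2": {"A": 0.5, "B": 0.5}})
        rep = proxy_agreement(f, f.copy())
        assert rep.mean_abs_diff == 0.0 and rep.max_abs_diff == 0.0 and rep.passed

    def test_difference_of_point_one(self):
        a = pd.DataFrame({"s": {"A": 0.2, "B": 0.8}})
        b = pd.DataFrame({"s": {"A": 0.3, "B": 0.7}})
        rep = proxy_agreement(a, b, tolerance=0.02)
        assert rep.mean_abs_diff == pytest.approx(0.10)
        assert not rep.passed

    def test_sample_mismatch_rejected(self):
        a = pd.DataFrame({"s1": {"A": 0.2, "B": 0.8}})
        b = pd.DataFrame({"s2": {"A": 0.2, "B": 0.8}})
        with pytest.raises(ValueError, match="sample mismatch"):
            proxy_agreement(a, b)


def test_table_tsv_round_trip(tmp_path):
    df = pd.DataFrame({"s1": {"THRA1": 120, "THRA2": 300}})
    p = tmp_path / "counts.tsv"
    write_table(df, p, comments=["unit test"])
    back = read_table(p)
    assert (back.values == df.values).all()
    assert list(back.index) == list(df.index)
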