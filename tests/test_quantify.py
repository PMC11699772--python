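"""Counting, normalisation and the differential-expression substitute."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xciseq.alignment import AlignmentRecord
from xciseq.annotation import GeneModel
from xciseq.errors import ConfigurationError, DataError
from xciseq.quantify import (
    AllelicCountMatrix,
    count_reads,
    differential_expression,
    expression_filter,
    size_factors,
    tpm,
)
from xciseq.simulate import simulate_count_matrix
from xciseq.tagging import AlleleTag, TaggedAlignment


def _gene(gene_id, start, end, chrom="chr1", strand="+"):
    return GeneModel(gene_id, chrom, strand, ((start, end),))


def _tagged(start, end, tag, chrom="chr1", rid="r"):
    rec = AlignmentRecord(rid, chrom, start, end - start)
    return TaggedAlignment(records=(rec,), tag=tag)


GENES = [_gene("gA", 100, 400), _gene("gB", 1000, 1600)]


class TestCountReads:
    def test_no_reads_zero_matrix(self):
        lc = count_reads([], GENES)
        assert (lc.counts == 0).all().all()

    def test_tag_split(self):
        tagged = (
            [_tagged(150, 225, AlleleTag.G1) for _ in range(10)]
            + [_tagged(150, 225, AlleleTag.G2) for _ in range(5)]
            + [_tagged(150, 225, AlleleTag.UA) for _ in range(3)]
        )
        lc = count_reads(tagged, GENES)
        row = lc.counts.loc["gA"]
        assert (row["total"], row["g1"], row["g2"]) == (18, 10, 5)

    def test_ambiguous_read_counted_in_neither(self):
        overlapping = [_gene("gA", 100, 400), _gene("gC", 300, 700)]
        lc = count_reads([_tagged(350, 380, AlleleTag.G1)], overlapping)
        assert lc.counts["total"].sum() == 0
        assert lc.ambiguous == 1

    def test_intergenic_accounting(self):
        lc = count_reads([_tagged(5000, 5075, AlleleTag.UA)], GENES)
        assert lc.intergenic == 1

    def test_empty_annotation_raises(self):
        with pytest.raises(DataError):
            count_reads([], [])

    def test_matches_interval_scan_oracle(self):
        rng = np.random.default_rng(11)
        genes = [_gene(f"g{i}", 1000 * i, 1000 * i + 500) for i in range(10)]
        tagged = []
        for i in range(500):
            start = int(rng.integers(0, 10_000))
            tagged.append(_tagged(start, start + 75, AlleleTag.UA, rid=f"r{i}"))
        lc = count_reads(tagged, genes)
        # brute-force: test every read against every gene interval
        for g in genes:
            expected = sum(
                1
                for ta in tagged
                if ta.records[0].start < g.end and g.start < ta.records[0].end
            )
            assert lc.counts.loc[g.gene_id, "total"] == expected

    def test_conservation(self):
        rng = np.random.default_rng(12)
        tagged = []
        for i in range(300):
            start = int(rng.integers(0, 3000))
            tagged.append(_tagged(start, start + 75, AlleleTag.UA, rid=f"r{i}"))
        lc = count_reads(tagged, GENES)
        assert lc.counts["total"].sum() + lc.ambiguous + lc.intergenic == len(tagged)


def _matrix(counts: dict, g1=None, g2=None):
    total = pd.DataFrame(counts)
    zero = total * 0
    return AllelicCountMatrix(
        total=total,
        g1=pd.DataFrame(g1) if g1 else zero.copy(),
        g2=pd.DataFrame(g2) if g2 else zero.copy(),
    )


class TestTPM:
    def test_single_gene_is_one_million(self):
        m = _matrix({"lib": [42]})
        m.total.index = ["g"]
        m.g1.index = m.g2.index = ["g"]
        expr = tpm(m, {"g": 500})
        assert expr.tpm.loc["g", "lib"] == pytest.approx(1e6)

    def test_equal_counts_equal_lengths_split_evenly(self):
        m = _matrix({"lib": [10, 10]})
        for df in (m.total, m.g1, m.g2):
            df.index = ["a", "b"]
        expr = tpm(m, {"a": 1000, "b": 1000})
        assert expr.tpm["lib"].tolist() == pytest.approx([5e5, 5e5])

    def test_hand_computed_example(self):
        # counts (10,20,30) over (1,2,3) kb -> equal rates -> equal TPM
        m = _matrix({"lib": [10, 20, 30]})
        for df in (m.total, m.g1, m.g2):
            df.index = ["a", "b", "c"]
        expr = tpm(m, {"a": 1000, "b": 2000, "c": 3000})
        assert expr.tpm["lib"].tolist() == pytest.approx([1e6 / 3] * 3)

    def test_zero_library_warns_and_zeroes(self):
        m = _matrix({"lib": [0, 0]})
        for df in (m.total, m.g1, m.g2):
            df.index = ["a", "b"]
        with pytest.warns(UserWarning):
            expr = tpm(m, {"a": 1000, "b": 1000})
        assert (expr.tpm["lib"] == 0).all()

    @settings(deadline=None, max_examples=25)
    @given(
        st.lists(
            st.tuples(st.integers(0, 5000), st.integers(100, 20_000)),
            min_size=2,
            max_size=20,
        )
    )
    def test_tpm_and_cpm_sum_to_one_million(self, rows):
        if sum(c for c, _ in rows) == 0:
            return
        counts = pd.DataFrame({"lib": [c for c, _ in rows]})
        counts.index = [f"g{i}" for i in range(len(rows))]
        m = AllelicCountMatrix(total=counts, g1=counts * 0, g2=counts * 0)
        expr = tpm(m, {f"g{i}": l for i, (_, l) in enumerate(rows)})
        assert expr.tpm["lib"].sum() == pytest.approx(1e6, rel=1e-6)
        assert expr.cpm["lib"].sum() == pytest.approx(1e6, rel=1e-6)


class TestExpressionFilter:
    def test_boundary_gene_retained(self):
        # exactly 2.5 CPM in exactly 2 of 4 libraries
        cpm = pd.DataFrame(
            {"l1": [2.5], "l2": [2.5], "l3": [1.0], "l4": [0.0]}, index=["g"]
        )
        assert "g" in expression_filter(cpm, min_cpm=2.5, min_libraries=2)

    def test_all_zero_gene_removed(self):
        cpm = pd.DataFrame({"l1": [0.0, 5.0], "l2": [0.0, 5.0]}, index=["z", "g"])
        kept = expression_filter(cpm, min_libraries=2)
        assert list(kept) == ["g"]

    def test_matches_per_gene_scan(self):
        rng = np.random.default_rng(4)
        cpm = pd.DataFrame(
            rng.uniform(0, 10, (50, 4)),
            index=[f"g{i}" for i in range(50)],
            columns=list("abcd"),
        )
        kept = set(expression_filter(cpm, min_cpm=2.5, min_libraries=2))
        expected = {
            g for g in cpm.index if sum(cpm.loc[g, l] >= 2.5 for l in cpm.columns) >= 2
        }
        assert kept == expected

    def test_min_libraries_exceeding_count_raises(self):
        cpm = pd.DataFrame({"l1": [1.0]}, index=["g"])
        with pytest.raises(ConfigurationError):
            expression_filter(cpm, min_libraries=2)


class TestDifferentialExpression:
    def test_identical_groups_give_no_calls(self):
        counts = pd.DataFrame(
            {
                "a1": [100, 50, 10],
                "a2": [120, 55, 12],
                "b1": [100, 50, 10],
                "b2": [120, 55, 12],
            },
            index=["g1", "g2", "g3"],
        )
        groups = {"a1": "wt", "a2": "wt", "b1": "ko", "b2": "ko"}
        res = differential_expression(counts, groups)
        assert np.allclose(res["log2_fold"], 0)
        assert not res["de"].any()

    def test_de_flag_matches_thresholds(self):
        counts, _, groups = simulate_count_matrix(3, de_fraction=0.1)
        res = differential_expression(counts, groups, reference="ref", test_group="test")
        expected = (res["fdr"] <= 0.1) & (res["log2_fold"].abs() >= 1.0)
        assert (res["de"] == expected).all()

    def test_size_factors_track_depth(self):
        counts, _, groups = simulate_count_matrix(5)
        doubled = counts.copy()
        doubled["ref0"] = counts["ref0"] * 2
        sf = size_factors(doubled)
        assert sf["ref0"] / sf["ref1"] == pytest.approx(
            2 * size_factors(counts)["ref0"] / size_factors(counts)["ref1"], rel=0.05
        )

    def test_missing_group_raises(self):
        counts = pd.DataFrame({"a": [1]}, index=["g"])
        with pytest.raises(ConfigurationError):
            differential_expression(counts, {"a": "wt"})
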