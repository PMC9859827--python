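"""Expression I/O contracts, the smallest-group CPM filter, and DEG set logic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from txconcord.exprio import (
    DEResultTable,
    ExpressionMatrix,
    deg_sets,
    filter_by_expression,
    log1p_tpm,
    overlap_sets,
    read_expression,
    write_expression,
)


def _matrix(tpm, meta):
    return ExpressionMatrix(metadata=meta, tpm=tpm)


class TestReadWrite:
    def test_round_trip_byte_identical(self, tmp_path, toy_matrix):
        tpm, meta = toy_matrix
        m = _matrix(tpm, meta)
        p1, mp1 = tmp_path / "a.tsv", tmp_path / "am.tsv"
        write_expression(m, p1, mp1, kind="tpm")
        m2 = read_expression(p1, mp1, kind="tpm")
        p2, mp2 = tmp_path / "b.tsv", tmp_path / "bm.tsv"
        write_expression(m2, p2, mp2, kind="tpm")
        assert p1.read_bytes() == p2.read_bytes()
        assert mp1.read_bytes() == mp2.read_bytes()

    def test_metadata_missing_sample_named(self, tmp_path, toy_matrix):
        tpm, meta = toy_matrix
        (tmp_path / "m.tsv").write_text(
            "gene_id\ts1\ts2\ts3\ng1\t1\t2\t3\n"
        )
        meta.drop("s3").to_csv(tmp_path / "meta.tsv", sep="\t", index_label="sample_id")
        with pytest.raises(ValueError, match="s3"):
            read_expression(tmp_path / "m.tsv", tmp_path / "meta.tsv")

    def test_duplicated_gene_id_rejected(self, tmp_path, toy_matrix):
        _, meta = toy_matrix
        (tmp_path / "m.tsv").write_text(
            "gene_id\ts1\ts2\ts3\ng1\t1\t2\t3\ng1\t4\t5\t6\n"
        )
        meta.to_csv(tmp_path / "meta.tsv", sep="\t", index_label="sample_id")
        with pytest.raises(ValueError, match="g1"):
            read_expression(tmp_path / "m.tsv", tmp_path / "meta.tsv")

    def test_non_numeric_cell_located(self, tmp_path, toy_matrix):
        _, meta = toy_matrix
        (tmp_path / "m.tsv").write_text(
            "gene_id\ts1\ts2\ts3\ng1\t1\toops\t3\n"
        )
        meta.to_csv(tmp_path / "meta.tsv", sep="\t", index_label="sample_id")
        with pytest.raises(ValueError, match="g1.*s2"):
            read_expression(tmp_path / "m.tsv", tmp_path / "meta.tsv")


class TestLog1p:
    def test_zeros_map_to_zeros_and_closed_form(self, toy_matrix):
        tpm, meta = toy_matrix
        tpm = tpm.copy()
        tpm.iloc[0, 0] = np.e - 1
        lg = log1p_tpm(_matrix(tpm, meta))
        assert lg.iloc[0, 0] == pytest.approx(1.0)
        assert (lg.to_numpy()[tpm.to_numpy() == 0] == 0).all()

    def test_monotone(self, toy_matrix):
        tpm, meta = toy_matrix
        lg = log1p_tpm(_matrix(tpm, meta))
        col = tpm["s1"].to_numpy()
        out = lg["s1"].to_numpy()
        order = np.argsort(col)
        assert (np.diff(out[order]) >= 0).all()

    def test_requires_tpm(self, toy_matrix):
        tpm, meta = toy_matrix
        counts = tpm.astype(int)
        m = ExpressionMatrix(metadata=meta, counts=counts)
        with pytest.raises(ValueError, match="TPM"):
            log1p_tpm(m)


class TestFilterByExpression:
    def _make(self, counts, groups):
        meta = pd.DataFrame(
            {
                "group": groups,
                "is_focus": [g == groups[0] for g in groups],
            },
            index=pd.Index(list(counts.columns), name="sample_id"),
        )
        return ExpressionMatrix(metadata=meta, counts=counts)

    def test_smallest_group_rule(self):
        # groups of sizes 2 and 3 -> n = 2; a gene clearing CPM >= 10 in
        # exactly 2 samples is kept
        counts = pd.DataFrame(
            {
                "a1": [100, 1, 0, 1000000],
                "a2": [100, 1, 0, 1000000],
                "b1": [0, 1, 99999, 1000000],
                "b2": [0, 1, 99999, 1000000],
                "b3": [0, 1, 99999, 1000000],
            },
            index=["keep", "low", "big", "filler"],
        )
        m = self._make(counts, ["a", "a", "b", "b", "b"])
        kept = filter_by_expression(m, 10.0)
        assert "keep" in kept.gene_ids
        assert "low" not in kept.gene_ids

    def test_library_size_arithmetic(self):
        # libsizes 100000 and 200000; counts (2,1) -> CPMs (20,5)
        fill1 = 100000 - 2
        fill2 = 200000 - 1
        counts = pd.DataFrame(
            {"s1": [2, fill1], "s2": [1, fill2]}, index=["g", "rest"]
        )
        m = self._make(counts, ["x", "y"])  # group sizes (1,1) -> n = 1
        assert "g" in filter_by_expression(m, 10.0).gene_ids
        counts2 = pd.DataFrame(
            {"s1": [0, 100000], "s2": [1, fill2]}, index=["g", "rest"]
        )
        m2 = self._make(counts2, ["x", "y"])  # CPMs (0, 5) -> dropped
        assert "g" not in filter_by_expression(m2, 10.0).gene_ids

    def test_all_zero_gene_removed(self, small_experiment):
        m, _ = small_experiment
        counts = m.counts.copy()
        counts.iloc[0] = 0
        m2 = ExpressionMatrix(metadata=m.metadata.copy(), counts=counts)
        kept = filter_by_expression(m2)
        assert counts.index[0] not in kept.gene_ids

    def test_idempotent(self, small_experiment):
        m, _ = small_experiment
        once = filter_by_expression(m)
        twice = filter_by_expression(once)
        assert once.gene_ids == twice.gene_ids
        pd.testing.assert_frame_equal(once.counts, twice.counts)

    def test_requires_counts(self, toy_matrix):
        tpm, meta = toy_matrix
        with pytest.raises(ValueError, match="counts"):
            filter_by_expression(_matrix(tpm, meta))


class TestDegSets:
    def _table(self, rows):
        return DEResultTable(
            pd.DataFrame(rows, columns=["gene_id", "lfc", "fdr"])
        )

    def test_strict_boundaries(self):
        t = self._table(
            [
                ("at_lfc", 0.5, 0.01),     # lfc not > 0.5 -> excluded
                ("up", 1.2, 0.049),        # in
                ("at_fdr", -0.6, 0.05),    # fdr not < 0.05 -> excluded
                ("down", -0.51, 0.049),    # in
                ("nan_fdr", 2.0, np.nan),  # missing fdr -> non-significant
            ]
        )
        up, down = deg_sets(t)
        assert up == {"up"}
        assert down == {"down"}

    def test_up_down_disjoint(self, rng):
        t = self._table(
            [(f"g{i}", lfc, fdr) for i, (lfc, fdr) in enumerate(
                zip(rng.normal(0, 2, 200), rng.uniform(0, 1, 200))
            )]
        )
        up, down = deg_sets(t)
        assert not up & down

    @settings(derandomize=True, max_examples=30)
    @given(
        lfc_cut=st.floats(0.0, 2.0),
        fdr_cut=st.floats(0.001, 0.2),
    )
    def test_monotone_in_cuts(self, lfc_cut, fdr_cut):
        rng = np.random.default_rng(99)
        t = self._table(
            [(f"g{i}", lfc, fdr) for i, (lfc, fdr) in enumerate(
                zip(rng.normal(0, 2, 100), rng.uniform(0, 1, 100))
            )]
        )
        up0, down0 = deg_sets(t, lfc_cut, fdr_cut)
        up1, down1 = deg_sets(t, lfc_cut + 0.1, fdr_cut / 2)
        assert up1 <= up0 and down1 <= down0


class TestOverlapSets:
    def test_two_set_enumeration(self):
        regions = overlap_sets({"A": {1, 2, 3}, "B": {2, 3, 4}})
        assert regions[frozenset({"A"})] == {1}
        assert regions[frozenset({"B"})] == {4}
        assert regions[frozenset({"A", "B"})] == {2, 3}

    def test_disjoint_sets(self):
        regions = overlap_sets({"A": {1}, "B": {2}})
        assert regions[frozenset({"A", "B"})] == set()

    def test_regions_partition_union(self, rng):
        sets = {
            name: set(rng.choice(6, size=rng.integers(0, 6), replace=False).tolist())
            for name in "ABC"
        }
        regions = overlap_sets(sets)
        union = set().union(*sets.values())
        assert sum(len(v) for v in regions.values()) == len(union)
        # brute-force membership check
        for el in union:
            member_of = frozenset(n for n, s in sets.items() if el in s)
            assert el in regions[member_of]

    def test_requires_two_sets(self):
        with pytest.raises(ValueError, match="2"):
            overlap_sets({"A": {1}})
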