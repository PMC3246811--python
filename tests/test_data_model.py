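"""Geometry-table semantics: I/O round-trips, filtering, grouping, pooling."""

import numpy as np
import pandas as pd
import pytest

from fragstat import (
    Descriptor,
    FormatError,
    GeometryTable,
    Selection,
    filter_rows,
    group_rows,
    parse_criteria,
    pool_equivalent,
    read_table,
    write_table,
)
from conftest import make_table, random_table


class TestDescriptor:
    def test_rejects_bad_kind_and_empty_name(self):
        with pytest.raises(ValueError):
            Descriptor("X", "nonsense")
        with pytest.raises(ValueError):
            Descriptor("", "linear")
        with pytest.raises(ValueError):
            Descriptor("T", "circular", period=0)


class TestReadWrite:
    def test_read_basic_csv(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("id,frag,TOR1\nAAA,1,10.5\nBBB,1,20.0\nCCC,1,-30.25\n")
        t = read_table(p)
        assert t.n_rows == 3
        assert t.columns == ["TOR1"]
        assert t.descriptor("TOR1").kind == "linear"
        np.testing.assert_allclose(t.values("TOR1"), [10.5, 20.0, -30.25])

    def test_kind_override_makes_circular(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("id,frag,TOR1\nAAA,1,10.5\nBBB,1,20.0\n")
        t = read_table(p, kinds={"TOR1": "circular"})
        d = t.descriptor("TOR1")
        assert d.kind == "circular" and d.period == 360.0

    def test_blank_cell_is_missing_not_zero(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("id,frag,D\nAAA,1,2.5\nBBB,1,\nCCC,1,3.0\n")
        t = read_table(p)
        v = t.values("D")
        assert t.n_rows == 3
        assert np.isnan(v[1]) and v[0] == 2.5

    def test_integer_kind_inferred(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("id,frag,HAL\nAAA,1,1\nBBB,1,2\nCCC,1,1\n")
        assert read_table(p).descriptor("HAL").kind == "integer"

    def test_ragged_row_names_line_number(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("id,frag,D\nAAA,1,2.5\nBBB,1\n")
        with pytest.raises(FormatError, match="line 3"):
            read_table(p)

    def test_duplicate_header_rejected(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("id,frag,D,D\nAAA,1,1.0,2.0\n")
        with pytest.raises(FormatError, match="duplicate"):
            read_table(p)

    @pytest.mark.parametrize("dialect", ["csv", "tsv"])
    def test_round_trip_values_kinds_hidden(self, tmp_path, dialect, simple_table):
        simple_table.hidden[1] = True
        path = tmp_path / f"t.{dialect}"
        write_table(simple_table, path, dialect=dialect)
        back = read_table(path, dialect=dialect)
        assert back.columns == simple_table.columns
        for c in ("D", "TOR"):
            np.testing.assert_array_equal(
                back.values(c, include_hidden=True),
                simple_table.values(c, include_hidden=True),
            )
        assert [d.kind for d in back.descriptors.values()] == [
            d.kind for d in simple_table.descriptors.values()
        ]
        np.testing.assert_array_equal(back.hidden, simple_table.hidden)

    def test_round_trip_random_tables_bit_identical(self, tmp_path):
        rng = np.random.default_rng(42)
        for i in range(20):
            t = random_table(rng)
            t.hidden[rng.random(t.n_rows) < 0.2] = True
            path = tmp_path / f"r{i}.csv"
            write_table(t, path)
            back = read_table(path)
            for c in t.columns:
                if t.descriptor(c).kind != "categorical":
                    np.testing.assert_array_equal(
                        back.values(c, include_hidden=True),
                        t.values(c, include_hidden=True),
                    )
            np.testing.assert_array_equal(back.hidden, t.hidden)


class TestTableInvariants:
    def test_duplicate_row_identity_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            GeometryTable(["A", "A"], [1, 1], pd.DataFrame({"D": [1.0, 2.0]}))

    def test_fragment_index_one_based(self):
        with pytest.raises(ValueError, match="1-based"):
            GeometryTable(["A"], [0], pd.DataFrame({"D": [1.0]}))

    def test_reserved_column_names_rejected(self):
        with pytest.raises(ValueError, match="reserved"):
            GeometryTable(["A"], [1], pd.DataFrame({"_hidden": [0]}))


class TestFilterRows:
    def test_boundary_inclusive(self):
        t = make_table({"D": [2.1, 2.5, 2.7]})
        sel = filter_rows(t, [("D", "<=", 2.5)])
        np.testing.assert_array_equal(sel.mask, [True, True, False])

    def test_empty_criteria_selects_all_visible(self, simple_table):
        simple_table.hidden[0] = True
        sel = filter_rows(simple_table, [])
        np.testing.assert_array_equal(sel.mask, ~simple_table.hidden)

    def test_conjunction_equals_mask_intersection(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            t = random_table(rng, n_cols=2, missing_rate=0.2)
            c1 = ("C0", "<=", float(rng.normal(0, 10)))
            c2 = ("C1", ">", float(rng.normal(0, 10)))
            both = filter_rows(t, [c1, c2]).mask
            expected = filter_rows(t, [c1]).mask & filter_rows(t, [c2]).mask
            np.testing.assert_array_equal(both, expected)

    def test_monotone_adding_criteria_never_grows(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            t = random_table(rng, n_cols=2)
            base = filter_rows(t, [("C0", ">", -5.0)]).mask
            more = filter_rows(t, [("C0", ">", -5.0), ("C1", "<", 5.0)]).mask
            assert not np.any(more & ~base)

    def test_missing_values_excluded(self):
        t = make_table({"D": [1.0, np.nan, 3.0]})
        sel = filter_rows(t, [("D", ">", 0.0)])
        np.testing.assert_array_equal(sel.mask, [True, False, True])

    def test_in_range_inclusive_both_ends(self):
        t = make_table({"D": [1.0, 2.0, 3.0, 4.0]})
        sel = filter_rows(t, [("D", "in-range", (2.0, 3.0))])
        np.testing.assert_array_equal(sel.mask, [False, True, True, False])

    def test_range_on_categorical_rejected(self, simple_table):
        with pytest.raises(TypeError):
            filter_rows(simple_table, [("LABEL", "in-range", (0, 1))])

    def test_hidden_rows_never_selected(self, simple_table):
        simple_table.hidden[:] = [True, False, True, False, False]
        sel = filter_rows(simple_table, [("GRP", ">=", 1)])
        assert not np.any(sel.mask & simple_table.hidden)

    def test_expression_parser_matches_tuples(self, simple_table):
        a = filter_rows(simple_table, parse_criteria("D <= 2.5 and GRP == 1"))
        b = filter_rows(simple_table, [("D", "<=", 2.5), ("GRP", "==", 1)])
        np.testing.assert_array_equal(a.mask, b.mask)
        c = filter_rows(simple_table, parse_criteria("D in 2.0..2.6"))
        d = filter_rows(simple_table, [("D", "in-range", (2.0, 2.6))])
        np.testing.assert_array_equal(c.mask, d.mask)


class TestGroupRows:
    def test_direct_partition(self):
        t = make_table({"G": [1, 2, 1]}, kinds={"G": "integer"})
        groups = group_rows(t, "G")
        assert set(groups) == {1, 2}
        np.testing.assert_array_equal(groups[1].mask, [True, False, True])
        np.testing.assert_array_equal(groups[2].mask, [False, True, False])

    def test_constant_column_single_group(self):
        t = make_table({"G": [3, 3, 3]}, kinds={"G": "integer"})
        groups = group_rows(t, "G")
        assert list(groups) == [3]
        assert groups[3].n_selected == 3

    def test_non_integer_descriptor_rejected(self, simple_table):
        with pytest.raises(TypeError):
            group_rows(simple_table, "D")

    def test_partition_property_on_random_tables(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            t = random_table(rng)
            t.hidden[rng.random(t.n_rows) < 0.3] = True
            groups = group_rows(t, "G")
            union = np.zeros(t.n_rows, dtype=bool)
            for a in groups.values():
                assert not np.any(union & a.mask)  # pairwise disjoint
                union |= a.mask
            eligible = ~t.hidden & ~np.isnan(t.values("G"))
            np.testing.assert_array_equal(union, eligible)


class TestPooling:
    def test_pool_is_multiset_of_sources(self):
        rng = np.random.default_rng(5)
        t = random_table(rng, n_rows=20, n_cols=3, missing_rate=0.2)
        pooled = pool_equivalent(t, ["C0", "C1", "C2"])
        expected = np.concatenate([t.nonmissing(c) for c in ["C0", "C1", "C2"]])
        np.testing.assert_array_equal(np.sort(pooled.values), np.sort(expected))

    def test_single_column_identity(self, simple_table):
        pooled = pool_equivalent(simple_table, ["D"])
        np.testing.assert_array_equal(pooled.values, simple_table.nonmissing("D"))

    def test_missing_cells_dropped(self):
        t = make_table({"A": [1.0, 2.0, 3.0], "B": [4.0, np.nan, 6.0]})
        pooled = pool_equivalent(t, ["A", "B"])
        assert len(pooled) == 5

    def test_column_major_provenance(self):
        t = make_table({"A": [1.0, 2.0], "B": [3.0, 4.0]})
        pooled = pool_equivalent(t, ["A", "B"])
        assert pooled.provenance == [(0, "A"), (1, "A"), (0, "B"), (1, "B")]
        np.testing.assert_array_equal(pooled.values, [1.0, 2.0, 3.0, 4.0])

    def test_mixed_kinds_rejected(self, simple_table):
        with pytest.raises(TypeError, match="mixed"):
            pool_equivalent(simple_table, ["D", "TOR"])

    def test_provenance_maps_to_real_cells(self):
        rng = np.random.default_rng(9)
        t = random_table(rng, n_rows=15, n_cols=2, missing_rate=0.3)
        pooled = pool_equivalent(t, ["C0", "C1"])
        for val, (row, col) in zip(pooled.values, pooled.provenance):
            assert t.values(col)[row] == val


class TestSelection:
    def test_complement_excludes_hidden(self, simple_table):
        simple_table.hidden[4] = True
        sel = Selection(np.array([True, False, False, False, False]))
        comp = sel.complement(simple_table)
        np.testing.assert_array_equal(comp.mask, [False, True, True, True, False])
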