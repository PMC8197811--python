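"""Geometry/charge file I/O and series loading."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from catdesc.structures import (
    Atom,
    ChargeTableError,
    Geometry,
    SeriesConfigError,
    XYZParseError,
    bond_length,
    load_series,
    read_charge_table,
    read_xyz,
    write_xyz,
)
from catdesc.synthetic import enzyme_demo_spec, generate_series


coord = st.floats(min_value=-100, max_value=100, allow_nan=False, width=32)


@st.composite
def geometries(draw):
    n = draw(st.integers(min_value=1, max_value=8))
    atoms = [
        Atom(draw(st.sampled_from(["C", "O", "Cl", "H", "N"])),
             np.array(draw(st.tuples(coord, coord, coord))))
        for _ in range(n)
    ]
    return Geometry(atoms=atoms, comment=draw(st.sampled_from(["", "energy=15.4", "x"])))


class TestXYZ:
    def test_two_atom_file_axis_aligned(self, tmp_path):
        p = tmp_path / "g.xyz"
        p.write_text("2\n\nO 0 0 0\nC 0 0 2.04\n")
        g = read_xyz(p)
        assert len(g) == 2
        assert bond_length(g, 1, 2) == pytest.approx(2.04, abs=1e-12)

    def test_count_mismatch_is_parse_error(self, tmp_path):
        p = tmp_path / "bad.xyz"
        p.write_text("3\ncomment\nO 0 0 0\nC 0 0 1\n")
        with pytest.raises(XYZParseError, match="3 atoms"):
            read_xyz(p)

    @pytest.mark.parametrize(
        "content, match",
        [
            ("", "empty"),
            ("nope\n\nO 0 0 0\n", "line 1"),
            ("1\n\nO 0 zero 0\n", "line 3"),
            ("1\n\nO 0 0\n", "line 3"),
        ],
    )
    def test_malformed_files_name_the_line(self, tmp_path, content, match):
        p = tmp_path / "bad.xyz"
        p.write_text(content)
        with pytest.raises(XYZParseError, match=match):
            read_xyz(p)

    @settings(deadline=None, max_examples=50)
    @given(g=geometries())
    def test_round_trip_preserves_coordinates(self, g, tmp_path_factory):
        path = tmp_path_factory.mktemp("xyz") / "g.xyz"
        write_xyz(g, path)
        g2 = read_xyz(path)
        assert len(g2) == len(g)
        assert np.allclose(g2.positions(), g.positions(), atol=1e-6)
        assert g2.comment == g.comment

    def test_comment_with_energy_preserved(self, tmp_path):
        g = Geometry([Atom("O", np.zeros(3))], comment="energy=15.4")
        p = tmp_path / "g.xyz"
        write_xyz(g, p)
        assert read_xyz(p).comment == "energy=15.4"

    def test_empty_geometry_rejected_before_write(self):
        with pytest.raises(ValueError, match="at least one atom"):
            Geometry(atoms=[])


class TestChargeTable:
    def test_reads_rows_keyed_by_index(self, tmp_path):
        p = tmp_path / "q.csv"
        p.write_text("index,label,charge\n1,O1,-0.88\n2,Cl1,-0.34\n")
        table = read_charge_table(p)
        assert len(table) == 2
        assert table.charge(1) == pytest.approx(-0.88)
        assert table.charge(2) == pytest.approx(-0.34)

    @pytest.mark.parametrize(
        "content, match",
        [
            ("index,label,charge\n1,O1,-0.88\n1,Cl1,-0.34\n", "duplicate"),
            ("", "no rows"),
            ("index,label,charge\n", "no rows"),
            ("index,label,charge\n1,O1,abc\n", "non-numeric"),
            ("idx,name,q\n1,O1,-0.88\n", "header"),
        ],
    )
    def test_malformed_tables_rejected(self, tmp_path, content, match):
        p = tmp_path / "q.csv"
        p.write_text(content)
        with pytest.raises(ChargeTableError, match=match):
            read_charge_table(p)


class TestBondLength:
    def test_axis_aligned_distance(self):
        g = Geometry([Atom("C", np.zeros(3)), Atom("Cl", np.array([0, 0, 2.47]))])
        assert bond_length(g, 1, 2) == pytest.approx(2.47, abs=1e-12)

    @settings(deadline=None, max_examples=100)
    @given(
        a=st.tuples(coord, coord, coord),
        b=st.tuples(coord, coord, coord),
        c=st.tuples(coord, coord, coord),
    )
    def test_metric_properties(self, a, b, c):
        """Symmetry, non-negativity, hand-computed formula, triangle inequality."""
        g = Geometry([Atom("C", np.array(a)), Atom("O", np.array(b)),
                      Atom("Cl", np.array(c))])
        d12 = bond_length(g, 1, 2)
        expected = math.sqrt(sum((ai - bi) ** 2 for ai, bi in zip(a, b)))
        assert d12 == pytest.approx(expected, rel=1e-12, abs=1e-12)
        assert d12 == bond_length(g, 2, 1)
        assert d12 >= 0
        assert d12 <= bond_length(g, 1, 3) + bond_length(g, 3, 2) + 1e-9

    def test_out_of_range_index(self):
        g = Geometry([Atom("C", np.zeros(3))])
        with pytest.raises(IndexError):
            bond_length(g, 1, 2)


class TestLoadSeries:
    def test_loads_generated_demo_series(self, tmp_path):
        series, config = generate_series(enzyme_demo_spec(), tmp_path)
        assert len(series) == 5
        assert series.labels == ["3", "2", "1", "0", "water"]
        reloaded = load_series(config)
        assert reloaded.labels == series.labels
        assert reloaded.get("3").barrier == pytest.approx(15.4)

    def test_duplicate_labels_rejected(self, tmp_path):
        _, config = generate_series(enzyme_demo_spec(), tmp_path)
        text = config.read_text().replace("label: '2'", "label: '3'")
        bad = tmp_path / "dup.yaml"
        bad.write_text(text)
        with pytest.raises(SeriesConfigError, match="duplicate"):
            load_series(bad)

    def test_bond_pairs_must_share_exactly_c1(self, tmp_path):
        from catdesc.structures import ReactionRecord
        from catdesc.synthetic import generate_record

        good = generate_record("x", 0.4, 0.2, 15.0, n_padding_atoms=1)
        # Disjoint pairs: leaving (2,3), forming (1,4) share no atom.
        with pytest.raises(SeriesConfigError, match="share exactly one"):
            ReactionRecord(label="x", ts=good.ts, rc=good.rc,
                           leaving_bond=(2, 3), forming_bond=(1, 4))
        # Identical pairs share two atoms: also rejected.
        with pytest.raises(SeriesConfigError, match="share exactly one"):
            ReactionRecord(label="x", ts=good.ts, rc=good.rc,
                           leaving_bond=(1, 2), forming_bond=(1, 2))

    def test_missing_file_rejected(self, tmp_path):
        _, config = generate_series(enzyme_demo_spec(), tmp_path)
        (tmp_path / "env_3_ts.xyz").unlink()
        with pytest.raises(SeriesConfigError, match="missing file"):
            load_series(config)

    def test_selection_out_of_range_rejected(self, tmp_path):
        _, config = generate_series(enzyme_demo_spec(), tmp_path)
        text = config.read_text().replace("cl1: 3", "cl1: 99")
        bad = tmp_path / "oor.yaml"
        bad.write_text(text)
        with pytest.raises(SeriesConfigError, match="out of range"):
            load_series(bad)
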