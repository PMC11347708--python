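import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_alignment, make_panel
from orthovar.alignment import (
    build_coordinate_map,
    parse_header,
    read_alignment,
    write_alignment,
)
from orthovar.errors import FormatError, ValidationError
from orthovar.panel import SpeciesEntry, SpeciesPanel, read_panel

MINIMAL_PANEL_TSV = (
    "species_id\tdisplay_name\tgroup\tmax_lifespan_years\n"
    "hsap\tHomo sapiens\treference\t122\n"
    "hatl\tOrange roughy\tfocal_a\t250\n"
    "hmed\tSilver roughy\tfocal_b\t11\n"
)


class TestSpeciesPanel:
    def test_minimal_three_species_panel_parses(self):
        panel = read_panel(io.StringIO(MINIMAL_PANEL_TSV))
        assert len(panel) == 3
        assert panel.reference_id == "hsap"
        assert panel.entry("hatl").max_lifespan_years == 250
        assert panel.entry("hmed").max_lifespan_years == 11

    def test_unknown_lifespan_is_none(self):
        tsv = MINIMAL_PANEL_TSV.replace("250", "")
        panel = read_panel(io.StringIO(tsv))
        assert panel.entry("hatl").max_lifespan_years is None

    def test_duplicate_species_id_is_format_error(self):
        tsv = MINIMAL_PANEL_TSV + "hmed\tAgain\tcomparison\t5\n"
        with pytest.raises(FormatError):
            read_panel(io.StringIO(tsv))

    @pytest.mark.parametrize(
        "mutation",
        [
            lambda t: t.replace("focal_a", "reference"),  # two references
            lambda t: t.replace("reference", "comparison"),  # zero references
            lambda t: t.replace("focal_b", "focal_a"),  # missing focal_b
            lambda t: t.replace("comparison", "???")
            + "xxx\tX\t???\t1\n",  # unknown group
        ],
    )
    def test_invariant_violations_raise(self, mutation):
        with pytest.raises(ValidationError):
            read_panel(io.StringIO(mutation(MINIMAL_PANEL_TSV)))


class TestReadAlignment:
    def test_two_identical_ungapped_rows(self, small_panel):
        fasta = ">hsap|XRCC5|copy1\nMKVLD\n>hatl|XRCC5|copy1\nMKVLD\n"
        aln = read_alignment(io.StringIO(fasta), small_panel)
        assert aln.length == 5
        assert aln.gene_symbol == "XRCC5"

    def test_header_grammar(self):
        assert parse_header("hsap|XRCC5|copy1") == ("hsap", "XRCC5", 1)
        assert parse_header("ssal|DOCK8|copy3") == ("ssal", "DOCK8", 3)
        with pytest.raises(FormatError):
            parse_header("hsap_XRCC5_1")

    def test_ragged_rows_are_format_error(self, small_panel):
        fasta = ">hsap|G|copy1\nMKVLDAQWER\n>hatl|G|copy1\nMKVLDAQWE\n"
        with pytest.raises(FormatError):
            read_alignment(io.StringIO(fasta), small_panel)

    def test_unknown_species_rejected(self, small_panel):
        fasta = ">zzzz|G|copy1\nMKVLD\n"
        with pytest.raises(ValidationError):
            read_alignment(io.StringIO(fasta), small_panel)

    def test_lowercase_uppercased_and_unknown_residue_coerced_to_x(self, small_panel):
        fasta = ">hsap|G|copy1\nmkvJd\n"
        aln = read_alignment(io.StringIO(fasta), small_panel)
        assert aln.row("hsap").seq == "MKVXD"

    def test_dot_gap_character_rejected(self, small_panel):
        with pytest.raises(FormatError):
            read_alignment(io.StringIO(">hsap|G|copy1\nMK.LD\n"), small_panel)

    def test_fasta_round_trip_with_wrapping(self, small_panel):
        seq_a = "".join("ACDEFGHIKLMNPQRSTVWY-" [i % 21] for i in range(150))
        aln = make_alignment({("hsap", 1): seq_a, ("hatl", 1): seq_a[::-1]})
        buf = io.StringIO()
        write_alignment(aln, buf)
        text = buf.getvalue()
        assert max(len(l) for l in text.splitlines() if not l.startswith(">")) <= 60
        back = read_alignment(io.StringIO(text), small_panel)
        assert back == aln


class TestCoordinateMap:
    def test_ungapped_reference_gives_identity_map(self):
        aln = make_alignment({("hsap", 1): "MKVLD", ("hatl", 1): "MKVLD"})
        cmap = build_coordinate_map(aln, "hsap")
        assert cmap.col_to_ref == {i: i for i in range(1, 6)}

    def test_gapped_reference_skips_gap_columns(self):
        aln = make_alignment({("hsap", 1): "M-KV", ("hatl", 1): "MAKV"})
        cmap = build_coordinate_map(aln, "hsap")
        assert cmap.col_to_ref == {1: 1, 3: 2, 4: 3}
        assert 2 not in cmap.col_to_ref
        assert cmap.ref_to_col == {1: 1, 2: 3, 3: 4}

    def test_reference_absent_or_multicopy_rejected(self):
        aln = make_alignment({("hatl", 1): "MKV", ("hmed", 1): "MKV"})
        with pytest.raises(ValidationError):
            build_coordinate_map(aln, "hsap")
        multi = make_alignment(
            {("hsap", 1): "MKV", ("hsap", 2): "MKV", ("hatl", 1): "MKV"}
        )
        with pytest.raises(ValidationError):
            build_coordinate_map(multi, "hsap")

    def test_round_trip_on_1000_seeded_gapped_rows(self):
        rng = np.random.default_rng(20240826)
        chars = np.array(list("ACDEFGHIKLMNPQRSTVWY-"))
        for _ in range(1000):
            length = int(rng.integers(1, 60))
            row = "".join(rng.choice(chars, size=length))
            if set(row) == {"-"}:
                row = row[:-1] + "M"
            aln = make_alignment({("hsap", 1): row, ("hatl", 1): "A" * length})
            cmap = build_coordinate_map(aln, "hsap")
            for col, pos in cmap.col_to_ref.items():
                assert cmap.ref_to_col[pos] == col
            positions = [cmap.col_to_ref[c] for c in sorted(cmap.col_to_ref)]
            assert positions == list(range(1, len(positions) + 1))
            assert len(cmap) == sum(ch != "-" for ch in row)

    @settings(derandomize=True, max_examples=200)
    @given(st.text(alphabet="MKVD-", min_size=1, max_size=40).filter(lambda s: set(s) != {"-"}))
    def test_round_trip_property(self, row):
        aln = make_alignment({("hsap", 1): row, ("hatl", 1): "A" * len(row)})
        cmap = build_coordinate_map(aln, "hsap")
        assert all(cmap.ref_to_col[cmap.col_to_ref[c]] == c for c in cmap.col_to_ref)
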