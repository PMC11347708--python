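import numpy as np
import pytest

from conftest import make_alignment, make_panel
from orthovar.alignment import build_coordinate_map
from orthovar.errors import BoundsError, ValidationError
from orthovar.scan import (
    annotate_paralog_sharing,
    profile_column,
    read_variants_tsv,
    scan_exclusive_variants,
    write_variants_tsv,
)
from oracle_utils import brute_force_scan, random_alignment_rows


def scan_toy(rows, panel=None, **kwargs):
    panel = panel or make_panel()
    aln = make_alignment(rows)
    cmap = build_coordinate_map(aln, "hsap")
    return scan_exclusive_variants(aln, cmap, panel, **kwargs)


class TestProfileColumn:
    def test_residues_and_missing_partition(self, small_panel, cmap_for):
        aln = make_alignment(
            {("hsap", 1): "E", ("hatl", 1): "Q", ("hmed", 1): "E", ("cmp01", 1): "-"}
        )
        prof = profile_column(aln, cmap_for(aln), 1)
        assert prof.residue_by_row == {
            ("hsap", 1): "E", ("hatl", 1): "Q", ("hmed", 1): "E"
        }
        assert prof.missing_rows == {("cmp01", 1)}
        assert prof.ref_pos == 1

    def test_out_of_range_column_raises(self, small_panel, cmap_for):
        aln = make_alignment({("hsap", 1): "E", ("hatl", 1): "E"})
        for bad in (0, 2):
            with pytest.raises(BoundsError):
                profile_column(aln, cmap_for(aln), bad)


class TestScanExclusiveVariants:
    def test_single_focal_a_difference_is_exclusive_a(self):
        variants = scan_toy(
            {("hsap", 1): "E", ("cmp01", 1): "E", ("cmp02", 1): "E",
             ("hatl", 1): "Q", ("hmed", 1): "E"}
        )
        (v,) = variants
        assert (v.ref_pos, v.ref_residue, v.alt_residue) == (1, "E", "Q")
        assert v.exclusivity == "exclusive_a"
        assert v.carrier_species == {"hatl"}
        assert v.label == "p.E1Q"

    def test_identical_columns_yield_no_variants(self):
        assert scan_toy(
            {("hsap", 1): "MKV", ("cmp01", 1): "MKV",
             ("hatl", 1): "MKV", ("hmed", 1): "MKV"}
        ) == []

    def test_panel_primary_carrier_revokes_exclusivity_but_stays_in_output(self):
        variants = scan_toy(
            {("hsap", 1): "E", ("cmp01", 1): "Q", ("cmp02", 1): "E",
             ("hatl", 1): "Q", ("hmed", 1): "E"}
        )
        (v,) = variants
        assert v.exclusivity == "not_exclusive"
        assert v.panel_carriers == {("cmp01", 1)}
        assert scan_toy(
            {("hsap", 1): "E", ("cmp01", 1): "Q", ("cmp02", 1): "E",
             ("hatl", 1): "Q", ("hmed", 1): "E"},
            exclusive_only=True,
        ) == []

    def test_both_focals_same_alt_is_exclusive_both(self):
        (v,) = scan_toy(
            {("hsap", 1): "S", ("cmp01", 1): "S",
             ("hatl", 1): "C", ("hmed", 1): "C"}
        )
        assert v.exclusivity == "exclusive_both"
        assert v.carrier_species == {"hatl", "hmed"}

    def test_two_alt_residues_give_two_records(self):
        # the two focal lineages diverge differently at one position
        variants = scan_toy(
            {("hsap", 1): "S", ("cmp01", 1): "S",
             ("hatl", 1): "C", ("hmed", 1): "R"}
        )
        assert [(v.alt_residue, v.exclusivity) for v in variants] == [
            ("C", "exclusive_a"), ("R", "exclusive_b")
        ]

    def test_missing_focal_or_reference_yields_no_variant(self):
        assert scan_toy(
            {("hsap", 1): "X", ("cmp01", 1): "E", ("hatl", 1): "Q", ("hmed", 1): "E"}
        ) == []
        assert scan_toy(
            {("hsap", 1): "E", ("cmp01", 1): "E", ("hatl", 1): "Q", ("hmed", 1): "-"}
        ) == []

    def test_reference_gap_columns_skipped(self):
        variants = scan_toy(
            {("hsap", 1): "-E", ("cmp01", 1): "AE", ("hatl", 1): "QQ", ("hmed", 1): "AE"}
        )
        assert [(v.ref_pos, v.alt_residue) for v in variants] == [(1, "Q")]

    def test_no_comparison_species_is_validation_error(self):
        panel = make_panel()
        aln = make_alignment({("hsap", 1): "E", ("hatl", 1): "Q", ("hmed", 1): "E"})
        cmap = build_coordinate_map(aln, "hsap")
        with pytest.raises(ValidationError):
            scan_exclusive_variants(aln, cmap, panel)


class TestParalogSharing:
    def rows_with_salmon_copies(self, copy_with_alt):
        rows = {
            ("hsap", 1): "R", ("cmp02", 1): "R",
            ("cmp01", 1): "R", ("cmp01", 2): "R", ("cmp01", 3): "R",
            ("hatl", 1): "R", ("hmed", 1): "H",
        }
        rows[("cmp01", copy_with_alt)] = "H"
        return rows

    def test_non_primary_copy_preserves_exclusivity_with_note(self):
        (v,) = scan_toy(self.rows_with_salmon_copies(3))
        aln = make_alignment(self.rows_with_salmon_copies(3))
        v = annotate_paralog_sharing(v, aln)
        assert v.exclusivity == "exclusive_b"
        assert v.paralog_note is not None and "copy 3" in v.paralog_note

    def test_primary_copy_revokes_exclusivity(self):
        (v,) = scan_toy(self.rows_with_salmon_copies(1))
        aln = make_alignment(self.rows_with_salmon_copies(1))
        assert annotate_paralog_sharing(v, aln).exclusivity == "not_exclusive"

    def test_no_sharing_leaves_variant_unchanged(self):
        rows = {("hsap", 1): "R", ("cmp01", 1): "R", ("hatl", 1): "R", ("hmed", 1): "H"}
        (v,) = scan_toy(rows)
        assert annotate_paralog_sharing(v, make_alignment(rows)) == v


def as_oracle_tuples(variants):
    return {
        (v.ref_pos, v.ref_residue, v.alt_residue, v.carrier_species,
         v.exclusivity, v.panel_carriers)
        for v in variants
    }


class TestOracleEquivalence:
    def test_matches_brute_force_on_random_alignments(self):
        """Column-by-column enumeration and the scanner agree exactly."""
        rng = np.random.default_rng(11)
        for _ in range(60):
            rows, groups = random_alignment_rows(rng, n_columns=40)
            aln = make_alignment(
                {(s, c): seq for s, c, seq in rows}, gene="GENE1"
            )
            from orthovar.panel import SpeciesEntry, SpeciesPanel

            panel = SpeciesPanel(
                [SpeciesEntry(s, s, g, 1.0) for s, g in groups.items()]
            )
            cmap = build_coordinate_map(aln, "hsap")
            got = as_oracle_tuples(scan_exclusive_variants(aln, cmap, panel))
            expected = brute_force_scan(rows, groups)
            assert got == expected

    def test_panel_monotonicity(self):
        """Adding a comparison species never creates a new exclusive variant."""
        rng = np.random.default_rng(17)
        for _ in range(30):
            rows, groups = random_alignment_rows(rng, max_species=10, n_columns=30)
            length = len(rows[0][2])
            extra = "".join(
                "ACDEFGHIKLMNPQRSTVWY-" [int(rng.integers(21))] for _ in range(length)
            )
            rows2 = rows + [("cmpxx", 1, extra)]
            groups2 = dict(groups, cmpxx="comparison")

            def exclusives(rws, grps):
                return {
                    (t[0], t[2], t[3]) for t in brute_force_scan(rws, grps)
                    if t[4] != "not_exclusive"
                }

            from orthovar.panel import SpeciesEntry, SpeciesPanel

            def scan_set(rws, grps):
                aln = make_alignment({(s, c): q for s, c, q in rws})
                panel = SpeciesPanel([SpeciesEntry(s, s, g, 1.0) for s, g in grps.items()])
                cmap = build_coordinate_map(aln, "hsap")
                return {
                    (v.ref_pos, v.alt_residue, v.carrier_species)
                    for v in scan_exclusive_variants(aln, cmap, panel, exclusive_only=True)
                }

            assert scan_set(rows2, groups2) <= scan_set(rows, groups)


def test_variants_tsv_round_trip():
    variants = scan_toy(
        {("hsap", 1): "SE", ("cmp01", 1): "SE",
         ("hatl", 1): "CE", ("hmed", 1): "RQ"}
    )
    import io

    buf = io.StringIO()
    write_variants_tsv(variants, buf)
    buf.seek(0)
    assert read_variants_tsv(buf) == variants
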