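import pytest

from orthovar.alignment import AlignmentRow, ProteinAlignment, build_coordinate_map
from orthovar.panel import SpeciesEntry, SpeciesPanel


def make_panel(n_comparison=2, n_long=1, n_short=1):
    """Small panel: hsap reference, hatl/hmed focals, cmpNN, lngNN, shtNN."""
    entries = [
        SpeciesEntry("hsap", "Homo sapiens", "reference", 122.0),
        SpeciesEntry("hatl", "Hoplostethus atlanticus", "focal_a", 250.0),
        SpeciesEntry("hmed", "Hoplostethus mediterraneus", "focal_b", 11.0),
    ]
    entries += [
        SpeciesEntry(f"cmp{i:02d}", f"Comparison {i}", "comparison", 10.0)
        for i in range(1, n_comparison + 1)
    ]
    entries += [
        SpeciesEntry(f"lng{i:02d}", f"Long-lived {i}", "long_lived", 100.0)
        for i in range(1, n_long + 1)
    ]
    entries += [
        SpeciesEntry(f"sht{i:02d}", f"Short-lived {i}", "short_lived", 2.0)
        for i in range(1, n_short + 1)
    ]
    return SpeciesPanel(entries)


def make_alignment(rows, gene="GENE1"):
    """rows: mapping (species_id, copy_index) -> aligned sequence string."""
    return ProteinAlignment(
        gene_symbol=gene,
        rows=[AlignmentRow(sp, copy, seq) for (sp, copy), seq in rows.items()],
    )


@pytest.fixture
def small_panel():
    return make_panel()


@pytest.fixture
def cmap_for():
    def _build(aln, reference="hsap"):
        return build_coordinate_map(aln, reference)

    return _build
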