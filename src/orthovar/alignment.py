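"""Per-gene protein alignments and reference-coordinate mapping.

Alignments arrive as aligned FASTA with the fixed header grammar
``species_id|gene|copyN`` (``copy1`` is the primary ortholog; higher copy
indices are within-species paralogs).  ``-`` is the only gap character; ``X``
marks unknown residues and ``*`` a premature stop.  All three are treated as
missing data downstream — they never enter any denominator.

Positions are reported in 1-based ungapped numbering along the reference
species' row; :class:`CoordinateMap` converts between alignment columns and
reference residue numbers in both directions.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, ValidationError
from .panel import SpeciesPanel

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
MISSING_CHARS = frozenset({"X", GAP, "*"})
_VALID_CHARS = frozenset(AMINO_ACIDS) | MISSING_CHARS

_HEADER_RE = re.compile(r"^(?P<species>[^|\s]+)\|(?P<gene>[^|\s]+)\|copy(?P<copy>[1-9]\d*)$")

FASTA_WRAP = 60


@dataclass(frozen=True)
class AlignmentRow:
    species_id: str
    copy_index: int
    seq: str

    @property
    def is_primary(self) -> bool:
        return self.copy_index == 1


@dataclass
class ProteinAlignment:
    """Aligned rows of one gene keyed by (species_id, copy_index)."""

    gene_symbol: str
    rows: list[AlignmentRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValidationError(f"alignment for {self.gene_symbol!r} has no rows")
        lengths = {len(r.seq) for r in self.rows}
        if len(lengths) != 1:
            raise FormatError(
                f"ragged alignment for {self.gene_symbol!r}: row lengths {sorted(lengths)}"
            )
        keys = [(r.species_id, r.copy_index) for r in self.rows]
        if len(set(keys)) != len(keys):
            raise ValidationError(
                f"duplicate (species, copy) rows in alignment {self.gene_symbol!r}"
            )

    @property
    def length(self) -> int:
        return len(self.rows[0].seq)

    def species_ids(self) -> set[str]:
        return {r.species_id for r in self.rows}

    def rows_for(self, species_id: str) -> list[AlignmentRow]:
        return [r for r in self.rows if r.species_id == species_id]

    def row(self, species_id: str, copy_index: int = 1) -> AlignmentRow:
        for r in self.rows:
            if r.species_id == species_id and r.copy_index == copy_index:
                return r
        raise KeyError((species_id, copy_index))

    def validate_against(self, panel: SpeciesPanel) -> None:
        unknown = self.species_ids() - {e.species_id for e in panel.entries}
        if unknown:
            raise ValidationError(
                f"alignment {self.gene_symbol!r} contains species not in panel: "
                f"{sorted(unknown)}"
            )
        ref_rows = self.rows_for(panel.reference_id)
        if ref_rows and all(set(r.seq) <= {GAP} for r in ref_rows):
            raise ValidationError(
                f"reference row of {self.gene_symbol!r} is entirely gapped"
            )


def _clean_sequence(raw: str, header: str) -> str:
    seq = raw.upper()
    if "." in seq:
        raise FormatError(f"'.' gap character not accepted (record {header!r})")
    cleaned = []
    coerced = 0
    for ch in seq:
        if ch in _VALID_CHARS:
            cleaned.append(ch)
        else:
            cleaned.append("X")
            coerced += 1
    if coerced:
        logger.warning(
            "record %r: coerced %d unknown residue character(s) to X", header, coerced
        )
    return "".join(cleaned)


def parse_header(header: str) -> tuple[str, str, int]:
    """Split a ``species_id|gene|copyN`` FASTA header."""
    m = _HEADER_RE.match(header)
    if m is None:
        raise FormatError(f"malformed FASTA header {header!r} (expected species|gene|copyN)")
    return m.group("species"), m.group("gene"), int(m.group("copy"))


def read_alignment(source, panel: Optional[SpeciesPanel] = None,
                   gene_symbol: Optional[str] = None) -> ProteinAlignment:
    """Read one gene's aligned FASTA.

    All records must name the same gene; rows must have identical length.
    When a panel is given, every species must be a panel member.
    """
    rows: list[AlignmentRow] = []
    gene = gene_symbol
    for record in SeqIO.parse(source, "fasta"):
        species, rec_gene, copy = parse_header(record.id)
        if gene is None:
            gene = rec_gene
        elif rec_gene != gene:
            raise FormatError(
                f"mixed genes in one alignment file: {gene!r} vs {rec_gene!r}"
            )
        rows.append(AlignmentRow(species, copy, _clean_sequence(str(record.seq), record.id)))
    if gene is None:
        raise FormatError("empty FASTA stream")
    aln = ProteinAlignment(gene_symbol=gene, rows=rows)
    if panel is not None:
        aln.validate_against(panel)
    logger.info("read alignment %s: %d rows x %d columns", gene, len(rows), aln.length)
    return aln


def write_alignment(aln: ProteinAlignment, target) -> None:
    """Write aligned FASTA wrapped at 60 columns (round-trips with read)."""
    records = [
        SeqRecord(Seq(r.seq), id=f"{r.species_id}|{aln.gene_symbol}|copy{r.copy_index}",
                  description="")
        for r in aln.rows
    ]
    writer = SeqIO.FastaIO.FastaWriter(target, wrap=FASTA_WRAP)
    writer.write_file(records)


@dataclass
class CoordinateMap:
    """Bidirectional column <-> reference-residue numbering for one gene.

    Columns where the reference row is gapped have no residue number and are
    absent from both maps; numbering starts at 1 at the first non-gap
    reference character.
    """

    gene_symbol: str
    col_to_ref: dict[int, int]
    ref_to_col: dict[int, int]

    def __len__(self) -> int:
        return len(self.col_to_ref)


def build_coordinate_map(aln: ProteinAlignment, reference_species: str) -> CoordinateMap:
    ref_rows = aln.rows_for(reference_species)
    if len(ref_rows) != 1:
        raise ValidationError(
            f"reference species {reference_species!r} must have exactly one row "
            f"in {aln.gene_symbol!r}, found {len(ref_rows)}"
        )
    col_to_ref: dict[int, int] = {}
    residue = 0
    for col, ch in enumerate(ref_rows[0].seq, start=1):
        if ch != GAP:
            residue += 1
            col_to_ref[col] = residue
    ref_to_col = {pos: col for col, pos in col_to_ref.items()}
    return CoordinateMap(aln.gene_symbol, col_to_ref, ref_to_col)
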