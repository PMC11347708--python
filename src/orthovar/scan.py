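"""Detection of residue variants exclusive to the focal species.

The selection rule operationalized here: a focal residue at a mapped column
is an *exclusive* variant when it differs from the reference residue and is
absent from the primary (copy 1) ortholog of every species in the
exclusivity panel (reference + comparison groups).  Extra paralog copies of
panel species may share the change without revoking exclusivity — such
sharing is recorded as a parallel-evolution note instead, mirroring how a
match in one of three salmon gene copies was reported, not used to discard.

Variant labels use 1-based reference numbering, ``p.<Ref><Pos><Alt>``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import pandas as pd

from .alignment import GAP, MISSING_CHARS, CoordinateMap, ProteinAlignment
from .errors import BoundsError, FormatError, ValidationError
from .panel import SpeciesPanel

logger = logging.getLogger(__name__)

EXCLUSIVITIES = ("exclusive_a", "exclusive_b", "exclusive_both", "not_exclusive")

VARIANTS_TSV_COLUMNS = [
    "gene", "ref_pos", "ref_residue", "alt_residue",
    "carriers", "exclusivity", "panel_carriers", "paralog_note",
]


@dataclass(frozen=True)
class ColumnProfile:
    """Residue content of one alignment column; missing rows listed apart."""

    gene_symbol: str
    column: int
    ref_pos: Optional[int]
    residue_by_row: dict[tuple[str, int], str]
    missing_rows: frozenset[tuple[str, int]]


@dataclass(frozen=True)
class ResidueVariant:
    gene_symbol: str
    ref_pos: int
    ref_residue: str
    alt_residue: str
    carrier_species: frozenset[str]
    carrier_copies: frozenset[tuple[str, int]]
    exclusivity: str
    panel_carriers: frozenset[tuple[str, int]]
    paralog_note: Optional[str] = None

    @property
    def label(self) -> str:
        return f"p.{self.ref_residue}{self.ref_pos}{self.alt_residue}"

    @property
    def is_exclusive(self) -> bool:
        return self.exclusivity in ("exclusive_a", "exclusive_b", "exclusive_both")


def profile_column(aln: ProteinAlignment, cmap: CoordinateMap, column: int) -> ColumnProfile:
    """Deterministic per-column residue profile (1-based column index)."""
    if not 1 <= column <= aln.length:
        raise BoundsError(f"column {column} out of range 1..{aln.length}")
    residue_by_row: dict[tuple[str, int], str] = {}
    missing: set[tuple[str, int]] = set()
    for row in aln.rows:
        ch = row.seq[column - 1]
        key = (row.species_id, row.copy_index)
        if ch in MISSING_CHARS:
            missing.add(key)
        else:
            residue_by_row[key] = ch
    return ColumnProfile(
        gene_symbol=aln.gene_symbol,
        column=column,
        ref_pos=cmap.col_to_ref.get(column),
        residue_by_row=residue_by_row,
        missing_rows=frozenset(missing),
    )


def _exclusivity_verdict(carriers: frozenset[str], panel: SpeciesPanel,
                         panel_carriers: frozenset[tuple[str, int]]) -> str:
    if any(copy == 1 for _, copy in panel_carriers):
        return "not_exclusive"
    in_a = bool(carriers & set(panel.ids_in_group("focal_a")))
    in_b = bool(carriers & set(panel.ids_in_group("focal_b")))
    if in_a and in_b:
        return "exclusive_both"
    return "exclusive_a" if in_a else "exclusive_b"


def scan_exclusive_variants(
    aln: ProteinAlignment,
    cmap: CoordinateMap,
    panel: SpeciesPanel,
    exclusive_only: bool = False,
) -> list[ResidueVariant]:
    """Scan every mapped column for focal-species residue variants.

    Returns the full scan output (including ``not_exclusive`` records with
    their panel carriers) sorted by (gene, ref_pos, alt_residue); pass
    ``exclusive_only=True`` to keep only the exclusive set.  Columns where
    the reference residue or any focal species is entirely missing yield no
    variant.
    """
    if not set(panel.ids_in_group("comparison")) & aln.species_ids():
        raise ValidationError(
            f"alignment {aln.gene_symbol!r} contains no comparison species"
        )
    ref_id = panel.reference_id
    focal_ids = [s for s in panel.focal_ids if s in aln.species_ids()]
    excl_panel = set(panel.exclusivity_panel_ids)

    variants: list[ResidueVariant] = []
    for column, ref_pos in cmap.col_to_ref.items():
        prof = profile_column(aln, cmap, column)
        ref_residue = prof.residue_by_row.get((ref_id, 1))
        if ref_residue is None:
            continue  # reference X/* at this column: no comparable residue
        # a focal species counts as missing when every copy is missing
        if any(
            all((s, r.copy_index) in prof.missing_rows for r in aln.rows_for(s))
            for s in focal_ids
        ):
            continue
        # group focal carriers by alternative residue
        by_alt: dict[str, set[tuple[str, int]]] = {}
        for (species, copy), residue in prof.residue_by_row.items():
            if species in focal_ids and residue != ref_residue:
                by_alt.setdefault(residue, set()).add((species, copy))
        for alt, copies in sorted(by_alt.items()):
            panel_carriers = frozenset(
                key for key, residue in prof.residue_by_row.items()
                if residue == alt and key[0] in excl_panel
            )
            carriers = frozenset(s for s, _ in copies)
            variants.append(
                ResidueVariant(
                    gene_symbol=aln.gene_symbol,
                    ref_pos=ref_pos,
                    ref_residue=ref_residue,
                    alt_residue=alt,
                    carrier_species=carriers,
                    carrier_copies=frozenset(copies),
                    exclusivity=_exclusivity_verdict(carriers, panel, panel_carriers),
                    panel_carriers=panel_carriers,
                )
            )
    variants.sort(key=lambda v: (v.gene_symbol, v.ref_pos, v.alt_residue))
    if exclusive_only:
        variants = [v for v in variants if v.is_exclusive]
    return variants


def annotate_paralog_sharing(v: ResidueVariant, aln: ProteinAlignment) -> ResidueVariant:
    """Re-derive the paralog-sharing note from the recorded panel carriers.

    Panel carriers with copy_index > 1 never revoke exclusivity; they are
    flagged as parallel changes in duplicate gene copies.  A primary-copy
    carrier revokes it (idempotent with the scan's own verdict).
    """
    primary = sorted(k for k in v.panel_carriers if k[1] == 1)
    paralog = sorted(k for k in v.panel_carriers if k[1] > 1)
    exclusivity = v.exclusivity
    if primary and exclusivity != "not_exclusive":
        exclusivity = "not_exclusive"
    note = None
    if paralog:
        shared = ", ".join(f"{s} copy {c}" for s, c in paralog)
        note = f"same change in non-primary copies: {shared}"
    return replace(v, exclusivity=exclusivity, paralog_note=note)


# -- TSV round trip ------------------------------------------------------


def _fmt_copies(copies: Iterable[tuple[str, int]]) -> str:
    return ";".join(f"{s}.{c}" for s, c in sorted(copies))


def _parse_copies(cell: str) -> frozenset[tuple[str, int]]:
    if not cell:
        return frozenset()
    out = set()
    for item in cell.split(";"):
        species, _, copy = item.rpartition(".")
        out.add((species, int(copy)))
    return frozenset(out)


def write_variants_tsv(variants: Iterable[ResidueVariant], target) -> None:
    rows = [
        {
            "gene": v.gene_symbol,
            "ref_pos": v.ref_pos,
            "ref_residue": v.ref_residue,
            "alt_residue": v.alt_residue,
            "carriers": _fmt_copies(v.carrier_copies),
            "exclusivity": v.exclusivity,
            "panel_carriers": _fmt_copies(v.panel_carriers),
            "paralog_note": v.paralog_note or "",
        }
        for v in variants
    ]
    pd.DataFrame(rows, columns=VARIANTS_TSV_COLUMNS).to_csv(target, sep="\t", index=False)


def read_variants_tsv(source) -> list[ResidueVariant]:
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in VARIANTS_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"variants TSV missing columns: {missing}")
    out = []
    for _, row in df.iterrows():
        copies = _parse_copies(row["carriers"])
        if row["exclusivity"] not in EXCLUSIVITIES:
            raise FormatError(f"unknown exclusivity {row['exclusivity']!r}")
        out.append(
            ResidueVariant(
                gene_symbol=row["gene"],
                ref_pos=int(row["ref_pos"]),
                ref_residue=row["ref_residue"],
                alt_residue=row["alt_residue"],
                carrier_species=frozenset(s for s, _ in copies),
                carrier_copies=copies,
                exclusivity=row["exclusivity"],
                panel_carriers=_parse_copies(row["panel_carriers"]),
                paralog_note=row["paralog_note"] or None,
            )
        )
    return out
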