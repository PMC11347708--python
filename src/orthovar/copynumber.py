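"""Gene copy-number comparison: species-unique amplification screening.

A gene is an amplification candidate when its copy counts differ between
the two focal species AND the higher focal count strictly exceeds the count
in every assessed comparison-panel species.  Absent cells mean "not
assessed", never zero.  Candidates then pass a wet-lab evidence gate: a
candidate is discarded when its amplification was not supported by PCR, or
when PCR found the extra copies in the other focal species as well.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import pandas as pd

from .errors import FormatError, ValidationError
from .panel import SpeciesPanel

logger = logging.getLogger(__name__)

COPYNUM_TSV_COLUMNS = ["gene", "species_id", "copies"]
AMP_EVIDENCE_COLUMNS = ["gene", "pcr_supported", "extra_copies_found_in_other"]


@dataclass
class CopyNumberTable:
    """Sparse (gene, species) -> copy count; absent cell = not assessed."""

    cells: dict[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (gene, species), count in self.cells.items():
            if count < 0:
                raise ValidationError(f"negative copy count for ({gene}, {species})")

    def genes(self) -> list[str]:
        return sorted({g for g, _ in self.cells})

    def count(self, gene: str, species: str) -> int | None:
        return self.cells.get((gene, species))


@dataclass(frozen=True)
class AmplificationCandidate:
    gene_symbol: str
    amplified_species: str
    focal_counts: tuple[int, int]  # (amplified species, other focal)
    panel_max: int
    status: str = "candidate"  # candidate | retained | discarded_validation


def find_unique_amplifications(
    table: CopyNumberTable, panel: SpeciesPanel
) -> list[AmplificationCandidate]:
    """Select genes amplified uniquely in one focal species.

    Requires strict excess of the higher focal count over the other focal
    species and over every assessed comparison-panel count; ties are never
    candidates.  Genes missing a focal cell are skipped with a warning.
    """
    focal_a = panel.ids_in_group("focal_a")
    focal_b = panel.ids_in_group("focal_b")
    comparison = panel.ids_in_group("reference", "comparison")
    candidates: list[AmplificationCandidate] = []
    for gene in table.genes():
        focal_counts = {
            s: table.count(gene, s) for s in focal_a + focal_b
        }
        if any(c is None for c in focal_counts.values()):
            logger.warning("gene %s missing a focal copy count; skipped", gene)
            continue
        by_group = {
            "focal_a": max(focal_counts[s] for s in focal_a),
            "focal_b": max(focal_counts[s] for s in focal_b),
        }
        if by_group["focal_a"] == by_group["focal_b"]:
            continue
        hi_group = max(by_group, key=by_group.get)
        lo_group = "focal_b" if hi_group == "focal_a" else "focal_a"
        hi_species = max(
            panel.ids_in_group(hi_group), key=lambda s: (focal_counts[s], s)
        )
        panel_counts = [
            c for s in comparison if (c := table.count(gene, s)) is not None
        ]
        panel_max = max(panel_counts) if panel_counts else 0
        if panel_counts and by_group[hi_group] <= panel_max:
            continue
        candidates.append(
            AmplificationCandidate(
                gene_symbol=gene,
                amplified_species=hi_species,
                focal_counts=(by_group[hi_group], by_group[lo_group]),
                panel_max=panel_max,
            )
        )
    return candidates


def apply_validation(
    candidates: Iterable[AmplificationCandidate],
    evidence: Mapping[str, Mapping[str, bool]],
) -> list[AmplificationCandidate]:
    """Gate candidates by PCR evidence; every candidate must be covered."""
    out = []
    for cand in candidates:
        if cand.gene_symbol not in evidence:
            raise ValidationError(
                f"no amplification evidence for candidate gene {cand.gene_symbol!r}"
            )
        ev = evidence[cand.gene_symbol]
        discarded = (not ev["pcr_supported"]) or ev["extra_copies_found_in_other"]
        out.append(replace(cand, status="discarded_validation" if discarded else "retained"))
    return out


# -- TSV I/O -------------------------------------------------------------


def read_copy_number_table(source) -> CopyNumberTable:
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in COPYNUM_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"copy-number TSV missing columns: {missing}")
    cells: dict[tuple[str, str], int] = {}
    for _, row in df.iterrows():
        key = (row["gene"], row["species_id"])
        if key in cells:
            raise FormatError(f"duplicate copy-number cell for {key}")
        try:
            cells[key] = int(row["copies"])
        except ValueError as exc:
            raise FormatError(f"bad copy count {row['copies']!r} for {key}") from exc
    table = CopyNumberTable(cells)
    logger.info("read copy-number table: %d cells, %d genes", len(cells), len(table.genes()))
    return table


def write_copy_number_table(table: CopyNumberTable, target) -> None:
    rows = [
        {"gene": g, "species_id": s, "copies": c}
        for (g, s), c in sorted(table.cells.items())
    ]
    pd.DataFrame(rows, columns=COPYNUM_TSV_COLUMNS).to_csv(target, sep="\t", index=False)


def read_amplification_evidence(source) -> dict[str, dict[str, bool]]:
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in AMP_EVIDENCE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"amplification-evidence TSV missing columns: {missing}")
    out: dict[str, dict[str, bool]] = {}
    for _, row in df.iterrows():
        out[row["gene"]] = {
            "pcr_supported": _parse_bool(row["pcr_supported"]),
            "extra_copies_found_in_other": _parse_bool(row["extra_copies_found_in_other"]),
        }
    return out


def _parse_bool(cell: str) -> bool:
    low = cell.strip().lower()
    if low in {"true", "yes", "1"}:
        return True
    if low in {"false", "no", "0"}:
        return False
    raise FormatError(f"bad boolean cell {cell!r}")
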