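"""Species panel: the comparison universe for exclusivity screening.

A panel names every species that appears in the per-gene alignments and
assigns each a role:

* ``reference`` — the single species whose ungapped residue numbering anchors
  all reported positions (variant labels ``p.<Ref><Pos><Alt>``),
* ``focal_a`` / ``focal_b`` — the two lineages being contrasted (here the
  long-lived and short-lived congeners),
* ``comparison`` — species against which exclusivity is assessed,
* ``long_lived`` / ``short_lived`` — extreme-lifespan annotation panels that
  never revoke exclusivity but flag parallel evolution.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

GROUPS = frozenset(
    {"focal_a", "focal_b", "reference", "comparison", "long_lived", "short_lived"}
)

PANEL_COLUMNS = ["species_id", "display_name", "group", "max_lifespan_years"]


@dataclass(frozen=True)
class SpeciesEntry:
    """One species in the panel; lifespan is ``None`` when unknown."""

    species_id: str
    display_name: str
    group: str
    max_lifespan_years: Optional[float] = None


@dataclass
class SpeciesPanel:
    entries: list[SpeciesEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for e in self.entries:
            if e.species_id in seen:
                raise FormatError(f"duplicate species_id {e.species_id!r}")
            seen.add(e.species_id)
            if e.group not in GROUPS:
                raise ValidationError(
                    f"unknown group {e.group!r} for species {e.species_id!r}"
                )
            if e.max_lifespan_years is not None and e.max_lifespan_years <= 0:
                raise ValidationError(
                    f"max_lifespan_years must be positive for {e.species_id!r}"
                )
        refs = self.ids_in_group("reference")
        if len(refs) != 1:
            raise ValidationError(
                f"panel must contain exactly one reference species, found {len(refs)}"
            )
        for g in ("focal_a", "focal_b"):
            if not self.ids_in_group(g):
                raise ValidationError(f"panel must contain at least one {g} species")

    # -- lookups ---------------------------------------------------------

    def __contains__(self, species_id: str) -> bool:
        return any(e.species_id == species_id for e in self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def entry(self, species_id: str) -> SpeciesEntry:
        for e in self.entries:
            if e.species_id == species_id:
                return e
        raise KeyError(species_id)

    def group_of(self, species_id: str) -> str:
        return self.entry(species_id).group

    def ids_in_group(self, *groups: str) -> list[str]:
        return [e.species_id for e in self.entries if e.group in groups]

    @property
    def reference_id(self) -> str:
        return self.ids_in_group("reference")[0]

    @property
    def focal_ids(self) -> list[str]:
        return self.ids_in_group("focal_a", "focal_b")

    @property
    def exclusivity_panel_ids(self) -> list[str]:
        """Species whose primary copies can revoke exclusivity."""
        return self.ids_in_group("reference", "comparison")


def read_panel(source) -> SpeciesPanel:
    """Parse a species-panel TSV (header ``species_id display_name group
    max_lifespan_years``); an empty lifespan field means unknown."""
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"panel TSV missing columns: {missing}")
    entries = []
    for _, row in df.iterrows():
        raw = row["max_lifespan_years"].strip()
        if raw:
            try:
                lifespan: Optional[float] = float(raw)
            except ValueError as exc:
                raise FormatError(
                    f"bad max_lifespan_years {raw!r} for {row['species_id']!r}"
                ) from exc
        else:
            lifespan = None
        entries.append(
            SpeciesEntry(
                species_id=row["species_id"].strip(),
                display_name=row["display_name"].strip(),
                group=row["group"].strip(),
                max_lifespan_years=lifespan,
            )
        )
    panel = SpeciesPanel(entries)
    logger.info("read species panel: %d species", len(panel))
    return panel


def write_panel(panel: SpeciesPanel, target) -> None:
    rows = [
        {
            "species_id": e.species_id,
            "display_name": e.display_name,
            "group": e.group,
            "max_lifespan_years": "" if e.max_lifespan_years is None else format(e.max_lifespan_years, "g"),
        }
        for e in panel.entries
    ]
    pd.DataFrame(rows, columns=PANEL_COLUMNS).to_csv(target, sep="\t", index=False)
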