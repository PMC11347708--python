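"""Extreme-lifespan panel annotation and parallel-evolution flagging.

Candidate variants are cross-checked in long-lived and short-lived fish
panels: a panel species can show the *same* change (identical alternative
residue at the same reference position), a *different* change there, or be
reference-like.  Sharing of the identical change — in a lifespan panel or
in a non-primary gene copy of a comparison species — flags a putative case
of parallel evolution.  The flag is advisory: it never filters a candidate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

from .alignment import MISSING_CHARS, CoordinateMap, ProteinAlignment
from .errors import BoundsError
from .panel import SpeciesPanel
from .scan import ResidueVariant

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PanelAnnotation:
    variant: ResidueVariant
    same_change_long: frozenset[str]
    same_change_short: frozenset[str]
    other_change_long: frozenset[tuple[str, str]]
    other_change_short: frozenset[tuple[str, str]]
    parallel_evolution: bool


def annotate_panels(
    v: ResidueVariant,
    aln: ProteinAlignment,
    cmap: CoordinateMap,
    panel: SpeciesPanel,
) -> PanelAnnotation:
    """Classify each lifespan-panel species at the variant's position.

    Primary copies only; species missing from the alignment or gapped at
    the position are ignored (logged).  Parallel evolution is flagged when
    any panel species shares the identical change, or when the variant's
    own panel carriers include non-primary copies.
    """
    if v.ref_pos not in cmap.ref_to_col:
        raise BoundsError(
            f"position {v.ref_pos} unmapped in alignment {aln.gene_symbol!r}"
        )
    column = cmap.ref_to_col[v.ref_pos]
    same: dict[str, set[str]] = {"long_lived": set(), "short_lived": set()}
    other: dict[str, set[tuple[str, str]]] = {"long_lived": set(), "short_lived": set()}
    for group in ("long_lived", "short_lived"):
        for species in panel.ids_in_group(group):
            try:
                row = aln.row(species, 1)
            except KeyError:
                logger.info(
                    "lifespan-panel species %s absent from alignment %s",
                    species, aln.gene_symbol,
                )
                continue
            ch = row.seq[column - 1]
            if ch in MISSING_CHARS or ch == v.ref_residue:
                continue
            if ch == v.alt_residue:
                same[group].add(species)
            else:
                other[group].add((species, ch))
    paralog_sharers = {s for s, c in v.panel_carriers if c > 1}
    parallel = bool(same["long_lived"] or same["short_lived"] or paralog_sharers)
    return PanelAnnotation(
        variant=v,
        same_change_long=frozenset(same["long_lived"]),
        same_change_short=frozenset(same["short_lived"]),
        other_change_long=frozenset(other["long_lived"]),
        other_change_short=frozenset(other["short_lived"]),
        parallel_evolution=parallel,
    )
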