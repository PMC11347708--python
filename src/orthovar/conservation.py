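"""Per-position conservation statistics and physicochemical change labels.

Conservation is the majority-residue fraction over one vote per species
(primary copy only), with missing residues excluded from the denominator.
A position is called highly conserved when that fraction strictly exceeds
the threshold (default 0.80, i.e. "maintained in more than 80% of the
species").

Residue classes follow a fixed four-way table: nonpolar, polar, positively
charged, negatively charged.  Cysteine and glycine sit in the nonpolar
class and histidine in the positively charged class; the table is frozen so
descriptors like "polar to nonpolar" (S->C) and "polar to positively
charged" (S->R) are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .alignment import AMINO_ACIDS, MISSING_CHARS, CoordinateMap, ProteinAlignment
from .errors import BoundsError, UndefinedStatisticError, ValidationError

CONSERVED_THRESHOLD = 0.80

RESIDUE_CLASS: dict[str, str] = {}
for _aa in "AVLIMFWPGC":
    RESIDUE_CLASS[_aa] = "nonpolar"
for _aa in "STYNQ":
    RESIDUE_CLASS[_aa] = "polar"
for _aa in "KRH":
    RESIDUE_CLASS[_aa] = "positively_charged"
for _aa in "DE":
    RESIDUE_CLASS[_aa] = "negatively_charged"

_CLASS_CHARGE = {
    "nonpolar": 0,
    "polar": 0,
    "positively_charged": 1,
    "negatively_charged": -1,
}

_CLASS_LABEL = {
    "nonpolar": "nonpolar",
    "polar": "polar",
    "positively_charged": "positively charged",
    "negatively_charged": "negatively charged",
}


@dataclass(frozen=True)
class ConservationStat:
    gene_symbol: str
    ref_pos: int
    majority_residue: str
    fraction: float
    n_counted: int
    highly_conserved: bool
    tie: bool = False


@dataclass(frozen=True)
class PropertyChange:
    from_class: str
    to_class: str
    charge_delta: int
    descriptor: str


def conservation_at(
    aln: ProteinAlignment,
    cmap: CoordinateMap,
    ref_pos: int,
    exclude: Iterable[str] = (),
    threshold: float = CONSERVED_THRESHOLD,
) -> ConservationStat:
    """Majority-residue fraction at a reference position.

    One species one vote via its primary copy; species in ``exclude``
    (typically the focal species) and missing residues do not count.
    Majority ties break to the alphabetically first residue with the tie
    flag set.
    """
    if ref_pos not in cmap.ref_to_col:
        raise BoundsError(f"reference position {ref_pos} is unmapped in {aln.gene_symbol!r}")
    column = cmap.ref_to_col[ref_pos]
    excluded = set(exclude)
    counts: dict[str, int] = {}
    for row in aln.rows:
        if row.copy_index != 1 or row.species_id in excluded:
            continue
        ch = row.seq[column - 1]
        if ch in MISSING_CHARS:
            continue
        counts[ch] = counts.get(ch, 0) + 1
    n_counted = sum(counts.values())
    if n_counted == 0:
        raise UndefinedStatisticError(
            f"no counted residues at {aln.gene_symbol} position {ref_pos}"
        )
    top = max(counts.values())
    leaders = sorted(res for res, c in counts.items() if c == top)
    fraction = top / n_counted
    return ConservationStat(
        gene_symbol=aln.gene_symbol,
        ref_pos=ref_pos,
        majority_residue=leaders[0],
        fraction=fraction,
        n_counted=n_counted,
        highly_conserved=fraction > threshold,
        tie=len(leaders) > 1,
    )


def classify_residue_change(ref_residue: str, alt_residue: str) -> PropertyChange:
    """Physicochemical class transition for a substitution; total on the
    400 ordered amino-acid pairs, undefined for X/gap/stop."""
    for res in (ref_residue, alt_residue):
        if res not in RESIDUE_CLASS:
            raise ValidationError(f"cannot classify non-standard residue {res!r}")
    from_class = RESIDUE_CLASS[ref_residue]
    to_class = RESIDUE_CLASS[alt_residue]
    delta = _CLASS_CHARGE[to_class] - _CLASS_CHARGE[from_class]
    delta = (delta > 0) - (delta < 0)
    if ref_residue == alt_residue:
        descriptor = "no change"
    elif from_class == to_class:
        descriptor = f"{_CLASS_LABEL[from_class]} conserved"
    else:
        descriptor = f"{_CLASS_LABEL[from_class]} to {_CLASS_LABEL[to_class]}"
    return PropertyChange(from_class=from_class, to_class=to_class,
                          charge_delta=delta, descriptor=descriptor)
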