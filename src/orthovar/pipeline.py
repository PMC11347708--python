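"""Candidate selection: exclusivity x database feature x validation evidence.

A point variant becomes a retained candidate when it

1. is exclusive to one (or both) of the focal species — absent from the
   primary ortholog of every reference/comparison species (rule 1),
2. is featured in at least one database (ClinVar link, conserved
   domain/motif, UniProt feature, or literature support; rule 2), and
3. is not contradicted by validation evidence: any explicit "no" in the
   RNA-seq, genomic or PCR columns discards it.  "no reads" (transcript not
   expressed in the sampled tissue) and "not done" are non-disqualifying,
   so a variant with genomic and PCR support but no RNA-seq coverage is
   retained.

Retained candidates are grouped by hallmark of aging via a gene->hallmark
map and summarized as counts (total, per species, per gene, per hallmark).
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Union

import pandas as pd

from .effects import EffectAnnotation
from .errors import FormatError, ValidationError
from .lifespan import PanelAnnotation
from .scan import EXCLUSIVITIES, ResidueVariant

logger = logging.getLogger(__name__)

HALLMARKS = (
    "genomic instability",
    "telomere attrition",
    "epigenetic alterations",
    "loss of proteostasis",
    "disabled macroautophagy",
    "deregulated nutrient sensing",
    "mitochondrial dysfunction",
    "cellular senescence",
    "stem cell exhaustion",
    "altered intercellular communication",
    "chronic inflammation",
    "dysbiosis",
)

RNASEQ_VALUES = ("yes", "no", "no_reads", "not_done")
GENOMIC_VALUES = ("yes", "no", "not_done")
PCR_VALUES = ("yes", "no", "not_done")

_VARIANT_LABEL_RE = re.compile(r"^(?:p\.)?([A-Z])(\d+)([A-Z])$")

_SIFT_CODE = {"affects_protein_function": "APF", "tolerated": "T"}
_SIFT_FROM_CODE = {v: k for k, v in _SIFT_CODE.items()}
_POLYPHEN_CODE = {"benign": "B", "possibly_damaging": "PsD", "probably_damaging": "PbD"}
_POLYPHEN_FROM_CODE = {v: k for k, v in _POLYPHEN_CODE.items()}

CANDIDATE_TABLE_COLUMNS = [
    "gene", "variant", "species", "exclusivity",
    "rnaseq_validation", "genomic_validation", "pcr_validation",
    "sift", "polyphen", "clinvar_accession", "database_flags",
    "hallmark", "retained", "note",
]


def parse_variant_label(label: str) -> tuple[str, int, str]:
    """Split ``p.E417Q`` (the ``p.`` prefix is optional) into (ref, pos, alt)."""
    m = _VARIANT_LABEL_RE.match(label.strip())
    if m is None:
        raise FormatError(f"malformed variant label {label!r}")
    return m.group(1), int(m.group(2)), m.group(3)


def normalize_variant_label(label: str) -> str:
    ref, pos, alt = parse_variant_label(label)
    return f"p.{ref}{pos}{alt}"


@dataclass(frozen=True)
class ValidationEvidence:
    rnaseq: str = "not_done"
    genomic: str = "not_done"
    pcr: str = "not_done"
    notes: str = ""

    def __post_init__(self) -> None:
        if self.rnaseq not in RNASEQ_VALUES:
            raise ValidationError(f"bad rnaseq evidence {self.rnaseq!r}")
        if self.genomic not in GENOMIC_VALUES:
            raise ValidationError(f"bad genomic evidence {self.genomic!r}")
        if self.pcr not in PCR_VALUES:
            raise ValidationError(f"bad pcr evidence {self.pcr!r}")

    @property
    def contradicted(self) -> bool:
        return "no" in (self.rnaseq, self.genomic, self.pcr)


@dataclass(frozen=True)
class VariantKey:
    """Identifier + exclusivity verdict for one candidate input."""

    gene_symbol: str
    variant_label: str
    species: str
    exclusivity: str

    def __post_init__(self) -> None:
        if self.exclusivity not in EXCLUSIVITIES:
            raise ValidationError(f"unknown exclusivity {self.exclusivity!r}")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.gene_symbol, self.variant_label, self.species)

    @property
    def ref_pos(self) -> int:
        return parse_variant_label(self.variant_label)[1]


@dataclass(frozen=True)
class CandidateRecord:
    gene_symbol: str
    variant_label: str
    species: str
    exclusivity: str
    evidence: ValidationEvidence
    effect: EffectAnnotation
    hallmark: str = "unassigned"
    retained: bool = False
    panel_annotation: Optional[PanelAnnotation] = None
    note: str = ""

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.gene_symbol, self.variant_label, self.species)

    @property
    def ref_pos(self) -> int:
        return parse_variant_label(self.variant_label)[1]


def _variant_keys(variants: Iterable[Union[VariantKey, ResidueVariant]]) -> list[VariantKey]:
    keys: list[VariantKey] = []
    for v in variants:
        if isinstance(v, VariantKey):
            keys.append(v)
        elif isinstance(v, ResidueVariant):
            for species in sorted(v.carrier_species):
                keys.append(
                    VariantKey(v.gene_symbol, v.label, species, v.exclusivity)
                )
        else:
            raise TypeError(f"unsupported variant input {type(v).__name__}")
    return keys


def select_candidates(
    variants: Iterable[Union[VariantKey, ResidueVariant]],
    effects: Mapping[tuple[str, str, str], EffectAnnotation],
    evidence: Mapping[tuple[str, str, str], ValidationEvidence],
) -> list[CandidateRecord]:
    """Apply rules 1 and 2 and the evidence gate to every variant input.

    All three inputs are keyed by (gene, variant_label, species); a variant
    without an effect annotation or evidence entry raises a validation
    error naming the key.  Output is sorted by (gene, ref_pos, species).
    """
    records: list[CandidateRecord] = []
    for vk in _variant_keys(variants):
        if vk.key not in effects:
            raise ValidationError(f"no effect annotation for variant {vk.key}")
        if vk.key not in evidence:
            raise ValidationError(f"no validation evidence for variant {vk.key}")
        eff = effects[vk.key]
        ev = evidence[vk.key]
        rule1 = vk.exclusivity in ("exclusive_a", "exclusive_b", "exclusive_both")
        rule2 = eff.database_featured()
        retained = rule1 and rule2 and not ev.contradicted
        records.append(
            CandidateRecord(
                gene_symbol=vk.gene_symbol,
                variant_label=normalize_variant_label(vk.variant_label),
                species=vk.species,
                exclusivity=vk.exclusivity,
                evidence=ev,
                effect=eff,
                retained=retained,
            )
        )
    records.sort(key=lambda r: (r.gene_symbol, r.ref_pos, r.species))
    return records


def reselect(records: Iterable[CandidateRecord]) -> list[CandidateRecord]:
    """Recompute the retained flag of existing records from their own
    stored exclusivity, flags and evidence (idempotent)."""
    recs = list(records)
    variants = [
        VariantKey(r.gene_symbol, r.variant_label, r.species, r.exclusivity)
        for r in recs
    ]
    effects = {r.key: r.effect for r in recs}
    evidence = {r.key: r.evidence for r in recs}
    selected = {r.key: r for r in select_candidates(variants, effects, evidence)}
    return [
        replace(r, retained=selected[r.key].retained)
        for r in sorted(recs, key=lambda r: (r.gene_symbol, r.ref_pos, r.species))
    ]


# -- hallmark grouping ---------------------------------------------------


@dataclass
class HallmarkMap:
    """Gene -> hallmark-of-aging label (one hallmark per gene)."""

    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, hallmark in self.mapping.items():
            if hallmark not in HALLMARKS:
                raise ValidationError(
                    f"unknown hallmark {hallmark!r} for gene {gene!r}"
                )

    def get(self, gene: str) -> Optional[str]:
        return self.mapping.get(gene)


def assign_hallmarks(
    records: Iterable[CandidateRecord], hallmark_map: HallmarkMap
) -> list[CandidateRecord]:
    out = []
    for r in records:
        hallmark = hallmark_map.get(r.gene_symbol)
        if hallmark is None:
            if r.retained:
                logger.warning("retained gene %s has no hallmark mapping", r.gene_symbol)
            hallmark = "unassigned"
        out.append(replace(r, hallmark=hallmark))
    return out


def read_hallmark_map(source) -> HallmarkMap:
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    for col in ("gene", "hallmark"):
        if col not in df.columns:
            raise FormatError(f"hallmark TSV missing column {col!r}")
    return HallmarkMap(dict(zip(df["gene"], df["hallmark"])))


# -- summaries -----------------------------------------------------------


@dataclass(frozen=True)
class CandidateSummary:
    total: int
    per_species: dict[str, int]
    per_gene: dict[str, int]
    per_hallmark: dict[str, int]
    per_gene_species: dict[tuple[str, str], int]

    def count(self, gene: Optional[str] = None, species: Optional[str] = None) -> int:
        if gene is not None and species is not None:
            return self.per_gene_species.get((gene, species), 0)
        if gene is not None:
            return self.per_gene.get(gene, 0)
        if species is not None:
            return self.per_species.get(species, 0)
        return self.total


def summarize(records: Iterable[CandidateRecord]) -> CandidateSummary:
    """Count retained candidates; totals are additive over every breakdown."""
    retained = [r for r in records if r.retained]
    return CandidateSummary(
        total=len(retained),
        per_species=dict(Counter(r.species for r in retained)),
        per_gene=dict(Counter(r.gene_symbol for r in retained)),
        per_hallmark=dict(Counter(r.hallmark for r in retained)),
        per_gene_species=dict(Counter((r.gene_symbol, r.species) for r in retained)),
    )


def format_summary(summary: CandidateSummary) -> str:
    lines = [f"retained candidate variants: {summary.total}", "", "by species:"]
    for species, n in sorted(summary.per_species.items()):
        lines.append(f"  {species}\t{n}")
    lines.append("by gene:")
    for gene, n in sorted(summary.per_gene.items()):
        lines.append(f"  {gene}\t{n}")
    lines.append("by hallmark:")
    for hallmark, n in sorted(summary.per_hallmark.items()):
        lines.append(f"  {hallmark}\t{n}")
    return "\n".join(lines)


EVIDENCE_TSV_COLUMNS = ["gene", "variant", "species", "rnaseq", "genomic", "pcr", "notes"]


def read_evidence_tsv(source) -> dict[tuple[str, str, str], ValidationEvidence]:
    """Read per-variant validation evidence keyed by (gene, label, species)."""
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in EVIDENCE_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"evidence TSV missing columns: {missing}")
    out: dict[tuple[str, str, str], ValidationEvidence] = {}
    for _, row in df.iterrows():
        key = (row["gene"], normalize_variant_label(row["variant"]), row["species"])
        out[key] = ValidationEvidence(
            rnaseq=_parse_evidence_cell(row["rnaseq"]),
            genomic=_parse_evidence_cell(row["genomic"]),
            pcr=_parse_evidence_cell(row["pcr"]),
            notes=row["notes"],
        )
    return out


# -- Table-2-style TSV round trip ---------------------------------------


_SCORE_CELL_RE = re.compile(r"^([A-Za-z]+) \(([0-9.]+)\)$")


def _format_score_cell(code_map: dict[str, str], category: Optional[str],
                       score: Optional[float]) -> str:
    if category is None:
        return "-"
    return f"{code_map[category]} ({format(score, 'g')})"


def _parse_score_cell(cell: str, from_code: dict[str, str], line: int):
    cell = cell.strip()
    if cell in ("", "-", "–"):
        return None, None
    m = _SCORE_CELL_RE.match(cell)
    if m is None or m.group(1) not in from_code:
        raise FormatError(f"line {line}: malformed score cell {cell!r}")
    return from_code[m.group(1)], float(m.group(2))


def _parse_evidence_cell(cell: str) -> str:
    low = cell.strip().lower().replace(" ", "_")
    if low in ("-", "–", ""):
        return "not_done"
    return low


def write_candidate_table(records: Iterable[CandidateRecord], target) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "gene": r.gene_symbol,
                "variant": r.variant_label,
                "species": r.species,
                "exclusivity": r.exclusivity,
                "rnaseq_validation": r.evidence.rnaseq,
                "genomic_validation": r.evidence.genomic,
                "pcr_validation": r.evidence.pcr,
                "sift": _format_score_cell(_SIFT_CODE, r.effect.sift_category,
                                           r.effect.sift_score),
                "polyphen": _format_score_cell(_POLYPHEN_CODE, r.effect.polyphen_category,
                                               r.effect.polyphen_score),
                "clinvar_accession": r.effect.clinvar_accession or "-",
                "database_flags": ";".join(sorted(r.effect.database_flags)),
                "hallmark": r.hallmark,
                "retained": "true" if r.retained else "false",
                "note": r.note,
            }
        )
    pd.DataFrame(rows, columns=CANDIDATE_TABLE_COLUMNS).to_csv(target, sep="\t", index=False)


def read_candidate_table(source) -> list[CandidateRecord]:
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in CANDIDATE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"candidate table missing columns: {missing}")
    records = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            sift_cat, sift_score = _parse_score_cell(row["sift"], _SIFT_FROM_CODE, line)
            pp_cat, pp_score = _parse_score_cell(row["polyphen"], _POLYPHEN_FROM_CODE, line)
            accession = row["clinvar_accession"].strip()
            if accession in ("-", "–"):
                accession = ""
            flags = frozenset(f for f in row["database_flags"].split(";") if f)
            effect = EffectAnnotation(
                sift_score=sift_score,
                sift_category=sift_cat,
                polyphen_score=pp_score,
                polyphen_category=pp_cat,
                database_flags=flags | ({"clinvar"} if accession else frozenset()),
                clinvar_accession=accession or None,
            )
            evidence = ValidationEvidence(
                rnaseq=_parse_evidence_cell(row["rnaseq_validation"]),
                genomic=_parse_evidence_cell(row["genomic_validation"]),
                pcr=_parse_evidence_cell(row["pcr_validation"]),
            )
            records.append(
                CandidateRecord(
                    gene_symbol=row["gene"],
                    variant_label=normalize_variant_label(row["variant"]),
                    species=row["species"],
                    exclusivity=row["exclusivity"] or "not_exclusive",
                    evidence=evidence,
                    effect=effect,
                    hallmark=row["hallmark"] or "unassigned",
                    retained=row["retained"].strip().lower() == "true",
                    note=row["note"],
                )
            )
        except (FormatError, ValidationError) as exc:
            raise FormatError(f"line {line}: {exc}") from exc
    logger.info("read candidate table: %d rows", len(records))
    return records
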