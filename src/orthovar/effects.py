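"""External effect-prediction scores and the database-feature rule.

SIFT and PolyPhen scores are consumed, never computed.  The default
categorization thresholds are the tool authors' published conventions:
SIFT calls a substitution "affects protein function" at score <= 0.05;
PolyPhen (HumDiv) calls benign below 0.452, possibly damaging up to 0.956
and probably damaging above it.  Both are configurable.

A variant satisfies the database-feature rule when at least one database
flag is set: a ClinVar-linked position, membership of a conserved domain or
motif, an annotated UniProt feature, or literature support.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .errors import FormatError, ValidationError

SIFT_THRESHOLD = 0.05
POLYPHEN_BENIGN_MAX = 0.452     # exclusive upper bound of the benign band
POLYPHEN_PROBABLY_MIN = 0.956   # exclusive lower bound of probably damaging

SIFT_CATEGORIES = ("affects_protein_function", "tolerated")
POLYPHEN_CATEGORIES = ("benign", "possibly_damaging", "probably_damaging")

DATABASE_FLAGS = frozenset(
    {"clinvar", "conserved_domain_motif", "uniprot_feature", "literature"}
)

EFFECTS_TSV_COLUMNS = [
    "gene", "variant", "species", "sift_score", "polyphen_score",
    "clinvar_accession", "flags",
]


def categorize_sift(score: float, threshold: float = SIFT_THRESHOLD) -> str:
    if not 0.0 <= score <= 1.0:
        raise ValidationError(f"SIFT score {score} outside [0, 1]")
    return "affects_protein_function" if score <= threshold else "tolerated"


def categorize_polyphen(
    score: float,
    benign_max: float = POLYPHEN_BENIGN_MAX,
    probably_min: float = POLYPHEN_PROBABLY_MIN,
) -> str:
    if not 0.0 <= score <= 1.0:
        raise ValidationError(f"PolyPhen score {score} outside [0, 1]")
    if score < benign_max:
        return "benign"
    if score <= probably_min:
        return "possibly_damaging"
    return "probably_damaging"


@dataclass(frozen=True)
class EffectAnnotation:
    """Scores plus derived categories and database-feature flags.

    A category is present exactly when its score is; either predictor may
    be absent (e.g. a fish position with no confident human mapping).
    """

    sift_score: Optional[float] = None
    sift_category: Optional[str] = None
    polyphen_score: Optional[float] = None
    polyphen_category: Optional[str] = None
    database_flags: frozenset[str] = frozenset()
    clinvar_accession: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.sift_score is None) != (self.sift_category is None):
            raise ValidationError("SIFT score and category must be present together")
        if (self.polyphen_score is None) != (self.polyphen_category is None):
            raise ValidationError("PolyPhen score and category must be present together")
        if self.sift_category is not None and self.sift_category not in SIFT_CATEGORIES:
            raise ValidationError(f"unknown SIFT category {self.sift_category!r}")
        if (self.polyphen_category is not None
                and self.polyphen_category not in POLYPHEN_CATEGORIES):
            raise ValidationError(f"unknown PolyPhen category {self.polyphen_category!r}")
        unknown = set(self.database_flags) - DATABASE_FLAGS
        if unknown:
            raise ValidationError(f"unknown database flags {sorted(unknown)}")

    def database_featured(self) -> bool:
        return bool(self.database_flags)

    @classmethod
    def from_scores(
        cls,
        sift_score: Optional[float] = None,
        polyphen_score: Optional[float] = None,
        database_flags: frozenset[str] | set[str] = frozenset(),
        clinvar_accession: Optional[str] = None,
    ) -> "EffectAnnotation":
        """Build an annotation, deriving categories with default thresholds."""
        flags = frozenset(database_flags)
        if clinvar_accession:
            flags = flags | {"clinvar"}
        return cls(
            sift_score=sift_score,
            sift_category=None if sift_score is None else categorize_sift(sift_score),
            polyphen_score=polyphen_score,
            polyphen_category=(
                None if polyphen_score is None else categorize_polyphen(polyphen_score)
            ),
            database_flags=flags,
            clinvar_accession=clinvar_accession or None,
        )


def read_effects_tsv(source) -> dict[tuple[str, str, str], EffectAnnotation]:
    """Read an effect-score TSV keyed by (gene, variant_label, species).

    Flags are a semicolon-separated list; empty score cells mean the
    predictor gave no call for that variant.
    """
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in EFFECTS_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"effects TSV missing columns: {missing}")
    out: dict[tuple[str, str, str], EffectAnnotation] = {}
    for _, row in df.iterrows():
        key = (row["gene"], row["variant"], row["species"])
        flags = {f for f in row["flags"].split(";") if f}
        out[key] = EffectAnnotation.from_scores(
            sift_score=float(row["sift_score"]) if row["sift_score"] else None,
            polyphen_score=float(row["polyphen_score"]) if row["polyphen_score"] else None,
            database_flags=flags,
            clinvar_accession=row["clinvar_accession"] or None,
        )
    return out


def write_effects_tsv(effects: dict[tuple[str, str, str], EffectAnnotation], target) -> None:
    rows = []
    for (gene, variant, species), ann in sorted(effects.items()):
        rows.append(
            {
                "gene": gene,
                "variant": variant,
                "species": species,
                "sift_score": "" if ann.sift_score is None else format(ann.sift_score, "g"),
                "polyphen_score": (
                    "" if ann.polyphen_score is None else format(ann.polyphen_score, "g")
                ),
                "clinvar_accession": ann.clinvar_accession or "",
                "flags": ";".join(sorted(ann.database_flags)),
            }
        )
    pd.DataFrame(rows, columns=EFFECTS_TSV_COLUMNS).to_csv(target, sep="\t", index=False)
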