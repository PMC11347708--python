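"""Synthetic panel datasets with known planted truth, plus packaged fixtures.

The generator emulates the study design: one reference species, two focal
congeners, a comparison panel, and long-/short-lived annotation panels.
Each gene starts from an ancestral sequence drawn uniformly over the 20
amino acids; every species row receives i.i.d. per-cell substitution noise
(to a uniformly random different residue), then planted species-exclusive
variants overwrite the designated focal carriers.  Planted columns are kept
free of gaps and of conflicting noise in the reference, the non-carrier
focal and the exclusivity panel, so planted truth is exactly recoverable;
noise elsewhere can create additional, genuine exclusive variants.  No
phylogenetic tree is simulated — the screening procedure is tree-free.

Copy-number tables carry planted species-unique amplifications; evidence
tables carry configurable PCR outcomes so the validation gate can be
exercised (including the all-discarded outcome).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .alignment import AMINO_ACIDS, GAP, AlignmentRow, ProteinAlignment, write_alignment
from .copynumber import CopyNumberTable, write_copy_number_table
from .effects import EffectAnnotation, write_effects_tsv
from .errors import ConfigError
from .panel import SpeciesEntry, SpeciesPanel, write_panel
from .pipeline import ValidationEvidence

FIXTURE_NAMES = ("table2_candidates", "species_panel", "hallmark_map")


@dataclass(frozen=True)
class SimConfig:
    """Study-design knobs; defaults mirror the panel actually used:
    ~10 comparison species plus the human reference, two focal congeners,
    four long-lived and four short-lived panel fishes."""

    n_comparison_species: int = 10
    n_long: int = 4
    n_short: int = 4
    n_genes: int = 5
    protein_length: int = 200
    n_planted_exclusive: int = 2       # per gene
    n_planted_convergent: int = 1      # per gene; subset of the exclusives
    substitution_noise_rate: float = 0.01
    gap_rate: float = 0.01
    paralog_probability: float = 0.10
    planted_amplifications: int = 3
    amplification_pcr_supported: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("substitution_noise_rate", "gap_rate", "paralog_probability"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name}={p} outside [0, 1]")
        for name in ("n_comparison_species", "n_long", "n_short", "n_genes",
                     "protein_length", "n_planted_exclusive", "n_planted_convergent",
                     "planted_amplifications"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        if self.n_comparison_species < 1:
            raise ConfigError("need at least one comparison species")
        if self.n_planted_exclusive > self.protein_length:
            raise ConfigError("more planted variants than residue positions")
        if self.n_planted_convergent > self.n_planted_exclusive:
            raise ConfigError("convergent plants must be a subset of the exclusives")


@dataclass(frozen=True)
class PlantedVariant:
    gene_symbol: str
    ref_pos: int
    ref_residue: str
    alt_residue: str
    carriers: frozenset[str]
    exclusivity: str
    convergent_sharers: frozenset[str] = frozenset()

    @property
    def label(self) -> str:
        return f"p.{self.ref_residue}{self.ref_pos}{self.alt_residue}"


@dataclass(frozen=True)
class PlantedAmplification:
    gene_symbol: str
    amplified_species: str
    amplified_count: int
    other_count: int
    pcr_supported: bool


@dataclass
class TruthSet:
    variants: list[PlantedVariant] = field(default_factory=list)
    amplifications: list[PlantedAmplification] = field(default_factory=list)


@dataclass
class SyntheticDataset:
    panel: SpeciesPanel
    alignments: dict[str, ProteinAlignment]
    copy_table: CopyNumberTable
    effects: dict[tuple[str, str, str], EffectAnnotation]
    evidence: dict[tuple[str, str, str], ValidationEvidence]
    amplification_evidence: dict[str, dict[str, bool]]


def _make_panel(cfg: SimConfig) -> SpeciesPanel:
    entries = [
        SpeciesEntry("ref", "Reference species", "reference", 80.0),
        SpeciesEntry("foca", "Focal species A (long-lived)", "focal_a", 250.0),
        SpeciesEntry("focb", "Focal species B (short-lived)", "focal_b", 11.0),
    ]
    entries += [
        SpeciesEntry(f"cmp{i:02d}", f"Comparison species {i}", "comparison", 10.0 + i)
        for i in range(1, cfg.n_comparison_species + 1)
    ]
    entries += [
        SpeciesEntry(f"lng{i:02d}", f"Long-lived panel fish {i}", "long_lived", 60.0 + 10 * i)
        for i in range(1, cfg.n_long + 1)
    ]
    entries += [
        SpeciesEntry(f"sht{i:02d}", f"Short-lived panel fish {i}", "short_lived", float(i))
        for i in range(1, cfg.n_short + 1)
    ]
    return SpeciesPanel(entries)


def generate_dataset(cfg: SimConfig) -> tuple[SyntheticDataset, TruthSet]:
    """Deterministic for a fixed config (all randomness from ``cfg.seed``)."""
    rng = np.random.default_rng(cfg.seed)
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1").astype("U1")
    panel = _make_panel(cfg)
    species = [e.species_id for e in panel.entries]
    excl_panel = set(panel.exclusivity_panel_ids)
    truth = TruthSet()
    alignments: dict[str, ProteinAlignment] = {}
    effects: dict[tuple[str, str, str], EffectAnnotation] = {}
    evidence: dict[tuple[str, str, str], ValidationEvidence] = {}

    lifespan_panel = panel.ids_in_group("long_lived", "short_lived")
    L = cfg.protein_length

    for g in range(1, cfg.n_genes + 1):
        gene = f"G{g:03d}"
        ancestral = rng.choice(aa, size=L)
        mat: dict[str, np.ndarray] = {}
        for sp in species:
            row = ancestral.copy()
            noise = rng.random(L) < cfg.substitution_noise_rate
            for j in np.flatnonzero(noise):
                choices = [c for c in aa if c != row[j]]
                row[j] = choices[rng.integers(len(choices))]
            mat[sp] = row

        planted_cols = rng.choice(L, size=cfg.n_planted_exclusive, replace=False)
        planted_cols.sort()
        planted_records = []
        for k, col in enumerate(planted_cols):
            carrier_kind = ("a", "b", "both")[rng.integers(3)]
            carriers = {
                "a": frozenset({"foca"}),
                "b": frozenset({"focb"}),
                "both": frozenset({"foca", "focb"}),
            }[carrier_kind]
            ref_res = ancestral[col]
            alt_choices = [c for c in aa if c != ref_res]
            alt = alt_choices[rng.integers(len(alt_choices))]
            # reset noise so the planted truth is exact: reference and every
            # exclusivity-panel species show the ancestral state, the
            # non-carrier focal stays reference-like, carriers get the alt
            for sp in excl_panel:
                mat[sp][col] = ref_res
            for sp in ("foca", "focb"):
                mat[sp][col] = alt if sp in carriers else ref_res
            sharers: frozenset[str] = frozenset()
            if k < cfg.n_planted_convergent and lifespan_panel:
                sharer = lifespan_panel[rng.integers(len(lifespan_panel))]
                mat[sharer][col] = alt
                sharers = frozenset({sharer})
            planted_records.append((col, ref_res, alt, carriers, carrier_kind, sharers))

        # per-cell gap noise, never at planted columns
        planted_set = set(int(c) for c in planted_cols)
        for sp in species:
            gaps = rng.random(L) < cfg.gap_rate
            for j in np.flatnonzero(gaps):
                if int(j) not in planted_set:
                    mat[sp][j] = GAP
        if all(c == GAP for c in mat["ref"]):  # keep the reference mappable
            mat["ref"][0] = ancestral[0]

        rows = [
            AlignmentRow(sp, 1, "".join(mat[sp])) for sp in species
        ]
        # occasional paralog copies of comparison species (extra noise copy)
        for sp in panel.ids_in_group("comparison"):
            if rng.random() < cfg.paralog_probability:
                row = mat[sp].copy()
                noise = rng.random(L) < max(cfg.substitution_noise_rate, 0.02)
                for j in np.flatnonzero(noise):
                    choices = [c for c in aa if c != row[j]]
                    row[j] = choices[rng.integers(len(choices))]
                rows.append(AlignmentRow(sp, 2, "".join(row)))
        aln = ProteinAlignment(gene_symbol=gene, rows=rows)
        alignments[gene] = aln

        # reference numbering of planted columns (reference has no gap there)
        ref_seq = mat["ref"]
        nongap = np.cumsum(ref_seq != GAP)
        for col, ref_res, alt, carriers, kind, sharers in planted_records:
            ref_pos = int(nongap[col])
            pv = PlantedVariant(
                gene_symbol=gene,
                ref_pos=ref_pos,
                ref_residue=str(ref_res),
                alt_residue=str(alt),
                carriers=carriers,
                exclusivity={"a": "exclusive_a", "b": "exclusive_b",
                             "both": "exclusive_both"}[kind],
                convergent_sharers=sharers,
            )
            truth.variants.append(pv)
            for sp in sorted(carriers):
                key = (gene, pv.label, sp)
                effects[key] = EffectAnnotation.from_scores(
                    sift_score=round(float(rng.uniform(0.0, 0.05)), 3),
                    polyphen_score=round(float(rng.uniform(0.957, 1.0)), 3),
                    database_flags={"clinvar"},
                    clinvar_accession=f"VCVSYN{g:03d}{ref_pos:04d}.1",
                )
                evidence[key] = ValidationEvidence(rnaseq="yes", genomic="yes", pcr="yes")

    # copy-number table: every gene assessed in every non-lifespan-panel
    # species at one copy, with species-unique amplifications planted
    assessed = ["ref", "foca", "focb"] + panel.ids_in_group("comparison")
    cells = {(g, sp): 1 for g in alignments for sp in assessed}
    amp_evidence: dict[str, dict[str, bool]] = {}
    n_amp = min(cfg.planted_amplifications, cfg.n_genes)
    for i, gene in enumerate(sorted(alignments)[:n_amp]):
        amplified = "foca" if i % 2 == 0 else "focb"
        count = 2 + i % 2
        cells[(gene, amplified)] = count
        truth.amplifications.append(
            PlantedAmplification(
                gene_symbol=gene,
                amplified_species=amplified,
                amplified_count=count,
                other_count=1,
                pcr_supported=cfg.amplification_pcr_supported,
            )
        )
        amp_evidence[gene] = {
            "pcr_supported": cfg.amplification_pcr_supported,
            "extra_copies_found_in_other": False,
        }

    dataset = SyntheticDataset(
        panel=panel,
        alignments=alignments,
        copy_table=CopyNumberTable(cells),
        effects=effects,
        evidence=evidence,
        amplification_evidence=amp_evidence,
    )
    return dataset, truth


# -- serialization -------------------------------------------------------


def write_dataset(dataset: SyntheticDataset, truth: TruthSet, outdir) -> None:
    """Emit the bundle as plain-text files (byte-identical per config)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "panel.tsv", "w") as fh:
        write_panel(dataset.panel, fh)
    for gene in sorted(dataset.alignments):
        with open(out / f"{gene}.aln.fasta", "w") as fh:
            write_alignment(dataset.alignments[gene], fh)
    with open(out / "copynum.tsv", "w") as fh:
        write_copy_number_table(dataset.copy_table, fh)
    with open(out / "effects.tsv", "w") as fh:
        write_effects_tsv(dataset.effects, fh)
    with open(out / "evidence.tsv", "w") as fh:
        fh.write("gene\tvariant\tspecies\trnaseq\tgenomic\tpcr\tnotes\n")
        for (gene, label, sp), ev in sorted(dataset.evidence.items()):
            fh.write(f"{gene}\t{label}\t{sp}\t{ev.rnaseq}\t{ev.genomic}\t{ev.pcr}\t{ev.notes}\n")
    with open(out / "amp_evidence.tsv", "w") as fh:
        fh.write("gene\tpcr_supported\textra_copies_found_in_other\n")
        for gene, ev in sorted(dataset.amplification_evidence.items()):
            fh.write(
                f"{gene}\t{str(ev['pcr_supported']).lower()}\t"
                f"{str(ev['extra_copies_found_in_other']).lower()}\n"
            )
    with open(out / "truth.json", "w") as fh:
        json.dump(truth_to_dict(truth), fh, indent=1, sort_keys=True)
        fh.write("\n")


def truth_to_dict(truth: TruthSet) -> dict:
    return {
        "variants": [
            {**dataclasses.asdict(v),
             "carriers": sorted(v.carriers),
             "convergent_sharers": sorted(v.convergent_sharers)}
            for v in truth.variants
        ],
        "amplifications": [dataclasses.asdict(a) for a in truth.amplifications],
    }


# -- packaged fixtures ---------------------------------------------------


def fixture_path(name: str) -> Path:
    """Path of a packaged fixture TSV (``table2_candidates``,
    ``species_panel`` or ``hallmark_map``)."""
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    return Path(__file__).parent / "fixtures" / f"{name}.tsv"


def load_fixture(name: str):
    """Load a packaged fixture as its parsed object.

    ``table2_candidates`` -> list of CandidateRecord (19 rows, hand-
    transcribed from the published candidate table); ``species_panel`` ->
    SpeciesPanel; ``hallmark_map`` -> HallmarkMap.
    """
    from .pipeline import read_candidate_table, read_hallmark_map

    path = fixture_path(name)
    if name == "table2_candidates":
        return read_candidate_table(path)
    if name == "species_panel":
        from .panel import read_panel

        return read_panel(path)
    return read_hallmark_map(path)
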