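# Methods

## Screening model

The pipeline formalizes a two-rule candidate screen over per-gene protein
multiple sequence alignments on a species panel with six roles: one
`reference` species (anchors residue numbering), two focal lineages
(`focal_a`, `focal_b`), a `comparison` set, and `long_lived`/`short_lived`
annotation panels.

**Rule 1 (exclusivity).** For each alignment column with a non-gap
reference residue `R` at reference position `p`, each focal residue
`A ≠ R` defines a variant `p.RpA`. The variant is exclusive iff no primary
copy (copy index 1) of any reference or comparison species carries `A` at
that column. The verdict is `exclusive_a`, `exclusive_b`, or
`exclusive_both` according to which focal lineages carry `A`;
`not_exclusive` records are kept in the full scan output with their panel
carriers. Assumptions baked into the rule:

- `X`, `-` and `*` are missing data everywhere: they never carry a
  variant, never revoke one, and never enter a denominator. A column where
  the reference residue is missing, or where every copy of a focal species
  is missing, yields no variant (an insertion in a focal species relative
  to the reference is therefore unmapped and skipped).
- A focal species with several copies carries a variant if at least one
  copy does.
- Paralog copies (copy index > 1) of panel species that share the change
  do not revoke exclusivity; they set a parallel-evolution note. This
  follows the screening convention of treating a match in a duplicate gene
  copy as independent recurrence, not as panel presence.
- The reference species itself belongs to the exclusivity panel; the
  lifespan panels do not, so recurrence there (e.g. the same change in
  another long-lived fish) is annotation, never a veto.

**Rule 2 (database feature).** A variant qualifies when at least one flag
is set: `clinvar` (a ClinVar-linked human position), `conserved_domain_motif`,
`uniprot_feature`, or `literature`. Flags are caller-supplied; the package
does not query live services.

**Evidence gate.** Validation columns take values
`yes / no / no_reads / not_done` (RNA-seq) and `yes / no / not_done`
(genomic, PCR). Only an explicit `no` discards; `no_reads` (transcript
absent from the sampled tissue) and `not_done` are non-disqualifying, so a
candidate with genomic and PCR support but no RNA-seq coverage survives.

**Variant labels.** Positions are 1-based along the ungapped reference
row; the "from" residue in a label is always the reference species'
residue at that column, even when the focal species' sister lineage
differs (hence two records `p.S2807C` and `p.S2807R` can coexist at one
position). The coordinate map is exposed for any chosen reference species
rather than hard-wiring one, since published positions may be anchored in
either the human or the fish sequence.

## Conservation and residue classes

Conservation at a position is the majority-residue fraction over one vote
per species (primary copies only), excluding a caller-given set (typically
the focal species). `highly_conserved` uses a strict inequality against
the 0.80 default ("more than 80%"), configurable. Ties break to the
alphabetically first residue and set a tie flag; an empty denominator is
an error, and `n_counted` is always reported so fractions are
interpretable against the panel size.

The four-way residue classification — nonpolar {A V L I M F W P G C},
polar {S T Y N Q}, positively charged {K R H}, negatively charged {D E} —
is frozen. Cysteine and glycine sit in the nonpolar class and histidine in
the positively charged class; this is the unique standard placement
consistent with the descriptors the screen must produce (S→C "polar to
nonpolar", S→R "polar to positively charged", R→H charge-conserving).

## Copy-number screen

"Unique amplification" is a strict count excess of one focal species over
both the other focal species and every *assessed* comparison-panel count;
ties are never candidates, and an absent cell means "not assessed" rather
than zero (genes are only compared where annotated in all species). The
validation gate discards a candidate when PCR did not support the
amplification or found the extra copies in the other focal species too.
Both the candidate set and the gate are order-invariant, and adding an
assessed comparison species can only shrink the candidate set.

## Effect-score categorization

SIFT: `affects_protein_function` iff score ≤ 0.05 (inclusive boundary),
else `tolerated`. PolyPhen (HumDiv convention): `benign` below 0.452,
`possibly_damaging` in [0.452, 0.956], `probably_damaging` above 0.956.
These are the predictors' published defaults, not values fitted here; both
are keyword-configurable. The packaged 19-row candidate fixture carries
every printed (score, category) pair, and a regression test checks the
default categorizers reproduce all of them with zero mismatches.

## Synthetic-data generator

`SimConfig` defaults encode the emulated study design: 10 comparison
species plus the reference, two focal congeners, four long-lived and four
short-lived panel fishes, 5 genes of 200 residues, 2 planted exclusive
variants per gene of which 1 also recurs in a lifespan-panel species,
substitution noise 0.01 per cell, gap noise 0.01 per cell, paralog
probability 0.10 per comparison species, and 3 planted species-unique
amplifications whose PCR evidence defaults to unsupported (so the gate's
all-discarded outcome is the default truth).

Mechanics: the ancestral sequence is uniform over the 20 amino acids;
species rows receive i.i.d. per-cell substitutions to a uniformly random
different residue; no phylogenetic tree is simulated because the screen
itself is tree-free. Planted columns are protected: noise in the
reference, the exclusivity panel and the non-carrier focal is reset to the
ancestral state, carriers are overwritten with the alternative residue,
and gap noise skips planted columns. Consequently planted truth is exactly
recoverable (recall 1.0 by construction); under nonzero noise the scan
also reports additional, genuine exclusive variants created by noise, so
precision against the planted truth is only meaningful at zero noise.
Effect scores for planted variants are drawn from [0, 0.05] (SIFT) and
[0.957, 1] (PolyPhen) so category recovery is deterministic. All
randomness flows from a single seed; emitted bundles are byte-identical
per configuration.

What the generator does **not** emulate — realistic substitution matrices,
indel evolution, rate heterogeneity, phylogenetic correlation between
species, alignment error — means passing tests demonstrate correctness of
the screening logic, not robustness of the biological inference on real
alignments.

## Packaged fixtures

`table2_candidates.tsv` is a hand transcription of the published 19-row
candidate table (validation cells, SIFT/PolyPhen calls, ClinVar
accessions), with database flags filled per row (accession-less rows carry
the motif/feature/literature flag that qualified them) and note fields
preserving the known text/table position discrepancies as printed (ACE
R509H text vs R508H table; DOCK8 R393H vs R398H; NUDT1 G58S vs G99S; FANCI
R393H vs S979T) and the alternative *Drosophila* numbering of the two BLM
variants. `species_panel.tsv` records the study panel; only the two focal
lifespans (250 and 11 years) are taken from the source — the remaining
lifespans are standard longevity-database values and nothing downstream
computes on them. `hallmark_map.tsv` assigns one hallmark per gene,
following the section in which each gene is discussed; genes relevant to
several hallmarks still get a single primary label, and unmapped genes are
reported as `unassigned` with a warning.

## Numerical and design choices

- Deterministic orderings everywhere: variants sort by (gene, position,
  alternative residue), candidate records by (gene, position, species);
  ties in majority votes break alphabetically with an explicit flag.
- `select_candidates` is strict — a variant without an effect annotation
  or evidence entry raises an error naming the key; the CLI offers
  `--skip-unannotated` for scan outputs where only a subset was annotated.
- Candidate tables round-trip losslessly through TSV with the
  printed-style score cells (`APF (0.03)`); score formatting uses the
  shortest general representation, so `1.00` re-emerges as `1` with equal
  value.
- The FASTA dialect is fixed: header grammar `species_id|gene|copyN`,
  gap `-` only (`.` is rejected), unknown characters coerced to `X` with a
  warning, output wrapped at 60 columns.

## Problem sizes

The test suite and acceptance script run at desk scale: oracle equivalence
uses 500 random alignments of up to ~20 species × 100 columns; the
coordinate round-trip property uses 1,000 random gapped rows; planted-truth
recovery uses 6 genes × 200 residues. These sizes exercise every code path
of the screen; genome-scale discovery (assembly, annotation, and the
original detection of the 19 variants from raw genomes) is outside the
package's scope and is represented by the fixture regression instead.

## Known limitations

- Truncating variants are not detected; `*` is accepted input but treated
  as missing data.
- Exclusivity is binary per column; no evolutionary model weighs the
  changes (no ancestral reconstruction, no convergence test).
- Conservation is majority-fraction only — no entropy or substitution-
  matrix scores.
- One hallmark per gene, though genes can act in several.
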