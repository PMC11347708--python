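"""Independent brute-force oracle for the exclusivity scan, plus a random
alignment generator.  Written as plain nested loops over raw strings so it
shares no code path with the package implementation."""

import numpy as np

MISSING = set("X-*")
AAS = "ACDEFGHIKLMNPQRSTVWY"


def brute_force_scan(rows, groups, gene="GENE1"):
    """Enumerate exclusive/non-exclusive focal variants column by column.

    rows: list of (species, copy, seq); groups: species -> group label.
    Returns a set of (ref_pos, ref_res, alt, carriers, exclusivity,
    panel_carriers) tuples covering every focal difference at mapped
    columns (the same universe the scanner reports).
    """
    ref_species = [s for s, g in groups.items() if g == "reference"][0]
    ref_seq = [seq for s, c, seq in rows if s == ref_species and c == 1][0]
    focal_species = sorted(s for s, g in groups.items()
                           if g in ("focal_a", "focal_b"))
    panel_species = {s for s, g in groups.items() if g in ("reference", "comparison")}
    length = len(ref_seq)

    results = set()
    ref_pos = 0
    for col in range(length):
        if ref_seq[col] == "-":
            continue
        ref_pos += 1
        ref_res = ref_seq[col]
        if ref_res in MISSING:
            continue
        # focal species entirely missing at this column => no variant here
        skip = False
        for fs in focal_species:
            chars = [seq[col] for s, c, seq in rows if s == fs]
            if chars and all(ch in MISSING for ch in chars):
                skip = True
        if skip:
            continue
        alts = {}
        for s, c, seq in rows:
            ch = seq[col]
            if s in focal_species and ch not in MISSING and ch != ref_res:
                alts.setdefault(ch, set()).add(s)
        for alt, carriers in alts.items():
            sharers = set()
            for s, c, seq in rows:
                if s in panel_species and seq[col] == alt:
                    sharers.add((s, c))
            if any(c == 1 for _, c in sharers):
                verdict = "not_exclusive"
            else:
                has_a = any(groups[s] == "focal_a" for s in carriers)
                has_b = any(groups[s] == "focal_b" for s in carriers)
                if has_a and has_b:
                    verdict = "exclusive_both"
                elif has_a:
                    verdict = "exclusive_a"
                else:
                    verdict = "exclusive_b"
            results.add((ref_pos, ref_res, alt, frozenset(carriers), verdict,
                         frozenset(sharers)))
    return results


def random_alignment_rows(rng, max_species=20, n_columns=100,
                          missing_rate=0.08, variant_rate=0.15):
    """Random panel + aligned rows with realistic missingness and variation."""
    n_comparison = int(rng.integers(1, max(2, max_species - 4)))
    groups = {"hsap": "reference", "hatl": "focal_a", "hmed": "focal_b"}
    for i in range(1, n_comparison + 1):
        groups[f"cmp{i:02d}"] = "comparison"
    rows = []
    for species in groups:
        n_copies = 1 + int(rng.random() < 0.2 and species != "hsap")
        for copy in range(1, n_copies + 1):
            chars = []
            for _ in range(n_columns):
                u = rng.random()
                if u < missing_rate:
                    chars.append("-X*"[int(rng.integers(3))])
                elif u < missing_rate + variant_rate:
                    chars.append(AAS[int(rng.integers(20))])
                else:
                    chars.append("A")  # mostly conserved background
            rows.append((species, copy, "".join(chars)))
    return rows, groups
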