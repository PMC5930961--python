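"""Genetic-code machinery: translation, codon GC accounting, substitution
classification, and relative synonymous codon usage (RSCU).

The directional-asymmetry analyses in this package all reduce to questions
about single codons: how many G/C nucleotides a codon carries, whether its
third position ends in G/C or A/T, and whether two aligned codons encode the
same amino acid. This module owns that vocabulary. Split codon families
(Ser, Leu, Arg) are treated as single amino-acid families throughout, the
convention used by CodonW-style RSCU reports.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from Bio.Data.CodonTable import unambiguous_dna_by_id

STOP = "*"
NUCLEOTIDES = frozenset("ACGT")
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class CodonPairClass(enum.Enum):
    """Relationship between two aligned sense codons."""

    IDENTICAL = "identical"
    SYNONYMOUS = "synonymous"
    NONSYNONYMOUS = "nonsynonymous"
    EXCLUDED = "excluded"


class ThirdPositionClass(enum.Enum):
    GC_ENDING = "GC_ending"
    AT_ENDING = "AT_ending"


@dataclass(frozen=True)
class GeneticCode:
    """A 64-entry codon translation table.

    ``table`` maps every DNA codon (uppercase A/C/G/T triplet) to a
    one-letter amino acid, with stop codons mapped to ``"*"``.
    """

    table: Mapping[str, str]
    name: str = "standard"

    def __post_init__(self) -> None:
        if len(self.table) != 64:
            raise ValueError(
                f"genetic code {self.name!r} has {len(self.table)} entries, expected 64"
            )
        encoded = {aa for aa in self.table.values() if aa != STOP}
        missing = set(AMINO_ACIDS) - encoded
        if missing:
            raise ValueError(f"genetic code {self.name!r} misses amino acids {sorted(missing)}")

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(c for c, aa in sorted(self.table.items()) if aa != STOP)

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return tuple(c for c, aa in sorted(self.table.items()) if aa == STOP)

    def codons_for(self, amino_acid: str) -> tuple[str, ...]:
        """All sense codons encoding ``amino_acid`` (split families merged)."""
        return tuple(c for c in self.sense_codons if self.table[c] == amino_acid)


def _standard_code() -> GeneticCode:
    bio = unambiguous_dna_by_id[1]
    table = dict(bio.forward_table)
    for stop in bio.stop_codons:
        table[stop] = STOP
    return GeneticCode(table=table, name="standard")


STANDARD_CODE = _standard_code()


def _check_codon(codon: str) -> str:
    if len(codon) != 3 or any(ch not in NUCLEOTIDES for ch in codon):
        raise ValueError(f"invalid codon {codon!r}: expected 3 characters from A/C/G/T")
    return codon


def translate_codon(codon: str, code: GeneticCode = STANDARD_CODE) -> str:
    """Translate one codon; stop codons return ``"*"``.

    Ambiguity characters (N, etc.) are rejected: sequences carrying them are
    dropped upstream rather than masked.
    """
    return code.table[_check_codon(codon)]


def gc_count(codon: str) -> int:
    """Number of G/C nucleotides in the codon (the codon's GC group, 0-3)."""
    _check_codon(codon)
    return sum(1 for ch in codon if ch in "GC")


def third_position_class(codon: str) -> ThirdPositionClass:
    """Whether the codon's third nucleotide is G/C or A/T."""
    _check_codon(codon)
    if codon[2] in "GC":
        return ThirdPositionClass.GC_ENDING
    return ThirdPositionClass.AT_ENDING


def classify_codon_pair(
    codon_a: str, codon_b: str, code: GeneticCode = STANDARD_CODE
) -> tuple[CodonPairClass, list[int]]:
    """Classify an aligned codon pair and list its differing positions (1-3).

    A pair is synonymous when the codons differ but translate identically,
    nonsynonymous when the translations differ, and excluded when either
    codon is a stop (stops never enter substitution tallies).
    """
    aa_a = translate_codon(codon_a, code)
    aa_b = translate_codon(codon_b, code)
    positions = [i + 1 for i in range(3) if codon_a[i] != codon_b[i]]
    if aa_a == STOP or aa_b == STOP:
        return CodonPairClass.EXCLUDED, positions
    if not positions:
        return CodonPairClass.IDENTICAL, positions
    if aa_a == aa_b:
        return CodonPairClass.SYNONYMOUS, positions
    return CodonPairClass.NONSYNONYMOUS, positions


def mean_gc_by_aa(code: GeneticCode = STANDARD_CODE) -> dict[str, float]:
    """Mean GC fraction of the codons encoding each amino acid.

    For amino acid *a* with sense codons c_1..c_n this is
    ``sum(gc_count(c_i)) / (3 n)`` — e.g. Gly (GGA/GGC/GGG/GGT) gives
    (2+3+3+2)/12 = 0.8333. Stop codons are excluded.
    """
    out: dict[str, float] = {}
    for aa in AMINO_ACIDS:
        codons = code.codons_for(aa)
        out[aa] = sum(gc_count(c) for c in codons) / (3 * len(codons))
    return out


@dataclass
class CodonCounts:
    """Codon occurrence counts over a CDS set for one species."""

    counts: dict[str, int] = field(default_factory=dict)
    species_label: str = ""

    def __post_init__(self) -> None:
        for codon, n in self.counts.items():
            _check_codon(codon)
            if n < 0:
                raise ValueError(f"negative count for codon {codon}")

    def add_cds(self, cds: str) -> None:
        """Accumulate codon counts from one in-frame CDS."""
        if len(cds) % 3:
            raise ValueError(f"CDS length {len(cds)} not divisible by 3")
        for i in range(0, len(cds), 3):
            codon = _check_codon(cds[i : i + 3])
            self.counts[codon] = self.counts.get(codon, 0) + 1


def count_codons(cds_sequences: Iterable[str], species_label: str = "") -> CodonCounts:
    counts = CodonCounts(species_label=species_label)
    for cds in cds_sequences:
        counts.add_cds(cds)
    return counts


def rscu(counts: CodonCounts, code: GeneticCode = STANDARD_CODE) -> dict[str, float | None]:
    """Relative synonymous codon usage for every sense codon.

    RSCU(c) = n_a * x_c / sum over the family of x, where n_a is the family
    degeneracy; uniform usage within a family gives RSCU = 1 for each codon
    and family totals always sum to the degeneracy. Families with zero total
    usage yield ``None`` (undefined). Stop codons are ignored.
    """
    out: dict[str, float | None] = {}
    for aa in AMINO_ACIDS:
        family = code.codons_for(aa)
        total = sum(counts.counts.get(c, 0) for c in family)
        for c in family:
            if total == 0:
                out[c] = None
            else:
                out[c] = len(family) * counts.counts.get(c, 0) / total
    return out


def codon_usage_gc_bias(
    rscu_values: Mapping[str, float | None], code: GeneticCode = STANDARD_CODE
) -> dict[str, float | None]:
    """Per-amino-acid GC-rich/GC-poor codon usage bias from RSCU values.

    For each amino acid with at least one G/C-ending and one A/T-ending
    codon, returns sum(RSCU of GC-ending codons) / sum(RSCU of AT-ending
    codons). Single-codon amino acids (Met, Trp) are omitted; a zero
    denominator or undefined family yields ``None``.
    """
    out: dict[str, float | None] = {}
    for aa in AMINO_ACIDS:
        family = code.codons_for(aa)
        gc_side = [c for c in family if third_position_class(c) is ThirdPositionClass.GC_ENDING]
        at_side = [c for c in family if third_position_class(c) is ThirdPositionClass.AT_ENDING]
        if not gc_side or not at_side:
            continue
        vals_gc = [rscu_values[c] for c in gc_side]
        vals_at = [rscu_values[c] for c in at_side]
        if any(v is None for v in vals_gc + vals_at):
            out[aa] = None
            continue
        denom = sum(vals_at)  # type: ignore[arg-type]
        out[aa] = (sum(vals_gc) / denom) if denom > 0 else None  # type: ignore[arg-type]
    return out
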