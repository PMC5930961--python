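"""Directional substitution asymmetry between a focal and a reference species.

The central quantities are the directional counts over aligned codon
columns: s1, sites where the focal (cold-water) species holds G/C and the
reference (tropical) species holds A/T, and s2 for the opposite direction.
Their ratio s1/s2 is the GC bias ratio — above 1 means G/C is enriched on
the focal side. The same numerator/denominator logic is applied per codon,
per amino acid, and per numeric amino-acid property, each with an attached
equal-split chi-square test.

Directional convention, stated once and used everywhere: the first index /
numerator is always the focal species' state; swapping species roles swaps
s1 with s2, transposes every count matrix, and inverts every ratio.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .codon_core import (
    AMINO_ACIDS,
    STANDARD_CODE,
    CodonPairClass,
    GeneticCode,
    ThirdPositionClass,
    classify_codon_pair,
    gc_count,
    mean_gc_by_aa,
    third_position_class,
    translate_codon,
)
from .ortholog_pairing import CodonAlignment, ProteinAlignment
from .properties import PropertyTable
from .stats_kit import RegressionResult, TestResult, chisq_gof, correlation, linregress

LOW_COUNT_THRESHOLD = 10
GC = frozenset("GC")
AT = frozenset("AT")


@dataclass
class SubstitutionTally:
    """Directional GC<->AT nucleotide counts for one substitution class."""

    s1: int = 0  # focal G/C, reference A/T
    s2: int = 0  # focal A/T, reference G/C
    class_label: str = "synonymous"
    n_sites_scanned: int = 0  # differing nucleotide sites examined

    def __add__(self, other: "SubstitutionTally") -> "SubstitutionTally":
        if self.class_label != other.class_label:
            raise ValueError("cannot add tallies of different classes")
        return SubstitutionTally(
            s1=self.s1 + other.s1,
            s2=self.s2 + other.s2,
            class_label=self.class_label,
            n_sites_scanned=self.n_sites_scanned + other.n_sites_scanned,
        )


@dataclass
class BiasResult:
    """A directional count ratio with its equal-split chi-square test.

    ``ratio`` is numerator/denominator (focal-direction over
    reference-direction); ``None`` marks a missing ratio (zero denominator
    or no observations). ``low_count`` flags denominators below 10 — such
    ratios are reported but should be read with care (no pseudocounts are
    applied).
    """

    numerator_count: int
    denominator_count: int
    label: str = ""

    @property
    def ratio(self) -> float | None:
        if self.denominator_count == 0:
            return None
        return self.numerator_count / self.denominator_count

    @property
    def test(self) -> TestResult:
        return chisq_gof([self.numerator_count, self.denominator_count])

    @property
    def chi2(self) -> float | None:
        return self.test.statistic

    @property
    def p_value(self) -> float | None:
        return self.test.p_value

    @property
    def low_count(self) -> bool:
        return self.denominator_count < LOW_COUNT_THRESHOLD

    @property
    def zero_substitutions(self) -> bool:
        return self.numerator_count == 0 and self.denominator_count == 0


def bias_ratio(tally: SubstitutionTally) -> BiasResult:
    """GC bias ratio s1/s2 for one tally, with chi-square attached."""
    return BiasResult(
        numerator_count=tally.s1,
        denominator_count=tally.s2,
        label=f"GC bias ratio ({tally.class_label})",
    )


def _iter_sense_columns(
    aln: CodonAlignment, code: GeneticCode
) -> Iterable[tuple[str, str, CodonPairClass, list[int]]]:
    """Yield non-gap, non-stop codon columns with their classification."""
    for codon_a, codon_b in aln.columns:
        if codon_a is None or codon_b is None:
            continue
        cls, positions = classify_codon_pair(codon_a, codon_b, code)
        if cls is CodonPairClass.EXCLUDED:
            continue
        yield codon_a, codon_b, cls, positions


_CLASS_OF = {
    "synonymous": CodonPairClass.SYNONYMOUS,
    "nonsynonymous": CodonPairClass.NONSYNONYMOUS,
}


def tally_gc_substitutions(
    aln: CodonAlignment,
    class_filter: str,
    code: GeneticCode = STANDARD_CODE,
    multi_hit: str = "codon_class",
) -> SubstitutionTally:
    """Count directional GC<->AT changes in columns of one substitution class.

    Every differing nucleotide in a matching-class codon column contributes:
    +1 to s1 when the focal base is G/C and the reference base A/T, +1 to s2
    in the opposite case. Changes that stay within a class (G<->C, A<->T)
    count toward ``n_sites_scanned`` only. Under the default
    ``multi_hit='codon_class'`` mode the codon-level class applies to every
    differing position of a multi-hit codon; ``multi_hit='strict'`` drops
    codon columns differing at more than one position.
    """
    want = _CLASS_OF[class_filter]
    tally = SubstitutionTally(class_label=class_filter)
    for codon_a, codon_b, cls, positions in _iter_sense_columns(aln, code):
        if cls is not want:
            continue
        if multi_hit == "strict" and len(positions) > 1:
            continue
        for pos in positions:
            base_a, base_b = codon_a[pos - 1], codon_b[pos - 1]
            tally.n_sites_scanned += 1
            if base_a in GC and base_b in AT:
                tally.s1 += 1
            elif base_a in AT and base_b in GC:
                tally.s2 += 1
    return tally


def tally_many(
    alns: Iterable[CodonAlignment],
    class_filter: str,
    code: GeneticCode = STANDARD_CODE,
    multi_hit: str = "codon_class",
) -> SubstitutionTally:
    """Pool :func:`tally_gc_substitutions` over many alignments."""
    total = SubstitutionTally(class_label=class_filter)
    for aln in alns:
        total = total + tally_gc_substitutions(aln, class_filter, code, multi_hit)
    return total


def per_codon_bias(
    alns: Sequence[CodonAlignment],
    class_filter: str,
    code: GeneticCode = STANDARD_CODE,
    multi_hit: str = "codon_class",
) -> dict[str, BiasResult]:
    """Directional bias ratio for each individual codon.

    For codon c the numerator counts columns where the focal species holds c
    against a partner codon of the opposite third-position class (A/T-ending
    partners for a G/C-ending c and vice versa), restricted to columns of
    ``class_filter``; the denominator counts the mirror-image columns where
    the reference holds c. Under GC-favouring evolution this yields the
    binomial pattern of ratios above 1 for G/C-ending codons and below 1 for
    A/T-ending ones.
    """
    want = _CLASS_OF[class_filter]
    num: dict[str, int] = {c: 0 for c in code.sense_codons}
    den: dict[str, int] = {c: 0 for c in code.sense_codons}
    for aln in alns:
        for codon_a, codon_b, cls, positions in _iter_sense_columns(aln, code):
            if cls is not want:
                continue
            if multi_hit == "strict" and len(positions) > 1:
                continue
            if third_position_class(codon_a) is not third_position_class(codon_b):
                num[codon_a] += 1
                den[codon_b] += 1
    return {
        c: BiasResult(numerator_count=num[c], denominator_count=den[c], label=f"codon {c}")
        for c in code.sense_codons
    }


@dataclass
class AASubstitutionMatrix:
    """Ordered 20x20 amino-acid replacement counts (focal row, reference column).

    Exactly 20*19 = 380 off-diagonal ordered cells form the substitution
    type space; identical columns are tracked separately as ``conserved``.
    """

    counts: dict[tuple[str, str], int] = field(
        default_factory=lambda: {
            (a, b): 0 for a, b in itertools.product(AMINO_ACIDS, repeat=2) if a != b
        }
    )
    conserved: int = 0

    N_SUBSTITUTION_TYPES = 380

    def __post_init__(self) -> None:
        if len(self.counts) != self.N_SUBSTITUTION_TYPES:
            raise ValueError(
                f"expected {self.N_SUBSTITUTION_TYPES} ordered cells, got {len(self.counts)}"
            )

    def total_changes(self) -> int:
        return sum(self.counts.values())

    def row_sum(self, aa: str) -> int:
        return sum(n for (a, _), n in self.counts.items() if a == aa)

    def col_sum(self, aa: str) -> int:
        return sum(n for (_, b), n in self.counts.items() if b == aa)

    def transposed(self) -> "AASubstitutionMatrix":
        return AASubstitutionMatrix(
            counts={(b, a): n for (a, b), n in self.counts.items()},
            conserved=self.conserved,
        )


def aa_substitution_matrix(
    alns: Sequence[ProteinAlignment | CodonAlignment],
    code: GeneticCode = STANDARD_CODE,
) -> AASubstitutionMatrix:
    """Count ordered amino-acid replacements over aligned residue columns."""
    matrix = AASubstitutionMatrix()
    for aln in alns:
        for aa_a, aa_b in _iter_residue_pairs(aln, code):
            if aa_a == aa_b:
                matrix.conserved += 1
            else:
                matrix.counts[(aa_a, aa_b)] += 1
    return matrix


def _iter_residue_pairs(
    aln: ProteinAlignment | CodonAlignment, code: GeneticCode
) -> Iterable[tuple[str, str]]:
    if isinstance(aln, CodonAlignment):
        for codon_a, codon_b, _, _ in _iter_sense_columns(aln, code):
            yield translate_codon(codon_a, code), translate_codon(codon_b, code)
    else:
        for res_a, res_b in aln.columns():
            if res_a != "-" and res_b != "-":
                yield res_a, res_b


def aa_bias_ratio(matrix: AASubstitutionMatrix, aa: str) -> BiasResult:
    """Bias ratio for one amino acid: (focal aa replaced) / (gained by focal).

    Numerator: columns where the focal species holds ``aa`` against a
    different reference residue; denominator: the reverse. A ratio above 1
    means the amino acid is favoured (retained/over-represented) on the
    focal side.
    """
    return BiasResult(
        numerator_count=matrix.row_sum(aa),
        denominator_count=matrix.col_sum(aa),
        label=f"amino acid {aa}",
    )


def property_bias(
    alns: Sequence[ProteinAlignment | CodonAlignment],
    table: PropertyTable,
    code: GeneticCode = STANDARD_CODE,
) -> BiasResult:
    """Smaller-vs-larger property asymmetry over differing residue columns.

    Numerator: columns where the focal residue has the smaller property
    value; denominator: where it has the larger. Ties (e.g. Leu vs Ile under
    molecular weight) contribute to neither count. A ratio above 1 means
    smaller-property residues are favoured on the focal side.
    """
    smaller = larger = 0
    for aln in alns:
        for aa_a, aa_b in _iter_residue_pairs(aln, code):
            if aa_a == aa_b:
                continue
            va, vb = table[aa_a], table[aa_b]
            if va < vb:
                smaller += 1
            elif va > vb:
                larger += 1
    return BiasResult(smaller, larger, label=f"{table.property_name} bias")


def property_bias_from_matrix(matrix: AASubstitutionMatrix, table: PropertyTable) -> BiasResult:
    """Same statistic as :func:`property_bias`, from a precomputed matrix."""
    smaller = larger = 0
    for (aa_a, aa_b), n in matrix.counts.items():
        va, vb = table[aa_a], table[aa_b]
        if va < vb:
            smaller += n
        elif va > vb:
            larger += n
    return BiasResult(smaller, larger, label=f"{table.property_name} bias")


def equal_gc_property_bias(
    alns: Sequence[CodonAlignment],
    table: PropertyTable,
    code: GeneticCode = STANDARD_CODE,
) -> BiasResult:
    """Property asymmetry restricted to equally GC-rich codon exchanges.

    Only nonsynonymous codon columns whose two codons carry the same number
    of G/C nucleotides are considered, removing GC pressure as a confounder
    so that a residual ratio above 1 reflects a genuine preference for
    smaller-property residues.
    """
    smaller = larger = 0
    for aln in alns:
        for codon_a, codon_b, cls, _ in _iter_sense_columns(aln, code):
            if cls is not CodonPairClass.NONSYNONYMOUS:
                continue
            if gc_count(codon_a) != gc_count(codon_b):
                continue
            va = table[translate_codon(codon_a, code)]
            vb = table[translate_codon(codon_b, code)]
            if va < vb:
                smaller += 1
            elif va > vb:
                larger += 1
    return BiasResult(smaller, larger, label=f"equal-GC {table.property_name} bias")


def gc_group_correlation(per_codon: Mapping[str, BiasResult]) -> TestResult:
    """Spearman correlation between codon GC group (0-3) and bias ratio."""
    xs: list[float] = []
    ys: list[float] = []
    for codon, result in per_codon.items():
        if result.ratio is None:
            continue
        xs.append(gc_count(codon))
        ys.append(result.ratio)
    if len(xs) < 3:
        return TestResult(None, None, None, "two_sided", "spearman correlation",
                          missing=True, missing_reason="fewer than 3 codons with defined ratios")
    return correlation(xs, ys, method="spearman")


def aa_gc_regression(
    per_aa_ratio: Mapping[str, BiasResult],
    mean_gc: Mapping[str, float] | None = None,
    code: GeneticCode = STANDARD_CODE,
) -> RegressionResult:
    """OLS of per-amino-acid bias ratio on mean codon GC fraction.

    With all 20 amino acids present the regression has df = 18; amino acids
    with missing ratios are dropped.
    """
    if mean_gc is None:
        mean_gc = mean_gc_by_aa(code)
    xs: list[float] = []
    ys: list[float] = []
    for aa in AMINO_ACIDS:
        result = per_aa_ratio.get(aa)
        if result is None or result.ratio is None:
            continue
        xs.append(mean_gc[aa])
        ys.append(result.ratio)
    return linregress(xs, ys)


def property_gc_correlation(
    table: PropertyTable,
    mean_gc: Mapping[str, float] | None = None,
    code: GeneticCode = STANDARD_CODE,
) -> TestResult:
    """Pearson correlation between a property index and mean codon GC.

    A genetic-code constant, independent of any alignment data: e.g. free
    amino-acid molecular weight correlates with mean codon GC at
    r = -0.36 under the standard code.
    """
    if mean_gc is None:
        mean_gc = mean_gc_by_aa(code)
    xs = [table[aa] for aa in AMINO_ACIDS]
    ys = [mean_gc[aa] for aa in AMINO_ACIDS]
    return correlation(xs, ys, method="pearson")
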