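"""Pairwise ortholog identification and codon-aware back-translation.

Putative orthologs between two species are found by reciprocal best hits
(RBH) under global protein alignment — a desk-scale stand-in for the
genome-scale BLASTP bidirectional-best-hit screen — then filtered on aligned
length and similarity, and finally back-translated onto the in-frame CDS to
yield paired codon columns (pal2nal-style).

Alignment is delegated to :class:`Bio.Align.PairwiseAligner` in global mode
with BLOSUM62 and affine gaps (open -11, extend -1, the BLASTP defaults).
Ties in the traceback are resolved by the aligner's deterministic first
traceback.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .codon_core import STOP, GeneticCode, STANDARD_CODE, translate_codon

GAP = None  # codon-column gap marker
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


@dataclass(frozen=True)
class Scoring:
    """Affine-gap protein scoring; defaults mirror BLASTP."""

    matrix_name: str = "BLOSUM62"
    gap_open: float = -11.0
    gap_extend: float = -1.0

    @property
    def matrix(self):
        if self.matrix_name == "BLOSUM62":
            return _BLOSUM62
        return substitution_matrices.load(self.matrix_name)


DEFAULT_SCORING = Scoring()


@dataclass
class ProteinAlignment:
    """A gapped global alignment of two protein sequences."""

    id_a: str
    id_b: str
    aligned_a: str
    aligned_b: str
    score: float
    similarity_mode: str = "positives"

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings differ in length")
        if any(a == "-" and b == "-" for a, b in zip(self.aligned_a, self.aligned_b)):
            raise ValueError("gap/gap column in alignment")

    @property
    def aligned_length(self) -> int:
        """Number of columns where neither side is a gap."""
        return sum(1 for a, b in zip(self.aligned_a, self.aligned_b) if a != "-" and b != "-")

    @property
    def similarity(self) -> float | None:
        return similarity(self, mode=self.similarity_mode)

    def columns(self) -> Iterable[tuple[str, str]]:
        return zip(self.aligned_a, self.aligned_b)


@dataclass
class CodonAlignment:
    """Paired in-frame codon columns for one ortholog pair.

    ``columns`` holds ``(codon_a, codon_b)`` tuples where a side is ``None``
    at a gap. Species A is the focal ("cold-water") side throughout the
    package; species B is the reference.
    """

    id_a: str
    id_b: str
    columns: list[tuple[str | None, str | None]]
    source: ProteinAlignment | None = None

    def ungapped(self, side: str) -> str:
        idx = 0 if side == "a" else 1
        return "".join(col[idx] for col in self.columns if col[idx] is not None)

    def swapped(self) -> "CodonAlignment":
        """Exchange focal and reference roles."""
        return CodonAlignment(
            id_a=self.id_b,
            id_b=self.id_a,
            columns=[(b, a) for a, b in self.columns],
            source=self.source,
        )


def _check_protein(seq: str, label: str) -> str:
    bad = set(seq) - PROTEIN_ALPHABET
    if bad:
        raise ValueError(f"{label}: invalid residue letters {sorted(bad)}")
    if not seq:
        raise ValueError(f"{label}: empty sequence")
    return seq


def _make_aligner(scoring: Scoring) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = scoring.matrix
    # BLAST convention: a gap of length L costs open + L*extend. Biopython's
    # open_gap_score is the score of the first gap position, so shift it.
    aligner.open_gap_score = scoring.gap_open + scoring.gap_extend
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def global_align(
    seq_a: str,
    seq_b: str,
    scoring: Scoring = DEFAULT_SCORING,
    id_a: str = "a",
    id_b: str = "b",
    similarity_mode: str = "positives",
) -> ProteinAlignment:
    """Optimal global alignment of two proteins under affine-gap scoring."""
    _check_protein(seq_a, id_a)
    _check_protein(seq_b, id_b)
    aligner = _make_aligner(scoring)
    best = aligner.align(seq_a, seq_b)[0]
    return ProteinAlignment(
        id_a=id_a,
        id_b=id_b,
        aligned_a=str(best[0]),
        aligned_b=str(best[1]),
        score=float(best.score),
        similarity_mode=similarity_mode,
    )


def align_score(seq_a: str, seq_b: str, scoring: Scoring = DEFAULT_SCORING) -> float:
    """Optimal global alignment score only (no traceback; faster for RBH)."""
    _check_protein(seq_a, "a")
    _check_protein(seq_b, "b")
    return float(_make_aligner(scoring).score(seq_a, seq_b))


def similarity(
    aln: ProteinAlignment, mode: str = "positives", scoring: Scoring = DEFAULT_SCORING
) -> float | None:
    """Fraction of aligned (non-gap) columns counted as similar.

    ``positives`` (default) counts columns whose residue pair scores
    strictly above zero under the substitution matrix, mirroring BLASTP's
    positives percentage; ``identity`` counts exact matches. Returns ``None``
    when there are no aligned columns.
    """
    matrix = scoring.matrix
    n_aligned = 0
    n_similar = 0
    for a, b in aln.columns():
        if a == "-" or b == "-":
            continue
        n_aligned += 1
        if mode == "identity":
            n_similar += a == b
        elif mode == "positives":
            n_similar += matrix[a, b] > 0
        else:
            raise ValueError(f"unknown similarity mode {mode!r}")
    if n_aligned == 0:
        return None
    return n_similar / n_aligned


@dataclass
class FilterLog:
    """Per-alignment rejection reasons from :func:`filter_pairs`."""

    rejected: list[tuple[str, str, str]] = field(default_factory=list)

    def add(self, aln: ProteinAlignment, reason: str) -> None:
        self.rejected.append((aln.id_a, aln.id_b, reason))


def filter_pairs(
    alignments: Sequence[ProteinAlignment],
    min_aligned_length: int = 21,
    min_similarity: float = 0.5,
) -> tuple[list[ProteinAlignment], FilterLog]:
    """Keep alignments longer than 20 aligned residues and more than 50% similar.

    Both thresholds are strict ("more than"): ``aligned_length >
    min_aligned_length - 1`` and ``similarity > min_similarity``.
    """
    log = FilterLog()
    kept: list[ProteinAlignment] = []
    for aln in alignments:
        if aln.aligned_length < min_aligned_length:
            log.add(aln, f"aligned_length {aln.aligned_length} <= {min_aligned_length - 1}")
            continue
        sim = aln.similarity
        if sim is None or sim <= min_similarity:
            log.add(aln, f"similarity {sim} <= {min_similarity}")
            continue
        kept.append(aln)
    return kept, log


def trim_terminal_stop(cds: str, code: GeneticCode = STANDARD_CODE) -> str:
    if len(cds) >= 3 and len(cds) % 3 == 0:
        if code.table.get(cds[-3:]) == STOP:
            return cds[:-3]
    return cds


def backtranslate(
    aln: ProteinAlignment,
    cds_a: str,
    cds_b: str,
    code: GeneticCode = STANDARD_CODE,
) -> CodonAlignment:
    """Thread the in-frame CDS through a protein alignment (pal2nal-style).

    Terminal stop codons are trimmed first. Each CDS must be exactly 3x its
    protein's length and translate to it codon-for-codon; violations raise
    ``ValueError`` so the pair can be rejected with a logged reason.
    """
    out_cols: list[tuple[str | None, str | None]] = []
    codons: dict[str, list[str]] = {}
    for label, aligned, cds in (("a", aln.aligned_a, cds_a), ("b", aln.aligned_b, cds_b)):
        cds = trim_terminal_stop(cds.upper().replace("U", "T"), code)
        protein = aligned.replace("-", "")
        if len(cds) != 3 * len(protein):
            raise ValueError(
                f"{label}: CDS length {len(cds)} is not 3x protein length {len(protein)}"
            )
        seq_codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        for codon, residue in zip(seq_codons, protein):
            if translate_codon(codon, code) != residue:
                raise ValueError(
                    f"{label}: codon {codon} translates to "
                    f"{translate_codon(codon, code)!r}, protein has {residue!r}"
                )
        codons[label] = seq_codons
    ia = ib = 0
    for res_a, res_b in aln.columns():
        codon_a = codon_b = None
        if res_a != "-":
            codon_a = codons["a"][ia]
            ia += 1
        if res_b != "-":
            codon_b = codons["b"][ib]
            ib += 1
        out_cols.append((codon_a, codon_b))
    return CodonAlignment(id_a=aln.id_a, id_b=aln.id_b, columns=out_cols, source=aln)


def reciprocal_best_pairs(
    proteome_a: Sequence[tuple[str, str]],
    proteome_b: Sequence[tuple[str, str]],
    scoring: Scoring = DEFAULT_SCORING,
    min_score: float = 0.0,
) -> list[tuple[str, str]]:
    """Reciprocal (bidirectional) best-hit pairs between two proteomes.

    ``proteome_a``/``proteome_b`` are ``(id, sequence)`` lists. A pair is
    retained iff each member is the unique top-scoring partner of the other
    and the score exceeds ``min_score`` (a raw-score floor in place of a
    database e-value cutoff). Ties for best partner disqualify the sequence.
    """
    if not proteome_a or not proteome_b:
        raise ValueError("both proteomes must be non-empty")
    scores: dict[tuple[str, str], float] = {}
    for id_a, seq_a in proteome_a:
        for id_b, seq_b in proteome_b:
            scores[(id_a, id_b)] = align_score(seq_a, seq_b, scoring)

    def unique_best(partner_scores: list[tuple[str, float]]) -> str | None:
        best = max(s for _, s in partner_scores)
        winners = [pid for pid, s in partner_scores if s == best]
        if len(winners) == 1 and best > min_score:
            return winners[0]
        return None

    best_of_a = {
        id_a: unique_best([(id_b, scores[(id_a, id_b)]) for id_b, _ in proteome_b])
        for id_a, _ in proteome_a
    }
    best_of_b = {
        id_b: unique_best([(id_a, scores[(id_a, id_b)]) for id_a, _ in proteome_a])
        for id_b, _ in proteome_b
    }
    pairs = [
        (id_a, id_b)
        for id_a, id_b in best_of_a.items()
        if id_b is not None and best_of_b.get(id_b) == id_a
    ]
    return sorted(pairs)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id->sequence map (first token of header).

    RNA is normalised to DNA (U -> T); sequences containing ambiguity
    characters are the caller's concern (dropped at pairing time).
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper().replace("U", "T")
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records
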