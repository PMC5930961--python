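"""Secondary-structure tracks and directional element-change accounting.

Tracks are 3-state strings (H helix, E strand, C coil) with a 0-9
per-residue prediction confidence, as produced by PSIPRED. Prediction
itself is out of scope: the module consumes PSIPRED's vertical (.ss2) and
horizontal (.horiz) output dialects plus a simple internal TSV used for
synthetic tracks. Aligned residue pairs survive only when BOTH sides pass
the confidence filter (strictly above 5 by default); the surviving fraction
is always reported so the filter's bite is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .ortholog_pairing import ProteinAlignment
from .properties import PropertyTable

SS_ELEMENTS = "HEC"


@dataclass
class SSTrack:
    """Per-residue 3-state secondary structure with 0-9 confidences."""

    id: str
    elements: str
    confidence: list[int]

    def __post_init__(self) -> None:
        if len(self.elements) != len(self.confidence):
            raise ValueError(
                f"{self.id}: {len(self.elements)} elements vs "
                f"{len(self.confidence)} confidence values"
            )
        bad = set(self.elements) - set(SS_ELEMENTS)
        if bad:
            raise ValueError(f"{self.id}: invalid elements {sorted(bad)}")
        if any(c < 0 or c > 9 for c in self.confidence):
            raise ValueError(f"{self.id}: confidence values must be 0-9")

    def __len__(self) -> int:
        return len(self.elements)


@dataclass
class SSSite:
    """One aligned residue column that survived the confidence filter."""

    element_a: str
    element_b: str
    aa_a: str
    aa_b: str


def read_ss_track(path: str | Path, track_id: str | None = None) -> SSTrack:
    """Read one track from a PSIPRED .ss2 / .horiz file or the internal TSV.

    The dialect is sniffed from the content. For the vertical (.ss2) dialect
    the confidence is derived as floor(10 * max state probability), capped
    at 9 — PSIPRED's own convention for its horizontal-format Conf line.
    """
    path = Path(path)
    text = path.read_text()
    if track_id is None:
        track_id = path.stem
    stripped = [ln for ln in text.splitlines() if ln.strip()]
    if not stripped:
        raise ValueError(f"{path}: empty track file")
    if any(ln.lstrip().startswith(("Conf:", "Pred:")) for ln in stripped):
        return _parse_horizontal(stripped, track_id)
    if "\t" in stripped[-1]:
        return _parse_internal_tsv(stripped, track_id)
    return _parse_vertical(stripped, track_id, path)


def _parse_horizontal(lines: list[str], track_id: str) -> SSTrack:
    conf_parts: list[str] = []
    pred_parts: list[str] = []
    for line in lines:
        body = line.strip()
        if body.startswith("Conf:"):
            conf_parts.append(body[5:].strip())
        elif body.startswith("Pred:"):
            pred_parts.append(body[5:].strip())
    conf = "".join(conf_parts)
    pred = "".join(pred_parts)
    if len(conf) != len(pred):
        raise ValueError(f"{track_id}: Conf/Pred length mismatch ({len(conf)} vs {len(pred)})")
    if not conf.isdigit():
        raise ValueError(f"{track_id}: malformed Conf line")
    return SSTrack(id=track_id, elements=pred, confidence=[int(ch) for ch in conf])


def _parse_vertical(lines: list[str], track_id: str, path: Path) -> SSTrack:
    elements: list[str] = []
    confidence: list[int] = []
    for line in lines:
        if line.lstrip().startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 6:
            raise ValueError(f"{path}: malformed .ss2 line {line!r}")
        state = fields[2]
        try:
            probs = [float(v) for v in fields[3:6]]
        except ValueError as exc:
            raise ValueError(f"{path}: malformed probabilities in {line!r}") from exc
        elements.append(state)
        confidence.append(min(9, int(10 * max(probs))))
    if not elements:
        raise ValueError(f"{path}: no residue lines found")
    return SSTrack(id=track_id, elements="".join(elements), confidence=confidence)


def _parse_internal_tsv(lines: list[str], track_id: str) -> SSTrack:
    # single data row: id <tab> elements <tab> comma-free digit string
    fields = lines[-1].split("\t")
    if len(fields) != 3:
        raise ValueError(f"{track_id}: internal TSV needs 3 columns (id, elements, confidences)")
    return SSTrack(id=fields[0], elements=fields[1], confidence=[int(ch) for ch in fields[2]])


def read_ss_tracks_tsv(path: str | Path) -> dict[str, SSTrack]:
    """Read the internal multi-track TSV (id, elements, confidence digits)."""
    tracks: dict[str, SSTrack] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#") or line.startswith("id\t"):
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise ValueError(f"{path}:{lineno}: expected 3 columns")
        track = SSTrack(id=fields[0], elements=fields[1], confidence=[int(ch) for ch in fields[2]])
        tracks[track.id] = track
    return tracks


def write_ss_tracks_tsv(tracks: Iterable[SSTrack], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\telements\tconfidence\n")
        for track in tracks:
            conf = "".join(str(c) for c in track.confidence)
            fh.write(f"{track.id}\t{track.elements}\t{conf}\n")


def paired_ss_sites(
    aln: ProteinAlignment,
    track_a: SSTrack,
    track_b: SSTrack,
    min_conf: int = 5,
    strictly_greater: bool = True,
) -> tuple[list[SSSite], float | None]:
    """Aligned residue columns where both confidences pass the filter.

    Low-reliability predictions are the main noise source in 3-state
    structure comparison, so a column is kept only when both sides exceed
    ``min_conf`` (``strictly_greater=False`` switches to >=). Returns the
    surviving sites and the retained fraction of non-gap columns (``None``
    when the alignment has no aligned columns).
    """
    seq_a = aln.aligned_a.replace("-", "")
    seq_b = aln.aligned_b.replace("-", "")
    if len(track_a) != len(seq_a):
        raise ValueError(f"track {track_a.id}: length {len(track_a)} != protein {len(seq_a)}")
    if len(track_b) != len(seq_b):
        raise ValueError(f"track {track_b.id}: length {len(track_b)} != protein {len(seq_b)}")
    sites: list[SSSite] = []
    n_aligned = 0
    ia = ib = 0
    for res_a, res_b in aln.columns():
        pa, pb = ia, ib
        if res_a != "-":
            ia += 1
        if res_b != "-":
            ib += 1
        if res_a == "-" or res_b == "-":
            continue
        n_aligned += 1
        ca, cb = track_a.confidence[pa], track_b.confidence[pb]
        passes = (ca > min_conf and cb > min_conf) if strictly_greater else (
            ca >= min_conf and cb >= min_conf
        )
        if passes:
            sites.append(SSSite(track_a.elements[pa], track_b.elements[pb], res_a, res_b))
    if n_aligned == 0:
        return sites, None
    return sites, len(sites) / n_aligned


@dataclass
class SSChangeMatrix:
    """3x3 directional element-change counts (focal row, reference column)."""

    counts: dict[tuple[str, str], int] = field(
        default_factory=lambda: {(a, b): 0 for a in SS_ELEMENTS for b in SS_ELEMENTS}
    )
    retained_fraction: float | None = None

    def total_changes(self) -> int:
        return sum(n for (a, b), n in self.counts.items() if a != b)

    def transposed(self) -> "SSChangeMatrix":
        return SSChangeMatrix(
            counts={(b, a): n for (a, b), n in self.counts.items()},
            retained_fraction=self.retained_fraction,
        )


def ss_change_matrix(sites: Sequence[SSSite], retained_fraction: float | None = None) -> SSChangeMatrix:
    """Tally directional element changes; equal-element sites are conserved."""
    matrix = SSChangeMatrix(retained_fraction=retained_fraction)
    for site in sites:
        matrix.counts[(site.element_a, site.element_b)] += 1
    return matrix


def net_change_percent(matrix: SSChangeMatrix) -> dict[str, float] | None:
    """Signed net gain of each element as a percentage of all changes.

    For element e: 100 * (changes into e on the focal side - changes away
    from e) / total changed sites. The three values sum to zero. ``None``
    when there are no changes.
    """
    total = matrix.total_changes()
    if total == 0:
        return None
    out: dict[str, float] = {}
    for e in SS_ELEMENTS:
        gained = sum(matrix.counts[(e, x)] for x in SS_ELEMENTS if x != e)
        lost = sum(matrix.counts[(x, e)] for x in SS_ELEMENTS if x != e)
        out[e] = 100.0 * (gained - lost) / total
    return out


def property_conditioned_ss_change(
    sites: Sequence[SSSite], table: PropertyTable
) -> SSChangeMatrix:
    """Element-change matrix restricted to smaller-on-focal-side residues.

    Keeps only sites where the focal amino acid has the strictly smaller
    property value (equal values, including identical residues, are
    excluded), isolating the structural consequences of residue shrinkage.
    """
    selected = [s for s in sites if table[s.aa_a] < table[s.aa_b]]
    return ss_change_matrix(selected)
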