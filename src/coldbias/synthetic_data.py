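"""Synthetic ortholog pairs with known directional substitution bias.

Every analysis stage in this package is exercised against data whose truth
is known by construction. A common ancestor CDS is drawn from sense codons
with its GC content tuned to a target; two descendant lineages then accept
Poisson numbers of single-nucleotide substitution proposals, with
synonymous and nonsynonymous proposals accepted at class-specific
intensities. The directional knob ``kappa_gc`` multiplies the acceptance
weight of AT->GC proposals on the focal lineage only, so the expected
synonymous/nonsynonymous bias ratios have a closed form computable from the
ancestor's substitution-opportunity spectrum — that expectation is frozen
into the :class:`TruthRecord` and used by parameter-recovery tests.

Secondary-structure tracks are simulated as segmental 3-state sequences
shared between the two species, flipped only at differing residues, with a
``coil_gain_bias`` weighting coil-gaining flips on the focal side.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .codon_core import (
    STOP,
    STANDARD_CODE,
    CodonPairClass,
    GeneticCode,
    classify_codon_pair,
    gc_count,
    translate_codon,
)
from .secstruct import SSTrack, write_ss_tracks_tsv

GC = frozenset("GC")
AT = frozenset("AT")
_NT = "ACGT"


@dataclass
class SimulationParams:
    """Generator conditions; defaults are the package's study conditions.

    Rates are expected substitutions per codon per lineage. ``kappa_gc`` is
    the directional multiplier (>1 inflates AT->GC acceptance on the focal
    lineage; 1 is the symmetric null). ``coil_gain_bias`` plays the same
    role for coil-gaining secondary-structure flips.
    """

    n_genes: int = 50
    codons_per_gene: int = 300
    ancestor_gc: float = 0.5
    syn_rate: float = 0.05
    nonsyn_rate: float = 0.02
    kappa_gc: float = 1.0
    coil_gain_bias: float = 1.0
    n_decoys: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.ancestor_gc < 1:
            raise ValueError("ancestor_gc must lie in (0, 1)")
        if self.syn_rate < 0 or self.nonsyn_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.kappa_gc <= 0 or self.coil_gain_bias <= 0:
            raise ValueError("kappa_gc and coil_gain_bias must be positive")
        if self.codons_per_gene < 1:
            raise ValueError("codons_per_gene must be >= 1")


@dataclass
class GeneTruth:
    """Per-gene realized and expected substitution bookkeeping."""

    gene_id: str
    accepted: dict[str, int] = field(default_factory=dict)  # "focal_syn_ATGC" etc.
    realized_s1_syn: int = 0
    realized_s2_syn: int = 0
    realized_s1_nonsyn: int = 0
    realized_s2_nonsyn: int = 0


@dataclass
class TruthRecord:
    """Ground truth for one simulated dataset."""

    genes: list[GeneTruth] = field(default_factory=list)
    expected_syn_ratio: float | None = None
    expected_nonsyn_ratio: float | None = None
    true_pairs: list[tuple[str, str]] = field(default_factory=list)
    decoys_a: list[str] = field(default_factory=list)
    decoys_b: list[str] = field(default_factory=list)

    def realized_tally(self, class_label: str) -> tuple[int, int]:
        if class_label == "synonymous":
            return (
                sum(g.realized_s1_syn for g in self.genes),
                sum(g.realized_s2_syn for g in self.genes),
            )
        return (
            sum(g.realized_s1_nonsyn for g in self.genes),
            sum(g.realized_s2_nonsyn for g in self.genes),
        )


def _codon_weights(code: GeneticCode, w: float) -> np.ndarray:
    sense = code.sense_codons
    raw = np.array([w ** gc_count(c) for c in sense], dtype=float)
    return raw / raw.sum()


def _expected_gc(code: GeneticCode, w: float) -> float:
    sense = code.sense_codons
    probs = _codon_weights(code, w)
    return float(sum(p * gc_count(c) / 3 for p, c in zip(probs, sense)))


def make_ancestor(
    n_codons: int,
    gc_target: float,
    rng: np.random.Generator,
    code: GeneticCode = STANDARD_CODE,
) -> str:
    """Draw an in-frame CDS of sense codons with expected GC == ``gc_target``.

    Codons are sampled with weight w^gc(codon); w is solved by bisection so
    the expected GC fraction hits the target (within 1e-6). Targets outside
    the attainable range are rejected.
    """
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    lo, hi = 1e-4, 1e4
    if not _expected_gc(code, lo) < gc_target < _expected_gc(code, hi):
        raise ValueError(f"GC target {gc_target} unattainable with sense codons")
    for _ in range(200):
        mid = (lo * hi) ** 0.5
        if _expected_gc(code, mid) < gc_target:
            lo = mid
        else:
            hi = mid
        if abs(_expected_gc(code, mid) - gc_target) < 1e-9:
            break
    w = (lo * hi) ** 0.5
    sense = code.sense_codons
    idx = rng.choice(len(sense), size=n_codons, p=_codon_weights(code, w))
    return "".join(sense[i] for i in idx)


def _direction(old: str, new: str) -> str:
    if old in AT and new in GC:
        return "ATGC"
    if old in GC and new in AT:
        return "GCAT"
    return "within"


_CODON_SPECTRUM_CACHE: dict[tuple[str, str], dict[tuple[str, str], int]] = {}


def _codon_spectrum(codon: str, code: GeneticCode) -> dict[tuple[str, str], int]:
    key = (code.name, codon)
    cached = _CODON_SPECTRUM_CACHE.get(key)
    if cached is not None:
        return cached
    counts: dict[tuple[str, str], int] = {}
    aa = translate_codon(codon, code)
    for pos in range(3):
        for alt in _NT:
            if alt == codon[pos]:
                continue
            new_codon = codon[:pos] + alt + codon[pos + 1 :]
            new_aa = translate_codon(new_codon, code)
            if new_aa == STOP:
                continue
            cls = "syn" if new_aa == aa else "nonsyn"
            k = (cls, _direction(codon[pos], alt))
            counts[k] = counts.get(k, 0) + 1
    _CODON_SPECTRUM_CACHE[key] = counts
    return counts


def opportunity_spectrum(cds: str, code: GeneticCode = STANDARD_CODE) -> dict[tuple[str, str], int]:
    """Count single-nucleotide substitution opportunities by (class, direction).

    Enumerates every (site, alternative base) that does not create a stop
    codon, classifying it as synonymous/nonsynonymous and AT->GC / GC->AT /
    within-class. This is the first-order expectation basis for the
    generator's bias ratios.
    """
    counts: dict[tuple[str, str], int] = {}
    for i in range(0, len(cds), 3):
        for key, n in _codon_spectrum(cds[i : i + 3], code).items():
            counts[key] = counts.get(key, 0) + n
    return counts


def expected_bias_ratios(cds: str, params: SimulationParams, code: GeneticCode = STANDARD_CODE) -> dict[str, float | None]:
    """Closed-form first-order expected s1/s2 per class for a given ancestor.

    With equal proposal budgets on both lineages and the kappa weight acting
    only on focal AT->GC acceptance, the class-c expectation is
    (kappa * n_ATGC + n_GCAT) / (n_GCAT + n_ATGC) over the ancestor's
    opportunity counts n. Class intensities cancel within a class.
    """
    spectrum = opportunity_spectrum(cds, code)
    out: dict[str, float | None] = {}
    for cls, label in (("syn", "synonymous"), ("nonsyn", "nonsynonymous")):
        n_atgc = spectrum.get((cls, "ATGC"), 0)
        n_gcat = spectrum.get((cls, "GCAT"), 0)
        denom = n_gcat + n_atgc
        out[label] = (params.kappa_gc * n_atgc + n_gcat) / denom if denom else None
    return out


def _evolve_lineage(
    ancestor: str,
    params: SimulationParams,
    rng: np.random.Generator,
    focal: bool,
    code: GeneticCode,
) -> tuple[str, dict[str, int]]:
    """Apply proposal/acceptance substitution events to one lineage."""
    total_rate = params.syn_rate + params.nonsyn_rate
    n_codons = len(ancestor) // 3
    accepted: dict[str, int] = {}
    if total_rate == 0:
        return ancestor, accepted
    wmax = max(params.kappa_gc, 1.0)
    spectrum = opportunity_spectrum(ancestor, code)
    n_ops = sum(spectrum.values())
    # reference-lineage mean acceptance; equal proposal budgets on both
    # lineages keep the closed-form expectation exact to first order
    mean_accept = sum(
        n * ((params.syn_rate if cls == "syn" else params.nonsyn_rate) / total_rate) / wmax
        for (cls, _), n in spectrum.items()
    ) / n_ops
    target_events = total_rate * n_codons
    n_proposals = int(rng.poisson(target_events / mean_accept))
    seq = list(ancestor)
    n_nt = len(seq)
    sites = rng.integers(0, n_nt, size=n_proposals)
    alt_draws = rng.integers(0, 3, size=n_proposals)
    unif = rng.random(n_proposals)
    for k in range(n_proposals):
        site = int(sites[k])
        # redraw loop: proposals creating stops are rejected and redrawn
        alt_k = int(alt_draws[k])
        for _attempt in range(100):
            ci = site - site % 3
            codon = "".join(seq[ci : ci + 3])
            old = seq[site]
            alt = _NT.replace(old, "")[alt_k]
            pos = site % 3
            new_codon = codon[:pos] + alt + codon[pos + 1 :]
            new_aa = translate_codon(new_codon, code)
            if new_aa != STOP:
                break
            site = int(rng.integers(0, n_nt))
            alt_k = int(rng.integers(0, 3))
        else:  # pragma: no cover - cannot happen for sense-codon sequences
            continue
        aa = translate_codon(codon, code)
        cls = "syn" if new_aa == aa else "nonsyn"
        rate = params.syn_rate if cls == "syn" else params.nonsyn_rate
        direction = _direction(old, alt)
        weight = params.kappa_gc if (focal and direction == "ATGC") else 1.0
        p_accept = (rate / total_rate) * weight / wmax
        if unif[k] < p_accept:
            seq[site] = alt
            key = f"{'focal' if focal else 'reference'}_{cls}_{direction}"
            accepted[key] = accepted.get(key, 0) + 1
    return "".join(seq), accepted


def _recount_pair(focal: str, reference: str, code: GeneticCode) -> dict[str, int]:
    """Generator-side recount of directional diffs between final sequences."""
    out = {"s1_syn": 0, "s2_syn": 0, "s1_nonsyn": 0, "s2_nonsyn": 0}
    for i in range(0, len(focal), 3):
        ca, cb = focal[i : i + 3], reference[i : i + 3]
        cls, positions = classify_codon_pair(ca, cb, code)
        if cls in (CodonPairClass.IDENTICAL, CodonPairClass.EXCLUDED):
            continue
        suffix = "syn" if cls is CodonPairClass.SYNONYMOUS else "nonsyn"
        for pos in positions:
            a, b = ca[pos - 1], cb[pos - 1]
            if a in GC and b in AT:
                out[f"s1_{suffix}"] += 1
            elif a in AT and b in GC:
                out[f"s2_{suffix}"] += 1
    return out


def evolve_pair(
    ancestor: str,
    params: SimulationParams,
    rng: np.random.Generator,
    gene_id: str = "gene",
    code: GeneticCode = STANDARD_CODE,
) -> tuple[str, str, GeneTruth]:
    """Evolve focal and reference descendants from one ancestor."""
    focal, acc_f = _evolve_lineage(ancestor, params, rng, focal=True, code=code)
    reference, acc_r = _evolve_lineage(ancestor, params, rng, focal=False, code=code)
    truth = GeneTruth(gene_id=gene_id, accepted={**acc_f, **acc_r})
    recount = _recount_pair(focal, reference, code)
    truth.realized_s1_syn = recount["s1_syn"]
    truth.realized_s2_syn = recount["s2_syn"]
    truth.realized_s1_nonsyn = recount["s1_nonsyn"]
    truth.realized_s2_nonsyn = recount["s2_nonsyn"]
    return focal, reference, truth


_SS_MEAN_RUN = {"H": 8.0, "E": 5.0, "C": 6.0}
_SS_FLIP_PROB = 0.5  # element flip probability at a differing-residue site


def _latent_track(length: int, rng: np.random.Generator) -> str:
    elements: list[str] = []
    current = "C"
    while len(elements) < length:
        run = int(rng.geometric(1.0 / _SS_MEAN_RUN[current]))
        elements.extend(current * run)
        others = [e for e in "HEC" if e != current]
        current = others[int(rng.integers(0, 2))]
    return "".join(elements[:length])


def simulate_ss_tracks(
    protein_focal: str,
    protein_reference: str,
    params: SimulationParams,
    rng: np.random.Generator,
    id_focal: str = "focal",
    id_reference: str = "reference",
) -> tuple[SSTrack, SSTrack]:
    """Simulate paired 3-state tracks over two equal-length ungapped proteins.

    Both species share a segmental latent track and its confidence profile;
    only sites where the residues differ may flip element, with coil-gaining
    flips on the focal side weighted by ``coil_gain_bias``. Identical
    proteins therefore yield identical tracks.
    """
    if len(protein_focal) != len(protein_reference):
        raise ValueError("proteins must have equal length")
    n = len(protein_focal)
    latent = _latent_track(n, rng)
    # confidences: high inside segments, low within 1 residue of a boundary
    boundary = [
        i == 0 or i == n - 1 or latent[i] != latent[i - 1] or latent[i] != latent[i + 1]
        for i in range(n)
    ]
    base_conf = [int(rng.integers(0, 7)) if boundary[i] else int(rng.integers(7, 10)) for i in range(n)]
    elems = {"focal": list(latent), "reference": list(latent)}
    conf = {"focal": list(base_conf), "reference": list(base_conf)}
    for i in range(n):
        if protein_focal[i] == protein_reference[i]:
            continue
        for species, bias in (("focal", params.coil_gain_bias), ("reference", 1.0)):
            if rng.random() >= _SS_FLIP_PROB:
                continue
            others = [e for e in "HEC" if e != elems[species][i]]
            weights = np.array([bias if e == "C" else 1.0 for e in others])
            weights = weights / weights.sum()
            elems[species][i] = others[int(rng.choice(2, p=weights))]
            conf[species][i] = int(rng.integers(0, 7))
    track_f = SSTrack(id=id_focal, elements="".join(elems["focal"]), confidence=conf["focal"])
    track_r = SSTrack(
        id=id_reference, elements="".join(elems["reference"]), confidence=conf["reference"]
    )
    return track_f, track_r


@dataclass
class SimulatedDataset:
    """In-memory simulated dataset plus its ground truth."""

    cds_a: dict[str, str]
    cds_b: dict[str, str]
    proteins_a: dict[str, str]
    proteins_b: dict[str, str]
    tracks_a: dict[str, SSTrack]
    tracks_b: dict[str, SSTrack]
    truth: TruthRecord


def simulate_pairs(params: SimulationParams, code: GeneticCode = STANDARD_CODE) -> SimulatedDataset:
    """Generate the full dataset: true ortholog pairs plus unpaired decoys."""
    rng = np.random.default_rng(params.seed)
    truth = TruthRecord()
    data = SimulatedDataset({}, {}, {}, {}, {}, {}, truth)
    exp_num = {"synonymous": 0.0, "nonsynonymous": 0.0}
    exp_den = {"synonymous": 0.0, "nonsynonymous": 0.0}
    for g in range(params.n_genes):
        gid = f"g{g + 1:04d}"
        id_a, id_b = f"{gid}_a", f"{gid}_b"
        ancestor = make_ancestor(params.codons_per_gene, params.ancestor_gc, rng, code)
        spectrum = opportunity_spectrum(ancestor, code)
        for cls, label in (("syn", "synonymous"), ("nonsyn", "nonsynonymous")):
            exp_num[label] += params.kappa_gc * spectrum.get((cls, "ATGC"), 0) + spectrum.get((cls, "GCAT"), 0)
            exp_den[label] += spectrum.get((cls, "GCAT"), 0) + spectrum.get((cls, "ATGC"), 0)
        focal, reference, gene_truth = evolve_pair(ancestor, params, rng, gid, code)
        data.cds_a[id_a] = focal
        data.cds_b[id_b] = reference
        prot_a = "".join(translate_codon(focal[i : i + 3], code) for i in range(0, len(focal), 3))
        prot_b = "".join(
            translate_codon(reference[i : i + 3], code) for i in range(0, len(reference), 3)
        )
        data.proteins_a[id_a] = prot_a
        data.proteins_b[id_b] = prot_b
        track_a, track_b = simulate_ss_tracks(prot_a, prot_b, params, rng, id_a, id_b)
        data.tracks_a[id_a] = track_a
        data.tracks_b[id_b] = track_b
        truth.genes.append(gene_truth)
        truth.true_pairs.append((id_a, id_b))
    for label in ("synonymous", "nonsynonymous"):
        key = "expected_syn_ratio" if label == "synonymous" else "expected_nonsyn_ratio"
        setattr(truth, key, exp_num[label] / exp_den[label] if exp_den[label] else None)
    for d in range(params.n_decoys):
        for side, cds_store, prot_store, decoy_list in (
            ("a", data.cds_a, data.proteins_a, truth.decoys_a),
            ("b", data.cds_b, data.proteins_b, truth.decoys_b),
        ):
            did = f"decoy{d + 1:03d}_{side}"
            cds = make_ancestor(params.codons_per_gene, params.ancestor_gc, rng, code)
            cds_store[did] = cds
            prot_store[did] = "".join(
                translate_codon(cds[i : i + 3], code) for i in range(0, len(cds), 3)
            )
            decoy_list.append(did)
    return data


def _write_fasta(records: dict[str, str], path: Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in records.items():
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def simulate_dataset(params: SimulationParams, outdir: str | Path) -> SimulatedDataset:
    """Simulate and write all pipeline inputs plus the truth record.

    Writes CDS and protein FASTA for both species, secondary-structure
    tracks in the internal TSV dialect, a per-gene truth TSV and the run
    parameters as YAML. Fully reproducible from ``params.seed``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = simulate_pairs(params)
    _write_fasta(data.cds_a, outdir / "species_a.cds.fasta")
    _write_fasta(data.cds_b, outdir / "species_b.cds.fasta")
    _write_fasta(data.proteins_a, outdir / "species_a.prot.fasta")
    _write_fasta(data.proteins_b, outdir / "species_b.prot.fasta")
    write_ss_tracks_tsv(data.tracks_a.values(), outdir / "species_a.ss.tsv")
    write_ss_tracks_tsv(data.tracks_b.values(), outdir / "species_b.ss.tsv")
    truth = data.truth
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write(
            "# expected_syn_ratio=%s expected_nonsyn_ratio=%s\n"
            % (truth.expected_syn_ratio, truth.expected_nonsyn_ratio)
        )
        fh.write(
            "gene_id\tid_a\tid_b\ts1_syn\ts2_syn\ts1_nonsyn\ts2_nonsyn\n"
        )
        for g, (id_a, id_b) in zip(truth.genes, truth.true_pairs):
            fh.write(
                f"{g.gene_id}\t{id_a}\t{id_b}\t{g.realized_s1_syn}\t{g.realized_s2_syn}"
                f"\t{g.realized_s1_nonsyn}\t{g.realized_s2_nonsyn}\n"
            )
        for did in truth.decoys_a:
            fh.write(f"{did}\t{did}\t-\t0\t0\t0\t0\n")
        for did in truth.decoys_b:
            fh.write(f"{did}\t-\t{did}\t0\t0\t0\t0\n")
    with open(outdir / "params.yaml", "w") as fh:
        yaml.safe_dump(asdict(params), fh, sort_keys=True)
    return data
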