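"""End-to-end orchestration: pair, align, filter, back-translate, tally, report.

A run consumes two species' protein+CDS FASTA sets (species A is the focal,
"cold-water" side; species B the tropical reference), finds reciprocal-best
ortholog pairs, filters alignments, back-translates them onto the CDS and
emits the full table set: directional GC tallies with bias ratios and
chi-square, per-codon ratios, RSCU and codon-usage GC bias per species,
amino-acid substitution matrix and per-amino-acid bias, property biases,
the equal-GC control, Spearman/regression results, secondary-structure
change tables when tracks are supplied, and a machine-readable summary.

Every table is TSV with a commented header stating the directional
convention — numerators are always the focal species' state.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import codon_core as cc
from . import ortholog_pairing as op
from . import secstruct as ss
from . import substitution_asymmetry as sa
from .properties import PropertyTable, default_property_tables, read_property_table
from .stats_kit import t_test

logger = logging.getLogger("coldbias")

_CONVENTION = (
    "# directional convention: species A is the focal (cold-water) side; "
    "numerators count the focal state, so ratios > 1 favour species A\n"
)


@dataclass
class RunConfig:
    """Validated configuration for one species-pair analysis."""

    protein_a: Path
    cds_a: Path
    protein_b: Path
    cds_b: Path
    ss_a: Path | None = None
    ss_b: Path | None = None
    out_dir: Path = Path("coldbias_out")
    label_a: str = "species_a"
    label_b: str = "species_b"
    min_aligned_length: int = 21
    min_similarity: float = 0.5
    similarity_mode: str = "positives"
    multi_hit: str = "codon_class"
    min_conf: int = 5
    conf_strictly_greater: bool = True
    min_rbh_score: float = 0.0
    per_gene_averaging: bool = False
    property_tables: dict[str, Path] = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("protein_a", "cds_a", "protein_b", "cds_b", "ss_a", "ss_b", "out_dir"):
            if raw.get(key) is not None:
                raw[key] = Path(raw[key])
        raw["property_tables"] = {
            k: Path(v) for k, v in (raw.get("property_tables") or {}).items()
        }
        config = cls(**raw)
        config.validate()
        return config

    def validate(self) -> None:
        for key in ("protein_a", "cds_a", "protein_b", "cds_b", "ss_a", "ss_b"):
            path = getattr(self, key)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{key}: {path} does not exist")
        if self.similarity_mode not in ("positives", "identity"):
            raise ValueError("similarity_mode must be 'positives' or 'identity'")
        if self.multi_hit not in ("codon_class", "strict"):
            raise ValueError("multi_hit must be 'codon_class' or 'strict'")
        if not 0 <= self.min_conf <= 9:
            raise ValueError("min_conf must be 0-9")

    def load_property_tables(self) -> dict[str, PropertyTable]:
        tables = default_property_tables()
        for name, path in self.property_tables.items():
            tables[name] = read_property_table(path)
        return tables


@dataclass
class ExclusionCounters:
    """Reconciliation of every dropped record against one named reason."""

    counts: dict[str, int] = field(default_factory=dict)

    def add(self, reason: str, n: int = 1) -> None:
        self.counts[reason] = self.counts.get(reason, 0) + n


def _drop_ambiguous(records: dict[str, str], alphabet: frozenset, label: str,
                    counters: ExclusionCounters) -> dict[str, str]:
    kept = {}
    for rid, seq in records.items():
        if set(seq) <= alphabet:
            kept[rid] = seq
        else:
            counters.add(f"{label}: ambiguous characters")
    return kept


def _ratio_str(r: float | None) -> str:
    return "NA" if r is None else f"{r:.6g}"


def _write_bias_table(path: Path, header: Sequence[str],
                      rows: Sequence[Sequence[object]]) -> None:
    with open(path, "w") as fh:
        fh.write(_CONVENTION)
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def build_codon_alignments(
    config: RunConfig, counters: ExclusionCounters
) -> tuple[list[op.CodonAlignment], list[tuple[str, str]], dict]:
    """Pair, align, filter and back-translate; returns alignments + pairing."""
    prot_a = op.read_fasta(config.protein_a)
    prot_b = op.read_fasta(config.protein_b)
    cds_a = op.read_fasta(config.cds_a)
    cds_b = op.read_fasta(config.cds_b)
    prot_a = _drop_ambiguous(prot_a, op.PROTEIN_ALPHABET, "protein A", counters)
    prot_b = _drop_ambiguous(prot_b, op.PROTEIN_ALPHABET, "protein B", counters)
    cds_a = _drop_ambiguous(cds_a, cc.NUCLEOTIDES, "CDS A", counters)
    cds_b = _drop_ambiguous(cds_b, cc.NUCLEOTIDES, "CDS B", counters)
    usable_a = [(rid, seq) for rid, seq in sorted(prot_a.items()) if rid in cds_a]
    usable_b = [(rid, seq) for rid, seq in sorted(prot_b.items()) if rid in cds_b]
    if not usable_a or not usable_b:
        raise ValueError("no records with both protein and CDS present in a species")
    pairs = op.reciprocal_best_pairs(usable_a, usable_b, min_score=config.min_rbh_score)
    logger.info("reciprocal best hits: %d pairs", len(pairs))
    alignments = []
    for id_a, id_b in pairs:
        aln = op.global_align(
            prot_a[id_a], prot_b[id_b], id_a=id_a, id_b=id_b,
            similarity_mode=config.similarity_mode,
        )
        alignments.append(aln)
    kept, filter_log = op.filter_pairs(
        alignments, config.min_aligned_length, config.min_similarity
    )
    for id_a, id_b, reason in filter_log.rejected:
        counters.add(f"filter: {reason.split()[0]}")
    codon_alns = []
    for aln in kept:
        try:
            codon_alns.append(op.backtranslate(aln, cds_a[aln.id_a], cds_b[aln.id_b]))
        except ValueError as exc:
            counters.add("backtranslate: CDS/protein mismatch")
            logger.warning("pair (%s, %s) rejected: %s", aln.id_a, aln.id_b, exc)
    stats = {
        "n_input_a": len(prot_a),
        "n_input_b": len(prot_b),
        "n_rbh_pairs": len(pairs),
        "n_filtered_pairs": len(kept),
        "n_codon_alignments": len(codon_alns),
    }
    return codon_alns, pairs, stats


def run_pair_analysis(config: RunConfig) -> dict:
    """Run the full species-pair analysis and write the report bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counters = ExclusionCounters()
    tables = config.load_property_tables()
    codon_alns, pairs, pair_stats = build_codon_alignments(config, counters)
    if not codon_alns:
        raise ValueError("no codon alignments survived pairing and filtering")

    summary: dict = {"pairing": pair_stats, "focal": config.label_a,
                     "reference": config.label_b}

    # --- directional GC tallies and bias ratios (pooled; per-gene optional)
    gc_rows = []
    for class_label in ("synonymous", "nonsynonymous"):
        tally = sa.tally_many(codon_alns, class_label, multi_hit=config.multi_hit)
        result = sa.bias_ratio(tally)
        if config.per_gene_averaging:
            per_gene = [
                sa.bias_ratio(sa.tally_gc_substitutions(a, class_label, multi_hit=config.multi_hit)).ratio
                for a in codon_alns
            ]
            defined = [r for r in per_gene if r is not None]
            mean_ratio = sum(defined) / len(defined) if defined else None
        else:
            mean_ratio = None
        test = result.test
        gc_rows.append([
            class_label, tally.s1, tally.s2, _ratio_str(result.ratio),
            _ratio_str(test.statistic), _ratio_str(test.p_value), test.stars,
            tally.n_sites_scanned, _ratio_str(mean_ratio),
        ])
        summary[f"{class_label}_s1"] = tally.s1
        summary[f"{class_label}_s2"] = tally.s2
        summary[f"{class_label}_bias_ratio"] = result.ratio
        summary[f"{class_label}_chi2_p"] = test.p_value
    _write_bias_table(out / "gc_bias.tsv",
                      ["class", "s1", "s2", "bias_ratio", "chi2", "p_value", "stars",
                       "n_sites_scanned", "per_gene_mean_ratio"], gc_rows)

    # --- per-codon ratios and chi-square (both classes)
    for class_label in ("synonymous", "nonsynonymous"):
        per_codon = sa.per_codon_bias(codon_alns, class_label, multi_hit=config.multi_hit)
        rows = []
        for codon, result in sorted(per_codon.items()):
            test = result.test
            rows.append([
                codon, cc.translate_codon(codon), cc.third_position_class(codon).value,
                cc.gc_count(codon), result.numerator_count, result.denominator_count,
                _ratio_str(result.ratio), _ratio_str(test.statistic),
                _ratio_str(test.p_value), test.stars, "low_count" if result.low_count else "",
            ])
        _write_bias_table(out / f"per_codon_{class_label}.tsv",
                          ["codon", "aa", "third_position", "gc_group", "n_focal",
                           "n_reference", "bias_ratio", "chi2", "p_value", "stars", "flag"],
                          rows)
        if class_label == "nonsynonymous":
            spearman = sa.gc_group_correlation(per_codon)
            summary["spearman_rho_gc_group"] = spearman.statistic
            summary["spearman_p_gc_group"] = spearman.p_value
            _write_bias_table(out / "spearman_gc_group.tsv",
                              ["rho", "p_value", "n"],
                              [[_ratio_str(spearman.statistic), _ratio_str(spearman.p_value),
                                int(spearman.df + 2) if spearman.df else "NA"]])

    # --- RSCU and codon-usage GC bias per species
    for label, side in ((config.label_a, "a"), (config.label_b, "b")):
        counts = cc.count_codons((a.ungapped(side) for a in codon_alns), label)
        rscu_values = cc.rscu(counts)
        usage_bias = cc.codon_usage_gc_bias(rscu_values)
        rows = [[codon, cc.translate_codon(codon), counts.counts.get(codon, 0),
                 _ratio_str(rscu_values[codon])] for codon in cc.STANDARD_CODE.sense_codons]
        _write_bias_table(out / f"rscu_{side}.tsv", ["codon", "aa", "count", "rscu"], rows)
        rows = [[aa, _ratio_str(v)] for aa, v in sorted(usage_bias.items())]
        _write_bias_table(out / f"codon_usage_gc_bias_{side}.tsv",
                          ["aa", "gc_over_at_rscu_ratio"], rows)

    # --- amino-acid substitution matrix and per-AA bias
    matrix = sa.aa_substitution_matrix(codon_alns)
    per_aa: dict[str, sa.BiasResult] = {}
    rows = []
    for aa in cc.AMINO_ACIDS:
        result = sa.aa_bias_ratio(matrix, aa)
        per_aa[aa] = result
        test = result.test
        rows.append([aa, result.numerator_count, result.denominator_count,
                     _ratio_str(result.ratio), _ratio_str(test.statistic),
                     _ratio_str(test.p_value), test.stars])
    _write_bias_table(out / "aa_bias.tsv",
                      ["aa", "n_focal", "n_reference", "bias_ratio", "chi2", "p_value",
                       "stars"], rows)
    with open(out / "aa_substitution_matrix.tsv", "w") as fh:
        fh.write(_CONVENTION)
        fh.write("focal\\reference\t" + "\t".join(cc.AMINO_ACIDS) + "\n")
        for a in cc.AMINO_ACIDS:
            row = [str(matrix.counts.get((a, b), 0)) if a != b else "." for b in cc.AMINO_ACIDS]
            fh.write(a + "\t" + "\t".join(row) + "\n")
    summary["total_aa_changes"] = matrix.total_changes()

    # --- regression of per-AA ratio on mean codon GC (nonsynonymous logic)
    regression = sa.aa_gc_regression(per_aa)
    summary["aa_gc_regression_r2"] = regression.r_squared
    _write_bias_table(out / "aa_gc_regression.tsv",
                      ["slope", "intercept", "r_squared", "df", "p_value"],
                      [[_ratio_str(regression.slope), _ratio_str(regression.intercept),
                        _ratio_str(regression.r_squared),
                        _ratio_str(regression.test.df), _ratio_str(regression.test.p_value)]])

    # --- property biases, equal-GC control, property/GC correlations
    rows = []
    for name, table in tables.items():
        result = sa.property_bias_from_matrix(matrix, table)
        equal_gc = sa.equal_gc_property_bias(codon_alns, table)
        corr = sa.property_gc_correlation(table)
        test = result.test
        rows.append([name, result.numerator_count, result.denominator_count,
                     _ratio_str(result.ratio), _ratio_str(test.p_value), test.stars,
                     equal_gc.numerator_count, equal_gc.denominator_count,
                     _ratio_str(equal_gc.ratio), _ratio_str(equal_gc.test.p_value),
                     _ratio_str(corr.statistic), _ratio_str(corr.p_value)])
        summary[f"property_bias_{name}"] = result.ratio
        summary[f"equal_gc_bias_{name}"] = equal_gc.ratio
    _write_bias_table(out / "property_bias.tsv",
                      ["property", "n_smaller_focal", "n_larger_focal", "bias_ratio",
                       "p_value", "stars", "equal_gc_n_smaller", "equal_gc_n_larger",
                       "equal_gc_ratio", "equal_gc_p", "pearson_r_vs_mean_gc",
                       "pearson_p_vs_mean_gc"], rows)

    # --- secondary structure (optional)
    if config.ss_a is not None and config.ss_b is not None:
        tracks_a = ss.read_ss_tracks_tsv(config.ss_a)
        tracks_b = ss.read_ss_tracks_tsv(config.ss_b)
        all_sites: list[ss.SSSite] = []
        retained: list[float] = []
        for aln in codon_alns:
            source = aln.source
            if source is None or source.id_a not in tracks_a or source.id_b not in tracks_b:
                counters.add("ss: missing track")
                continue
            sites, fraction = ss.paired_ss_sites(
                source, tracks_a[source.id_a], tracks_b[source.id_b],
                min_conf=config.min_conf, strictly_greater=config.conf_strictly_greater,
            )
            all_sites.extend(sites)
            if fraction is not None:
                retained.append(fraction)
        fraction_mean = sum(retained) / len(retained) if retained else None
        matrix_ss = ss.ss_change_matrix(all_sites, retained_fraction=fraction_mean)
        net = ss.net_change_percent(matrix_ss)
        mw_conditioned = ss.property_conditioned_ss_change(all_sites, tables["molecular_weight"])
        net_mw = ss.net_change_percent(mw_conditioned)
        rows = []
        for e in ss.SS_ELEMENTS:
            rows.append([e, _ratio_str(net[e] if net else None),
                         _ratio_str(net_mw[e] if net_mw else None)])
        _write_bias_table(out / "ss_net_change.tsv",
                          ["element", "net_change_percent", "net_change_percent_smaller_mw"],
                          rows)
        with open(out / "ss_change_matrix.tsv", "w") as fh:
            fh.write(_CONVENTION)
            fh.write("focal\\reference\t" + "\t".join(ss.SS_ELEMENTS) + "\n")
            for a in ss.SS_ELEMENTS:
                fh.write(a + "\t" + "\t".join(
                    str(matrix_ss.counts[(a, b)]) for b in ss.SS_ELEMENTS) + "\n")
        summary["ss_retained_fraction"] = fraction_mean
        summary["ss_net_change_percent"] = net

    # --- pairing table, exclusions, summary, run log
    with open(out / "pairs.tsv", "w") as fh:
        fh.write("id_a\tid_b\n")
        for id_a, id_b in pairs:
            fh.write(f"{id_a}\t{id_b}\n")
    with open(out / "exclusions.tsv", "w") as fh:
        fh.write("reason\tcount\n")
        for reason, n in sorted(counters.counts.items()):
            fh.write(f"{reason}\t{n}\n")
    summary["exclusions"] = counters.counts
    config_text = yaml.safe_dump(
        {k: str(v) for k, v in vars(config).items()}, sort_keys=True
    )
    summary["config_sha256"] = hashlib.sha256(config_text.encode()).hexdigest()
    summary["seed"] = config.seed
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    with open(out / "run_log.txt", "w") as fh:
        fh.write(f"coldbias run\nseed: {config.seed}\n")
        fh.write(f"config sha256: {summary['config_sha256']}\n")
        fh.write(f"pairs: {pair_stats}\nexclusions: {counters.counts}\n")
    return summary


def run_multi_pair(
    summaries: Sequence[Mapping],
    grouping: Mapping[str, Sequence[int]] | None = None,
    tail: str = "greater",
) -> dict:
    """Cross-pair comparisons over completed pair analyses.

    Runs the paired t-test of synonymous vs nonsynonymous bias ratios across
    species pairs (df = n_pairs - 1), and, when ``grouping`` names two
    groups of summary indices, a two-sample t-test between the groups'
    synonymous ratios.
    """
    if len(summaries) < 2:
        raise ValueError("need at least two completed pair analyses")
    syn = [s["synonymous_bias_ratio"] for s in summaries]
    nonsyn = [s["nonsynonymous_bias_ratio"] for s in summaries]
    if any(v is None for v in syn + nonsyn):
        raise ValueError("all pair analyses must have defined bias ratios")
    paired = t_test(syn, nonsyn, mode="paired", tail=tail)
    out: dict = {
        "n_pairs": len(summaries),
        "syn_ratios": syn,
        "nonsyn_ratios": nonsyn,
        "syn_vs_nonsyn_paired_t": {
            "statistic": paired.statistic, "df": paired.df,
            "p_value": paired.p_value, "tail": paired.tail,
        },
    }
    if grouping:
        if set(grouping) != set(list(grouping)[:2]) or len(grouping) != 2:
            raise ValueError("grouping must name exactly two groups")
        (name1, idx1), (name2, idx2) = grouping.items()
        g1 = [syn[i] for i in idx1]
        g2 = [syn[i] for i in idx2]
        two = t_test(g1, g2, mode="two_sample", tail=tail)
        out["group_comparison"] = {
            "groups": [name1, name2],
            "statistic": two.statistic, "df": two.df,
            "p_value": two.p_value, "tail": two.tail,
        }
    return out
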