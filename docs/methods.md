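# Methods

## Directional tallies and bias ratios

All statistics reduce to ordered counts over aligned codon or residue
columns between a focal species A and a reference species B. A codon
column enters a tally only if neither side is a gap and neither codon is a
stop; stop-containing columns are excluded silently but counted in the
run's exclusion log. A column's substitution class is decided at the codon
level: synonymous iff the two codons differ and translate identically
under the genetic code (standard table by default; any 64-entry table can
be supplied). Each differing nucleotide position of a matching-class
column then contributes to s1 (A: G/C vs B: A/T) or s2 (the reverse);
G↔C and A↔T changes cross no class boundary and contribute to neither,
though they are counted among scanned sites.

**Multi-hit codons.** When a codon pair differs at more than one position,
the default (`multi_hit="codon_class"`) applies the codon-level class to
every differing nucleotide. A `strict` mode drops multi-hit columns
entirely. Both are exposed because with independently accumulated
single-nucleotide changes a two-hit codon genuinely carries two events of
the same codon-level class, yet attributing per-site classes is ambiguous;
reports can be generated under either convention and compared.

**Ratios and tests.** Every bias ratio is a plain quotient of two ordered
counts — no pseudocounts or smoothing — with an equal-split χ²
goodness-of-fit (df = 1, no continuity correction) attached. Zero
denominators yield a flagged missing ratio rather than infinity;
denominators below 10 carry a `low_count` flag. Ratios are pooled over all
genes of a species pair by default (summing counts before dividing);
per-gene averaging is available behind a config switch since pooling and
averaging answer slightly different questions.

**Directional convention.** Numerators always count the focal species'
state. Swapping species roles swaps s1↔s2, transposes the amino-acid and
secondary-structure matrices, and inverts every ratio; this antisymmetry
is property-tested. Every report TSV begins with a comment line restating
the convention, which is the single most error-prone aspect of comparing
directional tables between tools.

## Ortholog pairing

Putative orthologs are found by reciprocal best hits under global protein
alignment: Needleman–Wunsch with affine gaps via Biopython's
`PairwiseAligner`, BLOSUM62, gap open −11 and extend −1 (BLASTP's
defaults; a gap of length L costs open + L·extend, and the aligner's
open score is shifted accordingly). A pair is kept iff each member is the
unique top scorer for the other and the score clears a configurable floor
(default > 0) — a raw-score stand-in for a database e-value cutoff, which
would require search-space statistics that have no meaning at desk scale.
Traceback ties are resolved by the aligner's deterministic first
traceback. This is an exact all-vs-all method intended for hundreds to a
few thousand sequences, not a heuristic seeded search for whole genomes.

Retained alignments must have strictly more than 20 aligned (non-gap)
residue columns and strictly more than 50% similarity. Similarity defaults
to the BLASTP-style "positives" fraction — aligned columns whose residue
pair scores above zero under BLOSUM62 — with an identity mode behind a
switch, since either reading of "similarity" is defensible.

Back-translation threads each in-frame CDS (terminal stop trimmed) through
the protein alignment, pal2nal-style: residue columns become codon
columns, protein gaps become codon gaps. The CDS must be exactly 3× the
protein length and translate to it codon-for-codon; violations reject the
pair with a logged reason. The round-trip invariant — ungapping the codon
alignment reproduces both input CDS byte-exactly — is enforced in tests on
1000 simulated pairs.

## Codon usage

RSCU(c) = n_a·x_c / Σx over the amino-acid family of c, where n_a is the
family degeneracy. Serine, leucine and arginine are treated as single
six-codon families (the CodonW convention). Per-amino-acid codon-usage GC
bias is Σ RSCU(G/C-ending) / Σ RSCU(A/T-ending); single-codon amino acids
(Met, Trp) are omitted and zero-usage families are flagged missing.

## Property tables

Five per-amino-acid indices ship as 2-column TSVs: molecular weight is
pinned to free-amino-acid masses in Da (Gly 75.07 … Trp 204.23) — the
scale on which statements like "small amino acids below 117 Da" are
meaningful. The other four (residue volume for size, a side-chain graph
shape index, Grantham polarity, Kyte–Doolittle hydropathy) are well-known
published scales chosen as reasonable substitutes for whichever specific
AAindex entries a given study used; conclusions that depend on the exact
index should load it via `read_property_table`. Under the standard code,
molecular weight correlates with mean codon GC fraction at Pearson
r = −0.36 (p = 0.12, n = 20) — a genetic-code constant the acceptance
script recomputes. Ties under a property (e.g. Leu/Ile in mass) contribute
to neither side of a property bias.

## Secondary structure

Tracks are 3-state (H/E/C) with integer 0–9 confidences, read from
PSIPRED's vertical `.ss2` dialect (confidence derived as
floor(10·max probability), capped at 9 — PSIPRED's own horizontal-format
rule), its horizontal `.horiz` dialect, or an internal one-line-per-track
TSV used for synthetic data. An aligned residue column survives only when
*both* confidences exceed the threshold; "above 5" is read strictly
(> 5) by default with a ≥ switch, and the retained fraction is always
reported so the filter's effect is auditable on any dataset. Net change
per element is 100·(gained − lost)/total changes; the three values sum to
zero by construction. Sites with equal elements but different residues
count as conserved structure.

## Synthetic data generator

The generator emulates exactly the statistical structure the analysis
assumes, and deliberately nothing more: no indels, no rate heterogeneity
across sites, no explicit time-reversible codon model, no phylogeny beyond
a two-leaf star. Passing tests therefore demonstrate the correctness of
the counting and calibration of the statistics — not robustness to
alignment error, assembly artefacts, or lineage-specific composition
drift present in real proteomes.

**Ancestor.** Codons are drawn i.i.d. from the 61 sense codons with
weight w^gc(codon); w is solved by bisection so the expected GC fraction
hits the target (default 0.5, attainability checked). No internal stops
can occur.

**Substitution process.** Each lineage receives a Poisson number of
single-nucleotide proposals (uniform site, uniform alternative base);
proposals creating stops are redrawn. A proposal is classified
synonymous/nonsynonymous against the current codon and accepted with
probability proportional to its class intensity (`syn_rate`,
`nonsyn_rate`, expected substitutions per codon per lineage; defaults
0.05/0.02, a plausibly mild divergence with the synonymous class faster)
times a directional weight: `kappa_gc` for AT→GC proposals on the focal
lineage, 1 otherwise, normalised by max(kappa_gc, 1). Both lineages get
equal proposal budgets, calibrated from the ancestor's
substitution-opportunity spectrum so realized counts sit near nominal.

**Closed-form expectation.** Enumerating the ancestor's non-stop
single-nucleotide neighbourhoods gives opportunity counts n(class,
direction); with equal budgets the first-order expected class-c ratio is
(kappa·n_ATGC + n_GCAT)/(n_GCAT + n_ATGC) ≈ (kappa+1)/2 at balanced
composition. The truth record stores this expectation plus per-event logs
and a final-sequence recount that the analyzer must reproduce exactly.
The expectation is first-order: multiple hits in one codon can reclassify
sites and drag the recounted ratio a few percent above the closed form at
high per-codon rates, so calibration and recovery runs use low rates over
long sequences (e.g. 0.07/codon over 10⁵–10⁶ codons) where the effect is
small relative to the 10% recovery tolerance.

**Structure tracks.** A latent segmental H/E/C sequence (geometric run
lengths, means 8/5/6) is shared by both species, with high confidences
(7–9) in segment interiors and low (0–6) within one residue of a
boundary. Only sites whose residues differ may flip element (probability
0.5), the focal side weighting coil-gaining flips by `coil_gain_bias`;
identical proteins therefore yield byte-identical tracks.

**Dataset.** `simulate_dataset` writes CDS/protein FASTA for both species,
tracks, decoy unpaired genes (default 10 per species) for
reciprocal-best-hit testing, a per-gene truth TSV and the parameters as
YAML — byte-reproducible from the seed.

## Statistical kit

Thin wrappers over scipy.stats with explicit tail contracts: one-sample
(null ratio 1), paired, and two-sample t-tests (Welch by default since
group variances are not assumed equal; pooled df available), equal-split
χ² (df = 1), Pearson/Spearman correlation (mid-rank ties, checked against
a brute-force ranking oracle), and OLS regression (R² = squared Pearson r,
df = n − 2). Degenerate inputs (zero variance, constant vectors, empty
counts) return flagged missing results instead of raising, so report
generation never aborts on a sparse table. Significance stars follow
* p < 0.05, ** p < 0.01; raw p-values are always emitted and an optional
Benjamini–Hochberg column is available (no correction is applied by
default).

## Problem sizes in the test and acceptance runs

Null calibration uses 200 replicates of 2 500 codons at rates 0.12/0.08
(≈1 000 accepted substitutions each); parameter recovery a single
750 000-codon pair at rates 0.05/0.02 (≈10⁵ accepted events); round-trip
1 000 pairs of 40 codons; the coil-bias check 150 pairs of 120 codons.
These sizes put Monte-Carlo noise well inside the stated tolerances while
keeping the whole suite under a minute of compute.

## Known limitations

- The exact all-vs-all pairing is quadratic in proteome size; genome-scale
  runs need an external BLAST-style prescreen feeding the same filters.
- Directional counts between extant species cannot separate focal-lineage
  gain from reference-lineage loss without an outgroup; ratios measure
  net asymmetry only, as the underlying comparative design intends.
- Secondary-structure analyses inherit whatever biases the upstream
  predictor has; the confidence filter trades coverage for reliability and
  the retained fraction should always be inspected.
- The equal-GC property control conditions on codon GC count, not on
  mutational opportunity; it removes GC pressure as a confounder but not,
  e.g., transition/transversion asymmetry.
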