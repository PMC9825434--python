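# Methods

This note documents the statistical procedures, the defaults and the design
choices behind funlink, and what the synthetic fixtures do and do not show
about real data.

## Benchmark truth labels

The gold standard is a collection of pathway-membership sets with an
exclusion list for homology-dominated sets. A pair is labeled **positive**
when both proteins share at least one non-excluded set, **negative** when
both are annotated (appear in ≥ 1 non-excluded set) but share none, and
**unbenchmarkable** when either protein is unannotated. Excluded sets never
contribute: a protein annotated only in excluded sets counts as unannotated.
Both-annotated-but-disjoint as the negative definition is the standard
co-membership reading; it treats cross-pathway pairs as negatives even
though a minority of them are genuinely associated, which makes measured
precisions slightly conservative.

## Calibration

Pairs are ranked by raw score (descending; ties broken by pair identity so
the ranking is reproducible), unbenchmarkable pairs are dropped, and
precision = positives / (positives + negatives) is measured in sliding
windows. Defaults: window = 50 benchmarkable pairs, step = window/2, with a
final window anchored at the tail so every pair is covered; a dataset
smaller than one window forms a single window. Window size 50 keeps the
binomial standard error of a window precision below ~0.07 while still
resolving structure in experiments of a few hundred pairs.

The (mean raw score, precision, weight = occupancy) points are fitted by
weighted isotonic regression (pool-adjacent-violators), evaluated by linear
interpolation between breakpoints and clamped outside the fitted range.
Isotonic regression was chosen over a parametric sigmoid because it is
assumption-free, exactly monotone and well-defined for any number of
points; the fitting function is a seam where a parametric form could be
substituted. Raw scores closer together than the fitting routine's
numerical merge tolerance are pooled as ties; raw scores in this package
live on coarse scales (Jaccard ratios, windowed means), where this never
matters.

## Experiments channel

- **Method filtering.** The PSI-MI controlled vocabulary is a DAG
  (term → parents). Kept: MI:0045 (*experimental interaction detection*)
  and descendants. Dropped: descendants of MI:0363, MI:0364 (author /
  curator inference) and MI:0063 (prediction), which win over inclusion.
  Records under MI:0254 (*genetic interference*) are kept but flagged
  functional-only; everything else kept is physical evidence. Records with
  a method term unknown to the ontology are dropped with a logged warning
  rather than failing the import.
- **Deduplication.** One record survives per (pair, publication, method);
  the surviving source database follows a configurable priority list,
  defaulting to alphabetical order. Deduplication is idempotent.
- **HT/LT split.** An experiment (publication × method) is high-throughput
  at ≥ 25 unique canonical pairs, low-throughput below.
- **HT raw score.** For pair (a, b) within one experiment the raw score is
  the Jaccard index |N(a) ∩ N(b)| / |N(a) ∪ N(b)| of the endpoints'
  within-experiment interactor sets, excluding a and b themselves; 0 when
  the union is empty. This realizes "more shared, fewer non-shared
  interactors → higher score" in a bounded, parameter-free way and is a
  pluggable seam.
- **HT scoring.** Each HT experiment is benchmarked and calibrated on its
  own pairs only. Experiments with zero benchmarkable pairs are unscorable;
  their pairs receive a configurable fallback (the global prior by default)
  with a warning.
- **LT scoring.** LT pairs are pooled per detection method across all LT
  experiments; the method's true-positive rate over benchmarkable pooled
  pairs becomes the confidence of every pair the method detected. No curve
  fitting is done at the method level: LT studies focus on specific
  pathways, so a within-method ranking is not informative. Methods with no
  benchmarkable pair are flagged and their pairs excluded with a warning.
- **Aggregation and grades.** All dataset scores of a pair (HT experiments
  and LT methods) merge by the prior-corrected noisy-OR below. Each dataset
  confidence is graded high (≥ 0.7), medium (≥ 0.4) or exploratory;
  boundaries are configurable and mirror the conventional high/medium
  cutoff ladder.

## Combination and recalibration

With prior p, each channel score is corrected to s' = max(0, (s−p)/(1−p)),
corrected scores merge as 1 − ∏(1 − s'), and the prior is re-added. The
prior is estimated from the supplied gold standard and pair universe (the
fraction of benchmarkable pairs that are positive) rather than hard-coded,
because it is benchmark-dependent; a degenerate all-positive universe is
capped just below 1 with a warning. Because evidence sources are not
independent, `recalibrate_combined` re-ranks edges by combined score and
maps them through a freshly fitted calibration curve; the transform is
monotone, so ranking is preserved up to ties. Recalibration is exposed for
any edge set, so it can be applied to one channel group (e.g. co-expression
sources) or to the whole network.

## Interolog transfer

For a source edge (a, b, s), the transfer level is the LCA of the source
and target organisms. Every target ortholog pair (a', b') at that level
receives s × f(depth) / (nₐ · n_b), where nₐ and n_b count the target
co-orthologs and f is a clade-depth transfer factor in (0, 1]. The
paralogy penalty splits the evidence democratically over ambiguous
many-to-many transfers and reduces to the identity for one-to-one
orthology; it is a design choice of this package, monotone and bounded,
and configurable per clade depth. Transfer factors default to 1.0 at every
depth (a strict mode errors on unconfigured depths instead). Candidates on
the same target pair merge by noisy-OR with prior 0, so repeated support
accumulates but never exceeds 1. Transfer of a network onto its own
organism is suppressed by default to avoid double counting; the
`allow_self_transfer` flag enables it (used by the identity round-trip
checks and by proteome resubmission).

## Proteome annotation

FASTA headers are parsed per record as UniProt (`db|ACC|ENTRY` with `GN=` /
`OS=` fields), Ensembl (`ENS…P` accession with `gene:` / `gene_symbol:` /
`description:` fields) or RefSeq (versioned accession with trailing
bracketed organism), falling back to first-token-as-identifier. Duplicate
identifiers, empty sequences and non-amino-acid characters are hard errors.

The aligner is an injectable contract. The bundled `KmerToyAligner`
(exact shared k-mer prefilter, k = 4, then local alignment under BLOSUM62
with affine gaps, reporting threshold 40 bits of raw score) is a small
built-in search suitable for toy-scale references; a production adapter
would shell out to an external translated-search tool. Best hits take the
highest score, ties broken lexicographically by subject identifier; hits
below the threshold leave the query unplaced. The threshold default is
conservative: on the synthetic families (length ≥ 30, ~2% substitutions
per branch) true family members score far above it.

Placement level is the LCA of the user taxon and the best hit's taxon; the
protein joins the hit's group at that level, or becomes a direct one-to-one
ortholog when none exists. Identical sequences in a resubmitted proteome
map directly to their hits. Annotation consensus at the most specific
group assigns terms carried by ≥ `consensus_fraction` (default 0.5) of the
group's *annotated* members — unannotated members do not enter the
denominator, since the consensus is over the annotations that exist. When
no member is annotated the consensus climbs to the parent group, stopping
at the root. A term is never assigned outside its taxonomic scope, the LCA
of all organisms historically annotated with it.

Network prediction for an upload routes through the generic interolog
machinery over a hierarchy built from the placement-derived groups only
(reference group + submitted protein, or a private two-member group for
one-to-one placements). Restricting to placement groups keeps the ortholog
lookup unambiguous; in particular, resubmitting a reference proteome
reproduces that organism's own network exactly. A consequence is that
edges transfer from an organism only when the placement level matches the
LCA of that organism and the upload — i.e. predictions draw on the clades
where best hits were actually found.

## Synthetic fixtures

All generators draw from named pseudorandom streams derived from one
integer seed (stream name hashed into the seed sequence), so outputs are
bitwise-reproducible and insensitive to the addition of new generators.
Sizes used by the bundled checks: gold standards of 800 proteins in 12
pathways of mean size 50 (prior ≈ 0.1); planted two-stratum rankings of
2000 pairs at precisions 0.8/0.2; LT methods of 1000 pairs at a 0.75
true-positive rate; HT experiments of a few hundred pairs with clique-
planted topology; proteomes of 2–8 species, sequence length 15–80,
~2% substitutions per branch. Planted truth coins are fixed per slot and
only the pair resampled on duplicate draws, so collision pressure cannot
bias the planted rates.

What the fixtures do **not** emulate: literature and curation bias (real LT
evidence concentrates on well-studied pathways), correlated errors between
detection methods, homology-driven spurious co-membership inside the gold
standard, realistic sequence evolution (no indels, no rate variation) and
namespace noise in identifiers. Passing the recovery tests therefore shows
the estimators are correct under clean sampling assumptions, not that real
benchmark curves will be unbiased.

## Numerical conventions

- Frequencies in cutoff summaries and the ×1000 integer score columns in
  link files round half away from zero (one decimal, and integer,
  respectively); internal computation stays in double precision.
- Curve evaluation clamps to the first/last fitted confidence outside the
  breakpoint range.
- Degenerate inputs: empty score multisets summarize to zero counts with a
  warning; zero-benchmarkable datasets raise (calibration), fall back to
  the prior (HT experiments), are excluded (LT methods) or become the
  identity transform (recalibration), each with a warning.

## Known limitations

The raw HT score and the transfer damping scheme are principled choices
behind stable seams, not uniquely determined by the problem; alternative
realizations plug in without touching the benchmarking machinery. The toy
aligner is quadratic per query-candidate pair and meant for fixtures only.
Identifier namespaces are opaque strings throughout; no accession mapping
is attempted.
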