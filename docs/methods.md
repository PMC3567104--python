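# Methods

This note documents the statistical procedures, the defaults and the design
choices behind `idpcmp`, and what the synthetic benchmark does and does not
establish.

## Dataset preparation

Proteomes are read from FASTA; the first header token is the protein id, a
configurable marker (default `(Fragment)`) flags fragments, and a UniProt
`GN=` token fills the optional gene id. Cleaning removes, in order:
duplicates (identical full amino-acid sequence; the first occurrence is
kept), fragments, sequences with non-standard residues (U, O) and sequences
with ambiguity codes (B, X, Z, J) — residues that per-residue disorder
predictors either reject or score unreliably. A record matching several
rules is counted under the first matching rule. "Duplicate" operates on the
sequence level deliberately: it also removes isoform redundancy, and the
filter stays well-defined for inputs without stable accessions. Filtering is
idempotent, order-preserving, and reports exact removal counts per rule.

## Disorder metrics

Score tracks assign each residue a disorder probability in [0, 1]. A residue
is called disordered when its score is **≥** the threshold (inclusive, to
match the ≥ 50% disordered-protein rule; defaults 0.5 for VSL2/IUPred-style
tracks, 0.05 for Disopred-style). Per protein:

| metric | definition | default parameters |
|---|---|---|
| `pct_disordered` | % residues called disordered | threshold 0.5 |
| `n_ldw`, `pct_in_ldw` | maximal disordered runs of ≥ `ldw_min` residues | `ldw_min` 30 |
| `is_disordered_protein` | `pct_disordered` ≥ cutoff (inclusive) | cutoff 50% |
| `n_dbr`, `pct_dbr_residues` | maximal binding-track runs of ≥ `dbr_min_len` | `dbr_min_len` 6 |

The DBR minimum length is exposed rather than fixed because binding-region
predictors differ in their internal segmentation; 6 avoids counting
single-residue noise as a region. Distributions of `pct_disordered` are
binned half-open `[a, b)` with the last bin closed; presets are deciles
`{0,10,…,100}` and the coarse `{0,30,50,100}` split.

Note a deliberate asymmetry among the metrics: lowering the threshold can
only grow `pct_disordered`, `pct_in_ldw` and `pct_dbr_residues`, and every
window called at a stricter threshold is nested in a window at the looser
threshold — but the window *counts* are not monotone, because a looser
threshold can bridge the gap between two windows and merge them.

### Built-in composition predictor

A fallback so the pipeline runs with no external predictor: per residue, a
foldability index `f = 2.785·⟨H⟩ − |⟨R⟩| − 1.151` over a centered window
(default 51, shrinking at the termini rather than padding), with `⟨H⟩` the
mean Kyte–Doolittle hydropathy rescaled to [0, 1] by `(KD + 4.5)/9` and
`⟨R⟩` the mean net charge (K, R = +1; D, E = −1). Charged, non-hydrophobic
stretches give `f < 0`; the reported score is the logistic squash of `−f`,
so `f < 0` maps above 0.5. This is a physics-flavoured baseline in the
charge/hydropathy-plane tradition, not a trained predictor, and it is never
used where real predictor tracks are supplied.

## Ontology handling

OBO parsing recognizes `id`, `name`, `namespace`, `is_a`,
`relationship` (e.g. `part_of`) and `is_obsolete`. Traversal defaults to
`is_a` only — the uncontested subsumption relation — with `part_of`
available by configuration; cross-namespace edges among the traversal
relations are rejected, and cycles and dangling parents are errors.
Annotations (GAF 2.x columns 2 and 5, `NOT` qualifiers dropped, or 2-column
TSV) are cleaned of obsolete terms and then closed under the ancestor
relation, so any two proteins are comparable at whatever level they share
terms. Expansion is idempotent and never removes a valid annotation;
annotations to unknown terms warn-and-drop by default because ontology and
annotation releases are routinely out of sync. The comparative analysis runs
over the *shared terms*: terms annotating at least one protein of each
organism after expansion.

## Cross-species class comparison

For a binary criterion (≥ 50% disordered residues, ≥ 1 LDW, or ≥ 1 DBR) and
each shared GO class, the 2×2 table of disordered vs non-disordered
annotated proteins in the two organisms is tested with Pearson's chi-square
with Yates' continuity correction,

    X² = Σ (|O − E| − c)² / E,   c = min(0.5, |O − E|),

p from χ²(1). Capping `c` at |O − E| (the convention of R's `chisq.test`)
makes the statistic exactly 0 when observed equals expected and prevents
inflation of sub-half-count deviations. A table with a zero marginal is
degenerate: statistic 0, p 1, flagged. Classes pass the directional filter
only when organism A's observed disordered count is ≥ (1 + 0.05) × the
expected count — boundary inclusive; when the expected count is 0 the
convention is to pass iff anything was observed. Benjamini–Hochberg runs
across exactly the classes tested in the call (the family is the set of
hypotheses actually tested), and `significant` means `p_adj ≤ α` *and* the
excess filter passed — so the result list is intentionally one-sided in
favour of organism A.

Quantitative criteria (e.g. `pct_disordered` itself) use a two-sided
Wilcoxon rank-sum test on per-protein values within the class, not on
organism-level pooled values; significance additionally requires the class
mean of organism A to exceed B's.

### Rank-sum p-values

With pooled size ≤ 12 and no ties the permutation null is enumerated exactly
(two-sided p = probability of a rank sum at least as far from its mean).
Otherwise a normal approximation is used: continuity-corrected, with the
standard tie correction to the variance, plus — in the tie-free case — a
second-order Edgeworth term using the closed-form excess kurtosis of the
rank-sum null, γ₂ = −(6/5)(n² + m² + nm + n + m)/(nm(N+1)). The plain
continuity-corrected normal can deviate from exact enumeration by up to
0.0155 at n = m = 6; the Edgeworth term reduces the worst-case gap to about
0.002, so the exact and approximate paths agree closely across their
boundary.

## Single-organism enrichment

The disordered-protein set (default: proteins with ≥ 1 LDW) is tested
against the proteome background per GO term with the one-sided
hypergeometric tail P(X ≥ k), or the EASE variant that removes one study hit
(floored at zero) before taking the tail — more conservative for terms
supported by few proteins. The background universe defaults to annotated
background proteins (chart tools ignore unannotated genes); the full
background is selectable. Results are BH-adjusted and filtered at
p_adj ≤ 0.05 (inclusive) with ≥ 2 study hits per term.

## Ortholog-restricted validation

Annotation depth differs between organisms, so a class can look
differentially disordered through annotation bias alone. For each candidate
class, ortholog pairs are retained when at least one member is annotated to
the class (`either`, the default, maximizes usable pairs; `both` is
stricter), and a disorder metric is averaged over each side. Across classes,
the class-level (mean_A, mean_B) pairs are tested with a paired t-test
(default — the values are naturally matched) or Welch's two-sample t-test;
two-sided for any difference and one-sided for the alternative that organism
A is more disordered. Classes are weighted equally (protein-equal weighting
is available through the `both`/`either` membership and the per-class pair
counts in the output). Classes with zero retained pairs are reported
explicitly and excluded from the tests; at least two usable classes are
required.

## Semantic summarization

Information content uses an explicit reference annotation corpus (by
default the organism-A expanded annotations — never an implicit external
database): p(t) is the annotated-protein count of t over the count of its
namespace root, IC = −ln p. SimRel similarity between two terms is
(2·IC(c)/(IC(t₁)+IC(t₂)))·(1−p(c)) where c is the maximum-IC common
ancestor; terms sharing only the root get 0. Natural log is used — only
ratios and the (1−p) factor matter for ranking.

Clustering is single-linkage at the similarity threshold (default 0.7):
repeatedly merging the most similar pair above threshold yields exactly the
connected components of the sim ≥ threshold graph. This choice is
deterministic, partitions the input, and provably makes the cluster count
monotone in the threshold; the trade-off is that in a chain a member may sit
below the threshold against its representative (the alternative —
leader-style clustering around representatives — guarantees the member-to-
representative bound but loses threshold monotonicity). The representative
is the member with the best (lowest) p-value, ties broken by higher IC and
then lexicographic id. Uniqueness of a term is 1 − its mean similarity to
all other input terms (1.0 for a singleton input). Representatives are
joined into superclusters by the same procedure at a lower threshold
(default 0.5). Treemap graphics are out of scope; outputs are plain TSV.

## Synthetic studies

The generator emulates the full input bundle under a two-state segmental
model. Each protein is drawn from one of two archetypes — mostly-ordered
(geometric run-length means: 70 ordered / 12 disordered residues) or
mostly-disordered (15 / 60) — because i.i.d. per-residue flags essentially
never produce ≥ 30-residue runs, which would make LDW statistics trivial.
Scores are Beta-distributed per state (means 0.15 / 0.80, concentration 12),
binding segments are whole disordered segments switched on with probability
0.35, and sequences draw residues from state-specific compositions with
P, E, S, K, Q enriched in disordered segments so the built-in predictor
responds to the same signal. Defaults: 600 proteins per organism, lengths
80–400, baseline disordered-archetype probability 0.30 per organism, a
60-term single-namespace DAG with ≤ 2 parents per term, non-planted class
sizes 20–60.

Planting acts on the class-conditional probability that a member protein is
disordered: members of each planted class (default 3 leaf terms of 200
members) are sampled from the *realized* disordered/ordered pools at the
configured per-organism rates (default 0.6 vs 0.2), so one truth table
serves all three binary criteria, and an unreachable rate raises a
configuration error rather than silently degrading. Null studies plant
nothing and share one generating distribution between organisms. All
randomness flows through a single integer-seeded generator and no unordered
container affects output order, so identical seeds give byte-identical
serialized studies.

What passing on synthetic data shows — and does not: the benchmark
establishes that the statistical machinery recovers planted class-level
effects at realistic sizes and controls the false-positive rate on nulls; it
does not mimic real predictor error profiles, sequence evolution,
inter-class annotation correlation beyond DAG ancestry, or the heavy-tailed
class-size distribution of real GO corpora.

## Pipeline and determinism

One config drives the end-to-end study; every user-facing parameter is
surfaced with its conventional default (thresholds 0.5/0.05, LDW 30,
disordered-protein cutoff 50%, α 0.05, excess 5%, min count 2). Outputs are
TSV/JSON with fixed float formatting and sorted keys, so identical inputs
and config reproduce byte-identical artifacts; `run_log.json` records
parameter values, library versions and input SHA-256 checksums, while
wall-clock stage timings go to a separate `timings.json`, the single
deliberately non-deterministic artifact. The three-way categorization
(enriched-only / comparison-only / both) partitions the union of the two
term lists by construction.

The acceptance script scales its simulations to desk size — 20 planted
studies of 600 proteins and 50 null studies of 200 proteins — chosen as the
smallest sizes at which the planted effect is overwhelmingly detectable and
the null rate estimate is stable.

## Known limitations

* The chi-square path treats proteins as independent within a class;
  paralog families violate this mildly in real proteomes.
* The EASE/Fisher enrichment reduces chart-style tooling to its statistical
  core; fuzzy clustering of annotation sources is not reproduced.
* SimRel clustering order internals of the original summarization web tool
  are unpublished; the documented greedy here is reproducible but not
  guaranteed to match it term-for-term.
* The built-in predictor is a composition baseline; its absolute disorder
  calls should not be interpreted biologically.
* One-to-many orthology is kept as given in the pair table; no weighting
  scheme is applied.
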