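# Methods

`sgltnet` implements a network-medicine workflow around a single drug
target gene (by default SGLT2 / SLC5A2, the sodium–glucose cotransporter
inhibited by the gliflozin drug class). The workflow has six analysis
stages over five inputs — an interactome, key-term gene sets, a
ligand–target binding table, a gene × tissue expression matrix, and a
disease/pathway annotation library — plus a synthetic-data generator that
emits all five with planted, recoverable structure.

## Network neighborhood

The interactome is an undirected graph over gene symbols with a per-edge
confidence in [0, 1] (a STRING-style combined score). Edges below
`min_confidence` are dropped before anything else; the default cutoff is
0.4, the conventional "medium confidence" STRING threshold, and is
configurable because published analyses rarely state the cutoff they
used. Symmetric duplicate rows merge to the maximum confidence; all
interaction types (physical and functional) are treated alike.

The target's **first-level** interactors are its direct neighbors after
filtering; the **second-level** set is the neighbors-of-neighbors minus
the first level and the target, so the two shells are disjoint by
construction and `1 + |first| + |second| ≤ |V|` with equality exactly
when every node is within two hops of the target. Symbols are compared
case-sensitively after alias mapping: human gene symbols are uppercase by
convention, and silent case-folding hides data errors.

## Path ranking

Paths from a key-term gene set (sources) to the target are ranked by a
super-source construction: a virtual node is attached to every surviving
source by a zero-cost edge and loopless (simple) paths to the target are
enumerated in nondecreasing real-edge count. Hop count is the only cost —
edge confidences are retained for display, never for ranking. Zero-edge
paths are excluded; if the target appears among the sources it is ignored
as a source.

The enumeration is a best-first search over partial simple paths with
priority `(edges_so_far + BFS_distance_to_target, node_sequence)`. The
BFS distance is an exact lower bound, so complete paths leave the
frontier in nondecreasing length; the node sequence breaks length ties
lexicographically. Because a sequence prefix always sorts before its
extensions, this yields a *total*, deterministic order — any equal-length
tie order a GUI tool might produce is unspecified, and a total order is
required for testability. The brute-force oracle (exhaustive simple-path
enumeration, sorted by the same key) is the primary correctness surface
in the tests and is never used as the implementation.

Defaults: `k = 50` paths per term for analysis, top `n = 10` for
reporting. The **last-edge census** tabulates, across terms, which
target-adjacent interaction closes each top-n path — the "which direct
interactor funnels this process into the target" question — sorted by
(number of terms, best rank, edge name).

## Interactor table

One row per gene on any term's top-50 paths (the target excluded). Per
term a gene's status is `both` (in the term's gene set *and* on its
top-50 paths), `proc` (gene set only), `net` (paths only) or `none`.
Genes present in fewer than two top-50 analyses are dropped. The ordering
key is (count of terms with `proc`/`both` desc, `n_top10` desc,
`n_top50` desc, symbol asc): the first two criteria are the published
ones; the last two were added to make the order total, and are the
package's own choice. Genes on paths but outside both shells are labeled
`external` rather than silently folded into level 2.

## Ligand prioritization

Binding records need at least one of Ki (nM) or IC50 (nM); rows with
neither are dropped and counted, censored values (`>x`, `<x`) are dropped
per cell rather than imputed (imputation would manufacture potency).
Replicates of one ligand–gene pair aggregate per measure with the median
(robust to database outliers; `min` and geometric mean are available).
Ki and IC50 form two parallel rankings over ligands with a value toward
the target — ascending, ties alphabetical — and are never merged into one
score, since IC50 is assay-dependent and systematically larger than Ki.
Rankings are therefore invariant under any strictly monotone transform of
one measure. The dual-target report restricts to ligands with IC50 for
both named transporters and orders by potency on the second; the network
scan lists, for every ligand (target binder or not), its profile genes
inside the network with first-level flags.

## Tissue ranking

For each tissue the four columns are: target expression, cotarget
expression, median expression of the *expressed* first-level interactors,
and the count of expressed interactors. "Expressed" means at least 25% of
the tissue's median expression over all genes (zeros included in the
median by default; configurable). Each column is discretized into four
bins — equal-width over [min, max], the OneR package's default binning;
equal-frequency is available — and the composite score is the unweighted
sum of the four labels, the simplest faithful reading of a joint ranking
over four binned columns. Ties break on raw target value, then tissue
name. A constant column gets all label 1 with a warning. Because reports
are inconsistent about mean versus median interactor expression, both are
computed and emitted; the median enters the score. Binning is invariant
under affine transforms of a column, so the ranking is insensitive to the
measurement scale (confidence 0–5 or TPM).

Per-drug tissue impact is the mean expression of the drug's profile genes
in each tissue (absent genes count 0), tissues ordered by impact.

## Enrichment

Overrepresentation uses the one-sided hypergeometric test (Fisher exact,
'greater'): `P[X ≥ k]` for a query of n genes, a term of K genes and a
universe of N, accumulated from log-pmf terms with logsumexp so small
tails stay accurate. The universe defaults to the union of the library's
gene sets and can be set to the interactome node set; proprietary
service-side backgrounds are not reproducible. BH step-up adjustment
(via `statsmodels`) spans exactly the tested terms (overlap ≥ 1), with
significance at adjusted p < 0.05. Odds ratios use the Haldane +0.5
correction when any contingency cell is zero, keeping degenerate tables
finite. Network queries include the target gene itself (the analyzed
network is target + shells, not the shells alone). The ligand-overlap
report crosses significant terms from both network analyses with ligand
profiles, flagging ligands whose within-term hits cover both transporters
of interest.

## Synthetic data

The generator is a pure function of `SyntheticConfig`; identical seeds
give byte-identical files. Defaults — chosen once as a realistic desk-
scale miniature of the real inputs, and not revisited: 250 genes grown by
preferential attachment with m = 2 (the human interactome is heavy-tailed
and every stage here depends on hub structure), 12 first-level
interactors, one planted mediator (named SIRT1 after the deacetylase that
dominates the motivating analysis), 7 key terms × 15 genes, 40 ligands,
12 tissues, edge confidences uniform on [0.15, 0.999] (the STRING score
range). The cotarget (SLC5A1) is planted as a second-level interactor,
reachable through the mediator, mirroring its position in the real
network.

Planted structure and what it guarantees:

* each mediator is a hub (wired to half the background), adjacent to the
  target and to ≥ 80% of every key-term set; key-term sets exclude all
  other direct target neighbors, so every non-mediator source is exactly
  two hops from the target with a mediator route among the shortest, and
  the mediator itself contributes the unique one-hop path — rank 1 in
  every term's ranking by construction;
* the binding table plants a target-specific ligand and a promiscuous
  ligand (target + cotarget + two first-level genes, graded IC50), plus
  valueless, censored-free and duplicated records to exercise the filter
  and the aggregation;
* one tissue is planted high (target and ≥ 90% of first-level interactors
  ≥ 4 of 5), one low (target < 1);
* the annotation library plants one set holding ≥ 60% of the first-level
  interactors and one transport-like set containing both transporters.

No attempt is made to mimic the real interactome's size or a binding
database's ligand counts — those are database-version artifacts. There
is no published null model for any of these inputs; all distributional
choices (uniform confidences, log-normal noise affinities, uniform
expression) are the package's own. Consequently, passing tests show the
*procedure* is correct and recovers known structure; they say nothing
about biological conclusions on real downloads, which depend on database
snapshots.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale: 200 random
graphs of ≤ 10 nodes for the path oracle, exhaustive subset enumeration
up to a 12-gene universe for the hypergeometric oracle, and 50 seeded
250-gene universes for planted-signal recovery — sizes at which the
brute-force oracles are exact and fast. Degenerate inputs are decided,
not left to chance: empty networks and unreadable rows raise with line
numbers, unreachable targets warn and return empty rankings, constant
columns bin to label 1, and an empty query after universe intersection
warns and returns no results.

## Known limitations

* The path ranking permutes equal-length ties relative to any tool whose
  internal tie order differs; only the (length, lexicographic) order is
  guaranteed.
* "Specificity" is reported two ways (potency rank toward the target, and
  breadth of targets) and deliberately never collapsed into one number.
* The pipeline is single-target; multi-target or isoform-aware analyses
  are out of scope, as are live database clients and figure rendering.
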