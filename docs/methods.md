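# Methods

This note documents the models and procedures implemented in `coocnet`, the
parameters that matter, the numerical choices made where the design was open,
and what the synthetic test bed does and does not demonstrate.

## Corpus model

A document is a PMID with title, abstract, author keywords ("Other Term"
fields), MEDLINE MeSH annotations (descriptor/qualifier pairs), and a review
flag. The mined text is the concatenation of title, abstract, and keywords
with single spaces; all text is normalized to Unicode NFC at construction.
The canonical offline input is JSONL (one record per line); MEDLINE citation
XML from efetch is parsed with lxml. A thin live e-utilities adapter exists
for interactive use but is deliberately untested: network responses are not
reproducible inputs.

MeSH annotations are filtered by tree number: categories A (Anatomy),
C (Diseases), D (Chemicals and Drugs), and G (Phenomena and Processes) are
retained, except descriptors whose only qualifying G trees fall under G01
(Physical Phenomena), G02 (Chemical Phenomena), or G17 (Mathematical
Concepts). Both the category letters and the exclusions are arguments with
these defaults. A descriptor/qualifier pair is one entity, rendered
`descriptor/qualifier`; each qualifier of a descriptor therefore yields its
own entity, which matches the query rendering downstream.

## Gene normalization

The normalizer trades recall for precision; every stage can only remove
candidate mentions:

1. **Transliteration.** Greek letters are rewritten to Latin names
   (α→alpha), matching the alias-table convention.
2. **Abbreviation validation.** Parenthetical single-word short forms and
   their definitions are detected with the Schwartz–Hearst character-matching
   rules (long-form window of min(|SF|+5, 2|SF|) words; the short form's
   first character must match at a word start). If the short form matches a
   gene alias, the definition is aligned against every alias of that gene
   with affine-gap Needleman–Wunsch (match +1, mismatch −1, gap open −1 for
   the first gapped position, extension −0.5). The score is divided by the
   longer string's length and clamped at zero; the mention is kept iff the
   best normalized score is ≥ 0.15. The threshold lives on a length-
   normalized scale (sensible choices fall in roughly [0.1, 0.2]); dividing
   by the longer string's length is our convention because it makes
   identical strings score exactly 1. Alignments are computed lower-cased,
   since definitions are free text.
3. **Cell-entity blocking.** A pluggable recognizer (the default is a
   dictionary/regex stub over a bundled cell-name list; any callable
   returning character spans can be registered) blocks all tokens inside
   recognized cell-line/cell-type spans, so "CD8" inside "CD8+ T cell" never
   becomes a gene.
4. **Tokenization.** Tokens are alphanumeric runs joined by hyphens or
   slashes; other punctuation splits. A hyphen/slash token is first tried
   whole against the alias table ("TNF-alpha"); if unmatched it is split
   only when every part is an alias ("Akt/PI3K/mTOR"), otherwise it yields
   nothing ("FcgammaR-TLR Cross-Talk"). Tokens on the English word list are
   discarded before lookup; alias matching is case-sensitive and exact.
   Multiple mentions of a gene in one abstract count once, and every emitted
   symbol records the token(s) that supported it.

An alias recorded under two reference symbols is an error at table load —
disambiguation belongs in the table, not in runtime heuristics.

## Network reconstruction

The multigraph has one parallel edge per (document, entity pair). The edge
null is the soft-configuration ensemble for undirected, unweighted counts:
conditional on the multigraph degree sequence, the observed count of a pair
follows the hypergeometric marginal with capacity Ξ_ij = d_i·d_j out of
Ξ_tot = Σ_{u<v} d_u·d_v, with m draws. We use unit propensities and no
self-capacity; p-values are the exact hypergeometric right tail (scipy), and
the test suite checks them against integer-combinatorics and full
multivariate enumeration oracles to 1e−10. BH correction at 1% FDR is
applied jointly over all observed pairs of an iteration (gene–gene,
gene–MeSH, MeSH–MeSH).

Weights: X̄ is the mean count over pairs observed at least once (the
zero-truncated weight law implies positive support; a switch to all-pairs
averaging exists, `mean_over="all"`). w = Ψ(X, X̄) with Ψ the zero-truncated
Poisson CDF; w̃ = 1 − w. Nodes in single-node Leiden communities
(modularity, resolution 1.0, w-weighted, seeded) are pruned. Each connected
component S gets a representativeness T_S — the fraction of corpus documents
mentioning at least one entity of S — and components with T_S below t
(default 0.01) are excluded from expansion. Node weights are
W = F_b(b)·F_d(d), with unweighted betweenness (the strength d is already
w-weighted) and the ≤-convention ECDF within S, so the maximum scores 1 and
W is never 0.

## Expansion and querying

Maximal cliques of order ≥ 3 (Bron–Kerbosch via networkx, deterministically
ordered) are scored with a network K-function: with node weights p and
mean-centred weights, K(s) = (1/n)·Σ_i p_i Σ_{j≠i} (p_j − p̄)·1[d_ij ≤ s]
over distance thresholds s placed at quantiles of the distinct finite
w̃-shortest-path lengths (25 bins by default), and AUK is the mean of K over
the bins. Per clique, the weights are the membership indicator and the null
permutes the weight vector over all nodes (default 1000 permutations, add-one
p-value); BH at 1% FDR selects cliques. The exact Knet variant is defined
against an exhaustive-permutation oracle in the tests rather than against
any external package.

Communities of the clique-pruned network come from seeded w-weighted Leiden.
Community-connecting graphlets have k nodes (default 4) in exactly two
communities, k−1 edges forming one connected component, and exactly one
crossing edge; structurally each side is a spanning tree of its members.
Enumeration is exhaustive over spanning trees per side but restricted to the
top-q nodes by W per community (default 15) — R = −log(∏W·∏w) favors
high-W nodes, so a generous q preserves the optimum while bounding the
combinatorial space. Routing: per community pair only the minimum-R graphlet
enters the community graph; edges violating the triangle inequality against
any two-hop alternative are dropped; missing pairs are completed by shortest
paths (metric closure); Christofides runs per connected component, and tour
edges are expanded back into their constituent real edges' graphlets.
Attempt a+1 removes the graphlets used by attempts ≤ a; later attempts run
only when earlier ones found no new articles.

Queries render MeSH entities as `"name"[MeSH Terms]`, genes as an OR-group
of all aliases tagged `[Title/Abstract]`, AND-join the k groups, and append
`NOT "review"[Publication Type]`. Double quotes in terms are escaped; a
round-trip parser for this grammar is part of the package and backs the
offline document source, which matches MeSH clauses against exact annotation
names (case-insensitive) and gene clauses by alias substring in the mined
text.

Iteration merging: new PMIDs are unioned with the corpus, everything is
recomputed on the merged corpus, and the previous network's edges are
unioned into the new significant set (with weights recomputed under the
merged statistics). Newly found entities must touch at least K (default 3)
of the previous iteration's communities or they are dropped with their
edges; previously existing nodes are never dropped by this filter. The loop
stops with exactly one code: `input_too_small` (<3 PMIDs), `no_entities`,
`empty_graph`, `no_cliques_or_single_community`, `no_connecting_path`,
`no_new_pmids`, `converged_single_component` (the network and, in full
scope, its gene-only and MeSH-only projections are each one connected
component passing the T_S gate), or `max_iterations` — an eighth code we
added because the loop needs a finite cap (default 10) and a run must always
terminate with a code.

All randomness flows from one root seed through named substreams (edge-test,
leiden, knet, tsp, cmeans, validation), so identical inputs and seeds yield
byte-identical output trees; the writers sort rows and write via
temp-file-then-rename.

## Post hoc analyses

**Q score.** For a reference physical-interaction network N (edge channel
scores combined as 1 − ∏(1−s), pruned below the 90th percentile, isolates
removed) and a co-occurrence gene network G, every gene g in N scores
Q(g) = d(g,N)^{-1} · Σ over ordered pairs (g_i, g_j) of distinct text-mined
genes adjacent to g in N (both ≠ g) of exp(−δ̃_G(g_i,g_j)), with δ̃_G the
w̃-weighted shortest path in G and disconnected pairs contributing nothing.
We read the distinctness indicator transitively (g, g_i, g_j pairwise
distinct, the common-neighbor interpretation); the relaxed two-hop reading
is available behind `strict_distinct=False`. Scores are ECDF-normalized to
decorrelate from degree; the tests verify the decorrelation on random
instances. Pathway enrichment runs Knet on the unweighted reference
distances with per-set weights equal to the normalized Q of member genes
(zero elsewhere), permuting weights over all reference nodes — permuting
within the non-member complement is the plausible alternative; all-node
permutation is the stricter exchangeability null and is what we implement.

**Context-aware gene sets.** Inverse log-weighted similarity
(Σ_z 1/log deg z over common neighbors), distance exp(−sim), column-wise
Z-scoring, Ward linkage with a dynamic tree cut for initial hard clusters,
then fuzzy c-means with fuzzifier m = 2 on the row vectors (optionally
PCA-reduced to the fewest components reaching a cumulative variance v). The
dynamic cut is our reimplementation of the hybrid idea: descend the merge
heights from the root and accept the finest partition in which every cluster
keeps at least `min_cluster_size` (default 3) members; a fixed-height
fallback is provided. Exact parity with the original R implementation is not
claimed. Fuzzy c-means is implemented in ~40 lines of standard alternating
updates (no suitable library is declared as a dependency); memberships are
row-stochastic and the objective is non-increasing, both test-enforced.
ORA is the one-sided hypergeometric tail with BH, with the universe
restricted to the network-derived genes by the caller; set comparisons use
the Szymkiewicz–Simpson overlap coefficient |X∩Y|/min(|X|,|Y|).

**Null-model validation.** Degree sequences qualify for DeltaCon testing
when ∏ d_i! ≥ 10 (at least ten realizations). Randomization proposes double
edge swaps (default 300 proposals, counting proposals rather than accepted
swaps; the alternative reading — 300 accepted swaps — would not terminate on
rigid graphs) and rejects self-loops and parallel edges, preserving the
degree sequence exactly. DeltaCon uses the exact dense inverse
S = (I + ε²D − εA)^{-1}, ε = 1/(1+max degree), the Matusita distance between
affinity matrices, and sim = 1/(1+d); the fast approximation is out of scope
at desk scale. Both the edge-count test (equal-size uniform node sets;
default 10^6 samples, 10^4 in test harnesses) and the DeltaCon permutation
test report add-one empirical p-values with their Monte-Carlo standard
error, and the suite checks super-uniformity of both under their own nulls.

## The synthetic test bed

The generator plants blocks of co-studied entities: each document is
assigned a block, mentions each block member with probability
`within_block_rate` (default 0.6) and every other entity with
`background_rate` (default 0.06 — a 10x contrast), embeds gene mentions as
alias tokens in generated filler text and MeSH entities as annotations.
Identical seeds give byte-identical corpora. Under these defaults (3 blocks
of 6 entities, 200 documents) the reconstruction recovers planted pairs with
~80–95% recall and ~100% precision at 1% FDR depending on the seed; the
acceptance suite pins the fixture seed. Unstructured corpora (singleton
blocks, uniform rate) calibrate the null: ≤2% of pairs pass 1% FDR across
500 seeds.

What the synthetic corpus does *not* emulate: real linguistic variation
(synonyms, misspellings, sentence structure — filler text is drawn from a
fixed common-word list), correlated block membership, long-tailed entity
frequencies, abstract length variation, and annotation noise in MeSH terms.
Passing tests therefore demonstrate the statistical and algorithmic
machinery, not NER performance on real abstracts; the normalizer's behavior
on real text is exercised only through hand-written sentence fixtures.

Pipeline fixtures add explicit "bridge" documents that co-mention entities
of two blocks far above background, which is what makes crossing edges
survive the configuration null; with homogeneous co-occurrence everything is
exactly as expected under the null and nothing is significant — a property,
not a bug, that the tests assert directly.

## Known limitations

- Graphlet enumeration grows quickly in k and q; defaults (k=4, q=15) keep
  desk-scale runs fast, but dense networks with large communities may need a
  smaller q.
- The clique Knet test needs enough permutations for BH at 1% FDR to be
  attainable (with 1000 permutations the floor is ~0.001); small networks
  with few cliques are sensitive to this resolution.
- The offline document source emulates PubMed field semantics only to the
  extent the grammar above covers; live PubMed ranking, synonym expansion,
  and MeSH explosion are not modeled.
- Problem sizes in the test and acceptance harnesses (corpus sizes of
  200–520 documents, 10^4 null samples, 10^2–10^3 permutations) are the
  package's chosen desk-scale defaults for reproducible runs; the library
  accepts larger values everywhere.
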