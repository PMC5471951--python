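# Methods

This note documents the models, algorithms and numerical conventions
behind `acsphylo`, the design choices that were genuinely open, and what
the validation experiments do and do not demonstrate.

## The statistic

For sequences X, Y over a common alphabet and a mismatch budget k ≥ 0,
`LCP_k(X_i, Y_j)` is the longest common prefix of the suffixes `X_i` and
`Y_j` with the first k mismatches forgiven (mismatch positions count
toward the length). It satisfies the recursion: with z the exact LCP,

    |LCP_k| = z                              if either suffix ends at offset z,
              z + 1 + |LCP_{k-1}| of the suffixes advanced past offset z+1
                                             otherwise.

**Boundary rule.** A mismatch is never charged at or past a sequence end:
when either suffix is exhausted the recursion stops and returns the length
so far. The alternative (charging "phantom" mismatches beyond the end)
would inflate match lengths at sequence tails; the rule here keeps
`|LCP_k| ≤ min(remaining lengths)` always.

The per-position match length is `λ_k(i) = max_j |LCP_k(X_i, Y_j)|`, the
similarity is `ACS_k(X,Y) = (1/|X|) Σ_i λ_k(i)`, and the distance is

    Dist_k(X,Y) = 1/2 (ln|Y|/ACS_k(X,Y) + ln|X|/ACS_k(Y,X))
                  − (ln|X|/|X| + ln|Y|/|Y|).

**Logarithm base.** Natural log throughout. The base is a global scale
factor on all distances and cannot change a neighbor-joining topology.

**Negative and infinite values.** `Dist_k` of two identical length-n
sequences is `2 ln n (1/(n+1) − 1/n) < 0`; e.g. n = 4 gives −0.138629.
Negative values are reported raw by default because they carry real rank
information; an opt-in clip-at-zero mode exists for consumers that reject
negatives. A zero similarity (no common symbol at all) maps to an
infinity flag. Self-comparison is never computed — `Dist_k(X,X) ≠ 0`
under the formula — and the matrix diagonal is defined as 0.

## Index

All estimators run on a generalized suffix array over the sentinel-joined
input: suffix array (prefix doubling on numpy lexsorts, O(N log N)),
inverse array, LCP array (Kasai), and a sparse-table RMQ giving O(1)
exact-LCP queries between arbitrary suffixes. Each sequence is terminated
by its own sentinel, all sentinels mutually distinct and ordered below
every residue, so no common prefix crosses a sequence boundary and
sentinel-led (exhausted) suffixes occupy the lowest ranks — which doubles
as the "reserved minimal key" convention below. Internal nodes of the
virtual suffix tree are materialized as lcp-intervals (depth, rank range)
by the classic stack sweep over the LCP array.

Residues are uppercased on ingest; any code point ≥ 33 is a legal symbol
(DNA, protein, ad hoc), `N` matches only `N`. External coordinates are
1-based local offsets.

## Estimators

- **exact** (`exact_lambda_profile`): dynamic program over all (i, j)
  pairs — an exact-LCP table filled bottom-up, then k gather rounds for
  the mismatch recursion. O(|X||Y|k) time; this is the oracle the
  heuristics are validated against, usable up to a few hundred residues.

- **exact seed** (`alpha_assignment`): the best exact-match partner of
  any X-suffix is rank-adjacent among Y-suffixes in the suffix array, so
  one sweep with nearest-preceding/following Y-rank arrays plus two RMQ
  evaluations per position finds `α_i` in O(n). Tie between the two rank
  neighbours goes to the smaller Y offset; when the best value is 0
  (every offset ties) the partner is reported as offset 1. Note the two
  compared candidates are the rank neighbours; an equal-LCP Y-suffix
  further away in rank but with a smaller offset is not considered — the
  seed *value* is exact regardless.

- **greedy 1-mismatch seed** (`beta_assignment`): for every internal node
  at string depth h, members agree on h symbols and may differ at symbol
  h+1; each member is keyed by the rank of its suffix h+1 symbols along
  (members whose extension passes their sequence end keep a reserved
  minimal key so the sort stays total), members are sorted by key (ties:
  origin, then offset), and every X-member is paired with its nearest
  Y-neighbour on each side. Candidate values are true `|LCP_1|` lengths
  (two RMQ rounds); per position the best examined value wins, smallest
  offset on ties. Every node's full member set is processed, as the
  O(nk + nH log n) formulation prescribes — no small-to-large shortcut —
  and processing the node at the lowest common ancestor of `X_i` and its
  optimal partner guarantees the recorded value equals the true
  1-mismatch maximum. The implementation flattens all per-node work into
  segment-tagged numpy passes (one global lexsort, segment-local
  neighbour search by cumulative extrema, batched RMQ), which is what
  makes 5 kb × 5 kb pairs take well under a second.

- **profile extension** (`lambda_profile`): `λ(i) = |LCP_k(X_i,
  Y_seed_i)|`, batched, O(nk).

**k = 0 collapses every estimator to classic ACS.** By definition the
0-mismatch statistic is the longest exact match, so at k = 0 the greedy
path substitutes the exact-LCP seed; extending a 1-mismatch-optimal
partner with budget 0 would undershoot the classic values. All three
estimators are byte-identical at k = 0, and the test suite asserts it.

For k > 1 both heuristics are genuinely heuristic: `λ'_k ≤ λ_k` and
`λ''_k ≤ λ_k` everywhere (asserted over a 200-pair corpus), with equality
for the greedy estimator at k ≤ 1. When several partners tie at the seed
value the recorded partner is the smallest *examined* offset; different
optimal seeds can extend differently at larger k, which is inherent to
seed-and-extend.

## Trees

Neighbor joining is the textbook Saitou–Nei iteration: join the pair
minimizing `Q = (r−2) d(p,q) − Σd(p,·) − Σd(q,·)`, limb lengths by the
split formula, reduction by the average rule, ties broken toward the
lowest (row, column) pair for determinism. Exact (topology and branch
lengths, verified to 1e−9) on additive matrices. Negative limb lengths
are kept by default; an opt-in mode zeroes them and transfers the deficit
to the sister limb, preserving the pair's summed length. The 3-cluster
terminal state becomes the trifurcating root of the nominally unrooted
output.

Robinson-Foulds distance is the unnormalized symmetric-difference count
over nontrivial bipartitions (one per internal edge, canonicalized as the
side not containing the alphabetically first leaf), matching the
PHYLIP-treedist convention in which 0 means exact topological identity.
Branch lengths are ignored. Both NJ and RF are cross-checked against
dendropy in the test suite.

Newick serialization quotes labels containing structural characters and
prints branch lengths at 10 significant digits; the parser reports the
character offset of any failure.

## Simulator

`simulate_random_tree` grows a fully resolved unrooted topology by random
sequential addition (each new taxon attaches to a uniformly chosen edge)
and then draws branch lengths i.i.d. uniform from a configurable range.
`evolve_sequences` draws a uniform root sequence and evolves it down the
tree: on a branch of length b each site independently substitutes with
probability p = 1 − exp(−b·rate), the replacement drawn uniformly from
the other symbols — the Jukes-Cantor mechanism, under which the expected
Hamming fraction across a path is ¾(1 − Π(1 − 4p_e/3)) for a 4-letter
alphabet. The configuration stores the **rate** (default 1.0) rather than
a fixed per-branch probability, because the probability is a function of
branch length; each branch's p is validated to stay below the 4-letter
saturation point 0.75. No insertions or deletions are introduced, so all
leaves share the root length (an optional geometric-indel mode exists for
robustness demonstrations only and is excluded from every validation
experiment). There is a single global rate — no among-site rate
heterogeneity.

**Default study conditions.** The default branch-length range is
U[0.015, 0.05] with rate 1.0: per-branch substitution probabilities of
1.5–5% and, for a 10-taxon family, mean pairwise divergences around 15%
(pairwise identity ~80–90%). This is the moderately diverged,
closely-related regime — think congeneric mitochondrial genomes — that
average-common-substring distances are designed for. At substantially
higher divergence (≳35–40% mean pairwise Hamming) the nonlinearity and
sampling noise of the ACS transform begin to cost short internal edges,
and recovery degrades even though the greedy profile is still exactly the
1-mismatch optimum; that regime is outside the method's intended
envelope, not a defect of the estimator.

**What the simulations do and do not show.** Passing recovery tests show
the estimators order moderately diverged, substitution-only, equal-length,
single-strand sequences correctly. Real genomes add indels (which this
distance systematically overestimates through shortened matches),
rearrangements and reverse-strand homology (not modeled — matches are
single-strand), compositional bias and rate heterogeneity. None of those
are exercised here.

## Validation experiment sizes

The test suite and `scripts/acceptance.py` use: 200 random pairs (lengths
20–200) for seed-exactness and domination checks; 500 random position
pairs × k ∈ {0..3} for LCP_k agreement; 50 random trees (5–12 leaves,
branches U[0.1, 2.0]) for NJ exactness; and 20 replicates of 10-taxon,
5 kb families at the default conditions for end-to-end topology recovery
(greedy k ∈ {1, 2}, plus the exact-seed comparison at k = 1). These sizes
give stable results while keeping a full run around a minute on one CPU.

## Known limitations

- The greedy seed sweep materializes all node-member incidences; its cost
  grows with total suffix-tree depth, so highly repetitive inputs (e.g. a
  single repeated letter) degrade toward quadratic memory/time, exactly
  as the O(nH log n) bound predicts for H ≈ n.
- `Dist_k` is not additive in evolutionary time; NJ on it is a heuristic
  (as for all ACS-family methods), exactness holds only for additive
  inputs.
- The exact estimator is quadratic and intended for validation, not
  production pairs beyond ~1 kb.
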