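# Methods

## The problem and the model

Aligning two protein complexes Q and T requires a one-to-one pairing of their
chains in addition to the residue-level alignment of each paired chain. The
number of possible pairings grows factorially with the chain count, so naive
TM-score maximization over assignments does not scale.

This package exploits a geometric observation: if Q and T are structurally
similar complexes, then for every correctly paired chain couple the rigid
superposition (rotation U, translation T) that maps the target chain onto its
query partner is the *same* transform — the complex-level superposition. A set
of chain-to-chain alignments is therefore mutually compatible, and defines a
complex alignment, exactly when their superpositions (near-)coincide.

The pipeline for one complex pair is:

1. **Chain-to-chain alignment** (`chain_align`). Every query chain is aligned
   against every target chain by a TM-align-style iterative aligner: rigid
   seeds come from gapless fragment threadings (fragment length
   min(L, 20), stride max(1, L/10) on the shorter chain) and from a
   sequence-identity Needleman–Wunsch alignment; each seed alternates Kabsch
   superposition on the current residue pairs, rescoring of all residue pairs
   with 1/(1+(d/d0)²), and Needleman–Wunsch realignment with linear gap
   penalty −0.6 (free end gaps, no extension penalty), until the pair set is
   stable or 30 iterations. The winning seed maximizes the sum of query- and
   target-normalized TM scores evaluated under its final fixed superposition;
   the running best within a seed is tracked, which makes the per-iteration
   score trace non-decreasing by construction. The aligner is deliberately
   the slow, global mode; the clustering core accepts externally supplied
   chain alignments, so a faster aligner can be dropped in.
2. **Superposition vectors** (`superposition_matrix`). Each chain alignment
   contributes a 12-component row (9 rotation entries row-major, 3
   translation components in Å). Columns with coefficient of variation
   s.d./|mean| below 0.1 are excluded as uninformative; for columns with
   |mean| < 1 the raw s.d. replaces the CV (a near-zero denominator would
   make the ratio meaningless). Retained columns are z-scored so rotation
   entries (order 1) and translations (tens of Å) contribute comparably to
   Euclidean distances. The s.d. uses denominator n; the absolute mean is
   used because the columns are signed. Both choices are keyword-exposed.
   If *every* column is excluded, all superpositions are effectively
   identical: the normalized matrix has zero columns, all row distances are
   0, and clustering degenerates to one cluster — the physically correct
   limit.
3. **Clustering** (`cluster_assign`). DBSCAN with minPts = 2 is run over a
   radius grid from the minimum to the maximum pairwise row distance in
   steps of 0.1 (normalized units). After each pass, clusters are checked
   for validity — no query or target chain used twice — and invalid clusters
   are rescued by admitting members in order of distance from the initiating
   core point, stopping (not skipping) at the first chain reuse. The biggest
   valid clusters seen anywhere on the grid are kept, ties included,
   deduplicated by chain-pairing set; finding a strictly bigger cluster
   purges the smaller candidates. Iteration stops early when the maximum
   possible size min(C_Q, C_T) is reached and max(C_Q, C_T) distinct
   candidates exist, or when a pass past the useful radius yields only
   clusters smaller than the current best. Two deliberate design choices:
   the DBSCAN expansion starts from the lowest-index unvisited core point
   rather than a random one (determinism is worth more than fidelity to an
   irrelevant randomization), and every row is pre-seeded as a trivially
   valid size-1 candidate, because a lone chain-to-chain alignment is a
   legal partial assignment yet minPts = 2 clustering can never produce
   singletons (this matters only for comparisons such as one chain against
   many).
4. **Complex TM-score** (`complex_score`). For each candidate, matched query
   chains are concatenated in file order, matched target chains in match
   order, and the per-chain residue pairs are pooled into the concatenated
   frame. The TM-score search seeds superpositions from contiguous fragments
   of the pooled alignment (lengths L_a, L_a/2, L_a/4, stride L_a/10), each
   refined by iterating Kabsch on the pairs closer than max(d0, 4.5 Å) until
   that subset is stable. d0 follows the standard TM-score convention
   d0(L) = 1.24·(L−15)^⅓ − 1.8 for L > 21, else 0.5. Both normalizations
   divide one unnormalized sum by the *total* residue count of the
   normalizing complex (unmatched chains included), evaluated with a single
   pair-level d0 = d0(min(L_Q, L_T)); this makes
   tm_query·L_Q = tm_target·L_T an exact identity, which the test suite
   asserts continuously. The best-scoring valid candidate wins; ties break
   on more aligned residues, then lexicographically smallest pairing.
5. **Search** (`search`). Pair mode, many-vs-many search with a report
   threshold of 0.65 on the reported score (default max of the two
   normalizations; the normalization choice is configurable because the
   field uses several conventions), and clustered-database search:
   representatives are searched first and clusters whose representative
   scores at least the expansion threshold (default 0.3; a TM-based stand-in
   for an E-value criterion, since this aligner produces no E-values) have
   all their members aligned in a second phase. With expansion threshold 0
   this is provably identical to exhaustive search, which the tests verify.
   Monomeric targets are rejected for multimeric queries unless requested.
   An optional pre-screen skips only pairs whose every chain-length ratio
   exceeds 3×, which cannot carry a genuine hit.

## Synthetic data

The fixture generator (`fixtures`) builds complexes from self-avoiding
random-walk Cα traces with consecutive spacing 3.8 ± 0.05 Å, direction
persistence, and a mild centroid pull calibrated so the radius of gyration
stays within a protein-like band around 2.2·L^0.38 Å. A fixture pair consists
of an assembled query and a target that is one global rigid copy with chains
renamed/permuted and Gaussian coordinate noise σ added, so the planted chain
pairing and the planted complex superposition are known exactly. A decoy
variant re-draws each target chain's placement independently: chains still
match one-to-one, but no shared superposition exists, emulating homologous
subunits assembled into a different quaternary arrangement. Default study
conditions used by the tests and the acceptance script: 2–4 chains of 30–60
residues, σ = 0.5 Å, random chain permutations.

What the generator does *not* emulate: real secondary structure and side
chains, internally flexible or partially disordered chains, domain motions,
sequence divergence between matched chains (matched chains are geometric
copies), and crystallographic artifacts (altlocs, gaps, multiple models are
exercised by handcrafted parser fixtures instead). Passing tests therefore
demonstrate the correctness of the assignment-by-superposition-clustering
machinery and the score computations, not robustness to conformational
change, which on real structures is bounded by the quality of the underlying
chain aligner.

## Numerical choices and degenerate inputs

- Kabsch uses the SVD formulation with reflection correction; point sets of
  rank < 2 (collinear) raise a degeneracy error, and fragment seeds that hit
  one are skipped. Validation is against an independently coded quaternion
  (Horn) closed form.
- DBSCAN neighborhoods are inclusive (distance ≤ ε plus a 1e-12 guard so
  grid values generated from distances are not lost to rounding).
- Chains with fewer than 3 Cα atoms are dropped on input (a warning),
  because no superposition is defined for them.
- No RNG anywhere in the alignment/clustering path; all candidate and seed
  orderings are index-based, so two runs are bit-identical.
- Problem sizes in tests and the acceptance script (100 assignment fixtures,
  1,000 Kabsch point sets, 200 DBSCAN clouds, 20 fixtures per noise level,
  100 matched/decoy trials, a 30-complex clustered database) were chosen as
  the smallest sets that exercise every code path with stable statistics.

## Known limitations

- The chain aligner targets correctness of the overall pipeline, not exact
  parity with TM-align; its scores are validated against dense-seeding
  oracles, not against TM-align output.
- Sequence-order-independent (non-sequential) alignment is not supported.
- Nucleic-acid chains and ligands are ignored on input.
- The shared-d0 normalization identity (see step 4) trades a small amount of
  convention fidelity — tools that recompute each normalization with its own
  d0 will differ slightly — for an exact internal consistency invariant.
- Biological assemblies are not generated from symmetry operators; the
  file's explicit chains are the complex.
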