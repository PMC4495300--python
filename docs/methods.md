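# Methods

This note records the model implemented by `slimq`, the defaults that
matter, what the synthetic data emulates, and the places where the design
was genuinely open and a choice had to be made.

## The over-representation model

A motif candidate is an ordered series of defined positions — a fixed
residue or an ambiguity set — separated by wildcard runs of length at most
`W` (default 2), with at most `L` (default 5) defined positions and at
least 2.  Significance is estimated by three chained cumulative binomials:

| score | event                              | k        | n               | p                |
|-------|------------------------------------|----------|-----------------|------------------|
| p1+   | motif occurs in one UPC            | 1+       | sites in UPC    | per-site probability |
| Prob  | observed (or greater) UPC support  | support  | number of UPCs  | mean p1+         |
| Sig   | any motif with Prob this small     | 1+       | motif space M   | Prob             |

The per-site probability is the product over defined positions of the
summed frequencies of allowed residues, estimated from the unmasked
residues of the dataset (wildcards contribute a factor of 1).  `M` is
`20^L (W+1)^(L−1)`, computed independently for each defined length, so no
additional correction is applied across lengths.  The model assumes
independence of sites and of clusters; it is a heuristic and empirically a
slightly conservative one, which is why the default reporting cutoff is
`Sig ≤ 0.1` rather than 0.05.

**Query restriction.**  In query mode the candidate set is exactly the set
of patterns present in the (masked) query region, enumerated per length;
`M` per length becomes the cardinality of that set.  The query's UPC is
excluded from support counting, from the UPC count, from the p1+ list and
from the frequency estimate, so a motif supported by `k` of `n` clusters in
the full dataset is scored as `k−1` of `n−1`.  Patterns present elsewhere
in the dataset but absent from the query are not candidates at all — that
exclusion *is* the motif-space restriction, and it is also why ambiguity
extension is off by default: variants found only outside the query cannot
be merged in without violating the space accounting.

## Parameters and defaults

- `L = 5`, `W = 2`: enumeration limits; `M(4, 2) = 4,320,000`.
- `min_support = 3` UPCs: matches the convention that a motif needs three
  unrelated instances to be discoverable at all.
- `sig_cutoff = 0.1`: see conservatism above.
- Disorder masking: residues with score `< 0.2` are masked, runs of either
  state shorter than 5 residues are smoothed away (see below), masked
  residues are written `X`.  Defined positions may never sit on an `X`;
  wildcards may cross one.
- Relatedness: Smith–Waterman local alignment (BLOSUM62, gap open −11,
  extend −1) with an extreme-value significance estimate
  `E = K m n e^{−λS}` (λ = 0.267, K = 0.041), threshold `E < 1e-4`.
  The constants are calibrated by contract rather than inherited: identical
  or 10%-mutated length-100 sequences must be related, and ≥ 99% of
  independently random length-100 pairs unrelated; both are enforced by
  tests.  A precomputed edge list (e.g. from an external homology search)
  can be supplied instead.
- Ambiguity equivalence groups: `[ILMVF] [FYW] [FYH] [KRH] [DE] [ST]`;
  a merged pattern is kept only when its UPC support strictly exceeds every
  contributing fixed variant's.
- Rating thresholds: a motif match needs ≥ 2 aligned defined positions,
  MatchIC ≥ 1.5 and NormIC ≥ 0.5; off-target calls use MatchIC ≥ 2.5 or
  NormIC ≥ 1.0.  Position information content is `1 − ln(a)/ln(20)` for an
  `a`-residue set, which places the calibration anchors where the
  thresholds expect them: one fixed plus one 3-fold degenerate position
  gives 1.633 and two 2-fold degenerate positions 1.537, both above 1.5.

## Numerical choices

- Binomial tails go through `scipy.special.bdtrc`; tails that underflow it
  (support probabilities can reach 1e-50 in clean simulated data) are
  recovered by a log-space sum of at most 400 terms.
- `1 − (1−p)^n` forms are computed as `−expm1(n·log1p(−p))`.
- Ranking ties on equal Sig break by higher support, then longer pattern,
  then lexicographic pattern, making runs bit-reproducible.
- Mean p1+ is the arithmetic mean.

## Design choices where the procedure was open

- **Run smoothing.**  Masking smooths by flipping the *first* (leftmost)
  run shorter than the minimum region size, recomputing runs, and
  iterating to a fixpoint; a lone full-sequence run is allowed.  The rule
  is deterministic, idempotent, and treats short ordered and short
  disordered runs symmetrically.
- **Window centring.**  For the `winN` strategies the window is
  `[c − N/2 + 1, c + N/2]` with `c = ⌊(start+end)/2⌋`, shifted to the
  terminal N residues when the instance lies within N/2 of a terminus, and
  the whole protein when shorter than N.
- **Sites per UPC.**  For a motif footprint of `s` residues, each member
  sequence contributes `Σ max(0, segment − s + 1)` over its maximal
  unmasked segments, and the cluster's site count is the **maximum** over
  members: homologous members largely duplicate content, and summing would
  inflate the trial count.  The rule is isolated in one function
  (`slimchance.upc_site_count`) for easy replacement.
- **Cloud edges.**  Two result motifs share a cloud when one's defined
  positions form a contiguous, gap-identical, set-compatible slice of the
  other's, or when at least two of their occurrences overlap in the same
  proteins; clouds are connected components.
- **Dataset enumeration.**  Whole-dataset enumeration grows patterns one
  defined position at a time and prunes branches below the support
  threshold.  Because a prefix occurs wherever its extension does, per-UPC
  support never increases with length and the pruned enumeration is
  exactly equivalent to exhaustive enumeration plus filtering (asserted by
  a self-consistency test that recounts every enumerated pattern with the
  independent occurrence matcher).
- **Signal selection after implantation.**  The benchmark generator checks
  pairwise unrelatedness of signal proteins *after* implanting the motif:
  a shared implanted peptide occasionally drags an otherwise-random pair's
  alignment E-value over the relatedness threshold, and selecting on the
  final sequences guarantees each signal protein is its own UPC under the
  same scorer the search uses.

## What the synthetic data does and does not emulate

`generate_proteome` draws independent sequences from a fixed vertebrate-like
residue profile, with lengths uniform on 150–300, alternating
ordered/disordered blocks (10–30 and 20–60 residues; scores below/above the
0.2 threshold), optional mutated families for homology structure, and full
reproducibility from a seed.  Implanted instances are placed uniformly
within disordered blocks.  This matches the independence assumptions of the
statistic, so the specificity measured on it is a clean test of the
arithmetic — real proteomes carry local compositional biases, repeats and
shared domains that make some patterns enriched by chance, and the
false-positive fraction observed here (≈ 6–9% of random 20-protein datasets
at Sig ≤ 0.1) should be read as a floor, not a forecast, for real data.
Likewise the near-perfect recovery of a 5-residue fixed implant from
signal-only datasets shows the bookkeeping and the query trade-off working,
not real-world sensitivity to degenerate motifs in noisy interactomes.

Problem sizes used by the tests and the acceptance script — 50 sensitivity
datasets of 10 signal proteins from 16-protein pools, 100–200 random
20-protein specificity datasets — are the package's chosen desk scale:
large enough for the binomial sampling error on a proportion to be a few
percent, small enough to iterate on quickly.

## Known limitations

- The relatedness scorer is a calibrated stand-in for a full homology
  search; marginal homology (1e-4 ≤ E < 1) is treated as unrelated, and
  profile/iterative search is out of scope.  Use the edge-list hook for
  fidelity to an external search.
- The pattern language has no negated classes (`[^P]`), quantifiers or
  alternation; complex curated definitions enter only through instance
  reduction (`slimmaker`), which is the intended route.
- Conservation masking is accepted only as a precomputed mask/score table;
  no alignment-based masking is computed internally.
- Ambiguity extension merges variants at a single position per pattern;
  multi-position degeneracy arises only through repeated application to
  already-merged patterns, which is not done by default.
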