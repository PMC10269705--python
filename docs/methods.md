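# Methods

This note documents the model behind the synthetic-cohort generator, the
default parameter choices, the numerical conventions used throughout the
package, and known limitations.

## Analysis chain

The analysis treats a cohort of bacterial strains labelled by habitat —
leaf-associated (LA), soil-associated (SA), other-associated (OA) — and asks
whether habitat leaves a recoverable signature in genome structure and gene
content.

**QC.** A strain enters the analysis only if estimated completeness ≥ 95%
and contamination ≤ 5% (both inclusive). Near-identical genomes are then
collapsed: two genomes are redundant when ANI ≥ 99.9% (inclusive) and the
*minimum* of the two directional alignment coverages is strictly greater
than 95%. Redundancy is closed over connected components (chains and
triangles collapse together) and one representative per component is kept,
drawn uniformly with a seeded RNG.

**Distances and clustering.** Strain relatedness is the cophenetic distance
on the strain phylogeny (total branch length along the leaf-to-leaf path).
PAM k-medoids minimizes the total distance of each strain to its cluster
medoid. For small instances (C(n, k) ≤ 10,000 candidate sets) the optimum is
found by exact enumeration; above that the classic Kaufman–Rousseeuw
BUILD + best-improvement SWAP heuristic is used. Exact enumeration exists
because single-swap local search provably misses the optimum on some
instances (observed at n = 11, k = 2 where both medoids must move at once).
k is chosen by scanning k = 2..k_max and maximizing the mean silhouette
coefficient s(i) = (b−a)/max(a,b) (singleton clusters contribute 0;
silhouette is undefined at k = 1 and k = n). Feature-profile clustering uses
complete-linkage agglomeration on Euclidean distances between per-Mb
profiles.

**Pan-genome.** A family is *core* if present (count ≥ 1) in every strain;
*unit-specific* if non-core and confined to exactly one taxon × habitat
unit; *accessory* otherwise. The classes are exclusive and exhaustive by
construction. Matched subsampling builds equal-sized habitat panels: the
reference habitat contributes all (or a seeded random subset of) its
strains; every other habitat is ranked by |mean distance to the reference
panel − grand mean| and the least deviant strains are taken, so outliers are
excluded first.

**Profiles.** Protein families are assigned by best hit under
Needleman–Wunsch global alignment with match +1, mismatch 0, gap −1.
Identity is matches / alignment columns, *including* gap columns; the
unknown residue X aligns but never matches. A query is kept only if its best
identity is strictly greater than 40%. Best-hit ties resolve to the longer
alignment, then the lexicographically smaller reference id. Traceback ties
resolve diagonal > up > left, so the reported alignment is deterministic.

**Statistics.** Two-sided pooled t tests and one-way ANOVA come from scipy;
degenerate zero-variance inputs are special-cased (equal means → statistic
0, p = 1; unequal → infinite statistic, smallest positive p). PERMANOVA is
implemented directly: SS_total = Σd²/(2n), within-group SS analogously per
group, pseudo-F = ((SS_total − SS_within)/(k−1)) / (SS_within/(n−k)), and
the permutation p-value uses the add-one convention
p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm), so the smallest attainable p at
999 permutations is 0.001. Phylogenetic PCA uses the Brownian-motion
covariance C_ij = shared root-to-MRCA branch length, GLS centering
a = (1ᵀC⁻¹X)/(1ᵀC⁻¹1), eigen-decomposition of XcᵀC⁻¹Xc/(n−1); on a star
tree it reduces exactly to ordinary PCA. Significance stars: **** p ≤ 1e-4,
*** ≤ 1e-3, ** ≤ 1e-2, * ≤ 0.05, else ns. The enrichment scan reports raw
p-values as primary and appends a Benjamini–Hochberg column; untestable
cells (group n < 2, or an all-zero feature) are marked, not dropped.

## Synthetic-cohort generator

The generator plants exactly the structures the analysis is meant to
recover; every draw is seeded and the truth is recorded.

* **Phylogeny.** Each habitat gets its own pure-birth (Yule) subtree with
  unit birth rate, simulated with event times so trees are clocklike
  (ultrametric within a clade). Subtrees are joined by branches of length
  `clade_separation` (default 10.0), making habitats monophyletic and well
  separated at assortativity 1. With assortativity a, each leaf keeps its
  clade's habitat with probability a; the remaining leaves have their labels
  shuffled among themselves, so group sizes are always preserved and a = 0
  is a uniform permutation.
* **Genomes.** Sizes are habitat-specific normals truncated at 0.5 Mb; GC is
  truncated to (20, 80)%. Defaults: size means 4.67 / 6.08 / 5.97 Mb and GC
  means 63.27 / 57.12 / 56.95% for LA / SA / OA, cohort sizes 195 / 283 / 95
  (total 573). No published dispersions exist for these, so the SDs are
  choices: size SD 0.8 / 1.2 / 1.5 Mb (soil and other habitats are more
  heterogeneous than the leaf niche) and GC SD 4.0 percentage points (wide
  enough that habitat GC ranges overlap, as real genera do). Completeness is
  U(96, 100) and contamination U(0, 3), i.e. simulated genomes pass the QC
  gate; QC rejection paths are tested with hand-built records.
* **Orthogroups.** Exactly `n_core` core families (the first
  min(14, n_core) single-copy everywhere, the rest forced multi-copy
  somewhere), `n_specific` families confined to one unit, `n_accessory`
  families spanning ≥ 2 units but absent from ≥ 1 strain. Default counts
  163 / 378 / 212 are the observed partition scaled to desk size (core kept
  at 163 so the single-copy sub-structure is realistic). Columns are
  shuffled so class is not recoverable from position.
* **Features.** Per-strain class counts are Poisson with mean
  rate_per_Mb × genome size. The default rates (GH 12–18/Mb, GT 10–14/Mb,
  smaller rates for AA/CBM/CE/PL and the BGC classes, soil richest) were
  chosen so per-genome CAZyme totals fall in the observed 82–417 range and
  soil > other > leaf, the contrast the tests must detect.
* **Redundancy.** `n_redundant_pairs` disjoint pairs get ANI in
  [99.9, 100.0) with coverages in (95.5, 99.5); decoy pairs deliberately
  fail exactly one rule.
* **Seeding.** A root seed expands to per-stage seeds via
  sha256("seed:stage") → first 4 bytes mod 2³¹, so any stage can be rerun
  alone with the stream it saw in a full run, and all seeds stay below 2³¹.

### Generator scope

The generator targets the statistical behaviour of the pipeline, not
biology: no sequences are simulated for genomes (only metadata and count
matrices), orthogroup contents are exchangeable given their class, ANI
values are drawn directly rather than computed from sequence, and protein
queries are substitution-only mutants of reference sequences (no indels), so
their global identity to the source is controllable to ≈ 2 percentage
points.

## Numerical conventions

* Printed percentages use **round half-up** to two decimals (0.275 → 0.28),
  not banker's rounding. Note 37,784/59,187 = 63.8384…% is reported as
  63.84 under this rule.
* Concordance percentages use **all strains** as the denominator.
* PAM ties (equal objectives/gains) break lexicographically by strain id;
  the RNG seed in the signature is never consulted because ids are unique.
* select_k ties go to the smaller k; k_max is clipped to n−1 with a warning.
* Cluster numbering: 1..k by sorted medoid label (PAM) or first appearance
  (hierarchical); medoids always belong to their own cluster.
* Majority-habitat ties in concordance go to the lexicographically smaller
  habitat name.
* The t/ANOVA/PERMANOVA degenerate cases are defined (not NaN) as described
  above.

## Problem sizes and runtime

The full default cohort (573 strains) simulates in < 1 s; select_k over
k = 2..20 on its cophenetic matrix takes ≈ 1.5 s; PERMANOVA with 999
permutations at n = 573 takes a few seconds. The test suite runs in ≈ 15 s
on one CPU.

## Limitations

* PAM above the exact-search limit is a local search: the objective is
  non-increasing and swap-optimal but not guaranteed globally optimal.
* Needleman–Wunsch is O(|a|·|b|) per pair with a Python inner loop — fine
  for the default 80-residue references, not for proteome-scale screens.
* The PERMANOVA permutation p is exact only in distribution; two runs agree
  only for equal seeds and n_perm.
* Phylogenetic PCA requires a non-singular Brownian covariance; duplicated
  tips at zero distance raise with advice to jitter branch lengths.
* The alignment identity reported under co-optimal alignments is the one
  selected by the deterministic traceback; other co-optimal alignments can
  carry different identities.
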