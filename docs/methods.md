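# Methods

## The distance model and its assumptions

The metric assumes that pMHC recognition is driven by short, contiguous
stretches of CDR loop residues, and that what matters about those stretches
is their physicochemistry rather than their exact sequence. Each loop is
therefore reduced to its set of 4-residue windows encoded as 4×5 Atchley
factor matrices, and two loops are scored by the **best-matching** window
pair (minimum Manhattan distance over all n × m pairs). Taking a minimum
means the metric rewards one shared motif and ignores the rest of the loop;
two receptors are at distance zero whenever every active loop pair shares at
least one identical admissible window, even if the loops differ elsewhere.
This is intentional — it is what lets receptor pairs with single CDR3
substitutions outside the matching window collapse to distance 0 — but it
also means the triangle inequality does **not** hold, and nothing in the
package or its tests assumes it does. Symmetry, non-negativity and
d(t, t) = 0 do hold and are property-tested.

Window admissibility per variant:

- sequence variants (`cdr3b`, `6cdrs`): all consecutive windows; for CDR3
  the first 4 and last 3 residues are dropped first (the germline-encoded
  anchors rarely touch the peptide). CDR1/CDR2 are used whole — trimming is
  a CDR3 rule only. The CDR3β-only variant applies the same trim; a
  `trim_cdr3=False` flag switches to whole-loop windows for users who want
  the untrimmed behaviour.
- `3d`: residues whose nSESA strictly exceeds the loop threshold (5% for
  CDR1/2, 20% for CDR3) are retained in order and windows are taken over
  the retained string, so a window may span residues that are not
  consecutive in sequence. Strict `>` is used for both loop classes; the
  boundary value (exactly 5.0/20.0) is excluded. This is one consistent
  reading of two conflicting inequality phrasings in circulation; the
  choice only matters for residues sitting exactly on a threshold.

### Normalization

Two nested normalizations are applied, chosen to reconcile the requirement
that per-window scores live on a fixed [0, 1] scale with the repertoire-level
rescaling by the largest observed distance:

1. **Per-comparison**: every minimum window distance is divided by the
   largest Manhattan distance attainable between two windows of that length
   (k × 15.871, the maximal per-position factor-difference sum over the
   20×20 residue alphabet, precomputed from the bundled table). Loop scores
   are therefore in [0, 1] before weighting, and so are weighted TCR scores.
2. **Per-repertoire**: pairwise TCR distances are divided by the largest
   value in the set. The normalization constant is reported alongside the
   matrix; if all raw distances are zero the constant is reported as 0 and
   the normalized matrix is all-zero rather than NaN. Distances normalized
   within different repertoires are not directly comparable; cross-set
   screening (deorphanization) therefore computes one combined matrix over
   queries + references so a single constant applies.

### Degenerate inputs and fallbacks

Loops shorter than the admissibility rules allow are handled
deterministically and flagged: if trimming or exposure filtering leaves
fewer than 4 residues, the whole loop is used instead (`fallback=True` on
the window set); if the loop itself has fewer than 4 residues, windows of
the loop's own length are used, and when two loops carry different window
lengths both are re-windowed at the shorter length, with the normalization
constant scaled to that length. Empty loops and non-standard residue
letters (X, \*, lowercase) are hard errors at parse time — the factor table
covers exactly the 20 standard amino acids and no substitution rule is
assumed; affected rows go to the repertoire's rejection report rather than
being silently dropped.

## Parameters

| parameter | default | meaning |
|---|---|---|
| loop weights | 0.1 (CDR1/2), 0.3 (CDR3), renormalized over active loops | published optimum for clustering quality |
| nSESA thresholds | 5% (CDR1/2), 20% (CDR3), strict `>` | published optimum for the 3D variant |
| window length | 4 | fixed by the metric definition |
| call threshold | 0.15 (strict `<`) | normalized distance below which a nearest-neighbour specificity call is made |
| EF top-n | 10 | neighbourhood size for the enrichment factor |
| AUC splits | 6 × 30% reference fraction | per-peptide cross-validation scheme |
| permutations B | ≥ 100 enforced | p = (1 + #{null ≤ obs}) / (B + 1), lower-is-better statistics |
| SASA probe | 1.4 Å, 960 sphere points | Shrake–Rupley parameters |

## Clustering statistics

UPGMA (average linkage) is computed on the normalized distances via scipy;
the tree is ultrametric with node heights at half the merge distance, so the
patristic (branch-length) distance between two leaves equals their
cophenetic merge distance — the Newick export and the pMHC-distance
statistic agree by construction, and both are cross-checked in the tests
against a hand-rolled textbook UPGMA and an independent Newick parser.

Leaf order is pinned: at every internal node the subtree containing the
smallest original input index comes first. Colour changes are counted
**circularly** (wrap-around included), matching how the trees are drawn;
the count depends on the leaf-order convention, while the pMHC-distance
depends only on cophenetic distances and is convention-free. The
pMHC-distance averages, with equal weight per peptide, the mean cophenetic
distance over all leaf pairs sharing that peptide; singleton peptides are
excluded (they carry no pairing information).

The permutation null shuffles the condensed distance vector itself — not
the labels — and re-clusters, which matches the published randomization
scheme; label shuffling is available as `permute="labels"` for sensitivity
analysis. The +1-corrected p-value never returns exactly zero.

## Specificity prediction

Leave-one-out top-k recovery reports both the success fraction and the
fraction of queries evaluated (when a distance threshold gates evaluation,
those queries whose nearest neighbour is below it). The per-peptide AUC
scores every non-reference receptor by minus its distance to the nearest
held-out reference of the peptide (30% of the peptide's receptors per
split, 6 splits) and computes the ROC with the peptide's remaining
receptors as positives; peptides with fewer than 20 receptors require an
explicit override, and splits leaving fewer than 2 positives are skipped
with a warning. The nearest-neighbour ROC construction is one of several
defensible readings of a pooled-classifier curve; the package pins the
per-peptide reference-split scheme and exposes its pieces (rankings,
scores) so alternatives can be assembled.

Deorphanization calls are emitted only when the nearest labelled neighbour
sits strictly below the call threshold; orphans above it are reported as
no-calls, never dropped. Each call carries the supporting reference, the
enrichment factor of the predicted specificity in the query's top-10, and,
when a distance→share-probability curve is supplied, the empirical
probability band at the call distance.

## Solvent accessibility

Surface areas are computed with the Shrake–Rupley rolling-probe algorithm
(probe 1.4 Å) rather than a molecular-surface (solvent-excluded) method;
reference areas are the published theoretical Gly-X-Gly maxima (Tien et
al. 2013), bundled as a plain table. Both choices make absolute nSESA
values tolerance-comparable, not bit-identical, to profiles computed with
molecular-surface packages; the tests therefore check inter-algorithm
agreement on constructed structures (an independent Shrake–Rupley
implementation from a second library, 20% relative band) and exact limits
only where geometry forces them (a fully caged residue → 0%; an isolated
residue exceeds its reference area and clips to 100%). Exposure masks are
monotone non-increasing in the threshold, which is property-tested. One
conformation per receptor is assumed; structure prediction is out of scope
— users supply structures or precomputed profiles.

## Synthetic data: what it does and does not emulate

The generator produces specificity groups by drawing a seed receptor
(random CDR3s with conserved C…F anchors, germline CDR1/2 from a V-gene
pool) and deriving members by a fixed number of interior CDR3 point
substitutions per chain, plus unrelated singletons. Defaults — 8 groups ×
5 receptors, 2 substitutions, 10 singletons, CDR3 lengths 12–16 — give
within-group distances well below between-group distances while keeping
singletons unpairable, mimicking the difficulty profile of real annotated
sets (which also contain singletons and high within-specificity sequence
variability). It does **not** emulate V(D)J junctional biases, indels,
shared public clonotypes across groups, or realistic amino-acid usage;
passing tests on synthetic data therefore demonstrate that the machinery
recovers planted physicochemical cluster structure, not that real
repertoires cluster this well. Exposure profiles are drawn per residue
(buried with probability 0.3, values clearly below/above threshold), so
3D-variant tests exercise the filtering logic, not structural realism.

The bundled V-gene → CDR1/CDR2 table is a synthetic stand-in with
plausible IMGT-style loops (see the data file header); analyses that
depend on germline loop identity across records are unaffected by its
accuracy, but production users should supply an authoritative IMGT-derived
table via `read_vgene_lookup`. Its boundary convention is IMGT positions
27–38 / 56–65 with gaps removed, documented rather than asserted.

## Problem sizes

The test suite and acceptance script run on repertoires of 14–100
receptors, permutation nulls of B = 199–999, and 20-seed sweeps for the
stochastic properties; these sizes give sub-second matrices and stable
Monte-Carlo bands while exercising every code path. The printed-pair
checks are exact and independent of size.

## Known limitations

- Dataset-dependent final normalization: distances from different
  repertoires live on different scales unless computed jointly.
- The minimum-over-windows construction ignores everything outside the
  best-matching 4-mer and breaks the triangle inequality.
- Fixed window length 4 under-uses long CDR3 loops.
- Absolute 3D-variant values depend on the surface algorithm and the
  structures supplied; only tolerance-based comparisons are meaningful.
- αβ receptors only; γδ chains and non-standard residues are rejected.
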