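# tcrpcdist

Physicochemical distances between αβ T-cell receptors (TCRs), for repertoire
clustering and antigen-specificity prediction.

A TCR recognizes a peptide presented by an MHC molecule (pMHC) mainly through
its six complementarity-determining loops — CDR1/2/3 on each chain. Receptors
with similar loop physicochemistry tend to bind the same pMHC, so a good
distance between receptors lets you (i) cluster a repertoire into putative
specificity groups and (ii) *deorphanize* a receptor of unknown specificity by
transferring the label of its nearest well-characterized neighbour. This
package implements such a distance together with the clustering-quality
statistics, permutation tests and nearest-neighbour prediction machinery
needed to use it.

## The metric

Each CDR loop is decomposed into sliding windows of 4 residues (4-mers). A
window is encoded as a 4×5 matrix of Atchley factors — five published numeric
factors per amino acid summarizing polarity/hydrophobicity (H), secondary
structure propensity (SS), size/mass (SM), codon degeneracy (CD) and charge
(ES). Two windows are compared by the Manhattan distance between their
matrices:

    d(M1, M2) = Σ_{i=1..4} |H1,i − H2,i| + |SS1,i − SS2,i| + |SM1,i − SM2,i|
                          + |CD1,i − CD2,i| + |ES1,i − ES2,i|

The distance between two corresponding loops is the **minimum** of d over all
n × m window pairs, normalized by the largest value any window pair of that
length could attain, so every per-loop score lies in [0, 1]. The distance
between two TCRs is the weighted sum over loops (10% per CDR1/CDR2, 30% per
CDR3 by default), and pairwise distances across a repertoire are finally
rescaled by the largest observed value.

Three variants control which residues form windows:

| variant | loops used  | window residues |
|---------|-------------|-----------------|
| `cdr3b` | CDR3β only  | consecutive, first 4 / last 3 residues trimmed |
| `6cdrs` | all six     | CDR1/2 whole; CDR3 trimmed as above |
| `3d`    | all six     | solvent-exposed residues only (nSESA > 5% for CDR1/2, > 20% for CDR3), windows over the retained residues in order — not necessarily consecutive in sequence |

Per-residue exposure (nSESA) is the residue's solvent-accessible surface area
in the receptor structure divided by its area in an extended Gly-X-Gly
tripeptide, in percent. Profiles can be supplied as TSV files or computed
from a PDB-format structure with a Shrake–Rupley rolling-probe calculation.

On top of the distance matrix the package provides UPGMA dendrograms, two
tree-quality statistics (circular colour changes and the pMHC-distance — the
mean cophenetic distance between leaves sharing a peptide, averaged with
equal peptide weights), distance-permutation nulls, leave-one-out top-k
specificity recovery, enrichment factors, distance→share-probability curves,
cross-validated per-peptide AUCs, and threshold-gated deorphanization calls.

## Worked example

```python
import tcrpcdist as t

rep = t.generate_repertoire(t.GeneratorConfig(
    n_specificities=3, tcrs_per_specificity=(4, 4), n_singletons=2, seed=42))
mat = t.pairwise_matrix(rep, variant="6cdrs")
tree = t.upgma(mat)
labels = rep.labels()

print("colour changes:", t.colour_changes(tree, labels))
overall, table = t.pmhc_distance(tree, labels)
print("pmhc-distance:", round(overall, 4))
res = t.permutation_null(mat, labels, "pmhc_distance", B=999, seed=42)
print("null mean:", round(res.null_mean, 3), "p:", round(res.p_value, 5))
```

prints

```
colour changes: 5
pmhc-distance: 0.0865
null mean: 0.634 p: 0.001
```

The synthetic repertoire contains 3 specificity groups of 4 receptors plus 2
singletons, i.e. 5 distinct labels: 5 colour changes is a perfect circular
grouping. The observed pMHC-distance (0.087) is far below the mean of 999
distance-permuted re-clusterings (0.634); p = 0.001 is the smallest value
attainable at B = 999 with the +1-corrected estimator.

The same pipeline is available from the shell:

```bash
tcrpcdist simulate --seed 42 --out rep.tsv
tcrpcdist distance --repertoire rep.tsv --variant 6cdrs --out matrix.tsv
tcrpcdist cluster --matrix matrix.tsv --labels labels.tsv \
    --out tree.nwk --report metrics.tsv --permutations 999 --seed 42
tcrpcdist predict --orphans orphans.tsv --references refs.tsv \
    --threshold 0.15 --out calls.tsv
```

## Layout

- `src/tcrpcdist/core.py` — Atchley table, window extraction, the metric
- `src/tcrpcdist/io.py` — repertoire/nSESA/matrix/Newick I/O, V-gene lookup
- `src/tcrpcdist/accessibility.py` — nSESA from structures, exposure masks
- `src/tcrpcdist/clustering.py` — UPGMA, tree statistics, permutation nulls
- `src/tcrpcdist/specificity.py` — rankings, top-k, EF, AUC, deorphanization
- `src/tcrpcdist/synthetic.py` — repertoire generator and printed fixtures
- `src/tcrpcdist/cli.py` — `tcrpcdist` subcommands
- `docs/methods.md` — model assumptions, parameter choices, limitations
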