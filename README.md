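# pathdens

Cluster-free, pathway-centric analysis of single-cell and spatial
transcriptomics data.

Conventional single-cell workflows cluster cells first and interpret
pathways second, which ties every biological conclusion to an arbitrary
clustering resolution. `pathdens` inverts that order. It co-embeds
**cells and genes into one low-dimensional space** by multiple
correspondence analysis (MCA) of fuzzy-coded expression, where a gene
sits near the cells that express it specifically. In that space it
answers four questions for any gene set *G*:

1. **Is G coordinated?** Compare the kernel density of *G*'s genes at
   grid points with the density of all genes via
   D_KL(P‖Q) = Σ P log(P/Q), and score it against size-matched random
   gene sets: z = (log D_KL − mean log D_KL,null)/sd, upper-tail normal
   p, BH-adjusted across sets. Coordinated sets occupy a compact region
   of the embedding — no clustering involved.
2. **Which cells is G active in?** Random walk with restart
   h ← (1−r)Th + rs on a cell–gene kNN graph, seeded at *G*'s genes
   (r = 0.75), yields a per-cell **pathway activity level (PAL)**,
   normalized to sum 1 over cells; cells split into positive/negative
   at the antimode of the PAL distribution.
3. **Is G spatially organized?** With per-cell coordinates, compare the
   PAL-weighted 2-D kernel density against the uniform-weight
   background with **delta-KLD** = log D_KL(P‖Q) − mean log D_KL(P_r‖Q)
   under label shuffling.
4. **Which cluster is G specific to?** Cluster-wise specificity
   CWS(L, G) = 1 − √JSD(I_L, W_G) ∈ [0, 1] against any provided
   labeling.

A synthetic-data module generates scRNA-seq with planted marker
programs at graded specificity (4× / 2.5× / 1.5× fold) and dropout
(65 / 78 / 90% zeros), the marker/random mixture sets used for
sensitivity benchmarking, and spatial datasets with hotspot / streak /
gradient patterns; an evaluation module implements the recovery-AUC and
cell-typing-accuracy (ACC) metrics for any PAL scorer. See
`docs/methods.md` for the full model description.

## Worked example

```python
import numpy as np
from pathdens import (
    simulate_scrnaseq, run_mca, test_coordination, build_graph,
    compute_pal, binarize_pal, GeneSetCollection,
)

# 3 cell types x 120 cells, 400 genes, 65% zeros, planted markers
ds = simulate_scrnaseq(n_types=3, cells_per_type=120, n_genes=400,
                       markers_per_type=25, target_sparsity=0.65, seed=1)
emb = run_mca(ds.expression, n_dims=20)

sets = GeneSetCollection({
    "planted": ds.marker_sets["type0.strong"],
    "random": list(np.random.default_rng(0).choice(emb.gene_ids, 25, False)),
})
for r in test_coordination(emb, sets, seed=1):
    print(f"{r.set_name:8s} kld={r.kld:.3f} z={r.z:+.2f} fdr={r.fdr:.2e}")

graph = build_graph(emb, k=100)
pal = compute_pal(graph, ds.marker_sets["type0.strong"], set_name="planted")
labels = binarize_pal(pal)
own = np.asarray(ds.true_labels) == "type0"
print(f"positives={labels.labels.sum()} "
      f"recall_of_type0={labels.labels[own].mean():.3f}")
```

Output:

```
planted  kld=0.008 z=+6.21 fdr=5.14e-10
random   kld=0.001 z=+0.02 fdr=4.94e-01
positives=92 recall_of_type0=0.750
```

The planted marker set is strongly coordinated (z ≈ +6, fdr ≈ 5e-10)
while the size-matched random set is indistinguishable from the null
(z ≈ 0); the antimode split labels 92 cells positive, 90 of them from
the planted type (precision 0.98, recall 0.75 of the 120 true type-0
cells).

The same operations are available from a shell:

```sh
pathdens embed --input matrix.mtx --format mtx --dims 20 --out emb.tsv
pathdens --seed 1 test-coordination --embedding emb.tsv --gmt sets.gmt --out coord.tsv
pathdens score --embedding emb.tsv --gmt sets.gmt --out pal.tsv
pathdens --seed 1 spatial --pal pal.tsv --coords coords.csv --out spatial.tsv
pathdens specificity --pal pal.tsv --clusters clusters.csv --out cws.tsv
```

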