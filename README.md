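# mvcpm — multiview clustering of multi-omics data by a penalty model

Patients profiled with several omics layers (gene expression, DNA
methylation, miRNA expression, ...) rarely partition into the same subtypes
in every layer.  `mvcpm` clusters such multiview data while allowing the
views to carry *consistent and differential* cluster patterns: each view
keeps its own labelling, and the views are softly coupled so that shared
structure is reinforced rather than imposed.

## The model

Each view m is a patient–patient similarity network with adjacency A_m and
combinatorial Laplacian L_m = D_m − A_m.  With one spectral embedding
X_m ∈ R^{N×K} per view, the method minimises the coupled trace objective

```
min  Tr(Xᵀ L X)    s.t.  XmᵀXm = I_K for every view m,
```

where X stacks the X_m and L couples the per-view Laplacians through
off-diagonal −β·I blocks:

```
L = blockdiag(L_1, …, L_M) − β · (ones-off-diagonal ⊗ I_N).
```

The first part is per-view spectral clustering; the coupling term
−β Σ_{m≠h} Tr(XmᵀXh) rewards agreement between the embeddings, which also
aligns their cluster labels so a single k-means on the N·M stacked rows
yields labels that are directly comparable across views.

The orthogonality constraints are handled with a smooth exact-penalty
method rather than manifold retractions: the solver takes plain gradient
steps of the augmented Lagrangian, using the closed-form symmetric
multiplier δ(X_m) = ψ(G_mᵀX_m), a Frobenius-ball safeguard of radius
1.04·√K, and alternating Barzilai–Borwein stepsizes.  The final blocks are
polished to exact orthonormality by a polar decomposition.

For raw omics matrices the package also provides the standard front end:
per-feature standardisation, a Gaussian similarity kernel with bandwidth
equal to the standard deviation of all pairwise sample distances, and
symmetric k-nearest-neighbour sparsification (default k = 5).

## Worked example

Three stochastic-block-model views over the same 150 nodes with different
cluster sizes per view — (50,50,50), (30,90,30), (40,60,50) — and the
noisiest connection-probability matrix P4:

```python
import scipy.sparse as sp
from mvcpm import (SBMConfig, SolverConfig, connection_probability_matrix,
                   generate_multiview_sbm, rand_index)
from mvcpm.evaluation import run_pipeline

cfg = SBMConfig(
    n_views=3,
    cluster_sizes_per_view=((50, 50, 50), (30, 90, 30), (40, 60, 50)),
    prob_matrix=connection_probability_matrix("P4", 150),
    prob_scale_n=150,
    seed=0,
)
graphs = generate_multiview_sbm(cfg)
result, x, state = run_pipeline(
    [sp.csr_matrix(a) for a in graphs.adjacencies], n_clusters=3,
    beta_couple=1.0, solver=SolverConfig(seed=0),
)
print("converged:", state.converged, "in", state.n_iter, "iterations")
print("pre-polish feasibility: %.2e" % state.pre_polar_feasibility)
for m in range(3):
    print("view", m, "Rand:",
          round(rand_index(result.per_view_labels[m], graphs.labels[m])[0], 4))
```

prints

```
converged: True in 200 iterations
pre-polish feasibility: 2.16e-07
view 0 Rand: 0.9734
view 1 Rand: 0.9896
view 2 Rand: 0.9911
```

The solver meets its gradient tolerance with the orthogonality residual
already at 2·10⁻⁷ before polishing, and each view's labels agree with that
view's ground-truth partition on 97–99% of node pairs, even though the
three ground truths differ from each other.

## Command line

```
mvcpm simulate -c configs/table1.yaml   # SBM replication study -> TSV table
mvcpm cluster  -c cluster.yaml          # omics matrices -> labels.tsv
mvcpm evaluate -c eval.yaml             # silhouettes + optional log-rank p
```

All commands are driven by YAML configs and a single master seed; every
defaulted decision is echoed into `run_metadata.json` next to the outputs.

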