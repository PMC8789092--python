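# helixcycle

Cell-cycle pseudotime estimation for single-cell RNA-seq, for anyone who
needs continuous cell-cycle timing and discrete G1/S/G2M stage calls from an
expression matrix without marker-gene annotations — and for anyone who then
wants to remove the cell-cycle effect from downstream analysis.

## The model

The cell cycle is a circular process: a cell's transcriptome loops through
G1 → S → G2/M and back. `helixcycle` embeds the genes × cells matrix
X ∈ R^{D×N} into three dimensions through an orthonormal basis W
(Z = WᵀX, WᵀW = I) and requires the embedded cells to lie near a circular
helix

    Ẑᵢ = (v·θᵢ, a·sin θᵢ, a·cos θᵢ),    a, v > 0,

two coordinates for the cycle, one axis for progression. A soft-clustering
term keeps cells of the same phase together. The full objective

    Σᵢ ‖Xᵢ − WZᵢ‖² + λ Σᵢ ‖Zᵢ − Ẑᵢ‖²
      + γ [ Σₖ Σᵢ r_{ik} ‖Zᵢ − Yₖ‖² + σ Σᵢₖ r_{ik} log r_{ik} ]

is minimized by alternating closed-form updates: softmax responsibilities,
weighted-mean centroids, a symmetric positive-definite solve for Z, an
orthogonal-Procrustes SVD for W, and block coordinate descent for the helix
(a, v, θ). Pseudotime is min–max-normalized θ; stages come from a
3-component Gaussian mixture on pseudotime, ordered G1 < S < G2M along the
axis. See `docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
import helixcycle as hx

# a synthetic cycling population with known phases: 200 genes x 150 cells
ds = hx.simulate_cycle(n_genes=200, n_cells=150, noise_sd=0.1, seed=1)

m = hx.filter_genes(hx.normalize_log2(ds.matrix))
state = hx.fit(m, hx.ModelConfig(seed=1))
print(state.n_iter, state.converged)        # 172 True

pt = hx.extract_pseudotime(state.helix)
stages = hx.assign_stages(pt, seed=1)
report = hx.classification_metrics(np.array(stages.labels),
                                   np.array(ds.true_phase))
print({k: round(v, 3) for k, v in report.as_dict().items()})
```

prints

```
{'accuracy': 0.967, 'macro_precision': 0.959, 'macro_recall': 0.973,
 'macro_fscore': 0.965, 'rand_index': 0.955, 'adjusted_rand_index': 0.902,
 'nmi': 0.879}
```

i.e. 96.7% of cells land in their true phase after optimally matching the
unsupervised stage labels to the generating ones (Hungarian assignment), and
the partition agrees with the truth well beyond chance (ARI 0.90). The
fitted angles reproduce the generating cell order exactly here (|Spearman|
= 1.00 between fitted and true θ).

The same pipeline from the shell:

```sh
helixcycle simulate --mode cycle --n-genes 200 --n-cells 150 --seed 1 \
    --out-prefix sim
helixcycle fit --input sim.mtx --format mtx --seed 1 --out-prefix run
helixcycle stages --pseudotime run.pseudotime.tsv --seed 1 --out stages.tsv
```

Every subcommand writes a JSON manifest (parameters, seed, input checksums,
version) sufficient to re-run it exactly. To remove the cell-cycle effect,
`helixcycle remove-cycle` drops genes whose log-expression variance is
explained by the inferred stages above a threshold (per-gene one-way
SS_between/SS_total).

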