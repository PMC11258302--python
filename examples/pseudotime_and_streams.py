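"""Cell-level pseudotime and velocity streams from per-gene fits.

Simulates a differentiation-like process (shared latent time on an arc, so
there are genuine start and end states), fits the genes, combines their
velocities into a transition matrix, detects root/end cells, computes
velocity pseudotime and selects stream genes.  Prints the agreement between
the inferred pseudotime and the simulator's hidden time.
"""

from scipy import stats

from velotf import pipeline, synthetic

bench = synthetic.generate_benchmark(n_genes=12, n_cells=300, noise_sd=0.1,
                                     seed=31, time_range=(0.05, 0.8))
fits = pipeline.fit_all_genes(bench.dataset, bench.priors, seed=31)
out = pipeline.compute_pseudotime(bench.dataset, fits)

res = out["result"]
rho = stats.spearmanr(res.pseudotime, bench.times).statistic
print(f"genes fitted                 : {len(fits)}")
print(f"root cells (earliest states) : {[int(c) for c in res.root_cells]}")
print(f"end cells (latest states)    : {[int(c) for c in res.end_cells]}")
print(f"spearman(pseudotime, t_true) : {rho:.3f}  "
      "(1.0 = perfect ordering of the hidden process)")
print(f"stream genes selected        : {len(out['stream_genes'])} "
      "(low loss and latent time aligned with pseudotime)")
print(f"embedding arrows shape       : {out['arrows'].shape} "
      "(per-cell flow on the 2D embedding)")
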