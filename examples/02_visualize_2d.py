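"""Project cells to 2D by KL-divergence neighbour embedding.

Compresses a 3-group simulation and trains the projection network; prints
the KL divergence before and after training (lower = the 2D neighbourhoods
match the latent-space neighbourhoods better) and the silhouette of the true
groups in the 2D plane (higher = better visual separation).
"""
from sklearn.metrics import silhouette_score

from schae import SimulationSpec, compress, fit_embedding, preprocess, simulate_counts

spec = SimulationSpec(n_cells=500, n_genes=2000, n_groups=3, dropout_target=0.3, seed=2)
matrix, truth = simulate_counts(spec)
z, _model = compress(preprocess(matrix), seed=2)

emb = fit_embedding(z, epochs=100, seed=2)
print(f"KL divergence: {emb.kl_history[0]:.3f} -> {emb.final_kl:.3f}")
print(f"silhouette of true groups in 2D: {silhouette_score(emb.coords, truth.labels):.3f}")
print("first three cells:", [tuple(round(c, 2) for c in row) for row in emb.coords[:3]])
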