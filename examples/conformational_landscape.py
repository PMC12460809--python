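"""Resolve discrete conformational states in a protomer ensemble.

Generates a synthetic ensemble of 30 D1 protomers planted in five
conformational clusters (hinge steps of 6 degrees, 0.3 A coordinate noise),
runs the landscape pipeline — per-subdomain superposition, Calpha
coordinate PCA, HDBSCAN — and compares the recovered clustering with the
ground truth.
"""

from sklearn.metrics import adjusted_rand_score

from ringscape import EnsembleSpec, analyze_landscape, generate_ensemble

ensemble = generate_ensemble(EnsembleSpec(seed=0))
matrix, landscape = analyze_landscape(
    ensemble.protomers, ensemble.domains, variance_target=0.99, min_cluster_size=3
)

n_clusters = len(set(landscape.cluster_labels)) - (1 if -1 in landscape.cluster_labels else 0)
ari = adjusted_rand_score(ensemble.truth["cluster"], landscape.cluster_labels)

print(f"protomers analysed:        {matrix.C.shape[0]}")
print(f"shared residues:           {matrix.C.shape[1]}")
print(f"components for 99% var:    {landscape.k}")
print(f"clusters found (noise=-1): {n_clusters}")
print(f"adjusted Rand index:       {ari:.3f}")
# An ARI of 1.0 means the density clustering in the latent space recovered
# the planted conformational states exactly; the PCA dimensionality shows
# how many coordinate modes carry 99% of the standardized variance.
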