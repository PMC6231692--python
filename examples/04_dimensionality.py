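"""How many model units / principal components carry the similarity?

Subsamples fixed percentages of a layer's differential units and truncates
the layer to its top principal components, tracking in both cases the
Spearman correlation with the neural RDM. Flat curves mean the similarity is
carried redundantly by many units and few dimensions.
"""

from shapersa import (build_shape_set, compute_rdm, make_geometry_profile,
                      pca_similarity_curve, pixel_features, simulate_layer_stack,
                      simulate_neurons, subsample_similarity)

shape_set = build_shape_set(seed=11)
pix = pixel_features(shape_set.images(), shape_set.ids())
profile = make_geometry_profile(shape_set.ids(), seed=7)
dataset = simulate_neurons(shape_set.ids(), profile, n_units=119, seed=5)
neural_rdm = compute_rdm(dataset.to_activation_matrix())

layer = simulate_layer_stack(pix, profile.target_rdm, 1, [800], [0.9],
                             redundancy=4, seed=3)[0]

curve = subsample_similarity(layer, neural_rdm, [0.5, 2.0, 10.0, 100.0],
                             n_samples=1000, seed=6)
print("unit subsampling (median rho [2.5-97.5% range]):")
for f, k, med, lo, hi in zip(curve.fractions, curve.unit_counts,
                             curve.median_rho, curve.lo_rho, curve.hi_rho):
    print(f"  {f:5.1f}% = {k:3d} units   rho {med:5.3f} [{lo:5.3f}, {hi:5.3f}]")

pca = pca_similarity_curve(layer, neural_rdm, max_k=10)
print("\nPCA truncation:")
for k, rho, ev in zip(pca.k_values, pca.rho_per_k,
                      pca.cumulative_explained_variance):
    print(f"  k={k:2d}   rho {rho:5.3f}   cumulative variance {ev:5.1%}")

print("\nIf a few percent of units, or a handful of components, already "
      "reach the full-population rho, the shape representation is "
      "low-dimensional and highly redundant across units.")
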