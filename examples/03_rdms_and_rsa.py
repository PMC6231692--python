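"""Layer-wise representational similarity analysis with bootstrap statistics.

Builds a surrogate "trained" layer stack whose geometry ramps from pixel-like
to the neural target, and an "untrained" stack locked to pixel geometry.
For each layer, the Spearman correlation between the neural RDM and the layer
RDM is computed with a 95% CI from 10,000-style unit bootstrap (reduced here),
a paired trained-vs-untrained test with BH-FDR, and the Spearman-Brown
split-half noise ceiling of the neural data.
"""

import numpy as np

from shapersa import (bootstrap_rsa, build_shape_set, compute_rdm, fdr_correct,
                      make_geometry_profile, paired_bootstrap_test,
                      pixel_features, simulate_layer_stack, simulate_neurons,
                      split_half_ceiling)

shape_set = build_shape_set(seed=11)
pix = pixel_features(shape_set.images(), shape_set.ids())
profile = make_geometry_profile(shape_set.ids(), seed=7)
dataset = simulate_neurons(shape_set.ids(), profile, n_units=119, seed=5)

n_layers = 6
mixing = list(np.linspace(0, 1, n_layers))
trained = simulate_layer_stack(pix, profile.target_rdm, n_layers,
                               [300] * n_layers, mixing, redundancy=2, seed=3)
untrained = simulate_layer_stack(pix, profile.target_rdm, n_layers,
                                 [300] * n_layers, [0.0] * n_layers,
                                 redundancy=2, seed=3)
rdms = [compute_rdm(l) for l in trained + untrained]

results = bootstrap_rsa(dataset, rdms, n_boot=1000, seed=9)
res_tr, res_un = results[:n_layers], results[n_layers:]
pvals = [paired_bootstrap_test(a, b).p for a, b in zip(res_tr, res_un)]
sig, qvals = fdr_correct(pvals, q_level=0.05)
ceiling = split_half_ceiling(dataset, n_splits=1000, seed=4)

print("layer  trained rho [95% CI]      untrained rho   q(tr>un)")
for k in range(n_layers):
    star = "*" if sig[k] else " "
    print(f"  {k + 1}    {res_tr[k].rho:5.3f} [{res_tr[k].ci_low:5.3f}, "
          f"{res_tr[k].ci_high:5.3f}]   {res_un[k].rho:6.3f}        "
          f"{qvals[k]:.4f}{star}")
print(f"\nnoise ceiling (split-half, Spearman-Brown): median "
      f"{ceiling.median:.3f} [{ceiling.lo:.3f}, {ceiling.hi:.3f}]")
print("\nThe trained curve rises toward the ceiling as layer geometry "
      "approaches the neural target; the untrained (pixel-locked) stack "
      "stays flat — the signature separating representation learning from "
      "architecture alone.")
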