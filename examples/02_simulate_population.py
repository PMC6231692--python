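"""Simulate a stimulus-selective neural population and check recovery.

A target dissimilarity template with the neural group structure (largest
response modulation for Regular pairs, then the curved-vs-straight contrast)
is embedded into unit tuning curves; spike counts are Poisson in a 250-ms
window with 5-15 trials per stimulus. The population RDM should rank-match
the template, degrading as trial noise grows.
"""

from shapersa import (compute_rdm, make_geometry_profile, screen_selective_units,
                      simulate_neurons)
from shapersa.rsa import spearman_uppertri
from shapersa.stimuli import GROUPS, stimulus_id

ids = [stimulus_id(g, j, m) for g in GROUPS for j in range(1, 9) for m in "ab"]
profile = make_geometry_profile(ids, seed=7)

for noise in (0.0, 1.0, 2.0):
    ds = simulate_neurons(ids, profile, n_units=119, noise_scale=noise, seed=5)
    ds = screen_selective_units(ds, alpha=0.05)
    rho = spearman_uppertri(compute_rdm(ds.to_activation_matrix()),
                            profile.target_rdm)
    print(f"noise_scale {noise:3.1f}: {ds.n_units:3d}/119 units selective "
          f"(ANOVA p<0.05), population-vs-template Spearman rho = {rho:.3f}")

print("\nrho near 1 at zero noise shows the generator embeds the intended "
      "geometry; the decline with noise is the trial-noise attenuation that "
      "the split-half noise ceiling quantifies.")
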