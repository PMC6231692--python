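# Methods

This note records the models, conventions and design choices behind
`shapersa`, in the order of the analysis graph.

## Stimulus synthesis

**Contour family.** Irregular shapes are radial Fourier boundary descriptors
about the centroid, r(θ) = r₀ + Σₖ aₖ cos(fₖθ + φₖ), sampled at uniform θ
into a closed polyline (default 512 vertices). This is the simplest family
that guarantees closed, star-shaped contours with independent phase /
frequency / amplitude knobs for pair perturbations. Descriptors must keep
r(θ) > 0 and yield a simple polygon (checked with shapely); violations are
rejected with a diagnostic rather than repaired.

Irregular Simple Curved (ISC) descriptors draw 3–5 harmonics with
frequencies 2–6 and amplitudes ∝ r₀/f. Irregular Complex (IC) contours add
4 harmonics up to frequency 12 with amplitudes ≈ 0.5·r₀/f (halved up to six
times if positivity fails). Irregular Simple Straight (ISS) contours replace
the curves of an ISC-family contour with chords through its curvature
extrema: discrete curvature (turn angle / local arc length) is smoothed with
a short circular window and isolated extrema are kept with a prominence
threshold of 5% of the curvature span. A constant-curvature contour (circle)
has no isolated extrema and cannot be straightened; an already-straight
contour is returned unchanged, making the operation idempotent.

**Pair construction.** The b-member of an irregular pair perturbs exactly
one descriptor field class (phase shifts of ±magnitude·U(0.5,1) rad;
amplitude scalings 1 ± magnitude·U(0.5,1); or an integer frequency step).
ISS members are straightened ISC-family contours from the same column:
ISS_a = straighten(ISC_a), while ISS_b straightens a perturbation of ISC_a's
descriptor with the ISS group's own magnitude. Giving ISS its own magnitude
is what lets pixel balancing adjust each group independently; with equal
magnitudes and seeds, ISS_b coincides with straighten(ISC_b).

**Regular catalog.** Eight pairs with a vertical symmetry axis; members
differ in exactly one NAP: rectangle vs isosceles trapezoid (parallel vs
non-parallel sides; skew = 0.4·magnitude, capped at 0.8) and regular n-gons
(n = 3–8) vs the same n-gon with outward sine-arched edges (straight vs
curved contour; bulge = 0.22·magnitude, capped at 0.45).

**Matching and rendering.** Within a column, all 8 contours are rescaled
anisotropically to the column's target polygon area (9–13% of canvas², so
shapes span roughly 60% of the canvas) and axis-aligned bounding-box aspect
ratio (0.8–1.25). The native frame is used for the bounding box rather than
a principal-axis frame: the catalog shapes are built in canonical
orientation, and principal axes are numerically unstable for near-isotropic
shapes (a square has degenerate axes). Rendering is binary scan-fill
(skimage), no anti-aliasing, fill 255 on background 128, origin top-left,
row-major; `scale_factor` scales the contour linearly before rasterization,
so 0.5 realizes the half-size condition with foreground area ≈ 0.25×.

**Pixel balancing.** The mean within-pair pixel distance per group is
equalized by a derivative-free multiplicative update: each group's
perturbation magnitude is scaled by (grand mean / group mean)^0.5 and the
set regenerated with the same seed, until every group mean is within the
tolerance (default 10%) of the grand mean. Convergence typically takes 2–3
iterations; non-convergence raises an error carrying the best imbalance.

## Synthetic neural populations

Unit rates follow r_i(s) = b_i + g·(w_i · x_s) with x_s the classical-MDS
embedding of the target RDM (rescaled to unit mean squared norm), baselines
b_i ~ U(0.6,1.4)·20 spikes/s, modulation scale g = 20 spikes/s, and a rate
floor of 0.5 spikes/s. Loading rows w_i are **whitened Gaussian**: W is
Gaussian but multiplied by (WᵀW)^(−1/2), so WᵀW ∝ I exactly. Units remain
heterogeneous in gain and tuning direction — which is what gives the unit
bootstrap its meaning — while the full population's squared distances are
exactly proportional to the template's, so recovery at zero noise
(ρ ≈ 0.997 at 200 units) is limited only by spike-count quantization.
Strictly positive loadings were considered and rejected: their common mean
adds a rank-one metric distortion (E[wwᵀ] = σ²I + μ²11ᵀ) that corrupts the
embedded geometry regardless of population size.

Trial counts live in a 250-ms window (rates are trial-mean counts × 4).
`noise_scale` = 1 gives exact Poisson counts; 0 gives deterministic rounded
counts; other values use a rounded, clipped Gaussian with variance
noise_scale² · λ — a variance-scaled Poisson surrogate that keeps counts
integer and non-negative. Trials per stimulus default to U{5..15}
(minimum 5, median 10). The selectivity screen is a one-way ANOVA across
the 64 stimuli on trial responses (α = 0.05); a unit with zero variance has
an undefined F and is excluded.

**Geometry templates.** `make_geometry_profile` places the 64 stimuli in a
12-dimensional latent space: one anchor per column, group offsets, and
within-pair displacements whose magnitudes are the per-contrast gains. The
curved-to-straight (NAP) offset is shared, slightly jittered, between the a
and b members, so both cross contrasts sit near the `ISCvsISS` gain while
the ISS within-pair distance tracks the ISC one (the nominal `ISS` gain is
recorded but realized only approximately). Neural defaults
(R 1.0 > ISCvsISS 0.85 > IC/ISC/ISS ≈ 0.4) follow the neural ordering;
`DEFAULT_HUMAN_GAINS` (ISCvsISS 1.15 > R 0.75) the human one. Because the
template is built from coordinates it is exactly Euclidean, so the MDS
embedding in the simulator recovers it without distortion.

**Sorting data** are binomial: for each unordered pair, the number of
subjects (default 23) separating the two stimuli is one draw at the pair's
separation probability; defaults set within-pair probabilities to
R 0.55, IC 0.35, ISC/ISS 0.30, curved-vs-straight 0.85, all other pairs
0.92, reproducing the human profile ordering.

**Layer stacks.** Layer ℓ units are random linear mixtures of a
pixel-geometry basis and a target-geometry basis (both unit-RMS-distance MDS
embeddings) weighted (1−m_ℓ, m_ℓ), with m non-decreasing; distinct units are
replicated `redundancy` times with small Gaussian noise (σ = 0.02),
emulating convolutional redundancy. When the number of distinct units
reaches the basis dimension the mixing frame is a scaled random orthonormal
basis, making the layer geometry essentially exact; below that it is plain
Gaussian. An all-zero schedule yields the "untrained" pixel-locked stack;
`random_projection_layer` (rectified Gaussian projections of the pixel
vectors) models an untrained first layer, whose RDM correlates with the
pixel RDM at r ≈ 0.99 on a default shape set.

## RDMs and statistics

Both metrics use average ranks for ties (relevant for rectified, sparse
activations); 1 − Spearman on a constant vector raises rather than returning
a sentinel — `filter_differential_units` (strict SD > 0, double precision)
exists to pre-filter. Upper triangles are row-major (i < j sorted by i then
j) everywhere, which is what makes second-order correlations well defined.
Percentile normalization (average rank × 100/count over off-diagonal
entries) is display-only and flagged as such.

The unit bootstrap resamples N units with replacement (N = population size);
the normalized-Euclidean path is vectorized as multiplicity-weighted sums of
per-unit squared differences, so 10,000 replicates of a 119 × 64 dataset
take seconds. All model RDMs in one call share the replicate set; results
carry a replicate key, and the paired test refuses inputs from different
keys. The paired p is two-sided percentile-of-zero, 2·min(P(d≤0), P(d≥0)),
floored at 2/n_boot and capped at 1. FDR is Benjamini–Hochberg step-up
(statsmodels) within one family — all layers of one network per comparison.
Degenerate replicates or splits (constant vector under 1 − Spearman) are
redrawn, keeping replicate counts exact. Split halves are ⌊N/2⌋ / ⌈N/2⌉
without replacement, each used once per split.

**Known limitation — percentile intervals at high ρ.** The percentile
unit-bootstrap of a rank correlation is attenuated: duplicated units add
count-multiplicity noise, shifting the bootstrap distribution below the
full-sample ρ by about the same amount as finite-N sampling keeps the
full-sample ρ below its large-N limit. The effect is multiplicative in ρ:
negligible below ρ ≈ 0.4 (reference coverage ≥ 95% in our calibration runs),
noticeable by ρ ≈ 0.7, and severe above ρ ≈ 0.9, where the interval no
longer covers the large-N value. Calibration checks therefore operate in
the moderate-correlation regime; CIs quoted for very high correlations
should be read as precision, not accuracy, statements.

## Dimensionality

Percent-to-count uses round-half-up with a floor of one unit
(0.1% of 3,136 units → 3). Subsets are drawn without replacement — a
"percentage of units" is a subset, not a resample — and fraction 100%
degenerates to the full population with zero spread. PCA centers per unit
across stimuli (the convention under which Euclidean distances are
rotation-invariant, since per-unit means cancel in every pairwise
difference) and keeps the source layer's unit count as the distance divisor,
so full rank reproduces the full-unit RDM to 1e−8 — the module's master
identity. No per-unit variance normalization is applied (raw covariance);
this is flagged for sensitivity analysis. Explained variance is cumulative
over the centered spectrum and reaches 1 at full rank.

## Group contrasts

Profiles take the a–b distance per column for each group and the column-wise
ISC–ISS distances for the a and b members (6 × 8 table; SEM = sd/√8).
Human sorting profiles have 5 entries; a model profile is collapsed by
averaging its two cross contrasts for that comparison. The
curved-vs-straight test forms d_j = mean(ISCa-vs-ISSa_j, ISCb-vs-ISSb_j) − R_j
per column and runs an exact two-sided Wilcoxon signed-rank by full
enumeration of the 2⁸ sign assignments; zeros are dropped (all-zero input
gives p = 1), ties get average ranks with enumeration kept exact, and with 8
untied non-zero differences the achievable p-values are multiples of 1/256.
Two-sided is the default because it is conservative; a one-sided alternative
is available via the `alternative` argument.

## Pipeline and reproducibility

`AnalysisConfig` is strictly validated (unknown keys rejected); its SHA-256
hash, the master seed and the package version stamp every artifact. Each
stage draws from a child stream derived from the master seed by a fixed
offset, so a single seed reproduces all tabular outputs byte-identically.
"Trained vs untrained" is realized as the geometry-ramped stack vs the
all-pixel stack, preserving the paired-test structure; the size comparison
regenerates stimuli per scale factor and shares the neural replicate set
across every (layer, scale) cell. Defaults match the full-replicate regime
(n_boot = n_splits = 10,000); tests and the acceptance script run reduced
replicate counts (150–2,000) chosen so the whole suite completes in a few
minutes, with the statistical contracts unchanged.

## What the synthetic data does and does not show

The generators emulate the *statistical structure* the analyses assume:
group-structured modulation with realistic trial counts and Poisson noise,
a layer hierarchy whose geometry interpolates between pixel-like and
abstract, subject-count sorting dissimilarities, and pixel-balanced stimuli.
They do not emulate the original shape parameters (unpublished), actual
network feature maps (activation matrices can be imported via CSV/HDF5
instead), spike-train temporal structure, inter-neuron noise correlations,
or individual differences between sorting subjects. Passing tests therefore
certify that the pipeline measures programmed geometry correctly and
calibrates its statistics at realistic sampling regimes — not that any
particular biological system behaves like the generators.
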