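"""Synthetic stand-ins for the three response sources the analyses compare.

No recordings or pretrained network weights ship with this package, so every
downstream stage is exercised on generated data with the statistical structure
the analyses assume:

* a **neural population** of stimulus-selective units whose expected
  dissimilarity geometry rank-matches a target RDM, with Poisson-like trial
  noise at realistic trial counts (minimum 5, median 10 presentations);
* a **layer stack** whose geometry interpolates from pixel-like (shallow) to
  an abstract target geometry (deep), standing in for a trained network's
  layer hierarchy; an all-pixel stack stands in for an untrained network;
* **human sorting dissimilarities**: per stimulus pair, the number of subjects
  (default 23) who placed the two stimuli in different groups, drawn
  binomially from configurable separation probabilities.

All generators are pure functions of their inputs and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import f_oneway

from .features import ActivationMatrix
from .rdm import RDM, compute_rdm, upper_triangle
from .stimuli import GROUPS, ShapeSet, stimulus_id

RESPONSE_WINDOW_S = 0.25  # spike-count window; rates are counts / window
RATE_FLOOR = 0.5  # spikes/s, avoids silent units


# ---------------------------------------------------------------------------
# domain types


@dataclass
class NeuralDataset:
    """Trial-level spike counts with per-stimulus trial numbers.

    ``trial_counts`` is (units, stimuli, max_trials); entries beyond a
    stimulus's trial count are zero and masked by ``n_trials_per_stimulus``.
    ``mean_rates`` are trial-mean counts converted to spikes/s.
    """

    trial_counts: np.ndarray
    n_trials_per_stimulus: np.ndarray
    stimulus_ids: list[str]
    selectivity_flags: np.ndarray | None = None

    def __post_init__(self):
        self.trial_counts = np.asarray(self.trial_counts)
        self.n_trials_per_stimulus = np.asarray(self.n_trials_per_stimulus, dtype=int)
        if self.trial_counts.ndim != 3:
            raise ValueError("trial_counts must be (units, stimuli, max_trials)")
        if np.any(self.trial_counts < 0):
            raise ValueError("spike counts must be non-negative")
        if np.any(self.n_trials_per_stimulus < 1):
            raise ValueError("every stimulus needs at least one trial")

    @property
    def n_units(self) -> int:
        return self.trial_counts.shape[0]

    @property
    def n_stimuli(self) -> int:
        return self.trial_counts.shape[1]

    @property
    def mean_rates(self) -> np.ndarray:
        """unit x stimulus firing rates in spikes/s (trial means / window)."""
        mask = np.arange(self.trial_counts.shape[2])[None, :] < self.n_trials_per_stimulus[:, None]
        sums = (self.trial_counts * mask[None, :, :]).sum(axis=2)
        return sums / self.n_trials_per_stimulus[None, :] / RESPONSE_WINDOW_S

    def to_activation_matrix(self, source_tag: str = "neurons") -> ActivationMatrix:
        return ActivationMatrix(self.mean_rates, list(self.stimulus_ids), source_tag)


@dataclass
class GeometryProfile:
    """Target dissimilarity template plus the per-contrast gains that shaped it."""

    target_rdm: RDM
    group_gain: dict = field(default_factory=dict)


@dataclass
class HumanDissimilarity:
    """Stimulus x stimulus count of subjects separating the two stimuli."""

    counts: np.ndarray
    n_subjects: int
    stimulus_ids: list[str]

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        c = self.counts
        if not np.array_equal(c, c.T) or np.any(np.diag(c) != 0):
            raise ValueError("counts must be symmetric with zero diagonal")
        if np.any(c < 0) or np.any(c > self.n_subjects):
            raise ValueError("counts must lie in [0, n_subjects]")

    def to_rdm(self) -> RDM:
        return RDM(self.counts.astype(float), "normalized_euclidean", list(self.stimulus_ids))


# ---------------------------------------------------------------------------
# geometry templates


def _pair_layout(shape_set_or_ids) -> list[str]:
    if isinstance(shape_set_or_ids, ShapeSet):
        return shape_set_or_ids.ids()
    return list(shape_set_or_ids)


DEFAULT_NEURAL_GAINS = {"R": 1.0, "IC": 0.45, "ISC": 0.40, "ISS": 0.42, "ISCvsISS": 0.85}
# Human-judgment ordering: the curved-vs-straight contrast dominates the
# Regular-pair modulation (the reverse of the neural ordering).
DEFAULT_HUMAN_GAINS = {"R": 0.75, "IC": 0.45, "ISC": 0.40, "ISS": 0.40, "ISCvsISS": 1.15}
# Human profile: curved-vs-straight separation dominates, regular next.
DEFAULT_HUMAN_PROBS = {"R": 0.55, "IC": 0.35, "ISC": 0.30, "ISS": 0.30,
                       "ISCvsISS": 0.85, "between": 0.92}


def make_geometry_profile(shape_set_or_ids, group_gain: dict | None = None,
                          between_scale: float = 2.0, latent_dim: int = 12,
                          seed: int = 0) -> GeometryProfile:
    """Latent-space construction of a target RDM with the neural group structure.

    Each column gets an anchor in a latent space; within-pair displacements
    have magnitude proportional to the group's gain, and the ISC->ISS
    displacement sets the curved-vs-straight cross distances. Distances
    between latent points form the (exactly Euclidean) target RDM, so a
    population embedded from it can recover the template.

    Default gains follow the neural ordering: Regular-pair modulation largest,
    curved-vs-straight next, within-irregular-group modulation smallest.
    The ISS within-pair distance is inherited from the ISC displacement plus
    the jitter of the shared curved-to-straight offset, so gains["ISS"] is
    realized only approximately (recorded for reference).
    """
    ids = _pair_layout(shape_set_or_ids)
    gains = dict(DEFAULT_NEURAL_GAINS if group_gain is None else group_gain)
    rng = np.random.default_rng(seed)
    coords = {}

    def unit_vec():
        v = rng.normal(size=latent_dim)
        return v / np.linalg.norm(v)

    for j in range(1, 9):
        anchor = rng.normal(scale=between_scale / np.sqrt(latent_dim), size=latent_dim)
        offs_g = {g: unit_vec() * 0.6 * between_scale for g in ("R", "IC", "ISC")}
        p_r = anchor + offs_g["R"]
        p_ic = anchor + offs_g["IC"]
        p_isc = anchor + offs_g["ISC"]
        coords[("R", j, "a")] = p_r
        coords[("R", j, "b")] = p_r + unit_vec() * gains["R"]
        coords[("IC", j, "a")] = p_ic
        coords[("IC", j, "b")] = p_ic + unit_vec() * gains["IC"]
        coords[("ISC", j, "a")] = p_isc
        delta_isc = unit_vec() * gains["ISC"]
        coords[("ISC", j, "b")] = p_isc + delta_isc
        # the curved->straight (NAP) offset is shared, slightly jittered,
        # between the a and b members: both cross contrasts ISCa-vs-ISSa and
        # ISCb-vs-ISSb then sit at ~gains["ISCvsISS"], while the ISS
        # within-pair distance stays close to the ISC one
        v_nap = unit_vec()
        v_nap_b = v_nap + 0.3 * unit_vec()
        v_nap_b = v_nap_b / np.linalg.norm(v_nap_b)
        coords[("ISS", j, "a")] = p_isc + v_nap * gains["ISCvsISS"]
        coords[("ISS", j, "b")] = (p_isc + delta_isc
                                   + v_nap_b * gains["ISCvsISS"] * rng.uniform(0.95, 1.05))

    X = np.stack([coords[_key_from_id(i)] for i in ids])
    diff = X[:, None, :] - X[None, :, :]
    d = np.sqrt((diff**2).sum(-1))
    np.fill_diagonal(d, 0.0)
    return GeometryProfile(RDM(d, "normalized_euclidean", ids), gains)


def _key_from_id(sid: str):
    group = "".join(ch for ch in sid if ch.isalpha() and not ch.islower())
    member = sid[-1]
    pair = int(sid[len(group):-1])
    return (group, pair, member)


def make_sorting_probabilities(shape_set_or_ids, probs: dict | None = None) -> tuple[np.ndarray, list[str]]:
    """Separation-probability matrix with the human judgment profile.

    Within-pair probabilities per group come from ``probs``; the
    curved-vs-straight (ISC vs ISS, same column, same member) pairs get the
    highest probability; all remaining pairs use the 'between' level.
    """
    ids = _pair_layout(shape_set_or_ids)
    p = dict(DEFAULT_HUMAN_PROBS if probs is None else probs)
    n = len(ids)
    keys = [_key_from_id(i) for i in ids]
    P = np.full((n, n), p["between"])
    for i in range(n):
        for k in range(i + 1, n):
            gi, ji, mi = keys[i]
            gk, jk, mk = keys[k]
            if gi == gk and ji == jk:
                P[i, k] = P[k, i] = p[gi]
            elif {gi, gk} == {"ISC", "ISS"} and ji == jk and mi == mk:
                P[i, k] = P[k, i] = p["ISCvsISS"]
    np.fill_diagonal(P, 0.0)
    return P, ids


# ---------------------------------------------------------------------------
# neural population simulator


def _classical_mds(d: np.ndarray) -> np.ndarray:
    """Embed a dissimilarity matrix into Euclidean coordinates (non-negative
    eigenvalue dimensions only)."""
    n = d.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (d**2) @ J
    w, V = np.linalg.eigh(B)
    keep = w > 1e-10 * w.max()
    return V[:, keep] * np.sqrt(w[keep])


def _random_frame(n_rows: int, dims: int, rng: np.random.Generator) -> np.ndarray:
    """Random loading frame with unit-RMS rows.

    For n_rows >= dims the frame is a scaled random orthonormal basis
    (W^T W proportional to I), so squared distances of projected points are
    exactly proportional to the source distances and the projection adds no
    geometry sampling error; below that rank a plain Gaussian frame is used.
    """
    G = rng.normal(size=(n_rows, dims))
    if n_rows >= dims:
        Q, _ = np.linalg.qr(G)
        return Q * np.sqrt(n_rows / dims)
    return G / np.sqrt(dims)


def _draw_trials(trials, n_stimuli: int, rng: np.random.Generator) -> np.ndarray:
    """Trials spec: an int (constant) or {'min': 5, 'median': 10} (uniform on
    [min, 2*median - min], matching the recorded sampling regime)."""
    if isinstance(trials, (int, np.integer)):
        if trials < 1:
            raise ValueError("need at least 1 trial per stimulus")
        return np.full(n_stimuli, int(trials))
    lo = int(trials["min"])
    med = int(trials["median"])
    hi = 2 * med - lo
    if lo < 1 or hi < lo:
        raise ValueError("invalid trials spec")
    return rng.integers(lo, hi + 1, size=n_stimuli)


def simulate_neurons(shape_set_or_ids, profile: GeometryProfile, n_units: int = 119,
                     trials=None, noise_scale: float = 1.0, seed: int = 0,
                     baseline_rate: float = 20.0, modulation_sd: float = 20.0) -> NeuralDataset:
    """Population of tuned units whose expected RDM rank-matches the target.

    Unit tuning vectors are random loadings on the classical-MDS embedding of
    the target RDM plus a unit-specific baseline, so expected pairwise
    normalized Euclidean distances are proportional to the template distances.
    Trial counts in the 250-ms window are Poisson around rate for
    ``noise_scale`` 1; 0 gives deterministic rounded counts; other values use
    a rounded Gaussian with variance noise_scale^2 * lambda (variance-scaled
    Poisson surrogate).
    """
    ids = _pair_layout(shape_set_or_ids)
    if n_units < 2:
        raise ValueError("n_units must be >= 2")
    d = profile.target_rdm.values
    if np.all(d == 0):
        raise ValueError("degenerate profile: target RDM is all zero")
    if profile.target_rdm.stimulus_ids != ids:
        raise ValueError("profile stimulus ids do not match the shape set")
    rng = np.random.default_rng(seed)
    X = _classical_mds(d)  # (stimuli, dims)
    # scale latent so that loading-projected modulation has sd ~ modulation_sd
    X = X / np.sqrt((X**2).sum(axis=1).mean())
    dims = X.shape[1]
    # whitened Gaussian loadings: rows are heterogeneous (units differ in
    # gain and tuning direction, which is what gives the unit bootstrap its
    # meaning) but W^T W is exactly proportional to the identity, so the
    # full population's squared distances are exactly proportional to the
    # template's and recovery at zero noise is limited only by spike-count
    # quantization
    G = rng.normal(size=(n_units, dims))
    if n_units >= dims:
        evals, evecs = np.linalg.eigh(G.T @ G)
        W = G @ (evecs * (1.0 / np.sqrt(evals))) @ evecs.T * np.sqrt(n_units / dims)
    else:
        W = G / np.sqrt(dims)
    baselines = rng.uniform(0.6, 1.4, size=n_units)[:, None] * baseline_rate
    rates = baselines + modulation_sd * (W @ X.T)
    rates = np.maximum(rates, RATE_FLOOR)
    lam = rates * RESPONSE_WINDOW_S

    n_stim = len(ids)
    n_trials = _draw_trials(trials if trials is not None else {"min": 5, "median": 10},
                            n_stim, rng)
    t_max = int(n_trials.max())
    lam3 = np.repeat(lam[:, :, None], t_max, axis=2)
    if noise_scale == 0:
        counts = np.rint(lam3).astype(np.int64)
    elif noise_scale == 1.0:
        counts = rng.poisson(lam3)
    else:
        z = rng.normal(size=lam3.shape)
        counts = np.rint(np.clip(lam3 + noise_scale * np.sqrt(lam3) * z, 0, None)).astype(np.int64)
    mask = np.arange(t_max)[None, :] < n_trials[:, None]
    counts = counts * mask[None, :, :]
    return NeuralDataset(counts, n_trials, ids)


def screen_selective_units(dataset: NeuralDataset, alpha: float = 0.05) -> NeuralDataset:
    """Keep units with significant stimulus selectivity (one-way ANOVA p < alpha).

    The test is run across the 64 stimuli on trial responses, mirroring the
    inclusion screen applied to recorded units. A unit with zero variance
    across all trials has an undefined F statistic and is excluded.
    """
    n_units = dataset.n_units
    flags = np.zeros(n_units, dtype=bool)
    t_max = dataset.trial_counts.shape[2]
    groups_idx = [np.arange(int(nt)) for nt in dataset.n_trials_per_stimulus]
    for u in range(n_units):
        samples = [dataset.trial_counts[u, s, idx] for s, idx in enumerate(groups_idx)]
        pooled = np.concatenate(samples)
        if np.ptp(pooled) == 0:
            continue  # no variance anywhere: F undefined, excluded
        try:
            _, p = f_oneway(*samples)
        except Exception:
            continue
        flags[u] = np.isfinite(p) and p < alpha
    if not flags.any():
        raise ValueError("no unit passed the selectivity screen")
    out = NeuralDataset(dataset.trial_counts[flags], dataset.n_trials_per_stimulus,
                        list(dataset.stimulus_ids))
    out.selectivity_flags = flags
    return out


# ---------------------------------------------------------------------------
# surrogate layer stacks and projections


def _geometry_basis(rdm_values: np.ndarray) -> np.ndarray:
    """Unit-RMS-distance Euclidean embedding of a dissimilarity matrix."""
    X = _classical_mds(np.asarray(rdm_values, dtype=float))
    X = X - X.mean(axis=0)
    diff = X[:, None, :] - X[None, :, :]
    rms = np.sqrt((diff**2).sum(-1)[np.triu_indices(X.shape[0], 1)].mean())
    return X / rms


def simulate_layer_stack(pixel_matrix: ActivationMatrix, target_rdm: RDM,
                         n_layers: int, units_per_layer, mixing_schedule,
                         redundancy: int = 1, noise_sd: float = 0.02,
                         seed: int = 0) -> list[ActivationMatrix]:
    """Surrogate layer hierarchy interpolating pixel geometry to target geometry.

    Layer l units are random linear mixtures of a pixel-geometry basis and a
    target-geometry basis with weights (1 - m_l, m_l); m_l must be
    non-decreasing across layers. Each distinct unit is replicated (with
    small noise) ``redundancy`` times, emulating the high unit redundancy of
    convolutional feature maps.
    """
    mixing = list(mixing_schedule)
    units = list(units_per_layer)
    if len(mixing) != n_layers or len(units) != n_layers:
        raise ValueError("mixing_schedule and units_per_layer must have n_layers entries")
    if any(m2 < m1 - 1e-12 for m1, m2 in zip(mixing, mixing[1:])):
        raise ValueError("mixing_schedule must be non-decreasing")
    if any(u < 2 for u in units):
        raise ValueError("units_per_layer entries must be >= 2")
    if any(not 0 <= m <= 1 for m in mixing):
        raise ValueError("mixing weights must lie in [0, 1]")
    if pixel_matrix.stimulus_ids != target_rdm.stimulus_ids:
        raise ValueError("pixel matrix and target RDM stimulus ids differ")

    from .rdm import compute_rdm as _crdm
    pix_rdm = _crdm(pixel_matrix, "normalized_euclidean")
    B_pix = _geometry_basis(pix_rdm.values)
    B_tar = _geometry_basis(target_rdm.values)
    rng = np.random.default_rng(seed)
    layers = []
    for l in range(n_layers):
        m = mixing[l]
        n_distinct = max(2, units[l] // max(1, redundancy))
        basis = np.hstack([(1.0 - m) * B_pix, m * B_tar])  # (stimuli, dp+dt)
        W = _random_frame(n_distinct, basis.shape[1], rng)
        acts = W @ basis.T  # (n_distinct, stimuli)
        reps = [acts + noise_sd * rng.normal(size=acts.shape) for _ in range(max(1, redundancy))]
        values = np.vstack(reps)[: units[l]]
        if values.shape[0] < units[l]:
            pad = values[rng.integers(0, values.shape[0], units[l] - values.shape[0])]
            values = np.vstack([values, pad + noise_sd * rng.normal(size=pad.shape)])
        layers.append(ActivationMatrix(values, list(pixel_matrix.stimulus_ids),
                                       source_tag=f"sim-layer-{l + 1}"))
    return layers


def random_projection_layer(images, n_units: int, seed: int = 0,
                            stimulus_ids=None) -> ActivationMatrix:
    """Rectified Gaussian random projection of the pixel vectors.

    Models an untrained first convolutional stage: each unit is
    max(0, w . x) with w ~ N(0, 1/p). Its RDM closely tracks the raw pixel
    RDM, the surrogate of the untrained-first-layer ~ pixel finding.
    """
    if n_units < 2:
        raise ValueError("n_units must be >= 2")
    from .features import pixel_features
    pix = pixel_features(images, stimulus_ids)
    p = pix.n_units
    rng = np.random.default_rng(seed)
    W = rng.normal(scale=1.0 / np.sqrt(p), size=(n_units, p))
    acts = np.maximum(0.0, W @ pix.values)
    return ActivationMatrix(acts, list(pix.stimulus_ids), source_tag="random-projection")


def simulate_sorting(probabilities: np.ndarray, n_subjects: int = 23, seed: int = 0,
                     stimulus_ids=None) -> HumanDissimilarity:
    """Binomial subject-separation counts from a symmetric probability matrix.

    Each unordered pair is drawn once (a single binomial draw symmetrized),
    emulating a sorting study in which each of ``n_subjects`` subjects either
    separates a pair or keeps it together.
    """
    P = np.asarray(probabilities, dtype=float)
    if not np.allclose(P, P.T):
        raise ValueError("probability matrix must be symmetric")
    if np.any(P < 0) or np.any(P > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    n = P.shape[0]
    rng = np.random.default_rng(seed)
    counts = np.zeros((n, n), dtype=int)
    iu = np.triu_indices(n, 1)
    draws = rng.binomial(n_subjects, P[iu])
    counts[iu] = draws
    counts = counts + counts.T
    ids = list(stimulus_ids) if stimulus_ids is not None else [f"s{k:02d}" for k in range(n)]
    return HumanDissimilarity(counts, n_subjects, ids)
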