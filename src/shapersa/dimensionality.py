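"""How model-data similarity depends on unit sample size and on retained PCs.

Two complementary analyses of a model layer's redundancy:

* **Unit subsampling** — draw a fixed percentage of the layer's differential
  units (without replacement, many times) and re-run the second-order
  correlation against the reference RDM. A flat curve down to small
  percentages means the similarity is distributed across many redundant
  units, not carried by a few.
* **PCA truncation** — project stimulus activation patterns onto the top-k
  principal components (stimuli as observations, per-unit means removed) and
  compute normalized Euclidean distances in score space, keeping the original
  unit count as the normalizing divisor so that full rank exactly reproduces
  the full-unit RDM. The number of components needed to plateau is the
  effective dimensionality of the layer's shape representation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .features import ActivationMatrix, filter_differential_units
from .rdm import RDM, upper_triangle
from .rsa import _pair_sq_diffs, _pearson_rows_vs_vec


@dataclass
class SubsampleCurve:
    fractions: list[float]
    median_rho: list[float]
    lo_rho: list[float]
    hi_rho: list[float]
    unit_counts: list[int]
    n_samples: int

    def __post_init__(self):
        for lo, med, hi in zip(self.lo_rho, self.median_rho, self.hi_rho):
            if not (lo <= med + 1e-12 and med <= hi + 1e-12):
                raise ValueError("percentile ordering violated")


@dataclass
class PCACurve:
    k_values: list[int]
    rho_per_k: list[float]
    cumulative_explained_variance: list[float]

    def __post_init__(self):
        ev = self.cumulative_explained_variance
        if any(b < a - 1e-12 for a, b in zip(ev, ev[1:])):
            raise ValueError("explained variance must be non-decreasing in k")


def percent_to_count(fraction: float, n_units: int) -> int:
    """Round-half-up percent-of-units rule with a floor of one unit
    (0.1% of a 3,136-unit layer -> 3 units)."""
    if not 0 < fraction <= 100:
        raise ValueError("fraction must lie in (0, 100]")
    return max(1, int(np.floor(fraction / 100.0 * n_units + 0.5)))


def subsample_similarity(model: ActivationMatrix, reference: RDM, fractions,
                         n_samples: int = 10_000,
                         metric: str = "normalized_euclidean",
                         seed: int = 0) -> SubsampleCurve:
    """Similarity-vs-sample-size curve over random unit subsets.

    The layer is first restricted to differential units (positive SD across
    stimuli), since only those contribute to a Euclidean distance. Per
    fraction, ``n_samples`` subsets are drawn without replacement; reported
    are the median and 2.5/97.5 percentiles of the Spearman correlation with
    the reference RDM. Fraction 100 reproduces the full-population rho with
    zero spread.
    """
    if metric != "normalized_euclidean":
        raise ValueError("subsampling is defined for the normalized Euclidean metric")
    model = filter_differential_units(model)
    if model.stimulus_ids != reference.stimulus_ids:
        raise ValueError("model and reference stimulus ids differ")
    n_units = model.n_units
    d2 = _pair_sq_diffs(model.values)
    ref_ranks = rankdata(upper_triangle(reference))
    rng = np.random.default_rng(seed)

    fractions = list(fractions)
    medians, los, his, counts = [], [], [], []
    for frac in fractions:
        k = percent_to_count(frac, n_units)
        counts.append(k)
        if k == n_units:
            ut = np.sqrt(d2.mean(axis=0))
            rho = float(_pearson_rows_vs_vec(rankdata(ut)[None, :], ref_ranks)[0])
            medians.append(rho)
            los.append(rho)
            his.append(rho)
            continue
        rhos = np.empty(n_samples)
        chunk = max(1, min(n_samples, int(2e8 // (8 * d2.shape[1]))))
        done = 0
        while done < n_samples:
            m = min(chunk, n_samples - done)
            idx = np.argsort(rng.random((m, n_units)), axis=1)[:, :k]
            ut = np.sqrt(d2[idx].mean(axis=1))
            ranks = rankdata(ut, axis=-1)
            rhos[done:done + m] = _pearson_rows_vs_vec(ranks, ref_ranks)
            done += m
        lo, med, hi = np.percentile(rhos, [2.5, 50, 97.5])
        medians.append(float(med))
        los.append(float(lo))
        his.append(float(hi))
    return SubsampleCurve(fractions, medians, los, his, counts, n_samples)


def _pca_scores(model: ActivationMatrix):
    """Stimulus scores on the principal axes of the unit-activation covariance
    (stimuli as observations, per-unit means removed)."""
    v = model.values
    centered = (v - v.mean(axis=1, keepdims=True)).T  # (stimuli, units)
    U, s, _ = np.linalg.svd(centered, full_matrices=False)
    return U * s, s**2  # scores (stimuli, r), component variances


def pca_truncated_rdm(model: ActivationMatrix, k: int) -> RDM:
    """Normalized Euclidean RDM in the top-k principal-component score space.

    The divisor stays the layer's original unit count, so k = full rank
    reproduces the full-unit RDM exactly (Euclidean distances are invariant
    to the rotation into the PC basis, and centering per unit cancels in
    every pairwise difference).
    """
    scores, _ = _pca_scores(model)
    max_k = min(model.n_units, model.n_stimuli - 1)
    if not 1 <= k <= max_k:
        raise ValueError(f"k must lie in [1, {max_k}]")
    d = squareform(pdist(scores[:, :k]) / np.sqrt(model.n_units))
    return RDM(d, "normalized_euclidean", list(model.stimulus_ids))


def pca_similarity_curve(model: ActivationMatrix, reference: RDM, max_k: int,
                         metric: str = "normalized_euclidean") -> PCACurve:
    """rho(reference, truncated RDM) for k = 1..max_k plus explained variance."""
    if metric != "normalized_euclidean":
        raise ValueError("PCA truncation is defined for the normalized Euclidean metric")
    if model.stimulus_ids != reference.stimulus_ids:
        raise ValueError("model and reference stimulus ids differ")
    scores, var = _pca_scores(model)
    rank = min(model.n_units, model.n_stimuli - 1)
    if not 1 <= max_k <= rank:
        raise ValueError(f"max_k must lie in [1, {rank}]")
    total = var[:rank].sum()
    ref_ranks = rankdata(upper_triangle(reference))
    ks, rhos, ev = [], [], []
    for k in range(1, max_k + 1):
        ut = pdist(scores[:, :k]) / np.sqrt(model.n_units)
        rho = float(_pearson_rows_vs_vec(rankdata(ut)[None, :], ref_ranks)[0])
        ks.append(k)
        rhos.append(rho)
        ev.append(float(var[:k].sum() / total))
    return PCACurve(ks, rhos, ev)
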