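"""Second-order RSA statistics: bootstrap CIs, paired tests, FDR, noise ceiling.

The population of recorded units is the random factor: confidence intervals
for the RDM correlation between a neural population and a model layer come
from resampling units with replacement (resample size = population size) and
recomputing the neural RDM each time. One shared set of unit resamples is
used for every model RDM in a call, which is what makes *paired* layer
comparisons valid: the difference distribution of two layers' bootstrap
correlations is taken replicate by replicate.

The noise ceiling is the Spearman-Brown-corrected split-half reliability of
the neural RDM: units are split into two halves, the two half-RDMs are
correlated (Spearman), and 2r/(1+r) predicts full-sample reliability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .rdm import RDM, upper_triangle
from .synth import NeuralDataset


@dataclass
class RSAResult:
    """Second-order Spearman correlation of one model RDM with the neural RDM."""

    layer_id: str
    rho: float
    ci_low: float
    ci_high: float
    boot_distribution: np.ndarray
    n_boot: int
    seed: int
    p: float | None = None
    q: float | None = None
    # provenance of the shared unit resamples; paired tests require equality
    replicate_key: tuple = field(default=())

    def __post_init__(self):
        self.boot_distribution = np.asarray(self.boot_distribution, dtype=float)
        if self.boot_distribution.size != self.n_boot:
            raise ValueError("boot_distribution length must equal n_boot")


@dataclass
class PairedTestResult:
    p: float
    direction: int
    q: float | None = None


@dataclass
class NoiseCeiling:
    median: float
    lo: float
    hi: float
    n_splits: int


def _rank_rows(a: np.ndarray) -> np.ndarray:
    return rankdata(a, axis=-1)


def _pearson_rows_vs_vec(rows: np.ndarray, vec: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of a matrix with one vector."""
    rc = rows - rows.mean(axis=1, keepdims=True)
    vc = vec - vec.mean()
    num = rc @ vc
    den = np.sqrt((rc**2).sum(axis=1) * (vc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    return out


def spearman_uppertri(rdm_a: RDM, rdm_b: RDM) -> float:
    """Spearman rho between the upper triangles of two RDMs (same stimuli)."""
    if rdm_a.stimulus_ids != rdm_b.stimulus_ids:
        raise ValueError("RDMs have mismatched stimulus ids or ordering")
    ua, ub = upper_triangle(rdm_a), upper_triangle(rdm_b)
    return float(_pearson_rows_vs_vec(rankdata(ua)[None, :], rankdata(ub))[0])


# alias matching the operation name used in the analysis plan
rdm_correlation = spearman_uppertri


def _pair_sq_diffs(rates: np.ndarray) -> np.ndarray:
    """(units, n_pairs) per-unit squared response differences for all i<j pairs."""
    n_stim = rates.shape[1]
    iu, ju = np.triu_indices(n_stim, k=1)
    return (rates[:, iu] - rates[:, ju]) ** 2


def _boot_euclidean_ut(rates: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Upper-triangle normalized Euclidean distances for unit-resampled
    populations given per-replicate unit multiplicities."""
    d2 = _pair_sq_diffs(rates)
    n = rates.shape[0]
    return np.sqrt(counts @ d2 / n)


def _spearman_ut(rates: np.ndarray) -> np.ndarray:
    """Upper triangle of the 1 - Spearman RDM of a unit x stimulus matrix.

    Raises if any stimulus column is constant across units.
    """
    if np.any(np.ptp(rates, axis=0) == 0):
        raise FloatingPointError("constant stimulus vector")
    ranks = rankdata(rates, axis=0)
    rho = np.corrcoef(ranks.T)
    d = 1.0 - rho
    iu = np.triu_indices(rates.shape[1], k=1)
    return d[iu]


def _neural_ut(rates: np.ndarray, metric: str) -> np.ndarray:
    if metric == "normalized_euclidean":
        d2 = _pair_sq_diffs(rates)
        return np.sqrt(d2.mean(axis=0))
    return _spearman_ut(rates)


def bootstrap_rsa(dataset: NeuralDataset, model_rdms: list[RDM],
                  metric: str = "normalized_euclidean", n_boot: int = 10_000,
                  seed: int = 0) -> list[RSAResult]:
    """Layer-wise RSA with unit-bootstrap CIs and shared replicates.

    Per replicate, units are resampled with replacement (size = population
    size) and the neural RDM recomputed; each model RDM is correlated
    (Spearman, upper triangles) against the same resampled neural RDM, so
    paired layer tests can difference the bootstrap distributions replicate
    by replicate. Point estimate is the full-sample rho; the CI spans the
    2.5th and 97.5th percentiles of the bootstrap distribution. Replicates
    where the metric is undefined (a constant vector under 1 - Spearman) are
    redrawn, keeping n_boot exact.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if dataset.n_units < 2:
        raise ValueError("need at least 2 units")
    rates = dataset.mean_rates
    n_units = rates.shape[0]
    ids0 = list(dataset.stimulus_ids)
    for m in model_rdms:
        if m.stimulus_ids != ids0:
            raise ValueError(f"model RDM {getattr(m, 'metric', '?')} id mismatch")

    full_ut = _neural_ut(rates, metric)
    full_ranks = rankdata(full_ut)
    model_uts = [upper_triangle(m) for m in model_rdms]
    model_ranks = [rankdata(u) for u in model_uts]
    full_rhos = [
        float(_pearson_rows_vs_vec(full_ranks[None, :], mr)[0]) for mr in model_ranks
    ]

    rng = np.random.default_rng(seed)
    n_redraw = 0
    if metric == "normalized_euclidean":
        counts = rng.multinomial(n_units, np.full(n_units, 1.0 / n_units), size=n_boot)
        boot_ut = _boot_euclidean_ut(rates, counts.astype(float))
        # a resample can degenerate only if all distances vanish; redraw those
        bad = np.ptp(boot_ut, axis=1) == 0
        while bad.any():
            n_redraw += int(bad.sum())
            counts_new = rng.multinomial(n_units, np.full(n_units, 1.0 / n_units),
                                         size=int(bad.sum()))
            boot_ut[bad] = _boot_euclidean_ut(rates, counts_new.astype(float))
            bad = np.ptp(boot_ut, axis=1) == 0
        boot_ranks = _rank_rows(boot_ut)
    else:
        boot_ranks = np.empty((n_boot, full_ut.size))
        b = 0
        while b < n_boot:
            idx = rng.integers(0, n_units, size=n_units)
            try:
                ut = _spearman_ut(rates[idx])
            except FloatingPointError:
                n_redraw += 1
                continue
            boot_ranks[b] = rankdata(ut)
            b += 1

    key = (int(seed), int(n_boot), int(n_units), metric)
    results = []
    for layer_idx, m in enumerate(model_rdms):
        rhos = _pearson_rows_vs_vec(boot_ranks, model_ranks[layer_idx])
        lo, hi = np.percentile(rhos, [2.5, 97.5])
        results.append(RSAResult(
            layer_id=getattr(m, "layer_id", None) or f"layer{layer_idx + 1}",
            rho=full_rhos[layer_idx], ci_low=float(lo), ci_high=float(hi),
            boot_distribution=rhos, n_boot=n_boot, seed=seed, replicate_key=key,
        ))
    return results


def paired_bootstrap_test(result_a: RSAResult, result_b: RSAResult) -> PairedTestResult:
    """Two-sided percentile-of-zero test on the paired difference distribution.

    d = boot_a - boot_b per shared replicate; p = 2 * min(P(d<=0), P(d>=0)),
    floored at 2/n_boot (zero never lies strictly outside a finite sample) and
    capped at 1. Requires that both results came from the same replicate set.
    """
    if result_a.replicate_key != result_b.replicate_key:
        raise ValueError("results do not share bootstrap replicates; run them in one call")
    d = result_a.boot_distribution - result_b.boot_distribution
    n = result_a.n_boot
    p = 2.0 * min((d <= 0).mean(), (d >= 0).mean())
    p = min(1.0, max(p, 2.0 / n))
    med = np.median(d)
    direction = int(np.sign(med))
    return PairedTestResult(p=float(p), direction=direction)


def fdr_correct(p_values, q_level: float = 0.05):
    """Benjamini-Hochberg step-up over one family (e.g. all layers of a network).

    Returns (reject flags, adjusted q-values).
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    reject, qvals, _, _ = multipletests(p, alpha=q_level, method="fdr_bh")
    return reject, qvals


def spearman_brown(r: float) -> float:
    """Predicted full-sample reliability from a half-sample correlation: 2r/(1+r)."""
    return 2.0 * r / (1.0 + r)


def split_half_ceiling(dataset: NeuralDataset, metric: str = "normalized_euclidean",
                       n_splits: int = 10_000, seed: int = 0) -> NoiseCeiling:
    """Noise ceiling: Spearman-Brown-corrected split-half RDM reliability.

    Per split, units are partitioned into halves of size floor(N/2) and
    ceil(N/2) without replacement, each half's RDM is computed, the two are
    correlated (Spearman over upper triangles), and 2r/(1+r) corrects for
    halving. Reported are the median and the 2.5/97.5 percentiles over
    splits. Splits where a half's metric is undefined are redrawn.
    """
    rates = dataset.mean_rates
    n_units = rates.shape[0]
    if n_units < 4:
        raise ValueError("need at least 4 units to split")
    half = n_units // 2
    rng = np.random.default_rng(seed)

    if metric == "normalized_euclidean":
        d2 = _pair_sq_diffs(rates)
        perms = np.argsort(rng.random((n_splits, n_units)), axis=1)
        ind1 = np.zeros((n_splits, n_units))
        np.put_along_axis(ind1, perms[:, :half], 1.0, axis=1)
        ind2 = 1.0 - ind1
        ut1 = np.sqrt(ind1 @ d2 / half)
        ut2 = np.sqrt(ind2 @ d2 / (n_units - half))
        r1 = _rank_rows(ut1)
        r2 = _rank_rows(ut2)
        a = r1 - r1.mean(axis=1, keepdims=True)
        b = r2 - r2.mean(axis=1, keepdims=True)
        r = (a * b).sum(axis=1) / np.sqrt((a**2).sum(axis=1) * (b**2).sum(axis=1))
    else:
        r = np.empty(n_splits)
        s = 0
        while s < n_splits:
            perm = rng.permutation(n_units)
            try:
                u1 = _spearman_ut(rates[perm[:half]])
                u2 = _spearman_ut(rates[perm[half:]])
            except FloatingPointError:
                continue
            ra, rb = rankdata(u1), rankdata(u2)
            r[s] = float(_pearson_rows_vs_vec(ra[None, :], rb)[0])
            s += 1

    corrected = 2.0 * r / (1.0 + r)
    lo, med, hi = np.percentile(corrected, [2.5, 50, 97.5])
    return NoiseCeiling(median=float(med), lo=float(lo), hi=float(hi), n_splits=n_splits)
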