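"""Bootstrap RSA, paired tests, FDR, and the split-half noise ceiling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst
from scipy.stats import rankdata

from shapersa import rdm as R
from shapersa import rsa
from shapersa import synth
from shapersa.features import ActivationMatrix


def toy_rdm(vals, ids):
    return R.RDM(vals, "normalized_euclidean", ids)


class TestRdmCorrelation:
    def test_self_correlation_one(self, rng):
        m = ActivationMatrix(rng.normal(size=(6, 5)), [f"s{k}" for k in range(5)])
        r = R.compute_rdm(m)
        assert np.isclose(rsa.rdm_correlation(r, r), 1.0)

    def test_rank_reversal_minus_one(self):
        ids = list("abcd")
        v = np.zeros((4, 4))
        iu = np.triu_indices(4, 1)
        v[iu] = [1, 2, 3, 4, 5, 6]
        v = v + v.T
        w = np.zeros((4, 4))
        w[iu] = [6, 5, 4, 3, 2, 1]
        w = w + w.T
        assert np.isclose(rsa.rdm_correlation(toy_rdm(v, ids), toy_rdm(w, ids)), -1.0)

    def test_matches_rank_then_pearson_oracle(self, rng):
        ids = list("abcd")
        a = R.compute_rdm(ActivationMatrix(rng.normal(size=(5, 4)), ids))
        b = R.compute_rdm(ActivationMatrix(rng.normal(size=(5, 4)), ids))
        ua, ub = R.upper_triangle(a), R.upper_triangle(b)
        oracle = np.corrcoef(rankdata(ua), rankdata(ub))[0, 1]
        assert np.isclose(rsa.rdm_correlation(a, b), oracle)

    def test_id_mismatch_errors(self, rng):
        a = R.compute_rdm(ActivationMatrix(rng.normal(size=(5, 4)), list("abcd")))
        b = R.compute_rdm(ActivationMatrix(rng.normal(size=(5, 4)), list("abce")))
        with pytest.raises(ValueError):
            rsa.rdm_correlation(a, b)


class TestBootstrapRSA:
    def test_fixed_seed_reproducible(self, neural_dataset, geometry):
        a = rsa.bootstrap_rsa(neural_dataset, [geometry.target_rdm], n_boot=200, seed=3)
        b = rsa.bootstrap_rsa(neural_dataset, [geometry.target_rdm], n_boot=200, seed=3)
        assert np.array_equal(a[0].boot_distribution, b[0].boot_distribution)
        assert a[0].rho == b[0].rho

    def test_ci_brackets_percentiles(self, neural_dataset, geometry):
        res = rsa.bootstrap_rsa(neural_dataset, [geometry.target_rdm],
                                n_boot=500, seed=3)[0]
        lo, hi = np.percentile(res.boot_distribution, [2.5, 97.5])
        assert res.ci_low == pytest.approx(lo)
        assert res.ci_high == pytest.approx(hi)
        assert res.ci_low <= res.ci_high

    def test_zero_noise_redundant_population_narrow_ci(self, ids64, geometry):
        ds = synth.simulate_neurons(ids64, geometry, n_units=400,
                                    noise_scale=0.0, seed=2)
        res = rsa.bootstrap_rsa(ds, [geometry.target_rdm], n_boot=500, seed=5)[0]
        assert res.ci_high - res.ci_low < 0.05

    def test_spearman_metric_path(self, ids64, geometry):
        ds = synth.simulate_neurons(ids64, geometry, n_units=40, seed=2)
        res = rsa.bootstrap_rsa(ds, [geometry.target_rdm],
                                metric="one_minus_spearman", n_boot=150, seed=5)[0]
        assert -1 <= res.rho <= 1
        assert res.boot_distribution.size == 150

    def test_n_boot_floor(self, neural_dataset, geometry):
        with pytest.raises(ValueError):
            rsa.bootstrap_rsa(neural_dataset, [geometry.target_rdm], n_boot=50)


class TestPairedBootstrap:
    def _results(self, neural_dataset, geometry, pixel_matrix):
        pix_rdm = R.compute_rdm(pixel_matrix)
        return rsa.bootstrap_rsa(neural_dataset, [geometry.target_rdm, pix_rdm],
                                 n_boot=400, seed=11)

    def test_identical_inputs_p_one(self, neural_dataset, geometry):
        res = rsa.bootstrap_rsa(neural_dataset, [geometry.target_rdm],
                                n_boot=200, seed=3)[0]
        out = rsa.paired_bootstrap_test(res, res)
        assert out.p == 1.0

    def test_all_positive_differences_floor(self, neural_dataset, geometry):
        res = rsa.bootstrap_rsa(neural_dataset, [geometry.target_rdm],
                                n_boot=200, seed=3)[0]
        import copy
        shifted = copy.copy(res)
        shifted.boot_distribution = res.boot_distribution - 1.0
        out = rsa.paired_bootstrap_test(res, shifted)
        assert out.p == 2.0 / 200
        assert out.direction == 1

    def test_antisymmetry(self, neural_dataset, geometry, pixel_matrix):
        a, b = self._results(neural_dataset, geometry, pixel_matrix)
        ab = rsa.paired_bootstrap_test(a, b)
        ba = rsa.paired_bootstrap_test(b, a)
        assert ab.p == ba.p
        assert ab.direction == -ba.direction

    def test_symmetric_null_p_near_one(self, neural_dataset, geometry):
        res = rsa.bootstrap_rsa(neural_dataset, [geometry.target_rdm],
                                n_boot=1000, seed=3)[0]
        import copy
        null = copy.copy(res)
        # construct a difference distribution symmetric around zero
        rng = np.random.default_rng(0)
        null.boot_distribution = res.boot_distribution + rng.choice(
            [-1e-6, 1e-6], size=res.n_boot)
        out = rsa.paired_bootstrap_test(res, null)
        assert out.p > 0.9

    def test_mismatched_replicates_rejected(self, neural_dataset, geometry):
        a = rsa.bootstrap_rsa(neural_dataset, [geometry.target_rdm], n_boot=200, seed=3)[0]
        b = rsa.bootstrap_rsa(neural_dataset, [geometry.target_rdm], n_boot=200, seed=4)[0]
        with pytest.raises(ValueError):
            rsa.paired_bootstrap_test(a, b)


def bh_stepup_oracle(p, q):
    """Textbook BH: largest k with p_(k) <= k q / m; reject all smaller."""
    p = np.asarray(p)
    m = p.size
    order = np.argsort(p)
    sorted_p = p[order]
    thresh = (np.arange(1, m + 1) / m) * q
    below = np.where(sorted_p <= thresh)[0]
    reject = np.zeros(m, dtype=bool)
    if below.size:
        reject[order[: below.max() + 1]] = True
    return reject


class TestFDR:
    def test_single_small_p_significant(self):
        reject, q = rsa.fdr_correct([0.01], 0.05)
        assert reject[0] and q[0] == pytest.approx(0.01)

    def test_worked_family(self):
        reject, _ = rsa.fdr_correct([0.01, 0.02, 0.04], 0.05)
        assert reject.all()

    def test_all_ones_none_significant(self):
        reject, _ = rsa.fdr_correct([1.0, 1.0, 1.0], 0.05)
        assert not reject.any()

    def test_empty_family_errors(self):
        with pytest.raises(ValueError):
            rsa.fdr_correct([], 0.05)

    @given(hst.integers(0, 2**32 - 1))
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_stepup(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(1, 25))
        p = rng.uniform(1e-6, 1.0, size=m)
        reject, _ = rsa.fdr_correct(p, 0.05)
        assert np.array_equal(reject, bh_stepup_oracle(p, 0.05))


class TestNoiseCeiling:
    def test_spearman_brown_values(self):
        assert rsa.spearman_brown(0.0) == 0.0
        assert rsa.spearman_brown(0.5) == pytest.approx(2 / 3)
        assert rsa.spearman_brown(1.0) == 1.0

    def test_duplicated_noise_free_population_is_one(self, ids64):
        # every unit a noise-free duplicate of one tuning curve: both halves
        # of any split carry the identical RDM, so corrected reliability is
        # exactly 1 at every split
        rng = np.random.default_rng(3)
        tuning = np.rint(rng.uniform(2, 50, size=64))
        counts = np.tile(tuning[None, :, None], (40, 1, 10)).astype(int)
        dup = synth.NeuralDataset(counts, np.full(64, 10), ids64)
        nc = rsa.split_half_ceiling(dup, n_splits=50, seed=1)
        assert nc.median == 1.0 and nc.lo == 1.0 and nc.hi == 1.0

    def test_highly_redundant_noisy_population_near_one(self, ids64, geometry):
        base = synth.simulate_neurons(ids64, geometry, n_units=20,
                                      noise_scale=0.0, trials=10, seed=3)
        dup = synth.NeuralDataset(
            np.concatenate([base.trial_counts] * 10),
            base.n_trials_per_stimulus, list(base.stimulus_ids))
        nc = rsa.split_half_ceiling(dup, n_splits=50, seed=1)
        assert nc.median > 0.95

    def test_percentile_ordering_and_determinism(self, neural_dataset):
        a = rsa.split_half_ceiling(neural_dataset, n_splits=200, seed=7)
        b = rsa.split_half_ceiling(neural_dataset, n_splits=200, seed=7)
        assert a.lo <= a.median <= a.hi
        assert (a.median, a.lo, a.hi) == (b.median, b.lo, b.hi)

    def test_ceiling_tracks_units_and_noise(self, ids64, geometry):
        # median increases with n_units and decreases with noise_scale
        grid = {}
        for n_units in (30, 119, 400):
            for noise in (0.5, 1.0, 2.0):
                ds = synth.simulate_neurons(ids64, geometry, n_units=n_units,
                                            trials=10, noise_scale=noise, seed=21)
                grid[(n_units, noise)] = rsa.split_half_ceiling(
                    ds, n_splits=120, seed=3).median
        for noise in (0.5, 1.0, 2.0):
            assert grid[(400, noise)] > grid[(30, noise)]
        for n_units in (30, 119, 400):
            assert grid[(n_units, 0.5)] > grid[(n_units, 2.0)]

    def test_too_few_units_rejected(self, ids64, geometry):
        ds = synth.simulate_neurons(ids64, geometry, n_units=3, seed=1)
        with pytest.raises(ValueError):
            rsa.split_half_ceiling(ds, n_splits=10)
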