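"""Binning, SNR, CV and mutual-information estimators against exact and
Monte-Carlo oracles."""

import numpy as np
import pytest
from scipy.stats import norm

from paracrine.fidelity import (
    ZeroNoiseError,
    bin_cells,
    cv_by_bin,
    cv_compare,
    knn_density,
    mutual_information,
    snr,
)
from paracrine.kernel import KernelSpec, paracrine_average
from paracrine.synthetic import (
    GradientProfile,
    HillCurve,
    NoiseModel,
    dose_response_field,
    scatter_cells,
    wound_field,
)

from conftest import make_field


def _field_from_values(cov, resp):
    n = len(cov)
    return make_field(np.zeros(n), np.zeros(n), response=resp, covariate=cov)


class TestBinning:
    def test_equal_count_ten_cells_five_bins(self):
        f = _field_from_values(np.arange(10.0), np.arange(10.0) + 1)
        s = bin_cells(f, "equal-count:5")
        assert list(s.counts) == [2, 2, 2, 2, 2]

    def test_identical_covariates_error(self):
        f = _field_from_values(np.ones(9), np.arange(9.0))
        with pytest.raises(ValueError, match="identical"):
            bin_cells(f, "equal-count:3")

    def test_by_group_bookkeeping(self):
        doses = [0.1, 0.3, 1.0, 3.0, 10.0, 30.0]
        hill = HillCurve()
        wells = []
        for i, d in enumerate(doses):
            pos = scatter_cells(150, 150, 1e-3, 20, seed=i)
            wells.append(dose_response_field(pos, d, hill, NoiseModel(cv=0.3), seed=i))
        from paracrine.sweep import combine_wells

        pooled = combine_wells(wells)
        s = bin_cells(pooled, "by-group")
        assert s.k == 6
        assert sorted(s.counts) == sorted(w.n for w in wells)


class TestSnr:
    def test_zero_noise_error(self):
        f = _field_from_values(np.array([0.0, 0.0, 1.0, 1.0]), np.array([0.0, 0.0, 1.0, 1.0]))
        with pytest.raises(ZeroNoiseError):
            snr(f, "equal-count:2")

    def test_hand_computed_two_bins(self):
        f = _field_from_values(np.array([0.0, 0.0, 1.0, 1.0]), np.array([0.0, 2.0, 4.0, 6.0]))
        r = snr(f, "equal-count:2")
        assert (r.signal, r.noise, r.snr) == (8.0, 2.0, 4.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        cov = rng.uniform(0, 1, 300)
        resp = np.exp(-cov) * rng.lognormal(0, 0.4, 300)
        f = _field_from_values(cov, resp)
        r1 = snr(f, "equal-count:10")
        r2 = snr(f.with_responses(3.5 * resp + 2.0), "equal-count:10")
        assert r1.snr == pytest.approx(r2.snr, rel=1e-12)

    def test_shuffling_destroys_signal(self):
        # permutation oracle: shuffled responses give far lower SNR than the
        # gradient field in at least 19/20 seeds
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            cov = rng.uniform(0, 1000, 600)
            resp = (3 * np.exp(-cov / 400) + 0.3) * rng.lognormal(-0.08, 0.4, 600)
            f = _field_from_values(cov, resp)
            observed = snr(f, "equal-count:10").snr
            shuffled = snr(
                _field_from_values(cov, rng.permutation(resp)), "equal-count:10"
            ).snr
            wins += shuffled < observed
        assert wins >= 19


class TestCv:
    def test_constant_responses_zero_cv(self):
        f = _field_from_values(np.arange(12.0), np.full(12, 3.0))
        s = cv_by_bin(f, "equal-count:3")
        assert np.all(s.cvs == 0.0)

    def test_identical_inputs_p_near_one(self):
        rng = np.random.default_rng(1)
        f = _field_from_values(rng.uniform(0, 1, 100), rng.lognormal(0, 0.5, 100))
        a = cv_by_bin(f, "equal-count:5")
        comp = cv_compare(a, a)
        assert comp.p_value == pytest.approx(1.0)
        assert comp.mean_cv_a == comp.mean_cv_b

    def test_paracrine_average_lowers_cv(self):
        # Ca-like raw noise vs its paracrine average at pcd = 100: the raw
        # field has the higher mean per-bin CV in at least 19/20 seeds
        wins = 0
        for seed in range(20):
            pos = scatter_cells(800, 800, 2e-3, 20, seed=seed)
            w = wound_field(
                pos, (400, 400), 100.0, GradientProfile(lam=400.0),
                NoiseModel(cv=0.8), seed=seed, patch_cv=0.0,
            )
            smoothed = paracrine_average(w, KernelSpec(pcd=100.0))
            comp = cv_compare(
                cv_by_bin(w, "equal-count:8"), cv_by_bin(smoothed, "equal-count:8")
            )
            wins += comp.mean_cv_a > comp.mean_cv_b
        assert wins >= 19


class TestKnnDensity:
    def test_uniform_grid_interior_value(self):
        # 101 grid points on [0,1]: the 10th NN of an interior point is 5
        # spacings away, so w = 2*0.05 and p = 10/(101*0.1)
        vals = np.linspace(0, 1, 101)
        p = knn_density(vals, k=10)
        assert p[50] == pytest.approx(10 / (101 * 0.1))

    def test_scaling_change_of_variables(self):
        rng = np.random.default_rng(2)
        vals = rng.lognormal(0, 0.5, 200)
        p1 = knn_density(vals, k=10)
        p2 = knn_density(4.0 * vals, k=10)
        assert np.allclose(p2, p1 / 4.0)

    def test_matches_normal_pdf_at_median(self):
        # seed-averaged estimate at the sample median within 10% of phi
        ratios = []
        for seed in range(20):
            x = np.random.default_rng(seed).standard_normal(10_000)
            i = int(np.argmin(np.abs(x - np.median(x))))
            ratios.append(knn_density(x, k=10)[i] / norm.pdf(x[i]))
        assert abs(np.mean(ratios) - 1.0) < 0.10

    def test_duplicate_values_substituted_with_warning(self):
        vals = np.concatenate([np.zeros(12), np.linspace(1, 2, 20)])
        with pytest.warns(UserWarning, match="duplicates"):
            p = knn_density(vals, k=10)
        assert np.all(np.isfinite(p)) and np.all(p > 0)


class TestMutualInformation:
    def test_independent_response_near_zero(self):
        intercepts = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            f = _field_from_values(rng.uniform(0, 1, 1500), rng.lognormal(0, 0.5, 1500))
            res = mutual_information(f)
            bs = np.array([b for b, _ in res.mi_curve], dtype=float)
            ivals = np.array([v for _, v in res.mi_curve])
            intercepts.append(np.polyfit(bs, ivals, 1)[1])  # unclamped
        se = np.std(intercepts, ddof=1) / np.sqrt(len(intercepts))
        assert abs(np.mean(intercepts)) < 3 * se

    def test_noiseless_channel_log2_bins(self):
        rng = np.random.default_rng(0)
        cov = rng.uniform(0, 1, 4000)
        f = _field_from_values(cov, cov)
        res = mutual_information(f, bin_counts=[4, 8, 16])
        for b, i_b in res.mi_curve:
            assert i_b == pytest.approx(np.log2(b), abs=0.15)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        cov = rng.uniform(0, 1, 5000)
        resp = np.exp(-cov) * rng.lognormal(0, 0.3, 5000)
        f1 = _field_from_values(cov, resp)
        f2 = f1.with_responses(np.log1p(resp) ** 3)
        m1 = mutual_information(f1).mi_bits
        m2 = mutual_information(f2).mi_bits
        assert abs(m1 - m2) < 0.1

    def test_small_bin_rejected_by_name(self):
        rng = np.random.default_rng(4)
        f = _field_from_values(rng.uniform(0, 1, 60), rng.lognormal(0, 0.3, 60))
        with pytest.raises(ValueError, match="bin"):
            mutual_information(f, bin_counts=[10])  # bins of 6 <= k_nn

    def test_nats_follow_bits(self):
        rng = np.random.default_rng(5)
        cov = rng.uniform(0, 1, 2000)
        f = _field_from_values(cov, np.exp(-cov) * rng.lognormal(0, 0.3, 2000))
        res = mutual_information(f)
        assert res.mi_nats == pytest.approx(res.mi_bits * np.log(2))
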