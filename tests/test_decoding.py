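import numpy as np
import pytest
from scipy.stats import beta as beta_dist

from assemblage.core import AlignedRateTensor
from assemblage.decoding import (
    compare_cp_beta,
    equalize_and_decode,
    fit_lda,
    hotelling_t2,
    loocv_cp,
    loocv_decode,
    train_correct_test_error,
)


def wrap_tensor(rates, areas=None):
    # decoding is invariant to a common shift; keep the tensor nonnegative
    rates = np.asarray(rates, float)
    if rates.min() < 0:
        rates = rates - rates.min()
    n_units = rates.shape[1]
    return AlignedRateTensor(
        rates=rates,
        times=0.05 * np.arange(rates.shape[2]),
        bin_s=0.05,
        align_event="sample",
        unit_ids=[f"u{i}" for i in range(n_units)],
        trial_indices=list(range(rates.shape[0])),
        areas=areas or ["dCA1"] * n_units,
    )


def brute_force_loocv(x, labels, lam):
    """Independent oracle: explicit per-fold refit with numpy lstsq-style LDA."""
    n = x.shape[0]
    correct = 0
    for j in range(n):
        keep = np.arange(n) != j
        xl = x[keep][labels[keep] == "L"]
        xr = x[keep][labels[keep] == "R"]
        ml, mr = xl.mean(0), xr.mean(0)
        w = ((xl - ml).T @ (xl - ml) + (xr - mr).T @ (xr - mr)) / (n - 1 - 2)
        w = w + lam * np.eye(x.shape[1])
        wt = np.linalg.solve(w, ml - mr)
        b = -0.5 * wt @ (ml + mr)
        pred = "L" if wt @ x[j] + b > 0 else "R"
        correct += pred == labels[j]
    return correct / n


class TestFitLDA:
    def test_1d_symmetric_boundary(self):
        x = np.array([[-1.2], [-0.8], [-1.0], [0.8], [1.2], [1.0]])
        model = fit_lda(x, np.array(list("RRRLLL")))
        assert model.weights[0] > 0
        assert model.bias == pytest.approx(0.0, abs=1e-12)
        assert list(model.predict(np.array([[2.0], [-2.0]]))) == ["L", "R"]

    def test_duplicated_features_need_regularization(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(10, 1))
        x = np.hstack([base, base])  # perfectly collinear
        lab = np.array(list("LLLLLRRRRR"))
        fit_lda(x, lab, lam=0.05)  # succeeds
        with pytest.raises(np.linalg.LinAlgError):
            fit_lda(x, lab, lam=0.0)

    def test_weights_match_closed_form(self):
        rng = np.random.default_rng(1)
        cov = np.array([[2.0, 0.6], [0.6, 1.0]])
        chol = np.linalg.cholesky(cov)
        mu_l, mu_r = np.array([1.0, 0.0]), np.array([-1.0, 0.5])
        xl = rng.normal(size=(4000, 2)) @ chol.T + mu_l
        xr = rng.normal(size=(4000, 2)) @ chol.T + mu_r
        x = np.vstack([xl, xr])
        lab = np.array(["L"] * 4000 + ["R"] * 4000)
        lam = 0.05
        model = fit_lda(x, lab, lam)
        expected = np.linalg.solve(cov + lam * np.eye(2), mu_l - mu_r)
        np.testing.assert_allclose(
            model.weights / np.linalg.norm(model.weights),
            expected / np.linalg.norm(expected),
            atol=0.02,
        )


class TestLOOCV:
    def test_chance_level_on_null(self, null_session):
        from tests.conftest import labels_of, tensor_of

        session, _ = null_session
        tens = tensor_of(session, window=(0.5, 0.5))
        res = loocv_decode(tens, labels_of(session))
        # the chance band a practitioner would draw at this trial count;
        # LOOCV's small-sample pessimism keeps the mean slightly below 0.5
        band = 1.96 * np.sqrt(0.25 / tens.n_trials)
        assert abs(res.cp.mean() - 0.5) <= band
        assert res.cp.mean() <= 0.55

    def test_separable_signal_reaches_one(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 0.1, size=(20, 3, 4))
        x[:10, :, 2] += 10.0  # bin 2 perfectly separates
        lab = np.array(["L"] * 10 + ["R"] * 10)
        res = loocv_decode(wrap_tensor(x), lab)
        assert res.cp[2] == 1.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(3):
            x = rng.normal(size=(24, 10))
            x[:12] += rng.normal(0.5, 0.2, size=10)  # ~1 SD planted offset
            lab = np.array(["L"] * 12 + ["R"] * 12)
            mine = loocv_cp(x, lab, 0.05)
            oracle = brute_force_loocv(x, lab, 0.05)
            assert mine == pytest.approx(oracle, abs=1e-12)

    def test_invariant_under_unit_permutation(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(20, 6))
        lab = np.array(["L"] * 10 + ["R"] * 10)
        perm = rng.permutation(6)
        assert loocv_cp(x, lab, 0.05) == pytest.approx(
            loocv_cp(x[:, perm], lab, 0.05), abs=1e-12
        )


class TestEqualize:
    def test_equal_sizes_no_draws(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(16, 6, 3))
        tens = wrap_tensor(x, areas=["dCA1"] * 3 + ["mPFC"] * 3)
        lab = np.array(["L"] * 8 + ["R"] * 8)
        out = equalize_and_decode(tens, lab, rng=np.random.default_rng(0))
        assert out["dCA1"].n_units == out["mPFC"].n_units == 3

    def test_draws_reproducible_with_seed(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(16, 9, 3))
        x[:8, :, 1] += 1.0
        tens = wrap_tensor(x, areas=["dCA1"] * 6 + ["mPFC"] * 3)
        lab = np.array(["L"] * 8 + ["R"] * 8)
        a = equalize_and_decode(tens, lab, rng=np.random.default_rng(42))
        b = equalize_and_decode(tens, lab, rng=np.random.default_rng(42))
        np.testing.assert_array_equal(a["dCA1"].cp, b["dCA1"].cp)


class TestBetaComparison:
    def test_equal_cp_not_significant(self):
        assert not compare_cp_beta(0.7, 0.7, 54)

    def test_large_gap_significant(self):
        # reference Beta(k+1, n-k+1) at cp = 0.5, n = 54; 0.90 escapes the 95%
        assert compare_cp_beta(0.5, 0.90, 54)
        k = round(0.5 * 54)
        assert 0.90 > beta_dist.ppf(0.95, k + 1, 54 - k + 1)

    def test_consistency_in_large_n(self):
        assert compare_cp_beta(0.6, 0.65, 100000)
        with pytest.raises(ValueError):
            compare_cp_beta(0.5, 0.9, 0)


class TestHotelling:
    def test_identical_samples_zero(self):
        x = np.tile([[1.0, 2.0]], (5, 1))
        t2, _ = hotelling_t2(x, x, lam=0.05)
        assert t2 == pytest.approx(0.0, abs=1e-12)

    def test_1d_equals_squared_t(self):
        rng = np.random.default_rng(0)
        xl = rng.normal(0, 1, (15, 1))
        xr = rng.normal(1, 1, (12, 1))
        from scipy.stats import ttest_ind

        t = ttest_ind(xl[:, 0], xr[:, 0]).statistic
        t2, _ = hotelling_t2(xl, xr, lam=0.0)
        assert t2 == pytest.approx(t * t, rel=1e-9)

    def test_null_type_one_error_rate(self):
        # lam = 0, n >> p: the F approximation should give ~5% false positives
        rng = np.random.default_rng(1)
        hits = 0
        n_sim = 400
        for _ in range(n_sim):
            xl = rng.normal(size=(30, 3))
            xr = rng.normal(size=(30, 3))
            _, p = hotelling_t2(xl, xr, lam=0.0)
            hits += p < 0.05
        assert abs(hits / n_sim - 0.05) < 0.03


class TestErrorGeneralization:
    def test_identical_error_tensor_no_drop(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(20, 4, 6))
        x[:10, :, 3] += 2.0
        lab = np.array(["L"] * 10 + ["R"] * 10)
        tens = wrap_tensor(x)
        err, corr = train_correct_test_error(
            tens, tens, lab, lab, n_perm=200, rng=np.random.default_rng(0)
        )
        assert not err.sig_mask.any()

    def test_flipped_error_labels_drop_below_chance(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(30, 4, 3))
        x[:15, :, 1] += 3.0
        lab_c = np.array(["L"] * 15 + ["R"] * 15)
        xe = x[:10].copy()
        lab_e = np.where(lab_c[:10] == "L", "R", "L")  # wrong-position code
        err, corr = train_correct_test_error(
            wrap_tensor(x), wrap_tensor(xe), lab_c, lab_e,
            n_perm=300, rng=np.random.default_rng(0),
        )
        assert err.cp[1] < 0.5
        assert err.sig_mask[1]
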