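import numpy as np
import pytest

from assemblage import assembly as asm
from assemblage.assembly import (
    Assembly,
    assemble,
    fit_fa,
    ica_assemblies,
    marchenko_pastur_bound,
    match_overlap,
    overlap,
    significant_loadings,
    trial_shuffle,
    varimax,
)


def simulate_fa_data(rng, gamma, psi, n_obs):
    """Draw exactly from the FA generative model."""
    n, p = gamma.shape
    z = rng.standard_normal((p, n_obs))
    eps = rng.standard_normal((n, n_obs)) * np.sqrt(psi)[:, None]
    return gamma @ z + eps


class TestFitFA:
    def test_recovers_planted_subspace(self):
        rng = np.random.default_rng(0)
        n, p, m = 30, 2, 5000
        gamma = np.zeros((n, p))
        gamma[:10, 0] = rng.uniform(0.8, 1.5, 10)
        gamma[10:20, 1] = rng.uniform(0.8, 1.5, 10)
        psi = rng.uniform(0.5, 1.5, n)
        X = simulate_fa_data(rng, gamma, psi, m)
        model = fit_fa(X, p)
        # subspace angle between fitted and true loading spans
        qa, _ = np.linalg.qr(gamma)
        qb, _ = np.linalg.qr(model.loadings)
        angles = np.degrees(
            np.arccos(np.clip(np.linalg.svd(qa.T @ qb)[1], -1, 1))
        )
        assert angles.max() < 5.0

    def test_p0_model_closed_form_loglik(self):
        rng = np.random.default_rng(1)
        X = rng.normal(2.0, 1.3, size=(5, 400))
        model = fit_fa(X, 0)
        mu = X.mean(axis=1)
        S = np.cov(X, bias=True)
        expected = -0.5 * 400 * (
            5 * np.log(2 * np.pi)
            + np.log(np.diag(S)).sum()
            + 5.0  # tr(diag(S)^-1 S restricted to diagonal) = n
        )
        assert model.loglik == pytest.approx(expected, rel=1e-10)

    def test_em_loglik_monotone(self):
        rng = np.random.default_rng(2)
        gamma = rng.uniform(0.5, 1.0, size=(12, 2))
        X = simulate_fa_data(rng, gamma, np.ones(12), 1500)
        model = fit_fa(X, 2)
        assert np.all(np.diff(model.loglik_path) > -1e-8)

    def test_p_must_be_below_unit_count(self):
        with pytest.raises(ValueError):
            fit_fa(np.ones((3, 100)), 3)

    def test_scores_shape_and_centering(self):
        rng = np.random.default_rng(3)
        gamma = rng.uniform(0.5, 1.0, size=(8, 1))
        X = simulate_fa_data(rng, gamma, np.ones(8), 900)
        model = fit_fa(X, 1)
        z = model.scores(X)
        assert z.shape == (1, 900)
        assert z.mean() == pytest.approx(0.0, abs=1e-10)
        # posterior-mean scores track the dominant shared fluctuation
        proj = gamma[:, 0] @ (X - X.mean(axis=1, keepdims=True))
        assert abs(np.corrcoef(z[0], proj)[0, 1]) > 0.95


class TestTrialShuffle:
    def _data(self, n_units=4, n_trials=6, seg=10, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n_units, n_trials * seg))
        tmap = np.repeat(np.arange(n_trials), seg)
        return X, tmap, rng

    def test_single_trial_unchanged(self):
        X, _, rng = self._data(n_trials=1)
        tmap = np.zeros(10, dtype=int)
        np.testing.assert_array_equal(trial_shuffle(X, tmap, rng), X)

    def test_marginals_preserved_exactly_with_equal_segments(self):
        X, tmap, rng = self._data()
        Xs = trial_shuffle(X, tmap, rng)
        for i in range(X.shape[0]):
            np.testing.assert_array_equal(np.sort(Xs[i]), np.sort(X[i]))

    def test_within_trial_autocorrelation_bit_identical(self):
        X, tmap, rng = self._data(seed=5)
        Xs = trial_shuffle(X, tmap, rng)
        def seg_acorr(row):
            return {
                tuple(np.round(row[tmap == t], 12)) for t in np.unique(tmap)
            }
        for i in range(X.shape[0]):
            assert seg_acorr(Xs[i]) == seg_acorr(X[i])  # same segment contents

    def test_cross_unit_correlation_destroyed(self):
        rng = np.random.default_rng(6)
        shared = rng.normal(size=20 * 40)
        X = np.vstack([shared + 0.3 * rng.normal(size=shared.size)
                       for _ in range(3)])
        tmap = np.repeat(np.arange(40), 20)
        Xs = trial_shuffle(X, tmap, rng)
        r_before = np.corrcoef(X[0], X[1])[0, 1]
        r_after = np.corrcoef(Xs[0], Xs[1])[0, 1]
        assert r_before > 0.8
        assert abs(r_after) < 0.15


class TestFactorCount:
    def test_pure_noise_selects_zero_factors(self):
        hits = 0
        for seed in range(8):
            rng = np.random.default_rng(seed)
            X = rng.normal(2.0, 1.0, size=(10, 1200))
            tmap = np.repeat(np.arange(30), 40)
            p = asm.select_n_factors(X, tmap, 3, n_boot=40,
                                     rng=np.random.default_rng(seed + 100))
            hits += p == 0
        assert hits >= 7

    def test_planted_factors_counted(self):
        rng = np.random.default_rng(7)
        gamma = np.zeros((12, 2))
        gamma[:4, 0] = 1.5
        gamma[4:8, 1] = 1.5
        # shared latent constant within 10-bin blocks (trial-level structure
        # is what the trial shuffle destroys)
        n_trials, seg = 60, 10
        z = np.repeat(rng.standard_normal((2, n_trials)), seg, axis=1)
        X = gamma @ z + rng.standard_normal((12, n_trials * seg))
        tmap = np.repeat(np.arange(n_trials), seg)
        p = asm.select_n_factors(X, tmap, 4, n_boot=60,
                                 rng=np.random.default_rng(8))
        assert p == 2

    def test_low_boot_count_warns(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(6, 300))
        tmap = np.repeat(np.arange(10), 30)
        with pytest.warns(UserWarning, match="coarse"):
            asm.select_n_factors(X, tmap, 2, n_boot=10,
                                 rng=np.random.default_rng(10))


class TestLoadingsAndAssemble:
    def test_degenerate_bootstrap_flags_all_with_warning(self):
        rng = np.random.default_rng(0)
        gamma = np.ones((6, 1))
        X = simulate_fa_data(rng, gamma, np.ones(6), 500)
        model = fit_fa(X, 1)
        with pytest.warns(UserWarning, match="degenerate"):
            mask = significant_loadings(model, np.zeros((10, 6, 1)))
        assert mask.all()

    def test_sign_convention_largest_member_positive(self):
        rng = np.random.default_rng(1)
        gamma = -np.ones((6, 1)) * rng.uniform(0.5, 1.5, 6)[:, None]
        X = simulate_fa_data(rng, gamma, np.ones(6), 2000)
        model = fit_fa(X, 1)
        asm.align_factor_signs(model)
        i = int(np.argmax(np.abs(model.loadings[:, 0])))
        assert model.loadings[i, 0] > 0

    def test_assemble_types_and_merge(self):
        areas = {"c1": "dCA1", "c2": "dCA1", "m1": "mPFC", "m2": "mPFC"}
        uids = ["c1", "c2", "m1", "m2"]
        # factor 0: inter {c1, c2, m1}; factor 1: within subset {c1, c2};
        # factor 2: singleton -> dropped
        mask = np.array(
            [[1, 1, 0], [1, 1, 0], [1, 0, 0], [0, 0, 1]], dtype=bool
        )
        out = assemble(mask, uids, areas)
        assert len(out) == 1
        a = out[0]
        assert a.kind == "inter-area"
        assert set(a.member_units) == {"c1", "c2", "m1"}
        assert a.merged_factors == [1]

    def test_within_mpfc_kind(self):
        areas = {"m1": "mPFC", "m2": "mPFC"}
        mask = np.ones((2, 1), dtype=bool)
        out = assemble(mask, ["m1", "m2"], areas)
        assert out[0].kind == "within-mPFC"


class TestActivationSignificance:
    def test_alpha_one_flags_everything(self):
        rng = np.random.default_rng(2)
        gamma = np.ones((6, 1))
        X = simulate_fa_data(rng, gamma, np.ones(6), 600)
        tmap = np.repeat(np.arange(20), 30)
        model = fit_fa(X, 1)
        mask = asm.activation_significance(model, X, tmap, alpha=1.0 - 1e-12,
                                           n_boot=10,
                                           rng=np.random.default_rng(3))
        assert mask.mean() > 0.95

    def test_shuffled_input_flag_rate_near_alpha(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(8, 1500))
        tmap = np.repeat(np.arange(30), 50)
        model = fit_fa(X, 1, ridge=0.01)
        mask = asm.activation_significance(model, X, tmap, alpha=0.05,
                                           n_boot=30,
                                           rng=np.random.default_rng(5))
        assert abs(mask.mean() - 0.05) < 0.05


class TestICA:
    def test_planted_assembly_detected_with_members(self):
        rng = np.random.default_rng(6)
        n, m = 12, 4000
        shared = rng.standard_normal(m)
        X = rng.standard_normal((n, m))
        members = [1, 4, 7, 9]
        for i in members:
            X[i] += 1.2 * shared
        uids = [f"u{i}" for i in range(n)]
        areas = {f"u{i}": ("dCA1" if i < 6 else "mPFC") for i in range(n)}
        out = ica_assemblies(X, uids, areas, seed=0)
        assert len(out) == 1
        assert set(out[0].member_units) == {f"u{i}" for i in members}
        assert out[0].kind == "inter-area"

    def test_independent_units_give_empty_list(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((10, 4000))
        uids = [f"u{i}" for i in range(10)]
        areas = {u: "dCA1" for u in uids}
        assert ica_assemblies(X, uids, areas, seed=0) == []

    def test_mp_bound_value(self):
        assert marchenko_pastur_bound(100, 10000) == pytest.approx(
            (1 + 0.1) ** 2
        )


class TestOverlap:
    def test_identities(self):
        assert overlap({1, 2, 3}, {1, 2, 3}) == 1.0
        assert overlap({1, 2}, {3, 4}) == 0.0
        assert overlap({1, 2, 3}, {2, 3, 4}) == pytest.approx(0.5)

    def test_match_overlap_best_pairs(self):
        a = [Assembly("a0", ["1", "2", "3"], 0, "within-dCA1")]
        b = [Assembly("b0", ["2", "3", "4"], 0, "within-dCA1")]
        assert match_overlap(a, b) == pytest.approx(0.5)
        assert match_overlap(a, a) == 1.0


class TestVarimax:
    def test_recovers_sparse_structure_after_rotation(self):
        rng = np.random.default_rng(8)
        L = np.zeros((10, 2))
        L[:5, 0] = rng.uniform(1, 2, 5)
        L[5:, 1] = rng.uniform(1, 2, 5)
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        back = varimax(L @ R)
        # same sparse pattern up to column order/sign
        patt = np.abs(back) > 0.5
        expected = np.abs(L) > 0.5
        assert (
            np.array_equal(patt, expected)
            or np.array_equal(patt, expected[:, ::-1])
        )


class TestSyntheticAssemblyCurve:
    def _tensor(self, rng, n_per=10, n_units=8, n_bins=6):
        from assemblage.core import AlignedRateTensor

        x = rng.normal(5, 1, size=(2 * n_per, n_units, n_bins))
        # units 0..3 carry graded signal, 4..7 none
        for i, d in enumerate([2.0, 1.5, 1.0, 0.5]):
            x[:n_per, i, 3] += d
        lab = np.array(["L"] * n_per + ["R"] * n_per)
        tens = AlignedRateTensor(
            rates=x - x.min(),
            times=0.05 * np.arange(n_bins),
            bin_s=0.05,
            align_event="sample",
            unit_ids=[f"u{i}" for i in range(n_units)],
            trial_indices=list(range(2 * n_per)),
            areas=["dCA1"] * (n_units // 2) + ["mPFC"] * (n_units // 2),
        )
        return tens, lab

    def test_rank1_units_lead_ranking(self):
        rng = np.random.default_rng(9)
        tens, lab = self._tensor(rng)
        curve = asm.synthetic_assembly_curve(tens, lab, sizes=(2, 4),
                                             ranks=(1, 2))
        ranked = curve.attrs["ranked_units"]
        assert set(ranked[:2]) <= {"u0", "u1", "u2"}
        # rank-1 blocks outperform rank-2 blocks on average
        by = curve.groupby("rank")["peak_cp"].mean()
        assert by[1] >= by[2]

    def test_blocks_beyond_pool_omitted(self):
        rng = np.random.default_rng(10)
        tens, lab = self._tensor(rng)
        curve = asm.synthetic_assembly_curve(tens, lab, sizes=(5,),
                                             ranks=(1, 2))
        assert set(curve["rank"]) == {1}  # 2nd block of 5 exceeds 8 units

    def test_noise_shuffle_preserves_signal_for_independent_units(self):
        from assemblage.decoding import loocv_decode

        rng = np.random.default_rng(11)
        tens, lab = self._tensor(rng, n_per=12)
        base = loocv_decode(tens, lab).cp
        shuf = asm.noise_shuffle_decoding(tens, lab, n_perm=10,
                                          mode="within-area",
                                          rng=np.random.default_rng(12))
        assert np.abs(shuf - base).mean() < 0.1


def test_assembly_rank_assignment_matches_closest_block():
    import pandas as pd

    curve = pd.DataFrame(
        {"size": [4, 4, 4], "rank": [1, 2, 3], "peak_cp": [0.9, 0.75, 0.6]}
    )
    assert asm.assign_assembly_rank(0.88, 4, curve) == 1
    assert asm.assign_assembly_rank(0.62, 4, curve) == 3
    with pytest.raises(ValueError):
        asm.assign_assembly_rank(0.8, 7, curve)


try:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        a=st.sets(st.integers(0, 30), max_size=12),
        b=st.sets(st.integers(0, 30), max_size=12),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_overlap_is_a_bounded_symmetric_similarity(a, b):
        o = overlap(a, b)
        assert 0.0 <= o <= 1.0
        assert o == overlap(b, a)
        assert overlap(a, a) == 1.0
        if a and b and not (a & b):
            assert o == 0.0
except ImportError:  # pragma: no cover - hypothesis is an optional extra
    pass
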