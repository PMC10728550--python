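"""Planted-truth validation benchmarks.

Each function simulates sessions with known ground truth, runs the
corresponding analysis stage, and returns plain-number summaries: analytic
identities, estimator cross-checks, null calibrations, and recovery of
planted assemblies, codes, and rhythms.  These back the acceptance checks
and give users a one-call health report of the whole pipeline on data where
the right answer is known.

Problem sizes are deliberately desk-scale (tens of units, tens of trials
per condition); the statistics are chosen so the expected outcome is stable
at that scale.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import assembly as asm
from . import rhythm as rhy
from .core import AlignedRateTensor, select_units
from .cross_temporal import cross_temporal_decode, ct_significance
from .decoding import hotelling_t2, loocv_decode, train_correct_test_error
from .rates import build_rate_tensor, cv_error_grid
from .single_unit import TScoreProfile, coding_distance
from .synthetic import AssemblySpec, GeneratorConfig, generate_session


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def _labels(trials) -> np.ndarray:
    return np.asarray([t.cue_side for t in trials])


def _tensor(session, trials, window, bandwidth, area=None, stride=1):
    bw = {u.unit_id: bandwidth for u in session.units}
    tens = build_rate_tensor(session, "sample", window, 0.05, bw, trials)
    if area is not None:
        tens = tens.subset_units(
            [i for i, a in enumerate(tens.areas) if a == area]
        )
    if stride > 1:
        tens = AlignedRateTensor(
            rates=tens.rates[:, :, ::stride],
            times=tens.times[::stride],
            bin_s=tens.bin_s * stride,
            align_event=tens.align_event,
            unit_ids=tens.unit_ids,
            trial_indices=tens.trial_indices,
            areas=tens.areas,
        )
    return tens


# ---------------------------------------------------------------------------
# 1. analytic t criterion


def analytic_t_criterion(n_trials: int = 54) -> float:
    """Upper-tail p < 0.05 two-sample t criterion at the given trial count."""
    from scipy.stats import t as tdist

    return float(tdist.ppf(0.95, n_trials - 2))


# ---------------------------------------------------------------------------
# 2. closed-form CVE vs numerical oracle


def kde_cve_max_rel_error(n_trains: int = 20, seed: int = 0) -> float:
    """Max relative disagreement between the closed-form CV error and a
    numerical quadrature + explicit leave-one-out oracle."""
    from scipy.stats import norm

    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_trains):
        n = int(rng.integers(20, 201))
        x = np.sort(rng.uniform(0, 20, n))
        for h in (0.05, 0.3, 1.0):
            grid = np.arange(x.min() - 10 * h, x.max() + 10 * h, h / 100)
            fhat = norm.pdf(grid[:, None], x[None, :], h).sum(axis=1) / n
            integral = np.trapezoid(fhat**2, grid)
            loo = sum(
                norm.pdf(x[i], np.delete(x, i), h).sum() / (n - 1)
                for i in range(n)
            )
            oracle = integral - 2 * loo / n
            cf = cv_error_grid(x, np.array([h]))[0]
            worst = max(worst, abs(cf - oracle) / abs(oracle))
    return worst


# ---------------------------------------------------------------------------
# 3. null decoder calibration


def null_decoder_calibration(
    n_sessions: int = 100, n_shuffle: int = 400, seed: int = 0
) -> dict:
    """LOOCV decoding of sessions with no planted cue signal.

    Returns the mean CP across sessions and bins, the 95% binomial chance
    band at the per-session trial count, and the fraction of bins flagged
    significant against the Bonferroni-corrected label-shuffle null.
    """
    seeds = _child_seeds(seed, n_sessions)
    mean_cps = []
    flagged = 0
    total_bins = 0
    n_trials = 48
    for s_ in seeds:
        cfg = GeneratorConfig(
            n_units_dca1=5, n_units_mpfc=5, trials_per_delay=n_trials,
            delays_s=(4.0,), dca1_tuned_frac=0, mpfc_tuned_frac=0,
            mpfc_tiling_frac=0, assemblies=(), rhythm_m=0.0, error_frac=0,
            seed=s_,
        )
        session, _ = generate_session(cfg)
        session = select_units(session)
        trials = session.completed_trials()
        tens = _tensor(session, trials, (0.3, 0.3), 0.1)
        res = loocv_decode(
            tens, _labels(trials), n_shuffle=n_shuffle,
            rng=np.random.default_rng(s_ + 1),
        )
        mean_cps.append(float(res.cp.mean()))
        flagged += int(res.sig_mask.sum())
        total_bins += res.cp.size
    return {
        "mean_cp": float(np.mean(mean_cps)),
        "chance_band": float(1.96 * np.sqrt(0.25 / n_trials)),
        "sig_bin_fraction": flagged / total_bins,
    }


# ---------------------------------------------------------------------------
# 4 & 5. FA assembly recovery and FA-ICA agreement


def _fa_session_cfg(seed: int) -> GeneratorConfig:
    return GeneratorConfig(
        n_units_dca1=12, n_units_mpfc=12, trials_per_delay=50,
        delays_s=(4.0, 8.0, 16.0),
        assemblies=(
            AssemblySpec("inter", 6),
            AssemblySpec("inter", 6),
            AssemblySpec("within-dCA1", 4),
        ),
        seed=seed,
    )


def _detect_fa(session, n_boot, rng, max_p=5):
    X, owners, uids = asm.build_fa_input(session, "joint")
    groups = asm.shuffle_groups(session)
    p = asm.select_n_factors(X, owners, max_p, n_boot=n_boot, rng=rng,
                             groups=groups)
    if p == 0:
        return p, [], (X, owners, uids)
    model = asm.fit_fa(X, p, ridge=asm.DEFAULT_RIDGE)
    boot = asm.bootstrap_loadings(X, owners, p, n_boot, rng, groups=groups,
                                  ridge=asm.DEFAULT_RIDGE)
    mask = asm.significant_loadings(model, boot)
    areas = {u.unit_id: u.area for u in session.units}
    return p, asm.assemble(mask, uids, areas), (X, owners, uids)


def fa_recovery(n_seeds: int = 20, n_boot: int = 100, seed: int = 0) -> dict:
    """Recovery of 2 inter-area + 1 within-area planted assemblies.

    A seed counts as a success when the selected factor count equals the
    planted count and every planted assembly is matched with Jaccard >= 0.9.
    """
    seeds = _child_seeds(seed, n_seeds)
    successes = 0
    count_correct = 0
    jaccards = []
    for s_ in seeds:
        cfg = _fa_session_cfg(s_)
        session, truth = generate_session(cfg)
        session = select_units(session)
        rng = np.random.default_rng(s_ + 7)
        p, assemblies, _ = _detect_fa(session, n_boot, rng)
        truth_sets = [set(m) for m in truth.assembly_members]
        js = [
            max(
                (asm.overlap(a.member_units, t) for a in assemblies),
                default=0.0,
            )
            for t in truth_sets
        ]
        jaccards.append(min(js))
        count_ok = p == len(truth_sets)
        count_correct += count_ok
        successes += count_ok and min(js) >= 0.9
    return {
        "success_fraction": successes / n_seeds,
        "count_correct_fraction": count_correct / n_seeds,
        "median_min_jaccard": float(np.median(jaccards)),
    }


def fa_ica_overlap(n_seeds: int = 3, n_boot: int = 100, seed: int = 0) -> float:
    """Mean best-pair Jaccard overlap between ICA and FA assembly sets."""
    seeds = _child_seeds(seed, n_seeds)
    scores = []
    for s_ in seeds:
        cfg = _fa_session_cfg(s_)
        session, _ = generate_session(cfg)
        session = select_units(session)
        rng = np.random.default_rng(s_ + 13)
        _, fa_set, _ = _detect_fa(session, n_boot, rng)
        Xc, _, uids = asm.build_count_input(session)
        areas = {u.unit_id: u.area for u in session.units}
        ica_set = asm.ica_assemblies(Xc, uids, areas, seed=s_ % (2**31))
        if fa_set and ica_set:
            scores.append(asm.match_overlap(fa_set, ica_set))
    return float(np.mean(scores)) if scores else float("nan")


# ---------------------------------------------------------------------------
# 6. cross-temporal code signatures


def cross_temporal_signature(
    n_resamples: int = 100, n_boot: int = 100, seed: int = 0
) -> dict:
    """Stable vs sequential planted delay codes in the train x test grid.

    A sustained side-selective rate (stable code) should produce significant
    decoding far off the diagonal; a sequence of short side-selective bumps
    (dynamic code) should confine significance near the diagonal.
    """
    out = {}
    s_stable, s_seq = _child_seeds(seed, 2)
    for kind, s_ in (("stable", s_stable), ("sequential", s_seq)):
        if kind == "stable":
            cfg = GeneratorConfig(
                n_units_dca1=10, n_units_mpfc=10, trials_per_delay=24,
                delays_s=(4.0,), dca1_tuned_frac=0.7, dca1_tuning_amp=1.2,
                tuning_width_s=3.0, mpfc_tuned_frac=0.0, mpfc_tiling_frac=0.0,
                assemblies=(), error_frac=0.0, seed=s_,
            )
            area = "dCA1"
        else:
            cfg = GeneratorConfig(
                n_units_dca1=10, n_units_mpfc=10, trials_per_delay=24,
                delays_s=(4.0,), dca1_tuned_frac=0.0, mpfc_tuned_frac=0.0,
                mpfc_tiling_frac=0.8, mpfc_tuning_amp=1.5, tiling_width_s=0.5,
                assemblies=(), error_frac=0.0, seed=s_,
            )
            area = "mPFC"
        session, _ = generate_session(cfg)
        session = select_units(session)
        trials = session.completed_trials()
        tens = _tensor(session, trials, (0.5, 4.0), 0.15, area=area, stride=2)
        lab = _labels(trials)
        rng = np.random.default_rng(s_ + 1)
        mat = cross_temporal_decode(tens, lab, n_resamples=n_resamples, rng=rng)
        sig = ct_significance(mat, tens, lab, n_boot=n_boot,
                              n_resamples_null=10, rng=rng)
        dt = np.abs(np.subtract.outer(mat.train_times, mat.test_times))
        out[f"{kind}_far_sig_fraction"] = float(sig[dt > 1.5].mean())
        out[f"{kind}_near_sig_fraction"] = float(sig[dt <= 0.3].mean())
    return out


# ---------------------------------------------------------------------------
# 7. rhythm detection


def _rhythm_session(seed: int, trials_per_delay: int = 50):
    cfg = GeneratorConfig(
        n_units_dca1=6, n_units_mpfc=6, trials_per_delay=trials_per_delay,
        delays_s=(4.0,), dca1_tuned_frac=0.3, mpfc_tuned_frac=0.1,
        mpfc_tiling_frac=0.3, baseline_median_hz=3.0,
        assemblies=(AssemblySpec("inter", 6),), error_frac=0.0, seed=seed,
    )
    return generate_session(cfg)


def _avg_member_ccg(session, truth, event_times, rng, n_draws=10):
    members = set(truth.assembly_members[0])
    ca1 = [u for u in session.units_in("dCA1") if u.unit_id in members]
    pfc = [u for u in session.units_in("mPFC") if u.unit_id in members]
    vals = []
    lags = None
    for uc in ca1:
        for um in pfc:
            c = rhy.crosscorrelogram(uc.spike_times, um.spike_times,
                                     event_times, n_draws=n_draws, rng=rng)
            if c is not None:
                vals.append(c.values / np.nanmean(c.values))
                lags = c.lags
    if not vals:
        return None
    return rhy.Correlogram(lags, np.mean(vals, axis=0), 0.02, kind="cross")


def _ccg_peak_in_band(ccg, band=(3.5, 5.5), search=(2.0, 8.0)):
    freqs, power = rhy.ccg_spectrum(ccg)
    win = (freqs >= search[0]) & (freqs <= search[1])
    pk = freqs[win][int(np.argmax(power[win]))]
    return bool(band[0] <= pk <= band[1])


def rhythm_detection(n_seeds: int = 20, seed: int = 0) -> dict:
    """Planted 4-5 Hz pre-sample co-modulation of inter-area members.

    Per seed: same-assembly inter-area pairs should carry more 3.5-5.5 Hz
    coherence than non-member pairs, and the member-pair cross-correlogram
    power spectrum should peak in-band before the sample press but not
    before the choice press (where no rhythm is planted).
    """
    seeds = _child_seeds(seed, n_seeds)
    coh_wins = 0
    peak_sample = 0
    peak_choice = 0
    for s_ in seeds:
        session, truth = _rhythm_session(s_)
        members = set(truth.assembly_members[0])
        sample_times = np.array([t.t_sample for t in session.trials])
        choice_times = np.array([t.t_choice for t in session.trials])
        epochs = [(t - 4.0, t) for t in sample_times]
        memb, non = [], []
        for uc in session.units_in("dCA1"):
            for um in session.units_in("mPFC"):
                same = uc.unit_id in members and um.unit_id in members
                both_out = (
                    uc.unit_id not in members and um.unit_id not in members
                )
                if not (same or both_out):
                    continue
                _, _, band = rhy.pair_coherence(
                    uc.spike_times, um.spike_times, epochs
                )
                (memb if same else non).append(band)
        coh_wins += np.mean(memb) > np.mean(non)
        rng = np.random.default_rng(s_ + 3)
        ccg_s = _avg_member_ccg(session, truth, sample_times, rng)
        ccg_c = _avg_member_ccg(session, truth, choice_times, rng)
        peak_sample += _ccg_peak_in_band(ccg_s)
        peak_choice += _ccg_peak_in_band(ccg_c)
    return {
        "coherence_member_win_fraction": coh_wins / n_seeds,
        "presample_ccg_peak_inband_fraction": peak_sample / n_seeds,
        "prechoice_ccg_peak_inband_fraction": peak_choice / n_seeds,
    }


# ---------------------------------------------------------------------------
# 8. error-trial machinery


def error_trial_checks(n_sessions: int = 5, seed: int = 0) -> dict:
    """Planted mPFC delay attenuation and rhythm attenuation on error trials.

    Per session: decoders trained on correct trials must lose significant
    accuracy on error trials during the delay for mPFC but not for dCA1
    around the sample press, and the member-pair CCG 3.5-5.5 Hz band power
    (relative to flanking bands) must drop on error trials pre-sample.
    """
    seeds = _child_seeds(seed, n_sessions)
    mpfc_drop = 0
    dca1_clean = 0
    ccg_drop = 0
    for s_ in seeds:
        cfg = GeneratorConfig(
            n_units_dca1=10, n_units_mpfc=10, trials_per_delay=80,
            delays_s=(8.0,), mpfc_tiling_frac=0.6, mpfc_tuning_amp=1.2,
            error_frac=0.3, baseline_median_hz=3.0,
            assemblies=(AssemblySpec("inter", 6),), seed=s_,
        )
        session, truth = generate_session(cfg)
        session = select_units(session)
        correct = [t for t in session.completed_trials() if t.outcome == "correct"]
        errors = [t for t in session.completed_trials() if t.outcome == "error"]
        lab_c, lab_e = _labels(correct), _labels(errors)
        rng = np.random.default_rng(s_ + 5)
        err_m, _ = train_correct_test_error(
            _tensor(session, correct, (0.0, 8.0), 0.2, "mPFC", stride=8),
            _tensor(session, errors, (0.0, 8.0), 0.2, "mPFC", stride=8),
            lab_c, lab_e, n_perm=400, rng=rng,
        )
        err_c, _ = train_correct_test_error(
            _tensor(session, correct, (1.0, 1.0), 0.2, "dCA1", stride=4),
            _tensor(session, errors, (1.0, 1.0), 0.2, "dCA1", stride=4),
            lab_c, lab_e, n_perm=400, rng=rng,
        )
        mpfc_drop += err_m.window_p < 0.05
        dca1_clean += err_c.window_p >= 0.05

        def band_ratio(trials):
            ev = np.array([t.t_sample for t in trials])
            ccg = _avg_member_ccg(session, truth, ev, rng)
            freqs, power = rhy.ccg_spectrum(ccg)
            band = (freqs >= 3.5) & (freqs <= 5.5)
            flank = ((freqs >= 2.0) & (freqs < 3.5)) | (
                (freqs > 5.5) & (freqs <= 8.0)
            )
            return power[band].mean() / power[flank].mean()

        ccg_drop += band_ratio(correct) > band_ratio(errors)
    return {
        "mpfc_delay_drop_fraction": mpfc_drop / n_sessions,
        "dca1_no_drop_fraction": dca1_clean / n_sessions,
        "ccg_band_drop_fraction": ccg_drop / n_sessions,
    }


# ---------------------------------------------------------------------------
# 9. algebraic identities


def identity_checks(seed: int = 0) -> dict:
    """Small algebraic identities: 1-D Hotelling vs t^2, overlap, distance."""
    from scipy.stats import ttest_ind

    rng = np.random.default_rng(seed)
    xl = rng.normal(0, 1, (15, 1))
    xr = rng.normal(1, 1, (12, 1))
    t = ttest_ind(xl[:, 0], xr[:, 0]).statistic
    t2, _ = hotelling_t2(xl, xr, lam=0.0)
    prof = TScoreProfile("a", np.arange(6) * 0.05,
                         np.array([1.0, -2.0, 0.5, 3.0, -1.0, 0.25]))
    prof_off = TScoreProfile("b", prof.times, prof.t + 4.2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cd = coding_distance(prof, prof_off)
    return {
        "hotelling_1d_rel_err": abs(t2 - t * t) / (t * t),
        "overlap_self": asm.overlap({1, 2, 3}, {1, 2, 3}),
        "overlap_disjoint": asm.overlap({1, 2}, {3, 4}),
        "coding_distance_offset_pair": cd,
    }
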