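"""Rhythmic spike-pair physiology and assembly dynamics.

The 4-5 Hz co-modulation that couples dCA1 and mPFC assembly members in the
pre-sample epoch is measured from spike times directly: rate-normalized
autocorrelograms and their band-power modulation index, multitaper coherence
of 10-ms binned counts between pairs, rate-matched cross-correlograms
(positive lag = dCA1 reference spike precedes the mPFC spike), CCG power
spectra with correct-vs-error permutation contrasts, lead/lag balance, and
LFP spike-phase locking (mean resultant length + Rayleigh test).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal, stats


@dataclass
class Correlogram:
    lags: np.ndarray  # bin centres, s
    values: np.ndarray
    bin_s: float
    kind: str = "auto"  # "auto" | "cross"
    n_draws: int = 0
    low_confidence: bool = False


@dataclass
class PhaseLocking:
    unit_id: str
    band_hz: tuple[float, float]
    mrl: float
    rayleigh_p: float
    preferred_phase: float
    n_spikes: int


def _lag_edges(max_lag: float, bin_s: float) -> np.ndarray:
    n = int(round(max_lag / bin_s))
    return bin_s * np.arange(-n, n + 1)


def _window_spikes(spikes: np.ndarray, t0: float, t1: float) -> np.ndarray:
    a, b = np.searchsorted(spikes, (t0, t1))
    return spikes[a:b]


def autocorrelogram(
    spikes: np.ndarray,
    bin_s: float = 0.02,
    max_lag: float = 1.0,
    epochs: list[tuple[float, float]] | None = None,
) -> Correlogram:
    """Rate-normalized spike-time autocorrelogram.

    Coincidence counts at each lag (zero-lag self-pairs excluded) divided by
    the edge-corrected expectation for a homogeneous Poisson train of the
    same rate per epoch, so an unstructured train gives values near 1 and a
    4.5 Hz modulated train shows peaks at multiples of 1/4.5 s = 222 ms.
    """
    spikes = np.sort(np.asarray(spikes, float))
    if epochs is None:
        t1 = spikes[-1] if spikes.size else 0.0
        epochs = [(0.0, t1 + 1e-9)]
    edges = _lag_edges(max_lag, bin_s)
    centres = 0.5 * (edges[:-1] + edges[1:])
    counts = np.zeros(centres.size)
    expected = np.zeros(centres.size)
    total = 0
    for t0, t1 in epochs:
        s = _window_spikes(spikes, t0, t1)
        total += s.size
        dur = t1 - t0
        if s.size < 2 or dur <= 0:
            continue
        hi = np.searchsorted(s, s + max_lag, side="right")
        diffs = [s[i + 1 : hi[i]] - s[i] for i in range(s.size - 1) if hi[i] > i + 1]
        if diffs:
            d = np.concatenate(diffs)
            h, _ = np.histogram(d, bins=edges[edges.size // 2 :])
            counts[centres.size // 2 :] += h
        # homogeneous expectation with triangular edge correction
        pos = centres[centres > 0]
        expected[centres.size // 2 :] += (
            s.size * s.size / dur * bin_s * np.maximum(1.0 - pos / dur, 0.0)
        )
    # symmetrize
    half = counts[centres.size // 2 :]
    exp_half = expected[centres.size // 2 :]
    counts = np.concatenate([half[::-1], half])
    expected = np.concatenate([exp_half[::-1], exp_half])
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(expected > 0, counts / expected, np.nan)
    lc = total < 50
    if lc:
        warnings.warn("fewer than 50 spikes in epochs; low-confidence ACG")
    return Correlogram(centres, values, bin_s, kind="auto", low_confidence=lc)


def acg_modulation_index(
    acg: Correlogram,
    band_hz: tuple[float, float] = (3.5, 5.5),
    total_band_hz: tuple[float, float] = (1.0, 15.0),
    max_lag: float = 1.0,
) -> float:
    """Fraction of ACG spectral power (mean-removed, |lag| <= 1 s) in a band.

    A flat correlogram gives ~0; the index grows monotonically with the
    depth of a periodic modulation inside the band.  This band-power
    fraction definition is this package's own (several variants exist in
    the literature); an alternative peak-trough contrast is available as
    :func:`acg_peak_trough_index`.
    """
    keep = np.abs(acg.lags) <= max_lag
    v = acg.values[keep]
    v = np.nan_to_num(v - np.nanmean(v))
    freqs = np.fft.rfftfreq(v.size, acg.bin_s)
    power = np.abs(np.fft.rfft(v)) ** 2
    inband = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    intotal = (freqs >= total_band_hz[0]) & (freqs <= total_band_hz[1])
    tot = power[intotal].sum()
    if tot == 0:
        return 0.0
    num = power[inband & intotal].sum()
    return float(np.clip(num / tot, 0.0, 1.0))


def acg_peak_trough_index(
    acg: Correlogram, lag_range: tuple[float, float] = (0.15, 0.3)
) -> float:
    """(peak - trough) / (peak + trough) of the ACG over 150-300 ms lags."""
    keep = (np.abs(acg.lags) >= lag_range[0]) & (np.abs(acg.lags) <= lag_range[1])
    v = acg.values[keep]
    pk, tr = np.nanmax(v), np.nanmin(v)
    if pk + tr == 0:
        return 0.0
    return float((pk - tr) / (pk + tr))


def pair_coherence(
    spikes_a: np.ndarray,
    spikes_b: np.ndarray,
    epochs: list[tuple[float, float]],
    bin_s: float = 0.01,
    nw: float = 3.0,
    n_tapers: int = 5,
    band_hz: tuple[float, float] = (3.5, 5.5),
) -> tuple[np.ndarray, np.ndarray, float]:
    """Multitaper magnitude-squared coherence of binned spike counts.

    Counts in ``bin_s`` bins are mean-subtracted per epoch; DPSS-tapered
    spectra are averaged over tapers and epochs.  Returns (freqs,
    coherence, mean coherence over ``band_hz``).  The estimator floor is
    roughly 1/(tapers x epochs) for independent trains.
    """
    if not epochs:
        raise ValueError("need at least one epoch")
    n_bins = int(round(min(t1 - t0 for t0, t1 in epochs) / bin_s))
    if n_bins < 8:
        raise ValueError("epochs too short for a spectral estimate")
    tapers = signal.windows.dpss(n_bins, nw, Kmax=n_tapers)
    sxx = syy = sxy = 0.0
    for t0, _ in epochs:
        edges = t0 + bin_s * np.arange(n_bins + 1)
        xa, _ = np.histogram(spikes_a, bins=edges)
        xb, _ = np.histogram(spikes_b, bins=edges)
        xa = xa - xa.mean()
        xb = xb - xb.mean()
        fa = np.fft.rfft(tapers * xa, axis=1)
        fb = np.fft.rfft(tapers * xb, axis=1)
        sxx = sxx + (np.abs(fa) ** 2).sum(axis=0)
        syy = syy + (np.abs(fb) ** 2).sum(axis=0)
        sxy = sxy + (fa * np.conj(fb)).sum(axis=0)
    freqs = np.fft.rfftfreq(n_bins, bin_s)
    with np.errstate(divide="ignore", invalid="ignore"):
        coh = np.where(sxx * syy > 0, np.abs(sxy) ** 2 / (sxx * syy), 0.0)
    inband = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    return freqs, coh, float(coh[inband].mean())


def crosscorrelogram(
    spikes_ref: np.ndarray,
    spikes_tgt: np.ndarray,
    event_times: np.ndarray,
    window: tuple[float, float] = (-4.0, 0.0),
    bin_s: float = 0.02,
    max_lag: float = 1.0,
    n_draws: int = 100,
    rng: np.random.Generator | None = None,
) -> Correlogram | None:
    """Rate-matched cross-correlogram over event-aligned windows.

    Per draw and window, the higher-count train is randomly subsampled to
    the lower count so rate offsets between the cells cannot masquerade as
    correlation; coincidences of (target - reference) lags are tallied,
    averaged over draws, and divided by the per-draw total spike count.
    Positive lag means the reference (dCA1 by convention) spike comes first.
    Returns None when either train is empty in every window.
    """
    if rng is None:
        rng = np.random.default_rng()
    ref = np.sort(np.asarray(spikes_ref, float))
    tgt = np.sort(np.asarray(spikes_tgt, float))
    edges = _lag_edges(max_lag, bin_s)
    centres = 0.5 * (edges[:-1] + edges[1:])

    wins = []
    for ev in np.asarray(event_times, float):
        r = _window_spikes(ref, ev + window[0], ev + window[1])
        t = _window_spikes(tgt, ev + window[0], ev + window[1])
        if r.size and t.size:
            wins.append((r, t))
    if not wins:
        return None

    matched_total = sum(2 * min(r.size, t.size) for r, t in wins)
    acc = np.zeros(centres.size)
    for _ in range(n_draws):
        counts = np.zeros(centres.size)
        for r, t in wins:
            k = min(r.size, t.size)
            rs = r if r.size == k else np.sort(rng.choice(r, size=k, replace=False))
            ts = t if t.size == k else np.sort(rng.choice(t, size=k, replace=False))
            d = (ts[None, :] - rs[:, None]).ravel()
            d = d[np.abs(d) <= max_lag]
            h, _ = np.histogram(d, bins=edges)
            counts += h
        acc += counts
    values = acc / n_draws / matched_total
    return Correlogram(centres, values, bin_s, kind="cross", n_draws=n_draws)


def ccg_spectrum(ccg: Correlogram) -> tuple[np.ndarray, np.ndarray]:
    """Power spectrum of the mean-removed cross-correlogram."""
    v = np.nan_to_num(ccg.values - np.nanmean(ccg.values))
    freqs = np.fft.rfftfreq(v.size, ccg.bin_s)
    return freqs, np.abs(np.fft.rfft(v)) ** 2


def ccg_band_contrast(
    spectra_a: np.ndarray,
    spectra_b: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-frequency paired permutation test between two conditions.

    ``spectra_a``/``spectra_b`` are (n_pairs, n_freqs) CCG power spectra of
    the same cell pairs under two conditions; the null flips each pair's
    condition assignment at random.  Bonferroni over frequencies; returns a
    boolean mask of frequencies with a significant change.
    """
    if rng is None:
        rng = np.random.default_rng()
    diff = spectra_a - spectra_b
    obs = diff.mean(axis=0)
    n_pairs, n_freq = diff.shape
    null = np.empty((n_perm, n_freq))
    for p in range(n_perm):
        flip = rng.choice([-1.0, 1.0], size=n_pairs)
        null[p] = (diff * flip[:, None]).mean(axis=0)
    a = alpha / n_freq
    lo = np.quantile(null, a / 2, axis=0)
    hi = np.quantile(null, 1 - a / 2, axis=0)
    return (obs < lo) | (obs > hi)


def lead_lag_balance(ccg: Correlogram, max_lag: float = 1.0) -> float:
    """Signed asymmetry of CCG mass: positive = reference (dCA1) leads.

    (sum over positive lags - sum over negative lags) / total, in [-1, 1].
    """
    keep = np.abs(ccg.lags) <= max_lag
    v = np.nan_to_num(ccg.values[keep])
    lags = ccg.lags[keep]
    eps = 0.25 * ccg.bin_s  # a bin centred exactly on zero is neither side
    pos = v[lags > eps].sum()
    neg = v[lags < -eps].sum()
    tot = v.sum()
    if tot == 0:
        return 0.0
    return float((pos - neg) / tot)


def lead_lag_contrast(balance_a: np.ndarray, balance_b: np.ndarray) -> tuple[float, float]:
    """Paired t test of lead/lag balance across pairs between conditions."""
    t, p = stats.ttest_rel(balance_a, balance_b)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# Assembly activation dynamics


def classify_assembly_phase(
    activation: np.ndarray,
    bin_times: np.ndarray,
    trials,
    window_s: float = 4.0,
    bin_s: float = 0.05,
    sig_mask: np.ndarray | None = None,
) -> str:
    """Sample-active vs choice-active classification of one assembly.

    The activation series (over concatenated task-epoch bins whose session
    times are ``bin_times``) is trial-averaged in the ``window_s`` preceding
    the sample press and the choice press; the class is the window holding
    the global peak of the averaged activation (ties go to sample).  With a
    significance mask supplied, an assembly with no significant pre-press
    activation is classified "none".
    """
    n_rel = int(round(window_s / bin_s))
    prof = {"sample": np.zeros(n_rel), "choice": np.zeros(n_rel)}
    cnt = {"sample": 0, "choice": 0}
    any_sig = False
    for tr in trials:
        if not tr.completed:
            continue
        for name, ev in (("sample", tr.t_sample), ("choice", tr.t_choice)):
            sel = (bin_times >= ev - window_s) & (bin_times < ev)
            if sel.sum() != n_rel:
                continue
            prof[name] += activation[sel]
            cnt[name] += 1
            if sig_mask is not None and np.any(sig_mask[sel]):
                any_sig = True
    if sig_mask is not None and not any_sig:
        return "none"
    for name in prof:
        if cnt[name]:
            prof[name] /= cnt[name]
    pk_s = prof["sample"].max() if cnt["sample"] else -np.inf
    pk_c = prof["choice"].max() if cnt["choice"] else -np.inf
    return "sample-active" if pk_s >= pk_c else "choice-active"


def error_activation_contrast(
    activation_by_trial: np.ndarray,
    outcomes: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Time bins where error trials change the (z-scored) activation.

    ``activation_by_trial`` is trials x bins (event-aligned); per bin the
    correct-minus-error mean difference is tested against a permutation of
    the outcome labels, two-sided, Bonferroni over bins.
    """
    if rng is None:
        rng = np.random.default_rng()
    is_err = np.asarray(outcomes) == "error"
    if not is_err.any() or is_err.all():
        return np.zeros(activation_by_trial.shape[1], dtype=bool)
    a = activation_by_trial
    obs = a[~is_err].mean(axis=0) - a[is_err].mean(axis=0)
    n_bins = a.shape[1]
    null = np.empty((n_perm, n_bins))
    for p in range(n_perm):
        perm = rng.permutation(is_err)
        null[p] = a[~perm].mean(axis=0) - a[perm].mean(axis=0)
    al = alpha / n_bins
    lo = np.quantile(null, al / 2, axis=0)
    hi = np.quantile(null, 1 - al / 2, axis=0)
    return (obs < lo) | (obs > hi)


# ---------------------------------------------------------------------------
# LFP phase locking


def spike_phase_locking(
    spike_times: np.ndarray,
    lfp: np.ndarray,
    fs_hz: float,
    band_hz: tuple[float, float],
    unit_id: str = "",
    min_spikes: int = 50,
) -> PhaseLocking:
    """Mean resultant length and Rayleigh test of spike phases in a band.

    The LFP is zero-phase band-passed (4th-order Butterworth, filtfilt),
    the analytic-signal phase is interpolated at spike times (peak of the
    oscillation = phase 0), and circular concentration is summarized by the
    mean resultant length with Rayleigh's test of uniformity.
    """
    spike_times = np.asarray(spike_times, float)
    if spike_times.size < min_spikes:
        raise ValueError(f"need >= {min_spikes} spikes, have {spike_times.size}")
    nyq = fs_hz / 2.0
    b, a = signal.butter(4, [band_hz[0] / nyq, band_hz[1] / nyq], btype="band")
    filt = signal.filtfilt(b, a, lfp)
    if np.max(np.abs(filt)) < 1e-12 * max(np.max(np.abs(lfp)), 1e-300):
        raise ValueError("band has no power; spike phase undefined")
    analytic = signal.hilbert(filt)
    phase = np.unwrap(np.angle(analytic))
    t = np.arange(lfp.size) / fs_hz
    ph = np.mod(np.interp(spike_times, t, phase) + np.pi, 2 * np.pi) - np.pi
    vec = np.exp(1j * ph).mean()
    mrl = float(np.abs(vec))
    n = ph.size
    # Rayleigh test with small-sample correction
    r = n * mrl
    z = r * r / n
    pval = float(
        np.exp(np.sqrt(1 + 4 * n + 4 * (n * n - r * r)) - (1 + 2 * n))
    )
    return PhaseLocking(
        unit_id=unit_id,
        band_hz=tuple(band_hz),
        mrl=mrl,
        rayleigh_p=min(max(pval, 0.0), 1.0),
        preferred_phase=float(np.angle(vec)),
        n_spikes=n,
    )


def theta_to_low_ratio(
    spike_times: np.ndarray,
    lfp: np.ndarray,
    fs_hz: float,
    theta_band: tuple[float, float] = (8.0, 12.0),
    low_band: tuple[float, float] = (3.5, 5.5),
    alpha: float = 0.05,
    unit_id: str = "",
) -> float:
    """Theta-MRL / 4-5 Hz-MRL ratio for a unit locked in both bands.

    NaN when the unit fails the Rayleigh test in either band.
    """
    th = spike_phase_locking(spike_times, lfp, fs_hz, theta_band, unit_id)
    lo = spike_phase_locking(spike_times, lfp, fs_hz, low_band, unit_id)
    if th.rayleigh_p >= alpha or lo.rayleigh_p >= alpha or lo.mrl == 0:
        return float("nan")
    return th.mrl / lo.mrl
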