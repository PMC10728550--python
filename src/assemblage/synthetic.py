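"""Synthetic DNMTS sessions with planted ground truth.

The generator emulates the statistical structure of simultaneous dCA1/mPFC
recordings during delayed non-match to sample: 150 trials (50 at each of
4/8/16 s delays, equal left/right counts per delay, order shuffled in blocks
of 10), inhomogeneous-Poisson spike trains with

  rate_i(t) = baseline_i x cue-tuning bump x delay-tiling bump
              x assembly gain x rhythmic factor,

where the assembly gain is a shared binary on/off latent (a two-state Markov
chain at 50-ms steps) common to all members of a planted assembly, and the rhythmic factor
(1 + m cos(2 pi f t + phi)) at 4.5 Hz with a common per-trial phase applies
to inter-area assembly members in the 4 s before the sample press only.
dCA1 cue tuning is a Gaussian bump at the sample press; a subset of mPFC
units carries side-selective bumps whose centres tile the delay period.  On
error trials the mPFC delay tuning and the rhythm depth are attenuated
(rates, not labels, are degraded), while dCA1 sample coding is untouched.

Every generated feature is returned in a GroundTruth record so downstream
detectors can be scored against what was actually planted.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass


import numpy as np

from .core import Session, Trial, Unit

BIN_S = 0.05
RHYTHM_WINDOW_S = 4.0  # pre-sample epoch carrying the planted rhythm
EPOCH_PRE_S = 5.0
EPOCH_POST_S = 5.0


@dataclass
class AssemblySpec:
    """A planted assembly: type and member count (split evenly across areas
    when inter-area)."""

    kind: str  # "inter" | "within-dCA1" | "within-mPFC"
    size: int


@dataclass
class GeneratorConfig:
    n_units_dca1: int = 30
    n_units_mpfc: int = 30
    delays_s: tuple[float, ...] = (4.0, 8.0, 16.0)
    trials_per_delay: int = 50
    block_size: int = 10
    baseline_median_hz: float = 2.0
    baseline_sigma_log: float = 0.5
    # cue tuning
    dca1_tuned_frac: float = 0.5
    mpfc_tuned_frac: float = 0.2  # mPFC units with sample-locked cue bumps
    mpfc_tiling_frac: float = 0.5  # mPFC units tiling the delay
    dca1_tuning_amp: float = 1.0  # peak multiplicative gain above 1
    mpfc_tuning_amp: float = 0.8
    tuning_width_s: float = 0.6
    tiling_width_s: float = 0.8
    # planted assemblies
    assemblies: tuple[AssemblySpec, ...] = (
        AssemblySpec("inter", 6),
        AssemblySpec("inter", 6),
        AssemblySpec("within-dCA1", 4),
    )
    assembly_gain_amp: float = 3.0  # rate multiplier is 1 + amp while "on"
    assembly_on_prob: float = 0.3  # stationary probability of the on state
    assembly_gain_tau_s: float = 0.2  # dwell/correlation time of the latent
    # rhythm
    rhythm_f_hz: float = 4.5
    rhythm_m: float = 0.3
    # outcomes
    error_frac: float = 0.1
    miss_frac: float = 0.0
    error_attenuation_tuning: float = 0.25  # mPFC delay tuning on errors
    error_attenuation_rhythm: float = 0.25
    # latencies (log-normal medians, s)
    iti_median_s: float = 12.0
    iti_sigma_log: float = 0.1
    cue_to_sample_median_s: float = 1.5
    tone_to_nosepoke_median_s: float = 0.7
    nosepoke_to_choice_median_s: float = 1.2
    latency_sigma_log: float = 0.25
    seed: int = 0

    @property
    def n_trials(self) -> int:
        return self.trials_per_delay * len(self.delays_s)


@dataclass
class GroundTruth:
    assembly_members: list[list[str]]
    assembly_types: list[str]
    cue_tuned_units: dict[str, dict]
    tiling_units: dict[str, dict]
    rhythm_f_hz: float
    rhythm_m: float
    rhythm_window_s: float
    error_trials: list[int]
    error_attenuation_tuning: float
    error_attenuation_rhythm: float
    seed: int

    def to_dict(self) -> dict:
        return asdict(self)


def _lognormal(rng, median, sigma_log, size=None):
    return median * np.exp(sigma_log * rng.standard_normal(size))


def _trial_sequence(cfg: GeneratorConfig, rng: np.random.Generator):
    """Balanced (side, delay) tuples, order shuffled in blocks."""
    pool = []
    for d in cfg.delays_s:
        half = cfg.trials_per_delay // 2
        if 2 * half != cfg.trials_per_delay:
            raise ValueError("trials_per_delay must be even for L/R balance")
        pool += [("L", d)] * half + [("R", d)] * half
    pool = [pool[i] for i in rng.permutation(len(pool))]
    return pool


def _assign_outcomes(cfg: GeneratorConfig, seq, rng):
    """Outcome per trial with the requested error/miss counts per delay."""
    outcomes = ["correct"] * len(seq)
    for d in cfg.delays_s:
        ix = [i for i, (_, dd) in enumerate(seq) if dd == d]
        n_err = int(round(cfg.error_frac * len(ix)))
        n_miss = int(round(cfg.miss_frac * len(ix)))
        chosen = rng.choice(ix, size=n_err + n_miss, replace=False)
        for j in chosen[:n_err]:
            outcomes[j] = "error"
        for j in chosen[n_err:]:
            outcomes[j] = "miss"
    return outcomes


def _build_trials(cfg: GeneratorConfig, rng) -> list[Trial]:
    seq = _trial_sequence(cfg, rng)
    outcomes = _assign_outcomes(cfg, seq, rng)
    trials = []
    t = 20.0  # lead-in
    for k, ((side, delay), outc) in enumerate(zip(seq, outcomes)):
        t_cue = t
        t_sample = t_cue + _lognormal(rng, cfg.cue_to_sample_median_s, cfg.latency_sigma_log)
        t_tone = t_sample + delay
        if outc == "miss":
            trials.append(
                Trial(k, side, delay, "miss", t_cue, t_sample, t_tone)
            )
            t = t_tone + 10.0 + _lognormal(rng, cfg.iti_median_s, cfg.iti_sigma_log)
            continue
        t_nosepoke = t_tone + 0.5 + _lognormal(
            rng, cfg.tone_to_nosepoke_median_s, cfg.latency_sigma_log
        )
        t_choice = t_nosepoke + _lognormal(
            rng, cfg.nosepoke_to_choice_median_s, cfg.latency_sigma_log
        )
        t_reward = t_choice + 0.1 if outc == "correct" else None
        trials.append(
            Trial(k, side, delay, outc, t_cue, t_sample, t_tone, t_nosepoke,
                  t_choice, t_reward)
        )
        iti = _lognormal(rng, cfg.iti_median_s, cfg.iti_sigma_log)
        if outc == "error":
            iti += 10.0
        t = t_choice + iti
    return trials


def _plant_assemblies(cfg: GeneratorConfig, ids_dca1, ids_mpfc, rng, baselines=None):
    """Draw disjoint member sets for each configured assembly.

    Members are recruited among cells at or above the median baseline rate
    when ``baselines`` is given: detectable co-firing needs spikes, and in
    real recordings assembly membership likewise skews toward active cells.
    """

    def by_rate(ids):
        if baselines is None:
            return list(ids)
        return sorted(ids, key=lambda u: -baselines[u])

    # free pools sorted most-active first; draws favour the upper half
    free = {"dCA1": by_rate(ids_dca1), "mPFC": by_rate(ids_mpfc)}
    half = {a: max(1, len(v) // 2) for a, v in free.items()}

    def draw(area):
        pool = free[area]
        return pool.pop(rng.integers(min(len(pool), half[area])))
    members, types = [], []
    for spec in cfg.assemblies:
        if spec.kind == "inter":
            n_c = spec.size // 2
            n_m = spec.size - n_c
            if n_c > len(free["dCA1"]) or n_m > len(free["mPFC"]):
                raise ValueError("assembly larger than available unit pool")
            mc = [draw("dCA1") for _ in range(n_c)]
            mm = [draw("mPFC") for _ in range(n_m)]
            members.append(mc + mm)
            types.append("inter-area")
        else:
            area = spec.kind.split("-")[1]
            if spec.size > len(free[area]):
                raise ValueError("assembly larger than available unit pool")
            m = [draw(area) for _ in range(spec.size)]
            members.append(m)
            types.append(f"within-{area}")
    return members, types


def generate_session(cfg: GeneratorConfig) -> tuple[Session, GroundTruth]:
    """Simulate one DNMTS session; returns (session, planted ground truth)."""
    rng = np.random.default_rng(cfg.seed)
    trials = _build_trials(cfg, rng)
    duration = (trials[-1].t_choice or trials[-1].t_tone) + 20.0

    ids_dca1 = [f"c{i:03d}" for i in range(cfg.n_units_dca1)]
    ids_mpfc = [f"m{i:03d}" for i in range(cfg.n_units_mpfc)]
    all_ids = ids_dca1 + ids_mpfc
    areas = {u: ("dCA1" if u in set(ids_dca1) else "mPFC") for u in all_ids}
    baselines = {
        u: _lognormal(rng, cfg.baseline_median_hz, cfg.baseline_sigma_log)
        for u in all_ids
    }

    # --- cue tuning assignments
    cue_tuned: dict[str, dict] = {}
    n_tuned_c = int(round(cfg.dca1_tuned_frac * cfg.n_units_dca1))
    for u in list(rng.choice(ids_dca1, size=n_tuned_c, replace=False)):
        cue_tuned[str(u)] = {
            "side": ("L" if rng.random() < 0.5 else "R"),
            "amp": cfg.dca1_tuning_amp * (0.5 + rng.random()),
            "center_s": float(rng.uniform(-0.5, 0.5)),  # rel. sample press
            "width_s": cfg.tuning_width_s,
        }
    n_tuned_m = int(round(cfg.mpfc_tuned_frac * cfg.n_units_mpfc))
    tuned_m = list(rng.choice(ids_mpfc, size=n_tuned_m, replace=False))
    for u in tuned_m:
        cue_tuned[str(u)] = {
            "side": ("L" if rng.random() < 0.5 else "R"),
            "amp": cfg.mpfc_tuning_amp * (0.5 + rng.random()),
            "center_s": float(rng.uniform(-0.5, 0.5)),
            "width_s": cfg.tuning_width_s,
        }

    # --- mPFC delay-tiling units: centres spread over the delay fraction
    tiling: dict[str, dict] = {}
    pool_m = [u for u in ids_mpfc if u not in cue_tuned]
    n_tile = min(int(round(cfg.mpfc_tiling_frac * cfg.n_units_mpfc)), len(pool_m))
    tile_units = list(rng.choice(pool_m, size=n_tile, replace=False))
    fracs = np.linspace(0.05, 0.95, n_tile) if n_tile else []
    for u, fr in zip(tile_units, fracs):
        tiling[str(u)] = {
            "side": ("L" if rng.random() < 0.5 else "R"),
            "amp": cfg.mpfc_tuning_amp * (0.8 + rng.random()),
            "frac": float(fr),  # centre = sample + frac * delay
            "width_s": cfg.tiling_width_s,
        }

    members, types = _plant_assemblies(cfg, ids_dca1, ids_mpfc, rng, baselines)
    member_of: dict[str, int] = {}
    for a, ms in enumerate(members):
        for u in ms:
            member_of[u] = a
    inter_members = {
        u for a, ms in enumerate(members) if types[a] == "inter-area" for u in ms
    }

    error_trials = [t.index for t in trials if t.outcome == "error"]

    # --- per-trial shared latents
    rho = float(np.exp(-BIN_S / cfg.assembly_gain_tau_s))
    spikes: dict[str, list[np.ndarray]] = {u: [] for u in all_ids}
    prev_end = 0.0
    for tr in trials:
        t_end_evt = tr.t_choice if tr.t_choice is not None else tr.t_tone
        w0 = max(tr.t_cue - EPOCH_PRE_S, prev_end)
        w1 = t_end_evt + EPOCH_POST_S
        n_steps = int(np.ceil((w1 - w0) / BIN_S))
        w1 = w0 + n_steps * BIN_S

        # homogeneous background between previous window and this one
        for u in all_ids:
            gap = w0 - prev_end
            if gap > 0:
                n_bg = rng.poisson(baselines[u] * gap)
                if n_bg:
                    spikes[u].append(prev_end + np.sort(rng.random(n_bg)) * gap)

        # shared assembly gains: one binary Markov latent per assembly whose
        # on/off state is common to all members (sticky, dwell time ~ tau)
        p_on = cfg.assembly_on_prob
        gains = np.empty((len(members), n_steps))
        for a in range(len(members)):
            g = np.empty(n_steps, dtype=bool)
            g[0] = rng.random() < p_on
            # transition probabilities preserving stationary p_on
            stay = rho + (1 - rho) * p_on  # P(on -> on)
            up = (1 - rho) * p_on  # P(off -> on)
            u = rng.random(n_steps - 1)
            for t_ in range(1, n_steps):
                g[t_] = u[t_ - 1] < (stay if g[t_ - 1] else up)
            gains[a] = 1.0 + cfg.assembly_gain_amp * g
        # common rhythm phase per (trial, assembly)
        phis = rng.uniform(0.0, 2.0 * np.pi, size=max(len(members), 1))

        is_err = tr.outcome == "error"
        m_eff = cfg.rhythm_m * (cfg.error_attenuation_rhythm if is_err else 1.0)
        step_t = w0 + BIN_S * np.arange(n_steps)

        for u in all_ids:
            base = baselines[u]
            lam = np.full(n_steps, base)

            ct = cue_tuned.get(u)
            if ct is not None and tr.cue_side == ct["side"]:
                c = tr.t_sample + ct["center_s"]
                lam *= 1.0 + ct["amp"] * np.exp(
                    -((step_t - c) ** 2) / (2 * ct["width_s"] ** 2)
                )
            tl = tiling.get(u)
            if tl is not None and tr.cue_side == tl["side"]:
                amp = tl["amp"] * (cfg.error_attenuation_tuning if is_err else 1.0)
                c = tr.t_sample + tl["frac"] * tr.delay_s
                lam *= 1.0 + amp * np.exp(
                    -((step_t - c) ** 2) / (2 * tl["width_s"] ** 2)
                )
            a = member_of.get(u)
            if a is not None:
                lam = lam * gains[a]
            if a is not None and u in inter_members and m_eff > 0:
                pre = (step_t >= tr.t_sample - RHYTHM_WINDOW_S) & (step_t < tr.t_sample)
                lam = lam * np.where(
                    pre,
                    1.0
                    + m_eff * np.cos(2 * np.pi * cfg.rhythm_f_hz * step_t + phis[a]),
                    1.0,
                )

            # piecewise-constant intensity: exact Poisson sampling per step
            counts = rng.poisson(lam * BIN_S)
            tot = int(counts.sum())
            if tot:
                offs = rng.random(tot) * BIN_S
                reps = np.repeat(step_t, counts)
                spikes[u].append(np.sort(reps + offs))
        prev_end = w1

    # trailing background
    for u in all_ids:
        gap = duration - prev_end
        if gap > 0:
            n_bg = rng.poisson(baselines[u] * gap)
            if n_bg:
                spikes[u].append(prev_end + np.sort(rng.random(n_bg)) * gap)

    units = [
        Unit(u, areas[u], np.sort(np.concatenate(spikes[u])) if spikes[u] else np.empty(0))
        for u in all_ids
    ]
    session = Session(units=units, trials=trials, duration_s=duration)

    truth = GroundTruth(
        assembly_members=[list(m) for m in members],
        assembly_types=list(types),
        cue_tuned_units=cue_tuned,
        tiling_units=tiling,
        rhythm_f_hz=cfg.rhythm_f_hz,
        rhythm_m=cfg.rhythm_m,
        rhythm_window_s=RHYTHM_WINDOW_S,
        error_trials=error_trials,
        error_attenuation_tuning=cfg.error_attenuation_tuning,
        error_attenuation_rhythm=cfg.error_attenuation_rhythm,
        seed=cfg.seed,
    )
    return session, truth


# ---------------------------------------------------------------------------
# LFP


def generate_lfp(
    session: Session,
    fs_hz: float = 250.0,
    theta_f_hz: float = 9.0,
    theta_amp: float = 1.0,
    low_f_hz: float = 4.5,
    low_amp: float = 0.5,
    noise_amp: float = 1.0,
    seed: int = 0,
) -> dict[str, tuple[np.ndarray, float]]:
    """Per-area LFP: 1/f background + theta sinusoid + optional 4.5 Hz term.

    Attached to ``session.lfp`` and returned.  Amplitudes are arbitrary
    units; set an amplitude to 0 to remove that component.
    """
    rng = np.random.default_rng(seed)
    n = int(np.ceil(session.duration_s * fs_hz))
    t = np.arange(n) / fs_hz
    out = {}
    for area in ("dCA1", "mPFC"):
        white = rng.standard_normal(n)
        spec = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(n, 1.0 / fs_hz)
        shaping = np.where(freqs > 0, 1.0 / np.sqrt(freqs), 0.0)
        pink = np.fft.irfft(spec * shaping, n)
        pink *= noise_amp / (pink.std() or 1.0)
        phase = rng.uniform(0, 2 * np.pi, size=2)
        sig = (
            pink
            + theta_amp * np.cos(2 * np.pi * theta_f_hz * t + phase[0])
            + low_amp * np.cos(2 * np.pi * low_f_hz * t + phase[1])
        )
        out[area] = (sig, fs_hz)
    session.lfp = out
    return out


def generate_phase_locked_spikes(
    lfp: np.ndarray,
    fs_hz: float,
    band_hz: tuple[float, float],
    kappa: float,
    mean_rate_hz: float,
    preferred_phase: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Spike train locked to the phase of an LFP band (von Mises intensity).

    ``kappa`` = 0 gives a homogeneous Poisson train; large kappa
    concentrates spikes at ``preferred_phase`` of the band-filtered
    oscillation.  Used to give the phase-locking detectors a planted
    positive.
    """
    from scipy.signal import butter, filtfilt, hilbert
    from scipy.special import i0

    rng = np.random.default_rng(seed)
    nyq = fs_hz / 2.0
    b, a = butter(4, [band_hz[0] / nyq, band_hz[1] / nyq], btype="band")
    phase = np.angle(hilbert(filtfilt(b, a, lfp)))
    lam = mean_rate_hz * np.exp(kappa * np.cos(phase - preferred_phase)) / i0(kappa)
    dt = 1.0 / fs_hz
    counts = rng.poisson(lam * dt)
    t = np.arange(lfp.size) * dt
    reps = np.repeat(t, counts)
    return np.sort(reps + rng.random(reps.size) * dt)


def write_truth(truth: GroundTruth, path) -> None:
    import json

    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1, default=float)
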