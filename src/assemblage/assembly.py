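"""Cell-assembly detection by maximum-likelihood factor analysis.

The rate vector v_t of N simultaneously recorded units in 50-ms task-epoch
bins is modelled as a linear mixing of p uncorrelated latent factors,

    v_t = mu + Gamma z_t + eps,   z_t ~ N(0, I),  eps ~ N(0, Psi diagonal),

so all cross-unit correlation must be carried by the factors.  Units that
load significantly on a common factor form a cell assembly, and the factor
score z_lt is the assembly's moment-to-moment activation.

Model order and loading significance are calibrated with a trial-shuffle
bootstrap: per unit, whole-trial rate segments are permuted across trials of
equal length, preserving each unit's autocorrelation and within-trial rate
profile while destroying cross-unit dependence.  The number of factors is
the longest run of incremental likelihood-ratio gains that exceed the upper
1% confidence limit of the same statistic on shuffled data; a unit joins an
assembly when its varimax-rotated |loading| exceeds the 99th percentile of
that unit's own bootstrap loading distribution.

An independent-component cross-check (Marchenko-Pastur component count +
FastICA, membership at 2.5 SD of a component's weights, >= 3 members)
validates the FA assemblies; agreement is quantified by the Jaccard overlap
O = |A & B| / |A | B|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import AlignedRateTensor, Session, excise_task_epochs
from .decoding import DEFAULT_LAMBDA, loocv_cp

_LOG2PI = np.log(2.0 * np.pi)

#: default loading-ridge used across the assembly-detection workflow
DEFAULT_RIDGE = 0.01


def shuffle_groups(session: Session) -> dict:
    """Trial-shuffle groups: trials exchange only within the same delay,
    cue side and outcome, so every stimulus- and outcome-locked rate
    component is preserved in the bootstrap null and only trial-by-trial
    co-fluctuation is destroyed."""
    return {t.index: (t.delay_s, t.cue_side, t.outcome) for t in session.trials}


# ---------------------------------------------------------------------------
# FA model


@dataclass
class FactorModel:
    mu: np.ndarray  # (N,)
    loadings: np.ndarray  # (N, p)
    psi: np.ndarray  # (N,) diagonal noise variances
    p: int
    loglik: float
    n_obs: int
    n_iter: int = 0
    converged: bool = True
    heywood: bool = False
    loglik_path: np.ndarray | None = None

    def scores(self, X: np.ndarray) -> np.ndarray:
        """Posterior-mean factor scores for columns of X (N x M) -> (p x M)."""
        if self.p == 0:
            return np.empty((0, X.shape[1]))
        beta = self._beta()
        return beta @ (X - self.mu[:, None])

    def _beta(self) -> np.ndarray:
        sigma = self.loadings @ self.loadings.T + np.diag(self.psi)
        return self.loadings.T @ np.linalg.inv(sigma)


def _fa_loglik(S: np.ndarray, gamma: np.ndarray, psi: np.ndarray, m: int) -> float:
    n = S.shape[0]
    sigma = gamma @ gamma.T + np.diag(psi)
    sign, logdet = np.linalg.slogdet(sigma)
    tr = float(np.trace(np.linalg.solve(sigma, S)))
    return -0.5 * m * (n * _LOG2PI + logdet + tr)


def fit_fa(
    X: np.ndarray,
    p: int,
    tol: float = 1e-6,
    max_iter: int = 500,
    ridge: float = 0.0,
) -> FactorModel:
    """ML factor analysis by EM on the sample covariance.

    ``X`` is units x time-bins.  EM operates on the sufficient statistics
    (mean and covariance), so the per-iteration cost is independent of the
    number of time bins.  Initialization is principal-axis; convergence when
    the relative log-likelihood gain drops below ``tol``.  Noise variances
    are floored at 1e-6 of each unit's variance (Heywood guard, flagged).

    ``ridge`` adds a small L2 penalty on the loadings (per observation).
    When the data carry no cross-unit correlation, the ML solution is
    degenerate: a surplus factor can split a single unit's variance
    arbitrarily between its loading and its noise term at identical
    likelihood.  A tiny ridge breaks that flat direction and drives
    unsupported loadings to zero while leaving correlation-anchored
    loadings essentially untouched; use the same value when fitting real
    and bootstrap data so the two remain comparable.
    """
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    if p >= n:
        raise ValueError("factor count must be below the unit count")
    if p > 0 and m < 10 * p:
        warnings.warn(f"only {m} bins for p={p} factors; fit may be unstable")
    mu = X.mean(axis=1)
    xc = X - mu[:, None]
    S = (xc @ xc.T) / m
    var = np.diag(S).copy()
    floor = 1e-6 * np.maximum(var, 1e-300)

    if p == 0:
        psi = np.maximum(var, floor)
        ll = _fa_loglik(S, np.zeros((n, 0)), psi, m)
        return FactorModel(mu, np.zeros((n, 0)), psi, 0, ll, m)

    # principal-axis start
    evals, evecs = np.linalg.eigh(S)
    order = np.argsort(evals)[::-1]
    lead = np.sqrt(np.maximum(evals[order[:p]], 1e-12))
    gamma = evecs[:, order[:p]] * lead
    psi = np.maximum(var - (gamma * gamma).sum(axis=1), np.maximum(0.25 * var, floor))

    ll_prev = -np.inf
    path = []
    heywood = False
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        sigma = gamma @ gamma.T + np.diag(psi)
        beta = np.linalg.solve(sigma, gamma).T  # (p, N)
        ezz = np.eye(p) - beta @ gamma + beta @ S @ beta.T
        sbt = S @ beta.T  # (N, p)
        gamma = sbt @ np.linalg.inv(ezz + ridge * np.eye(p))
        psi_new = var - (gamma * sbt).sum(axis=1)
        if np.any(psi_new < floor):
            heywood = True
            psi_new = np.maximum(psi_new, floor)
        psi = psi_new
        ll = _fa_loglik(S, gamma, psi, m)
        path.append(ll)
        # with a ridge, track the penalized objective: the likelihood is flat
        # along the degenerate single-unit direction, so an unpenalized check
        # would declare convergence while surplus loadings are still decaying
        obj = ll - 0.5 * ridge * m * float((gamma * gamma).sum())
        if np.isfinite(ll_prev) and (obj - ll_prev) < tol * abs(ll_prev):
            converged = True
            break
        ll_prev = obj
    if not converged:
        warnings.warn(f"FA EM did not converge in {max_iter} iterations (p={p})")
    if heywood:
        warnings.warn("Heywood case: noise variance floored for some unit(s)")

    model = FactorModel(
        mu=mu,
        loadings=gamma,
        psi=psi,
        p=p,
        loglik=path[-1],
        n_obs=m,
        n_iter=it,
        converged=converged,
        heywood=heywood,
        loglik_path=np.asarray(path),
    )
    return model


# ---------------------------------------------------------------------------
# FA input and the trial-shuffle bootstrap


def build_fa_input(
    session: Session,
    variant: str = "joint",
    bandwidths: dict[str, float] | float | None = 0.1,
    pre_s: float = 5.0,
    post_s: float = 5.0,
    bin_s: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Units x task-epoch-bins KDE rate matrix for assembly analysis.

    Columns are 50-ms bins from cue - ``pre_s`` to choice + ``post_s`` of
    every completed trial, concatenated (overlaps merged).  ``variant``
    selects mPFC only (``"mpfc"``), dCA1 only (``"dca1"``), or both
    concatenated (``"joint"``).  Returns (X, trial-of-column, unit ids).

    ``bandwidths`` is a common KDE width in seconds (default 100 ms, twice
    the bin), a per-unit dict, or None for per-unit cross-validated widths.
    A common kernel is the default here because a shared latent smoothed by
    *different* per-unit kernels is no longer exactly low-rank, which blurs
    the factor count; the co-firing timescale of interest is the bin scale.
    """
    from .rates import evaluate_kde, select_bandwidths

    bins, owners = excise_task_epochs(session, pre_s, post_s, bin_s)
    if bins.size == 0:
        raise ValueError("no task epochs (no completed trials)")
    sel = {
        "joint": session.units,
        "dca1": session.units_in("dCA1"),
        "mpfc": session.units_in("mPFC"),
    }[variant]
    if bandwidths is None:
        bandwidths = select_bandwidths(session)
    elif np.isscalar(bandwidths):
        bandwidths = {u.unit_id: float(bandwidths) for u in session.units}
    times = bins * bin_s
    X = np.empty((len(sel), bins.size))
    for i, u in enumerate(sel):
        X[i] = evaluate_kde(u.spike_times, times, bandwidths[u.unit_id])
    return X, owners, [u.unit_id for u in sel]


def build_count_input(
    session: Session,
    pre_s: float = 5.0,
    post_s: float = 5.0,
    bin_s: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Units x task-epoch-bins spike-count matrix (no kernel smoothing).

    Same epoch layout as :func:`build_fa_input` but raw 50-ms counts; this
    is the input the eigenvalue/ICA assembly route expects, since the
    Marchenko-Pastur bound assumes unsmoothed, approximately independent
    samples.
    """
    bins, owners = excise_task_epochs(session, pre_s, post_s, bin_s)
    if bins.size == 0:
        raise ValueError("no task epochs (no completed trials)")
    X = np.empty((len(session.units), bins.size))
    left = bins * bin_s
    for i, u in enumerate(session.units):
        lo = np.searchsorted(u.spike_times, left)
        hi = np.searchsorted(u.spike_times, left + bin_s)
        X[i] = hi - lo
    return X, owners, [u.unit_id for u in session.units]


def trial_shuffle(
    X: np.ndarray,
    trial_map: np.ndarray,
    rng: np.random.Generator,
    groups: dict | None = None,
) -> np.ndarray:
    """Permute whole-trial column segments across trials, per unit.

    Each unit's per-trial rate segment moves as a block, so within-trial
    time courses (and hence autocorrelations and trial rate profiles) are
    untouched while the alignment *between* units is destroyed.  Trials are
    shuffled within groups (``groups`` maps trial id -> group key; typically
    the delay condition so event-locked structure stays comparable; default
    one group).  Segments are exchanged aligned at their start; when a
    segment lands in a slightly longer slot (task segments differ in
    duration through response-latency jitter) it is extended by wrapping
    around its own start, so no column keeps its original cross-unit
    alignment.  With equal-length segments this reduces to a plain
    whole-segment permutation that preserves each unit's marginal exactly.
    """
    trial_map = np.asarray(trial_map)
    tids, starts = np.unique(trial_map, return_index=True)
    tids = tids[np.argsort(starts)]
    seg_cols = {t: np.flatnonzero(trial_map == t) for t in tids}
    by_group: dict = {}
    for t in tids:
        key = groups.get(t, 0) if groups is not None else 0
        by_group.setdefault(key, []).append(t)

    out = np.empty_like(X)
    for members in by_group.values():
        if len(members) < 2:
            for t in members:
                out[:, seg_cols[t]] = X[:, seg_cols[t]]
            continue
        blocks = [seg_cols[t] for t in members]
        for i in range(X.shape[0]):
            perm = rng.permutation(len(members))
            for dst, src in zip(blocks, (blocks[j] for j in perm)):
                seg = X[i, src]
                out[i, dst] = np.resize(seg, dst.size)  # wrap if slot longer
    return out


def fa_loglik_ladder(
    X: np.ndarray, max_p: int, tol: float = 1e-6, max_iter: int = 500
) -> np.ndarray:
    """Log-likelihoods of FA fits with 0..max_p factors."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return np.array([fit_fa(X, p, tol, max_iter).loglik for p in range(max_p + 1)])


def select_n_factors(
    X: np.ndarray,
    trial_map: np.ndarray,
    max_p: int,
    n_boot: int = 500,
    q: float = 0.99,
    rng: np.random.Generator | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    groups: dict | None = None,
    return_details: bool = False,
):
    """Number of significant factors by the incremental-LLR bootstrap ladder.

    The observed log-likelihood-ratio gain of adding factor l (over l-1) is
    compared with the ``q`` (upper 1%) quantile of the same gain across
    ``n_boot`` trial-shuffled datasets; the selected p is the longest
    initial run of significant gains (stop at the first failure).
    """
    if rng is None:
        rng = np.random.default_rng()
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} gives coarse bootstrap quantiles")
    ll = fa_loglik_ladder(X, max_p, tol, max_iter)
    llr_obs = 2.0 * np.diff(ll)  # gain of factor l over l-1, l = 1..max_p

    llr_boot = np.zeros((n_boot, max_p))
    for b in range(n_boot):
        xs = trial_shuffle(X, trial_map, rng, groups)
        llb = fa_loglik_ladder(xs, max_p, tol, max_iter)
        llr_boot[b] = 2.0 * np.diff(llb)
    thresh = np.quantile(llr_boot, q, axis=0)

    p_sig = 0
    for l in range(max_p):
        if llr_obs[l] > thresh[l]:
            p_sig = l + 1
        else:
            break
    if return_details:
        return p_sig, {"llr_obs": llr_obs, "llr_boot": llr_boot, "thresh": thresh}
    return p_sig


def bootstrap_loadings(
    X: np.ndarray,
    trial_map: np.ndarray,
    p: int,
    n_boot: int,
    rng: np.random.Generator,
    tol: float = 1e-6,
    max_iter: int = 500,
    groups: dict | None = None,
    ridge: float = 0.0,
) -> np.ndarray:
    """|loading| samples from FA fits to trial-shuffled data, (n_boot, N, p)."""
    out = np.zeros((n_boot, X.shape[0], p))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for b in range(n_boot):
            xs = trial_shuffle(X, trial_map, rng, groups)
            out[b] = np.abs(varimax(fit_fa(xs, p, tol, max_iter, ridge=ridge).loadings))
    return out


def varimax(loadings: np.ndarray, max_iter: int = 100, tol: float = 1e-8) -> np.ndarray:
    """Varimax rotation of a loading matrix (N x p) toward simple structure.

    The FA likelihood is invariant under orthogonal rotation of the factors,
    so raw EM loadings can mix two genuine assemblies into overlapping
    factors depending on initialization.  Varimax picks the rotation that
    maximizes the variance of squared loadings per factor, aligning each
    factor with one assembly; membership calibration applies it to real and
    bootstrap fits alike.
    """
    L = np.asarray(loadings, float).copy()
    n, p = L.shape
    if p < 2:
        return L
    R = np.eye(p)
    d_old = 0.0
    for _ in range(max_iter):
        LR = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (LR**3 - LR @ np.diag((LR**2).sum(axis=0)) / n)
        )
        R = u @ vt
        d = s.sum()
        if d_old != 0 and (d - d_old) < tol * d_old:
            break
        d_old = d
    return L @ R


def align_factor_signs(model: FactorModel) -> FactorModel:
    """Flip each factor so its largest-|loading| unit loads positively."""
    if model.p == 0:
        return model
    g = model.loadings
    for l in range(model.p):
        i = int(np.argmax(np.abs(g[:, l])))
        if g[i, l] < 0:
            g[:, l] = -g[:, l]
    return model


def significant_loadings(
    model: FactorModel,
    boot_loadings: np.ndarray,
    q: float = 0.99,
    mode: str = "per_unit",
) -> np.ndarray:
    """Unit x factor membership mask from the bootstrap loading distribution.

    A unit belongs to factor l when |Gamma_il| exceeds the ``q`` quantile of
    the bootstrap |loading| distribution.  Loadings are varimax-rotated
    first (see :func:`varimax`); the default threshold is per unit, pooled
    across factors, because loading magnitudes scale with each unit's firing
    rate and variance; ``mode`` selects "per_unit", "pooled" (all units and
    factors together) or "per_factor".
    """
    model.loadings = varimax(model.loadings)
    align_factor_signs(model)
    absg = np.abs(model.loadings)
    if boot_loadings.size == 0 or np.all(boot_loadings == 0):
        warnings.warn("degenerate (all-zero) bootstrap loadings; all units pass")
        return absg > 0
    if mode == "per_factor":
        thr = np.quantile(boot_loadings.reshape(-1, model.p), q, axis=0)
    elif mode == "per_unit":
        n = model.loadings.shape[0]
        thr = np.quantile(boot_loadings.transpose(1, 0, 2).reshape(n, -1), q, axis=1)[
            :, None
        ]
    elif mode == "pooled":
        thr = np.quantile(boot_loadings.ravel(), q)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return absg > thr


# ---------------------------------------------------------------------------
# Assemblies


@dataclass
class Assembly:
    id: str
    member_units: list[str]
    factor_index: int
    kind: str  # "within-dCA1" | "within-mPFC" | "inter-area"
    activation: np.ndarray | None = None
    sig_activation_mask: np.ndarray | None = None
    phase_class: str = "none"
    merged_factors: list[int] = field(default_factory=list)

    @property
    def member_set(self) -> frozenset:
        return frozenset(self.member_units)


def _kind(members: list[str], areas: dict[str, str]) -> str:
    kinds = {areas[u] for u in members}
    if kinds == {"dCA1"}:
        return "within-dCA1"
    if kinds == {"mPFC"}:
        return "within-mPFC"
    return "inter-area"


def assemble(
    mask: np.ndarray,
    unit_ids: list[str],
    areas: dict[str, str],
    min_members: int = 2,
) -> list[Assembly]:
    """Turn a unit x factor significance mask into typed assemblies.

    Factors with fewer than ``min_members`` significant units are dropped.
    A within-area assembly whose member set is a subset of an inter-area
    assembly's members is reported as part of the larger one.
    """
    raw: list[Assembly] = []
    for l in range(mask.shape[1]):
        members = [unit_ids[i] for i in np.flatnonzero(mask[:, l])]
        if len(members) < min_members:
            continue
        raw.append(Assembly(f"A{l}", members, l, _kind(members, areas)))

    inter = [a for a in raw if a.kind == "inter-area"]
    out: list[Assembly] = []
    for a in raw:
        if a.kind != "inter-area":
            host = next(
                (b for b in inter if a.member_set <= b.member_set and a is not b), None
            )
            if host is not None:
                host.merged_factors.append(a.factor_index)
                continue
        out.append(a)
    return out


def activation_significance(
    model: FactorModel,
    X: np.ndarray,
    trial_map: np.ndarray,
    alpha: float = 0.01,
    n_boot: int = 100,
    rng: np.random.Generator | None = None,
    groups: dict | None = None,
) -> np.ndarray:
    """Per-factor activation mask: score above the shuffled-score quantile.

    The fitted model projects trial-shuffled data; the (1 - alpha) quantile
    of those null scores (pooled over time, per factor) thresholds the real
    factor-score series.  Returns a factors x bins boolean mask.
    """
    if rng is None:
        rng = np.random.default_rng()
    align_factor_signs(model)
    z = model.scores(X)
    null = np.empty((model.p, 0))
    samples = []
    for _ in range(n_boot):
        xs = trial_shuffle(X, trial_map, rng, groups)
        samples.append(model.scores(xs))
    null = np.concatenate(samples, axis=1)
    thr = np.quantile(null, 1.0 - alpha, axis=1)
    return z > thr[:, None]


# ---------------------------------------------------------------------------
# ICA cross-check


def marchenko_pastur_bound(n_units: int, n_bins: int) -> float:
    """Upper eigenvalue bound of a random correlation matrix."""
    return (1.0 + np.sqrt(n_units / n_bins)) ** 2


def ica_assemblies(
    X: np.ndarray,
    unit_ids: list[str],
    areas: dict[str, str],
    sd_thresh: float = 2.5,
    min_members: int = 3,
    seed: int = 0,
) -> list[Assembly]:
    """Assemblies by the eigenvalue/ICA route, as a cross-check on FA.

    Rows of ``X`` are z-scored; the number of co-activation components is
    the count of correlation-matrix eigenvalues above the Marchenko-Pastur
    bound; FastICA on the retained subspace yields component weight vectors,
    and a unit is a member when its weight exceeds the component mean by
    ``sd_thresh`` SDs.  Assemblies need at least 3 members.
    """
    from sklearn.decomposition import FastICA

    n, m = X.shape
    sd = X.std(axis=1, keepdims=True)
    z = (X - X.mean(axis=1, keepdims=True)) / np.where(sd == 0, 1.0, sd)
    corr = (z @ z.T) / m
    evals, evecs = np.linalg.eigh(corr)
    bound = marchenko_pastur_bound(n, m)
    n_comp = int(np.sum(evals > bound))
    if n_comp == 0:
        return []
    if sd_thresh <= 0:
        warnings.warn("non-positive SD threshold: every unit becomes a member")

    ica = FastICA(n_components=n_comp, random_state=seed, max_iter=1000, tol=1e-4)
    ica.fit(z.T)
    patterns = ica.mixing_  # (N, n_comp), columns = assembly patterns
    out = []
    for c in range(n_comp):
        w = patterns[:, c].copy()
        i = int(np.argmax(np.abs(w)))
        if w[i] < 0:
            w = -w
        # background weight spread estimated robustly (median/MAD): members
        # themselves would otherwise inflate a plain mean/SD threshold
        med = np.median(w)
        mad = 1.4826 * np.median(np.abs(w - med))
        scale = mad if mad > 0 else w.std()
        members = [
            unit_ids[j] for j in np.flatnonzero(w > med + sd_thresh * scale)
        ]
        if len(members) >= min_members:
            out.append(Assembly(f"IC{c}", members, c, _kind(members, areas)))
    return out


def overlap(a, b) -> float:
    """Jaccard overlap O = |A & B| / |A | B| between two member sets."""
    a, b = set(a), set(b)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def match_overlap(set_a: list[Assembly], set_b: list[Assembly]) -> float:
    """Mean best-pair overlap: for each assembly in ``set_b`` take its best
    match in ``set_a``, then average."""
    if not set_b:
        return float("nan")
    scores = []
    for b in set_b:
        best = max((overlap(a.member_units, b.member_units) for a in set_a), default=0.0)
        scores.append(best)
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# Rank-ordered synthetic assemblies and noise-correlation shuffles


def synthetic_assembly_curve(
    tensor: AlignedRateTensor,
    labels: np.ndarray,
    sizes=range(2, 21),
    ranks=range(1, 11),
    lam: float = DEFAULT_LAMBDA,
):
    """Peak decoding of rank-ordered synthetic unit groups.

    Units are ranked by their individual peak LOOCV correct fraction over
    the tensor's bins; for each group size s and rank r the r-th consecutive
    block of s ranked units is decoded jointly and its peak CP recorded.
    Blocks exceeding the unit pool are omitted.  Returns a DataFrame with
    columns size, rank, peak_cp, and the ranked unit order as an attribute.
    """
    import pandas as pd

    n_trials, n_units, n_bins = tensor.rates.shape
    single_peak = np.zeros(n_units)
    for i in range(n_units):
        cps = [loocv_cp(tensor.rates[:, [i], b], labels, lam) for b in range(n_bins)]
        single_peak[i] = max(cps)
    order = np.argsort(-single_peak, kind="stable")

    rows = []
    for s in sizes:
        for r in ranks:
            lo, hi = (r - 1) * s, r * s
            if hi > n_units:
                continue
            block = order[lo:hi]
            cps = [
                loocv_cp(tensor.rates[:, block, b], labels, lam) for b in range(n_bins)
            ]
            rows.append({"size": s, "rank": r, "peak_cp": max(cps)})
    df = pd.DataFrame(rows)
    df.attrs["ranked_units"] = [tensor.unit_ids[i] for i in order]
    df.attrs["single_peak_cp"] = single_peak[order]
    return df


def assign_assembly_rank(peak_cp: float, size: int, curve) -> int:
    """Rank of the closest-performing size-matched synthetic assembly."""
    sub = curve[curve["size"] == size]
    if sub.empty:
        raise ValueError(f"no synthetic draws of size {size}")
    i = (sub["peak_cp"] - peak_cp).abs().idxmin()
    return int(sub.loc[i, "rank"])


def noise_shuffle_decoding(
    tensor: AlignedRateTensor,
    labels: np.ndarray,
    n_perm: int = 50,
    mode: str = "within-area",
    lam: float = DEFAULT_LAMBDA,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """CP curve after destroying trial-by-trial noise correlations.

    Cue labels are kept; trial order is permuted within each cue class so
    the signal (class means) is untouched while shared trial-to-trial rate
    fluctuations are broken.  ``mode="within-area"`` permutes every unit
    independently (destroys all noise correlations); ``mode="between-area"``
    applies one common permutation per area (preserves within-area, destroys
    inter-area correlations).  Returns the CP curve averaged over ``n_perm``
    permutations.
    """
    from .decoding import loocv_decode

    if rng is None:
        rng = np.random.default_rng()
    lab = np.asarray(labels)
    classes = [np.flatnonzero(lab == c) for c in ("L", "R")]
    areas = np.asarray(tensor.areas)
    curves = []
    for _ in range(n_perm):
        rates = tensor.rates.copy()
        if mode == "within-area":
            for i in range(tensor.n_units):
                for ix in classes:
                    rates[ix, i, :] = rates[rng.permutation(ix), i, :]
        elif mode == "between-area":
            for area in ("dCA1", "mPFC"):
                cols = np.flatnonzero(areas == area)
                for ix in classes:
                    perm = rng.permutation(ix)
                    rates[np.ix_(ix, cols)] = rates[np.ix_(perm, cols)]
        else:
            raise ValueError(f"unknown mode {mode!r}")
        shuf = AlignedRateTensor(
            rates=rates,
            times=tensor.times,
            bin_s=tensor.bin_s,
            align_event=tensor.align_event,
            unit_ids=tensor.unit_ids,
            trial_indices=tensor.trial_indices,
            areas=list(tensor.areas),
        )
        curves.append(loocv_decode(shuf, labels, lam).cp)
    return np.mean(curves, axis=0)
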