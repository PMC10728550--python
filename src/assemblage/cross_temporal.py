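"""Cross-temporal population decoding: train at t1, test at t2.

A decoder trained at one delay time point and tested at another probes
whether the cue code is stable (an extended off-diagonal block of
significant decoding) or dynamic/sequential (significance confined near the
diagonal).  To equalize training-set size across delays and sessions, each
grid is built from repeated random draws of eight trials per cue side; within
each draw a leave-one-pair-out split keeps training and testing trials
separate.  Per-cell significance comes from label-shuffle bootstraps, and a
250-ms Gaussian kernel may be applied for display after significance
testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import AlignedRateTensor
from .decoding import DEFAULT_LAMBDA


@dataclass
class CrossTemporalMatrix:
    train_times: np.ndarray
    test_times: np.ndarray
    perf: np.ndarray  # (n_train, n_test) mean correct fraction
    sig_mask: np.ndarray | None = None
    smoothed: bool = False
    bin_s: float = 0.05
    resample_grids: np.ndarray | None = None  # (n_resamples, n_train, n_test)

    @property
    def diagonal(self) -> np.ndarray:
        return np.diag(self.perf)


def _ct_perf_once(
    rates: np.ndarray,
    is_l: np.ndarray,
    n_per_class: int,
    n_resamples: int,
    lam: float,
    rng: np.random.Generator,
    keep_resamples: bool = False,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Mean train x test correct fraction over random 8+8-trial draws.

    Within each draw, a leave-one-pair-out split (train 7+7, test 1+1) keeps
    training and testing sets disjoint; every pair is held out in turn.
    """
    n_trials, n_units, n_bins = rates.shape
    li = np.flatnonzero(is_l)
    ri = np.flatnonzero(~is_l)
    if li.size < n_per_class or ri.size < n_per_class:
        raise ValueError(
            f"need >= {n_per_class} trials per class, have L={li.size} R={ri.size}"
        )
    acc = np.zeros((n_bins, n_bins))
    grids = np.zeros((n_resamples, n_bins, n_bins)) if keep_resamples else None
    eye = lam * np.eye(n_units)
    denom = 2 * n_per_class - 2 - 2  # pooled-cov dof for 7+7 training trials

    for r in range(n_resamples):
        dl = rng.choice(li, size=n_per_class, replace=False)
        dr = rng.choice(ri, size=n_per_class, replace=False)
        xl = rates[dl]  # (8, N, B)
        xr = rates[dr]
        g = np.zeros((n_bins, n_bins))
        for f in range(n_per_class):
            keep = np.arange(n_per_class) != f
            tl, tr_ = xl[keep], xr[keep]
            ml = tl.mean(axis=0)  # (N, B)
            mr = tr_.mean(axis=0)
            dml = tl - ml
            dmr = tr_ - mr
            w = np.einsum("knb,kmb->bnm", dml, dml) + np.einsum(
                "knb,kmb->bnm", dmr, dmr
            )
            cov = w / denom + eye
            wts = np.linalg.solve(cov, (ml - mr).T[..., None])[..., 0]  # (B, N)
            bias = -0.5 * np.einsum("bn,nb->b", wts, ml + mr)
            # held-out pair at every test time
            dec_l = np.einsum("bn,nc->bc", wts, xl[f]) + bias[:, None]
            dec_r = np.einsum("bn,nc->bc", wts, xr[f]) + bias[:, None]
            g += 0.5 * ((dec_l > 0).astype(float) + (dec_r <= 0).astype(float))
        g /= n_per_class
        acc += g
        if keep_resamples:
            grids[r] = g
    return acc / n_resamples, grids


def cross_temporal_decode(
    tensor: AlignedRateTensor,
    labels: np.ndarray,
    n_per_class: int = 8,
    n_resamples: int = 500,
    lam: float = DEFAULT_LAMBDA,
    rng: np.random.Generator | None = None,
    keep_resamples: bool = False,
) -> CrossTemporalMatrix:
    """Full train x test decoding grid on the tensor's time bins."""
    if rng is None:
        rng = np.random.default_rng()
    is_l = np.asarray(labels) == "L"
    perf, grids = _ct_perf_once(
        tensor.rates, is_l, n_per_class, n_resamples, lam, rng, keep_resamples
    )
    return CrossTemporalMatrix(
        train_times=tensor.times,
        test_times=tensor.times,
        perf=perf,
        bin_s=tensor.bin_s,
        resample_grids=grids,
    )


def ct_significance(
    matrix: CrossTemporalMatrix,
    tensor: AlignedRateTensor,
    labels: np.ndarray,
    n_boot: int = 1000,
    n_resamples_null: int = 10,
    n_per_class: int = 8,
    lam: float = DEFAULT_LAMBDA,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-cell significance against label-shuffle bootstrap grids.

    Each bootstrap shuffles the cue labels and rebuilds a (smaller) grid;
    a cell is significant when the observed performance exceeds the
    (1 - alpha) quantile of its null values.  Stored on ``matrix.sig_mask``.
    """
    if rng is None:
        rng = np.random.default_rng()
    is_l = np.asarray(labels) == "L"
    nb = matrix.perf.shape[0]
    null = np.zeros((n_boot, nb, nb))
    for b in range(n_boot):
        perm = rng.permutation(is_l)
        null[b], _ = _ct_perf_once(
            tensor.rates, perm, n_per_class, n_resamples_null, lam, rng
        )
    if alpha >= 1.0:  # degenerate limit: everything is "significant"
        thresh = np.full_like(matrix.perf, -np.inf)
    else:
        thresh = np.quantile(null, 1.0 - alpha, axis=0)
    matrix.sig_mask = matrix.perf > thresh
    return matrix.sig_mask


def ct_smooth(matrix: CrossTemporalMatrix, fwhm_s: float = 0.25) -> CrossTemporalMatrix:
    """Gaussian smoothing of the performance map for display.

    The 250-ms kernel width is read as FWHM, sigma = FWHM / 2.355.  Applied
    after significance testing; the significance mask is never smoothed.
    """
    sigma_bins = (fwhm_s / 2.355) / matrix.bin_s
    sm = gaussian_filter(matrix.perf, sigma=sigma_bins, mode="nearest")
    return CrossTemporalMatrix(
        train_times=matrix.train_times,
        test_times=matrix.test_times,
        perf=sm,
        sig_mask=matrix.sig_mask,
        smoothed=True,
        bin_s=matrix.bin_s,
    )


def ct_difference(
    matrix_a: CrossTemporalMatrix,
    matrix_b: CrossTemporalMatrix,
    n_perm: int = 1000,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Condition difference map (A - B) with a per-cell permutation test.

    Both matrices must carry per-resample grids (``keep_resamples=True``);
    the null permutes the pooled resample grids between conditions.  Returns
    (difference map, boolean significance mask); antisymmetric in its
    arguments.
    """
    if matrix_a.resample_grids is None or matrix_b.resample_grids is None:
        raise ValueError("run cross_temporal_decode with keep_resamples=True")
    if rng is None:
        rng = np.random.default_rng()
    ga, gb = matrix_a.resample_grids, matrix_b.resample_grids
    na = ga.shape[0]
    pool = np.concatenate([ga, gb], axis=0)
    diff = ga.mean(axis=0) - gb.mean(axis=0)
    null = np.zeros((n_perm,) + diff.shape)
    for p in range(n_perm):
        ix = rng.permutation(pool.shape[0])
        null[p] = pool[ix[:na]].mean(axis=0) - pool[ix[na:]].mean(axis=0)
    thresh = np.quantile(np.abs(null), 1.0 - alpha, axis=0)
    return diff, np.abs(diff) > thresh
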