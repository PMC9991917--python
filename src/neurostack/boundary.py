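"""Boundary-versus-inner theta analysis for the walking task.

Each crossing of the room is split at 1/3 and 2/3 of its duration; the
middle third is the *inner* condition and the final third the *boundary*
condition.  Per-channel band-power means are equalized by repeatedly
subsampling the larger condition to the size of the smaller one (500
iterations by default), and the conditions are compared with a two-sided
paired permutation test over channels (random sign flips of the paired
differences; exhaustive enumeration when feasible).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import CoreError, EventStream
from .spectral import BandpowerSeries


@dataclass
class ConditionSplit:
    inner_intervals: list = field(default_factory=list)  # (start_s, end_s)
    boundary_intervals: list = field(default_factory=list)
    fractions: tuple = (1.0 / 3.0, 2.0 / 3.0)


def split_crossings(events: EventStream) -> ConditionSplit:
    """Pair crossing_start/crossing_end events and split each crossing.

    For a crossing [t0, t1]: A = t0 + (t1-t0)/3 and B = t0 + 2(t1-t0)/3;
    inner = [A, B), boundary = [B, t1).
    """
    starts = events.times_of("crossing_start")
    ends = events.times_of("crossing_end")
    if starts.size != ends.size:
        raise CoreError(
            f"{starts.size} crossing_start vs {ends.size} crossing_end events"
        )
    split = ConditionSplit()
    for t0, t1 in zip(starts, ends):
        if t1 <= t0:
            raise CoreError(f"crossing_end {t1} not after crossing_start {t0}")
        a = t0 + (t1 - t0) / 3.0
        b = t0 + 2.0 * (t1 - t0) / 3.0
        split.inner_intervals.append((a, b))
        split.boundary_intervals.append((b, t1))
    return split


def _gather(bp: BandpowerSeries, intervals: list) -> np.ndarray:
    idx = []
    for s, e in intervals:
        i0 = int(np.ceil((s - bp.t0) * bp.fs))
        i1 = int(np.ceil((e - bp.t0) * bp.fs))
        idx.append(np.arange(max(i0, 0), min(i1, bp.values.size)))
    return bp.values[np.concatenate(idx)] if idx else np.empty(0)


def equalized_condition_means(
    bps: list[BandpowerSeries],
    split: ConditionSplit,
    n_iter: int = 500,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel (inner_mean, boundary_mean) with sample-count equalization.

    Per iteration the larger condition is randomly subsampled (without
    replacement) to the smaller condition's sample count; reported means are
    averaged over ``n_iter`` iterations.  Seed-deterministic.
    """
    rng = np.random.default_rng(seed)
    inner_means = np.empty(len(bps))
    boundary_means = np.empty(len(bps))
    for ci, bp in enumerate(bps):
        inner = _gather(bp, split.inner_intervals)
        boundary = _gather(bp, split.boundary_intervals)
        if inner.size == 0 or boundary.size == 0:
            raise CoreError("empty condition segment")
        m = min(inner.size, boundary.size)
        if inner.size == boundary.size:
            inner_means[ci] = inner.mean()
            boundary_means[ci] = boundary.mean()
            continue
        im = np.empty(n_iter)
        bm = np.empty(n_iter)
        for it in range(n_iter):
            ii = inner if inner.size == m else rng.choice(inner, m, replace=False)
            bb = boundary if boundary.size == m else rng.choice(boundary, m, replace=False)
            im[it] = ii.mean()
            bm[it] = bb.mean()
        inner_means[ci] = im.mean()
        boundary_means[ci] = bm.mean()
    return inner_means, boundary_means


def paired_permutation_test(
    a: np.ndarray,
    b: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
    alternative: str = "two-sided",
    smoothed: bool = False,
    exact: str | bool = "auto",
) -> dict:
    """Paired permutation test by random sign flips of per-pair differences.

    The null distribution is the mean of sign-flipped differences; the
    two-sided p-value is the fraction of permuted |means| that equal or
    exceed the observed |mean| (ties counted as exceedances).  When
    ``exact`` ('auto' and 2^n <= n_perm, or True) all 2^n sign patterns are
    enumerated instead of sampled.  ``smoothed`` applies the (k+1)/(n+1)
    estimator (never returns exactly 0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise CoreError("paired test needs two equal-length vectors, n >= 2")
    d = a - b
    n = d.size
    observed = d.mean()

    use_exact = exact is True or (exact == "auto" and 2**n <= n_perm)
    if use_exact:
        patterns = np.arange(2**n, dtype=np.int64)
        signs = ((patterns[:, None] >> np.arange(n, dtype=np.int64)) & 1).astype(
            float
        ) * 2 - 1
        perm_means = signs @ d / n
        n_total = perm_means.size
    else:
        rng = np.random.default_rng(seed)
        signs = rng.integers(0, 2, size=(n_perm, n)).astype(float) * 2 - 1
        perm_means = signs @ d / n
        n_total = n_perm

    # ties count as exceedances (conservative); a roundoff-scale tolerance
    # keeps exact ties (e.g. the identity sign pattern) from being missed
    tol = 1e-12 * (abs(observed) + np.abs(d).max())
    if alternative == "two-sided":
        k = int(np.sum(np.abs(perm_means) >= abs(observed) - tol))
    elif alternative == "greater":
        k = int(np.sum(perm_means >= observed - tol))
    elif alternative == "less":
        k = int(np.sum(perm_means <= observed + tol))
    else:
        raise CoreError(f"unknown alternative {alternative!r}")

    p = (k + 1) / (n_total + 1) if smoothed else k / n_total
    return {
        "p_value": float(p),
        "observed_diff": float(observed),
        "n_permutations": int(n_total),
        "exact": bool(use_exact),
    }
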