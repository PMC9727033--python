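"""Independent oracles used to cross-check pipeline implementations.

Everything here is deliberately naive (O(n^2) scans, finite differences,
dense grids, direct Monte-Carlo of the generative law) and shares no code
path with the implementations under test.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf


# ---------------------------------------------------------------------------
# DBSCAN: brute-force density connectivity with deterministic scan order


def brute_force_dbscan(points: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """O(n^2) DBSCAN labels; minPts counts the point itself.

    Border points go to the first core cluster that reaches them in
    ascending-index scan order (the pinned tie-breaking convention).
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    neigh = d2 <= eps * eps
    core = neigh.sum(axis=1) >= min_pts
    labels = np.full(n, -1, dtype=np.int64)
    cid = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        labels[i] = cid
        queue = [i]
        while queue:
            j = queue.pop()
            if not core[j]:
                continue
            for k in np.nonzero(neigh[j])[0]:
                if labels[k] == -1:
                    labels[k] = cid
                    queue.append(int(k))
        cid += 1
    return labels


def same_partition(labels_a: np.ndarray, labels_b: np.ndarray) -> bool:
    """Partitions equal up to relabeling (noise must match exactly)."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        return False
    if not np.array_equal(a == -1, b == -1):
        return False
    mapping: dict[int, int] = {}
    seen_b: set[int] = set()
    for x, y in zip(a, b):
        if x == -1:
            continue
        if x not in mapping:
            if int(y) in seen_b:
                return False
            mapping[int(x)] = int(y)
            seen_b.add(int(y))
        elif mapping[int(x)] != y:
            return False
    return True


# ---------------------------------------------------------------------------
# integrated-Gaussian spot model (independent re-derivation)


def spot_expectation(size: int, x: float, y: float, photons: float, bg: float,
                     sigma: float) -> np.ndarray:
    """Expected photons per pixel for one spot over a size x size window."""
    e = np.arange(size + 1, dtype=float)
    sq2 = np.sqrt(2.0) * sigma
    fx = 0.5 * (erf((e[1:] - x) / sq2) - erf((e[:-1] - x) / sq2))
    fy = 0.5 * (erf((e[1:] - y) / sq2) - erf((e[:-1] - y) / sq2))
    return bg + photons * np.outer(fy, fx)


def numeric_crlb_xy(size: int, x: float, y: float, photons: float, bg: float,
                    sigma: float, h: float = 1e-4) -> float:
    """CRLB of the position estimate from a finite-difference Fisher matrix.

    Returns sqrt of the mean of the x and y CRLB variances (px).
    """
    theta = np.array([x, y, photons, bg])

    def mu(t):
        return spot_expectation(size, t[0], t[1], t[2], t[3], sigma)

    grads = []
    for k in range(4):
        dp = theta.copy()
        dm = theta.copy()
        step = h * max(abs(theta[k]), 1.0)
        dp[k] += step
        dm[k] -= step
        grads.append((mu(dp) - mu(dm)) / (2 * step))
    m0 = np.clip(mu(theta), 1e-12, None)
    fisher = np.array([[(ga * gb / m0).sum() for gb in grads] for ga in grads])
    cov = np.linalg.inv(fisher)
    return float(np.sqrt(0.5 * (cov[0, 0] + cov[1, 1])))


def grid_search_mle_xy(window: np.ndarray, photons: float, bg: float, sigma: float,
                       center: tuple, half_range: float = 0.6,
                       resolution: float = 1e-3) -> tuple:
    """Dense grid minimization of the Poisson NLL over (x, y) only.

    Coarse-to-fine: a 0.02 px grid over +-half_range, then a fine grid at
    ``resolution`` around the coarse optimum.
    """
    size = window.shape[0]

    def nll(x, y):
        m = np.clip(spot_expectation(size, x, y, photons, bg, sigma), 1e-12, None)
        return float((m - window * np.log(m)).sum())

    def scan(x0, y0, half, step):
        xs = np.arange(x0 - half, x0 + half + step / 2, step)
        ys = np.arange(y0 - half, y0 + half + step / 2, step)
        best = (np.inf, x0, y0)
        for yv in ys:
            for xv in xs:
                v = nll(xv, yv)
                if v < best[0]:
                    best = (v, xv, yv)
        return best

    _, cx, cy = scan(center[0], center[1], half_range, 0.02)
    _, fx, fy = scan(cx, cy, 0.025, resolution)
    return fx, fy


# ---------------------------------------------------------------------------
# lifetime statistics


def truncated_exp_mean(mean: float, cutoff: float) -> float:
    """E[L | L < cutoff] for an exponential with the given mean."""
    q = np.exp(-cutoff / mean)
    return mean - cutoff * q / (1.0 - q)


def lifetime_recovery_oracle(
    n_clusters: int,
    duration_s: float,
    frame_rate: float,
    short_mean: float,
    long_mean: float,
    long_fraction: float,
    pool_mean: float,
    activation_rate: float,
    bleach_rate: float,
    n_min: int,
    cutoff: float,
    seed: int,
):
    """Monte-Carlo of the generative law: observed burst lifetimes.

    Replicates cluster birth/death, pooled activation, geometric ON tracks
    and frame quantization directly from the model definition (no pipeline
    code), returning the detection-span lifetime of every cluster with at
    least ``n_min`` detections.
    """
    rng = np.random.default_rng(seed)
    T, fr = duration_s, frame_rate
    b = rng.uniform(0, T, n_clusters)
    is_long = rng.random(n_clusters) < long_fraction
    L = np.where(
        is_long,
        rng.exponential(long_mean, n_clusters),
        rng.exponential(short_mean, n_clusters),
    )
    stop = np.minimum(b + L, T)
    live = stop - b
    p_act = -np.expm1(-activation_rate * live)
    n_act = rng.binomial(rng.poisson(pool_mean, n_clusters), p_act)

    idx = np.repeat(np.arange(n_clusters), n_act)
    u = rng.random(idx.size)
    t_act = b[idx] - np.log1p(-u * p_act[idx]) / activation_rate
    f_start = (t_act * fr).astype(np.int64)
    f_stop = np.minimum(np.ceil(stop[idx] * fr), T * fr).astype(np.int64) - 1
    g = rng.geometric(min(bleach_rate / fr, 1.0), idx.size)  # ON frames
    f_end = np.minimum(f_start + g - 1, f_stop)
    valid = f_start <= f_stop

    first = np.full(n_clusters, np.iinfo(np.int64).max)
    last = np.full(n_clusters, -1)
    count = np.zeros(n_clusters, dtype=np.int64)
    np.minimum.at(first, idx[valid], f_start[valid])
    np.maximum.at(last, idx[valid], f_end[valid])
    np.add.at(count, idx[valid], f_end[valid] - f_start[valid] + 1)

    detected = count >= n_min
    return (last[detected] - first[detected]) / fr


# ---------------------------------------------------------------------------
# misc


def binomial_upper_bound(n: int, p: float, alpha: float = 0.01) -> int:
    """Smallest k with P(Binomial(n, p) > k) <= alpha (normal approx guard)."""
    from scipy.stats import binom

    return int(binom.ppf(1.0 - alpha, n, p))
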