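"""Independent oracles used by the test suite.

Each function recomputes a quantity by a route independent of the
implementation it checks: normal-equations least squares for the
pseudo-inverse unmixer, an exhaustive candidate scan for the
moment-preserving threshold, full rank-permutation enumeration for the
Mann-Whitney test, and a brute-force correlation scan for offsets.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def normal_equations_unmix(spectra: np.ndarray, design: np.ndarray):
    """Per-voxel least squares via the normal equations A^T A x = A^T y."""
    ata = design.T @ design
    coeffs = np.linalg.solve(ata, design.T @ spectra.T).T
    resid = np.linalg.norm(spectra - coeffs @ design.T, axis=-1)
    return coeffs, resid


def moment_scan_threshold_bin(hist) -> int:
    """Exhaustive scan over all candidate cut-offs for the moment criterion.

    For each candidate, build the two-level image whose below-fraction is
    the candidate's CDF and whose two levels preserve m1 and m2 exactly;
    its third moment increases monotonically with the below-fraction, so
    the moment-preserving cut is the first candidate whose two-level third
    moment reaches the histogram's m3.
    """
    m1, m2, m3 = hist.raw_moments()
    var = m2 - m1 * m1
    counts = hist.counts.astype(float)
    total = counts.sum()
    cum = np.cumsum(counts)
    for t in range(len(counts)):
        n_below = cum[t]
        if n_below == 0 or n_below == total:
            continue
        p = n_below / total
        z0 = m1 - np.sqrt((1 - p) / p * var)
        z1 = m1 + np.sqrt(p / (1 - p) * var)
        if p * z0**3 + (1 - p) * z1**3 >= m3:
            return t
    raise ValueError("no candidate cut-off reaches the third moment")


def exact_mwu_enumeration(a, b) -> tuple[float, float]:
    """Mann-Whitney U and exact two-sided p by full rank enumeration.

    Enumerates every assignment of pooled ranks to group a (tie-free data
    required); p = 2 * min(P(U <= u), P(U >= u)), capped at 1.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate([a, b])
    assert np.unique(pooled).size == pooled.size, "oracle requires no ties"
    ranks = pooled.argsort().argsort() + 1
    n_a = len(a)
    u_obs = float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2)
    all_ranks = np.arange(1, len(pooled) + 1)
    u_null = np.array(
        [
            sum(c) - n_a * (n_a + 1) / 2
            for c in combinations(all_ranks, n_a)
        ],
        dtype=float,
    )
    p_low = np.mean(u_null <= u_obs)
    p_high = np.mean(u_null >= u_obs)
    return u_obs, float(min(1.0, 2 * min(p_low, p_high)))


def brute_force_offset(frame_a, frame_b, max_shift: int):
    """Best shift by per-candidate np.corrcoef (independent of the
    implementation's hand-rolled Pearson)."""
    a = np.asarray(frame_a, float)
    b = np.asarray(frame_b, float)
    n = a.shape[0]
    best, best_score = 0, -np.inf
    for s in range(max_shift + 1):
        x = a[s:].ravel()
        y = b[: n - s].ravel() if s else b.ravel()
        if x.std() == 0 or y.std() == 0:
            score = 0.0
        else:
            score = float(np.corrcoef(x, y)[0, 1])
        if score > best_score:
            best, best_score = s, score
    return best, best_score


def sort_based_quantiles(values):
    """Median/quartiles by explicit order statistics with linear
    interpolation (independent of np.percentile)."""
    x = np.sort(np.asarray(values, float))
    n = len(x)

    def q(p):
        h = (n - 1) * p
        lo = int(np.floor(h))
        hi = min(lo + 1, n - 1)
        return x[lo] + (h - lo) * (x[hi] - x[lo])

    return q(0.5), q(0.25), q(0.75)
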