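"""Circular binary segmentation (CBS) of normalized copy-ratio profiles.

The signal on each chromosome is treated as a circle; for every arc the
two-sample statistic

    Z_ij = (mean_in - mean_out) / (s * sqrt(1/k + 1/(n-k)))

is computed, with ``k`` the arc length and ``s`` the pooled
within-group SD.  The maximizing arc is tested by permutation: the
p-value is the fraction of random shuffles of the segment whose maximal
statistic reaches the observed one.  A significant arc splits the
segment at its boundaries (two breakpoints for an interior arc, one for
an arc touching an edge) and the procedure recurses.

Complementary arcs have identical |Z| on a circle, so the search runs
over linear sub-intervals only.  The permutation loop stops early as
soon as the exceedance count already guarantees p > alpha — the
split/no-split decision is identical to the full run, just cheaper.

Each segment gets an approximated z-score,
``z = (mean_ratio - 1) * sqrt(n_bins) / noise_sd``, the deviation of
its mean from diploid in units of the profile's per-bin noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .genome import GenomeModel
from .normalize import NormalizedProfile

MIN_SPLIT_LEN = 4  # below this no split statistic is defined (s has 0 df)


@dataclass(frozen=True)
class Segment:
    """An equal-level region of one chromosome.

    ``start_bin``/``end_bin`` are half-open indices into the
    chromosome's mappable bins; ``start_bp``/``end_bp`` bound the
    corresponding bins in genome coordinates.
    """

    chrom: str
    start_bin: int
    end_bin: int
    start_bp: int
    end_bp: int
    mean_ratio: float
    n_bins: int
    z_score: float


# The search maximizes the between-group sum of squares
#     V_ij = U_ij^2 / (k (n-k)),   U_ij = (S_j - S_i) - k * mean(x),
# which is a strictly increasing function of |Z|:
#     Z^2 = n V (n-2) / (W - n V),   W = total sum of squares,
# and W is invariant under permutation of x.  Maximizing V is therefore
# equivalent to maximizing |Z|, and a permutation exceeds the observed
# statistic iff its maximal V does — which allows a 3-flop inner loop
# and early exit per shuffle.


@njit(cache=True)
def _centered_prefix(x: np.ndarray) -> np.ndarray:  # pragma: no cover
    n = x.size
    mu = x.sum() / n
    C = np.empty(n + 1)
    C[0] = 0.0
    for t in range(n):
        C[t + 1] = C[t] + (x[t] - mu)
    # exactly zero by construction; forcing it keeps the structural tie
    # between an edge arc (0, b) and its complement (b, n) bitwise exact,
    # so the smallest-(i, j) tie-break is deterministic
    C[n] = 0.0
    return C


@njit(cache=True)
def _best_arc_v(x: np.ndarray, min_seg: int):  # pragma: no cover - JIT
    """Arc maximizing V with every resulting piece >= min_seg.

    Returns (V_best, i, j); ties broken by smallest i, then smallest j.
    (-1.0, -1, -1) when no admissible arc exists.
    """
    n = x.size
    C = _centered_prefix(x)
    inv = np.empty(n + 1)
    for k in range(1, n):
        inv[k] = 1.0 / (k * (n - k))
    best = -1.0
    bi = -1
    bj = -1
    for i in range(n):
        if i != 0 and i < min_seg:
            continue
        ci = C[i]
        for j in range(i + 1, n + 1):
            k = j - i
            if k < min_seg or k > n - min_seg:
                continue
            if j != n and n - j < min_seg:
                continue
            u = C[j] - ci
            v = u * u * inv[k]
            if v > best:
                best = v
                bi = i
                bj = j
    return best, bi, bj


@njit(cache=True)
def _scan_exceeds(x: np.ndarray, v_obs: float, min_seg: int,
                  inv: np.ndarray) -> bool:  # pragma: no cover - JIT
    """True iff some admissible arc of ``x`` has V >= v_obs."""
    n = x.size
    C = _centered_prefix(x)
    for i in range(n):
        if i != 0 and i < min_seg:
            continue
        ci = C[i]
        for j in range(i + 1, n + 1):
            k = j - i
            if k < min_seg or k > n - min_seg:
                continue
            if j != n and n - j < min_seg:
                continue
            u = C[j] - ci
            if u * u * inv[k] >= v_obs:
                return True
    return False


@njit(cache=True)
def _perm_significant(x: np.ndarray, v_obs: float, min_seg: int,
                      n_perm: int, allow: int,
                      seed: int) -> bool:  # pragma: no cover - JIT
    """Permutation decision: p <= alpha iff at most ``allow`` of
    ``n_perm`` shuffles reach the observed V.

    Stops as soon as the exceedance count rules significance out; the
    decision is identical to the full run.
    """
    n = x.size
    inv = np.empty(n + 1)
    for k in range(1, n):
        inv[k] = 1.0 / (k * (n - k))
    np.random.seed(seed)
    y = x.copy()
    exceed = 0
    for _ in range(n_perm):
        np.random.shuffle(y)
        if _scan_exceeds(y, v_obs, min_seg, inv):
            exceed += 1
            if exceed > allow:
                return False
    return True


def _v_to_t(v: float, w: float, n: int) -> float:
    """Convert the maximal V to the two-sample |Z| statistic."""
    denom = w - n * v
    if denom <= 1e-12 * max(1.0, w):
        return math.inf
    return math.sqrt(n * v * (n - 2) / denom)


def _max_arc(x: np.ndarray, min_seg: int) -> tuple[float, int, int]:
    """Maximal |Z| arc of ``x``; (0.0, -1, -1) for constant input."""
    n = x.size
    w = float(((x - x.mean()) ** 2).sum())
    if w <= 1e-12 * max(1.0, float((x * x).sum())):
        return 0.0, -1, -1
    v, i, j = _best_arc_v(x, min_seg)
    if i < 0:
        return 0.0, -1, -1
    # V as computed uses per-bin scaling: Z^2 = nV(n-2)/(W-nV)
    return _v_to_t(v, w, n), i, j


def cbs_split_statistic(values: np.ndarray) -> tuple[float, int, int]:
    """Maximal circular split statistic over all arcs.

    Parameters
    ----------
    values
        Sequence of length >= 4.

    Returns
    -------
    (T_max, i, j)
        The maximal |Z| and the half-open arc ``values[i:j]`` attaining
        it; ties resolved to the smallest i, then smallest j.  A
        constant input yields ``(0.0, -1, -1)``.
    """
    x = np.ascontiguousarray(values, dtype=np.float64)
    if x.size < MIN_SPLIT_LEN:
        raise ValueError(f"need at least {MIN_SPLIT_LEN} values, got {x.size}")
    t, i, j = _max_arc(x, 1)
    return float(t), int(i), int(j)


def cbs_segment(
    values: np.ndarray,
    alpha: float = 0.01,
    n_perm: int = 1000,
    min_width: int = 2,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[int]:
    """Recursive CBS: return sorted interior breakpoints of ``values``.

    A segment is split where its maximal arc statistic is significant at
    ``alpha`` under ``n_perm`` permutations; segments shorter than
    ``min_width`` bins are never created.  Deterministic given the seed.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if min_width < 1:
        raise ValueError("min_width must be >= 1")
    x = np.ascontiguousarray(values, dtype=np.float64)
    if rng is None:
        rng = np.random.default_rng(seed)

    allow = int(math.floor(alpha * n_perm))
    breakpoints: list[int] = []
    # explicit left-to-right recursion keeps the RNG stream deterministic
    segments = [(0, x.size)]
    while segments:
        lo, hi = segments.pop(0)
        n = hi - lo
        if n < max(MIN_SPLIT_LEN, 2 * min_width):
            continue
        seg = np.ascontiguousarray(x[lo:hi])
        w = float(((seg - seg.mean()) ** 2).sum())
        if w <= 1e-12 * max(1.0, float((seg * seg).sum())):
            continue  # constant segment: nothing to split
        v_obs, i, j = _best_arc_v(seg, min_width)
        if i < 0:
            continue
        perm_seed = int(rng.integers(0, 2 ** 31 - 1))
        if not _perm_significant(seg, v_obs, min_width, n_perm, allow,
                                 perm_seed):
            continue
        cuts = [c for c in (i, j) if 0 < c < n]
        for c in cuts:
            breakpoints.append(lo + c)
        bounds = [lo] + [lo + c for c in cuts] + [hi]
        # recurse left-to-right on the newly created pieces
        pieces = [(bounds[t], bounds[t + 1]) for t in range(len(bounds) - 1)]
        segments = pieces + segments
    return sorted(breakpoints)


def segment_zscore(mean_ratio: float, n_bins: int, noise_sd: float) -> float:
    """Approximated z-score of a segment: departure of its mean from the
    diploid ratio 1, in per-bin noise units, scaled by sqrt(n_bins)."""
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    return (mean_ratio - 1.0) * math.sqrt(n_bins) / noise_sd


def segment_profile(
    profile: NormalizedProfile,
    model: GenomeModel,
    alpha: float = 0.01,
    n_perm: int = 1000,
    min_width: int = 2,
    seed: int | None = None,
) -> list[Segment]:
    """Segment every chromosome of a normalized profile.

    The per-chromosome segments partition its mappable bins without gap
    or overlap; each carries the mean ratio and approximated z-score.
    """
    mb = model.mappable_view()
    if profile.ratio.size != mb.n:
        raise ValueError("profile does not match the model's bin grid")
    rng = np.random.default_rng(seed)
    out: list[Segment] = []
    for chrom, sl in mb.chrom_slices():
        vals = profile.ratio[sl]
        starts = mb.start[sl]
        ends = mb.end[sl]
        n = vals.size
        if n >= max(MIN_SPLIT_LEN, 2 * min_width):
            bps = cbs_segment(vals, alpha=alpha, n_perm=n_perm,
                              min_width=min_width, rng=rng)
        else:
            bps = []
        bounds = [0] + bps + [n]
        for a, b in zip(bounds[:-1], bounds[1:]):
            mean = float(vals[a:b].mean())
            out.append(Segment(
                chrom=chrom,
                start_bin=a,
                end_bin=b,
                start_bp=int(starts[a]),
                end_bp=int(ends[b - 1]),
                mean_ratio=mean,
                n_bins=b - a,
                z_score=segment_zscore(mean, b - a, profile.noise_sd),
            ))
    return out
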