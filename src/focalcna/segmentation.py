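"""Normalization, circular binary segmentation, and gain/loss calling.

Per-sample log2ratio profiles are median normalized, partitioned into
constant-level segments by circular binary segmentation (CBS), recentred so the
modal (assumed diploid) segment level sits at 0, and called loss/neutral/gain
by symmetric thresholds.

CBS considers, within each chromosome (and recursively within each accepted
segment), every arc of probes against its complement and accepts the
best-scoring arc as a split when a permutation test on the circular two-sample
t-like statistic is significant. For long segments the arc-width search uses
all widths up to a cutoff plus a geometric width grid, followed by a local
exhaustive refinement of the accepted boundaries; for short segments (n below
``FULL_SEARCH_MAX``) the search is fully exhaustive, so small-input behaviour
is identical to a brute-force scan over all split pairs. The permutation test
stops early once the running p-value bound decides against (or for) alpha.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "median_normalize",
    "cbs_segment",
    "segment_mode",
    "mode_normalize",
    "call_states",
    "CbsParams",
]

# Segments with at most this many probes are searched over every (i, j) pair.
FULL_SEARCH_MAX = 130
# Above the cutoff: all arc widths up to GRID_FULL_WIDTHS, then geometric.
GRID_FULL_WIDTHS = 32
GRID_RATIO = 1.3


@dataclass(frozen=True)
class CbsParams:
    """CBS settings: split significance, permutation budget, width/merge rules."""

    alpha: float = 0.01
    n_perm: int = 1000
    min_width: int = 3
    merge_tol: float = 0.05

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_width < 2:
            raise ValueError("min_width must be >= 2")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


def median_normalize(values):
    """Shift a profile so the median of its non-missing log2ratios is 0."""
    arr = np.asarray(values, dtype=float)
    finite = np.isfinite(arr)
    if not finite.any():
        raise ValueError("profile has no non-missing values")
    med = np.median(arr[finite])
    out = arr - med
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return out


# ---------------------------------------------------------------------------
# CBS core
# ---------------------------------------------------------------------------

def _width_grid(n: int, min_width: int) -> np.ndarray:
    """Candidate arc widths k with min_width <= k <= n - min_width."""
    kmax = n - min_width
    if kmax < min_width:
        return np.array([], dtype=int)
    if n <= FULL_SEARCH_MAX:
        return np.arange(min_width, kmax + 1)
    ks = list(range(min_width, min(GRID_FULL_WIDTHS, kmax) + 1))
    k = float(ks[-1])
    while ks[-1] < kmax:
        k *= GRID_RATIO
        ks.append(min(int(math.ceil(k)), kmax))
    return np.unique(np.array(ks, dtype=int))


def _count_exceed(cs: np.ndarray, n: int, ks: np.ndarray, observed: float) -> int:
    """Rows of a (m, n+1) cumulative-sum matrix whose max statistic >= observed.

    Rows must come from mean-centred data (row total ~ 0), which removes the
    arc-mean correction term. Exits early once every row has exceeded.
    """
    # Any arc deviation |S_j - S_i| is bounded by the row's cumsum range, so a
    # row can only exceed if ptp(cs) >= observed * min_k sqrt(k(n-k)/n).
    obs = observed - 1e-12
    min_scale = math.sqrt(min(int(k) * (n - int(k)) for k in ks) / n)
    candidate = np.flatnonzero(np.ptp(cs, axis=1) >= obs * min_scale)
    exceeded = np.zeros(candidate.size, dtype=bool)
    for k in ks:
        thr = obs * math.sqrt(k * (n - k) / n)
        live = ~exceeded
        if not live.any():
            break
        rows = candidate[live]
        dev = cs[rows, k:] - cs[rows, : n + 1 - k]
        hit = (dev.max(axis=1) >= thr) | (dev.min(axis=1) <= -thr)
        exceeded[np.flatnonzero(live)[hit]] = True
    return int(exceeded.sum())


def _argmax_stat(x: np.ndarray, ks: np.ndarray):
    """Best (stat, i, j) over arcs [i, j) with widths in ks (x mean-centred)."""
    n = x.size
    cs = np.concatenate([[0.0], np.cumsum(x)])
    best, bi, bj = -1.0, 0, n
    for k in ks:
        dev = np.abs(cs[k:] - cs[: n + 1 - k])
        i = int(np.argmax(dev))
        u = dev[i] / math.sqrt(k * (n - k) / n)
        if u > best + 1e-15:
            best, bi, bj = u, i, i + k
    return best, bi, bj


def _refine(x: np.ndarray, i: int, j: int, min_width: int):
    """Exhaustive re-search of widths near an accepted grid solution."""
    n = x.size
    if n <= FULL_SEARCH_MAX:
        return i, j
    k = j - i
    lo = max(min_width, int(k / GRID_RATIO) - 2)
    hi = min(n - min_width, int(math.ceil(k * GRID_RATIO)) + 2)
    ks = np.arange(lo, hi + 1)
    _, ri, rj = _argmax_stat(x, ks)
    return ri, rj


def _perm_pvalue(x, observed, ks, rng, params: CbsParams):
    """Sequential permutation p-value for the max circular statistic.

    Returns the permutation p estimate (1 + exceedances) / (1 + permutations).
    Stops early when the count of exceedances already forces p >= alpha, or
    when enough exceedance-free permutations guarantee p < alpha.
    """
    n = x.size
    n_perm = params.n_perm
    reject_count = math.floor(params.alpha * n_perm) + 1
    accept_m = int(math.ceil(1.0 / params.alpha)) + 1  # (1+0)/(1+m) < alpha
    chunks, done, count = [24, accept_m - 24, 299, 600], 0, 0
    tiled = np.tile(x, (1, 1))
    while done < n_perm:
        m = min(chunks[0] if chunks else 256, n_perm - done)
        if chunks:
            chunks.pop(0)
        xs = rng.permuted(np.repeat(tiled, m, axis=0), axis=1)
        cs = np.concatenate(
            [np.zeros((m, 1)), np.cumsum(xs, axis=1)], axis=1
        )
        count += _count_exceed(cs, n, ks, observed)
        done += m
        if count >= reject_count:
            return max((1 + count) / (1 + done), params.alpha)
        if count == 0 and done >= accept_m:
            return (1 + count) / (1 + done)
    return (1 + count) / (1 + n_perm)


def _segment_indices(x: np.ndarray, params: CbsParams, rng) -> list:
    """Changepoint indices (excluding 0 and n) for one chromosome's values."""
    n = x.size
    boundaries: list = []
    stack = [(0, n)]
    while stack:
        lo, hi = stack.pop()
        seg = x[lo:hi]
        m = hi - lo
        if m < 2 * params.min_width or np.ptp(seg) < 1e-12:
            continue
        seg = seg - seg.mean()  # statistic is location-invariant
        ks = _width_grid(m, params.min_width)
        if ks.size == 0:
            continue
        observed, i, j = _argmax_stat(seg, ks)
        if observed <= 0:
            continue
        p = _perm_pvalue(seg, observed, ks, rng, params)
        if p >= params.alpha:
            continue
        i, j = _refine(seg, i, j, params.min_width)
        if i < params.min_width:
            i = 0
        if m - j < params.min_width:
            j = m
        if i == 0 and j == m:
            continue
        cuts = [c for c in (i, j) if 0 < c < m]
        for c in cuts:
            boundaries.append(lo + c)
        edges = [0] + cuts + [m]
        for a, b in zip(edges[:-1], edges[1:]):
            stack.append((lo + a, lo + b))
    return sorted(boundaries)


def _merge_close(x: np.ndarray, bounds: list, tol: float) -> list:
    """Drop boundaries between segments whose means differ by < tol."""
    changed = True
    bounds = list(bounds)
    while changed and bounds:
        changed = False
        edges = [0] + bounds + [x.size]
        means = [np.nanmean(x[a:b]) for a, b in zip(edges[:-1], edges[1:])]
        diffs = np.abs(np.diff(means))
        if diffs.size and diffs.min() < tol:
            worst = int(np.argmin(diffs))
            bounds.pop(worst)
            changed = True
    return bounds


def cbs_segment(
    grid: pd.DataFrame,
    values,
    alpha: float = 0.01,
    n_perm: int = 1000,
    min_width: int = 3,
    seed: int | None = None,
    merge_tol: float = 0.05,
    sample_id: str = "sample",
) -> pd.DataFrame:
    """Segment one sample's profile into constant-level segments per chromosome.

    Parameters
    ----------
    grid : DataFrame with columns chrom, pos (sorted; one row per probe).
    values : array-like of log2ratios aligned to the grid; NaN marks missing
        probes. Missing probes are excluded from all statistics but stay inside
        the enclosing segment (they inherit its state downstream).
    seed : seed for the permutation tests (required for reproducibility).

    Returns a DataFrame with one row per segment:
    [sample_id, chrom, start_idx, end_idx, start_bp, end_bp, mean, n_probes],
    where start_idx/end_idx are inclusive chromosome-local probe indices and
    [start_bp, end_bp) tiles the chromosome's probed extent contiguously (each
    segment ends where the next one starts; the last ends one bp past its last
    probe).
    """
    params = CbsParams(alpha=alpha, n_perm=n_perm, min_width=min_width,
                       merge_tol=merge_tol)
    params.validate()
    rng = np.random.default_rng(seed)
    arr = np.asarray(values, dtype=float)
    if len(arr) != len(grid):
        raise ValueError("values not aligned to probe grid")

    records = []
    for chrom in grid["chrom"].unique():
        cidx = np.flatnonzero((grid["chrom"] == chrom).to_numpy())
        pos = grid["pos"].to_numpy()[cidx]
        v = arr[cidx]
        present = np.flatnonzero(np.isfinite(v))
        if present.size < params.min_width:
            logger.warning(
                "chromosome %s has %d usable probes (< min_width); "
                "emitting a single segment", chrom, present.size
            )
            bounds: list = []
        else:
            x = v[present]
            bounds = _segment_indices(x, params, rng)
            bounds = _merge_close(x, bounds, params.merge_tol)
        # map compressed boundaries back to chromosome-local probe indices
        local = [0] + [int(present[b]) for b in bounds] + [len(cidx)]
        for a, b in zip(local[:-1], local[1:]):
            seg_vals = v[a:b]
            mean = float(np.nanmean(seg_vals)) if np.isfinite(seg_vals).any() else np.nan
            start_bp = int(pos[a])
            end_bp = int(pos[b]) if b < len(cidx) else int(pos[-1]) + 1
            records.append(
                (sample_id, chrom, a, b - 1, start_bp, end_bp, mean, b - a)
            )
    return pd.DataFrame(
        records,
        columns=["sample_id", "chrom", "start_idx", "end_idx",
                 "start_bp", "end_bp", "mean", "n_probes"],
    )


# ---------------------------------------------------------------------------
# mode normalization and calling
# ---------------------------------------------------------------------------

def segment_mode(segments: pd.DataFrame, bandwidth: float = 0.05) -> float:
    """Probe-weighted kernel-density peak over segment means.

    The density is a Gaussian mixture over segment means weighted by probe
    counts, evaluated on a fixed grid spanning the means. When several peaks
    tie (within relative 1e-9), the one closest to zero wins — the modal level
    is assumed diploid, and of equally common levels the least aberrant is the
    safer diploid guess.
    """
    means = segments["mean"].to_numpy(dtype=float)
    weights = segments["n_probes"].to_numpy(dtype=float)
    ok = np.isfinite(means)
    means, weights = means[ok], weights[ok]
    if means.size == 0:
        raise ValueError("no segments with defined means")
    if means.size == 1:
        return float(means[0])
    pad = 3 * bandwidth
    gx = np.linspace(means.min() - pad, means.max() + pad, 2001)
    dens = (weights[:, None]
            * np.exp(-0.5 * ((gx[None, :] - means[:, None]) / bandwidth) ** 2)
            ).sum(axis=0)
    # locate local maxima, refine each by parabolic interpolation so that
    # equally tall peaks compare exactly rather than at grid resolution
    interior = np.flatnonzero(
        (dens[1:-1] >= dens[:-2]) & (dens[1:-1] >= dens[2:])
    ) + 1
    if interior.size == 0:
        interior = np.array([int(np.argmax(dens))])
    peaks = []
    step = gx[1] - gx[0]
    for i in interior:
        if 0 < i < len(gx) - 1:
            denom = dens[i - 1] - 2 * dens[i] + dens[i + 1]
            off = 0.0 if denom == 0 else 0.5 * (dens[i - 1] - dens[i + 1]) / denom
            off = float(np.clip(off, -0.5, 0.5))
            xs = gx[i] + off * step
            fs = dens[i] - 0.25 * (dens[i - 1] - dens[i + 1]) * off
        else:
            xs, fs = gx[i], dens[i]
        peaks.append((xs, fs))
    fmax = max(f for _, f in peaks)
    cand = [x for x, f in peaks if f >= fmax * (1 - 1e-9)]
    return float(min(cand, key=abs))


def mode_normalize(segments: pd.DataFrame, bandwidth: float = 0.05):
    """Recentre segment means so the modal level is 0.

    Returns (segments, shift); callers should subtract the same shift from the
    underlying probe-level profile so segments and probes stay consistent.
    """
    shift = segment_mode(segments, bandwidth=bandwidth)
    out = segments.copy()
    out["mean"] = out["mean"] - shift
    return out, shift


def call_states(
    segments: pd.DataFrame,
    loss_threshold: float = -0.2,
    gain_threshold: float = 0.2,
) -> pd.DataFrame:
    """Call each segment loss/neutral/gain by inclusive symmetric thresholds."""
    if not loss_threshold < 0 < gain_threshold:
        raise ValueError("need loss_threshold < 0 < gain_threshold")
    out = segments.copy()
    mean = out["mean"].to_numpy(dtype=float)
    state = np.where(mean <= loss_threshold, "loss",
                     np.where(mean >= gain_threshold, "gain", "neutral"))
    state[~np.isfinite(mean)] = "neutral"
    out["state"] = state
    return out
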