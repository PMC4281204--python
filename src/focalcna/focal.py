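"""Focal aberration extraction, germline-CNV filtering, and HFR computation.

A focal aberration is a called gain or loss spanning at most 3 Mb — small
enough that it plausibly pinpoints a single selected driver gene. Two rules
remove germline copy-number variants (CNVs) masquerading as somatic events:

1. a focal aberration mostly covered by intervals from a germline CNV catalog
   (e.g. a Database of Genomic Variants snapshot) is removed;
2. a genomic location where focal gains recur (>=2 samples) AND focal losses
   recur is a polymorphic locus, not a selected somatic event, and every focal
   aberration there is removed.

Surviving recurrent focal aberrations are reduced per direction to their
high-frequency region (HFR): the smallest genomic run where the number of
distinct samples with a covering focal aberration is maximal. Each HFR also
counts the samples whose aberrations of any size contain it (the "total").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Aberration",
    "FilterLedger",
    "HFR",
    "extract_aberrations",
    "filter_catalog_overlap",
    "filter_bidirectional",
    "compute_hfrs",
    "count_total",
    "count_totals",
    "make_ledger",
    "run_focal_stage",
    "hfrs_to_frame",
]

FOCAL_LIMIT_BP = 3_000_000  # inclusive: "3 Mb and smaller"


@dataclass(frozen=True)
class Aberration:
    """One contiguous same-direction aberrant run in one sample (bp half-open)."""

    sample_id: str
    chrom: str
    start_bp: int
    end_bp: int
    direction: str  # "gain" | "loss"
    focal: bool

    @property
    def size_bp(self) -> int:
        return self.end_bp - self.start_bp


@dataclass
class FilterLedger:
    """Bookkeeping of the two germline-CNV removal steps."""

    n_recurrent_observed: int
    n_removed_catalog: int
    n_removed_bidirectional: int
    n_retained: int

    def __post_init__(self):
        expected = (self.n_recurrent_observed - self.n_removed_catalog
                    - self.n_removed_bidirectional)
        if min(self.n_recurrent_observed, self.n_removed_catalog,
               self.n_removed_bidirectional) < 0 or expected < 0:
            raise ValueError("inconsistent filter ledger counts")
        if self.n_retained != expected:
            raise ValueError(
                f"ledger identity violated: {self.n_retained} != {expected}"
            )


@dataclass
class HFR:
    """A recurrent high-frequency region (one direction)."""

    chrom: str
    start_bp: int
    end_bp: int
    direction: str
    focal_count: int
    total_count: int = 0
    member_aberrations: list = field(default_factory=list)
    genes: list = field(default_factory=list)


def make_ledger(stage_counts) -> FilterLedger:
    """Build a FilterLedger from (observed, removed_catalog, removed_bidir)."""
    n_obs, n_cat, n_bid = (int(c) for c in stage_counts)
    return FilterLedger(n_obs, n_cat, n_bid, n_obs - n_cat - n_bid)


def extract_aberrations(
    calls: pd.DataFrame, focal_limit_bp: int = FOCAL_LIMIT_BP
) -> list:
    """Merge adjacent same-state non-neutral segments into aberrations.

    ``calls`` is the segment table from the caller (one or many samples) with
    columns sample_id, chrom, start_bp, end_bp, state; segments must tile each
    chromosome. The focal flag is inclusive: size <= focal_limit_bp.
    """
    out = []
    for (sample, chrom), sub in calls.groupby(["sample_id", "chrom"], sort=False):
        sub = sub.sort_values("start_bp")
        cur = None  # (state, start, end)
        for row in sub.itertuples(index=False):
            if row.state == "neutral":
                if cur:
                    out.append(_mk_ab(sample, chrom, cur, focal_limit_bp))
                    cur = None
                continue
            if cur and cur[0] == row.state:
                cur = (cur[0], cur[1], row.end_bp)
            else:
                if cur:
                    out.append(_mk_ab(sample, chrom, cur, focal_limit_bp))
                cur = (row.state, row.start_bp, row.end_bp)
        if cur:
            out.append(_mk_ab(sample, chrom, cur, focal_limit_bp))
    return out


def _mk_ab(sample, chrom, cur, limit):
    state, start, end = cur
    return Aberration(
        sample_id=sample, chrom=chrom, start_bp=int(start), end_bp=int(end),
        direction=state, focal=(end - start) <= limit,
    )


def _merged_intervals(df: pd.DataFrame) -> dict:
    """Per-chromosome merged (start, end) interval lists from a BED3 frame."""
    merged = {}
    for chrom, sub in df.groupby("chrom"):
        ivals = sorted(zip(sub["start"], sub["end"]))
        acc = []
        for s, e in ivals:
            if acc and s <= acc[-1][1]:
                acc[-1] = (acc[-1][0], max(acc[-1][1], e))
            else:
                acc.append((s, e))
        merged[chrom] = acc
    return merged


def filter_catalog_overlap(
    aberrations: list,
    catalog: pd.DataFrame,
    min_covered_fraction: float = 0.5,
):
    """Remove focal aberrations mostly covered by germline-CNV catalog intervals.

    A focal aberration is removed when the union of catalog intervals covers at
    least ``min_covered_fraction`` of its length. Non-focal aberrations are
    never removed by this rule. Returns (kept, removed).
    """
    if any(not sub["start"].is_monotonic_increasing
           for _, sub in catalog.groupby("chrom")):
        catalog = catalog.sort_values(["chrom", "start"])
        logger.warning("CNV catalog was unsorted; sorted internally")
    merged = _merged_intervals(catalog)
    kept, removed = [], []
    for ab in aberrations:
        if not ab.focal:
            kept.append(ab)
            continue
        cov = 0
        for s, e in merged.get(ab.chrom, ()):
            if s >= ab.end_bp:
                break
            cov += max(0, min(e, ab.end_bp) - max(s, ab.start_bp))
        if cov >= min_covered_fraction * ab.size_bp:
            removed.append(ab)
        else:
            kept.append(ab)
    return kept, removed


def _single_linkage_clusters(aberrations: list) -> list:
    """Cluster intervals by >=1 bp overlap (single linkage) per chromosome."""
    clusters = []
    by_chrom: dict = {}
    for ab in aberrations:
        by_chrom.setdefault(ab.chrom, []).append(ab)
    for chrom in sorted(by_chrom):
        abs_sorted = sorted(by_chrom[chrom], key=lambda a: (a.start_bp, a.end_bp))
        cur, cur_end = [], None
        for ab in abs_sorted:
            if cur and ab.start_bp < cur_end:
                cur.append(ab)
                cur_end = max(cur_end, ab.end_bp)
            else:
                if cur:
                    clusters.append(cur)
                cur, cur_end = [ab], ab.end_bp
        if cur:
            clusters.append(cur)
    return clusters


def filter_bidirectional(aberrations: list, recurrence_min: int = 2):
    """Remove focal clusters with recurrent gains AND recurrent losses.

    Focal aberrations (both directions pooled) are clustered by single-linkage
    genomic overlap; a cluster is removed in full when it holds focal gains
    from >= recurrence_min distinct samples and focal losses from
    >= recurrence_min distinct samples. Returns (kept, removed); non-focal
    aberrations pass straight into kept.
    """
    focal = [a for a in aberrations if a.focal]
    kept = [a for a in aberrations if not a.focal]
    removed = []
    for cluster in _single_linkage_clusters(focal):
        gains = {a.sample_id for a in cluster if a.direction == "gain"}
        losses = {a.sample_id for a in cluster if a.direction == "loss"}
        if len(gains) >= recurrence_min and len(losses) >= recurrence_min:
            removed.extend(cluster)
        else:
            kept.extend(cluster)
    return kept, removed


def _depth_runs(members: list):
    """Per-base depth of distinct-sample coverage: leftmost maximal run at max depth.

    Each sample's intervals are unioned first so one sample never counts twice.
    Returns (start, end, max_depth).
    """
    per_sample: dict = {}
    for ab in members:
        per_sample.setdefault(ab.sample_id, []).append((ab.start_bp, ab.end_bp))
    events = []
    for ivals in per_sample.values():
        ivals.sort()
        acc = []
        for s, e in ivals:
            if acc and s <= acc[-1][1]:
                acc[-1] = (acc[-1][0], max(acc[-1][1], e))
            else:
                acc.append((s, e))
        for s, e in acc:
            events.append((s, 1))
            events.append((e, -1))
    events.sort()
    depth, best_depth = 0, 0
    run_start, best = None, None
    i = 0
    while i < len(events):
        x = events[i][0]
        while i < len(events) and events[i][0] == x:
            depth += events[i][1]
            i += 1
        if depth > best_depth:
            best_depth, run_start, best = depth, x, None
        elif run_start is not None and depth < best_depth and best is None:
            best = (run_start, x)
    return best[0], best[1], best_depth


def compute_hfrs(aberrations: list, recurrence_min: int = 2) -> list:
    """Smallest-overlap high-frequency regions of recurrent focal aberrations.

    Per direction, focal aberrations are clustered by single-linkage overlap;
    within each cluster the HFR is the (leftmost) maximal contiguous genomic
    run attaining the cluster's maximum per-base count of distinct covering
    samples. Clusters whose maximum count is below ``recurrence_min`` yield no
    HFR.
    """
    hfrs = []
    for direction in ("gain", "loss"):
        focal = [a for a in aberrations if a.focal and a.direction == direction]
        for cluster in _single_linkage_clusters(focal):
            if len({a.sample_id for a in cluster}) < recurrence_min:
                continue
            start, end, depth = _depth_runs(cluster)
            if depth < recurrence_min:
                continue
            hfrs.append(HFR(
                chrom=cluster[0].chrom, start_bp=start, end_bp=end,
                direction=direction, focal_count=depth,
                member_aberrations=list(cluster),
            ))
    hfrs.sort(key=lambda h: (h.chrom, h.start_bp, h.direction))
    return hfrs


def count_total(hfr: HFR, all_aberrations: list) -> HFR:
    """Count distinct samples with any same-direction aberration containing the HFR."""
    samples = {
        ab.sample_id
        for ab in all_aberrations
        if ab.chrom == hfr.chrom and ab.direction == hfr.direction
        and ab.start_bp <= hfr.start_bp and ab.end_bp >= hfr.end_bp
    }
    hfr.total_count = len(samples)
    return hfr


def count_totals(hfrs: list, all_aberrations: list) -> list:
    return [count_total(h, all_aberrations) for h in hfrs]


def run_focal_stage(
    calls: pd.DataFrame,
    catalog: pd.DataFrame,
    focal_limit_bp: int = FOCAL_LIMIT_BP,
    min_covered_fraction: float = 0.5,
    recurrence_min: int = 2,
):
    """Extraction -> catalog filter -> bidirectional filter -> HFRs + ledger.

    The ledger counts focal aberration records that are recurrent before any
    filtering (member of a same-direction single-linkage cluster covering
    >= recurrence_min distinct samples), then the removals among them.
    Returns dict with aberrations, kept, hfrs, ledger.
    """
    aberrations = extract_aberrations(calls, focal_limit_bp)
    recurrent = set()
    for direction in ("gain", "loss"):
        focal = [a for a in aberrations if a.focal and a.direction == direction]
        for cluster in _single_linkage_clusters(focal):
            if len({a.sample_id for a in cluster}) >= recurrence_min:
                recurrent.update(id(a) for a in cluster)

    kept1, removed_cat = filter_catalog_overlap(
        aberrations, catalog, min_covered_fraction
    )
    kept2, removed_bid = filter_bidirectional(kept1, recurrence_min)
    n_obs = len(recurrent)
    n_cat = sum(1 for a in removed_cat if id(a) in recurrent)
    n_bid = sum(1 for a in removed_bid if id(a) in recurrent)
    ledger = make_ledger((n_obs, n_cat, n_bid))

    hfrs = compute_hfrs(kept2, recurrence_min)
    count_totals(hfrs, kept2)
    return {
        "aberrations": aberrations,
        "kept": kept2,
        "removed_catalog": removed_cat,
        "removed_bidirectional": removed_bid,
        "hfrs": hfrs,
        "ledger": ledger,
    }


def hfrs_to_frame(hfrs: list, one_based: bool = False) -> pd.DataFrame:
    """HFR table in the published layout (one row per region, both directions).

    Coordinates default to 0-based half-open; ``one_based`` switches to 1-based
    inclusive for display.
    """
    rows = []
    for h in hfrs:
        start = h.start_bp + 1 if one_based else h.start_bp
        end = h.end_bp if one_based else h.end_bp
        rows.append({
            "Chrom": h.chrom,
            "Start": start,
            "End": end,
            "Size_kb": round((h.end_bp - h.start_bp) / 1000.0, 3),
            "Focal_gain": h.focal_count if h.direction == "gain" else 0,
            "Focal_loss": h.focal_count if h.direction == "loss" else 0,
            "Total_gain": h.total_count if h.direction == "gain" else 0,
            "Total_loss": h.total_count if h.direction == "loss" else 0,
            "Genes": ",".join(h.genes),
        })
    return pd.DataFrame(
        rows, columns=["Chrom", "Start", "End", "Size_kb", "Focal_gain",
                       "Focal_loss", "Total_gain", "Total_loss", "Genes"],
    )
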