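"""Gene-set enrichment and between-cohort aberration-frequency comparison.

Enrichment of a gene set (e.g. the genes inside retained focal aberrations) in
a curated driver census is tested with the upper-tail hypergeometric
distribution, optionally cross-checked by a seeded permutation test that draws
random same-size gene sets from the universe.

Cohort comparison remaps two call sets onto their common genomic bins and
tests, per bin, the per-sample ordinal state scores (loss=-1, neutral=0,
gain=+1) with a rank-sum test with ties; Benjamini-Hochberg q-values control
the FDR across bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentResult",
    "census_enrichment",
    "remap_to_common_grid",
    "compare_cohorts",
]

_STATE_SCORE = {"loss": -1, "neutral": 0, "gain": 1}


@dataclass
class EnrichmentResult:
    n_universe: int
    n_census_in_universe: int
    n_query: int
    n_overlap: int
    p_value: float
    p_permutation: float | None = None


def census_enrichment(
    query_genes,
    census_genes,
    universe_genes,
    n_perm: int = 0,
    seed: int | None = None,
) -> EnrichmentResult:
    """Upper-tail hypergeometric enrichment P(X >= overlap).

    The census is intersected with the universe; the query must be a subset of
    the universe. With ``n_perm`` > 0 a permutation p-value is added: the
    (+1/+1)-corrected fraction of seeded random same-size draws from the
    universe whose census overlap is at least the observed one.
    """
    universe = set(universe_genes)
    if not universe:
        raise ValueError("empty gene universe")
    query = set(query_genes)
    if not query <= universe:
        raise ValueError("query genes must be a subset of the universe")
    census = set(census_genes) & universe
    n, big_n = len(query), len(universe)
    k_census = len(census)
    overlap = len(query & census)
    p = float(sps.hypergeom.sf(overlap - 1, big_n, k_census, n))

    p_perm = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        uni = np.array(sorted(universe))
        is_census = np.isin(uni, sorted(census))
        hits = 0
        for _ in range(n_perm):
            draw = rng.choice(len(uni), size=n, replace=False)
            if int(is_census[draw].sum()) >= overlap:
                hits += 1
        p_perm = (hits + 1) / (n_perm + 1)
    return EnrichmentResult(
        n_universe=big_n, n_census_in_universe=k_census, n_query=n,
        n_overlap=overlap, p_value=min(p, 1.0), p_permutation=p_perm,
    )


def _call_matrix(calls: pd.DataFrame, bins: pd.DataFrame) -> pd.DataFrame:
    """Per-sample state score for every bin (bins never straddle boundaries)."""
    samples = sorted(calls["sample_id"].unique())
    mat = np.zeros((len(bins), len(samples)), dtype=int)
    for j, sample in enumerate(samples):
        sub = calls[calls["sample_id"] == sample]
        for chrom, csub in sub.groupby("chrom"):
            sel = bins["chrom"] == chrom
            if not sel.any():
                continue
            starts = csub["start_bp"].to_numpy()
            order = np.argsort(starts)
            starts = starts[order]
            ends = csub["end_bp"].to_numpy()[order]
            scores = csub["state"].map(_STATE_SCORE).to_numpy()[order]
            bstart = bins.loc[sel, "start"].to_numpy()
            idx = np.searchsorted(starts, bstart, side="right") - 1
            ok = (idx >= 0) & (bstart < ends[np.clip(idx, 0, None)])
            vals = np.where(ok, scores[np.clip(idx, 0, None)], 0)
            mat[np.flatnonzero(sel.to_numpy()), j] = vals
    out = pd.DataFrame(mat, columns=samples)
    return out


def remap_to_common_grid(calls_a: pd.DataFrame, calls_b: pd.DataFrame):
    """Remap two cohorts' per-sample calls onto shared intersection bins.

    ``calls_*`` hold one row per called interval: [sample_id, chrom, start_bp,
    end_bp, state]. Shared bins are the intersection tiling of both cohorts'
    interval boundaries, restricted per chromosome to the range covered by both
    cohorts; every sample's state propagates to each bin its interval covers.

    Returns (bins, scores_a, scores_b) where scores_* are bin x sample state
    score matrices.
    """
    chroms = sorted(set(calls_a["chrom"]) & set(calls_b["chrom"]))
    if not chroms:
        raise ValueError("cohorts share no chromosomes; disjoint genomes")
    rows = []
    for chrom in chroms:
        a = calls_a[calls_a["chrom"] == chrom]
        b = calls_b[calls_b["chrom"] == chrom]
        lo = max(a["start_bp"].min(), b["start_bp"].min())
        hi = min(a["end_bp"].max(), b["end_bp"].max())
        if hi <= lo:
            continue
        cuts = np.unique(np.concatenate([
            a["start_bp"].to_numpy(), a["end_bp"].to_numpy(),
            b["start_bp"].to_numpy(), b["end_bp"].to_numpy(), [lo, hi],
        ]))
        cuts = cuts[(cuts >= lo) & (cuts <= hi)]
        for s, e in zip(cuts[:-1], cuts[1:]):
            rows.append((chrom, int(s), int(e)))
    bins = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return bins, _call_matrix(calls_a, bins), _call_matrix(calls_b, bins)


def compare_cohorts(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    n_perm: int = 0,
    seed: int | None = None,
    fdr_q: float = 0.05,
) -> pd.DataFrame:
    """Per-bin rank-sum test (with ties) of state scores between two cohorts.

    Frequencies report the aberrant (non-neutral) sample fraction per bin.
    With ``n_perm`` > 0 the p-values come from a seeded permutation version of
    the rank-sum test; otherwise the tie-corrected asymptotic one. q-values are
    Benjamini-Hochberg; ``differs`` marks bins with q < fdr_q.
    """
    bins, sa, sb = remap_to_common_grid(calls_a, calls_b)
    if sa.shape[1] < 2 or sb.shape[1] < 2:
        raise ValueError("need >= 2 samples per cohort")
    method = "asymptotic"
    if n_perm > 0:
        method = sps.PermutationMethod(
            n_resamples=n_perm, rng=np.random.default_rng(seed)
        )
    pvals = np.ones(len(bins))
    for i in range(len(bins)):
        x, y = sa.iloc[i].to_numpy(), sb.iloc[i].to_numpy()
        if np.ptp(np.concatenate([x, y])) == 0:
            continue  # all-tied bin: no rank difference, p = 1
        pvals[i] = sps.mannwhitneyu(
            x, y, alternative="two-sided", method=method
        ).pvalue
    qvals = multipletests(pvals, method="fdr_bh")[1] if len(bins) else np.array([])
    out = bins.copy()
    out["freq_A"] = (sa != 0).mean(axis=1).to_numpy()
    out["freq_B"] = (sb != 0).mean(axis=1).to_numpy()
    out["p"] = pvals
    out["q"] = qvals
    out["differs"] = out["q"] < fdr_q
    return out
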