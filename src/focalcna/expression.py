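"""Expression normalization, fold changes, and copy-number concordance scoring.

Tumor expression intensities are compared against the mean of a reference
(osteoblast) profile as linear-scale fold changes (FC). A gene located in a
focal loss is scored underexpressed in a tumor when FC <= 0.75; a gene in a
focal gain is scored overexpressed when FC >= 1.5 (both thresholds inclusive
by default). A gene whose concordant aberrant expression reaches >= 35% of the
tumors is a candidate driver (tumor suppressor for losses, oncogene for
gains); candidates are confirmed when the same frequency rule holds in an
independent expression set.

Normalization follows standard two-channel microarray practice: a per-sample
intensity-dependent trend of the log2ratio is removed by local (LOESS)
regression, then quantile normalization equalizes the per-sample
distributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

logger = logging.getLogger(__name__)

__all__ = [
    "Thresholds",
    "FoldChangeTable",
    "CandidateDriver",
    "normalize_expression",
    "quantile_normalize",
    "compute_fold_changes",
    "fold_changes_from_log2",
    "flag_aberrant_expression",
    "select_candidates",
    "validate_candidates",
    "gene_flag_report",
]


@dataclass(frozen=True)
class Thresholds:
    """Selection thresholds for the concordance analysis."""

    fc_under: float = 0.75
    fc_over: float = 1.5
    freq_min: float = 0.35
    focal_limit_bp: int = 3_000_000
    recurrence_min: int = 2
    fdr_q: float = 0.05
    strict_fc: bool = False  # True: use strict < / > instead of <= / >=

    def __post_init__(self):
        if not 0 < self.fc_under < 1 < self.fc_over:
            raise ValueError("need 0 < fc_under < 1 < fc_over")
        if not 0 < self.freq_min <= 1:
            raise ValueError("freq_min must be in (0, 1]")


@dataclass
class FoldChangeTable:
    """Gene x tumor fold changes (linear scale) plus genes without a probe."""

    values: pd.DataFrame
    no_information: list = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class CandidateDriver:
    """A gene with concordant copy-number and expression change."""

    gene: str
    direction: str  # "loss" -> candidate tumor suppressor, "gain" -> oncogene
    freq_discovery: float  # fraction of tumors flagged, 0..1
    freq_validation: float | None = None
    status: str = "candidate"  # candidate | confirmed | not_confirmed | no_information


def _check_positive(df: pd.DataFrame, what: str) -> None:
    if (df.to_numpy() <= 0).any():
        raise ValueError(
            f"{what} contains non-positive intensities; expected linear scale"
        )


def quantile_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Classic quantile normalization: every column gets the mean sorted vector."""
    arr = df.to_numpy(dtype=float)
    order = np.argsort(arr, axis=0)
    sorted_vals = np.take_along_axis(arr, order, axis=0)
    mean_sorted = sorted_vals.mean(axis=1)
    ranks = df.rank(axis=0, method="average").to_numpy() - 1.0
    out = np.interp(ranks, np.arange(arr.shape[0]), mean_sorted)
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def normalize_expression(
    tumors: pd.DataFrame,
    reference: pd.DataFrame,
    span: float = 0.3,
) -> pd.DataFrame:
    """LOESS-detrended, quantile-normalized log2ratio matrix (tumor vs reference).

    Per sample, the log2ratio M = log2(tumor) - log2(mean reference) is
    regressed on the average log2 intensity A and the fitted trend subtracted;
    quantile normalization then equalizes the per-sample M distributions.
    Rows are the intersection of tumor and reference genes (>= 10 required).
    """
    if tumors.shape[1] < 2:
        raise ValueError("need >= 2 tumor samples")
    shared = tumors.index.intersection(reference.index)
    if len(shared) < 10:
        raise ValueError("fewer than 10 shared rows; local regression undefined")
    t = tumors.loc[shared]
    r = reference.loc[shared]
    _check_positive(t, "tumor matrix")
    _check_positive(r, "reference matrix")
    ref_log = np.log2(r.to_numpy(dtype=float)).mean(axis=1)
    m = np.log2(t.to_numpy(dtype=float)) - ref_log[:, None]
    a = 0.5 * (np.log2(t.to_numpy(dtype=float)) + ref_log[:, None])
    for j in range(m.shape[1]):
        fit = lowess(m[:, j], a[:, j], frac=span, return_sorted=False)
        m[:, j] = m[:, j] - fit
    out = pd.DataFrame(m, index=shared, columns=t.columns)
    return quantile_normalize(out)


def _collapse_probes(values: pd.DataFrame, probe_map: pd.DataFrame,
                     intensity: pd.DataFrame) -> pd.DataFrame:
    """Per gene keep the probe with highest mean intensity across all samples."""
    pm = probe_map.set_index("probe")["gene"]
    mean_int = intensity.mean(axis=1)
    keep = {}
    for probe, gene in pm.items():
        if probe not in values.index:
            continue
        if gene not in keep or mean_int[probe] > mean_int[keep[gene]]:
            keep[gene] = probe
    collapsed = values.loc[[keep[g] for g in keep]]
    collapsed.index = list(keep)
    return collapsed


def compute_fold_changes(
    tumors: pd.DataFrame,
    reference: pd.DataFrame,
    probe_map: pd.DataFrame | None = None,
    genes: list | None = None,
) -> FoldChangeTable:
    """Linear fold changes: tumor intensity over mean reference intensity.

    ``probe_map`` (columns probe, gene) collapses multi-probe genes by the
    probe with the highest mean intensity across all samples. ``genes``
    restricts and audits the query: requested genes with no usable probe are
    reported in ``no_information`` rather than silently dropped.
    """
    if reference.shape[1] < 1:
        raise ValueError("reference must have >= 1 sample")
    _check_positive(tumors, "tumor matrix")
    _check_positive(reference, "reference matrix")
    shared = tumors.index.intersection(reference.index)
    t = tumors.loc[shared]
    ref_mean = reference.loc[shared].mean(axis=1)
    fc = t.div(ref_mean, axis=0)
    if probe_map is not None:
        intensity = pd.concat([t, reference.loc[shared]], axis=1)
        fc = _collapse_probes(fc, probe_map, intensity)
    no_info: list = []
    if genes is not None:
        genes = list(genes)
        no_info = [g for g in genes if g not in fc.index]
        fc = fc.loc[[g for g in genes if g in fc.index]]
        if no_info:
            logger.info("%d gene(s) without a usable probe", len(no_info))
    return FoldChangeTable(values=fc, no_information=no_info)


def fold_changes_from_log2(
    normalized: pd.DataFrame,
    probe_map: pd.DataFrame | None = None,
    intensity: pd.DataFrame | None = None,
    genes: list | None = None,
) -> FoldChangeTable:
    """Fold changes from a normalized log2ratio matrix (FC = 2**M)."""
    fc = 2.0 ** normalized
    if probe_map is not None:
        if intensity is None:
            intensity = fc
        fc = _collapse_probes(fc, probe_map, intensity)
    no_info: list = []
    if genes is not None:
        genes = list(genes)
        no_info = [g for g in genes if g not in fc.index]
        fc = fc.loc[[g for g in genes if g in fc.index]]
    return FoldChangeTable(values=fc, no_information=no_info)


def flag_aberrant_expression(
    fc: FoldChangeTable,
    directions,
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Boolean gene x sample matrix of direction-concordant aberrant expression.

    ``directions`` maps every gene in the table to "loss" or "gain" (from its
    HFR). Loss-direction genes are flagged where FC <= fc_under; gain-direction
    genes where FC >= fc_over (strict inequalities when thresholds.strict_fc).
    """
    directions = dict(directions)
    missing = [g for g in fc.values.index if g not in directions]
    if missing:
        raise ValueError(f"genes lack an HFR direction: {missing[:5]}")
    flags = pd.DataFrame(False, index=fc.values.index, columns=fc.values.columns)
    vals = fc.values
    for gene in vals.index:
        row = vals.loc[gene]
        if directions[gene] == "loss":
            flags.loc[gene] = (row < thresholds.fc_under if thresholds.strict_fc
                               else row <= thresholds.fc_under)
        elif directions[gene] == "gain":
            flags.loc[gene] = (row > thresholds.fc_over if thresholds.strict_fc
                               else row >= thresholds.fc_over)
        else:
            raise ValueError(f"invalid direction for {gene}: {directions[gene]!r}")
    return flags


def select_candidates(
    flags: pd.DataFrame,
    thresholds: Thresholds,
    n_samples: int,
    directions,
) -> list:
    """Genes whose flagged fraction reaches freq_min (inclusive) of all tumors.

    The denominator is the full tumor expression set, not only copy-number
    carriers. Frequencies are kept unrounded; format as percentages only for
    display.
    """
    directions = dict(directions)
    out = []
    for gene in flags.index:
        freq = float(flags.loc[gene].sum()) / n_samples
        if freq >= thresholds.freq_min:
            out.append(CandidateDriver(
                gene=gene, direction=directions[gene],
                freq_discovery=freq, status="candidate",
            ))
    out.sort(key=lambda c: (c.direction, -c.freq_discovery, c.gene))
    return out


def validate_candidates(
    candidates: list,
    validation_fc: FoldChangeTable,
    thresholds: Thresholds = Thresholds(),
) -> list:
    """Confirm candidates in an independent expression set by the same rule.

    confirmed: validation flagged frequency >= freq_min; not_confirmed
    otherwise; no_information when the validation platform has no usable probe
    for the gene.
    """
    out = []
    n = validation_fc.n_samples
    no_probe = set(validation_fc.no_information)
    for cand in candidates:
        c = CandidateDriver(**vars(cand))
        if cand.gene in no_probe or cand.gene not in validation_fc.values.index:
            c.status = "no_information"
            c.freq_validation = None
        else:
            flags = flag_aberrant_expression(
                FoldChangeTable(validation_fc.values.loc[[cand.gene]]),
                {cand.gene: cand.direction}, thresholds,
            )
            c.freq_validation = float(flags.loc[cand.gene].sum()) / n
            c.status = ("confirmed" if c.freq_validation >= thresholds.freq_min
                        else "not_confirmed")
        out.append(c)
    return out


def gene_flag_report(flags: pd.DataFrame, directions) -> pd.DataFrame:
    """Per-gene report: direction, number and percent of tumors flagged."""
    directions = dict(directions)
    n = flags.shape[1]
    rows = [
        (g, directions.get(g, "?"), int(flags.loc[g].sum()),
         100.0 * flags.loc[g].sum() / n)
        for g in flags.index
    ]
    return pd.DataFrame(rows, columns=["gene", "direction", "n_flagged", "pct_flagged"])
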