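"""Synthetic osteosarcoma-like cohorts with planted copy-number and expression truth.

Every downstream stage of the pipeline (segmentation, germline-CNV filtering,
high-frequency-region computation, expression integration) is testable against
the truth records emitted here, without any external array data.

The generator plants four event classes on a shared probe grid:

* broad arm-level gains/losses (q-arms only, so focal loci stay interpretable),
* recurrent focal (<3 Mb) somatic aberrations around designated driver genes,
* non-recurrent focal passenger aberrations,
* shared polymorphic germline CNV loci — loci present in the CNV catalog carry a
  fixed inherited direction; loci absent from the catalog are bidirectional
  (gain and loss carriers at the same location), the signature the second
  germline filter removes.

Expression matrices couple planted drivers to dosage: loss-driver carriers are
under-expressed and gain-driver carriers over-expressed relative to a reference
(osteoblast-like) profile, on a log-normal intensity background.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomeSpec",
    "Genome",
    "TruthSet",
    "default_spec",
    "generate_genome",
    "generate_cn_cohort",
    "generate_expression",
    "write_profiles_tsv",
    "write_genes_bed",
    "write_cnv_catalog_bed",
    "write_expression_tsv",
    "write_truth_tsv",
]

# Default planted log2ratio amplitudes: ideal single-copy gain/loss in a
# diploid background (log2(3/2), log2(1/2)).
GAIN_AMPLITUDE = 0.58
LOSS_AMPLITUDE = -1.0


@dataclass(frozen=True)
class GenomeSpec:
    """Layout of the synthetic genome, probe grid, and catalogs."""

    chromosomes: tuple = (("chr1", 25_000_000),)
    probe_spacing_bp: int = 10_000
    n_genes: int = 100
    gene_length_range_bp: tuple = (20_000, 200_000)
    n_polymorphic_loci: int = 4
    catalog_fraction: float = 0.5

    def validate(self) -> None:
        if not self.chromosomes:
            raise ValueError("at least one chromosome required")
        for name, length in self.chromosomes:
            if length < self.probe_spacing_bp:
                raise ValueError(
                    f"chromosome {name} shorter than one probe spacing"
                )
        if self.probe_spacing_bp <= 0:
            raise ValueError("probe_spacing_bp must be positive")
        lo, hi = self.gene_length_range_bp
        if not (0 < lo <= hi):
            raise ValueError("invalid gene_length_range_bp")
        if not 0.0 <= self.catalog_fraction <= 1.0:
            raise ValueError("catalog_fraction must be in [0, 1]")
        if self.n_polymorphic_loci < 0 or self.n_genes < 0:
            raise ValueError("counts must be non-negative")


def default_spec() -> GenomeSpec:
    """Study-scale default: 20 chromosomes x 25 Mb at 10 kb spacing = 50,000 probes."""
    return GenomeSpec(
        chromosomes=tuple((f"chr{i}", 25_000_000) for i in range(1, 21)),
        probe_spacing_bp=10_000,
        n_genes=400,
        gene_length_range_bp=(20_000, 200_000),
        n_polymorphic_loci=10,
        catalog_fraction=0.6,
    )


@dataclass
class Genome:
    """A generated genome: probe grid plus gene and germline-CNV catalogs.

    grid:    DataFrame [probe_id, chrom, pos]         (pos 0-based)
    genes:   DataFrame [chrom, start, end, symbol, score, strand]  (BED convention)
    catalog: DataFrame [chrom, start, end]            (germline CNV catalog, BED3)
    loci:    DataFrame [chrom, start, end, in_catalog]  (all polymorphic loci)
    """

    spec: GenomeSpec
    grid: pd.DataFrame
    genes: pd.DataFrame
    catalog: pd.DataFrame
    loci: pd.DataFrame


@dataclass
class TruthSet:
    """Record of every planted event, for parameter-recovery tests.

    planted_broad:      list of (sample, chrom, (start, end), direction)
    planted_focal:      list of (sample, chrom, (start, end), direction, gene or None)
    planted_cnv_events: list of (sample, chrom, (start, end), direction, locus_index)
    planted_cnv_loci:   list of (chrom, (start, end), in_catalog)
    planted_drivers:    list of (gene, direction, effect_multiplier)
    """

    planted_broad: list = field(default_factory=list)
    planted_focal: list = field(default_factory=list)
    planted_cnv_events: list = field(default_factory=list)
    planted_cnv_loci: list = field(default_factory=list)
    planted_drivers: list = field(default_factory=list)
    driver_carrier_prob: float = 0.6

    def driver_genes(self) -> list:
        return [g for g, _, _ in self.planted_drivers]


def generate_genome(spec: GenomeSpec, seed: int) -> Genome:
    """Deterministically generate probe grid, gene catalog, and CNV catalog.

    Probes are evenly spaced at ``spec.probe_spacing_bp`` starting at 0. Genes
    are non-overlapping within a chromosome and never extend past chromosome
    ends. Exactly ``round(catalog_fraction * n_polymorphic_loci)`` polymorphic
    loci are archived in the CNV catalog; the rest stay uncatalogued (those are
    the bidirectional loci the second germline filter must catch).
    """
    spec.validate()
    rng = np.random.default_rng(seed)

    rows = []
    for chrom, length in spec.chromosomes:
        n = length // spec.probe_spacing_bp
        pos = np.arange(n, dtype=np.int64) * spec.probe_spacing_bp
        for p in pos:
            rows.append((chrom, int(p)))
    grid = pd.DataFrame(rows, columns=["chrom", "pos"])
    grid.insert(0, "probe_id", [f"p{i:07d}" for i in range(len(grid))])

    genes = _place_genes(spec, rng)
    loci = _place_loci(spec, rng, genes)
    n_in_catalog = int(round(spec.catalog_fraction * spec.n_polymorphic_loci))
    in_catalog = np.zeros(len(loci), dtype=bool)
    if len(loci):
        chosen = rng.choice(len(loci), size=n_in_catalog, replace=False)
        in_catalog[chosen] = True
    loci["in_catalog"] = in_catalog
    catalog = (
        loci.loc[loci["in_catalog"], ["chrom", "start", "end"]]
        .sort_values(["chrom", "start"])
        .reset_index(drop=True)
    )
    return Genome(spec=spec, grid=grid, genes=genes, catalog=catalog, loci=loci)


def _place_genes(spec: GenomeSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Place non-overlapping genes, allocated to chromosomes by length."""
    lo, hi = spec.gene_length_range_bp
    lengths = np.array([L for _, L in spec.chromosomes], dtype=float)
    weights = lengths / lengths.sum()
    counts = np.floor(weights * spec.n_genes).astype(int)
    # distribute the remainder deterministically to the longest chromosomes
    for i in np.argsort(-lengths)[: spec.n_genes - counts.sum()]:
        counts[i] += 1

    records = []
    gid = 0
    for (chrom, length), k in zip(spec.chromosomes, counts):
        if k == 0:
            continue
        # carve k non-overlapping intervals: pick sorted starts with min gap
        glens = rng.integers(lo, hi + 1, size=k)
        free = length - int(glens.sum())
        if free < 0:
            raise ValueError(f"chromosome {chrom} too short for {k} genes")
        gaps = rng.multinomial(free, np.ones(k + 1) / (k + 1))
        start = 0
        for j in range(k):
            start += int(gaps[j])
            end = start + int(glens[j])
            strand = "+" if rng.random() < 0.5 else "-"
            records.append((chrom, start, end, f"GENE{gid:04d}", 0, strand))
            start = end
            gid += 1
    return pd.DataFrame(
        records, columns=["chrom", "start", "end", "symbol", "score", "strand"]
    )


# Focal driver/germline loci live on p-arms (first chromosome half); broad
# arm-level events are planted on q-arms only, so the planted event classes
# never mix within one locus.
def _arm_split(length: int) -> int:
    return length // 2


def _place_loci(
    spec: GenomeSpec, rng: np.random.Generator, genes: pd.DataFrame
) -> pd.DataFrame:
    """Place polymorphic CNV loci on p-arms, clear of each other."""
    out = []
    chroms = list(spec.chromosomes)
    attempts = 0
    while len(out) < spec.n_polymorphic_loci and attempts < 10_000:
        attempts += 1
        chrom, length = chroms[rng.integers(len(chroms))]
        size = int(rng.integers(80_000, 300_001))
        arm_end = _arm_split(length)
        if arm_end <= size:
            continue
        start = int(rng.integers(0, arm_end - size))
        end = start + size
        if any(c == chrom and start < e + 1_000_000 and s - 1_000_000 < end
               for c, s, e in out):
            continue
        out.append((chrom, start, end))
    if len(out) < spec.n_polymorphic_loci:
        raise ValueError("could not place all polymorphic loci; genome too small")
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def generate_cn_cohort(
    genome: Genome,
    n_samples: int,
    noise_sd: float,
    seed: int,
    *,
    n_loss_drivers: int = 5,
    n_gain_drivers: int = 3,
    driver_carrier_prob: float = 0.6,
    cnv_carrier_prob: float = 0.6,
    broad_arm_prob: float = 0.3,
    passenger_rate: float = 2.0,
    gain_amplitude: float = GAIN_AMPLITUDE,
    loss_amplitude: float = LOSS_AMPLITUDE,
    loss_multiplier: float = 0.5,
    gain_multiplier: float = 2.0,
):
    """Generate per-sample probe log2ratio profiles with planted truth.

    Each probe value is the sum of the planted segment effects at its position
    plus Gaussian noise of sd ``noise_sd``. Driver loci are focal (<3 Mb)
    intervals containing a designated driver gene; carriers are drawn i.i.d.
    per sample at ``driver_carrier_prob`` (at least two carriers per driver are
    guaranteed, so every planted driver is recurrent). Polymorphic loci are
    assigned i.i.d. per sample at ``cnv_carrier_prob``; uncatalogued loci give
    each carrier a random direction, so both gain and loss carriers occur.

    Returns (profiles, truth): profiles is a DataFrame indexed like the probe
    grid with one column per sample.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    grid = genome.grid
    truth = TruthSet(driver_carrier_prob=driver_carrier_prob)
    samples = [f"S{i + 1:02d}" for i in range(n_samples)]

    chrom_len = dict(genome.spec.chromosomes)
    chrom_index = {c: np.flatnonzero(grid["chrom"].to_numpy() == c)
                   for c, _ in genome.spec.chromosomes}
    pos = grid["pos"].to_numpy()
    values = np.zeros((len(grid), n_samples))

    def add(sample_j, chrom, start, end, amp):
        idx = chrom_index[chrom]
        sel = idx[(pos[idx] >= start) & (pos[idx] < end)]
        values[sel, sample_j] += amp

    # --- broad arm-level events (q-arms) ---
    for j in range(n_samples):
        for chrom, length in genome.spec.chromosomes:
            if rng.random() < broad_arm_prob:
                direction = "gain" if rng.random() < 0.5 else "loss"
                amp = gain_amplitude if direction == "gain" else loss_amplitude
                start, end = _arm_split(length), length
                add(j, chrom, start, end, amp)
                truth.planted_broad.append(
                    (samples[j], chrom, (start, end), direction)
                )

    # --- recurrent focal driver loci ---
    drivers = _pick_driver_genes(
        genome, rng, n_loss_drivers + n_gain_drivers
    )
    directions = ["loss"] * n_loss_drivers + ["gain"] * n_gain_drivers
    occupied = []  # (chrom, start, end) regions holding loci, to keep passengers away
    for (gene_row, direction) in zip(drivers.itertuples(index=False), directions):
        mult = loss_multiplier if direction == "loss" else gain_multiplier
        truth.planted_drivers.append((gene_row.symbol, direction, mult))
        carriers = rng.random(n_samples) < driver_carrier_prob
        if carriers.sum() < 2:  # guarantee recurrence of every planted driver
            forced = rng.choice(n_samples, size=2, replace=False)
            carriers[forced] = True
        amp = gain_amplitude if direction == "gain" else loss_amplitude
        arm_end = _arm_split(chrom_len[gene_row.chrom])
        occupied.append((gene_row.chrom, gene_row.start - 2_000_000,
                         gene_row.end + 2_000_000))
        for j in np.flatnonzero(carriers):
            glen = gene_row.end - gene_row.start
            size = int(rng.integers(max(glen + 40_000, 200_000), 1_500_001))
            lo = max(0, gene_row.end - size)
            hi = min(gene_row.start, arm_end - size)
            start = int(rng.integers(lo, hi + 1)) if hi >= lo else lo
            end = start + size
            add(j, gene_row.chrom, start, end, amp)
            truth.planted_focal.append(
                (samples[j], gene_row.chrom, (start, end), direction,
                 gene_row.symbol)
            )

    # --- germline CNV loci ---
    for li, locus in enumerate(genome.loci.itertuples(index=False)):
        truth.planted_cnv_loci.append(
            (locus.chrom, (locus.start, locus.end), bool(locus.in_catalog))
        )
        occupied.append((locus.chrom, locus.start - 1_000_000,
                         locus.end + 1_000_000))
        fixed_direction = "gain" if rng.random() < 0.5 else "loss"
        for j in range(n_samples):
            if rng.random() >= cnv_carrier_prob:
                continue
            if locus.in_catalog:
                direction = fixed_direction
            else:  # bidirectional locus: per-carrier direction
                direction = "gain" if rng.random() < 0.5 else "loss"
            amp = gain_amplitude if direction == "gain" else loss_amplitude
            add(j, locus.chrom, locus.start, locus.end, amp)
            truth.planted_cnv_events.append(
                (samples[j], locus.chrom, (locus.start, locus.end),
                 direction, li)
            )

    # --- non-recurrent focal passengers ---
    for j in range(n_samples):
        for _ in range(rng.poisson(passenger_rate)):
            for _attempt in range(50):
                chrom, length = genome.spec.chromosomes[
                    rng.integers(len(genome.spec.chromosomes))
                ]
                size = int(rng.integers(100_000, 800_001))
                arm_end = _arm_split(length)
                if arm_end <= size:
                    continue
                start = int(rng.integers(0, arm_end - size))
                end = start + size
                if any(c == chrom and start < e and s < end
                       for c, s, e in occupied):
                    continue
                direction = "gain" if rng.random() < 0.5 else "loss"
                amp = gain_amplitude if direction == "gain" else loss_amplitude
                add(j, chrom, start, end, amp)
                truth.planted_focal.append(
                    (samples[j], chrom, (start, end), direction, None)
                )
                break

    if noise_sd > 0:
        values += rng.normal(0.0, noise_sd, size=values.shape)

    profiles = pd.DataFrame(values, columns=samples)
    profiles.index = grid["probe_id"]
    return profiles, truth


def _pick_driver_genes(
    genome: Genome, rng: np.random.Generator, n: int
) -> pd.DataFrame:
    """Pick driver genes on p-arms, well separated from each other."""
    chrom_len = dict(genome.spec.chromosomes)
    g = genome.genes
    eligible = g[
        [e < _arm_split(chrom_len[c]) - 1_600_000 and s > 100_000
         for c, s, e in zip(g["chrom"], g["start"], g["end"])]
    ]
    # keep clear of polymorphic loci
    def clear(row):
        for locus in genome.loci.itertuples(index=False):
            if (locus.chrom == row.chrom
                    and row.start < locus.end + 2_000_000
                    and locus.start - 2_000_000 < row.end):
                return False
        return True

    eligible = eligible[[clear(r) for r in eligible.itertuples(index=False)]]
    chosen: list = []
    order = rng.permutation(len(eligible))
    for i in order:
        row = eligible.iloc[i]
        if any(r["chrom"] == row["chrom"]
               and abs(r["start"] - row["start"]) < 4_000_000
               for r in chosen):
            continue
        chosen.append(row)
        if len(chosen) == n:
            break
    if len(chosen) < n:
        raise ValueError("genome too small to place requested driver loci")
    return pd.DataFrame(chosen).reset_index(drop=True)


def generate_expression(
    genome: Genome,
    truth: TruthSet,
    n_tumors: int,
    n_reference: int,
    seed: int,
    *,
    noise_sd: float = 0.25,
    base_mean: float = 8.0,
    base_sd: float = 1.5,
    sample_prefix: str = "T",
):
    """Generate dosage-coupled tumor and reference expression matrices.

    Gene baselines are log-normal (log2 intensity ~ N(base_mean, base_sd)).
    For each planted driver, tumor carriers (drawn i.i.d. at the truth's
    carrier probability) have their linear intensity multiplied by the driver's
    effect multiplier; all other genes are uncoupled from copy number.

    Returns (tumors, reference, carriers) where carriers is a boolean
    DataFrame (driver gene x tumor sample). The carrier table is an extra
    convenience for truth-based checks; the pipeline itself never uses it.
    """
    if n_tumors < 2:
        raise ValueError("n_tumors must be >= 2")
    if n_reference < 1:
        raise ValueError("n_reference must be >= 1")
    known = set(genome.genes["symbol"])
    for gene, _, _ in truth.planted_drivers:
        if gene not in known:
            raise ValueError(f"driver gene {gene} absent from gene catalog")

    rng = np.random.default_rng(seed)
    genes = genome.genes["symbol"].tolist()
    tumor_ids = [f"{sample_prefix}{i + 1:02d}" for i in range(n_tumors)]
    ref_ids = [f"REF{i + 1}" for i in range(n_reference)]

    mu = rng.normal(base_mean, base_sd, size=len(genes))
    log_t = mu[:, None] + rng.normal(0, noise_sd, size=(len(genes), n_tumors))
    log_r = mu[:, None] + rng.normal(0, noise_sd, size=(len(genes), n_reference))

    gene_idx = {g: i for i, g in enumerate(genes)}
    carrier_rows = {}
    for gene, _direction, mult in truth.planted_drivers:
        carriers = rng.random(n_tumors) < truth.driver_carrier_prob
        carrier_rows[gene] = carriers
        log_t[gene_idx[gene], carriers] += np.log2(mult)

    tumors = pd.DataFrame(2.0 ** log_t, index=genes, columns=tumor_ids)
    reference = pd.DataFrame(2.0 ** log_r, index=genes, columns=ref_ids)
    carriers = pd.DataFrame(carrier_rows, index=tumor_ids).T
    tumors.index.name = reference.index.name = "gene"
    return tumors, reference, carriers


# ---------------------------------------------------------------------------
# writers (all coordinates 0-based half-open, BED convention)
# ---------------------------------------------------------------------------

def write_profiles_tsv(genome: Genome, profiles: pd.DataFrame, path) -> None:
    out = genome.grid.copy()
    out = pd.concat([out, profiles.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_genes_bed(genome: Genome, path) -> None:
    genome.genes[["chrom", "start", "end", "symbol", "score", "strand"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def write_cnv_catalog_bed(genome: Genome, path) -> None:
    genome.catalog.to_csv(path, sep="\t", index=False, header=False)


def write_expression_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", float_format="%.6g")


def write_truth_tsv(truth: TruthSet, path) -> None:
    rows = []
    for s, c, (a, b), d in truth.planted_broad:
        rows.append(("broad", s, c, a, b, d, ""))
    for s, c, (a, b), d, g in truth.planted_focal:
        rows.append(("focal", s, c, a, b, d, g or ""))
    for s, c, (a, b), d, li in truth.planted_cnv_events:
        rows.append(("cnv", s, c, a, b, d, f"locus{li}"))
    for c, (a, b), flag in truth.planted_cnv_loci:
        rows.append(("cnv_locus", "", c, a, b, "", "catalog" if flag else "bidirectional"))
    for g, d, m in truth.planted_drivers:
        rows.append(("driver", "", "", "", "", d, f"{g}:{m}"))
    pd.DataFrame(
        rows,
        columns=["kind", "sample", "chrom", "start", "end", "direction", "detail"],
    ).to_csv(path, sep="\t", index=False)
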