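"""Gene and germline-CNV catalog I/O plus gene-to-HFR mapping.

Catalogs are file-based (BED or GFF3) rather than fetched from a live
annotation service, so runs are reproducible offline. All coordinates are
normalized to 0-based half-open internally; GFF3's 1-based inclusive
convention is converted on read.

The published osteosarcoma HFR table (72 gene-bearing regions, 94 distinct
genes) ships as a packaged fixture for validating the table layout and the
distinct-gene accounting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "read_gene_catalog",
    "write_gene_catalog_bed",
    "read_cnv_catalog",
    "map_genes_to_hfrs",
    "genes_to_frame",
    "load_published_hfr_table",
    "load_published_validation_table",
    "hfr_table_gene_stats",
]


@dataclass(frozen=True)
class GeneModel:
    """One gene locus (0-based half-open; strand kept but ignored for overlap)."""

    symbol: str
    chrom: str
    start_bp: int
    end_bp: int
    strand: str = "."

    def __post_init__(self):
        if not self.symbol:
            raise ValueError("gene symbol must be non-empty")
        if not self.start_bp < self.end_bp:
            raise ValueError(f"invalid gene interval for {self.symbol}")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")


def read_gene_catalog(path, format: str = "bed") -> list:
    """Read a gene catalog from BED (>=4 columns) or GFF3.

    Duplicate symbols on the same interval are collapsed. Malformed lines
    raise with the offending line number.
    """
    fmt = format.lower()
    if fmt == "bed":
        genes = _read_bed_genes(path)
    elif fmt == "gff3":
        genes = _read_gff3_genes(path)
    else:
        raise ValueError(f"unknown gene catalog format: {format!r}")
    if not genes:
        logger.warning("gene catalog %s is empty", path)
    seen, out = set(), []
    for g in genes:
        key = (g.symbol, g.chrom, g.start_bp, g.end_bp)
        if key not in seen:
            seen.add(key)
            out.append(g)
    return out


def _read_bed_genes(path) -> list:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(
                    f"{path}: line {lineno}: BED gene records need >=4 fields"
                )
            try:
                chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: malformed BED line ({exc})"
                ) from None
            strand = parts[5] if len(parts) >= 6 else "."
            if strand in {"−"}:  # tolerate unicode minus
                strand = "-"
            genes.append(GeneModel(name, chrom, start, end, strand))
    return genes


def _read_gff3_genes(path) -> list:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type("gene"):
        symbol = (feat.attributes.get("Name")
                  or feat.attributes.get("gene_name")
                  or feat.attributes.get("ID") or [feat.id])[0]
        strand = feat.strand if feat.strand in {"+", "-"} else "."
        # GFF3 is 1-based inclusive
        genes.append(GeneModel(symbol, feat.seqid, feat.start - 1, feat.end, strand))
    return genes


def write_gene_catalog_bed(genes: list, path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.start_bp)):
            fh.write(f"{g.chrom}\t{g.start_bp}\t{g.end_bp}\t{g.symbol}\t0\t{g.strand}\n")


def read_cnv_catalog(path) -> pd.DataFrame:
    """Read a germline CNV catalog (BED3) into a sorted DataFrame."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2])))
            except (IndexError, ValueError) as exc:
                raise ValueError(
                    f"{path}: line {lineno}: malformed BED3 line ({exc})"
                ) from None
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    if ((df["end"] - df["start"]) <= 0).any():
        raise ValueError(f"{path}: catalog contains empty or inverted intervals")
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def genes_to_frame(genes: list) -> pd.DataFrame:
    return pd.DataFrame(
        [(g.chrom, g.start_bp, g.end_bp, g.symbol, 0, g.strand) for g in genes],
        columns=["chrom", "start", "end", "symbol", "score", "strand"],
    )


def map_genes_to_hfrs(hfrs: list, genes: list) -> list:
    """Attach genes overlapping each HFR by >=1 bp ("within or overlapping").

    HFRs with no gene are retained (empty gene list). Raises when HFR
    chromosome names are absent from the gene catalog's naming.
    """
    gene_chroms = {g.chrom for g in genes}
    missing = sorted({h.chrom for h in hfrs} - gene_chroms)
    if missing and genes:
        raise ValueError(
            "chromosome names absent from gene catalog: " + ", ".join(missing)
        )
    by_chrom: dict = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for h in hfrs:
        h.genes = sorted(
            g.symbol for g in by_chrom.get(h.chrom, ())
            if g.start_bp < h.end_bp and h.start_bp < g.end_bp
        )
    return hfrs


# ---------------------------------------------------------------------------
# packaged published tables
# ---------------------------------------------------------------------------

def _load_packaged(name: str) -> pd.DataFrame:
    with resources.files("focalcna.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def load_published_hfr_table() -> pd.DataFrame:
    """The published osteosarcoma HFR table (1-based hg18 coordinates)."""
    df = _load_packaged("published_hfr_table.tsv")
    df["Chrom"] = df["Chrom"].astype(str)
    return df


def load_published_validation_table() -> pd.DataFrame:
    """Published candidate-driver discovery/validation frequency table."""
    return _load_packaged("published_validation_table.tsv")


def hfr_table_gene_stats(df: pd.DataFrame) -> dict:
    """Record/gene accounting over an HFR table's Genes column.

    Returns n_records, n_gene_bearing, n_gene_entries (one per attachment;
    a symbol spanning two regions counts twice) and n_distinct_genes.
    """
    gene_lists = [
        [g for g in str(cell).split(",") if g and g != "nan"]
        for cell in df["Genes"].fillna("")
    ]
    entries = [g for lst in gene_lists for g in lst]
    return {
        "n_records": len(df),
        "n_gene_bearing": sum(1 for lst in gene_lists if lst),
        "n_gene_entries": len(entries),
        "n_distinct_genes": len(set(entries)),
    }
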