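"""End-to-end pipeline: simulate/read -> segment -> call -> filter -> integrate.

A single :class:`PipelineConfig` drives every stage with deterministic seeding
(one master seed, per-stage child seeds). Each run directory receives the
serialized config, a run log, and TSV reports mirroring the analysis tables:
the filter ledger, the HFR table (region coordinates, focal/total counts,
genes), the per-gene expression report, the candidate table with validation
status, and the census enrichment result. Every tabular output carries a
header comment naming the coordinate convention and the config hash, so runs
are auditable and byte-identical given identical config and seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation, expression, focal, segmentation, stats, synthetic

logger = logging.getLogger("focalcna.pipeline")

__all__ = ["PipelineConfig", "run_pipeline", "default_config"]


def _default_stages() -> dict:
    return {"expression": True, "validation": True, "enrichment": True}


@dataclass
class PipelineConfig:
    """All pipeline settings; nested dicts are merged over these defaults."""

    seed: int = 17
    simulate: bool = True
    # file inputs, used when simulate is False
    inputs: dict = field(default_factory=lambda: {
        "profiles": None, "genes": None, "gene_format": "bed",
        "cnv_catalog": None, "tumor_expression": None,
        "reference_expression": None, "validation_expression": None,
        "validation_reference": None, "census": None,
    })
    genome: dict = field(default_factory=lambda: {
        "n_chromosomes": 20, "chromosome_length_bp": 25_000_000,
        "probe_spacing_bp": 10_000, "n_genes": 400,
        "gene_length_range_bp": [20_000, 200_000],
        "n_polymorphic_loci": 10, "catalog_fraction": 0.6,
    })
    cohort: dict = field(default_factory=lambda: {
        "n_samples": 26, "noise_sd": 0.15, "n_loss_drivers": 5,
        "n_gain_drivers": 3, "driver_carrier_prob": 0.6,
        "cnv_carrier_prob": 0.6, "broad_arm_prob": 0.3, "passenger_rate": 2.0,
    })
    expression_sim: dict = field(default_factory=lambda: {
        "n_tumors": 31, "n_reference": 3, "n_validation_tumors": 84,
        "n_validation_reference": 3, "noise_sd": 0.25,
        "n_census_extras": 20,
    })
    cbs: dict = field(default_factory=lambda: {
        "alpha": 0.01, "n_perm": 1000, "min_width": 3, "merge_tol": 0.05,
    })
    call: dict = field(default_factory=lambda: {
        "loss_threshold": -0.2, "gain_threshold": 0.2,
    })
    focal: dict = field(default_factory=lambda: {
        "limit_bp": 3_000_000, "catalog_min_covered_fraction": 0.5,
        "recurrence_min": 2,
    })
    expression: dict = field(default_factory=lambda: {
        "fc_under": 0.75, "fc_over": 1.5, "freq_min": 0.35,
        "strict_fc": False, "normalize_first": True, "span": 0.3,
    })
    enrich: dict = field(default_factory=lambda: {"n_perm": 2000})
    stages: dict = field(default_factory=_default_stages)
    output: dict = field(default_factory=lambda: {"one_based": False})

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        cfg = cls()
        for key, value in (data or {}).items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key: {key}")
            current = getattr(cfg, key)
            if isinstance(current, dict):
                unknown = set(value) - set(current)
                if unknown:
                    raise ValueError(f"unknown keys in {key}: {sorted(unknown)}")
                current.update(value)
            else:
                setattr(cfg, key, value)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]

    def thresholds(self) -> expression.Thresholds:
        return expression.Thresholds(
            fc_under=self.expression["fc_under"],
            fc_over=self.expression["fc_over"],
            freq_min=self.expression["freq_min"],
            focal_limit_bp=self.focal["limit_bp"],
            recurrence_min=self.focal["recurrence_min"],
            strict_fc=self.expression["strict_fc"],
        )


def default_config(**overrides) -> PipelineConfig:
    return PipelineConfig.from_dict(overrides)


def _child_seeds(seed: int, n: int) -> list:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s & 0x7FFFFFFF) for s in state]


def _write_table(df: pd.DataFrame, path: Path, cfg: PipelineConfig, note: str):
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg.config_hash()}\n# {note}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def _genome_spec(cfg: PipelineConfig) -> synthetic.GenomeSpec:
    g = cfg.genome
    return synthetic.GenomeSpec(
        chromosomes=tuple(
            (f"chr{i}", int(g["chromosome_length_bp"]))
            for i in range(1, int(g["n_chromosomes"]) + 1)
        ),
        probe_spacing_bp=int(g["probe_spacing_bp"]),
        n_genes=int(g["n_genes"]),
        gene_length_range_bp=tuple(g["gene_length_range_bp"]),
        n_polymorphic_loci=int(g["n_polymorphic_loci"]),
        catalog_fraction=float(g["catalog_fraction"]),
    )


def simulate_inputs(cfg: PipelineConfig, outdir: Path | None = None):
    """Generate the synthetic genome, CN cohort, and expression sets.

    Returns a dict with genome, profiles, truth, expression matrices, and the
    census list; writes them under ``outdir/inputs`` when outdir is given.
    """
    seeds = _child_seeds(cfg.seed, 6)
    spec = _genome_spec(cfg)
    genome = synthetic.generate_genome(spec, seeds[0])
    profiles, truth = synthetic.generate_cn_cohort(
        genome, n_samples=int(cfg.cohort["n_samples"]),
        noise_sd=float(cfg.cohort["noise_sd"]), seed=seeds[1],
        n_loss_drivers=int(cfg.cohort["n_loss_drivers"]),
        n_gain_drivers=int(cfg.cohort["n_gain_drivers"]),
        driver_carrier_prob=float(cfg.cohort["driver_carrier_prob"]),
        cnv_carrier_prob=float(cfg.cohort["cnv_carrier_prob"]),
        broad_arm_prob=float(cfg.cohort["broad_arm_prob"]),
        passenger_rate=float(cfg.cohort["passenger_rate"]),
    )
    es = cfg.expression_sim
    tumors, reference, _ = synthetic.generate_expression(
        genome, truth, int(es["n_tumors"]), int(es["n_reference"]),
        seed=seeds[2], noise_sd=float(es["noise_sd"]), sample_prefix="T",
    )
    val_tumors, val_reference, _ = synthetic.generate_expression(
        genome, truth, int(es["n_validation_tumors"]),
        int(es["n_validation_reference"]), seed=seeds[3],
        noise_sd=float(es["noise_sd"]), sample_prefix="V",
    )
    # census: the planted drivers plus a seeded draw of unrelated genes,
    # emulating a curated cancer-gene list that the focal genes partly overlap
    rng = np.random.default_rng(seeds[4])
    drivers = truth.driver_genes()
    others = [g for g in genome.genes["symbol"] if g not in set(drivers)]
    n_extra = min(int(es["n_census_extras"]), len(others))
    census = sorted(drivers + list(rng.choice(others, size=n_extra, replace=False)))

    sim = {
        "genome": genome, "profiles": profiles, "truth": truth,
        "tumors": tumors, "reference": reference,
        "val_tumors": val_tumors, "val_reference": val_reference,
        "census": census,
    }
    if outdir is not None:
        inp = Path(outdir) / "inputs"
        inp.mkdir(parents=True, exist_ok=True)
        synthetic.write_profiles_tsv(genome, profiles, inp / "profiles.tsv")
        synthetic.write_genes_bed(genome, inp / "genes.bed")
        synthetic.write_cnv_catalog_bed(genome, inp / "cnv_catalog.bed")
        synthetic.write_expression_tsv(tumors, inp / "tumor_expression.tsv")
        synthetic.write_expression_tsv(reference, inp / "reference_expression.tsv")
        synthetic.write_expression_tsv(val_tumors, inp / "validation_expression.tsv")
        synthetic.write_expression_tsv(val_reference, inp / "validation_reference.tsv")
        synthetic.write_truth_tsv(truth, inp / "truth.tsv")
        (inp / "census.txt").write_text("\n".join(census) + "\n")
    return sim


def _load_inputs(cfg: PipelineConfig):
    paths = cfg.inputs
    prof = pd.read_csv(paths["profiles"], sep="\t")
    grid = prof[["probe_id", "chrom", "pos"]]
    profiles = prof.drop(columns=["probe_id", "chrom", "pos"])
    profiles.index = prof["probe_id"]
    genes = annotation.read_gene_catalog(
        paths["genes"], format=paths.get("gene_format", "bed")
    )
    catalog = annotation.read_cnv_catalog(paths["cnv_catalog"])
    out = {
        "grid": grid, "profiles": profiles,
        "genes": genes, "catalog": catalog, "truth": None,
        "tumors": None, "reference": None,
        "val_tumors": None, "val_reference": None, "census": None,
    }
    if paths.get("tumor_expression"):
        out["tumors"] = pd.read_csv(paths["tumor_expression"], sep="\t", index_col=0)
        out["reference"] = pd.read_csv(
            paths["reference_expression"], sep="\t", index_col=0
        )
    if paths.get("validation_expression"):
        out["val_tumors"] = pd.read_csv(
            paths["validation_expression"], sep="\t", index_col=0
        )
        out["val_reference"] = pd.read_csv(
            paths["validation_reference"], sep="\t", index_col=0
        )
    if paths.get("census"):
        out["census"] = [
            line.strip() for line in open(paths["census"]) if line.strip()
        ]
    return out


def segment_and_call(cfg: PipelineConfig, grid: pd.DataFrame,
                     profiles: pd.DataFrame) -> pd.DataFrame:
    """Median-normalize, CBS-segment, mode-normalize, and call every sample."""
    seeds = _child_seeds(int(cfg.seed) + 1_000_003, profiles.shape[1])
    calls = []
    for j, sample in enumerate(profiles.columns):
        values = segmentation.median_normalize(profiles[sample].to_numpy())
        segs = segmentation.cbs_segment(
            grid, values,
            alpha=float(cfg.cbs["alpha"]), n_perm=int(cfg.cbs["n_perm"]),
            min_width=int(cfg.cbs["min_width"]), seed=seeds[j],
            merge_tol=float(cfg.cbs["merge_tol"]), sample_id=str(sample),
        )
        segs, _shift = segmentation.mode_normalize(segs)
        segs = segmentation.call_states(
            segs, loss_threshold=float(cfg.call["loss_threshold"]),
            gain_threshold=float(cfg.call["gain_threshold"]),
        )
        calls.append(segs)
        logger.info("segmented %s: %d segments", sample, len(segs))
    return pd.concat(calls, ignore_index=True)


def _gene_directions(hfrs: list) -> dict:
    """Gene -> HFR direction; on conflict keep the direction seen more often."""
    votes: dict = {}
    for h in hfrs:
        for g in h.genes:
            votes.setdefault(g, {"gain": 0, "loss": 0})
            votes[g][h.direction] += h.focal_count
    out = {}
    for g, v in votes.items():
        if v["gain"] and v["loss"]:
            logger.warning("gene %s sits in both gain and loss HFRs", g)
        out[g] = "gain" if v["gain"] >= v["loss"] else "loss"
    return out


def _fold_changes(cfg, tumors, reference, genes):
    if cfg.expression["normalize_first"]:
        norm = expression.normalize_expression(
            tumors, reference, span=float(cfg.expression["span"])
        )
        return expression.fold_changes_from_log2(norm, genes=genes)
    return expression.compute_fold_changes(tumors, reference, genes=genes)


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Execute all configured stages, writing reports into ``outdir``.

    Returns a dict of in-memory results (calls, ledger, hfrs, candidates,
    enrichment, truth when simulated). Any stage failure aborts with the stage
    name in the log; artifacts written so far stay in place.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("focalcna")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    (outdir / "config.yaml").write_text(cfg.to_yaml())
    results: dict = {}
    stage = "setup"
    try:
        # --- inputs ---
        stage = "simulate" if cfg.simulate else "load"
        if cfg.simulate:
            sim = simulate_inputs(cfg, outdir)
            genome = sim["genome"]
            grid = genome.grid
            gene_models = [
                annotation.GeneModel(r.symbol, r.chrom, int(r.start),
                                     int(r.end), r.strand)
                for r in genome.genes.itertuples(index=False)
            ]
            catalog = genome.catalog
            data = sim
        else:
            data = _load_inputs(cfg)
            grid, gene_models, catalog = (
                data["grid"], data["genes"], data["catalog"]
            )
        results["truth"] = data.get("truth")

        # --- segmentation & calling ---
        stage = "segment"
        calls = segment_and_call(cfg, grid, data["profiles"])
        results["calls"] = calls
        _write_table(
            calls[["sample_id", "chrom", "start_bp", "end_bp",
                   "n_probes", "mean", "state"]],
            outdir / "calls.tsv", cfg,
            "called segments; coordinates 0-based half-open bp",
        )

        # --- focal filtering & HFRs ---
        stage = "focal"
        focal_out = focal.run_focal_stage(
            calls, catalog,
            focal_limit_bp=int(cfg.focal["limit_bp"]),
            min_covered_fraction=float(cfg.focal["catalog_min_covered_fraction"]),
            recurrence_min=int(cfg.focal["recurrence_min"]),
        )
        ledger = focal_out["ledger"]
        results.update(focal_out)
        logger.info(
            "filter ledger: observed=%d removed_catalog=%d "
            "removed_bidirectional=%d retained=%d",
            ledger.n_recurrent_observed, ledger.n_removed_catalog,
            ledger.n_removed_bidirectional, ledger.n_retained,
        )
        _write_table(
            pd.DataFrame([dataclasses.asdict(ledger)]),
            outdir / "ledger.tsv", cfg, "germline-CNV filter ledger",
        )

        # --- gene annotation ---
        stage = "annotate"
        hfrs = annotation.map_genes_to_hfrs(focal_out["hfrs"], gene_models)
        results["hfrs"] = hfrs
        hfr_table = focal.hfrs_to_frame(
            hfrs, one_based=bool(cfg.output["one_based"])
        )
        convention = ("1-based inclusive" if cfg.output["one_based"]
                      else "0-based half-open")
        _write_table(hfr_table, outdir / "hfr_table.tsv", cfg,
                     f"high-frequency regions; coordinates {convention} bp")

        # --- expression integration ---
        candidates = []
        if cfg.stages.get("expression", True) and data.get("tumors") is not None:
            stage = "integrate"
            directions = _gene_directions(hfrs)
            hfr_genes = sorted(directions)
            thresholds = cfg.thresholds()
            fc = _fold_changes(cfg, data["tumors"], data["reference"], hfr_genes)
            flags = expression.flag_aberrant_expression(fc, directions, thresholds)
            report = expression.gene_flag_report(flags, directions)
            _write_table(report, outdir / "gene_expression_report.tsv", cfg,
                         "per-gene concordant aberrant-expression frequencies")
            candidates = expression.select_candidates(
                flags, thresholds, fc.n_samples, directions
            )
            logger.info("selected %d candidate driver genes", len(candidates))

            if cfg.stages.get("validation", True) and data.get("val_tumors") is not None:
                stage = "validate"
                val_fc = _fold_changes(
                    cfg, data["val_tumors"], data["val_reference"], hfr_genes
                )
                candidates = expression.validate_candidates(
                    candidates, val_fc, thresholds
                )
            results["candidates"] = candidates
            _write_table(_candidates_frame(candidates),
                         outdir / "candidates.tsv", cfg,
                         "candidate drivers; frequencies in percent")
        else:
            logger.warning("expression stage disabled; candidate table not produced")

        # --- enrichment ---
        if cfg.stages.get("enrichment", True) and data.get("census"):
            stage = "enrich"
            universe = [g.symbol for g in gene_models]
            query = sorted({g for h in hfrs for g in h.genes})
            if query:
                seeds = _child_seeds(int(cfg.seed) + 2_000_003, 1)
                enr = stats.census_enrichment(
                    query, data["census"], universe,
                    n_perm=int(cfg.enrich["n_perm"]), seed=seeds[0],
                )
                results["enrichment"] = enr
                _write_table(pd.DataFrame([dataclasses.asdict(enr)]),
                             outdir / "enrichment.tsv", cfg,
                             "driver-census enrichment of HFR genes")
    except Exception:
        logger.exception("pipeline aborted during stage %r", stage)
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
    return results


def _candidates_frame(candidates: list) -> pd.DataFrame:
    rows = []
    for c in candidates:
        rows.append({
            "Gene": c.gene,
            "Direction": c.direction,
            "Freq_discovery": round(100.0 * c.freq_discovery, 1),
            "Freq_validation": ("NI" if c.freq_validation is None
                                else round(100.0 * c.freq_validation, 1)),
            "Status": c.status,
        })
    return pd.DataFrame(
        rows, columns=["Gene", "Direction", "Freq_discovery",
                       "Freq_validation", "Status"],
    )
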