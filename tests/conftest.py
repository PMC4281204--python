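"""Shared fixtures: small deterministic genomes, grids, and call tables."""

import numpy as np
import pandas as pd


def make_grid(n_probes, chrom="chr1", spacing=10_000):
    """Uniform probe grid for one chromosome (0-based positions)."""
    return pd.DataFrame({
        "probe_id": [f"p{i:05d}" for i in range(n_probes)],
        "chrom": chrom,
        "pos": np.arange(n_probes, dtype=np.int64) * spacing,
    })


def make_calls(rows):
    """Call table from (sample_id, chrom, start_bp, end_bp, state) tuples."""
    return pd.DataFrame(
        rows, columns=["sample_id", "chrom", "start_bp", "end_bp", "state"]
    )
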