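"""Shared fixtures: hand-built site tables and a small synthetic experiment."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mosaicma.containers import BASES, SiteTable, empty_alt_frame, empty_genotype_frame
from mosaicma.synthetic_data import SimulationConfig, simulate_experiment

BASE_CODE = {b: i for i, b in enumerate(BASES)}


def build_table(
    ref: str,
    lines: list[str],
    depth: int | np.ndarray = 26,
    alt_events: list[tuple[int, str, str, int]] | None = None,
    genotypes: list[tuple[int, str, str]] | None = None,
    chrom: str = "chr1",
) -> SiteTable:
    """Construct a small SiteTable by hand.

    ``alt_events`` are (pos, line, base, count); ``genotypes`` are
    (pos, line, gt).  Depth may be a scalar or an (L, n_lines) array.
    """
    L = len(ref)
    ref_codes = np.array([BASE_CODE[b] for b in ref.upper()], dtype=np.uint8)
    if np.isscalar(depth):
        d = np.full((L, len(lines)), depth, dtype=np.uint16)
    else:
        d = np.asarray(depth, dtype=np.uint16)
    if alt_events:
        alt = pd.DataFrame(
            [
                {"chrom": chrom, "pos": p, "line": l, "base": np.int8(BASE_CODE[b]), "count": np.int32(c)}
                for p, l, b, c in alt_events
            ]
        )
    else:
        alt = empty_alt_frame()
    table = SiteTable(lines=lines, ref={chrom: ref_codes}, depth={chrom: d}, alt=alt)
    if genotypes:
        table.genotypes = pd.DataFrame(
            [{"chrom": chrom, "pos": p, "line": l, "gt": g} for p, l, g in genotypes]
        )
    return table


@pytest.fixture(scope="session")
def mosaic_experiment():
    """Synthetic experiment with an inflated mutation rate and n_cells=8."""
    cfg = SimulationConfig(
        genome_length=300_000,
        n_lines=10,
        per_site_mutation_rate=2e-7,
        n_cells=8,
        seed=11,
    )
    ancestor, truth, table = simulate_experiment(cfg)
    return cfg, ancestor, truth, table


@pytest.fixture(scope="session")
def clean_experiment():
    """Mutation-free, error-free experiment: nothing but reference reads."""
    cfg = SimulationConfig(
        genome_length=50_000,
        n_lines=6,
        per_site_mutation_rate=0.0,
        sequencing_error_rate=0.0,
        ancestral_het_density=0.0,
        dup_region_count=0,
        seed=4,
    )
    return (cfg, *simulate_experiment(cfg))
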