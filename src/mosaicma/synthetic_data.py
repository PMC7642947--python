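"""Synthetic mutation-accumulation experiments with known ground truth.

Generates the full input stack the pipeline consumes — a diploid ancestor
with sparse heterozygosity plus dense "collapsed duplication" artifact
regions, de novo mutations whose within-plant frequencies drift under the
multi-cell descent model, and per-line Poisson-depth read counts with
sequencing errors — together with a truth table for parameter-recovery
tests.

The defaults mirror the study conditions this package models: ~60 clonal
generations per MA line, mean per-line depth 26, 14 lines per genotype, and
a per-bp per-generation SNP mutation rate of order 1e-10.  The genome length
defaults to 1 Mb so a full experiment is generated in seconds; rate-recovery
exercises inflate the mutation rate instead of the genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._rng import as_rng
from .containers import (
    BASES,
    GT_HET,
    GT_HOM_ALT,
    GT_MISSING,
    SiteTable,
    empty_alt_frame,
    empty_genotype_frame,
)
from .lineage_sim import propagate_counts

__all__ = [
    "SimulationConfig",
    "Ancestor",
    "simulate_ancestor",
    "simulate_ma_lines",
    "simulate_reads",
    "simulate_experiment",
    "call_genotypes",
]

TRUTH_COLUMNS = [
    "line",
    "chrom",
    "pos",
    "ref",
    "alt",
    "freq",
    "origin_generation",
    "mutant_lineages",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic MA experiment.

    Rates are probabilities per base pair (and per generation where noted);
    lengths are base pairs; depth is reads.
    """

    genome_length: int = 1_000_000
    n_lines: int = 14
    generations_per_line: int = 60
    per_site_mutation_rate: float = 8.4e-11  # per bp per generation, per copy
    n_cells: int = 8  # founder cell lineages per clonal generation
    mean_depth: float = 26.0
    sequencing_error_rate: float = 1e-3
    ancestral_het_density: float = 5e-5
    dup_region_count: int = 5
    dup_region_length: int = 1_000
    dup_het_density: float = 0.02  # in-phase het density inside artifact regions
    dup_alt_bias: float = 0.2  # reference-biased alt-read fraction inside them
    seed: int = 0
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        if self.genome_length < 1 or self.n_lines < 1 or self.generations_per_line < 1:
            raise ValueError("lengths and counts must be positive")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.dup_region_count < 0 or self.dup_region_length < 1:
            raise ValueError("invalid duplication-region parameters")
        for name in (
            "per_site_mutation_rate",
            "sequencing_error_rate",
            "ancestral_het_density",
            "dup_het_density",
            "dup_alt_bias",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0,1], got {v}")
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be non-negative")

    @property
    def line_names(self) -> list[str]:
        return [f"line{i + 1:02d}" for i in range(self.n_lines)]

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Ancestor:
    """Diploid ancestral genome: reference plus ancestral heterozygosity."""

    chrom: str
    ref: np.ndarray  # uint8 base codes, positions 1..L
    het_pos: np.ndarray  # 1-based positions of ancestral heterozygous sites
    het_alt: np.ndarray  # uint8 alt-base code per het site
    het_in_dup: np.ndarray  # flag: site lies in a collapsed-duplication region
    dup_regions: np.ndarray  # (k, 2) 1-based inclusive intervals

    @property
    def length(self) -> int:
        return len(self.ref)

    def hom_mask(self) -> np.ndarray:
        m = np.ones(self.length, dtype=bool)
        m[self.het_pos - 1] = False
        return m


def simulate_ancestor(
    config: SimulationConfig, rng: int | np.random.Generator | None = None
) -> Ancestor:
    """Draw the ancestral diploid genome.

    Heterozygous sites are placed as independent Bernoulli trials at
    ``ancestral_het_density`` outside the collapsed-duplication regions and
    at ``dup_het_density`` (dense, in-phase) inside them.  Duplication
    regions are non-overlapping and model reference mis-assembly, not real
    variation; downstream filters are expected to mask them.
    """
    rng = as_rng(rng if rng is not None else config.seed)
    L = config.genome_length
    k, dlen = config.dup_region_count, config.dup_region_length
    if k * dlen * 2 > L:
        raise ValueError(
            f"genome of {L} bp too short to place {k} duplication regions of {dlen} bp"
        )
    ref = rng.integers(0, 4, size=L, dtype=np.uint8)

    # non-overlapping duplication regions by rejection sampling
    regions: list[tuple[int, int]] = []
    attempts = 0
    while len(regions) < k:
        attempts += 1
        if attempts > 1000 * max(k, 1):
            raise ValueError("could not place non-overlapping duplication regions")
        s = int(rng.integers(1, L - dlen + 2))
        e = s + dlen - 1
        if all(e < rs or s > re for rs, re in regions):
            regions.append((s, e))
    regions.sort()
    dup_arr = np.asarray(regions, dtype=np.int64).reshape(-1, 2)

    density = np.full(L, config.ancestral_het_density)
    in_dup = np.zeros(L, dtype=bool)
    for s, e in regions:
        in_dup[s - 1 : e] = True
    density[in_dup] = config.dup_het_density
    het = rng.random(L) < density
    het_pos = np.nonzero(het)[0].astype(np.int64) + 1
    het_alt = (ref[het_pos - 1] + rng.integers(1, 4, size=het_pos.size)).astype(np.uint8) % 4
    return Ancestor(
        chrom=config.chrom,
        ref=ref,
        het_pos=het_pos,
        het_alt=het_alt,
        het_in_dup=in_dup[het_pos - 1],
        dup_regions=dup_arr,
    )


def simulate_ma_lines(
    ancestor: Ancestor,
    config: SimulationConfig,
    rng: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Accumulate de novo mutations along each MA line; return the truth table.

    Per line and generation, new mutations arise with probability
    ``2 * per_site_mutation_rate`` per (ancestrally homozygous) site — two
    homologous copies.  Each mutation starts in one of the ``n_cells``
    founder lineages of the generation in which it arose and then drifts
    under :func:`mosaicma.lineage_sim.propagate_counts` until sequencing at
    generation ``generations_per_line``.  Mutations lost within their line
    are dropped; the recorded truth frequency is
    ``mutant_lineages / (2 n_cells)``.
    """
    rng = as_rng(rng)
    L = ancestor.length
    G = config.generations_per_line
    hom_mask = ancestor.hom_mask()
    n_hom = int(hom_mask.sum())
    mean_arising = 2.0 * config.per_site_mutation_rate * n_hom * G

    records = []
    for line in config.line_names:
        n_mut = int(rng.poisson(mean_arising))
        if n_mut == 0:
            continue
        # unique hom-site positions per line
        chosen: set[int] = set()
        while len(chosen) < n_mut:
            cand = rng.integers(1, L + 1, size=n_mut - len(chosen))
            for p in cand:
                p = int(p)
                if hom_mask[p - 1]:
                    chosen.add(p)
        pos = np.fromiter(chosen, dtype=np.int64, count=n_mut)
        origin = rng.integers(1, G + 1, size=n_mut)
        final = propagate_counts(
            config.n_cells, np.ones(n_mut, dtype=np.int64), G - origin, rng
        )
        alive = final > 0
        ref_codes = ancestor.ref[pos - 1]
        alt_codes = (ref_codes + rng.integers(1, 4, size=n_mut).astype(np.uint8)) % 4
        for p, o, c, rc, ac in zip(
            pos[alive], origin[alive], final[alive], ref_codes[alive], alt_codes[alive]
        ):
            records.append(
                {
                    "line": line,
                    "chrom": ancestor.chrom,
                    "pos": int(p),
                    "ref": BASES[rc],
                    "alt": BASES[ac],
                    "freq": float(c) / (2 * config.n_cells),
                    "origin_generation": int(o),
                    "mutant_lineages": int(c),
                }
            )
    truth = pd.DataFrame(records, columns=TRUTH_COLUMNS)
    return truth.sort_values(["line", "pos"], ignore_index=True)


def _cap_to_depth(events: pd.DataFrame, depth: np.ndarray, lines: list[str]) -> pd.DataFrame:
    """Trim error-origin counts where combined non-reference reads exceed depth."""
    if events.empty:
        return events
    line_idx = events["line"].map({l: j for j, l in enumerate(lines)}).to_numpy()
    site_idx = events["pos"].to_numpy() - 1
    totals = events.groupby(["pos", "line"], sort=False)["count"].transform("sum").to_numpy()
    d = depth[site_idx, line_idx].astype(np.int64)
    over = totals > d
    if not over.any():
        return events
    events = events.copy()
    for (pos, line), grp in events[over].groupby(["pos", "line"], sort=False):
        j = lines.index(line)
        excess = int(grp["count"].sum()) - int(depth[pos - 1, j])
        # reduce error rows first (structural draws were <= depth by construction)
        for idx in grp.sort_values("is_error", ascending=False).index:
            if excess <= 0:
                break
            take = min(excess, int(events.at[idx, "count"]))
            events.at[idx, "count"] -= take
            excess -= take
    return events[events["count"] > 0]


def simulate_reads(
    ancestor: Ancestor,
    truth: pd.DataFrame,
    config: SimulationConfig,
    rng: int | np.random.Generator | None = None,
) -> SiteTable:
    """Draw per-line read counts and genotype calls; return the SiteTable.

    Depth is Poisson(``mean_depth``) per line and site.  Mutant-supporting
    reads at a truth site are Binomial(depth, truth frequency); ancestral
    heterozygous sites draw alternate reads at frequency 0.5 (or
    ``dup_alt_bias`` inside duplication regions, modelling reference-biased
    mis-mapping); sequencing errors hit each read with probability
    ``sequencing_error_rate`` and land on a uniformly chosen non-reference
    base.  Genotypes come from the built-in threshold caller
    (:func:`call_genotypes`).
    """
    rng = as_rng(rng)
    L = ancestor.length
    lines = config.line_names
    n_lines = len(lines)
    depth = np.empty((L, n_lines), dtype=np.uint16)
    for j in range(n_lines):
        depth[:, j] = rng.poisson(config.mean_depth, size=L).astype(np.uint16)

    ev_pos: list[np.ndarray] = []
    ev_line: list[np.ndarray] = []
    ev_base: list[np.ndarray] = []
    ev_count: list[np.ndarray] = []
    ev_err: list[np.ndarray] = []

    def emit(pos, line_j, base, count, is_error):
        keep = count > 0
        if not np.any(keep):
            return
        ev_pos.append(pos[keep].astype(np.int64))
        ev_line.append(np.full(int(keep.sum()), line_j, dtype=np.int32))
        ev_base.append(base[keep].astype(np.int8))
        ev_count.append(count[keep].astype(np.int32))
        ev_err.append(np.full(int(keep.sum()), is_error, dtype=bool))

    # ancestral heterozygous sites, every line
    if ancestor.het_pos.size:
        p_alt = np.where(ancestor.het_in_dup, config.dup_alt_bias, 0.5)
        for j in range(n_lines):
            d = depth[ancestor.het_pos - 1, j].astype(np.int64)
            counts = rng.binomial(d, p_alt)
            emit(ancestor.het_pos, j, ancestor.het_alt, counts, False)

    # de novo mutations, focal line only
    base_code = {b: i for i, b in enumerate(BASES)}
    for line, sub in truth.groupby("line", sort=False):
        j = lines.index(line)
        pos = sub["pos"].to_numpy(dtype=np.int64)
        d = depth[pos - 1, j].astype(np.int64)
        counts = rng.binomial(d, sub["freq"].to_numpy())
        alt = sub["alt"].map(base_code).to_numpy()
        emit(pos, j, alt, counts, False)

    # sequencing errors, multinomial over the three non-reference bases
    e = config.sequencing_error_rate
    if e > 0:
        for j in range(n_lines):
            errs = rng.binomial(depth[:, j].astype(np.int64), e)
            nz = np.nonzero(errs)[0]
            if nz.size == 0:
                continue
            split = rng.multinomial(errs[nz], [1 / 3, 1 / 3, 1 / 3])
            for slot in range(3):
                base = (ancestor.ref[nz] + 1 + slot) % 4
                emit(nz + 1, j, base, split[:, slot], True)

    if ev_pos:
        events = pd.DataFrame(
            {
                "pos": np.concatenate(ev_pos),
                "line_j": np.concatenate(ev_line),
                "base": np.concatenate(ev_base),
                "count": np.concatenate(ev_count),
                "is_error": np.concatenate(ev_err),
            }
        )
        events["line"] = pd.Categorical.from_codes(events["line_j"], categories=lines).astype(
            object
        )
        events = _cap_to_depth(events, depth, lines)
        alt = (
            events.groupby(["pos", "line", "base"], sort=False, as_index=False)["count"]
            .sum()
            .assign(chrom=ancestor.chrom)[["chrom", "pos", "line", "base", "count"]]
            .sort_values(["pos", "line", "base"], ignore_index=True)
        )
        alt["base"] = alt["base"].astype(np.int8)
        alt["count"] = alt["count"].astype(np.int32)
    else:
        alt = empty_alt_frame()

    table = SiteTable(
        lines=lines, ref={ancestor.chrom: ancestor.ref}, depth={ancestor.chrom: depth}, alt=alt
    )
    table.genotypes = call_genotypes(table)
    return table


def call_genotypes(
    table: SiteTable,
    min_alt_reads: int = 2,
    min_fraction: float = 0.10,
    hom_alt_fraction: float = 0.90,
) -> pd.DataFrame:
    """Threshold genotype caller over a SiteTable's base counts.

    A (site, line) is called heterozygous when its best-supported single
    alternate base has at least ``min_alt_reads`` reads making up at least
    ``min_fraction`` of depth; homozygous-alternate above
    ``hom_alt_fraction``; missing at zero depth; hom-ref otherwise (and
    hom-ref rows are not materialised).
    """
    frames = []
    if not table.alt.empty:
        for chrom, sub in table.alt.groupby("chrom", sort=False):
            best = (
                sub.groupby(["pos", "line"], sort=False, as_index=False)["count"]
                .max()
                .rename(columns={"count": "best"})
            )
            line_idx = best["line"].map({l: j for j, l in enumerate(table.lines)}).to_numpy()
            d = table.depth[chrom][best["pos"].to_numpy() - 1, line_idx].astype(np.int64)
            frac = np.divide(best["best"], d, out=np.zeros(len(best)), where=d > 0)
            gt = np.full(len(best), "", dtype=object)
            called = (best["best"].to_numpy() >= min_alt_reads) & (frac >= min_fraction)
            gt[called & (frac < hom_alt_fraction)] = GT_HET
            gt[called & (frac >= hom_alt_fraction)] = GT_HOM_ALT
            keep = gt != ""
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": best["pos"].to_numpy()[keep],
                        "line": best["line"].to_numpy()[keep],
                        "gt": gt[keep],
                    }
                )
            )
    # zero-depth (site, line) pairs are uncallable
    for chrom in table.chroms:
        zs, zl = np.nonzero(table.depth[chrom] == 0)
        if zs.size:
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": zs.astype(np.int64) + 1,
                        "line": np.asarray(table.lines, dtype=object)[zl],
                        "gt": GT_MISSING,
                    }
                )
            )
    if not frames:
        return empty_genotype_frame()
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["chrom", "pos", "line"], ignore_index=True)


def simulate_experiment(
    config: SimulationConfig, seed: int | None = None
) -> tuple[Ancestor, pd.DataFrame, SiteTable]:
    """Run the three stages end to end under a single seeded stream."""
    rng = as_rng(seed if seed is not None else config.seed)
    ancestor = simulate_ancestor(config, rng)
    truth = simulate_ma_lines(ancestor, config, rng)
    table = simulate_reads(ancestor, truth, config, rng)
    return ancestor, truth, table
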