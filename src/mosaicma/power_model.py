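"""Detection power for sub-heterozygous de novo mutations.

A mutation segregating in a mosaic individual may be supported by far fewer
than half the reads, so the probability that it clears the five-read calling
threshold depends on the (unknown) within-plant mutant frequency.  Power is
estimated by site resampling: sample sites where a mutation could have been
called (all lines hom-ref, at most one stray alternate read), pick a line at
random, discard a third of the sites that already carry one alternate read
(a coincidental sequencing error matching the mutant base would have
disqualified a real mutation there, with chance ~1/3), then draw mutant
reads from Binomial(depth, assumed fraction).  Power is the fraction of the
original sample with at least ``min_reads`` mutant reads, and multiplies the
callable-site x generation exposure in the mutation-rate denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from ._rng import as_rng
from .containers import CallableMask, SiteTable

__all__ = [
    "EligibleSites",
    "PowerEstimate",
    "ExposureDenominator",
    "select_eligible_sites",
    "estimate_power",
    "build_denominator",
]

ASSUMED_FRACTION_GRID = (0.50, 0.34, 0.28, 0.20, 0.10)
DEFAULT_N_SAMPLE = 500_000
DEFAULT_MIN_READS = 5


@dataclass
class EligibleSites:
    """Sites with non-zero, quantifiable detection power.

    All lines are hom-ref and the pileup carries at most one alternate base
    call (one less than a site could tolerate if it held a real mutation).
    """

    chrom_names: list[str]
    chrom_code: np.ndarray  # per eligible site
    pos: np.ndarray  # 1-based
    alt_calls: np.ndarray  # 0 or 1 stray alternate reads at the site
    depth: dict[str, np.ndarray] = field(repr=False)  # (L, n_lines) per chromosome
    n_lines: int = 0

    @property
    def n_sites(self) -> int:
        return int(self.pos.size)

    def line_depths(self, site_idx: np.ndarray, line_idx: np.ndarray) -> np.ndarray:
        """Depth of ``line_idx[i]`` at eligible site ``site_idx[i]``."""
        out = np.empty(site_idx.size, dtype=np.int64)
        codes = self.chrom_code[site_idx]
        for code, chrom in enumerate(self.chrom_names):
            sel = codes == code
            if sel.any():
                out[sel] = self.depth[chrom][self.pos[site_idx[sel]] - 1, line_idx[sel]]
        return out


def select_eligible_sites(table: SiteTable, mask: CallableMask) -> EligibleSites:
    """Callable sites where every line is hom-ref and alternate calls <= 1."""
    chrom_names = table.chroms
    codes, positions, altc = [], [], []
    nonref = table.genotypes
    alt_tot = (
        table.alt.groupby(["chrom", "pos"], sort=False)["count"].sum()
        if not table.alt.empty
        else None
    )
    for code, chrom in enumerate(chrom_names):
        L = table.chrom_length(chrom)
        ok = mask.boolean(chrom, L)
        if not nonref.empty:
            bad = nonref[nonref["chrom"] == chrom]["pos"].unique()
            ok[np.asarray(bad, dtype=np.int64) - 1] = False
        alt_counts = np.zeros(L, dtype=np.int64)
        if alt_tot is not None and chrom in alt_tot.index.get_level_values(0):
            sub = alt_tot.loc[chrom]
            alt_counts[np.asarray(sub.index, dtype=np.int64) - 1] = sub.to_numpy()
        ok &= alt_counts <= 1
        pos = np.nonzero(ok)[0].astype(np.int64) + 1
        codes.append(np.full(pos.size, code, dtype=np.int32))
        positions.append(pos)
        altc.append(alt_counts[pos - 1].astype(np.int8))
    return EligibleSites(
        chrom_names=chrom_names,
        chrom_code=np.concatenate(codes) if codes else np.empty(0, np.int32),
        pos=np.concatenate(positions) if positions else np.empty(0, np.int64),
        alt_calls=np.concatenate(altc) if altc else np.empty(0, np.int8),
        depth=table.depth,
        n_lines=table.n_lines,
    )


@dataclass(frozen=True)
class PowerEstimate:
    """Monte-Carlo detection power at one assumed mutant-read fraction."""

    assumed_mutant_fraction: float
    power: float
    n_sites_sampled: int
    min_reads: int = DEFAULT_MIN_READS
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.power <= 1.0:
            raise ValueError("power must lie in [0,1]")


def estimate_power(
    eligible: EligibleSites,
    assumed_mutant_fraction: float,
    n_sample: int = DEFAULT_N_SAMPLE,
    min_reads: int = DEFAULT_MIN_READS,
    seed: int | np.random.Generator | None = None,
    discard_one_alt_fraction: float = 1 / 3,
) -> PowerEstimate:
    """Site-resampling power estimate at one assumed mutant frequency.

    Samples ``n_sample`` eligible sites (without replacement when enough are
    available), picks one line per site uniformly, randomly discards
    ``discard_one_alt_fraction`` of sites carrying one stray alternate read,
    draws mutant reads from Binomial(line depth, fraction), and reports the
    proportion of the original sample reaching ``min_reads``.  Discarded
    sites count as failures, so the estimate already absorbs the expected
    loss of true mutations to the cross-line error filter.
    """
    if not 0.0 < assumed_mutant_fraction <= 1.0:
        raise ValueError("assumed_mutant_fraction must lie in (0, 1]")
    if n_sample < 1:
        raise ValueError("n_sample must be >= 1")
    if eligible.n_sites == 0:
        raise ValueError("no eligible sites")
    rng = as_rng(seed)
    replace = eligible.n_sites < n_sample
    site_idx = rng.choice(eligible.n_sites, size=n_sample, replace=replace)
    line_idx = rng.integers(0, eligible.n_lines, size=n_sample)
    keep = np.ones(n_sample, dtype=bool)
    one_alt = eligible.alt_calls[site_idx] == 1
    keep[one_alt] = rng.random(int(one_alt.sum())) >= discard_one_alt_fraction
    depths = eligible.line_depths(site_idx[keep], line_idx[keep])
    reads = rng.binomial(depths, assumed_mutant_fraction)
    detected = int((reads >= min_reads).sum())
    return PowerEstimate(
        assumed_mutant_fraction=assumed_mutant_fraction,
        power=detected / n_sample,
        n_sites_sampled=n_sample,
        min_reads=min_reads,
        seed=seed if isinstance(seed, int) else None,
    )


@dataclass(frozen=True)
class ExposureDenominator:
    """Power-adjusted site-generation exposure of a set of lines.

    ``total = sum_lines(callable_i * generations_i) * power * ploidy`` —
    the number of base-pair copies observed over one generation each,
    discounted by detection power.
    """

    site_generations: float  # sum over lines of callable sites x generations
    power: float
    ploidy: int = 2
    per_line: Mapping[str, float] = field(default_factory=dict)

    @property
    def total(self) -> float:
        return self.site_generations * self.power * self.ploidy


def build_denominator(
    callable_sites: Mapping[str, float],
    generations: Mapping[str, float],
    power: PowerEstimate | float,
) -> ExposureDenominator:
    """Assemble the mutation-rate denominator from per-line exposures.

    ``callable_sites`` and ``generations`` map line name -> value; lines
    present in both are used.
    """
    pw = power.power if isinstance(power, PowerEstimate) else float(power)
    lines = [l for l in callable_sites if l in generations]
    if not lines:
        raise ValueError("no lines shared between callable_sites and generations")
    per_line = {l: float(callable_sites[l]) * float(generations[l]) for l in lines}
    denom = ExposureDenominator(
        site_generations=sum(per_line.values()), power=pw, per_line=per_line
    )
    if denom.total <= 0:
        raise ValueError("exposure denominator is zero; mutation rate undefined")
    return denom
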