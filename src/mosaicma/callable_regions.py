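"""Callable-genome filtering: coverage bounds and heterozygosity windows.

Two filters reduce the genome to the sites at which a de novo mutation could
have been detected.  First, sites whose depth summed across lines falls
outside ``median +/- delta`` are removed (collapsed duplications inflate
coverage; deletions and poorly mapped regions deflate it).  Second, a
consensus genotype is formed per set of lines — a site is
consensus-heterozygous when more than one line calls it heterozygous — and
any site overlapped by a sliding window (1000 bp, 100 bp step) containing
more than ``max_het`` consensus-heterozygous calls is masked, removing
variant-rich artifact regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import GT_HET, CallableMask, SiteTable

__all__ = [
    "CoverageFilter",
    "coverage_bounds",
    "consensus_heterozygous_sites",
    "window_filter",
    "make_callable_mask",
]

DEFAULT_WINDOW = 1000
DEFAULT_STEP = 100
DEFAULT_MAX_HET = 10
DEFAULT_COVERAGE_DELTA = 200


@dataclass
class CoverageFilter:
    """Result of the summed-coverage filter."""

    median: float
    low: float
    high: float
    pass_mask: dict[str, np.ndarray]  # per chromosome, index 0 = position 1

    @property
    def n_passing(self) -> int:
        return int(sum(m.sum() for m in self.pass_mask.values()))


def coverage_bounds(table: SiteTable, delta: float = DEFAULT_COVERAGE_DELTA) -> CoverageFilter:
    """Pass sites whose cross-line summed depth is within ``median +/- delta``.

    The median is taken over every site of every chromosome.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    if table.total_sites == 0:
        raise ValueError("empty site table")
    summed = {c: table.summed_depth(c) for c in table.chroms}
    med = float(np.median(np.concatenate(list(summed.values()))))
    low, high = med - delta, med + delta
    pass_mask = {c: (s >= low) & (s <= high) for c, s in summed.items()}
    return CoverageFilter(median=med, low=low, high=high, pass_mask=pass_mask)


def consensus_heterozygous_sites(
    table: SiteTable, min_lines: int = 2
) -> dict[str, np.ndarray]:
    """Positions called heterozygous in at least ``min_lines`` lines.

    Missing genotypes do not count as heterozygous.  Returns a sorted
    1-based position array per chromosome (chromosomes with none are
    omitted).
    """
    if table.n_lines < 1:
        raise ValueError("site table has no lines")
    het = table.genotypes[table.genotypes["gt"] == GT_HET]
    out: dict[str, np.ndarray] = {}
    if het.empty:
        return out
    counts = het.groupby(["chrom", "pos"], sort=True).size()
    hits = counts[counts >= min_lines]
    for (chrom, pos) in hits.index:
        out.setdefault(chrom, []).append(pos)  # type: ignore[union-attr]
    return {c: np.asarray(v, dtype=np.int64) for c, v in out.items()}


def window_filter(
    consensus_het: dict[str, np.ndarray],
    chrom_lengths: dict[str, int],
    coverage_mask: dict[str, np.ndarray] | None = None,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    max_het: int = DEFAULT_MAX_HET,
) -> CallableMask:
    """Mask every site overlapped by a window with more than ``max_het`` hets.

    Windows are anchored at positions 1, 1+step, 1+2*step, ... along each
    chromosome (terminal partial windows are evaluated against the same
    absolute threshold).  A site is callable iff it passes the coverage
    filter and no overlapping window exceeds ``max_het``
    consensus-heterozygous calls.
    """
    if not (window >= step >= 1):
        raise ValueError("window must be >= step >= 1")
    if max_het < 0:
        raise ValueError("max_het must be >= 0")
    masks: dict[str, np.ndarray] = {}
    for chrom, L in chrom_lengths.items():
        ok = np.ones(L, dtype=bool)
        if coverage_mask is not None:
            ok &= coverage_mask[chrom]
        het_pos = consensus_het.get(chrom)
        if het_pos is not None and het_pos.size:
            ind = np.zeros(L + 1, dtype=np.int64)  # cumulative het count, 1-based
            ind[het_pos] = 1
            cum = np.cumsum(ind)
            bad = np.zeros(L + 2, dtype=np.int64)  # difference array over positions
            for start in range(1, L + 1, step):
                end = min(start + window - 1, L)
                if cum[end] - cum[start - 1] > max_het:
                    bad[start] += 1
                    bad[end + 1] -= 1
            ok &= np.cumsum(bad[1 : L + 1]) == 0
        masks[chrom] = ok
    return CallableMask.from_boolean(masks)


def make_callable_mask(
    table: SiteTable,
    coverage_delta: float = DEFAULT_COVERAGE_DELTA,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    max_het: int = DEFAULT_MAX_HET,
) -> tuple[CallableMask, CoverageFilter]:
    """Run both filters; returns the mask and the coverage-filter diagnostics."""
    cov = coverage_bounds(table, coverage_delta)
    het = consensus_heterozygous_sites(table)
    lengths = {c: table.chrom_length(c) for c in table.chroms}
    mask = window_filter(het, lengths, cov.pass_mask, window, step, max_het)
    return mask, cov
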