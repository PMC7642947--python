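"""Core in-memory containers shared across pipeline stages.

The pipeline's central object is the :class:`SiteTable`: per-site, per-line
sequencing depth and base counts for every position of the genome, as an
mpileup-derived table.  Because the overwhelming majority of sites carry only
reference reads, the table stores depth densely (one ``uint16`` per site per
line) and everything else sparsely: non-reference read counts and
non-hom-ref genotype calls live in long-format DataFrames keyed by
(chromosome, position, line).  Reference read counts are implied
(``depth - sum(non-reference)``), which keeps a 10 Mb, 14-line table well
under a gigabyte.

:class:`CallableMask` is a per-chromosome set of disjoint 1-based inclusive
intervals of sites that survived the coverage and heterozygosity filters;
it serialises to standard BED (0-based half-open).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["BASES", "SiteTable", "CallableMask", "GT_HET", "GT_HOM_ALT", "GT_MISSING"]

BASES = "ACGT"
_BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}

GT_HET = "het"
GT_HOM_ALT = "hom_alt"
GT_MISSING = "missing"

ALT_COLUMNS = ["chrom", "pos", "line", "base", "count"]
GT_COLUMNS = ["chrom", "pos", "line", "gt"]
INDEL_COLUMNS = ["chrom", "pos", "line", "ref", "alt", "alt_reads", "depth"]


def encode_base(base: str) -> int:
    try:
        return _BASE_TO_CODE[base.upper()]
    except KeyError:
        raise ValueError(f"not an A/C/G/T base: {base!r}") from None


def empty_alt_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=object),
            "pos": pd.Series(dtype=np.int64),
            "line": pd.Series(dtype=object),
            "base": pd.Series(dtype=np.int8),
            "count": pd.Series(dtype=np.int32),
        }
    )


def empty_genotype_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=object),
            "pos": pd.Series(dtype=np.int64),
            "line": pd.Series(dtype=object),
            "gt": pd.Series(dtype=object),
        }
    )


def empty_indel_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=object),
            "pos": pd.Series(dtype=np.int64),
            "line": pd.Series(dtype=object),
            "ref": pd.Series(dtype=object),
            "alt": pd.Series(dtype=object),
            "alt_reads": pd.Series(dtype=np.int32),
            "depth": pd.Series(dtype=np.int32),
        }
    )


@dataclass
class SiteTable:
    """Per-site, per-line depth and base counts over whole chromosomes.

    Attributes
    ----------
    lines
        Ordered MA-line names; columns of each ``depth`` matrix.
    ref
        Per chromosome, ``uint8`` codes (0..3 = A,C,G,T) of the reference
        base at positions 1..L.
    depth
        Per chromosome, an ``(L, n_lines)`` matrix of total read depth.
    alt
        Long-format non-reference read counts: columns
        ``chrom, pos, line, base, count`` (``base`` is a 0..3 code).
    genotypes
        Long-format non-hom-ref genotype calls: columns
        ``chrom, pos, line, gt`` with ``gt`` in {het, hom_alt, missing}.
        Absent rows mean hom-ref.
    indels
        Optional long-format heterozygous short-indel calls: columns
        ``chrom, pos, line, ref, alt, alt_reads, depth``.
    """

    lines: list[str]
    ref: dict[str, np.ndarray]
    depth: dict[str, np.ndarray]
    alt: pd.DataFrame = field(default_factory=empty_alt_frame)
    genotypes: pd.DataFrame = field(default_factory=empty_genotype_frame)
    indels: pd.DataFrame = field(default_factory=empty_indel_frame)

    def __post_init__(self) -> None:
        self.lines = list(self.lines)
        for chrom in self.ref:
            if chrom not in self.depth:
                raise ValueError(f"no depth matrix for chromosome {chrom!r}")
            d = self.depth[chrom]
            if d.ndim != 2 or d.shape != (len(self.ref[chrom]), len(self.lines)):
                raise ValueError(
                    f"depth matrix for {chrom!r} must be (L, n_lines)="
                    f"({len(self.ref[chrom])}, {len(self.lines)}), got {d.shape}"
                )

    @property
    def chroms(self) -> list[str]:
        return list(self.ref)

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    def chrom_length(self, chrom: str) -> int:
        return len(self.ref[chrom])

    @property
    def total_sites(self) -> int:
        return sum(len(r) for r in self.ref.values())

    def line_index(self, line: str) -> int:
        return self.lines.index(line)

    def summed_depth(self, chrom: str) -> np.ndarray:
        """Depth summed across lines at each site of ``chrom`` (int64)."""
        return self.depth[chrom].sum(axis=1, dtype=np.int64)

    def counts_at(self, chrom: str, pos: int) -> np.ndarray:
        """Full ``(n_lines, 4)`` base-count matrix at one site.

        Reference counts are reconstructed as depth minus non-reference
        reads; intended for spot checks and small-table IO, not bulk loops.
        """
        ref_code = int(self.ref[chrom][pos - 1])
        counts = np.zeros((self.n_lines, 4), dtype=np.int64)
        counts[:, ref_code] = self.depth[chrom][pos - 1].astype(np.int64)
        sub = self.alt[(self.alt["chrom"] == chrom) & (self.alt["pos"] == pos)]
        for row in sub.itertuples(index=False):
            j = self.line_index(row.line)
            counts[j, row.base] += row.count
            counts[j, ref_code] -= row.count
        if (counts < 0).any():
            raise ValueError(f"non-reference reads exceed depth at {chrom}:{pos}")
        return counts

    def het_positions_by_line(self) -> pd.DataFrame:
        return self.genotypes[self.genotypes["gt"] == GT_HET]

    def validate(self) -> None:
        """Check structural invariants; raises ValueError on violation."""
        if self.alt["count"].lt(1).any():
            raise ValueError("alt counts must be >= 1")
        if not self.alt["base"].isin(range(4)).all():
            raise ValueError("alt base codes must be 0..3")
        for frame, name in ((self.alt, "alt"), (self.genotypes, "genotypes")):
            bad = ~frame["line"].isin(self.lines)
            if bad.any():
                raise ValueError(f"{name} frame refers to unknown lines")
            for chrom, sub in frame.groupby("chrom"):
                if chrom not in self.ref:
                    raise ValueError(f"{name} frame refers to unknown chromosome {chrom!r}")
                if sub["pos"].lt(1).any() or sub["pos"].gt(self.chrom_length(chrom)).any():
                    raise ValueError(f"{name} frame has out-of-range positions on {chrom}")
        # non-reference reads never exceed depth
        key = self.alt.groupby(["chrom", "pos", "line"], sort=False)["count"].sum()
        for (chrom, pos, line), total in key.items():
            d = int(self.depth[chrom][pos - 1, self.line_index(line)])
            if total > d:
                raise ValueError(
                    f"non-reference reads ({total}) exceed depth ({d}) at {chrom}:{pos} line {line}"
                )


def _bool_to_intervals(mask: np.ndarray) -> np.ndarray:
    """Boolean per-site vector (index 0 = position 1) -> (k,2) 1-based inclusive."""
    if mask.size == 0 or not mask.any():
        return np.empty((0, 2), dtype=np.int64)
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.nonzero(diff == 1)[0] + 1
    ends = np.nonzero(diff == -1)[0]
    return np.column_stack([starts, ends]).astype(np.int64)


@dataclass
class CallableMask:
    """Disjoint sorted per-chromosome intervals of callable sites.

    Intervals are 1-based inclusive internally; BED IO converts to 0-based
    half-open.
    """

    intervals: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for chrom, iv in self.intervals.items():
            iv = np.asarray(iv, dtype=np.int64).reshape(-1, 2)
            if iv.size:
                if (iv[:, 0] > iv[:, 1]).any():
                    raise ValueError(f"interval start > end on {chrom}")
                if (np.diff(iv[:, 0]) <= 0).any() or (iv[1:, 0] <= iv[:-1, 1]).any():
                    raise ValueError(f"intervals must be sorted and disjoint on {chrom}")
            self.intervals[chrom] = iv

    @classmethod
    def from_boolean(cls, masks: dict[str, np.ndarray]) -> "CallableMask":
        return cls({c: _bool_to_intervals(np.asarray(m, dtype=bool)) for c, m in masks.items()})

    def boolean(self, chrom: str, length: int) -> np.ndarray:
        out = np.zeros(length, dtype=bool)
        for s, e in self.intervals.get(chrom, np.empty((0, 2), dtype=np.int64)):
            out[s - 1 : e] = True
        return out

    def contains(self, chrom: str, positions) -> np.ndarray:
        """Vectorised membership test for 1-based positions."""
        pos = np.atleast_1d(np.asarray(positions, dtype=np.int64))
        iv = self.intervals.get(chrom)
        if iv is None or iv.size == 0:
            return np.zeros(pos.shape, dtype=bool)
        idx = np.searchsorted(iv[:, 0], pos, side="right") - 1
        ok = idx >= 0
        ok[ok] &= pos[ok] <= iv[idx[ok], 1]
        return ok

    @property
    def total_callable_sites(self) -> int:
        return int(
            sum((iv[:, 1] - iv[:, 0] + 1).sum() for iv in self.intervals.values() if iv.size)
        )

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, iv in self.intervals.items():
                for s, e in iv:
                    fh.write(f"{chrom}\t{s - 1}\t{e}\n")

    @classmethod
    def from_bed(cls, path) -> "CallableMask":
        intervals: dict[str, list[list[int]]] = {}
        with open(path) as fh:
            for ln in fh:
                ln = ln.strip()
                if not ln or ln.startswith(("#", "track", "browser")):
                    continue
                chrom, start, end = ln.split("\t")[:3]
                intervals.setdefault(chrom, []).append([int(start) + 1, int(end)])
        return cls({c: np.asarray(v, dtype=np.int64) for c, v in intervals.items()})
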