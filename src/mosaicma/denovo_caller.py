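"""Candidate de novo mutation calling within callable regions.

A SNP candidate is a callable site at which exactly one MA line is called
heterozygous — with at least five reads supporting a single non-reference
base — while every other line is called homozygous.  Candidates are then
vetted against the raw pileup counts: any read supporting the mutant base in
another line rejects the site (the variant pre-dates the focal line), and
more than two reads of third alleles across all lines reject it as an
error-rich site.  Short indels follow the same logic plus a proximity filter
against indel calls in other lines, which absorbs spurious mapping in
repetitive regions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import (
    BASES,
    GT_HET,
    GT_HOM_ALT,
    GT_MISSING,
    CallableMask,
    SiteTable,
)

__all__ = [
    "find_candidates",
    "pileup_filters",
    "find_indel_candidates",
    "summarize_allelic_bias",
    "flag_linked_artifacts",
    "CANDIDATE_COLUMNS",
]

CANDIDATE_COLUMNS = [
    "line",
    "chrom",
    "pos",
    "ref",
    "alt",
    "alt_reads",
    "depth",
    "fraction",
    "kind",
    "validation_status",
]

KEEP = "keep"
REASON_CROSS_LINE = "cross_line_support"
REASON_ERROR_RICH = "error_rich_site"


def _empty_candidates() -> pd.DataFrame:
    return pd.DataFrame(columns=CANDIDATE_COLUMNS)


def _check_mask_coordinates(table: SiteTable, mask: CallableMask) -> None:
    for chrom, iv in mask.intervals.items():
        if chrom not in table.ref:
            raise ValueError(f"mask chromosome {chrom!r} not present in site table")
        if iv.size and iv[:, 1].max() > table.chrom_length(chrom):
            raise ValueError(f"mask intervals extend past the end of {chrom!r}")


def find_candidates(
    table: SiteTable, mask: CallableMask, min_alt_reads: int = 5
) -> pd.DataFrame:
    """One-line-heterozygote candidate SNPs inside the callable mask.

    Returns a DataFrame with one row per candidate (columns
    ``CANDIDATE_COLUMNS``); ``validation_status`` starts as ``not_checked``.
    """
    _check_mask_coordinates(table, mask)
    g = table.genotypes
    if g.empty:
        return _empty_candidates()
    tallies = (
        g.groupby(["chrom", "pos", "gt"], sort=False).size().unstack("gt", fill_value=0)
    )
    for col in (GT_HET, GT_HOM_ALT, GT_MISSING):
        if col not in tallies:
            tallies[col] = 0
    ok = tallies[(tallies[GT_HET] == 1) & (tallies[GT_HOM_ALT] == 0) & (tallies[GT_MISSING] == 0)]
    if ok.empty:
        return _empty_candidates()
    sites = ok.reset_index()[["chrom", "pos"]]
    focal = g[g["gt"] == GT_HET].merge(sites, on=["chrom", "pos"])

    # best-supported single non-reference base of the focal line at the site
    alt = table.alt.merge(focal[["chrom", "pos", "line"]], on=["chrom", "pos", "line"])
    if alt.empty:
        return _empty_candidates()
    best = alt.loc[alt.groupby(["chrom", "pos", "line"], sort=False)["count"].idxmax()]
    best = best[best["count"] >= min_alt_reads]
    if best.empty:
        return _empty_candidates()

    rows = []
    for chrom, sub in best.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy(dtype=np.int64)
        inside = mask.contains(chrom, pos)
        sub = sub[inside]
        if sub.empty:
            continue
        pos = sub["pos"].to_numpy(dtype=np.int64)
        line_idx = sub["line"].map({l: j for j, l in enumerate(table.lines)}).to_numpy()
        depth = table.depth[chrom][pos - 1, line_idx].astype(np.int64)
        ref_codes = table.ref[chrom][pos - 1]
        rows.append(
            pd.DataFrame(
                {
                    "line": sub["line"].to_numpy(),
                    "chrom": chrom,
                    "pos": pos,
                    "ref": [BASES[c] for c in ref_codes],
                    "alt": [BASES[c] for c in sub["base"]],
                    "alt_reads": sub["count"].to_numpy(dtype=np.int64),
                    "depth": depth,
                    "fraction": sub["count"].to_numpy() / depth,
                    "kind": "snp",
                    "validation_status": "not_checked",
                }
            )
        )
    if not rows:
        return _empty_candidates()
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["chrom", "pos"], ignore_index=True)[CANDIDATE_COLUMNS]


def pileup_filters(
    candidates: pd.DataFrame, table: SiteTable, max_other_alt: int = 2
) -> pd.DataFrame:
    """Vet candidates against raw pileup counts across all lines.

    Adds a ``decision`` column (``keep``/``cross_line_support``/
    ``error_rich_site``): a candidate is rejected if any other line carries
    even one read of the mutant base, or if reads supporting alleles other
    than the reference and the focal mutant base exceed ``max_other_alt``
    summed over all lines.

    Raises
    ------
    ValueError
        If a candidate's site is not covered by the table.
    """
    if candidates.empty:
        out = candidates.copy()
        out["decision"] = pd.Series(dtype=object)
        return out
    base_code = {b: i for i, b in enumerate(BASES)}
    decisions = []
    site_alt = table.alt.merge(
        candidates[["chrom", "pos"]].drop_duplicates(), on=["chrom", "pos"]
    )
    grouped = {k: v for k, v in site_alt.groupby(["chrom", "pos"], sort=False)}
    for row in candidates.itertuples(index=False):
        if row.chrom not in table.ref or not 1 <= row.pos <= table.chrom_length(row.chrom):
            raise ValueError(f"candidate site {row.chrom}:{row.pos} absent from site table")
        sub = grouped.get((row.chrom, row.pos))
        mut = base_code[row.alt]
        if sub is None:
            decisions.append(KEEP)  # no non-reference reads anywhere
            continue
        cross = sub[(sub["base"] == mut) & (sub["line"] != row.line)]["count"].sum()
        if cross >= 1:
            decisions.append(REASON_CROSS_LINE)
            continue
        ref = base_code[row.ref]
        third = sub[~sub["base"].isin([ref, mut])]["count"].sum()
        if third > max_other_alt:
            decisions.append(REASON_ERROR_RICH)
            continue
        decisions.append(KEEP)
    out = candidates.copy()
    out["decision"] = decisions
    return out


def find_indel_candidates(
    table: SiteTable,
    mask: CallableMask,
    exclusion_radius: int = 2000,
    min_alt_reads: int = 5,
    max_indel_length: int = 10,
) -> pd.DataFrame:
    """Candidate de novo short indels under the one-line rule.

    A candidate must be the only line with an indel call at its site, have
    at least ``min_alt_reads`` supporting reads, an allele-length change of
    at most ``max_indel_length`` bp, and lie at least ``exclusion_radius``
    bp from every indel call in any other line (inclusive boundary: exactly
    ``exclusion_radius`` bp away is retained).
    """
    _check_mask_coordinates(table, mask)
    ind = table.indels
    if ind is None or ind.empty:
        return _empty_candidates()
    ind = ind.copy()
    ind["indel_len"] = (ind["alt"].str.len() - ind["ref"].str.len()).abs()
    per_site = ind.groupby(["chrom", "pos"], sort=False)["line"].nunique()
    solo = per_site[per_site == 1].index
    cand = ind.set_index(["chrom", "pos"]).loc[solo].reset_index()
    cand = cand[(cand["alt_reads"] >= min_alt_reads) & (cand["indel_len"] <= max_indel_length)]

    rows = []
    for row in cand.itertuples(index=False):
        if not bool(mask.contains(row.chrom, row.pos)[0]):
            continue
        others = ind[(ind["chrom"] == row.chrom) & (ind["line"] != row.line)]
        if len(others) and (np.abs(others["pos"] - row.pos) < exclusion_radius).any():
            continue
        rows.append(
            {
                "line": row.line,
                "chrom": row.chrom,
                "pos": row.pos,
                "ref": row.ref,
                "alt": row.alt,
                "alt_reads": int(row.alt_reads),
                "depth": int(row.depth),
                "fraction": row.alt_reads / row.depth,
                "kind": "indel",
                "validation_status": "not_checked",
            }
        )
    if not rows:
        return _empty_candidates()
    return pd.DataFrame(rows, columns=CANDIDATE_COLUMNS).sort_values(
        ["chrom", "pos"], ignore_index=True
    )


def summarize_allelic_bias(
    candidates: pd.DataFrame, groups: dict[str, str] | None = None
) -> pd.DataFrame:
    """Mean and sample SD of the mutant read fraction per genotype group.

    ``groups`` maps line name -> group label; with ``None`` all candidates
    form one group.  SD is reported as NaN for single-candidate groups.
    """
    if candidates.empty:
        raise ValueError("no candidates to summarise")
    df = candidates.copy()
    df["group"] = df["line"].map(groups) if groups is not None else "all"
    out = df.groupby("group")["fraction"].agg(n="size", mean="mean", sd="std")
    return out.reset_index()


def flag_linked_artifacts(candidates: pd.DataFrame, table: SiteTable) -> pd.Series:
    """Heuristic stand-in for visual inspection of linked non-reference reads.

    Flags candidates whose focal line carries a second non-reference allele
    with two or more reads at the same site — the count-table signature of a
    hidden duplication where mutant-looking reads travel with other
    mismatches.  Read-level linkage is outside the input contract, so this
    is a coarse screen, reported but not applied automatically.
    """
    flags = []
    base_code = {b: i for i, b in enumerate(BASES)}
    for row in candidates.itertuples(index=False):
        sub = table.alt[
            (table.alt["chrom"] == row.chrom)
            & (table.alt["pos"] == row.pos)
            & (table.alt["line"] == row.line)
            & (table.alt["base"] != base_code[row.alt])
        ]
        flags.append(bool((sub["count"] >= 2).any()))
    return pd.Series(flags, index=candidates.index, name="linked_artifact")
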