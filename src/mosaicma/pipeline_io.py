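"""End-to-end orchestration and file formats.

The canonical interchange format is a pileup-like TSV with one row per site
(``chrom, pos, ref`` then ``depth, A, C, G, T`` per line), which preserves
the raw base counts the cross-line filters need.  VCF input/output (pysam)
covers allelic-depth-bearing variant records; BED carries the callable
mask; line metadata (genotype group, treatment, MA generations) and
candidate/validation tables are plain TSV.

:func:`analyze` runs callable-region filtering, candidate calling, power
estimation and rate statistics over an in-memory :class:`SiteTable`,
independently per genotype group, and returns a JSON-serialisable report
with per-filter tallies and full provenance.  :func:`run_pipeline` is the
file-based wrapper around it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._rng import spawn
from .containers import BASES, CallableMask, SiteTable, empty_alt_frame
from .callable_regions import (
    DEFAULT_COVERAGE_DELTA,
    DEFAULT_MAX_HET,
    DEFAULT_STEP,
    DEFAULT_WINDOW,
    make_callable_mask,
)
from .denovo_caller import (
    KEEP,
    find_candidates,
    pileup_filters,
    summarize_allelic_bias,
)
from .power_model import (
    DEFAULT_MIN_READS,
    DEFAULT_N_SAMPLE,
    ASSUMED_FRACTION_GRID,
    build_denominator,
    estimate_power,
    select_eligible_sites,
)
from .rate_stats import (
    chi_square_contrast,
    mutation_rate,
    pool_groups,
    spectrum_summary,
    true_positive_rate,
)
from .synthetic_data import call_genotypes

__all__ = [
    "RunConfig",
    "analyze",
    "run_pipeline",
    "read_site_table",
    "write_pileup_tsv",
    "read_pileup_tsv",
    "write_vcf",
    "read_vcf",
    "read_metadata",
    "write_metadata",
    "write_reference_fasta",
]

METADATA_COLUMNS = ["line", "group", "treatment", "generations"]


def _jsonify(obj):
    """Recursively convert numpy scalars so the report serialises cleanly."""
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    return obj


# ---------------------------------------------------------------------------
# pileup TSV

def write_pileup_tsv(table: SiteTable, path, chunk: int = 200_000) -> None:
    """Write the full per-site, per-line base-count table.

    Columns: ``chrom  pos  ref`` then ``<line>.depth <line>.A <line>.C
    <line>.G <line>.T`` for each line; reference counts are reconstructed
    from depth minus non-reference reads.
    """
    header = ["chrom", "pos", "ref"]
    for line in table.lines:
        header += [f"{line}.depth"] + [f"{line}.{b}" for b in BASES]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for chrom in table.chroms:
            L = table.chrom_length(chrom)
            alt = table.alt[table.alt["chrom"] == chrom]
            line_of = {l: j for j, l in enumerate(table.lines)}
            a_pos = alt["pos"].to_numpy(dtype=np.int64)
            a_line = alt["line"].map(line_of).to_numpy(dtype=np.int64) if len(alt) else np.empty(0, np.int64)
            a_base = alt["base"].to_numpy(dtype=np.int64) if len(alt) else np.empty(0, np.int64)
            a_count = alt["count"].to_numpy(dtype=np.int64) if len(alt) else np.empty(0, np.int64)
            for start in range(0, L, chunk):
                stop = min(start + chunk, L)
                n = stop - start
                depth = table.depth[chrom][start:stop].astype(np.int64)
                counts = np.zeros((n, table.n_lines, 4), dtype=np.int64)
                ref_codes = table.ref[chrom][start:stop]
                rows = np.arange(n)
                for j in range(table.n_lines):
                    counts[rows, j, ref_codes] = depth[:, j]
                sel = (a_pos > start) & (a_pos <= stop)
                if sel.any():
                    i = a_pos[sel] - 1 - start
                    # np.add.at: a line may carry several alt bases at one site
                    np.add.at(counts, (i, a_line[sel], a_base[sel]), a_count[sel])
                    np.subtract.at(counts, (i, a_line[sel], ref_codes[i]), a_count[sel])
                cols: dict[str, object] = {
                    "chrom": chrom,
                    "pos": np.arange(start + 1, stop + 1),
                    "ref": np.array(list(BASES))[ref_codes],
                }
                for j, line in enumerate(table.lines):
                    cols[f"{line}.depth"] = depth[:, j]
                    for b, base in enumerate(BASES):
                        cols[f"{line}.{base}"] = counts[:, j, b]
                pd.DataFrame(cols).to_csv(fh, sep="\t", header=False, index=False)


def read_pileup_tsv(path) -> SiteTable:
    """Read a pileup TSV back into a :class:`SiteTable`.

    Positions must be strictly increasing within each chromosome; gaps are
    filled with zero-depth (uncallable) sites.  Records whose depth does not
    equal the sum of the four base counts are rejected with their line
    number.
    """
    df = pd.read_csv(path, sep="\t")
    if df.columns[0].startswith("#"):
        df = df.rename(columns={df.columns[0]: df.columns[0].lstrip("#")})
    lines = [c[: -len(".depth")] for c in df.columns if c.endswith(".depth")]
    if not lines:
        raise ValueError(f"{path}: no '<line>.depth' columns found")
    base_cols = {l: [f"{l}.{b}" for b in BASES] for l in lines}
    for l in lines:
        sums = df[base_cols[l]].sum(axis=1)
        bad = sums != df[f"{l}.depth"]
        if bad.any():
            rows = (df.index[bad] + 2).tolist()[:5]  # +2: header + 1-based
            raise ValueError(
                f"{path}: depth != sum of base counts for line {l} at file line(s) {rows}"
            )
    ref: dict[str, np.ndarray] = {}
    depth: dict[str, np.ndarray] = {}
    alt_frames = []
    for chrom, sub in df.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy(dtype=np.int64)
        if (np.diff(pos) <= 0).any():
            raise ValueError(f"{path}: positions not strictly increasing on {chrom}")
        L = int(pos.max())
        r = np.zeros(L, dtype=np.uint8)
        base_map = {b: i for i, b in enumerate(BASES)}
        r[pos - 1] = sub["ref"].map(base_map).to_numpy(dtype=np.uint8)
        d = np.zeros((L, len(lines)), dtype=np.uint16)
        for j, l in enumerate(lines):
            d[pos - 1, j] = sub[f"{l}.depth"].to_numpy()
        ref[chrom] = r
        depth[chrom] = d
        ref_codes = r[pos - 1]
        for j, l in enumerate(lines):
            counts = sub[base_cols[l]].to_numpy(dtype=np.int64)
            counts[np.arange(len(pos)), ref_codes] = 0
            nz_site, nz_base = np.nonzero(counts)
            if nz_site.size:
                alt_frames.append(
                    pd.DataFrame(
                        {
                            "chrom": chrom,
                            "pos": pos[nz_site],
                            "line": l,
                            "base": nz_base.astype(np.int8),
                            "count": counts[nz_site, nz_base].astype(np.int32),
                        }
                    )
                )
    alt = (
        pd.concat(alt_frames, ignore_index=True).sort_values(
            ["chrom", "pos", "line", "base"], ignore_index=True
        )
        if alt_frames
        else empty_alt_frame()
    )
    return SiteTable(lines=lines, ref=ref, depth=depth, alt=alt)


# ---------------------------------------------------------------------------
# VCF (variant sites only, allelic depths required)

def write_vcf(table: SiteTable, path) -> None:
    """Write sites carrying any non-reference reads as a multi-sample VCF.

    Genotypes come from the table's calls and per-sample AD fields carry
    (ref, alt...) read counts.  Non-variant sites are not represented, so a
    VCF round trip preserves variant records only.
    """
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">')
    for chrom in table.chroms:
        header.contigs.add(chrom, length=table.chrom_length(chrom))
    for line in table.lines:
        header.add_sample(line)
    gt_lookup = {
        (r.chrom, r.pos, r.line): r.gt for r in table.genotypes.itertuples(index=False)
    }
    by_site: dict[tuple, dict[str, dict[int, int]]] = {}
    for r in table.alt.itertuples(index=False):
        by_site.setdefault((r.chrom, r.pos), {}).setdefault(r.line, {})[int(r.base)] = int(r.count)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        if table.alt.empty:
            return
        for (chrom, pos) in sorted(by_site):
            per_line = by_site[(chrom, pos)]
            ref_code = int(table.ref[chrom][pos - 1])
            alts = sorted({b for counts in per_line.values() for b in counts})
            rec = out.new_record(
                contig=chrom,
                start=int(pos) - 1,
                stop=int(pos),
                alleles=[BASES[ref_code]] + [BASES[b] for b in alts],
            )
            for j, line in enumerate(table.lines):
                d = int(table.depth[chrom][pos - 1, j])
                counts = per_line.get(line, {})
                ad = [d - sum(counts.values())] + [counts.get(b, 0) for b in alts]
                rec.samples[line]["AD"] = tuple(ad)
                gt = gt_lookup.get((chrom, pos, line))
                if gt == "het":
                    rec.samples[line]["GT"] = (0, 1)
                elif gt == "hom_alt":
                    rec.samples[line]["GT"] = (1, 1)
                elif gt == "missing":
                    rec.samples[line]["GT"] = (None,)
                else:
                    rec.samples[line]["GT"] = (0, 0)
            out.write(rec)


def read_vcf(path) -> SiteTable:
    """Read an allelic-depth-bearing VCF into a :class:`SiteTable`.

    Depth per sample is the sum of its AD field.  Sites absent from the VCF
    get zero depth, so coverage-based stages need the pileup TSV instead;
    the VCF route serves candidate interchange.
    """
    import pysam

    with pysam.VariantFile(str(path)) as vcf:
        lines = list(vcf.header.samples)
        lengths = {c: vcf.header.contigs[c].length for c in vcf.header.contigs}
        if any(v is None for v in lengths.values()):
            raise ValueError(f"{path}: VCF header must declare contig lengths")
        ref = {c: np.zeros(L, dtype=np.uint8) for c, L in lengths.items()}
        depth = {c: np.zeros((L, len(lines)), dtype=np.uint16) for c, L in lengths.items()}
        base_map = {b: i for i, b in enumerate(BASES)}
        alt_rows = []
        gt_rows = []
        for rec in vcf:
            if rec.ref is None or len(rec.ref) != 1 or rec.ref not in base_map:
                continue
            pos = rec.pos
            ref[rec.contig][pos - 1] = base_map[rec.ref]
            alleles = rec.alleles or ()
            for j, line in enumerate(lines):
                sample = rec.samples[line]
                ad = sample.get("AD")
                if ad is None or any(a is None for a in ad):
                    continue
                depth[rec.contig][pos - 1, j] = sum(ad)
                for k, allele in enumerate(alleles[1:], start=1):
                    if k < len(ad) and ad[k] and len(allele) == 1 and allele in base_map:
                        alt_rows.append((rec.contig, pos, line, base_map[allele], int(ad[k])))
                gt = sample.get("GT")
                if gt is not None and gt != (None,) and any(a for a in gt if a):
                    call = "hom_alt" if all(a == gt[0] and a for a in gt) else "het"
                    gt_rows.append((rec.contig, pos, line, call))
                elif gt == (None,):
                    gt_rows.append((rec.contig, pos, line, "missing"))
    alt = (
        pd.DataFrame(alt_rows, columns=["chrom", "pos", "line", "base", "count"])
        if alt_rows
        else empty_alt_frame()
    )
    if len(alt):
        alt["base"] = alt["base"].astype(np.int8)
        alt["count"] = alt["count"].astype(np.int32)
    table = SiteTable(lines=lines, ref=ref, depth=depth, alt=alt)
    if gt_rows:
        table.genotypes = pd.DataFrame(gt_rows, columns=["chrom", "pos", "line", "gt"])
    return table


# ---------------------------------------------------------------------------
# small tables / FASTA

def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing metadata columns {sorted(missing)}")
    return df


def write_metadata(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_reference_fasta(ref: dict[str, np.ndarray], path, width: int = 70) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq("".join(BASES[c] for c in codes)), id=chrom, description="")
        for chrom, codes in ref.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# orchestration

@dataclass
class RunConfig:
    """One pipeline run: inputs, stage parameters, outputs."""

    pileup: str
    metadata: str
    out_dir: str
    validation: str | None = None  # TSV: line, chrom, pos, validation_status
    reference_fasta: str | None = None
    coverage_delta: float = DEFAULT_COVERAGE_DELTA
    window: int = DEFAULT_WINDOW
    step: int = DEFAULT_STEP
    max_het: int = DEFAULT_MAX_HET
    min_alt_reads: int = DEFAULT_MIN_READS
    assumed_fractions: tuple[float, ...] = ASSUMED_FRACTION_GRID
    headline_fraction: float = 0.28
    power_n_sample: int = DEFAULT_N_SAMPLE
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "assumed_fractions" in data:
            data["assumed_fractions"] = tuple(data["assumed_fractions"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["assumed_fractions"] = list(self.assumed_fractions)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def _subset_table(table: SiteTable, lines: list[str]) -> SiteTable:
    idx = [table.line_index(l) for l in lines]
    sub = SiteTable(
        lines=lines,
        ref=table.ref,
        depth={c: d[:, idx] for c, d in table.depth.items()},
        alt=table.alt[table.alt["line"].isin(lines)].reset_index(drop=True),
        genotypes=table.genotypes[table.genotypes["line"].isin(lines)].reset_index(drop=True),
        indels=table.indels[table.indels["line"].isin(lines)].reset_index(drop=True)
        if table.indels is not None and len(table.indels)
        else table.indels,
    )
    return sub


def analyze(
    table: SiteTable,
    metadata: pd.DataFrame,
    config: RunConfig | None = None,
    validation: pd.DataFrame | None = None,
) -> dict:
    """Run the full analysis over an in-memory table; return the report.

    Lines are partitioned by genotype ``group`` (each group gets its own
    consensus, mask and power estimates, as each genotype has its own
    reference behaviour), rates are estimated per group x treatment at the
    headline assumed mutant-read fraction, and chi-square contrasts compare
    treatments within groups and groups within treatments.
    """
    config = config or RunConfig(pileup="", metadata="", out_dir="")
    unknown = set(metadata["line"]) - set(table.lines)
    if unknown:
        raise ValueError(f"metadata refers to lines absent from the table: {sorted(unknown)}")
    if table.genotypes.empty and not table.alt.empty:
        table.genotypes = call_genotypes(table)

    # experiment-wide TP from all Sanger-tested candidates
    if validation is not None and len(validation):
        n_val = int((validation["validation_status"] == "validated").sum())
        n_fail = int((validation["validation_status"] == "failed").sum())
        tp = true_positive_rate(n_val, n_fail)
    else:
        n_val = n_fail = 0
        tp = 1.0

    report: dict = {
        "provenance": {
            "package": "mosaicma",
            "version": __version__,
            "parameters": {**asdict(config), "assumed_fractions": list(config.assumed_fractions)},
        },
        "true_positive_rate": {"tp": tp, "n_validated": n_val, "n_failed": n_fail},
        "groups": {},
        "contrasts": {},
    }

    group_rates: dict[tuple[str, str], tuple[float, float]] = {}
    for gi, (group, glines_df) in enumerate(sorted(metadata.groupby("group"))):
        glines = list(glines_df["line"])
        sub = _subset_table(table, glines)
        mask, cov = make_callable_mask(
            sub, config.coverage_delta, config.window, config.step, config.max_het
        )
        candidates = find_candidates(sub, mask, config.min_alt_reads)
        vetted = pileup_filters(candidates, sub)
        kept = vetted[vetted["decision"] == KEEP].drop(columns="decision")
        if validation is not None and len(validation):
            kept = kept.drop(columns="validation_status").merge(
                validation[["line", "chrom", "pos", "validation_status"]],
                on=["line", "chrom", "pos"],
                how="left",
            )
            kept["validation_status"] = kept["validation_status"].fillna("not_checked")

        eligible = select_eligible_sites(sub, mask)
        powers = {
            f: estimate_power(
                eligible,
                f,
                n_sample=config.power_n_sample,
                min_reads=config.min_alt_reads,
                seed=spawn(config.seed, gi * 101 + k),
            )
            for k, f in enumerate(config.assumed_fractions)
        }
        headline = powers.get(config.headline_fraction) or estimate_power(
            eligible,
            config.headline_fraction,
            n_sample=config.power_n_sample,
            min_reads=config.min_alt_reads,
            seed=spawn(config.seed, gi * 101 + 99),
        )

        ginfo: dict = {
            "lines": glines,
            "coverage_filter": {
                "median_summed_depth": cov.median,
                "low": cov.low,
                "high": cov.high,
                "sites_passing": cov.n_passing,
            },
            "callable_sites": mask.total_callable_sites,
            "candidates_raw": int(len(candidates)),
            "candidates_kept": int(len(kept)),
            "rejections": vetted[vetted["decision"] != KEEP]["decision"]
            .value_counts()
            .to_dict(),
            "power": {
                f"{f:.2f}": {"power": p.power, "n_sites_sampled": p.n_sites_sampled}
                for f, p in powers.items()
            },
            "eligible_sites": eligible.n_sites,
            "rates": {},
        }
        if len(kept):
            bias = summarize_allelic_bias(kept)
            ginfo["allelic_bias"] = {
                "mean_fraction": float(bias["mean"].iloc[0]),
                "sd_fraction": float(bias["sd"].iloc[0]) if len(kept) > 1 else None,
            }
            spectrum = spectrum_summary(kept, table.ref)
            ginfo["spectrum"] = {
                "class_counts": dict(spectrum.class_counts),
                "ti": spectrum.ti,
                "tv": spectrum.tv,
                "titv": None if spectrum.tv == 0 else spectrum.titv,
                "cpg_fraction_of_c_to_t": None
                if np.isnan(spectrum.cpg_fraction_of_c_to_t)
                else spectrum.cpg_fraction_of_c_to_t,
            }

        for treatment, tlines_df in sorted(glines_df.groupby("treatment")):
            tlines = list(tlines_df["line"])
            gens = dict(zip(tlines_df["line"], tlines_df["generations"]))
            denom = build_denominator(
                {l: mask.total_callable_sites for l in tlines}, gens, headline
            )
            tcand = kept[kept["line"].isin(tlines)]
            est = mutation_rate(tcand, tp, denom, group=group, treatment=treatment)
            ginfo["rates"][treatment] = {
                "numerator": est.numerator,
                "denominator": est.denominator,
                "rate": est.rate,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "n_validated": est.n_validated,
                "n_not_checked": est.n_not_checked,
                "n_failed": est.n_failed,
                "power": headline.power,
                "assumed_fraction": config.headline_fraction,
            }
            group_rates[(group, treatment)] = (est.numerator, est.denominator)
        report["groups"][group] = ginfo

    # treatment contrast within each group; group contrast within each treatment
    groups = sorted({g for g, _ in group_rates})
    treatments = sorted({t for _, t in group_rates})
    for g in groups:
        pairs = [(t, group_rates[(g, t)]) for t in treatments if (g, t) in group_rates]
        if len(pairs) == 2:
            stat, p = chi_square_contrast(pairs[0][1], pairs[1][1])
            report["contrasts"][f"{g}:{pairs[0][0]}_vs_{pairs[1][0]}"] = {
                "chi2": stat,
                "p": p,
            }
    for t in treatments:
        pairs = [(g, group_rates[(g, t)]) for g in groups if (g, t) in group_rates]
        for i in range(len(pairs)):
            for j in range(i + 1, len(pairs)):
                stat, p = chi_square_contrast(pairs[i][1], pairs[j][1])
                report["contrasts"][f"{pairs[i][0]}_vs_{pairs[j][0]}:{t}"] = {
                    "chi2": stat,
                    "p": p,
                }
    return _jsonify(report)


def run_pipeline(config: RunConfig) -> dict:
    """File-based pipeline: read inputs, analyse, write outputs.

    Writes ``report.json``, per-group ``callable.<group>.bed`` and a
    ``candidates.tsv`` into ``config.out_dir``; returns the report.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = read_site_table(config.pileup)
    metadata = read_metadata(config.metadata)
    validation = None
    if config.validation:
        validation = pd.read_csv(config.validation, sep="\t")
    if table.genotypes.empty:
        table.genotypes = call_genotypes(table)
    report = analyze(table, metadata, config, validation)

    all_candidates = []
    for gi, (group, glines_df) in enumerate(sorted(metadata.groupby("group"))):
        sub = _subset_table(table, list(glines_df["line"]))
        mask, _ = make_callable_mask(
            sub, config.coverage_delta, config.window, config.step, config.max_het
        )
        mask.to_bed(out / f"callable.{group}.bed")
        cand = pileup_filters(find_candidates(sub, mask, config.min_alt_reads), sub)
        cand.insert(0, "group", group)
        all_candidates.append(cand)
    pd.concat(all_candidates, ignore_index=True).to_csv(
        out / "candidates.tsv", sep="\t", index=False
    )
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=False)
        fh.write("\n")
    return report


def read_site_table(path, fmt: str | None = None) -> SiteTable:
    """Dispatch on format: ``pileup`` TSV (canonical) or ``vcf``."""
    path = str(path)
    if fmt is None:
        fmt = "vcf" if path.endswith((".vcf", ".vcf.gz", ".bcf")) else "pileup"
    if fmt == "pileup":
        return read_pileup_tsv(path)
    if fmt == "vcf":
        return read_vcf(path)
    raise ValueError(f"unknown site-table format {fmt!r}")
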