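"""One-line-heterozygote candidate calling and pileup-level filters."""

import numpy as np
import pandas as pd
import pytest

from conftest import build_table
from mosaicma.callable_regions import make_callable_mask
from mosaicma.containers import BASES, CallableMask, SiteTable
from mosaicma.denovo_caller import (
    KEEP,
    REASON_CROSS_LINE,
    REASON_ERROR_RICH,
    find_candidates,
    find_indel_candidates,
    pileup_filters,
    summarize_allelic_bias,
)

LINES = [f"l{i:02d}" for i in range(14)]


def full_mask(table: SiteTable) -> CallableMask:
    return CallableMask.from_boolean(
        {c: np.ones(table.chrom_length(c), dtype=bool) for c in table.chroms}
    )


def one_candidate_table(alt_reads=7, depth=25, ref="A", alt="C", extra_alt=(), extra_gt=()):
    table = build_table(
        ref * 10,
        LINES,
        depth=depth,
        alt_events=[(5, LINES[0], alt, alt_reads)] + list(extra_alt),
        genotypes=[(5, LINES[0], "het")] + list(extra_gt),
    )
    return table


def test_single_het_line_with_enough_reads_is_a_candidate():
    table = one_candidate_table(alt_reads=7, depth=25)
    cand = find_candidates(table, full_mask(table))
    assert len(cand) == 1
    row = cand.iloc[0]
    assert (row.line, row.pos, row.ref, row.alt) == (LINES[0], 5, "A", "C")
    assert row.alt_reads == 7 and row.depth == 25
    assert row.fraction == pytest.approx(0.28)
    assert row.validation_status == "not_checked"


def test_fewer_than_five_supporting_reads_is_not_a_candidate():
    table = one_candidate_table(alt_reads=4)
    assert find_candidates(table, full_mask(table)).empty


def test_two_heterozygous_lines_disqualify_the_site():
    table = one_candidate_table(
        extra_alt=[(5, LINES[1], "C", 6)], extra_gt=[(5, LINES[1], "het")]
    )
    assert find_candidates(table, full_mask(table)).empty


def test_missing_or_hom_alt_lines_disqualify_the_site():
    for gt in ("missing", "hom_alt"):
        table = one_candidate_table(extra_gt=[(5, LINES[3], gt)])
        assert find_candidates(table, full_mask(table)).empty


def test_candidates_respect_the_callable_mask():
    table = one_candidate_table()
    mask = CallableMask({"chr1": np.array([[6, 10]])})  # site 5 excluded
    assert find_candidates(table, mask).empty


def test_mask_on_unknown_chromosome_is_rejected():
    table = one_candidate_table()
    with pytest.raises(ValueError):
        find_candidates(table, CallableMask({"chrX": np.array([[1, 5]])}))


def test_cross_line_mutant_read_rejects_the_candidate():
    table = one_candidate_table(extra_alt=[(5, LINES[2], "C", 1)])
    cand = find_candidates(table, full_mask(table))
    vetted = pileup_filters(cand, table)
    assert vetted["decision"].tolist() == [REASON_CROSS_LINE]


def test_clean_candidate_is_kept():
    table = one_candidate_table()
    vetted = pileup_filters(find_candidates(table, full_mask(table)), table)
    assert vetted["decision"].tolist() == [KEEP]


def test_third_allele_reads_above_two_reject_as_error_rich():
    # three reads of a third allele (G) across other lines: > 2 threshold
    table = one_candidate_table(
        extra_alt=[(5, LINES[4], "G", 2), (5, LINES[5], "G", 1)]
    )
    vetted = pileup_filters(find_candidates(table, full_mask(table)), table)
    assert vetted["decision"].tolist() == [REASON_ERROR_RICH]


def test_exactly_two_third_allele_reads_are_tolerated():
    table = one_candidate_table(extra_alt=[(5, LINES[4], "G", 2)])
    vetted = pileup_filters(find_candidates(table, full_mask(table)), table)
    assert vetted["decision"].tolist() == [KEEP]


def test_filter_rejects_candidate_outside_the_table():
    table = one_candidate_table()
    ghost = pd.DataFrame(
        [
            {
                "line": LINES[0],
                "chrom": "chr1",
                "pos": 99,
                "ref": "A",
                "alt": "C",
                "alt_reads": 6,
                "depth": 20,
                "fraction": 0.3,
                "kind": "snp",
                "validation_status": "not_checked",
            }
        ]
    )
    with pytest.raises(ValueError):
        pileup_filters(ghost, table)


def _indel_table(rows):
    table = build_table("A" * 10_000, ["a", "b", "c"], depth=20)
    table.indels = pd.DataFrame(
        rows, columns=["chrom", "pos", "line", "ref", "alt", "alt_reads", "depth"]
    )
    return table


def test_indel_near_another_lines_indel_is_rejected():
    table = _indel_table(
        [
            ("chr1", 3000, "a", "AT", "A", 8, 20),
            ("chr1", 4500, "b", "A", "AG", 9, 20),  # 1500 bp away
        ]
    )
    cand = find_indel_candidates(table, full_mask(table))
    assert cand.empty


def test_isolated_indel_is_retained():
    table = _indel_table([("chr1", 3000, "a", "AT", "A", 8, 20)])
    cand = find_indel_candidates(table, full_mask(table))
    assert len(cand) == 1 and cand.iloc[0].kind == "indel"


def test_indel_exactly_at_the_exclusion_radius_is_retained():
    table = _indel_table(
        [
            ("chr1", 3000, "a", "AT", "A", 8, 20),
            ("chr1", 5000, "b", "A", "AG", 9, 20),  # exactly 2000 bp
        ]
    )
    cand = find_indel_candidates(table, full_mask(table))
    assert set(cand["line"]) == {"a", "b"}


def test_long_indels_and_weak_support_are_dropped():
    table = _indel_table(
        [
            ("chr1", 100, "a", "A", "A" + "T" * 11, 9, 20),  # 11 bp insertion
            ("chr1", 5000, "b", "AT", "A", 4, 20),  # only 4 reads
        ]
    )
    assert find_indel_candidates(table, full_mask(table)).empty


def test_allelic_bias_summary_hand_values():
    cand = pd.DataFrame(
        {
            "line": ["a", "a", "b"],
            "fraction": [0.2, 0.3, 0.4],
        }
    )
    out = summarize_allelic_bias(cand)
    assert out.loc[0, "mean"] == pytest.approx(0.30)
    assert out.loc[0, "sd"] == pytest.approx(0.10)
    single = summarize_allelic_bias(cand.iloc[:1])
    assert single.loc[0, "mean"] == pytest.approx(0.2)
    assert np.isnan(single.loc[0, "sd"])
    with pytest.raises(ValueError):
        summarize_allelic_bias(cand.iloc[:0])


def test_clean_input_yields_zero_candidates(clean_experiment):
    _, _, _, table = clean_experiment
    mask, _ = make_callable_mask(table)
    cand = find_candidates(table, mask)
    assert cand.empty


def brute_force_expected_candidates(table, truth, mask, min_alt_reads=5):
    """Per-truth-site re-derivation of the candidate rules via counts_at."""
    expected = []
    base_code = {b: i for i, b in enumerate(BASES)}
    for row in truth.itertuples(index=False):
        if not bool(mask.contains(row.chrom, row.pos)[0]):
            continue
        counts = table.counts_at(row.chrom, row.pos)
        j = table.line_index(row.line)
        ref_c, mut_c = base_code[row.ref], base_code[row.alt]
        mut_reads = counts[j, mut_c]
        depth = counts[j].sum()
        if mut_reads < min_alt_reads or depth == 0:
            continue
        # focal genotype must be het and its top alt must be the mutant base
        gt = table.genotypes
        focal = gt[(gt["chrom"] == row.chrom) & (gt["pos"] == row.pos) & (gt["line"] == row.line)]
        if len(focal) != 1 or focal.iloc[0]["gt"] != "het":
            continue
        nonref = np.delete(np.arange(4), ref_c)
        if counts[j, nonref].max() > mut_reads:
            continue
        others = gt[(gt["chrom"] == row.chrom) & (gt["pos"] == row.pos) & (gt["line"] != row.line)]
        if len(others):
            continue
        if counts[np.arange(len(table.lines)) != j, mut_c].sum() >= 1:
            continue
        third = np.delete(np.arange(4), [ref_c, mut_c])
        if counts[:, third].sum() > 2:
            continue
        expected.append((row.line, row.chrom, row.pos, row.alt))
    return set(expected)


def test_every_detectable_truth_mutation_is_recovered(mosaic_experiment):
    """The vectorised caller agrees with a per-site brute-force oracle."""
    _, _, truth, table = mosaic_experiment
    mask, _ = make_callable_mask(table)
    vetted = pileup_filters(find_candidates(table, mask), table)
    kept = vetted[vetted["decision"] == KEEP]
    recovered = set(zip(kept["line"], kept["chrom"], kept["pos"], kept["alt"]))
    expected = brute_force_expected_candidates(table, truth, mask)
    assert expected <= recovered  # no silent drops of detectable truth
    # anything recovered beyond truth must be an error site, not a truth site
    truth_keys = set(zip(truth["line"], truth["chrom"], truth["pos"], truth["alt"]))
    assert recovered & truth_keys == expected


def test_filters_commute_with_mask_intersection(mosaic_experiment):
    _, _, _, table = mosaic_experiment
    mask, _ = make_callable_mask(table)
    a = pileup_filters(find_candidates(table, mask), table)
    a = a[a["decision"] == KEEP]

    b = pileup_filters(find_candidates(table, full_mask(table)), table)
    b = b[b["decision"] == KEEP]
    b = b[mask.contains("chr1", b["pos"].to_numpy())]
    pd.testing.assert_frame_equal(a.reset_index(drop=True), b.reset_index(drop=True))
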