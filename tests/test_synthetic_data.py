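"""Synthetic MA-experiment generator: ground-truth structure and read model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mosaicma.containers import BASES
from mosaicma.synthetic_data import (
    SimulationConfig,
    call_genotypes,
    simulate_ancestor,
    simulate_experiment,
    simulate_ma_lines,
    simulate_reads,
)

BASE_CODE = {b: i for i, b in enumerate(BASES)}


def test_config_validates_rates_and_counts():
    with pytest.raises(ValueError):
        SimulationConfig(per_site_mutation_rate=1.5)
    with pytest.raises(ValueError):
        SimulationConfig(n_lines=0)
    with pytest.raises(ValueError):
        SimulationConfig(n_cells=0)


def test_ancestor_with_no_heterozygosity_is_clean():
    cfg = SimulationConfig(
        genome_length=20_000, ancestral_het_density=0.0, dup_region_count=0, seed=1
    )
    anc = simulate_ancestor(cfg)
    assert anc.het_pos.size == 0
    assert anc.dup_regions.shape == (0, 2)


def test_ancestor_rejects_genome_too_short_for_duplications():
    with pytest.raises(ValueError):
        simulate_ancestor(
            SimulationConfig(genome_length=5_000, dup_region_count=5, dup_region_length=1_000)
        )


def test_duplication_regions_are_dense_and_flagged():
    """In-region het density ~20/kb clears the downstream window threshold."""
    cfg = SimulationConfig(
        genome_length=100_000,
        ancestral_het_density=1e-4,
        dup_region_count=3,
        dup_region_length=1_000,
        dup_het_density=0.02,
        seed=2,
    )
    anc = simulate_ancestor(cfg)
    for s, e in anc.dup_regions:
        in_region = (anc.het_pos >= s) & (anc.het_pos <= e)
        assert in_region.sum() >= 10  # expected ~20, Binomial(1000, .02)
        assert anc.het_in_dup[in_region].all()
    out = ~anc.het_in_dup
    # outside regions the density is ~1e-4
    assert anc.het_in_dup.sum() > out.sum() * 0.5


def test_genomewide_het_count_matches_binomial_expectation():
    cfg = SimulationConfig(
        genome_length=500_000, ancestral_het_density=2e-4, dup_region_count=0, seed=3
    )
    anc = simulate_ancestor(cfg)
    mean = cfg.genome_length * cfg.ancestral_het_density
    sd = np.sqrt(mean * (1 - cfg.ancestral_het_density))
    assert abs(anc.het_pos.size - mean) < 3 * sd


def test_zero_mutation_rate_gives_empty_truth():
    cfg = SimulationConfig(genome_length=20_000, per_site_mutation_rate=0.0, seed=1)
    anc = simulate_ancestor(cfg)
    truth = simulate_ma_lines(anc, cfg, np.random.default_rng(0))
    assert truth.empty


def test_truth_frequencies_and_positions_are_valid(mosaic_experiment):
    cfg, anc, truth, _ = mosaic_experiment
    assert (truth["freq"] > 0).all() and (truth["freq"] <= 0.5).all()
    assert truth.groupby("line")["pos"].apply(lambda s: s.is_unique).all()
    assert truth["origin_generation"].between(1, cfg.generations_per_line).all()
    # mutations only at ancestrally homozygous sites
    assert not truth["pos"].isin(anc.het_pos).any()


def test_surviving_mutation_count_matches_drift_oracle():
    """Surviving truth mutations are Poisson with a drift-thinned mean.

    The oracle re-simulates survival with a plain numpy binomial loop,
    independent of the package's vectorised propagation.
    """
    cfg = SimulationConfig(
        genome_length=200_000,
        n_lines=12,
        per_site_mutation_rate=5e-7,
        n_cells=8,
        dup_region_count=0,
        ancestral_het_density=0.0,
        seed=7,
    )
    anc = simulate_ancestor(cfg)
    truth = simulate_ma_lines(anc, cfg, np.random.default_rng(21))

    rng = np.random.default_rng(99)
    G, n = cfg.generations_per_line, cfg.n_cells
    reps = 20_000
    origins = rng.integers(1, G + 1, size=reps)
    survived = 0
    for o in origins:
        c = 1
        for _ in range(G - o):
            c = rng.binomial(n, c / n)
            if c == 0 or c == n:
                break
        survived += c > 0
    p_survive = survived / reps
    mean_arising = 2 * cfg.per_site_mutation_rate * cfg.genome_length * G * cfg.n_lines
    mean_surviving = mean_arising * p_survive
    assert abs(len(truth) - mean_surviving) < 4 * np.sqrt(mean_surviving)


def test_mosaic_truth_frequencies_skew_below_half():
    base = dict(genome_length=100_000, n_lines=10, per_site_mutation_rate=1e-6, seed=13)
    single = simulate_ma_lines(
        simulate_ancestor(SimulationConfig(n_cells=1, **base)),
        SimulationConfig(n_cells=1, **base),
        np.random.default_rng(1),
    )
    mosaic = simulate_ma_lines(
        simulate_ancestor(SimulationConfig(n_cells=8, **base)),
        SimulationConfig(n_cells=8, **base),
        np.random.default_rng(1),
    )
    assert (single["freq"] == 0.5).all()
    assert mosaic["freq"].mean() < 0.4
    assert (mosaic["freq"] < 0.5).mean() > 0.5  # skewed toward low values


def test_clean_reads_are_pure_reference(clean_experiment):
    _, _, truth, table = clean_experiment
    assert truth.empty
    assert table.alt.empty
    assert table.genotypes[table.genotypes["gt"] != "missing"].empty


def test_mutant_read_counts_follow_the_binomial_tail():
    """At truth frequency 0.28, P(>=5 mutant reads) matches the Poisson-depth
    binomial mixture tail."""
    cfg = SimulationConfig(
        genome_length=30_000,
        n_lines=1,
        mean_depth=26,
        sequencing_error_rate=0.0,
        ancestral_het_density=0.0,
        dup_region_count=0,
        seed=5,
    )
    anc = simulate_ancestor(cfg)
    pos = np.arange(1, cfg.genome_length + 1, 3)
    truth = pd.DataFrame(
        {
            "line": cfg.line_names[0],
            "chrom": cfg.chrom,
            "pos": pos,
            "ref": [BASES[c] for c in anc.ref[pos - 1]],
            "alt": [BASES[(c + 1) % 4] for c in anc.ref[pos - 1]],
            "freq": 0.28,
            "origin_generation": 1,
            "mutant_lineages": 1,
        }
    )
    table = simulate_reads(anc, truth, cfg, np.random.default_rng(8))
    counts = np.zeros(len(pos), dtype=int)
    hits = table.alt.set_index("pos")["count"]
    common = hits.index.intersection(pos)
    counts[np.searchsorted(pos, common)] = hits.loc[common].to_numpy()
    observed = (counts >= 5).mean()
    d = np.arange(0, 80)
    expected = float((stats.poisson.pmf(d, 26) * stats.binom.sf(4, d, 0.28)).sum())
    se = np.sqrt(expected * (1 - expected) / len(pos))
    assert abs(observed - expected) < 3 * se


def test_sequencing_error_tail_matches_binomial_mixture():
    cfg = SimulationConfig(
        genome_length=200_000,
        n_lines=1,
        mean_depth=26,
        sequencing_error_rate=1e-3,
        ancestral_het_density=0.0,
        dup_region_count=0,
        per_site_mutation_rate=0.0,
        seed=6,
    )
    anc = simulate_ancestor(cfg)
    truth = simulate_ma_lines(anc, cfg, np.random.default_rng(0))
    table = simulate_reads(anc, truth, cfg, np.random.default_rng(9))
    per_site = table.alt.groupby("pos")["count"].sum()
    observed = (per_site >= 2).sum() / cfg.genome_length
    d = np.arange(0, 80)
    expected = float(
        (stats.poisson.pmf(d, 26) * (1 - stats.binom.cdf(1, d, 1e-3))).sum()
    )
    se = np.sqrt(expected * (1 - expected) / cfg.genome_length)
    assert abs(observed - expected) < 3 * se


def test_genotype_caller_flags_heterozygotes_and_missing():
    cfg = SimulationConfig(
        genome_length=20_000,
        n_lines=4,
        ancestral_het_density=5e-3,
        dup_region_count=0,
        sequencing_error_rate=0.0,
        per_site_mutation_rate=0.0,
        seed=10,
    )
    anc, truth, table = simulate_experiment(cfg)
    het_calls = table.genotypes[table.genotypes["gt"] == "het"]
    # ancestral het sites at depth ~26 and 50% alt reads are nearly always called
    frac_called = het_calls["pos"].nunique() / anc.het_pos.size
    assert frac_called > 0.95
    assert set(het_calls["pos"]).issubset(set(anc.het_pos))


def test_fixed_seed_reproduces_the_experiment_exactly():
    cfg = SimulationConfig(genome_length=30_000, per_site_mutation_rate=1e-6, seed=17)
    a1, t1, s1 = simulate_experiment(cfg)
    a2, t2, s2 = simulate_experiment(cfg)
    assert np.array_equal(a1.ref, a2.ref)
    pd.testing.assert_frame_equal(t1, t2)
    pd.testing.assert_frame_equal(s1.alt, s2.alt)
    for c in s1.chroms:
        assert np.array_equal(s1.depth[c], s2.depth[c])


def test_total_mutation_count_is_poisson_over_replicates():
    """Chi-square goodness of fit of arising-mutation counts to Poisson."""
    cfg = SimulationConfig(
        genome_length=50_000,
        n_lines=1,
        per_site_mutation_rate=1e-6,
        n_cells=1,  # no drift loss: surviving == arising
        ancestral_het_density=0.0,
        dup_region_count=0,
        seed=0,
    )
    anc = simulate_ancestor(cfg)
    mean = 2 * cfg.per_site_mutation_rate * cfg.genome_length * cfg.generations_per_line
    counts = [
        len(simulate_ma_lines(anc, cfg, np.random.default_rng(1000 + i))) for i in range(200)
    ]
    edges = [-0.5, 2.5, 4.5, 6.5, 8.5, np.inf]
    observed, _ = np.histogram(counts, bins=edges)
    cdf = stats.poisson.cdf(np.array(edges), mean)
    expected = np.diff(cdf) * len(counts)
    chi2 = ((observed - expected) ** 2 / expected).sum()
    p = stats.chi2.sf(chi2, df=len(observed) - 1)
    assert p > 0.01
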