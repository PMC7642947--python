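"""Neutral drift of mutant cell lineages under multi-cell clonal descent.

Vegetatively reproducing plants such as duckweed can transmit several cell
lineages from parent to clonal offspring.  The model here assumes each
daughter is founded by ``n`` parental cells drawn at random, with all cell
lineages growing at equal rates: mutant-lineage frequency then performs
neutral Wright–Fisher drift on a population of ``n`` cell lineages.  A new
heterozygous mutation starts in one founder cell, i.e. at cell-lineage
frequency ``1/n`` and allele frequency ``1/(2n)``, and eventually fixes
within the clone (probability ``1/n``) or is lost (probability ``(n-1)/n``).
With ``n = 1`` the model collapses to conventional single-cell descent and a
new mutation is an ordinary 50%-frequency heterozygote.

All functions take an integer ``seed`` or a ``numpy.random.Generator``; no
global random state is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from ._rng import as_rng

__all__ = [
    "CellPopulation",
    "LineageTrajectory",
    "MrcaSummary",
    "introduce_mutation",
    "propagate",
    "propagate_counts",
    "time_to_mrca",
]

FIXED = "fixed"
LOST = "lost"
SEGREGATING = "segregating"


@dataclass(frozen=True)
class CellPopulation:
    """State of the ``n`` founder cell lineages of one clonal individual.

    Parameters
    ----------
    n_cells
        Number of founder cell lineages per generation (the model's ``n``).
    mutant_count
        Number of those lineages carrying the heterozygous mutation.
    generation
        Generations elapsed since the population was created.
    """

    n_cells: int
    mutant_count: int = 0
    generation: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError(f"n_cells must be >= 1, got {self.n_cells}")
        if not 0 <= self.mutant_count <= self.n_cells:
            raise ValueError(
                f"mutant_count must lie in [0, {self.n_cells}], got {self.mutant_count}"
            )
        if self.generation < 0:
            raise ValueError("generation must be non-negative")

    @property
    def lineage_frequency(self) -> float:
        """Fraction of cell lineages carrying the mutation."""
        return self.mutant_count / self.n_cells

    @property
    def allele_frequency(self) -> float:
        """Within-individual frequency of the mutant allele.

        The mutation is heterozygous in every carrier lineage, so the allele
        frequency is ``mutant_count / (2 n)`` and never exceeds 0.5.
        """
        return self.mutant_count / (2 * self.n_cells)


@dataclass(frozen=True)
class LineageTrajectory:
    """Per-generation mutant-lineage frequencies of one drift realisation."""

    frequencies: tuple[float, ...]
    outcome: str
    generations_elapsed: int

    def __post_init__(self) -> None:
        if self.outcome not in (FIXED, LOST, SEGREGATING):
            raise ValueError(f"unknown outcome {self.outcome!r}")


def introduce_mutation(pop: CellPopulation) -> CellPopulation:
    """Place a new heterozygous mutation in one founder cell lineage.

    The returned population has ``mutant_count = 1``, i.e. an allele
    frequency of ``1/(2 n_cells)``.

    Raises
    ------
    ValueError
        If the population already carries a mutation.
    """
    if pop.mutant_count != 0:
        raise ValueError("population already carries a mutation")
    return replace(pop, mutant_count=1)


def propagate(
    pop: CellPopulation,
    generations: int,
    seed: int | np.random.Generator | None = None,
) -> LineageTrajectory:
    """Drift a mutant lineage forward for up to ``generations`` generations.

    Each generation the next ``mutant_count`` is drawn from
    ``Binomial(n_cells, current lineage frequency)`` — neutral Wright–Fisher
    resampling of the ``n_cells`` founder lineages.  The trajectory stops
    early once the mutation fixes among lineages or is lost, and the outcome
    and the generation at which it occurred are recorded.
    """
    if generations < 1:
        raise ValueError("generations must be >= 1")
    rng = as_rng(seed)
    n = pop.n_cells
    count = pop.mutant_count
    freqs = [count / n]
    elapsed = 0
    outcome = SEGREGATING
    if count in (0, n):
        outcome = LOST if count == 0 else FIXED
        return LineageTrajectory(tuple(freqs), outcome, 0)
    for _ in range(generations):
        count = int(rng.binomial(n, count / n))
        elapsed += 1
        freqs.append(count / n)
        if count == 0:
            outcome = LOST
            break
        if count == n:
            outcome = FIXED
            break
    return LineageTrajectory(tuple(freqs), outcome, elapsed)


def propagate_counts(
    n_cells: int,
    counts: np.ndarray,
    generations: np.ndarray,
    rng: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Vectorised drift of many independent mutant lineages.

    ``counts[i]`` lineages out of ``n_cells`` drift for ``generations[i]``
    generations; the final counts are returned.  Used by the synthetic-data
    generator, where each mutation has its own number of generations between
    origin and sequencing.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = as_rng(rng)
    counts = np.asarray(counts, dtype=np.int64).copy()
    generations = np.asarray(generations, dtype=np.int64)
    if counts.shape != generations.shape:
        raise ValueError("counts and generations must have the same shape")
    if np.any(generations < 0):
        raise ValueError("generations must be non-negative")
    max_gen = int(generations.max(initial=0))
    for g in range(1, max_gen + 1):
        active = (generations >= g) & (counts > 0) & (counts < n_cells)
        if not active.any():
            break
        counts[active] = rng.binomial(n_cells, counts[active] / n_cells)
    return counts


@dataclass(frozen=True)
class MrcaSummary:
    """Monte-Carlo summary of the time until all lineages coalesce."""

    n_cells: int
    replicates: int
    mean: float
    variance: float
    times: np.ndarray = field(repr=False, compare=False)


def time_to_mrca(
    n_cells: int,
    replicates: int,
    seed: int | np.random.Generator | None = None,
    max_generations: int = 100_000,
) -> MrcaSummary:
    """Simulate generations until ``n_cells`` labelled lineages coalesce.

    Each generation every one of the ``n`` new founder cells picks its parent
    uniformly at random among the previous ``n``; coalescence is reached when
    a single ancestral label remains.  For cell lineages this mirrors
    coalescence in a haploid population of size ``n``: roughly ``2n``
    generations on average, with variance growing like ``n**2``.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = as_rng(seed)
    if n_cells == 1:
        times = np.zeros(replicates, dtype=np.int64)
        return MrcaSummary(1, replicates, 0.0, 0.0, times)

    labels = np.tile(np.arange(n_cells), (replicates, 1))
    times = np.zeros(replicates, dtype=np.int64)
    alive = np.ones(replicates, dtype=bool)
    for gen in range(1, max_generations + 1):
        idx = np.nonzero(alive)[0]
        if idx.size == 0:
            break
        parents = rng.integers(0, n_cells, size=(idx.size, n_cells))
        labels[idx] = np.take_along_axis(labels[idx], parents, axis=1)
        done = (labels[idx] == labels[idx, :1]).all(axis=1)
        times[idx[done]] = gen
        alive[idx[done]] = False
    if alive.any():  # pragma: no cover - generous cap
        raise RuntimeError("coalescence not reached within max_generations")
    mean = float(times.mean())
    var = float(times.var(ddof=1)) if replicates > 1 else 0.0
    return MrcaSummary(n_cells, replicates, mean, var, times)
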