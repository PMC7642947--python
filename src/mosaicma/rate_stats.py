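"""Validation-corrected mutation rates, contrasts and mutation spectra.

The per-bp per-generation SNP mutation rate for a set of lines is

    rate = (n_validated + TP * n_not_checked) / (sum_i(callable_i * G_i) * power * 2)

where TP = n_validated / (n_validated + n_failed) is the experiment-wide
Sanger true-positive rate, candidates that failed validation are excluded
outright, and the denominator counts both homologous copies of every
callable site over every MA generation, discounted by detection power.
Confidence intervals treat each site-generation copy as a Bernoulli trial
and use the Agresti–Coull adjusted-Wald interval; treatment and species
contrasts use 1-df chi-square tests on 2x2 count tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .containers import BASES
from .power_model import ExposureDenominator

__all__ = [
    "true_positive_rate",
    "RateEstimate",
    "mutation_rate",
    "mutation_rate_from_counts",
    "agresti_coull_interval",
    "chi_square_contrast",
    "pool_groups",
    "SpectrumSummary",
    "spectrum_summary",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
PYRIMIDINE_CLASSES = ("C>T", "C>A", "C>G", "T>A", "T>C", "T>G")
TRANSITION_CLASSES = ("C>T", "T>C")


def true_positive_rate(n_validated: int, n_failed: int) -> float:
    """Fraction of Sanger-tested candidates that validated.

    Estimated once from all tested mutations across the experiment and used
    to down-weight unchecked candidates in the rate numerator.
    """
    if n_validated < 0 or n_failed < 0:
        raise ValueError("counts must be non-negative")
    total = n_validated + n_failed
    if total == 0:
        raise ValueError("true-positive rate undefined with no tested mutations")
    return n_validated / total


def agresti_coull_interval(
    successes: float, trials: float, confidence: float = 0.95
) -> tuple[float, float]:
    """Agresti–Coull adjusted-Wald binomial interval, truncated to [0, 1].

    With z the standard-normal (1+confidence)/2 quantile:
    n~ = trials + z^2, p~ = (successes + z^2/2) / n~, and the interval is
    p~ +/- z * sqrt(p~ (1-p~) / n~).  Fractional success counts (the
    TP-weighted numerator) are accepted.
    """
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must lie in (0, 1)")
    if trials <= 0:
        raise ValueError("trials must be positive")
    if not 0 <= successes <= trials:
        raise ValueError("successes must lie in [0, trials]")
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    n_tilde = trials + z * z
    p_tilde = (successes + z * z / 2.0) / n_tilde
    half = z * math.sqrt(p_tilde * (1.0 - p_tilde) / n_tilde)
    return max(0.0, p_tilde - half), min(1.0, p_tilde + half)


@dataclass(frozen=True)
class RateEstimate:
    """A per-bp per-generation mutation rate with its 95% interval."""

    numerator: float  # effective mutation count (may be fractional)
    denominator: float  # power-adjusted site-generations (x ploidy)
    rate: float
    ci_low: float
    ci_high: float
    n_validated: int = 0
    n_not_checked: int = 0
    n_failed: int = 0
    tp: float = 1.0
    group: str | None = None
    treatment: str | None = None

    def __post_init__(self) -> None:
        if not self.ci_low <= self.rate <= self.ci_high:
            raise ValueError("interval must bracket the point estimate")


def mutation_rate_from_counts(
    n_validated: int,
    n_not_checked: int,
    tp: float,
    denominator: ExposureDenominator | float,
    n_failed: int = 0,
    confidence: float = 0.95,
    group: str | None = None,
    treatment: str | None = None,
) -> RateEstimate:
    """Rate from explicit candidate counts (failed candidates are excluded)."""
    if min(n_validated, n_not_checked, n_failed) < 0:
        raise ValueError("counts must be non-negative")
    if not 0.0 <= tp <= 1.0:
        raise ValueError("tp must lie in [0, 1]")
    total = denominator.total if isinstance(denominator, ExposureDenominator) else float(denominator)
    if total <= 0:
        raise ValueError("denominator must be positive")
    numerator = n_validated + tp * n_not_checked
    low, high = agresti_coull_interval(numerator, total, confidence)
    return RateEstimate(
        numerator=numerator,
        denominator=total,
        rate=numerator / total,
        ci_low=low,
        ci_high=high,
        n_validated=n_validated,
        n_not_checked=n_not_checked,
        n_failed=n_failed,
        tp=tp,
        group=group,
        treatment=treatment,
    )


def mutation_rate(
    candidates: pd.DataFrame,
    tp: float,
    denominator: ExposureDenominator | float,
    confidence: float = 0.95,
    group: str | None = None,
    treatment: str | None = None,
) -> RateEstimate:
    """Validation-corrected rate for one set of candidate mutations.

    ``candidates`` must carry a ``validation_status`` column with values in
    {validated, failed, not_checked}; failed candidates are dropped from the
    numerator entirely and unchecked ones are weighted by ``tp``.
    """
    status = candidates["validation_status"] if len(candidates) else pd.Series(dtype=object)
    known = {"validated", "failed", "not_checked"}
    bad = set(status.unique()) - known
    if bad:
        raise ValueError(f"unknown validation statuses: {sorted(bad)}")
    return mutation_rate_from_counts(
        n_validated=int((status == "validated").sum()),
        n_not_checked=int((status == "not_checked").sum()),
        n_failed=int((status == "failed").sum()),
        tp=tp,
        denominator=denominator,
        confidence=confidence,
        group=group,
        treatment=treatment,
    )


def chi_square_contrast(
    group_a: tuple[float, float], group_b: tuple[float, float]
) -> tuple[float, float]:
    """1-df chi-square test of rate equality between two sets of lines.

    Each group is (effective mutation count, site-generation exposure); the
    2x2 table is [mutations, exposure - mutations] per group with effective
    counts rounded to the nearest integer.  Returns (statistic, p-value).
    """
    (m_a, e_a), (m_b, e_b) = group_a, group_b
    if e_a <= 0 or e_b <= 0:
        raise ValueError("both exposures must be positive")
    m_a, m_b = round(m_a), round(m_b)
    if m_a == 0 and m_b == 0:
        return 0.0, 1.0  # degenerate table: no mutations anywhere
    table = np.array([[m_a, round(e_a) - m_a], [m_b, round(e_b) - m_b]], dtype=np.int64)
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def pool_groups(groups: Iterable[tuple[float, float]]) -> tuple[float, float]:
    """Merge (mutations, power-scaled exposure) pairs by summation.

    Used for the species contrast, which pools the two conspecific genotypes
    per treatment before testing.
    """
    ms, es = zip(*groups)
    return float(sum(ms)), float(sum(es))


@dataclass(frozen=True)
class SpectrumSummary:
    """Strand-collapsed substitution spectrum of a candidate set."""

    class_counts: Mapping[str, int]
    ti: int
    tv: int
    n_snps: int
    n_skipped: int = 0
    cpg_c_to_t: int | None = None  # requires a reference sequence

    @property
    def titv(self) -> float:
        if self.tv == 0:
            return math.inf if self.ti > 0 else math.nan
        return self.ti / self.tv

    @property
    def cpg_fraction_of_c_to_t(self) -> float:
        c_to_t = self.class_counts.get("C>T", 0)
        if self.cpg_c_to_t is None or c_to_t == 0:
            return math.nan
        return self.cpg_c_to_t / c_to_t


def _collapse(ref: str, alt: str) -> str:
    if ref in "CT":
        return f"{ref}>{alt}"
    return f"{_COMPLEMENT[ref]}>{_COMPLEMENT[alt]}"


def spectrum_summary(
    candidates: pd.DataFrame, reference: Mapping[str, object] | None = None
) -> SpectrumSummary:
    """Classify candidate SNPs into the six pyrimidine-collapsed classes.

    Transitions are C>T plus T>C after strand collapse.  With a reference
    (chromosome -> sequence string or 0..3 base-code array), C>T mutations
    are checked for CpG context: a mutated C immediately followed by G, or
    the reverse-strand equivalent (mutated G immediately preceded by C).
    Non-SNP records (indels, non-ACGT alleles) are skipped and counted.
    """
    counts = {c: 0 for c in PYRIMIDINE_CLASSES}
    cpg = 0 if reference is not None else None
    skipped = 0
    for row in candidates.itertuples(index=False):
        ref, alt = str(row.ref).upper(), str(row.alt).upper()
        if getattr(row, "kind", "snp") != "snp" or len(ref) != 1 or len(alt) != 1:
            skipped += 1
            continue
        if ref not in "ACGT" or alt not in "ACGT" or ref == alt:
            skipped += 1
            continue
        cls = _collapse(ref, alt)
        counts[cls] += 1
        if reference is not None and cls == "C>T":
            seq = reference[row.chrom]
            if _is_cpg(seq, int(row.pos), ref):
                cpg += 1
    ti = sum(counts[c] for c in TRANSITION_CLASSES)
    n = sum(counts.values())
    return SpectrumSummary(
        class_counts=counts, ti=ti, tv=n - ti, n_snps=n, n_skipped=skipped, cpg_c_to_t=cpg
    )


def _base_at(seq, pos: int) -> str | None:
    """1-based lookup into a sequence string or uint8 base-code array."""
    if pos < 1:
        return None
    if isinstance(seq, (str, bytes)):
        if pos > len(seq):
            return None
        b = seq[pos - 1]
        return chr(b) if isinstance(b, int) else b
    arr = np.asarray(seq)
    if pos > arr.size:
        return None
    return BASES[int(arr[pos - 1])]


def _is_cpg(seq, pos: int, ref: str) -> bool:
    if ref == "C":
        return _base_at(seq, pos + 1) == "G"
    if ref == "G":
        return _base_at(seq, pos - 1) == "C"
    return False
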