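"""Genome-instability rates, spectra and contingency statistics.

Rates are expressed per genome per cell division: the event count divided
by the total genome-divisions of the subculture design (and additionally
by genome size for per-base point-mutation rates).  Reported values are
rounded to two significant figures, matching common presentation; the
unrounded value is always retained.

Contingency statistics follow the conventions that reproduce the
published worked examples: two-sided Fisher's exact test by the
point-probability rule (the sum of table probabilities not exceeding the
observed table's), and the chi-square enrichment test with one degree of
freedom and no continuity correction, with expected counts rounded to
their reported precision (two significant figures) before the statistic
is formed — see ``docs/methods.md`` for the rationale.  No
multiple-testing correction is applied anywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome import CultureDesign
from .simulate import SPECTRUM_CLASSES

__all__ = [
    "round_sig",
    "RateEstimate", "EnrichmentResult", "SpectrumTally", "FrequencyResult",
    "estimate_event_rate", "estimate_base_rate", "fold_change",
    "fisher_exact_2x2", "region_enrichment",
    "tally_spectrum", "compare_spectra",
    "mutant_frequency", "breakpoint_distribution", "ratio_table",
    "OXIDATION_CLASSES",
]

OXIDATION_CLASSES = ("CG>TA", "CG>AT")


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (0 stays 0)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def _divisions(design: CultureDesign | int) -> int:
    if isinstance(design, CultureDesign):
        return design.total_divisions
    d = int(design)
    if d <= 0:
        raise ValueError("total divisions must be positive")
    return d


@dataclass(frozen=True)
class RateEstimate:
    """An event rate per genome (or per base) per cell division."""

    n_events: int
    total_divisions: int
    genome_size: int | None = None

    def __post_init__(self) -> None:
        if self.n_events < 0:
            raise ValueError("negative event count")
        if self.total_divisions <= 0:
            raise ValueError("total_divisions must be positive")

    @property
    def rate(self) -> float:
        """Events per genome per cell division."""
        return self.n_events / self.total_divisions

    @property
    def rate_per_base(self) -> float | None:
        if self.genome_size is None:
            return None
        return self.rate / self.genome_size

    @property
    def rate_2sf(self) -> float:
        """The rate as reported, to two significant figures."""
        r = self.rate_per_base if self.genome_size is not None else self.rate
        return round_sig(r, 2)

    @property
    def se(self) -> float:
        """Binomial standard error of the per-genome rate."""
        p = self.rate
        return math.sqrt(p * (1 - p) / self.total_divisions)

    def __str__(self) -> str:
        unit = "per base per division" if self.genome_size else "per genome per division"
        return f"{self.n_events}/{self.total_divisions} -> {self.rate_2sf:.2g} {unit}"


def estimate_event_rate(n_events: int, design: CultureDesign | int) -> RateEstimate:
    """Events per genome per cell division under a subculture design."""
    return RateEstimate(n_events=int(n_events), total_divisions=_divisions(design))


def estimate_base_rate(
    n: int, design: CultureDesign | int, genome_size: int
) -> RateEstimate:
    """Point-mutation rate per base per cell division (diploid genome size)."""
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    return RateEstimate(n_events=int(n), total_divisions=_divisions(design),
                        genome_size=int(genome_size))


def fold_change(rate_a, rate_b) -> float:
    """Ratio of two rates; accepts floats or :class:`RateEstimate`.

    Raises on a zero baseline.  Note that published fold changes are
    typically ratios of the *reported* (2-significant-figure) rates; use
    ``RateEstimate.rate_2sf`` to reproduce them.
    """
    a = rate_a.rate if isinstance(rate_a, RateEstimate) else float(rate_a)
    b = rate_b.rate if isinstance(rate_b, RateEstimate) else float(rate_b)
    if b == 0:
        raise ZeroDivisionError(
            "zero baseline rate; fold change undefined — compare counts directly"
        )
    return a / b


# ---------------------------------------------------------------------------
# Contingency statistics
# ---------------------------------------------------------------------------


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher's exact p for a 2x2 count table.

    Two-sided by the point-probability rule: the sum of hypergeometric
    probabilities of all tables (with the observed margins) whose
    probability does not exceed the observed table's.  An empty margin
    gives p = 1.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("cells must be nonnegative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        import warnings

        warnings.warn("empty margin: association undefined, p = 1", stacklevel=2)
        return 1.0
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


@dataclass(frozen=True)
class EnrichmentResult:
    """Observed vs expected events in a genomic region."""

    observed: int
    total: int
    region_bp: int
    genome_bp: int
    expected: float          # exact: region_bp / genome_bp * total
    expected_reported: float  # rounded to reported precision (2 sig figs)
    chi_square: float
    p_value: float

    def __str__(self) -> str:
        return (
            f"{self.observed} observed vs {self.expected_reported:g} expected "
            f"in {self.region_bp}/{self.genome_bp} bp "
            f"(chi2 = {self.chi_square:.2f}, p = {self.p_value:.3g})"
        )


def region_enrichment(
    observed: int,
    total: int,
    region_bp: int,
    genome_bp: int,
    *,
    round_expected_to: int | None = 2,
) -> EnrichmentResult:
    """Chi-square test for enrichment of events inside a region.

    The expected in-region count is ``region_bp / genome_bp * total``.
    The chi-square sums ``(O - E)^2 / E`` over the in-region and
    out-of-region cells, df = 1, no continuity correction.  By default
    the expected counts are rounded to 2 significant figures (their
    reported precision) before the statistic; pass
    ``round_expected_to=None`` for the exact expectation.
    """
    if not (0 <= observed <= total):
        raise ValueError("need 0 <= observed <= total")
    if not (0 < region_bp <= genome_bp):
        raise ValueError("need 0 < region_bp <= genome_bp")
    expected = region_bp / genome_bp * total
    e_in = expected if round_expected_to is None else round_sig(expected, round_expected_to)
    if e_in <= 0:
        raise ValueError("zero expected count; test undefined")
    e_out = total - e_in
    o_in, o_out = observed, total - observed
    chi2 = (o_in - e_in) ** 2 / e_in
    if e_out > 0:
        chi2 += (o_out - e_out) ** 2 / e_out
    elif o_out > 0:
        raise ValueError("zero expected count outside region with nonzero observed")
    p = float(sps.chi2.sf(chi2, df=1)) if chi2 > 0 else 1.0
    return EnrichmentResult(
        observed=observed, total=total, region_bp=region_bp, genome_bp=genome_bp,
        expected=expected, expected_reported=round_sig(expected, 2),
        chi_square=float(chi2), p_value=p,
    )


# ---------------------------------------------------------------------------
# Mutation spectra
# ---------------------------------------------------------------------------

_PAIR = {"A": "T", "C": "G", "G": "C", "T": "A"}


# Collapse by strand symmetry to a C/T reference, then name by the
# destination pair: from C -> {T: CG>TA, A: CG>AT, G: CG>GC}; from T ->
# {C: TA>CG, A: TA>AT, G: TA>GC}.
_CLASS_OF = {
    ("C", "T"): "CG>TA", ("C", "A"): "CG>AT", ("C", "G"): "CG>GC",
    ("T", "C"): "TA>CG", ("T", "A"): "TA>AT", ("T", "G"): "TA>GC",
}


def _classify_snv(ref: str, alt: str) -> str | None:
    ref, alt = ref.upper(), alt.upper()
    if ref not in _PAIR or alt not in _PAIR or ref == alt:
        return None
    if ref in ("G", "A"):
        ref, alt = _PAIR[ref], _PAIR[alt]
    return _CLASS_OF.get((ref, alt))


@dataclass(frozen=True)
class SpectrumTally:
    """Counts over the six collapsed substitution classes."""

    counts: tuple[int, ...]  # ordered as SPECTRUM_CLASSES

    @property
    def total(self) -> int:
        return sum(self.counts)

    @property
    def proportions(self) -> tuple[float, ...]:
        t = self.total
        return tuple(c / t for c in self.counts) if t else tuple(0.0 for _ in self.counts)

    def count(self, klass: str) -> int:
        return self.counts[SPECTRUM_CLASSES.index(klass)]

    @property
    def oxidation_count(self) -> int:
        """CG>TA + CG>AT: the oxidative-damage signature classes."""
        return sum(self.count(k) for k in OXIDATION_CLASSES)

    @property
    def oxidation_fraction(self) -> float:
        return self.oxidation_count / self.total if self.total else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "class": SPECTRUM_CLASSES,
            "count": self.counts,
            "proportion": self.proportions,
        })


def tally_spectrum(snvs: Iterable) -> SpectrumTally:
    """Tally SNVs into the six collapsed substitution classes.

    Accepts ``(ref, alt)`` pairs, ``"C>T"`` strings, objects with
    ``ref``/``alt`` attributes, class names themselves, or simulated
    events carrying ``snv_class``.  Records with non-ACGT bases are
    skipped with a warning.
    """
    import warnings

    counts = [0] * len(SPECTRUM_CLASSES)
    for s in snvs:
        klass: str | None
        if isinstance(s, str):
            if s in SPECTRUM_CLASSES:
                klass = s
            else:
                parts = s.split(">")
                klass = (_classify_snv(parts[0], parts[1])
                         if len(parts) == 2 and len(parts[0]) == 1 else None)
        elif isinstance(s, (tuple, list)) and len(s) == 2:
            klass = _classify_snv(s[0], s[1])
        elif getattr(s, "snv_class", None):
            klass = s.snv_class if s.snv_class in SPECTRUM_CLASSES else None
        elif hasattr(s, "ref") and hasattr(s, "alt"):
            klass = _classify_snv(s.ref, s.alt)
        else:
            klass = None
        if klass is None:
            warnings.warn(f"skipping unclassifiable SNV record {s!r}", stacklevel=2)
            continue
        counts[SPECTRUM_CLASSES.index(klass)] += 1
    return SpectrumTally(counts=tuple(counts))


def compare_spectra(tally_a: SpectrumTally, tally_b: SpectrumTally) -> float:
    """Fisher's exact p comparing the oxidation-class share (CG>TA+CG>AT
    vs all others) between two spectra."""
    if tally_a.total == 0 or tally_b.total == 0:
        raise ValueError("both tallies must be nonempty")
    table = [
        [tally_a.oxidation_count, tally_a.total - tally_a.oxidation_count],
        [tally_b.oxidation_count, tally_b.total - tally_b.oxidation_count],
    ]
    return fisher_exact_2x2(table)


# ---------------------------------------------------------------------------
# Mutant frequencies, breakpoints, ratio table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FrequencyResult:
    """Mutant frequencies across parallel cultures."""

    per_culture: tuple[float, ...]
    median: float
    mean: float


def mutant_frequency(
    mutant_counts: Sequence[int], viable_counts: Sequence[int]
) -> FrequencyResult:
    """Per-culture mutant frequencies with median and mean summaries.

    The median is the headline summary (robust to jackpot cultures in a
    fluctuation-style experiment); the mean is reported alongside.
    """
    if len(mutant_counts) != len(viable_counts):
        raise ValueError("mutant_counts and viable_counts must have equal length")
    if len(mutant_counts) == 0:
        raise ValueError("need at least one culture")
    freqs = []
    for m, v in zip(mutant_counts, viable_counts):
        if v <= 0:
            raise ValueError("viable counts must be positive")
        if m < 0:
            raise ValueError("mutant counts must be nonnegative")
        freqs.append(m / v)
    return FrequencyResult(
        per_culture=tuple(freqs),
        median=float(np.median(freqs)),
        mean=float(np.mean(freqs)),
    )


def breakpoint_distribution(breakpoints: Sequence, window: tuple[int, int]) -> float:
    """Fraction of breakpoint midpoints inside the bp window (inclusive).

    ``breakpoints`` may be numbers or objects with a ``midpoint``.
    """
    if len(breakpoints) == 0:
        raise ValueError("no breakpoints supplied; proportion undefined")
    lo, hi = window
    mids = np.array([getattr(b, "midpoint", b) for b in breakpoints], dtype=float)
    return float(np.mean((mids >= lo) & (mids <= hi)))


def ratio_table(event_counts: pd.DataFrame | dict) -> pd.DataFrame:
    """Per-condition row percentages of event-class counts.

    Input: mapping of condition -> {class: count} or an equivalent
    DataFrame (conditions as rows).  Output: percentages (count / row
    total x 100) rounded to one decimal, plus an ``n_total`` column.
    """
    df = pd.DataFrame(event_counts).T if isinstance(event_counts, dict) else event_counts.copy()
    if (df.to_numpy() < 0).any():
        raise ValueError("negative counts")
    totals = df.sum(axis=1)
    if (totals == 0).any():
        bad = totals.index[totals == 0].tolist()
        raise ValueError(f"zero row total for condition(s) {bad}")
    pct = (df.div(totals, axis=0) * 100).round(1)
    pct["n_total"] = totals
    return pct
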