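"""Synthetic hybrid-diploid data with known ground truth.

Generates karyotypes with spiked genomic alterations — interstitial and
terminal loss of heterozygosity (I-LOH, T-LOH), terminal deletions and
duplications (T-DEL, T-DUP), whole-chromosome trisomy/monosomy,
uniparental disomy (UPD) and point mutations — and emits the two kinds of
observable the pipeline consumes:

* sequencing allele depths: per SNP site, per homolog, Poisson reads with
  mean ``mean_depth * copies / 2`` (so a balanced heterozygous site at
  total depth 50 averages 25 reads per homolog);
* SNP-microarray hybridization ratios: level 0.2 / 1.0 / 1.5 for 0 / 1 /
  2+ copies plus Gaussian noise.

Sequencing noise is Poisson only (no mapping bias, no GC bias): this is
sufficient to exercise the relative-coverage thresholds the caller uses.
Event breakpoints snap to inter-SNP midpoints so the ground truth is
well-defined at SNP resolution.  All randomness flows through a seeded
``numpy`` generator; the same seed gives bit-identical outputs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import HOMOLOGS, GenomeMap

__all__ = [
    "ILOH", "TLOH", "TDEL", "TDUP", "TRISOMY", "MONOSOMY", "UPD", "SNV", "INDEL",
    "COPY_EVENT_TYPES", "SPECTRUM_CLASSES",
    "FURFURAL_RATES", "CONTROL_RATES", "FURFURAL_SPECTRUM", "UNTREATED_SPECTRUM",
    "TrueEvent", "Karyotype", "SimulationConfig",
    "spike_events", "simulate_allele_depths", "simulate_array", "simulate_mutations",
    "write_truth", "read_truth", "match_events", "MatchResult", "other_homolog",
]

ILOH = "I-LOH"
TLOH = "T-LOH"
TDEL = "T-DEL"
TDUP = "T-DUP"
TRISOMY = "TRISOMY"
MONOSOMY = "MONOSOMY"
UPD = "UPD"
SNV = "SNV"
INDEL = "INDEL"

COPY_EVENT_TYPES = (ILOH, TLOH, TDEL, TDUP, TRISOMY, MONOSOMY, UPD)
_WHOLE_CHROM_TYPES = (TRISOMY, MONOSOMY, UPD)

SPECTRUM_CLASSES = ("CG>TA", "CG>AT", "CG>GC", "TA>CG", "TA>AT", "TA>GC")

# Per-genome per-division event rates of the furfural subculture condition
# (0.6 g/L arm): LOH and rearrangement rates as published, aneuploidy split
# by the observed trisomy:monosomy:UPD proportions (15:17:4 of 36).
FURFURAL_RATES: dict[str, float] = {
    ILOH: 2.2e-3,
    TLOH: 3.4e-3,
    TDEL: 7.0e-4 * 6 / 8,
    TDUP: 7.0e-4 * 2 / 8,
    TRISOMY: 3.2e-3 * 15 / 36,
    MONOSOMY: 3.2e-3 * 17 / 36,
    UPD: 3.2e-3 * 4 / 36,
}

# Untreated serial-transfer condition: only the two LOH rates are pinned by
# the study; other classes are rare and left at zero by default.
CONTROL_RATES: dict[str, float] = {ILOH: 1.2e-3, TLOH: 4.0e-4}

# Six-class single-nucleotide substitution spectra (probabilities).  The
# furfural spectrum puts 60% of mass on the two oxidation-linked classes
# (CG>TA + CG>AT); the untreated spectrum puts 22% + 26% on them.
FURFURAL_SPECTRUM: dict[str, float] = {
    "CG>TA": 0.32, "CG>AT": 0.28, "CG>GC": 0.10,
    "TA>CG": 0.10, "TA>AT": 0.10, "TA>GC": 0.10,
}
UNTREATED_SPECTRUM: dict[str, float] = {
    "CG>TA": 0.22, "CG>AT": 0.26, "CG>GC": 0.13,
    "TA>CG": 0.13, "TA>AT": 0.13, "TA>GC": 0.13,
}


def other_homolog(h: str) -> str:
    w, y = HOMOLOGS
    return y if h == w else w


@dataclass(frozen=True)
class TrueEvent:
    """A spiked genomic alteration (ground truth).

    ``homolog`` is the *affected* homolog: the one lost for LOH, deletion,
    monosomy and UPD; the one gained for duplication and trisomy.
    ``start``/``end`` are 1-based inclusive bp; whole-chromosome events
    span (1, chromosome length).  For SNVs, ``snv_class`` is one of the
    six collapsed substitution classes.
    """

    type: str
    chrom: str
    start: int
    end: int
    homolog: str = "W"
    snv_class: str | None = None
    event_id: str = ""

    def __post_init__(self) -> None:
        if self.type not in COPY_EVENT_TYPES + (SNV, INDEL):
            raise ValueError(f"unknown event type {self.type!r}")
        if self.homolog not in HOMOLOGS:
            raise ValueError(f"unknown homolog {self.homolog!r}")
        if self.start > self.end:
            raise ValueError(f"{self.event_id or self.type}: start > end")

    @property
    def retained_homolog(self) -> str:
        """The homolog left at elevated copy for copy-neutral events."""
        return other_homolog(self.homolog)


class EventConflictError(ValueError):
    """Two spiked events make contradictory claims about one homolog."""


@dataclass
class Karyotype:
    """Per-homolog copy number over SNP positions, defined by an event list.

    The default (no events) is one copy of each homolog everywhere; each
    copy-class event perturbs copy numbers over its interval.
    """

    genome: GenomeMap
    events: tuple[TrueEvent, ...] = ()

    def __post_init__(self) -> None:
        self.events = tuple(self.events)
        self._validate()
        self._cn: dict[str, dict[str, np.ndarray]] | None = None

    def _validate(self) -> None:
        copy_events = [e for e in self.events if e.type in COPY_EVENT_TYPES]
        for e in copy_events:
            spec = self.genome.chromosome(e.chrom)
            if e.start < 1 or e.end > spec.length:
                raise ValueError(f"{e.event_id or e.type}: interval outside {e.chrom}")
        for a, b in itertools.combinations(copy_events, 2):
            if a.chrom != b.chrom:
                continue
            if a.start <= b.end and b.start <= a.end:
                raise EventConflictError(
                    f"conflicting events on {a.chrom}: "
                    f"{a.event_id or a.type} overlaps {b.event_id or b.type}"
                )

    def _effects(self, event: TrueEvent) -> dict[str, int]:
        """Copy number of each homolog inside the event interval."""
        w, y = HOMOLOGS
        aff, ret = event.homolog, event.retained_homolog
        if event.type in (ILOH, TLOH, UPD):
            return {aff: 0, ret: 2}
        if event.type in (TDEL, MONOSOMY):
            return {aff: 0}
        if event.type in (TDUP, TRISOMY):
            return {aff: 2}
        return {}

    def copy_numbers(self) -> pd.DataFrame:
        """Copy number of each homolog at every SNP site: columns
        chrom, pos, cn_w, cn_y."""
        if self._cn is None:
            cn: dict[str, dict[str, np.ndarray]] = {}
            for chrom in self.genome.chrom_names:
                pos = self.genome.snp_positions(chrom)
                cn[chrom] = {h: np.ones(len(pos), dtype=int) for h in HOMOLOGS}
            for e in self.events:
                if e.type not in COPY_EVENT_TYPES:
                    continue
                pos = self.genome.snp_positions(e.chrom)
                inside = (pos >= e.start) & (pos <= e.end)
                for h, c in self._effects(e).items():
                    cn[e.chrom][h][inside] = c
            self._cn = cn
        rows = []
        for chrom in self.genome.chrom_names:
            pos = self.genome.snp_positions(chrom)
            rows.append(
                pd.DataFrame(
                    {"chrom": chrom, "pos": pos,
                     "cn_w": self._cn[chrom][HOMOLOGS[0]],
                     "cn_y": self._cn[chrom][HOMOLOGS[1]]}
                )
            )
        return pd.concat(rows, ignore_index=True)

    def copies(self, chrom: str, homolog: str, pos: int) -> int:
        """Copy number of ``homolog`` at an arbitrary position (not
        necessarily a SNP site)."""
        if homolog not in HOMOLOGS:
            raise ValueError(f"unknown homolog {homolog!r}")
        c = 1
        for e in self.events:
            if e.type in COPY_EVENT_TYPES and e.chrom == chrom and e.start <= pos <= e.end:
                c = self._effects(e).get(homolog, c)
        return c


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generator; the defaults are the study conditions.

    ``mean_depth`` is the total diploid-baseline reads per SNP site;
    ``rates`` are per-genome per-division event rates (ignored when
    ``events`` is given explicitly); ``divisions`` is the number of
    genome-divisions an isolate accumulates events over (400 = 8 furfural
    cycles x 2 colony formations x 25 divisions); the seed is mandatory.
    """

    rng_seed: int
    mean_depth: float = 50.0
    array_noise_sd: float = 0.05
    divisions: int = 400
    rates: Mapping[str, float] | None = None
    events: Sequence[TrueEvent] | None = None
    spectrum: Mapping[str, float] = field(default_factory=lambda: dict(FURFURAL_SPECTRUM))
    min_snps: int = 3
    max_terminal_fraction: float = 0.90
    interior_margin_snps: int = 3

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if self.array_noise_sd < 0:
            raise ValueError("array_noise_sd must be >= 0")
        tot = sum(self.spectrum.get(k, 0.0) for k in SPECTRUM_CLASSES)
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"spectrum probabilities sum to {tot}, not 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)


# ---------------------------------------------------------------------------
# Event spiking
# ---------------------------------------------------------------------------


def _snap_interval(pos: np.ndarray, i: int, j: int, length: int) -> tuple[int, int]:
    """Bp interval covering SNP indices i..j, snapped to inter-SNP midpoints
    (or the chromosome ends when the run is terminal)."""
    lo = 1 if i == 0 else int((pos[i - 1] + pos[i]) // 2 + 1)
    hi = length if j == len(pos) - 1 else int((pos[j] + pos[j + 1]) // 2)
    return lo, hi


def _place_interior(rng, pos, length, cfg: SimulationConfig) -> tuple[int, int] | None:
    n = len(pos)
    m = cfg.interior_margin_snps
    if n < cfg.min_snps + 2 * m:
        return None
    tract = rng.uniform(2_000.0, 50_000.0)  # bp; gene-conversion scale
    i = int(rng.integers(m, n - m - cfg.min_snps + 1))
    j = i + cfg.min_snps - 1
    while j + 1 < n - m and pos[j + 1] - pos[i] <= tract:
        j += 1
    return i, j


def _place_terminal(rng, pos, cfg: SimulationConfig) -> tuple[int, int] | None:
    n = len(pos)
    k_max = int(cfg.max_terminal_fraction * n)
    if k_max < cfg.min_snps:
        return None
    k = int(rng.integers(cfg.min_snps, k_max + 1))  # SNPs covered
    if rng.random() < 0.5:
        return 0, k - 1  # left-telomeric
    return n - k, n - 1  # right-telomeric


def spike_events(
    genome: GenomeMap,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[Karyotype, list[TrueEvent]]:
    """Draw a karyotype: explicit events, or Poisson counts at the
    configured per-division rates placed uniformly over the genome.

    Whole-chromosome events claim their chromosome outright; segmental
    events are re-placed (bounded retries) rather than dropped when they
    would overlap an earlier event, so realised counts stay Poisson.
    """
    if config.events is not None:
        events = [replace(e, event_id=e.event_id or f"true_{k}")
                  for k, e in enumerate(config.events)]
        return Karyotype(genome, tuple(events)), events
    if config.rates is None:
        return Karyotype(genome, ()), []
    rng = config.rng() if rng is None else rng
    lengths = np.array([c.length for c in genome.chromosomes], dtype=float)
    p_chrom = lengths / lengths.sum()
    names = genome.chrom_names
    events: list[TrueEvent] = []
    occupied: dict[str, list[tuple[int, int]]] = {n: [] for n in names}
    whole: set[str] = set()
    counter = 0
    for etype in COPY_EVENT_TYPES + (SNV, INDEL):
        lam = float(config.rates.get(etype, 0.0)) * config.divisions
        if lam <= 0:
            continue
        n_ev = int(rng.poisson(lam))
        for _ in range(n_ev):
            for _try in range(200):
                chrom = names[int(rng.choice(len(names), p=p_chrom))]
                if chrom in whole:
                    continue
                spec = genome.chromosome(chrom)
                pos = genome.snp_positions(chrom)
                homolog = HOMOLOGS[int(rng.integers(0, 2))]
                if etype in _WHOLE_CHROM_TYPES:
                    if occupied[chrom]:
                        continue
                    ev = TrueEvent(etype, chrom, 1, spec.length, homolog,
                                   event_id=f"true_{counter}")
                    whole.add(chrom)
                    occupied[chrom].append((1, spec.length))
                elif etype in (SNV, INDEL):
                    p = int(rng.integers(1, spec.length + 1))
                    klass = (
                        str(rng.choice(SPECTRUM_CLASSES,
                                       p=[config.spectrum.get(k, 0.0) for k in SPECTRUM_CLASSES]))
                        if etype == SNV else None
                    )
                    ev = TrueEvent(etype, chrom, p, p, homolog, snv_class=klass,
                                   event_id=f"true_{counter}")
                else:
                    ij = (_place_interior(rng, pos, spec.length, config)
                          if etype == ILOH else _place_terminal(rng, pos, config))
                    if ij is None:
                        continue
                    lo, hi = _snap_interval(pos, ij[0], ij[1], spec.length)
                    if any(lo <= e and s <= hi for s, e in occupied[chrom]):
                        continue
                    ev = TrueEvent(etype, chrom, lo, hi, homolog, event_id=f"true_{counter}")
                    occupied[chrom].append((lo, hi))
                events.append(ev)
                counter += 1
                break
    return Karyotype(genome, tuple(events)), events


# ---------------------------------------------------------------------------
# Observables
# ---------------------------------------------------------------------------


def simulate_allele_depths(
    karyotype: Karyotype,
    genome: GenomeMap,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Sequencing allele depths: ``depth_h ~ Poisson(mean_depth * cn_h / 2)``
    at every SNP site.  Columns chrom, pos, w_depth, y_depth."""
    rng = config.rng() if rng is None else rng
    cn = karyotype.copy_numbers()
    out = cn[["chrom", "pos"]].copy()
    out["w_depth"] = rng.poisson(config.mean_depth * cn["cn_w"].to_numpy() / 2.0)
    out["y_depth"] = rng.poisson(config.mean_depth * cn["cn_y"].to_numpy() / 2.0)
    return out


_ARRAY_LEVELS = {0: 0.2, 1: 1.0, 2: 1.5}


def simulate_array(
    karyotype: Karyotype,
    genome: GenomeMap,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Microarray hybridization ratios, long format: columns chrom, pos,
    homolog, hyb_ratio.  Level 0.2/1.0/1.5 for 0/1/2 copies (>=2 clamps to
    1.5) plus Gaussian noise of sd ``array_noise_sd``."""
    rng = config.rng() if rng is None else rng
    cn = karyotype.copy_numbers()
    frames = []
    for homolog, col in zip(HOMOLOGS, ("cn_w", "cn_y")):
        level = np.array([_ARRAY_LEVELS[min(int(c), 2)] for c in cn[col]])
        noise = rng.normal(0.0, config.array_noise_sd, size=len(level)) if config.array_noise_sd else 0.0
        frames.append(
            pd.DataFrame({"chrom": cn["chrom"], "pos": cn["pos"],
                          "homolog": homolog, "hyb_ratio": level + noise})
        )
    return (
        pd.concat(frames, ignore_index=True)
        .sort_values(["chrom", "pos", "homolog"], kind="stable")
        .reset_index(drop=True)
    )


def simulate_mutations(
    config: SimulationConfig,
    n: int,
    rng: np.random.Generator | None = None,
    genome: GenomeMap | None = None,
) -> list[TrueEvent]:
    """``n`` SNVs with classes multinomially distributed per the configured
    six-class spectrum; positions uniform over the genome when one is given."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = config.rng() if rng is None else rng
    probs = [config.spectrum.get(k, 0.0) for k in SPECTRUM_CLASSES]
    classes = rng.choice(len(SPECTRUM_CLASSES), size=n, p=probs)
    out = []
    for k, ci in enumerate(classes):
        if genome is not None:
            lengths = np.array([c.length for c in genome.chromosomes], dtype=float)
            ci_chrom = int(rng.choice(len(lengths), p=lengths / lengths.sum()))
            chrom = genome.chrom_names[ci_chrom]
            p = int(rng.integers(1, genome.chromosomes[ci_chrom].length + 1))
        else:
            chrom, p = "I", k + 1
        out.append(
            TrueEvent(SNV, chrom, p, p, HOMOLOGS[int(rng.integers(0, 2))],
                      snv_class=SPECTRUM_CLASSES[ci], event_id=f"snv_{k}")
        )
    return out


# ---------------------------------------------------------------------------
# Truth IO and evaluation against truth
# ---------------------------------------------------------------------------

_TRUTH_COLS = ["true_id", "true_type", "true_chrom", "true_start", "true_end",
               "true_homolog", "true_snv_class"]


def write_truth(events: Iterable[TrueEvent], path: str | Path) -> None:
    rows = [
        {"true_id": e.event_id, "true_type": e.type, "true_chrom": e.chrom,
         "true_start": e.start, "true_end": e.end, "true_homolog": e.homolog,
         "true_snv_class": e.snv_class or ""}
        for e in events
    ]
    pd.DataFrame(rows, columns=_TRUTH_COLS).to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> list[TrueEvent]:
    df = pd.read_csv(path, sep="\t", dtype={"true_chrom": str}, keep_default_na=False)
    return [
        TrueEvent(r.true_type, str(r.true_chrom), int(r.true_start), int(r.true_end),
                  r.true_homolog, snv_class=(r.true_snv_class or None),
                  event_id=str(r.true_id))
        for r in df.itertuples(index=False)
    ]


@dataclass
class MatchResult:
    """Outcome of comparing calls against spiked truth."""

    matched: list[tuple[TrueEvent, object]]
    missed: list[TrueEvent]
    spurious: list[object]

    @property
    def recall(self) -> float:
        n = len(self.matched) + len(self.missed)
        return len(self.matched) / n if n else float("nan")

    @property
    def precision(self) -> float:
        n = len(self.matched) + len(self.spurious)
        return len(self.matched) / n if n else float("nan")


def _snp_span(genome: GenomeMap, chrom: str, start: int, end: int) -> tuple[int, int] | None:
    pos = genome.snp_positions(chrom)
    i = int(np.searchsorted(pos, start, side="left"))
    j = int(np.searchsorted(pos, end, side="right")) - 1
    return (i, j) if j >= i else None


def _call_affected_homolog(call) -> str:
    # EventCall stores the retained homolog for copy-neutral events.
    if call.type in (ILOH, TLOH, UPD):
        return other_homolog(call.homolog)
    return call.homolog


def match_events(
    truth: Sequence[TrueEvent],
    calls: Sequence,
    genome: GenomeMap,
    *,
    exact: bool = True,
    min_overlap: float = 0.5,
    min_snps: int = 3,
    count_unclassified: bool = False,
) -> MatchResult:
    """Match called events to spiked truth by type, homolog and SNP span.

    ``exact`` requires the identical SNP index span (the noiseless
    contract); otherwise a call matches when its SNP span overlaps the
    true span by at least ``min_overlap`` of the shorter one.  Truth
    events spanning fewer than ``min_snps`` sites are outside the
    caller's contract and excluded from scoring.  UNCLASSIFIED regions
    are diagnostic output, not taxonomy calls, and are excluded from the
    spurious tally unless ``count_unclassified`` is set.
    """
    if not count_unclassified:
        calls = [c for c in calls if c.type in COPY_EVENT_TYPES]
    truth_cn = [t for t in truth if t.type in COPY_EVENT_TYPES]
    scored = []
    for t in truth_cn:
        span = _snp_span(genome, t.chrom, t.start, t.end)
        if span and span[1] - span[0] + 1 >= min_snps:
            scored.append((t, span))
    matched, missed = [], []
    used: set[int] = set()
    for t, (ti, tj) in scored:
        hit = None
        for k, c in enumerate(calls):
            if k in used or c.chrom != t.chrom or c.type != t.type:
                continue
            if _call_affected_homolog(c) != t.homolog:
                continue
            cspan = _snp_span(genome, c.chrom, c.start, c.end)
            if cspan is None:
                continue
            ci, cj = cspan
            if exact:
                ok = (ci, cj) == (ti, tj)
            else:
                ov = min(cj, tj) - max(ci, ti) + 1
                shorter = min(cj - ci, tj - ti) + 1
                ok = ov > 0 and ov / shorter >= min_overlap
            if ok:
                hit = k
                break
        if hit is None:
            missed.append(t)
        else:
            used.add(hit)
            matched.append((t, calls[hit]))
    spurious = [c for k, c in enumerate(calls) if k not in used]
    return MatchResult(matched=matched, missed=missed, spurious=spurious)
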