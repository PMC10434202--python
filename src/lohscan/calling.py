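"""Copy-state segmentation, event calling and translocation pairing.

From a homolog-resolved RC profile the caller proceeds in three steps:

1. **Segmentation** — each SNP is assigned a per-homolog copy state by
   symmetric thresholds around the RC levels 0/0.5/1 (defaults: <0.25 is
   0 copies, <0.75 is 1, <1.25 is 2, else 3), and runs shorter than
   ``min_snps`` are merged into their dominant (longer) neighbor.
2. **Event calling** — joint (W, Y) states over maximal regions are
   mapped to the event taxonomy: copy-neutral (0, 2) regions are
   interstitial LOH in the chromosome interior, terminal LOH when they
   reach one telomere, and uniparental disomy chromosome-wide; (0, 1)
   regions reaching a telomere are terminal deletions, (2, 1) terminal
   duplications; whole-chromosome single-homolog gains/losses are
   trisomy/monosomy.  A whole-chromosome call requires the state over at
   least 95% of the chromosome's SNPs (edge noise tolerated); anything
   not in the taxonomy is reported as UNCLASSIFIED rather than dropped.
   Terminal LOH with an extra conversion tract near the breakpoint is
   flagged conversion-associated (class B5).
3. **Breakpoint resolution** — every within-chromosome state transition
   is localised to the interval between the last SNP of the old state
   and the first SNP of the new state; transitions at chromosome ends
   clamp to position 1 or the chromosome length.

Paired terminal duplications (and, via their retained complements, paired
terminal deletions) on different chromosomes are combined into
translocation hypotheses under the monocentric constraint: exactly one of
the two fragments must carry its centromere, and the predicted product
size is the sum of the fragment lengths.

The statsmodels-style entry point is :class:`CopyStateModel`; its
``fit()`` returns a :class:`CopyStateResults` holding segments, events,
breakpoints and summaries.  The step functions are also public.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import HOMOLOGS, ChromosomeSpec, GenomeMap
from .profiles import smooth_profile
from .simulate import (
    ILOH, MONOSOMY, TDEL, TDUP, TLOH, TRISOMY, UPD, other_homolog,
)

UNCLASSIFIED = "UNCLASSIFIED"

DEFAULT_THRESHOLDS = (0.25, 0.75, 1.25)
DEFAULT_MIN_SNPS = 3
DEFAULT_ANEUPLOIDY_FRACTION = 0.95
DEFAULT_B5_GAP_SNPS = 10

__all__ = [
    "UNCLASSIFIED", "DEFAULT_THRESHOLDS", "DEFAULT_MIN_SNPS",
    "HomologSegment", "BreakpointInterval", "EventCall", "Fragment",
    "TranslocationHypothesis", "PairingResult",
    "segment_copy_states", "call_events", "resolve_breakpoint",
    "classify_event", "pair_translocations",
    "CopyStateModel", "CopyStateResults",
    "events_to_frame", "write_events_tsv", "read_events_tsv", "write_events_bed",
    "translocations_to_frame", "write_translocations_tsv",
]


@dataclass(frozen=True)
class HomologSegment:
    """Maximal run of one homolog at one copy state."""

    chrom: str
    homolog: str
    start_idx: int
    end_idx: int
    start_bp: int
    end_bp: int
    state: int

    @property
    def n_snps(self) -> int:
        return self.end_idx - self.start_idx + 1


@dataclass(frozen=True)
class BreakpointInterval:
    """The two SNP flanks bracketing a copy-state transition."""

    chrom: str
    lo: int
    hi: int

    @property
    def midpoint(self) -> float:
        return (self.lo + self.hi) / 2.0


@dataclass(frozen=True)
class EventCall:
    """A classified genomic alteration.

    ``homolog`` is the retained homolog for copy-neutral events (LOH,
    UPD) and the affected homolog for CNV/aneuploidy events.
    """

    type: str
    chrom: str
    start: int
    end: int
    homolog: str
    n_snps: int
    class_code: str = ""
    states: tuple[int, int] = (1, 1)  # (W, Y) inside the region
    bp_left: BreakpointInterval | None = None
    bp_right: BreakpointInterval | None = None
    whole_chromosome: bool = False
    conversion_associated: bool = False
    isolate: str = ""
    event_id: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Fragment:
    """A chromosome fragment implicated in a rearrangement."""

    chrom: str
    start: int
    end: int
    has_centromere: bool

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class TranslocationHypothesis:
    """A monocentric recombined chromosome: centric acceptor + acentric donor."""

    donor: Fragment
    acceptor: Fragment
    supporting: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.donor.has_centromere == self.acceptor.has_centromere:
            raise ValueError("exactly one fragment must carry a centromere")

    @property
    def predicted_size(self) -> int:
        return self.donor.length + self.acceptor.length


@dataclass
class PairingResult:
    """Translocation hypotheses plus terminal CNVs left unexplained."""

    hypotheses: list[TranslocationHypothesis]
    unresolved: list[EventCall]
    rejected: list[str] = field(default_factory=list)

    def __iter__(self):
        return iter(self.hypotheses)

    def __len__(self) -> int:
        return len(self.hypotheses)


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------


def _runs(states: np.ndarray) -> list[tuple[int, int, int]]:
    """Run-length encode: list of (start, end, state), inclusive indices."""
    if len(states) == 0:
        return []
    change = np.flatnonzero(np.diff(states)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change - 1, [len(states) - 1]))
    return [(int(s), int(e), int(states[s])) for s, e in zip(starts, ends)]


def _merge_short_runs(states: np.ndarray, min_snps: int) -> np.ndarray:
    """Merge runs shorter than ``min_snps`` into the longer neighbor
    (left on ties), shortest offender first, until stable."""
    runs = _runs(states)
    while len(runs) > 1:
        lens = [e - s + 1 for s, e, _ in runs]
        short = [k for k, L in enumerate(lens) if L < min_snps]
        if not short:
            break
        k = min(short, key=lambda q: (lens[q], q))
        if k == 0:
            tgt = 1
        elif k == len(runs) - 1:
            tgt = k - 1
        else:
            tgt = k - 1 if lens[k - 1] >= lens[k + 1] else k + 1
        s, e, _ = runs[k]
        runs[k] = (s, e, runs[tgt][2])
        merged: list[tuple[int, int, int]] = []
        for r in runs:  # coalesce equal-state neighbors
            if merged and merged[-1][2] == r[2]:
                merged[-1] = (merged[-1][0], r[1], r[2])
            else:
                merged.append(r)
        runs = merged
    out = states.copy()
    for s, e, st in runs:
        out[s : e + 1] = st
    return out


_STATE_LEVELS = (0.0, 0.5, 1.0, 1.5)  # expected RC of 0/1/2/3 copies


def _confirm_runs(states: np.ndarray, raw: np.ndarray) -> np.ndarray:
    """Reassign any run whose *unsmoothed* RC mean sits closer to an
    adjacent run's level than to its own; kills smoothing-induced noise
    runs while leaving genuine short tracts (raw mean at their level)
    untouched."""
    for _ in range(8):  # converges in one or two passes
        runs = _runs(states)
        if len(runs) <= 1:
            break
        changed = False
        for k, (s, e, st) in enumerate(runs):
            m = float(np.mean(raw[s : e + 1]))
            d_self = abs(m - _STATE_LEVELS[min(st, 3)])
            nb_states = [runs[q][2] for q in (k - 1, k + 1) if 0 <= q < len(runs)]
            d_nb, st_nb = min(
                (abs(m - _STATE_LEVELS[min(q, 3)]), q) for q in nb_states
            )
            if d_nb < d_self:
                states[s : e + 1] = st_nb
                changed = True
        if not changed:
            break
    return states


def _refine_boundaries(states: np.ndarray, raw: np.ndarray, window: int) -> np.ndarray:
    """Re-localise each state transition on the unsmoothed RC by minimal
    absolute misfit within ``window`` SNPs of the smoothed boundary
    (running-median smoothing shifts transitions by up to half a window)."""
    runs = _runs(states)
    if len(runs) <= 1:
        return states
    bounds = [s for s, _, _ in runs[1:]]  # transition = start of each later run
    new_bounds: list[int] = []
    prev = 0
    for b_i, t in enumerate(bounds):
        la = _STATE_LEVELS[min(runs[b_i][2], 3)]
        lb = _STATE_LEVELS[min(runs[b_i + 1][2], 3)]
        lo = max(runs[b_i][0] + 1, t - window, prev + 1)
        hi = min(runs[b_i + 1][1], t + window)
        best = (float("inf"), 0, t)
        for k in range(lo, hi + 1):
            span_l = raw[max(lo - 1, runs[b_i][0]) : k]
            span_r = raw[k : hi + 1]
            cost = float(np.abs(span_l - la).sum() + np.abs(span_r - lb).sum())
            key = (cost, abs(k - t), k)
            if key < best:
                best = key
        new_bounds.append(best[2])
        prev = best[2]
    out = np.empty_like(states)
    edges = [0] + new_bounds + [len(states)]
    for k, (_, _, st) in enumerate(runs):
        out[edges[k] : edges[k + 1]] = st
    return out


def segment_copy_states(
    profile: pd.DataFrame,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    min_snps: int = DEFAULT_MIN_SNPS,
    *,
    raw_profile: pd.DataFrame | None = None,
    refine_window: int = 5,
) -> list[HomologSegment]:
    """Assign per-SNP copy states by thresholds and emit maximal runs.

    The profile must be sorted by chromosome then position (smoothing, if
    wanted, is applied beforehand — see :func:`smooth_profile` or
    :class:`CopyStateModel`).  When the pre-smoothing profile is supplied
    as ``raw_profile``, runs are confirmed against it (a run must fit its
    own RC level better than a neighbor's) and transition boundaries are
    re-localised on it.  Empty chromosomes are simply absent.
    """
    thresholds = tuple(thresholds)
    segments: list[HomologSegment] = []
    raw_by_chrom = (
        {c: g for c, g in raw_profile.groupby("chrom", sort=False)}
        if raw_profile is not None else {}
    )
    for chrom, grp in profile.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        if len(pos) == 0:
            continue
        for homolog, col in zip(HOMOLOGS, ("rc_w", "rc_y")):
            states = np.digitize(grp[col].to_numpy(), thresholds)
            states = _merge_short_runs(states, min_snps)
            if chrom in raw_by_chrom:
                raw = raw_by_chrom[chrom][col].to_numpy()
                states = _confirm_runs(states, raw)
                states = _merge_short_runs(states, min_snps)
                states = _refine_boundaries(states, raw, refine_window)
            for s, e, st in _runs(states):
                segments.append(
                    HomologSegment(
                        chrom=chrom, homolog=homolog,
                        start_idx=s, end_idx=e,
                        start_bp=int(pos[s]), end_bp=int(pos[e]), state=st,
                    )
                )
    return segments


# ---------------------------------------------------------------------------
# Event calling
# ---------------------------------------------------------------------------

def _coalesce_slivers(
    regions: list[tuple[int, int, int]], min_snps: int
) -> list[tuple[int, int, int]]:
    """Merge two identical joint-state regions split by an aberrant run
    shorter than ``min_snps`` (a noise dip inside one long event); the
    heterozygous state (1,1) is never treated as a sliver."""
    changed = True
    while changed:
        changed = False
        out: list[tuple[int, int, int]] = []
        k = 0
        while k < len(regions):
            s, e, st = regions[k]
            if (st != 11 and e - s + 1 < min_snps and out and k + 1 < len(regions)
                    and out[-1][2] == regions[k + 1][2]):
                out[-1] = (out[-1][0], regions[k + 1][1], out[-1][2])
                k += 2
                changed = True
            else:
                out.append((s, e, st))
                k += 1
        regions = out
    return regions


# Joint (W-state, Y-state) -> (type family, recorded homolog) for segmental
# regions; the recorded homolog is retained for copy-neutral, affected
# otherwise.  W = HOMOLOGS[0], Y = HOMOLOGS[1].
_NEUTRAL = {(0, 2): HOMOLOGS[1], (2, 0): HOMOLOGS[0]}  # -> retained
_DELETION = {(0, 1): HOMOLOGS[0], (1, 0): HOMOLOGS[1]}  # -> lost
_DUPLICATION = {(2, 1): HOMOLOGS[0], (1, 2): HOMOLOGS[1]}  # -> gained


def _ambiguity_flanks(
    raw_cols: list[np.ndarray], levels: list[tuple[float, float]],
    boundary: int, lo_lim: int, hi_lim: int, margin: float,
) -> tuple[int, int]:
    """Indices of the last clearly-old and first clearly-new SNP around a
    transition at ``boundary`` (first index of the new state).

    A site is *clearly* in a state when its raw RC fits that state's
    level better than the other's by more than ``margin``, for every
    homolog whose state changes; sites in between are ambiguous and the
    breakpoint interval widens over them.
    """

    def clearly(j: int, new: bool) -> bool:
        for raw, (la, lb) in zip(raw_cols, levels):
            d_old, d_new = abs(raw[j] - la), abs(raw[j] - lb)
            if new and not (d_new < d_old - margin):
                return False
            if not new and not (d_old < d_new - margin):
                return False
        return True

    lo = boundary - 1
    while lo > lo_lim and not clearly(lo, new=False):
        lo -= 1
    hi = boundary
    while hi < hi_lim and not clearly(hi, new=True):
        hi += 1
    return lo, hi


def _breakpoints(
    pos: np.ndarray, i: int, j: int, spec: ChromosomeSpec,
    sw: np.ndarray | None = None, sy: np.ndarray | None = None,
    raw: tuple[np.ndarray, np.ndarray] | None = None,
    margin: float = 0.25,
) -> tuple[BreakpointInterval, BreakpointInterval]:
    n = len(pos)
    if i == 0:
        left = BreakpointInterval(spec.name, 1, int(pos[0]))
    elif raw is not None and sw is not None:
        cols, lev = [], []
        for h_states, h_raw in zip((sw, sy), raw):
            if h_states[i - 1] != h_states[i]:
                cols.append(h_raw)
                lev.append((_STATE_LEVELS[min(h_states[i - 1], 3)],
                            _STATE_LEVELS[min(h_states[i], 3)]))
        lo, hi = _ambiguity_flanks(cols, lev, i, max(0, i - 6), min(n - 1, i + 5), margin) \
            if cols else (i - 1, i)
        left = BreakpointInterval(spec.name, int(pos[lo]), int(pos[hi]))
    else:
        left = BreakpointInterval(spec.name, int(pos[i - 1]), int(pos[i]))
    if j == n - 1:
        right = BreakpointInterval(spec.name, int(pos[n - 1]), spec.length)
    elif raw is not None and sw is not None:
        cols, lev = [], []
        for h_states, h_raw in zip((sw, sy), raw):
            if h_states[j] != h_states[j + 1]:
                cols.append(h_raw)
                lev.append((_STATE_LEVELS[min(h_states[j], 3)],
                            _STATE_LEVELS[min(h_states[j + 1], 3)]))
        lo, hi = _ambiguity_flanks(cols, lev, j + 1, max(0, j - 5), min(n - 1, j + 6), margin) \
            if cols else (j, j + 1)
        right = BreakpointInterval(spec.name, int(pos[lo]), int(pos[hi]))
    else:
        right = BreakpointInterval(spec.name, int(pos[j]), int(pos[j + 1]))
    return left, right


def call_events(
    segments: Sequence[HomologSegment],
    genome: GenomeMap,
    *,
    positions: Mapping[str, np.ndarray] | None = None,
    raw_rc: Mapping[str, tuple[np.ndarray, np.ndarray]] | None = None,
    min_snps: int = DEFAULT_MIN_SNPS,
    aneuploidy_fraction: float = DEFAULT_ANEUPLOIDY_FRACTION,
    b5_gap_snps: int = DEFAULT_B5_GAP_SNPS,
    taxonomy: Mapping[str, str] | None = None,
    isolate: str = "",
) -> list[EventCall]:
    """Map joint homolog copy states to classified event calls.

    ``positions`` optionally supplies the SNP positions underlying the
    segmented profile per chromosome (defaults to the genome map's);
    ``raw_rc`` optionally supplies the pre-smoothing (rc_w, rc_y) arrays
    per chromosome, used to widen breakpoint intervals over sites whose
    state assignment is ambiguous.  Regions of unclassifiable joint state
    shorter than ``min_snps`` SNPs are treated as noise slivers: when
    flanked by two regions of identical joint state the flanks are
    coalesced across the sliver, otherwise the sliver is suppressed.
    Longer unclassifiable regions are reported as UNCLASSIFIED rather
    than dropped.
    """
    by_chrom: dict[str, dict[str, list[HomologSegment]]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, {h: [] for h in HOMOLOGS})[seg.homolog].append(seg)
    calls: list[EventCall] = []
    counter = 0
    for chrom in genome.chrom_names:
        if chrom not in by_chrom:
            continue
        spec = genome.chromosome(chrom)
        pos = (np.asarray(positions[chrom]) if positions is not None
               else genome.snp_positions(chrom))
        n = len(pos)
        state = {h: np.ones(n, dtype=int) for h in HOMOLOGS}
        for h in HOMOLOGS:
            for seg in by_chrom[chrom][h]:
                state[h][seg.start_idx : seg.end_idx + 1] = seg.state
        sw, sy = state[HOMOLOGS[0]], state[HOMOLOGS[1]]
        joint = sw * 10 + sy
        regions = _runs(joint)
        regions = _coalesce_slivers(regions, min_snps)
        raw = raw_rc.get(chrom) if raw_rc is not None else None

        # whole-chromosome call when one aberrant joint state dominates
        tallies: dict[int, int] = {}
        for s, e, st in regions:
            if st != 11:
                tallies[st] = tallies.get(st, 0) + e - s + 1
        whole = None
        for st, cnt in sorted(tallies.items()):
            if cnt >= aneuploidy_fraction * n:
                key = (st // 10, st % 10)
                if key in _NEUTRAL:
                    whole = (UPD, _NEUTRAL[key], key)
                elif key in _DELETION:
                    whole = (MONOSOMY, _DELETION[key], key)
                elif key in _DUPLICATION:
                    whole = (TRISOMY, _DUPLICATION[key], key)
                break
        if whole is not None:
            etype, homolog, key = whole
            bl, br = _breakpoints(pos, 0, n - 1, spec)
            calls.append(EventCall(
                type=etype, chrom=chrom, start=1, end=spec.length, homolog=homolog,
                n_snps=tallies[key[0] * 10 + key[1]], states=key,
                bp_left=bl, bp_right=br, whole_chromosome=True,
                isolate=isolate, event_id=f"ev_{counter}",
            ))
            counter += 1
            continue

        chrom_calls: list[EventCall] = []
        for s, e, st in regions:
            key = (st // 10, st % 10)
            if key == (1, 1):
                continue
            touches_l, touches_r = s == 0, e == n - 1
            n_reg = e - s + 1
            if key in _NEUTRAL:
                homolog = _NEUTRAL[key]
                if touches_l and touches_r:
                    etype = UPD
                elif touches_l or touches_r:
                    etype = TLOH
                else:
                    etype = ILOH
            elif key in _DELETION:
                homolog = _DELETION[key]
                if touches_l and touches_r:
                    etype = MONOSOMY
                elif touches_l or touches_r:
                    etype = TDEL
                else:
                    etype = UNCLASSIFIED
            elif key in _DUPLICATION:
                homolog = _DUPLICATION[key]
                if touches_l and touches_r:
                    etype = TRISOMY
                elif touches_l or touches_r:
                    etype = TDUP
                else:
                    etype = UNCLASSIFIED
            else:
                homolog, etype = HOMOLOGS[0], UNCLASSIFIED
            if etype == UNCLASSIFIED and n_reg < min_snps:
                continue  # boundary sliver between offset W/Y transitions
            bl, br = _breakpoints(pos, s, e, spec, sw, sy, raw)
            start = 1 if touches_l else int(pos[s])
            end = spec.length if touches_r else int(pos[e])
            chrom_calls.append(EventCall(
                type=etype, chrom=chrom, start=start, end=end, homolog=homolog,
                n_snps=n_reg, states=key, bp_left=bl, bp_right=br,
                whole_chromosome=touches_l and touches_r,
                isolate=isolate, event_id=f"ev_{counter}",
            ))
            counter += 1
        chrom_calls = _absorb_conversion_tracts(chrom_calls, pos, b5_gap_snps)
        calls.extend(chrom_calls)
    return [replace(c, class_code=classify_event(c, genome, taxonomy)) for c in calls]


def _absorb_conversion_tracts(
    calls: list[EventCall], pos: np.ndarray, b5_gap_snps: int
) -> list[EventCall]:
    """Merge an interstitial conversion tract lying within ``b5_gap_snps``
    SNPs of a terminal-LOH breakpoint (same retained homolog) into the
    terminal event, flagging it conversion-associated."""
    tlohs = [c for c in calls if c.type == TLOH]
    ilohs = [c for c in calls if c.type == ILOH]
    if not tlohs or not ilohs:
        return calls
    absorbed: set[str] = set()
    out: list[EventCall] = []
    for c in calls:
        if c.type != TLOH:
            if c.event_id not in absorbed:
                out.append(c)
            continue
        mate = None
        for i in ilohs:
            if i.homolog != c.homolog or i.event_id in absorbed:
                continue
            # SNP-index gap between tract and the T-LOH's interior edge
            gap_bp = (c.start - i.end) if i.end < c.start else (i.start - c.end)
            if gap_bp < 0:
                continue
            k = np.searchsorted(pos, [min(i.end, c.end), max(i.start, c.start)])
            gap_snps = int(k[1] - k[0]) - 1
            if 0 <= gap_snps <= b5_gap_snps:
                mate = i
                break
        if mate is None:
            out.append(c)
            continue
        absorbed.add(mate.event_id)
        out.append(replace(
            c,
            start=min(c.start, mate.start), end=max(c.end, mate.end),
            n_snps=c.n_snps + mate.n_snps,
            bp_left=mate.bp_left if mate.start < c.start else c.bp_left,
            bp_right=mate.bp_right if mate.end > c.end else c.bp_right,
            conversion_associated=True,
        ))
    return [c for c in out if c.event_id not in absorbed]


def resolve_breakpoint(
    event: EventCall, profile: pd.DataFrame, side: str = "auto"
) -> BreakpointInterval:
    """Breakpoint interval of an event's within-chromosome transition.

    ``side`` selects the left or right edge; ``"auto"`` picks the
    non-telomeric edge of a terminal event and the left edge otherwise.
    The interval spans the last SNP in the old state and the first SNP in
    the new state; at a chromosome end it clamps to position 1 (or the
    chromosome length).
    """
    pos = profile.loc[profile["chrom"] == event.chrom, "pos"].to_numpy()
    if len(pos) == 0:
        raise ValueError(f"profile has no SNPs on {event.chrom}")
    if side == "auto":
        if event.bp_left is not None and event.bp_left.lo == 1 and event.start <= pos[0]:
            side = "right"
        else:
            side = "left"
    if side == "left":
        i = int(np.searchsorted(pos, event.start, side="left"))
        if i == 0:
            return BreakpointInterval(event.chrom, 1, int(pos[0]))
        return BreakpointInterval(event.chrom, int(pos[i - 1]), int(pos[i]))
    j = int(np.searchsorted(pos, event.end, side="right")) - 1
    if j >= len(pos) - 1:
        hi = event.bp_right.hi if event.bp_right is not None else int(pos[-1])
        return BreakpointInterval(event.chrom, int(pos[-1]), max(hi, int(pos[-1])))
    return BreakpointInterval(event.chrom, int(pos[j]), int(pos[j + 1]))


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

W, Y = HOMOLOGS


def classify_event(
    event: EventCall,
    genome: GenomeMap | None = None,
    taxonomy: Mapping[str, str] | None = None,
) -> str:
    """Class code of an event (A1..D4 taxonomy).

    A1/A2: interstitial LOH retaining Y/W.  B1/B2: simple terminal LOH
    retaining Y/W with the tract confined to one arm; B3/B4: the same but
    with the tract spanning the centromere (i.e. the breakpoint sits on
    the arm opposite the telomere reached); B5: conversion-associated
    terminal LOH.  C1/C2: terminal deletion of W/Y; C3/C4: terminal
    duplication of W/Y.  D1/D2: trisomy via an extra W/Y copy; D3:
    monosomy; D4: uniparental disomy.  ``taxonomy`` remaps the default
    codes (e.g. ``{"B3": "B1"}``).  UNCLASSIFIED events pass through.
    """
    t, h = event.type, event.homolog
    if t == ILOH:
        code = "A1" if h == Y else "A2"
    elif t == TLOH:
        if event.conversion_associated:
            code = "B5"
        else:
            spans = False
            if genome is not None:
                spans = genome.chromosome(event.chrom).contains_centromere(event.start, event.end)
            if not spans:
                code = "B1" if h == Y else "B2"
            else:
                code = "B3" if h == Y else "B4"
    elif t == TDEL:
        code = "C1" if h == W else "C2"
    elif t == TDUP:
        code = "C3" if h == W else "C4"
    elif t == TRISOMY:
        code = "D1" if h == W else "D2"
    elif t == MONOSOMY:
        code = "D3"
    elif t == UPD:
        code = "D4"
    else:
        code = "NA"
    if taxonomy:
        code = taxonomy.get(code, code)
    return code


# ---------------------------------------------------------------------------
# Translocation pairing
# ---------------------------------------------------------------------------


def _fragment_for(event: EventCall, genome: GenomeMap) -> Fragment | None:
    spec = genome.chromosome(event.chrom)
    left_terminal = event.start == 1 or (event.bp_left is not None and event.bp_left.lo == 1)
    right_terminal = event.end >= spec.length or (
        event.bp_right is not None and event.bp_right.hi >= spec.length
    )
    if left_terminal == right_terminal:  # interior or whole-chromosome: not pairable
        return None
    if event.type == TDUP:
        # the duplicated fragment, extended to the telomere it abuts
        lo, hi = (1, event.end) if left_terminal else (event.start, spec.length)
    elif event.type == TDEL:
        # retained complement of the deleted terminal segment
        lo, hi = (event.end + 1, spec.length) if left_terminal else (1, event.start - 1)
        if lo > hi:
            return None
    else:
        return None
    return Fragment(event.chrom, int(lo), int(hi), spec.contains_centromere(int(lo), int(hi)))


def pair_translocations(
    events: Sequence[EventCall], genome: GenomeMap
) -> PairingResult:
    """Pair terminal CNVs of one isolate into translocation hypotheses.

    Terminal duplications pair directly (the duplicated fragments joined);
    terminal deletions pair via their retained complements (the mechanism
    leaves the two retained pieces fused in the sister cell).  A pair is
    emitted only when exactly one fragment carries its centromere; the
    predicted product size is the sum of the fragment lengths.  When
    several pairings are possible the one minimising the total length of
    unexplained (unpaired) fragments wins, ties broken by chromosome
    order.  Unpaired terminal CNVs are reported unresolved.
    """
    chrom_order = {n: i for i, n in enumerate(genome.chrom_names)}
    rejected: list[str] = []
    cand: dict[str, list[tuple[EventCall, Fragment]]] = {TDUP: [], TDEL: []}
    unresolved: list[EventCall] = []
    for ev in events:
        if ev.type not in (TDUP, TDEL):
            continue
        frag = _fragment_for(ev, genome)
        if frag is None:
            unresolved.append(ev)
            continue
        cand[ev.type].append((ev, frag))
    hypotheses: list[TranslocationHypothesis] = []
    for etype in (TDUP, TDEL):
        items = sorted(cand[etype], key=lambda t: (chrom_order[t[1].chrom], t[1].start))
        best: tuple[int, list[tuple[int, int]]] | None = None
        idx = list(range(len(items)))

        def matchings(free: list[int]):
            if len(free) < 2:
                yield []
                return
            a = free[0]
            yield from ([m for m in matchings(free[1:])])
            for b in free[1:]:
                rest = [x for x in free[1:] if x != b]
                for m in matchings(rest):
                    yield [(a, b)] + m

        for m in matchings(idx):
            ok = True
            for a, b in m:
                fa, fb = items[a][1], items[b][1]
                if fa.chrom == fb.chrom or fa.has_centromere == fb.has_centromere:
                    ok = False
                    break
            if not ok:
                continue
            paired = {i for ab in m for i in ab}
            cost = sum(items[i][1].length for i in idx if i not in paired)
            key = (cost, sorted(m))
            if best is None or key < (best[0], best[1]):
                best = (cost, sorted(m))
        pairs = best[1] if best else []
        paired_idx = {i for ab in pairs for i in ab}
        for a, b in pairs:
            fa, fb = items[a][1], items[b][1]
            donor, acceptor = (fa, fb) if fb.has_centromere else (fb, fa)
            hypotheses.append(TranslocationHypothesis(
                donor=donor, acceptor=acceptor,
                supporting=(items[a][0].event_id, items[b][0].event_id),
            ))
        for i in idx:
            if i not in paired_idx:
                unresolved.append(items[i][0])
        # log centromere-constraint rejections among leftover same-category pairs
        for a, b in itertools.combinations(idx, 2):
            fa, fb = items[a][1], items[b][1]
            if fa.chrom != fb.chrom and fa.has_centromere == fb.has_centromere:
                rejected.append(
                    f"{items[a][0].event_id}+{items[b][0].event_id}: "
                    f"{'both' if fa.has_centromere else 'neither'} fragment centric"
                )
    return PairingResult(hypotheses=hypotheses, unresolved=unresolved, rejected=rejected)


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------


class CopyStateModel:
    """Homolog copy-state model for one isolate's RC profile.

    Parameters
    ----------
    profile
        RC profile (``chrom, pos, rc_w, rc_y``) from sequencing depths or
        array ratios, sorted by chromosome then position.
    genome
        The genome map the profile was computed against.
    thresholds, min_snps, smooth_window, aneuploidy_fraction, b5_gap_snps
        Caller tuning; see the module docstring for the semantics.
    """

    def __init__(
        self,
        profile: pd.DataFrame,
        genome: GenomeMap,
        *,
        thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
        min_snps: int = DEFAULT_MIN_SNPS,
        smooth_window: int = 5,
        aneuploidy_fraction: float = DEFAULT_ANEUPLOIDY_FRACTION,
        b5_gap_snps: int = DEFAULT_B5_GAP_SNPS,
        taxonomy: Mapping[str, str] | None = None,
        isolate: str = "",
    ) -> None:
        self.profile = profile
        self.genome = genome
        self.thresholds = tuple(thresholds)
        self.min_snps = int(min_snps)
        self.smooth_window = int(smooth_window)
        self.aneuploidy_fraction = float(aneuploidy_fraction)
        self.b5_gap_snps = int(b5_gap_snps)
        self.taxonomy = dict(taxonomy) if taxonomy else None
        self.isolate = isolate

    @classmethod
    def from_depths(cls, depths: pd.DataFrame, genome: GenomeMap, **kwargs) -> "CopyStateModel":
        from .profiles import compute_rc

        return cls(compute_rc(depths, genome), genome, **kwargs)

    @classmethod
    def from_array(cls, array: pd.DataFrame, genome: GenomeMap, **kwargs) -> "CopyStateModel":
        from .profiles import array_to_copy_signal

        kwargs.setdefault("smooth_window", 1)  # level-called signal is already discrete
        return cls(array_to_copy_signal(array, genome), genome, **kwargs)

    def fit(self) -> "CopyStateResults":
        smoothed = smooth_profile(self.profile, self.smooth_window)
        segments = segment_copy_states(
            smoothed, self.thresholds, self.min_snps,
            raw_profile=self.profile if self.smooth_window > 1 else None,
            refine_window=self.smooth_window,
        )
        positions = {
            chrom: grp["pos"].to_numpy()
            for chrom, grp in smoothed.groupby("chrom", sort=False)
        }
        raw_rc = {
            chrom: (grp["rc_w"].to_numpy(), grp["rc_y"].to_numpy())
            for chrom, grp in self.profile.groupby("chrom", sort=False)
        }
        events = call_events(
            segments, self.genome, positions=positions, raw_rc=raw_rc,
            min_snps=self.min_snps,
            aneuploidy_fraction=self.aneuploidy_fraction,
            b5_gap_snps=self.b5_gap_snps,
            taxonomy=self.taxonomy, isolate=self.isolate,
        )
        return CopyStateResults(self, smoothed, segments, events)


class CopyStateResults:
    """Fitted copy states: segments, classified events, breakpoints."""

    def __init__(
        self,
        model: CopyStateModel,
        smoothed_profile: pd.DataFrame,
        segments: list[HomologSegment],
        events: list[EventCall],
    ) -> None:
        self.model = model
        self.smoothed_profile = smoothed_profile
        self.segments = segments
        self.events = events

    @property
    def n_events(self) -> int:
        return len(self.events)

    def counts_by_type(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for e in self.events:
            out[e.type] = out.get(e.type, 0) + 1
        return out

    def translocations(self) -> PairingResult:
        return pair_translocations(self.events, self.model.genome)

    def to_frame(self) -> pd.DataFrame:
        return events_to_frame(self.events)

    def summary(self) -> str:
        lines = [
            "Homolog copy-state fit",
            f"  isolate:        {self.model.isolate or '-'}",
            f"  SNP sites:      {len(self.model.profile)}",
            f"  thresholds:     {self.model.thresholds}",
            f"  min SNPs/run:   {self.model.min_snps}   smoothing window: {self.model.smooth_window}",
            f"  events called:  {self.n_events}",
        ]
        for t, n in sorted(self.counts_by_type().items()):
            lines.append(f"    {t:<13}{n}")
        if self.events:
            lines.append("  calls:")
            for e in self.events:
                span = f"{e.chrom}:{e.start}-{e.end}"
                lines.append(
                    f"    {e.class_code:<4}{e.type:<13}{span:<26}"
                    f"homolog={e.homolog}  n_snps={e.n_snps}"
                )
        return "\n".join(lines)

    def plot(self, chrom: str, ax=None):
        """RC scatter for one chromosome with event intervals shaded."""
        import matplotlib

        if ax is None:
            matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 2.5))
        grp = self.model.profile[self.model.profile["chrom"] == chrom]
        ax.plot(grp["pos"] / 1e3, grp["rc_w"], ".", ms=2, color="firebrick", label="W")
        ax.plot(grp["pos"] / 1e3, grp["rc_y"], ".", ms=2, color="steelblue", label="Y")
        for e in self.events:
            if e.chrom == chrom:
                ax.axvspan(e.start / 1e3, e.end / 1e3, alpha=0.15, color="gray")
        spec = self.model.genome.chromosome(chrom)
        ax.axvline(spec.centromere_mid / 1e3, color="k", lw=1, ls=":")
        ax.set_xlabel(f"chr {chrom} position (kb)")
        ax.set_ylabel("RC")
        ax.set_ylim(-0.1, 1.6)
        ax.legend(loc="upper right", fontsize=8)
        return ax


# ---------------------------------------------------------------------------
# Tabular IO
# ---------------------------------------------------------------------------

_EVENT_COLS = [
    "isolate", "chrom", "start", "end", "type", "class_code", "homolog",
    "n_snps", "bp_left_lo", "bp_left_hi", "bp_right_lo", "bp_right_hi",
]


def events_to_frame(events: Iterable[EventCall]) -> pd.DataFrame:
    rows = []
    for e in events:
        rows.append({
            "isolate": e.isolate, "chrom": e.chrom, "start": e.start, "end": e.end,
            "type": e.type, "class_code": e.class_code, "homolog": e.homolog,
            "n_snps": e.n_snps,
            "bp_left_lo": e.bp_left.lo if e.bp_left else "",
            "bp_left_hi": e.bp_left.hi if e.bp_left else "",
            "bp_right_lo": e.bp_right.lo if e.bp_right else "",
            "bp_right_hi": e.bp_right.hi if e.bp_right else "",
        })
    return pd.DataFrame(rows, columns=_EVENT_COLS)


def write_events_tsv(events: Iterable[EventCall], path: str | Path) -> None:
    events_to_frame(events).to_csv(path, sep="\t", index=False)


def read_events_tsv(path: str | Path) -> list[EventCall]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "isolate": str}, keep_default_na=False)
    out = []
    for k, r in enumerate(df.itertuples(index=False)):
        bp_l = (BreakpointInterval(str(r.chrom), int(r.bp_left_lo), int(r.bp_left_hi))
                if str(r.bp_left_lo) != "" else None)
        bp_r = (BreakpointInterval(str(r.chrom), int(r.bp_right_lo), int(r.bp_right_hi))
                if str(r.bp_right_lo) != "" else None)
        out.append(EventCall(
            type=r.type, chrom=str(r.chrom), start=int(r.start), end=int(r.end),
            homolog=r.homolog, n_snps=int(r.n_snps), class_code=r.class_code,
            bp_left=bp_l, bp_right=bp_r, isolate=str(r.isolate), event_id=f"ev_{k}",
        ))
    return out


def write_events_bed(events: Iterable[EventCall], path: str | Path) -> None:
    """BED export: 0-based half-open, name = type/class/homolog."""
    with open(path, "w") as fh:
        for e in events:
            fh.write(f"{e.chrom}\t{e.start - 1}\t{e.end}\t{e.type}|{e.class_code}|{e.homolog}\n")


def translocations_to_frame(result: PairingResult) -> pd.DataFrame:
    rows = []
    for h in result.hypotheses:
        rows.append({
            "donor_chrom": h.donor.chrom, "donor_start": h.donor.start,
            "donor_end": h.donor.end,
            "acceptor_chrom": h.acceptor.chrom, "acceptor_start": h.acceptor.start,
            "acceptor_end": h.acceptor.end,
            "predicted_size": h.predicted_size,
            "supporting": ",".join(h.supporting),
        })
    return pd.DataFrame(rows, columns=[
        "donor_chrom", "donor_start", "donor_end",
        "acceptor_chrom", "acceptor_start", "acceptor_end",
        "predicted_size", "supporting",
    ])


def write_translocations_tsv(result: PairingResult, path: str | Path) -> None:
    translocations_to_frame(result).to_csv(path, sep="\t", index=False)
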