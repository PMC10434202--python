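"""Packaged *Saccharomyces cerevisiae* genome fixture and study designs.

Chromosome lengths and centromere coordinates are the real sacCer3/SGD
values (16 chromosomes, 12.07 Mb haploid).  The homolog-specific SNP site
list (~50,000 sites, one per ~240 bp, the density of a W303-1A x YJM789
hybrid) and the Ty/repeat interval list are synthetic: they are generated
deterministically from a fixed seed with realistic density and spacing,
standing in for the hybrid's true site list, which this pipeline never
needs verbatim because all downstream logic depends only on positions.

Also provides the canonical subculture designs of the furfural-exposure
experiment:

* ``furfural_design()`` — 28 isolates x 8 cycles plus 3 isolates x 1
  cycle, two colony formations per cycle (selection plate + purification
  plate), 25 divisions per colony: 11,350 genome-divisions.
* ``control_design()`` — 20 isolates x 20 cycles x 1 colony x 25
  divisions: 10,000 genome-divisions.
* ``sequenced_furfural_design()`` — the 21 sequenced furfural isolates
  (18 x 8 cycles + 3 x 1 cycle): 7,350 genome-divisions; the denominator
  for per-base point-mutation rates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import ChromosomeSpec, CultureDesign, CultureGroup, GenomeMap

__all__ = [
    "yeast_chromosomes",
    "yeast_genome",
    "furfural_design",
    "control_design",
    "sequenced_furfural_design",
    "DEFAULT_N_SNPS",
]

DEFAULT_N_SNPS = 50_000
_FIXTURE_SEED = 94_121  # fixed: the packaged map must be identical across sessions

# sacCer3 (SGD) chromosome lengths and centromere intervals, 1-based inclusive.
_CHROMS: list[tuple[str, int, int, int]] = [
    ("I", 230_218, 151_465, 151_582),
    ("II", 813_184, 238_207, 238_323),
    ("III", 316_620, 114_385, 114_501),
    ("IV", 1_531_933, 449_711, 449_821),
    ("V", 576_874, 151_987, 152_104),
    ("VI", 270_161, 148_510, 148_627),
    ("VII", 1_090_940, 496_920, 497_038),
    ("VIII", 562_643, 105_586, 105_703),
    ("IX", 439_888, 355_629, 355_745),
    ("X", 745_751, 436_307, 436_425),
    ("XI", 666_816, 440_129, 440_246),
    ("XII", 1_078_177, 150_828, 150_947),
    ("XIII", 924_431, 268_031, 268_149),
    ("XIV", 784_333, 628_758, 628_875),
    ("XV", 1_091_291, 326_584, 326_702),
    ("XVI", 948_066, 555_957, 556_073),
]

_TY_LENGTH = 5_900  # full-length Ty element, bp
_TY_PER_MB = 4.0  # ~50 dispersed full-length elements genome-wide


def _synthetic_repeats(rng: np.random.Generator) -> dict[str, tuple[tuple[int, int], ...]]:
    """Synthetic dispersed Ty/repeat intervals, a few per chromosome."""
    out: dict[str, tuple[tuple[int, int], ...]] = {}
    for name, length, cen_lo, cen_hi in _CHROMS:
        n = max(1, int(round(_TY_PER_MB * length / 1e6)))
        starts: list[int] = []
        tries = 0
        while len(starts) < n and tries < 200:
            tries += 1
            s = int(rng.integers(10_000, max(10_001, length - _TY_LENGTH - 10_000)))
            e = s + _TY_LENGTH - 1
            if s <= cen_hi and e >= cen_lo:  # keep centromeres repeat-free
                continue
            if any(abs(s - s0) < 3 * _TY_LENGTH for s0 in starts):
                continue
            starts.append(s)
        out[name] = tuple(sorted((s, s + _TY_LENGTH - 1) for s in starts))
    return out


def yeast_chromosomes(with_repeats: bool = True) -> list[ChromosomeSpec]:
    """The 16 sacCer3 chromosomes, optionally with synthetic repeat intervals."""
    rng = np.random.default_rng(_FIXTURE_SEED)
    repeats = _synthetic_repeats(rng) if with_repeats else {}
    return [
        ChromosomeSpec(name=n, length=L, centromere=(lo, hi), repeats=repeats.get(n, ()))
        for n, L, lo, hi in _CHROMS
    ]


def yeast_genome(
    n_snps: int = DEFAULT_N_SNPS,
    seed: int = _FIXTURE_SEED,
    exclude_repeats: bool = True,
) -> GenomeMap:
    """Packaged hybrid-diploid genome map with a synthetic SNP site list.

    SNP sites are placed uniformly along each chromosome (count
    proportional to length), by default avoiding repeat intervals, and
    tagged with distinct W/Y alleles.  Deterministic for a given
    ``(n_snps, seed)``; the default (~50,000 sites) matches the SNP
    density of the study strain.
    """
    if n_snps <= 0:
        raise ValueError("n_snps must be positive")
    chroms = yeast_chromosomes()
    rng = np.random.default_rng(seed)
    haploid = sum(c.length for c in chroms)
    bases = np.array(list("ACGT"))
    frames = []
    for c in chroms:
        n_c = max(4, int(round(n_snps * c.length / haploid)))
        pos = np.sort(rng.choice(np.arange(1, c.length + 1), size=min(n_c, c.length), replace=False))
        if exclude_repeats and c.repeats:
            mask = np.ones(len(pos), dtype=bool)
            for lo, hi in c.repeats:
                mask &= ~((pos >= lo) & (pos <= hi))
            pos = pos[mask]
        w_idx = rng.integers(0, 4, size=len(pos))
        shift = rng.integers(1, 4, size=len(pos))
        y_idx = (w_idx + shift) % 4
        frames.append(
            pd.DataFrame(
                {
                    "chrom": c.name,
                    "pos": pos.astype(int),
                    "w_allele": bases[w_idx],
                    "y_allele": bases[y_idx],
                }
            )
        )
    snps = pd.concat(frames, ignore_index=True)
    return GenomeMap(chromosomes=chroms, snps=snps)


def furfural_design() -> CultureDesign:
    """Furfural subculture arm: 11,350 genome-divisions.

    Each cycle on a furfural plate is followed by a purification colony on
    a plain plate, i.e. two colony formations (50 divisions) per cycle.
    """
    return CultureDesign(
        groups=(
            CultureGroup(n_isolates=28, cycles=8, colonies_per_cycle=2, divisions_per_colony=25),
            CultureGroup(n_isolates=3, cycles=1, colonies_per_cycle=2, divisions_per_colony=25),
        )
    )


def control_design() -> CultureDesign:
    """Untreated serial-transfer arm: 20 isolates x 500 divisions = 10,000."""
    return CultureDesign(
        groups=(CultureGroup(n_isolates=20, cycles=20, colonies_per_cycle=1, divisions_per_colony=25),)
    )


def sequenced_furfural_design() -> CultureDesign:
    """The 21 whole-genome-sequenced furfural isolates: 7,350 divisions."""
    return CultureDesign(
        groups=(
            CultureGroup(n_isolates=18, cycles=8, colonies_per_cycle=2, divisions_per_colony=25),
            CultureGroup(n_isolates=3, cycles=1, colonies_per_cycle=2, divisions_per_colony=25),
        )
    )
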