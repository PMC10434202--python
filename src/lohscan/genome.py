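"""Data model for a hybrid diploid genome and the subculture experiment design.

A hybrid diploid carries two distinguishable homologs of every chromosome
(here labelled ``W`` and ``Y`` after the two parental backgrounds of the
W303-1A x YJM789 cross).  Tens of thousands of single-nucleotide
polymorphisms distinguish the homologs, so homolog-specific read depth at
those sites resolves the copy number of each homolog along every
chromosome.  This module holds the static genome description (chromosome
lengths, centromeres, repeat intervals, the homolog-specific SNP site
list) and the division-accounting model that converts a serial-subculture
design into a total number of genome-divisions, the denominator of every
event-rate estimate.

Coordinates are 1-based inclusive throughout (SGD convention); BED export
converts to 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

HOMOLOGS = ("W", "Y")

__all__ = [
    "HOMOLOGS",
    "ChromosomeSpec",
    "GenomeMap",
    "CultureGroup",
    "CultureDesign",
    "total_divisions",
    "load_genome_map",
    "write_genome_map",
    "load_culture_design",
    "write_culture_design",
]


class GenomeMapError(ValueError):
    """Raised for malformed or inconsistent genome-map inputs."""


@dataclass(frozen=True)
class ChromosomeSpec:
    """One chromosome: length, centromere interval and repeat intervals.

    Intervals are 1-based inclusive ``(start, end)`` tuples.  Exactly one
    centromere per chromosome; repeat intervals mark Ty/repeat elements
    that are excluded from coverage normalisation.
    """

    name: str
    length: int
    centromere: tuple[int, int]
    repeats: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise GenomeMapError(f"{self.name}: non-positive length {self.length}")
        lo, hi = self.centromere
        if not (1 <= lo <= hi <= self.length):
            raise GenomeMapError(
                f"{self.name}: centromere {self.centromere} outside [1, {self.length}]"
            )
        for r in self.repeats:
            if not (1 <= r[0] <= r[1] <= self.length):
                raise GenomeMapError(f"{self.name}: repeat {r} outside chromosome bounds")

    @property
    def centromere_mid(self) -> float:
        return (self.centromere[0] + self.centromere[1]) / 2.0

    def contains_centromere(self, start: int, end: int) -> bool:
        """True if the 1-based inclusive interval covers the centromere midpoint."""
        return start <= self.centromere_mid <= end


@dataclass
class GenomeMap:
    """Chromosome set plus the homolog-specific SNP site list.

    ``snps`` is a DataFrame with columns ``chrom, pos, w_allele, y_allele,
    in_repeat`` sorted by chromosome (map order) then position; positions
    are strictly increasing within a chromosome.
    """

    chromosomes: list[ChromosomeSpec]
    snps: pd.DataFrame
    homologs: tuple[str, str] = HOMOLOGS

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise GenomeMapError("duplicate chromosome names")
        required = {"chrom", "pos", "w_allele", "y_allele"}
        missing = required - set(self.snps.columns)
        if missing:
            raise GenomeMapError(f"SNP table missing columns: {sorted(missing)}")
        unknown = set(self.snps["chrom"]) - set(names)
        if unknown:
            raise GenomeMapError(f"SNP table references unknown chromosomes: {sorted(unknown)}")
        order = {n: i for i, n in enumerate(names)}
        snps = self.snps.copy()
        snps["_ord"] = snps["chrom"].map(order)
        snps = snps.sort_values(["_ord", "pos"]).drop(columns="_ord").reset_index(drop=True)
        for chrom, grp in snps.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if len(pos) and not (np.all(np.diff(pos) > 0)):
                raise GenomeMapError(f"{chrom}: SNP positions not strictly increasing")
            spec = self.chromosome(chrom)
            if len(pos) and (pos[0] < 1 or pos[-1] > spec.length):
                raise GenomeMapError(f"{chrom}: SNP positions outside [1, {spec.length}]")
        if "in_repeat" not in snps.columns:
            snps["in_repeat"] = self._flag_repeats(snps)
        self.snps = snps

    def _flag_repeats(self, snps: pd.DataFrame) -> np.ndarray:
        flag = np.zeros(len(snps), dtype=bool)
        for chrom, grp in snps.groupby("chrom", sort=False):
            spec = self.chromosome(chrom)
            if not spec.repeats:
                continue
            pos = grp["pos"].to_numpy()
            m = np.zeros(len(pos), dtype=bool)
            for lo, hi in spec.repeats:
                m |= (pos >= lo) & (pos <= hi)
            flag[grp.index] = m
        return flag

    # -- basic queries -------------------------------------------------
    def chromosome(self, name: str) -> ChromosomeSpec:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def chrom_names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    @property
    def haploid_size(self) -> int:
        return int(sum(c.length for c in self.chromosomes))

    @property
    def diploid_size(self) -> int:
        return 2 * self.haploid_size

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def snp_positions(self, chrom: str) -> np.ndarray:
        return self.snps.loc[self.snps["chrom"] == chrom, "pos"].to_numpy()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<GenomeMap {len(self.chromosomes)} chromosomes, "
            f"{self.n_snps} SNPs, haploid {self.haploid_size/1e6:.2f} Mb>"
        )


# ---------------------------------------------------------------------------
# Culture design / division accounting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CultureGroup:
    """One arm of the subculture design.

    ``divisions_per_colony`` defaults to 25, the canonical number of cell
    divisions needed to grow a visible colony from a single yeast cell.
    ``colonies_per_cycle`` counts colony formations per subculture cycle:
    a plain serial transfer is 1; a selection plating followed by a
    purification plating is 2.
    """

    n_isolates: int
    cycles: int
    colonies_per_cycle: int = 1
    divisions_per_colony: int = 25

    def __post_init__(self) -> None:
        for name in ("n_isolates", "cycles", "colonies_per_cycle", "divisions_per_colony"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise ValueError(f"CultureGroup.{name} must be a positive integer, got {v!r}")

    @property
    def divisions_per_isolate(self) -> int:
        return self.cycles * self.colonies_per_cycle * self.divisions_per_colony

    @property
    def total_divisions(self) -> int:
        return self.n_isolates * self.divisions_per_isolate


@dataclass(frozen=True)
class CultureDesign:
    """A set of culture groups; total divisions sum over groups."""

    groups: tuple[CultureGroup, ...]

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("CultureDesign needs at least one group")

    @property
    def n_isolates(self) -> int:
        return sum(g.n_isolates for g in self.groups)

    @property
    def total_divisions(self) -> int:
        return sum(g.total_divisions for g in self.groups)


def total_divisions(design: CultureDesign | CultureGroup) -> int:
    """Total genome-divisions of a subculture design.

    Sum over groups of ``n_isolates * cycles * colonies_per_cycle *
    divisions_per_colony``.
    """
    return int(design.total_divisions)


# ---------------------------------------------------------------------------
# File IO
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path, columns: Sequence[str], what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise GenomeMapError(f"{path}: cannot parse {what} table: {exc}") from exc
    missing = set(columns) - set(df.columns)
    if missing:
        raise GenomeMapError(f"{path}: {what} table missing columns {sorted(missing)}")
    for i, row in enumerate(df.itertuples(index=False), start=2):
        for col in columns:
            if pd.isna(getattr(row, col)):
                raise GenomeMapError(f"{path}: line {i}: missing value in column {col!r}")
    return df


def load_genome_map(
    chrom_path: str | Path,
    snp_path: str | Path,
    repeats_path: str | Path | None = None,
) -> GenomeMap:
    """Load a genome map from its on-disk representation.

    ``chrom_path``: TSV with columns chrom, length, cen_start, cen_end.
    ``snp_path``: TSV with columns chrom, pos, w_allele, y_allele.
    ``repeats_path``: optional BED (chrom, start, end[, name]), 0-based
    half-open, converted to 1-based inclusive intervals.
    """
    chroms_df = _read_tsv(chrom_path, ["chrom", "length", "cen_start", "cen_end"], "chromosome")
    if chroms_df["chrom"].duplicated().any():
        dup = chroms_df.loc[chroms_df["chrom"].duplicated(), "chrom"].tolist()
        raise GenomeMapError(f"{chrom_path}: overlapping centromere definitions for {dup}")
    repeats: dict[str, list[tuple[int, int]]] = {}
    if repeats_path is not None:
        bed = pd.read_csv(
            repeats_path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "name"], usecols=[0, 1, 2, 3],
            dtype={0: str},
        )
        for row in bed.itertuples(index=False):
            repeats.setdefault(str(row.chrom), []).append((int(row.start) + 1, int(row.end)))
    specs = [
        ChromosomeSpec(
            name=str(r.chrom),
            length=int(r.length),
            centromere=(int(r.cen_start), int(r.cen_end)),
            repeats=tuple(repeats.get(str(r.chrom), ())),
        )
        for r in chroms_df.itertuples(index=False)
    ]
    snps = _read_tsv(snp_path, ["chrom", "pos", "w_allele", "y_allele"], "SNP")
    snps["pos"] = snps["pos"].astype(int)
    return GenomeMap(chromosomes=specs, snps=snps)


def write_genome_map(
    genome: GenomeMap,
    chrom_path: str | Path,
    snp_path: str | Path,
    repeats_path: str | Path | None = None,
) -> None:
    """Write a genome map back to TSV/BED; inverse of :func:`load_genome_map`."""
    chrom_rows = [
        {"chrom": c.name, "length": c.length, "cen_start": c.centromere[0], "cen_end": c.centromere[1]}
        for c in genome.chromosomes
    ]
    pd.DataFrame(chrom_rows).to_csv(chrom_path, sep="\t", index=False)
    genome.snps[["chrom", "pos", "w_allele", "y_allele"]].to_csv(snp_path, sep="\t", index=False)
    if repeats_path is not None:
        rows = []
        for c in genome.chromosomes:
            for i, (lo, hi) in enumerate(c.repeats):
                rows.append({"chrom": c.name, "start": lo - 1, "end": hi, "name": f"repeat_{c.name}_{i}"})
        pd.DataFrame(rows, columns=["chrom", "start", "end", "name"]).to_csv(
            repeats_path, sep="\t", index=False, header=False
        )


def load_culture_design(path: str | Path) -> CultureDesign:
    """Load a culture design from YAML: a list of group mappings."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if isinstance(data, dict) and "groups" in data:
        data = data["groups"]
    if not isinstance(data, list):
        raise ValueError(f"{path}: expected a list of culture groups")
    groups = tuple(CultureGroup(**{k: int(v) for k, v in g.items()}) for g in data)
    return CultureDesign(groups=groups)


def write_culture_design(design: CultureDesign, path: str | Path) -> None:
    data = {
        "groups": [
            {
                "n_isolates": g.n_isolates,
                "cycles": g.cycles,
                "colonies_per_cycle": g.colonies_per_cycle,
                "divisions_per_colony": g.divisions_per_colony,
            }
            for g in design.groups
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
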