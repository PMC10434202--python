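"""Relative-coverage (RC) profiles from allele depths or array ratios.

The central statistic: the read depth of each homolog-specific SNP is
divided by the genome-wide mean per-SNP coverage over SNPs outside
repeat intervals, on a scale where one homolog copy maps to RC 0.5.
Concretely the normalizer is the mean per-SNP *total* coverage
(``w_depth + y_depth``) over nonrepeat sites, so RC 0 / 0.5 / 1
corresponds to 0 / 1 / 2 copies of a homolog.  Microarray hybridization ratios (levels ~0.2 / 1.0 / 1.5 for
0 / 1 / 2 copies) are mapped onto the same scale so one caller serves
both platforms.

An RC profile is a DataFrame with columns ``chrom, pos, rc_w, rc_y`` (and
``in_repeat``); the normalizer is carried in ``profile.attrs``.
Repeat-overlapping SNPs stay in the profile but never enter the
normalizer.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genome import HOMOLOGS, GenomeMap

__all__ = [
    "compute_rc",
    "array_to_copy_signal",
    "smooth_profile",
    "read_depth_table",
    "read_depth_tsv",
    "read_depth_vcf",
    "write_rc_profile",
    "read_rc_profile",
]


class NormalizationError(ValueError):
    """No usable SNPs outside repeats, or zero mean coverage."""


DEPTH_COLUMNS = ["chrom", "pos", "w_depth", "y_depth"]


def compute_rc(depths: pd.DataFrame, genome: GenomeMap, robust: bool = True) -> pd.DataFrame:
    """Per-SNP relative coverage per homolog.

    Parameters
    ----------
    depths
        Allele-depth table with columns ``chrom, pos, w_depth, y_depth``;
        one row per heterozygous SNP site of one isolate.
    genome
        Genome map supplying the repeat annotation.
    robust
        Use the median (default) rather than the mean per-SNP total
        coverage as the normalizer.  The two coincide on a euploid
        genome, but the median keeps the RC scale anchored at 0/0.5/1
        even when a sizeable fraction of the genome (up to half) is
        monosomic or trisomic, where the genome-wide mean drifts and
        drags every RC value with it.

    Returns
    -------
    DataFrame with ``rc_w = w_depth / normalizer`` and likewise for Y,
    the normalizer being the median (or mean) per-SNP total coverage
    (``w_depth + y_depth``) over SNPs outside repeat intervals.  On this
    scale a 1-copy homolog sits at RC 0.5 and a fully heterozygous
    diploid satisfies ``mean(rc_w + rc_y) = 1`` exactly.  The normalizer
    is stored in ``.attrs["normalizer"]``.
    """
    missing = set(DEPTH_COLUMNS) - set(depths.columns)
    if missing:
        raise ValueError(f"depth table missing columns {sorted(missing)}")
    if (depths[["w_depth", "y_depth"]].to_numpy() < 0).any():
        raise ValueError("negative depths")
    df = depths.merge(
        genome.snps[["chrom", "pos", "in_repeat"]], on=["chrom", "pos"], how="left"
    )
    if df["in_repeat"].isna().any():
        bad = df.loc[df["in_repeat"].isna(), ["chrom", "pos"]].head(3)
        raise ValueError(f"depth table has sites absent from the SNP map, e.g.\n{bad}")
    nonrep = ~df["in_repeat"].astype(bool)
    if not nonrep.any():
        raise NormalizationError("all SNPs fall in repeat intervals; cannot normalize")
    total = df.loc[nonrep, "w_depth"] + df.loc[nonrep, "y_depth"]
    normalizer = float(total.median() if robust else total.mean())
    if normalizer <= 0:
        raise NormalizationError("zero mean coverage over nonrepeat SNPs")
    out = df[["chrom", "pos"]].copy()
    out["rc_w"] = df["w_depth"] / normalizer
    out["rc_y"] = df["y_depth"] / normalizer
    out["in_repeat"] = df["in_repeat"].astype(bool)
    out.attrs["normalizer"] = normalizer
    return out


# Midpoints between the array levels 0.2 / 1.0 / 1.5.
_ARRAY_THRESHOLDS = (0.6, 1.25)
_ARRAY_RC = (0.0, 0.5, 1.0)


def array_to_copy_signal(array: pd.DataFrame, genome: GenomeMap | None = None) -> pd.DataFrame:
    """Map hybridization ratios to the RC scale by nearest-level assignment.

    Input is long format (``chrom, pos, homolog, hyb_ratio``).  Ratios
    below 0.6 map to RC 0.0 (0 copies), below 1.25 to 0.5 (1 copy), and
    1.25 or above to 1.0 (2 copies); ties at a threshold round up.  The
    raw ratios are retained as ``hr_w``/``hr_y`` for segmentation
    diagnostics.
    """
    required = {"chrom", "pos", "homolog", "hyb_ratio"}
    missing = required - set(array.columns)
    if missing:
        raise ValueError(f"array table missing columns {sorted(missing)}")
    unknown = set(array["homolog"]) - set(HOMOLOGS)
    if unknown:
        raise ValueError(f"unknown homolog labels {sorted(unknown)}; expected {HOMOLOGS}")
    sig = np.asarray(_ARRAY_RC)[np.digitize(array["hyb_ratio"], _ARRAY_THRESHOLDS)]
    tmp = array[["chrom", "pos", "homolog"]].copy()
    tmp["rc"] = sig
    tmp["hr"] = array["hyb_ratio"].to_numpy()
    wide = tmp.pivot_table(index=["chrom", "pos"], columns="homolog",
                           values=["rc", "hr"], aggfunc="first")
    out = pd.DataFrame({
        "chrom": [c for c, _ in wide.index],
        "pos": [p for _, p in wide.index],
        "rc_w": wide[("rc", HOMOLOGS[0])].to_numpy(),
        "rc_y": wide[("rc", HOMOLOGS[1])].to_numpy(),
        "hr_w": wide[("hr", HOMOLOGS[0])].to_numpy(),
        "hr_y": wide[("hr", HOMOLOGS[1])].to_numpy(),
    })
    if genome is not None:
        order = {n: i for i, n in enumerate(genome.chrom_names)}
        out = (out.assign(_o=out["chrom"].map(order))
                  .sort_values(["_o", "pos"]).drop(columns="_o").reset_index(drop=True))
    else:
        out = out.sort_values(["chrom", "pos"]).reset_index(drop=True)
    out["in_repeat"] = False
    out.attrs["normalizer"] = float("nan")
    return out


def smooth_profile(profile: pd.DataFrame, window: int) -> pd.DataFrame:
    """Running median of RC over ``window`` consecutive SNPs per homolog,
    within each chromosome; ends use shrunken windows.  Window must be odd
    (1 = identity).  Median, not mean: robust to isolated mismapped sites."""
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    out = profile.copy()
    if window == 1:
        return out
    for col in ("rc_w", "rc_y"):
        out[col] = (
            profile.groupby("chrom", sort=False)[col]
            .transform(lambda s: s.rolling(window, center=True, min_periods=1).median())
        )
    out.attrs.update(profile.attrs)
    return out


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def read_depth_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(DEPTH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df["pos"] = df["pos"].astype(int)
    return df[DEPTH_COLUMNS]


def read_depth_vcf(path: str | Path, genome: GenomeMap, sample: int = 0) -> pd.DataFrame:
    """Allele depths from a VCF by matching REF/ALT against the SNP map's
    W/Y alleles.

    Uses the per-sample AD (allele depth) field; a site whose REF matches
    the W allele contributes AD[0] to ``w_depth`` and AD[1] to
    ``y_depth``, and vice versa.  Sites absent from the SNP map or with
    alleles matching neither orientation are skipped.
    """
    from cyvcf2 import VCF  # deferred: optional at runtime for TSV-only use

    lookup = {
        (r.chrom, int(r.pos)): (str(r.w_allele), str(r.y_allele))
        for r in genome.snps.itertuples(index=False)
    }
    rows = []
    for v in VCF(str(path)):
        key = (v.CHROM, int(v.POS))
        if key not in lookup or not v.ALT:
            continue
        w_al, y_al = lookup[key]
        ad = v.format("AD")
        if ad is None:
            continue
        ref_d, alt_d = int(ad[sample][0]), int(ad[sample][1])
        if v.REF == w_al and v.ALT[0] == y_al:
            rows.append((v.CHROM, v.POS, ref_d, alt_d))
        elif v.REF == y_al and v.ALT[0] == w_al:
            rows.append((v.CHROM, v.POS, alt_d, ref_d))
    return pd.DataFrame(rows, columns=DEPTH_COLUMNS)


def read_depth_table(path: str | Path, genome: GenomeMap | None = None) -> pd.DataFrame:
    """Dispatch on extension: ``.vcf``/``.vcf.gz`` needs a genome map,
    anything else is read as TSV."""
    p = str(path)
    if p.endswith((".vcf", ".vcf.gz")):
        if genome is None:
            raise ValueError("reading VCF allele depths requires a genome map")
        return read_depth_vcf(path, genome)
    return read_depth_tsv(path)


def write_rc_profile(profile: pd.DataFrame, path: str | Path) -> None:
    profile[["chrom", "pos", "rc_w", "rc_y"]].to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def read_rc_profile(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    df["pos"] = df["pos"].astype(int)
    if "in_repeat" not in df.columns:
        df["in_repeat"] = False
    return df
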