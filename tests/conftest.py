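import numpy as np
import pandas as pd
import pytest

import lohscan as ls


@pytest.fixture(scope="session")
def yeast():
    """Packaged yeast genome at reduced SNP density (fast, same topology)."""
    return ls.yeast_genome(n_snps=8000)


@pytest.fixture(scope="session")
def yeast_full():
    """Packaged yeast genome at the study's full ~50k SNP density."""
    return ls.yeast_genome()


@pytest.fixture()
def toy_genome():
    """One 100-kb chromosome with a SNP every 1 kb and a central repeat."""
    chrom = ls.ChromosomeSpec(
        name="I", length=100_000, centromere=(45_000, 46_000),
        repeats=((70_000, 75_000),),
    )
    pos = np.arange(1_000, 100_000, 1_000)
    snps = pd.DataFrame({
        "chrom": "I", "pos": pos,
        "w_allele": "A", "y_allele": "G",
    })
    return ls.GenomeMap(chromosomes=[chrom], snps=snps)


def exact_depths(karyotype: ls.Karyotype, depth: float = 50.0) -> pd.DataFrame:
    """Noiseless allele depths: exactly the Poisson means."""
    cn = karyotype.copy_numbers()
    out = cn[["chrom", "pos"]].copy()
    out["w_depth"] = depth * cn["cn_w"] / 2.0
    out["y_depth"] = depth * cn["cn_y"] / 2.0
    return out


@pytest.fixture()
def exact_depths_fn():
    return exact_depths
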