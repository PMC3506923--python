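import numpy as np
import pandas as pd
import pytest

from tenderqtl.genotypes import GenotypeMatrix
from tenderqtl.simulate import SimConfig, simulate_cohort


def make_genotypes(codes, chrom=None, pos=None, sex=None, breed=None,
                   unique=None, sire=None):
    """Small GenotypeMatrix from a raw A-allele-count array."""
    codes = np.asarray(codes, dtype=np.int8)
    n, m = codes.shape
    chrom = ["1"] * m if chrom is None else list(chrom)
    pos = list(range(1000, 1000 + 1000 * m, 1000)) if pos is None else list(pos)
    snp_map = pd.DataFrame({
        "snp_id": [f"s{j}" for j in range(m)],
        "chrom": chrom, "pos": pos,
        "unique": [True] * m if unique is None else list(unique),
    })
    return GenotypeMatrix(
        animal_ids=np.array([f"a{i}" for i in range(n)], dtype=object),
        snp_ids=snp_map["snp_id"].to_numpy(dtype=object),
        codes=codes,
        sex=np.array(["M"] * n if sex is None else sex, dtype=object),
        breed=np.array(["B1"] * n if breed is None else breed, dtype=object),
        sire=None if sire is None else np.array(sire, dtype=object),
        snp_map=snp_map,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """One-breed half-sib cohort reused across tests (n=400, complete)."""
    cfg = SimConfig(
        n_breeds=1, sires_per_breed=10, progeny_per_sire=40,
        n_snps=800, n_x_snps=60, dense_regions=(), qtl_spec=(),
        h2_per_breed=(0.4,), var_a_per_breed=(0.4,),
        founder_haplotypes=40, pool_generations=10,
        missing_rate=0.0, cg_sd=0.3, seed=11,
    )
    return simulate_cohort(cfg)
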