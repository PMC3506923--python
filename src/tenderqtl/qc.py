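"""SNP and animal quality-control filters.

The SNP filter keeps markers that (a) map uniquely to an autosome or
the X, (b) have call rate strictly above the threshold, and (c) have a
minor allele frequency strictly above the threshold within every breed.
Animals are kept when their genotype call rate is at or above the
animal threshold (the exclusion rule is "< threshold"). The SNP filter
is applied first, over all genotyped animals; the animal filter then
uses the retained SNPs. One pass only: re-running on filtered output is
a no-op.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, VALID_CHROMS

SNP_CALL_RATE_MIN = 0.89
ANIMAL_CALL_RATE_MIN = 0.85
MAF_MIN = 0.01


def filter_snps(g: GenotypeMatrix, call_rate_min: float = SNP_CALL_RATE_MIN,
                maf_min: float = MAF_MIN):
    """Return (retained SNP ids, exclusion log).

    The exclusion log is a DataFrame (snp_id, reason) recording the
    first failing rule per dropped SNP, checked in the order
    non_unique -> call_rate -> maf.
    """
    breeds = pd.unique(g.breed)
    for b in breeds:
        if (g.breed == b).sum() == 0:
            raise ValueError(f"breed {b} has no animals; MAF undefined")
    if len(breeds) == 0:
        raise ValueError("no animals; MAF undefined")

    unique_ok = (g.snp_map["unique"].to_numpy().astype(bool)
                 & g.snp_map["chrom"].isin(VALID_CHROMS).to_numpy())
    call_ok = g.snp_call_rate() > call_rate_min
    maf_ok = np.ones(g.n_snps, dtype=bool)
    for b in breeds:
        maf = g.minor_allele_freq(animal_mask=(g.breed == b))
        maf_ok &= np.nan_to_num(maf, nan=0.0) > maf_min

    reason = np.full(g.n_snps, "", dtype=object)
    reason[~maf_ok] = "maf"
    reason[~call_ok] = "call_rate"
    reason[~unique_ok] = "non_unique"
    dropped = reason != ""
    log = pd.DataFrame({"snp_id": g.snp_ids[dropped], "reason": reason[dropped]})
    return list(g.snp_ids[~dropped]), log


def filter_animals(g: GenotypeMatrix,
                   call_rate_min: float = ANIMAL_CALL_RATE_MIN):
    """Return ids of animals whose call rate is >= ``call_rate_min``."""
    keep = g.animal_call_rate() >= call_rate_min
    return list(g.animal_ids[keep])


def apply_qc(g: GenotypeMatrix, snp_call_rate_min: float = SNP_CALL_RATE_MIN,
             animal_call_rate_min: float = ANIMAL_CALL_RATE_MIN,
             maf_min: float = MAF_MIN):
    """SNP filter then animal filter; returns (filtered matrix, log dict)."""
    snps, snp_log = filter_snps(g, snp_call_rate_min, maf_min)
    g1 = g.subset(snp_ids=snps)
    if g1.n_snps == 0:
        g2 = g1   # animal call rate undefined with no SNPs
    else:
        animals = filter_animals(g1, animal_call_rate_min)
        g2 = g1.subset(animal_ids=animals)
    log = {
        "snps_in": g.n_snps, "snps_out": g2.n_snps,
        "animals_in": g.n_animals, "animals_out": g2.n_animals,
        "snp_exclusions": snp_log,
    }
    return g2, log
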