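"""Marker incidence matrix and genomic relationship matrix (GRM).

The marker matrix M codes each genotype as a deviation from its allele
frequency expectation: column i takes the values 2q_i, q_i - p_i and
-2p_i for diploid AA, AB and BB genotypes, and q_i and -p_i for the
hemizygous male-X AY and BY genotypes (p_i is the A-allele frequency,
q_i = 1 - p_i). The realized relationship matrix is the first VanRaden
form

    G = M M' / c,        c = 2 * sum_i p_i q_i,

with c summed over every SNP in the analysis. How X-linked loci enter
c is a convention the original description leaves open: the default
weights them like autosomes (2*p*q); ``x_half_weight=True`` uses p*q
instead. G from near-duplicate genotypes can be singular, so a blended
regularization (1-eps)G + eps*I is available for the back-solve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotypes import GenotypeMatrix, is_x_linked


@dataclass
class MarkerDesign:
    """Centered marker codes M with the frequencies and scale used to build them."""

    M: np.ndarray              # (n_animals, n_snps) float64
    p: np.ndarray              # A-allele frequency per SNP
    c: float                   # 2 * sum p*q (X weight per convention)
    snp_ids: np.ndarray
    animal_ids: np.ndarray


@dataclass
class Grm:
    G: np.ndarray
    c: float
    epsilon: float = 0.0       # identity blend actually applied
    animal_ids: np.ndarray | None = None

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.G)[0])


def code_genotype(genotype: str, p: float, sex: str, chrom_class: str) -> float:
    """Code one genotype call as its centered marker value.

    ``chrom_class`` is "autosome", "X" or "XP" (pseudoautosomal, coded
    as diploid). Missing genotypes are rejected: imputation must precede
    coding.
    """
    if not 0 < p < 1:
        raise ValueError("allele frequency must be in (0, 1)")
    q = 1.0 - p
    hemizygous = chrom_class == "X" and sex == "M"
    if genotype in ("AY", "BY"):
        if not hemizygous:
            raise ValueError(f"{genotype} only valid for males on the X")
        return q if genotype == "AY" else -p
    if genotype in ("NA", None, ""):
        raise ValueError("missing genotype: impute before coding")
    if hemizygous:
        raise ValueError("male X cells must carry AY/BY codes")
    try:
        return {"AA": 2 * q, "AB": q - p, "BB": -2 * p}[genotype]
    except KeyError:
        raise ValueError(f"unknown genotype code {genotype!r}") from None


def marker_design(g: GenotypeMatrix, freqs: np.ndarray | None = None,
                  x_half_weight: bool = False) -> MarkerDesign:
    """Build M and the scaling constant c from a complete genotype matrix.

    Frequencies default to in-sample estimates over the analysis
    animals, so within-breed runs automatically use within-breed
    frequencies and the across-breed run pooled ones.
    """
    if g.missing_mask().any():
        raise ValueError("missing genotypes present: impute before building M")
    p = g.allele_freq() if freqs is None else np.asarray(freqs, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        bad = g.snp_ids[(p <= 0) | (p >= 1)]
        raise ValueError(
            f"monomorphic SNPs in analysis set (e.g. {bad[:3]}); run filter_snps")
    ploidy = g.ploidy().astype(np.float64)
    M = g.codes.astype(np.float64) - ploidy * p[None, :]
    pq = p * (1 - p)
    weight = np.where(is_x_linked(g.snp_map["chrom"].to_numpy()) & x_half_weight,
                      1.0, 2.0)
    c = float(np.sum(weight * pq))
    return MarkerDesign(M=M, p=p, c=c, snp_ids=g.snp_ids,
                        animal_ids=g.animal_ids)


def build_grm(g: GenotypeMatrix, freqs: np.ndarray | None = None,
              x_half_weight: bool = False) -> Grm:
    """G = MM'/c, the first VanRaden form with X-linked male coding."""
    d = marker_design(g, freqs=freqs, x_half_weight=x_half_weight)
    G = d.M @ d.M.T / d.c
    return Grm(G=G, c=d.c, epsilon=0.0, animal_ids=d.animal_ids)


def regularize_grm(grm: Grm, epsilon: float = 0.01) -> Grm:
    """Blend toward the identity: (1-eps) G + eps I, recording eps."""
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if epsilon == 0:
        return Grm(G=grm.G.copy(), c=grm.c, epsilon=grm.epsilon,
                   animal_ids=grm.animal_ids)
    n = grm.G.shape[0]
    G = (1 - epsilon) * grm.G + epsilon * np.eye(n)
    return Grm(G=G, c=grm.c, epsilon=epsilon, animal_ids=grm.animal_ids)


def write_grm_tsv(grm: Grm, path) -> None:
    ids = (grm.animal_ids if grm.animal_ids is not None
           else [f"a{i}" for i in range(grm.G.shape[0])])
    with open(path, "w") as fh:
        fh.write("animal_id\t" + "\t".join(map(str, ids)) + "\n")
        fh.write(f"#c={grm.c!r}\tepsilon={grm.epsilon!r}\n")
        for aid, row in zip(ids, grm.G):
            fh.write(str(aid) + "\t" + "\t".join(f"{v!r}" for v in row) + "\n")


def read_grm_tsv(path) -> Grm:
    with open(path) as fh:
        ids = fh.readline().rstrip("\n").split("\t")[1:]
        meta = fh.readline().rstrip("\n").split("\t")
        c = float(meta[0].split("=")[1])
        eps = float(meta[1].split("=")[1])
        rows = [line.rstrip("\n").split("\t")[1:] for line in fh]
    G = np.array(rows, dtype=np.float64)
    return Grm(G=G, c=c, epsilon=eps, animal_ids=np.array(ids, dtype=object))
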