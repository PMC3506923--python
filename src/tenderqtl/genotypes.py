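"""Genotype containers and file adapters.

Genotypes are called in A/B space. Internally every cell stores the
number of copies of the A allele: 2/1/0 for diploid AA/AB/BB, 1/0 for
hemizygous male-X AY/BY, and -1 for missing. Chromosomes are the 29
bovine autosomes ("1".."29"), the X ("X") and the pseudoautosomal
region ("XP", diploid in both sexes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AUTOSOMES = tuple(str(i) for i in range(1, 30))
VALID_CHROMS = AUTOSOMES + ("X", "XP")

MISSING = -1

_DIPLOID_STR = {2: "AA", 1: "AB", 0: "BB", MISSING: "NA"}
_HAPLOID_STR = {1: "AY", 0: "BY", MISSING: "NA"}


def is_x_linked(chrom: np.ndarray | str) -> np.ndarray | bool:
    """True for the non-pseudoautosomal X, where males are hemizygous."""
    if isinstance(chrom, str):
        return chrom == "X"
    return np.asarray(chrom) == "X"


@dataclass
class GenotypeMatrix:
    """Animals x SNPs genotype matrix with map and animal metadata.

    Attributes
    ----------
    animal_ids, snp_ids : arrays of unique string identifiers.
    codes : int8 array (n_animals, n_snps) of A-allele counts (-1 missing).
    sex : array of "M"/"F" per animal.
    breed : array of breed labels per animal.
    sire : array of sire ids per animal ("0" if unknown).
    snp_map : DataFrame with columns snp_id, chrom, pos, unique, aligned
        with ``snp_ids``; pos is 1-based bp, strictly increasing within
        each chromosome; ``unique`` flags unique assembly placement.
    """

    animal_ids: np.ndarray
    snp_ids: np.ndarray
    codes: np.ndarray
    sex: np.ndarray
    breed: np.ndarray
    snp_map: pd.DataFrame
    sire: np.ndarray = field(default=None)

    def __post_init__(self):
        self.animal_ids = np.asarray(self.animal_ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.codes = np.asarray(self.codes, dtype=np.int8)
        self.sex = np.asarray(self.sex, dtype=object)
        self.breed = np.asarray(self.breed, dtype=object)
        if self.sire is None:
            self.sire = np.full(len(self.animal_ids), "0", dtype=object)
        self.sire = np.asarray(self.sire, dtype=object)
        self.snp_map = self.snp_map.reset_index(drop=True)
        self.validate()

    # -- structure ---------------------------------------------------------
    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def validate(self) -> None:
        if self.codes.shape != (self.n_animals, self.n_snps):
            raise ValueError("codes shape does not match ids")
        if len(set(self.animal_ids)) != self.n_animals:
            raise ValueError("duplicate animal ids")
        if len(set(self.snp_ids)) != self.n_snps:
            raise ValueError("duplicate SNP ids")
        if not np.array_equal(self.snp_map["snp_id"].to_numpy(), self.snp_ids):
            raise ValueError("snp_map misaligned with snp_ids")
        bad = ~self.snp_map["chrom"].isin(VALID_CHROMS)
        if bad.any():
            raise ValueError(
                f"invalid chromosome labels: {sorted(set(self.snp_map['chrom'][bad]))}"
            )
        for chrom, grp in self.snp_map.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")
        # male non-PAR X cells are hemizygous: only 0/1/missing allowed
        xcols = is_x_linked(self.snp_map["chrom"].to_numpy())
        males = self.sex == "M"
        if xcols.any() and males.any():
            cells = self.codes[np.ix_(males, xcols)]
            if cells.max(initial=0) > 1:
                raise ValueError("diploid code in a male X cell")

    def ploidy(self) -> np.ndarray:
        """Per-cell ploidy (n_animals, n_snps): 1 for male non-PAR X, else 2."""
        p = np.full((self.n_animals, self.n_snps), 2, dtype=np.int8)
        xcols = is_x_linked(self.snp_map["chrom"].to_numpy())
        p[np.ix_(self.sex == "M", xcols)] = 1
        return p

    def missing_mask(self) -> np.ndarray:
        return self.codes == MISSING

    def subset(self, animal_ids=None, snp_ids=None) -> "GenotypeMatrix":
        """Return a copy restricted to the given animals and/or SNPs (order kept)."""
        arow = np.arange(self.n_animals)
        acol = np.arange(self.n_snps)
        if animal_ids is not None:
            keep = set(animal_ids)
            arow = arow[[a in keep for a in self.animal_ids]]
        if snp_ids is not None:
            keep = set(snp_ids)
            acol = acol[[s in keep for s in self.snp_ids]]
        return GenotypeMatrix(
            animal_ids=self.animal_ids[arow],
            snp_ids=self.snp_ids[acol],
            codes=self.codes[np.ix_(arow, acol)].copy(),
            sex=self.sex[arow],
            breed=self.breed[arow],
            sire=self.sire[arow],
            snp_map=self.snp_map.iloc[acol],
        )

    # -- summaries ---------------------------------------------------------
    def snp_call_rate(self) -> np.ndarray:
        return 1.0 - self.missing_mask().mean(axis=0)

    def animal_call_rate(self) -> np.ndarray:
        return 1.0 - self.missing_mask().mean(axis=1)

    def allele_freq(self, animal_mask=None) -> np.ndarray:
        """Frequency of the A allele per SNP from observed genotypes.

        Hemizygous male X cells contribute a single allele. SNPs with no
        observed alleles get NaN.
        """
        if animal_mask is None:
            animal_mask = np.ones(self.n_animals, dtype=bool)
        codes = self.codes[animal_mask].astype(np.float64)
        obs = codes >= 0
        ploidy = self.ploidy()[animal_mask]
        n_alleles = np.where(obs, ploidy, 0).sum(axis=0).astype(float)
        n_a = np.where(obs, codes, 0.0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_alleles > 0, n_a / n_alleles, np.nan)

    def minor_allele_freq(self, animal_mask=None) -> np.ndarray:
        """Per-SNP MAF from observed allele counts (exact at boundaries,
        unlike min(p, 1-p) which suffers 1-p rounding)."""
        if animal_mask is None:
            animal_mask = np.ones(self.n_animals, dtype=bool)
        codes = self.codes[animal_mask].astype(np.int64)
        obs = codes >= 0
        ploidy = self.ploidy()[animal_mask]
        n_alleles = np.where(obs, ploidy, 0).sum(axis=0)
        n_a = np.where(obs, codes, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            maf = np.minimum(n_a, n_alleles - n_a) / n_alleles
        return np.where(n_alleles > 0, maf, np.nan)

    def genotype_strings(self) -> np.ndarray:
        """Cell codes as AA/AB/BB (diploid), AY/BY (male X), NA (missing)."""
        out = np.empty(self.codes.shape, dtype=object)
        hap = self.ploidy() == 1
        for val, s in _DIPLOID_STR.items():
            out[(self.codes == val) & ~hap] = s
        for val, s in _HAPLOID_STR.items():
            out[(self.codes == val) & hap] = s
        return out


# -- PLINK ped/map ---------------------------------------------------------

_PLINK_CHROM_OUT = {"X": "X", "XP": "XY"}
# cattle have 29 autosomes, so only the lettered X codes are aliased
_PLINK_CHROM_IN = {"X": "X", "XY": "XP"}


def write_plink(g: GenotypeMatrix, ped_path, map_path) -> None:
    """Write PLINK .ped/.map text files (alleles A/B, missing 0).

    Family id carries the breed, paternal id the sire. Hemizygous male-X
    genotypes are written with the allele doubled, the PLINK convention.
    """
    with open(map_path, "w") as fh:
        for _, row in g.snp_map.iterrows():
            chrom = _PLINK_CHROM_OUT.get(row["chrom"], row["chrom"])
            fh.write(f"{chrom}\t{row['snp_id']}\t0\t{row['pos']}\n")
    sexcode = {"M": "1", "F": "2"}
    with open(ped_path, "w") as fh:
        for i in range(g.n_animals):
            fields = [
                str(g.breed[i]), str(g.animal_ids[i]), str(g.sire[i]), "0",
                sexcode.get(g.sex[i], "0"), "-9",
            ]
            row = g.codes[i]
            for c in row:
                if c == MISSING:
                    fields += ["0", "0"]
                elif c == 2:
                    fields += ["A", "A"]
                elif c == 0:
                    fields += ["B", "B"]
                else:
                    fields += ["A", "B"]
            fh.write(" ".join(fields) + "\n")


def read_plink(ped_path, map_path) -> GenotypeMatrix:
    """Read PLINK .ped/.map written by :func:`write_plink` (or compatible)."""
    rows = []
    with open(map_path) as fh:
        for line in fh:
            chrom, snp_id, _, pos = line.split()
            rows.append((snp_id, _PLINK_CHROM_IN.get(chrom, chrom), int(pos), True))
    snp_map = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "unique"])
    n_snps = len(snp_map)
    ids, sexes, breeds, sires, codes = [], [], [], [], []
    with open(ped_path) as fh:
        for line in fh:
            f = line.split()
            if len(f) != 6 + 2 * n_snps:
                raise ValueError("ped row length does not match map")
            breeds.append(f[0]); ids.append(f[1]); sires.append(f[2])
            sexes.append({"1": "M", "2": "F"}.get(f[4], "M"))
            a = np.array(f[6::2]); b = np.array(f[7::2])
            c = np.full(n_snps, MISSING, dtype=np.int8)
            called = (a != "0") & (b != "0")
            c[called] = (a[called] == "A").astype(np.int8) + (b[called] == "A")
            codes.append(c)
    g = GenotypeMatrix(
        animal_ids=np.array(ids, dtype=object),
        snp_ids=snp_map["snp_id"].to_numpy(dtype=object),
        codes=np.array(codes, dtype=np.int8),
        sex=np.array(sexes, dtype=object),
        breed=np.array(breeds, dtype=object),
        sire=np.array(sires, dtype=object),
        snp_map=snp_map,
    )
    # PLINK doubles the allele on the male X; collapse back to hemizygous
    xcols = is_x_linked(g.snp_map["chrom"].to_numpy())
    males = g.sex == "M"
    if xcols.any() and males.any():
        block = g.codes[np.ix_(males, xcols)]
        block[block == 2] = 1
        g.codes[np.ix_(males, xcols)] = block
    return g


# -- TSV dialect -----------------------------------------------------------
# UTF-8, tab-separated, header row, '.' decimal, "NA" for missing.

def write_genotypes_tsv(g: GenotypeMatrix, geno_path, animals_path, snps_path) -> None:
    strings = g.genotype_strings()
    with open(geno_path, "w") as fh:
        fh.write("animal_id\t" + "\t".join(map(str, g.snp_ids)) + "\n")
        for i in range(g.n_animals):
            fh.write(str(g.animal_ids[i]) + "\t" + "\t".join(strings[i]) + "\n")
    pd.DataFrame(
        {"animal_id": g.animal_ids, "breed": g.breed, "sex": g.sex, "sire": g.sire}
    ).to_csv(animals_path, sep="\t", index=False)
    g.snp_map.to_csv(snps_path, sep="\t", index=False)


_STR_TO_CODE = {"AA": 2, "AB": 1, "BA": 1, "BB": 0, "AY": 1, "BY": 0, "NA": MISSING}


def read_genotypes_tsv(geno_path, animals_path, snps_path) -> GenotypeMatrix:
    snp_map = pd.read_csv(snps_path, sep="\t", dtype={"chrom": str})
    animals = pd.read_csv(animals_path, sep="\t", dtype=str)
    geno = pd.read_csv(geno_path, sep="\t", dtype=str, keep_default_na=False)
    codes = np.array(
        [[_STR_TO_CODE[v] for v in row[1:]] for row in geno.itertuples(index=False)],
        dtype=np.int8,
    )
    return GenotypeMatrix(
        animal_ids=geno["animal_id"].to_numpy(dtype=object),
        snp_ids=snp_map["snp_id"].to_numpy(dtype=object),
        codes=codes,
        sex=animals["sex"].to_numpy(dtype=object),
        breed=animals["breed"].to_numpy(dtype=object),
        sire=animals["sire"].to_numpy(dtype=object),
        snp_map=snp_map,
    )
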