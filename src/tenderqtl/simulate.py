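"""Synthetic multi-breed half-sib cohorts with known genetic truth.

The generator emulates the design of a multi-breed beef-cattle progeny
test: five breeds, each contributed by a modest number of sires mated to
unobserved dams, male progeny measured once for Warner-Bratzler shear
force (WBSF, kg). Breed divergence follows a Balding-Nichols draw of
breed allele frequencies around shared ancestral frequencies; local
linkage disequilibrium arises from a finite founder-haplotype pool per
breed and from the large chromosomal segments sires transmit to their
half-sib progeny (Haldane recombination at 1 cM/Mb). Two locally
densified SNP regions mimic the fine-mapped calpastatin (*CAST*, BTA7)
and calpain-1 (*CAPN1*, BTA29) intervals.

Phenotypes follow

    y = mean + contemporary group + sum_j m_j * a_j + polygenic + residual

where the polygenic term is a sum of small effects over all SNPs scaled
so the per-breed additive variance (net of planted QTL) matches the
configured sigma2_A, and the residual variance is set from the
configured per-breed heritability.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import AUTOSOMES, GenotypeMatrix, is_x_linked

# Approximate bovine chromosome lengths (bp), UMD3-like scale.
CHROM_LENGTHS_BP: dict[str, int] = {
    "1": 161_000_000, "2": 141_000_000, "3": 128_000_000, "4": 124_000_000,
    "5": 126_000_000, "6": 123_000_000, "7": 112_000_000, "8": 117_000_000,
    "9": 108_000_000, "10": 106_000_000, "11": 110_000_000, "12": 85_000_000,
    "13": 84_000_000, "14": 81_000_000, "15": 85_000_000, "16": 78_000_000,
    "17": 76_000_000, "18": 66_000_000, "19": 65_000_000, "20": 76_000_000,
    "21": 69_000_000, "22": 62_000_000, "23": 53_000_000, "24": 65_000_000,
    "25": 44_000_000, "26": 52_000_000, "27": 49_000_000, "28": 46_000_000,
    "29": 52_000_000, "X": 149_000_000,
}

MORGAN_PER_BP = 1e-8  # 1 cM/Mb

DEFAULT_BREEDS = ("Angus", "Charolais", "Hereford", "Limousin", "Simmental")


@dataclass
class SimConfig:
    """Study-design parameters for :func:`simulate_cohort`.

    Defaults reproduce the structure of the five-breed shear-force
    cohort: ~40k autosomal + X SNPs with densified *CAST*/*CAPN1*
    regions, 18-29 sires per breed with ~29 progeny each, per-breed
    heritabilities spanning 0.08-0.52, and one major QTL per dense
    region explaining 1-2% of phenotypic variance.
    """

    n_breeds: int = 5
    sires_per_breed: int = 23
    progeny_per_sire: int = 29
    n_snps: int = 40_000          # autosomal SNPs spread over chromosomes 1..29
    n_x_snps: int = 1_500
    dense_regions: tuple = (("7", 96_500_000, 99_400_000, 44),
                            ("29", 43_000_000, 46_120_000, 100))
    breed_fst: float = 0.10
    # (snp_index, effect_kg or None, var_frac or None); None -> one QTL at the
    # centre of each dense region with the var fractions below
    qtl_spec: tuple | None = None
    default_qtl_var_frac: tuple = (0.0102, 0.0185)
    h2_per_breed: tuple = (0.52, 0.46, 0.17, 0.09, 0.08)
    var_a_per_breed: tuple = (0.22, 0.23, 0.15, 0.07, 0.06)
    var_e_per_breed: tuple | None = None  # default: var_a * (1 - h2) / h2
    n_herds: int = 5
    n_slaughter_dates: int = 6
    cg_sd: float = 0.5            # SD (kg) of contemporary-group effects
    mean_wbsf: float = 4.37
    missing_rate: float = 0.0089
    founder_haplotypes: int = 100  # per-breed founder pool size (haplotypes)
    pool_generations: int = 30     # drift/recombination generations in the pool
    pool_recomb_scale: float = 4.0  # crossover-rate multiplier per pool generation
    min_dense_poly_frac: float = 0.3  # assay regions conditioned to stay variable
    breed_names: tuple = DEFAULT_BREEDS
    # dam breed per breed: purebred Angus/Hereford, Continental x Angus dams
    dam_breed_index: tuple = (0, 0, 2, 0, 0)
    # animals deliberately given a low genotype call rate (for QC tests)
    n_low_call_animals: int = 0
    low_call_rate: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if min(self.n_breeds, self.sires_per_breed, self.progeny_per_sire,
               self.n_snps) < 1:
            raise ValueError("all counts must be >= 1")
        if not 0 <= self.breed_fst < 1:
            raise ValueError("breed_fst must be in [0, 1)")
        for h2 in self.h2_per_breed[: self.n_breeds]:
            if not 0 <= h2 < 1:
                raise ValueError("heritabilities must be in [0, 1)")
        if len(self.h2_per_breed) < self.n_breeds:
            raise ValueError("need one h2 per breed")
        for chrom, start, end, _ in self.dense_regions:
            if chrom not in CHROM_LENGTHS_BP:
                raise ValueError(f"unknown chromosome {chrom}")
            if not 0 < start < end <= CHROM_LENGTHS_BP[chrom]:
                raise ValueError("dense region outside chromosome")

    @property
    def breeds(self) -> tuple:
        return tuple(self.breed_names[: self.n_breeds])


@dataclass
class TruthRecord:
    """Generative ground truth retained for parameter-recovery tests."""

    allele_freq_by_breed: dict          # breed -> configured (pre-drift) freq
    qtl: pd.DataFrame                   # snp_id, snp_index, chrom, pos, effect_kg
    breeding_values: pd.Series          # animal_id -> true additive value (kg)
    var_a_by_breed: dict
    var_e_by_breed: dict
    cg_effects: dict                    # contemporary group label -> effect (kg)
    low_call_animals: tuple = ()
    pool_freq_by_breed: dict | None = None  # realized founder-pool frequencies
    sire_genotypes: pd.DataFrame | None = None  # sire id x snp A-allele counts

    def to_tsv(self, path) -> None:
        self.breeding_values.rename("tbv_kg").to_frame().to_csv(path, sep="\t")


def _build_map(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Lay SNPs uniformly along chromosomes, plus the dense regions."""
    lens = np.array([CHROM_LENGTHS_BP[c] for c in AUTOSOMES], dtype=float)
    per_chrom = np.maximum(1, np.round(cfg.n_snps * lens / lens.sum()).astype(int))
    chroms, positions = [], []
    for chrom, n in zip(AUTOSOMES, per_chrom):
        pos = np.sort(rng.choice(CHROM_LENGTHS_BP[chrom] - 1, size=n, replace=False)) + 1
        chroms += [chrom] * n
        positions.append(pos)
    if cfg.n_x_snps:
        pos = np.sort(rng.choice(CHROM_LENGTHS_BP["X"] - 1, size=cfg.n_x_snps,
                                 replace=False)) + 1
        chroms += ["X"] * cfg.n_x_snps
        positions.append(pos)
    df = pd.DataFrame({"chrom": chroms, "pos": np.concatenate(positions),
                       "dense": False})
    dense = []
    for chrom, start, end, count in cfg.dense_regions:
        pos = np.sort(rng.choice(np.arange(start, end), size=count, replace=False))
        dense.append(pd.DataFrame({"chrom": chrom, "pos": pos, "dense": True}))
    if dense:
        df = pd.concat([df] + dense, ignore_index=True)
    order = [c for c in AUTOSOMES] + ["X"]
    df["chrom"] = pd.Categorical(df["chrom"], categories=order, ordered=True)
    df = (df.sort_values(["chrom", "pos"])
            .drop_duplicates(["chrom", "pos"])
            .reset_index(drop=True))
    df["chrom"] = df["chrom"].astype(str)
    df["snp_id"] = [f"snp{i:06d}" for i in range(len(df))]
    df["unique"] = True
    return df[["snp_id", "chrom", "pos", "unique", "dense"]]


def _recombined_gamete(pool: np.ndarray, i1: int, i2: int, chrom_slices,
                       pos_by_chrom, rng, rate_scale: float = 1.0) -> np.ndarray:
    """One gamete from haplotypes ``pool[i1]``/``pool[i2]`` with Haldane crossovers."""
    gam = np.empty(pool.shape[1], dtype=np.int8)
    for sl, pos in zip(chrom_slices, pos_by_chrom):
        length_m = (pos[-1] - pos[0]) * MORGAN_PER_BP if len(pos) > 1 else 0.0
        k = rng.poisson(length_m * rate_scale)
        start = rng.integers(2)
        if k == 0:
            src = pool[i1 if start == 0 else i2, sl]
        else:
            xovers = np.sort(rng.uniform(pos[0], pos[-1], size=k))
            phase = (np.searchsorted(xovers, pos) + start) % 2
            src = np.where(phase == 0, pool[i1, sl], pool[i2, sl])
        gam[sl] = src
    return gam


def simulate_cohort(cfg: SimConfig):
    """Simulate genotypes, phenotypes and ground truth for one cohort.

    Returns
    -------
    (GenotypeMatrix, pandas.DataFrame, TruthRecord)
        The phenotype table has one record per animal with columns
        animal_id, breed, sire, sex, herd, slaughter_date, cg, wbsf_kg.
        All progeny are male (steers); dams are unobserved.

    Raises
    ------
    ValueError
        If the configuration is infeasible, e.g. the planted QTL
        variance exceeds a breed's additive variance.
    """
    rng = np.random.default_rng(cfg.seed)
    snp_map = _build_map(cfg, rng)
    n_snps = len(snp_map)
    chrom_arr = snp_map["chrom"].to_numpy()
    pos_arr = snp_map["pos"].to_numpy()
    chrom_slices, pos_by_chrom = [], []
    for chrom in pd.unique(chrom_arr):
        idx = np.flatnonzero(chrom_arr == chrom)
        chrom_slices.append(slice(idx[0], idx[-1] + 1))
        pos_by_chrom.append(pos_arr[idx[0]: idx[-1] + 1])
    x_mask = is_x_linked(chrom_arr)

    breeds = cfg.breeds
    # Balding-Nichols breed frequencies around a shared ancestral frequency;
    # densified-region SNPs mimic a validated custom assay, ascertained to
    # intermediate frequency, unlike the randomly ascertained backbone
    p0 = rng.uniform(0.05, 0.95, size=n_snps)
    dense_cols = snp_map["dense"].to_numpy()
    if dense_cols.any():
        p0[dense_cols] = rng.uniform(0.25, 0.75, size=int(dense_cols.sum()))
    freq = {}
    for b in breeds:
        if cfg.breed_fst > 0:
            f = cfg.breed_fst
            pb = rng.beta(p0 * (1 - f) / f, (1 - p0) * (1 - f) / f)
        else:
            pb = p0.copy()
        freq[b] = np.clip(pb, 0.01, 0.99)

    # Founder haplotype pools: start from independent-site draws, then
    # drift forward through a small fixed-size population with
    # recombination, so linkage disequilibrium decays with distance
    # instead of being uniform across a chromosome.
    dense_idx = [np.flatnonzero((chrom_arr == chrom) & (pos_arr >= start)
                                & (pos_arr <= end))
                 for chrom, start, end, _ in cfg.dense_regions]

    def _evolve_pool(pb):
        pool = (rng.uniform(size=(cfg.founder_haplotypes, n_snps))
                < pb[None, :]).astype(np.int8)
        for _ in range(cfg.pool_generations):
            nxt = np.empty_like(pool)
            for k in range(cfg.founder_haplotypes):
                i1, i2 = rng.integers(cfg.founder_haplotypes, size=2)
                nxt[k] = _recombined_gamete(pool, i1, i2, chrom_slices,
                                            pos_by_chrom, rng,
                                            cfg.pool_recomb_scale)
            pool = nxt
        return pool

    # Drift can sweep a local region to one lineage in a breed; condition
    # the pools on the assay regions staying jointly variable across
    # breeds, as a targeted assay of sites known to segregate would be.
    joint_ok = [np.ones(idx.size, dtype=bool) for idx in dense_idx]
    pools = {}
    for b in breeds:
        for _ in range(30):
            pool = _evolve_pool(freq[b])
            ok = []
            for idx, jmask in zip(dense_idx, joint_ok):
                pf = pool[:, idx].mean(axis=0)
                ok.append(jmask & (np.minimum(pf, 1 - pf) > 0.05))
            if all(o.mean() >= cfg.min_dense_poly_frac for o in ok) or not ok:
                joint_ok = ok if ok else joint_ok
                break
        pools[b] = pool

    # QTL plan
    if cfg.qtl_spec is None:
        # default: one QTL per dense region, at an interior SNP whose
        # realized pooled frequency is closest to 1/2 (a degenerate,
        # pool-monomorphic causal variant carries no signal)
        qtl_spec = []
        for (chrom, start, end, _), frac in zip(cfg.dense_regions,
                                                cfg.default_qtl_var_frac):
            inside = np.flatnonzero((chrom_arr == chrom) & (pos_arr >= start)
                                    & (pos_arr <= end))
            interior = inside[8:-8] if inside.size > 20 else inside
            p_by_breed = np.stack([pools[b][:, inside].mean(axis=0)
                                   for b in breeds])
            p_all = p_by_breed.mean(axis=0)
            maf_all_breeds = np.minimum(p_by_breed, 1 - p_by_breed).min(axis=0)
            maf_ok = maf_all_breeds > 0.05
            # prefer a variant local haplotypes can tag: segregating in
            # every breed, intermediate frequency, polymorphic flanks
            best, best_key = interior[len(interior) // 2], (-1.0, -1.0)
            for j in interior:
                k = int(np.searchsorted(inside, j))
                flank = min(maf_ok[max(k - 8, 0): k].sum(),
                            maf_ok[k + 1: k + 9].sum())
                key = (float(flank), -abs(p_all[k] - 0.5))
                if maf_ok[k] and key > best_key:
                    best, best_key = j, key
            qtl_spec.append((int(best), None, frac))
    else:
        qtl_spec = list(cfg.qtl_spec)
    var_p = {b: (cfg.var_a_per_breed[i] / cfg.h2_per_breed[i]
                 if cfg.h2_per_breed[i] > 0 else cfg.var_a_per_breed[i])
             for i, b in enumerate(breeds)}
    mean_var_p = float(np.mean(list(var_p.values()))) if breeds else 0.0
    qtl_rows, qtl_effects = [], np.zeros(n_snps)
    for spec in qtl_spec:
        j, effect, frac = spec
        if not 0 <= j < n_snps:
            raise ValueError(f"QTL index {j} out of range")
        pbar = float(np.mean([pools[b][:, j].mean() for b in breeds]))
        het = 2 * pbar * (1 - pbar)
        if het <= 0:
            raise ValueError(
                f"QTL SNP {j} is monomorphic in the founder pools")
        if effect is None:
            effect = float(np.sqrt(frac * mean_var_p / het)) * rng.choice([-1.0, 1.0])
        qtl_effects[j] += effect
        qtl_rows.append((snp_map["snp_id"].iloc[j], j, chrom_arr[j],
                         int(pos_arr[j]), float(effect)))
    qtl_df = pd.DataFrame(
        qtl_rows, columns=["snp_id", "snp_index", "chrom", "pos", "effect_kg"])
    qtl_idx = qtl_df["snp_index"].to_numpy() if len(qtl_df) else np.array([], int)

    # per-breed feasibility: QTL variance must fit inside sigma2_A
    qtl_var_by_breed = {}
    for i, b in enumerate(breeds):
        v = 0.0
        for j in qtl_idx:
            p = float(pools[b][:, j].mean())   # realized founder-pool frequency
            v += 2 * p * (1 - p) * qtl_effects[j] ** 2
        if v > cfg.var_a_per_breed[i] + 1e-12:
            raise ValueError(
                f"planted QTL variance {v:.4f} exceeds sigma2_A "
                f"{cfg.var_a_per_breed[i]:.4f} in breed {b}")
        qtl_var_by_breed[b] = v

    # draw animals
    ids, sexes, breed_col, sire_col = [], [], [], []
    sire_records: dict = {}
    hap1 = np.empty((cfg.n_breeds * cfg.sires_per_breed * cfg.progeny_per_sire,
                     n_snps), dtype=np.int8)
    hap2 = np.empty_like(hap1)
    row = 0
    for bi, b in enumerate(breeds):
        dam_b = breeds[cfg.dam_breed_index[bi]] if cfg.dam_breed_index[bi] < len(
            breeds) else b
        pool_s, pool_d = pools[b], pools[dam_b]
        for s in range(cfg.sires_per_breed):
            sire_id = f"{b[:3].upper()}_S{s:03d}"
            i1, i2 = rng.integers(cfg.founder_haplotypes, size=2)
            scode = (pool_s[i1] + pool_s[i2]).astype(np.int8)
            scode[x_mask] = pool_s[i1][x_mask]   # sires are male: one X
            sire_records[sire_id] = scode
            for k in range(cfg.progeny_per_sire):
                ids.append(f"{b[:3].upper()}{s:03d}_{k:03d}")
                sexes.append("M")
                breed_col.append(b)
                sire_col.append(sire_id)
                hap1[row] = _recombined_gamete(pool_s, i1, i2, chrom_slices,
                                               pos_by_chrom, rng)
                j1, j2 = rng.integers(cfg.founder_haplotypes, size=2)
                hap2[row] = _recombined_gamete(pool_d, j1, j2, chrom_slices,
                                               pos_by_chrom, rng)
                row += 1
    n_animals = row
    codes = (hap1 + hap2).astype(np.int8)
    # males carry a single dam-derived X allele (sire transmits Y)
    codes[:, x_mask] = hap2[:, x_mask]
    breed_col = np.array(breed_col, dtype=object)

    # true breeding values: planted QTL + background polygenic term
    ploidy = np.where(x_mask[None, :], 1, 2)
    tbv = np.zeros(n_animals)
    for i, b in enumerate(breeds):
        mask = breed_col == b
        pb = freq[b]
        m_centered = codes[mask].astype(np.float64) - ploidy * pb[None, :]
        c_b = float(np.sum(2 * pb * (1 - pb)))
        var_bg = cfg.var_a_per_breed[i] - qtl_var_by_breed[b]
        effects = rng.normal(0.0, np.sqrt(max(var_bg, 0.0) / c_b), size=n_snps)
        effects[qtl_idx] = 0.0
        u_bg = m_centered @ effects
        # finite founder pools deflate the realized marker variance, so
        # rescale the background term to deliver the configured variance
        sv = float(u_bg.var())
        if sv > 0 and var_bg > 0:
            u_bg *= np.sqrt(var_bg / sv)
        tbv[mask] = u_bg + m_centered[:, qtl_idx] @ qtl_effects[qtl_idx]

    # contemporary groups: breed x herd x sex x slaughter date
    herd = rng.integers(cfg.n_herds, size=n_animals)
    date = rng.integers(cfg.n_slaughter_dates, size=n_animals)
    cg_labels = np.array(
        [f"{b}|h{h}|M|d{d}" for b, h, d in zip(breed_col, herd, date)],
        dtype=object)
    cg_effects = {lab: rng.normal(0.0, cfg.cg_sd)
                  for lab in sorted(set(cg_labels))}
    cg_vals = np.array([cg_effects[lab] for lab in cg_labels])

    var_e = {}
    resid = np.empty(n_animals)
    for i, b in enumerate(breeds):
        h2 = cfg.h2_per_breed[i]
        if cfg.var_e_per_breed is not None:
            ve = cfg.var_e_per_breed[i]
        elif h2 > 0:
            ve = cfg.var_a_per_breed[i] * (1 - h2) / h2
        else:
            raise ValueError(
                "h2 = 0 needs an explicit var_e_per_breed entry")
        var_e[b] = ve
        mask = breed_col == b
        resid[mask] = rng.normal(0.0, np.sqrt(ve), size=mask.sum())
    y = cfg.mean_wbsf + cg_vals + tbv + resid

    # missingness: MCAR background plus deliberately low-call animals
    if cfg.missing_rate > 0:
        codes[rng.uniform(size=codes.shape) < cfg.missing_rate] = -1
    low_call = ()
    if cfg.n_low_call_animals:
        pick = rng.choice(n_animals, size=cfg.n_low_call_animals, replace=False)
        for i in pick:
            drop = rng.uniform(size=n_snps) < (1 - cfg.low_call_rate)
            codes[i, drop] = -1
        low_call = tuple(np.array(ids, dtype=object)[np.sort(pick)])

    g = GenotypeMatrix(
        animal_ids=np.array(ids, dtype=object),
        snp_ids=snp_map["snp_id"].to_numpy(dtype=object),
        codes=codes,
        sex=np.array(sexes, dtype=object),
        breed=breed_col,
        sire=np.array(sire_col, dtype=object),
        snp_map=snp_map,
    )
    pheno = pd.DataFrame({
        "animal_id": ids, "breed": breed_col, "sire": sire_col,
        "sex": sexes, "herd": herd, "slaughter_date": date,
        "cg": cg_labels, "wbsf_kg": y,
    })
    truth = TruthRecord(
        allele_freq_by_breed=freq,
        qtl=qtl_df,
        breeding_values=pd.Series(tbv, index=pd.Index(ids, name="animal_id")),
        var_a_by_breed={b: cfg.var_a_per_breed[i] for i, b in enumerate(breeds)},
        var_e_by_breed=var_e,
        cg_effects=cg_effects,
        low_call_animals=low_call,
        pool_freq_by_breed={b: pools[b].mean(axis=0) for b in breeds},
        sire_genotypes=pd.DataFrame.from_dict(
            sire_records, orient="index",
            columns=snp_map["snp_id"].tolist()),
    )
    return g, pheno, truth


def table2_fixture() -> pd.DataFrame:
    """The packaged 79-region across-breed QTL concordance table.

    Columns: bta, start, end, tag_snp, tag_pos, n_snps, n_top500,
    in_qtldb, breeds (supporting breeds at rank threshold 500) and the
    six minimum t-rank columns rank_angus .. rank_all.
    """
    ref = importlib.resources.files("tenderqtl.data") / "table2.tsv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    if len(df) != 79 or df.isna().any().any():
        raise RuntimeError("packaged region table is corrupt")
    rank_cols = [c for c in df.columns if c.startswith("rank_")]
    if (df[rank_cols] < 1).any().any():
        raise RuntimeError("packaged region table has non-positive ranks")
    return df
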