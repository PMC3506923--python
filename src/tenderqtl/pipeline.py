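"""End-to-end orchestration: qc -> phase -> grm -> reml -> ase ->
regions -> finemap, with a provenance manifest.

All stage outputs are TSV (UTF-8, tab-separated, header row, '.'
decimal, "NA" for missing) so a run is reproducible and diffable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .finemap import GlsContext, best_windows, window_scan
from .genotypes import GenotypeMatrix, read_genotypes_tsv, read_plink
from .grm import Grm, build_grm, marker_design, regularize_grm
from .phasing import phase_impute
from .qc import apply_qc
from .regions import (ALT_RANK_THRESHOLD, GAP_MAX, MAX_SPAN, MIN_BREEDS,
                      RANK_THRESHOLD, TOP_K, build_regions, detect_shared_qtl,
                      rank_table, summarize_support)
from .reml import backsolve_ase, build_model_spec, fit_reml


@dataclass
class RunConfig:
    """Serializable run configuration; defaults follow the published
    analysis where it states a value."""

    genotypes: str = ""            # .ped path or genotype TSV
    map_file: str = ""             # .map path (PLINK input only)
    animals_file: str = ""         # TSV-dialect inputs
    snps_file: str = ""
    phenotypes: str = ""           # TSV with animal_id, cg, wbsf_kg
    out_dir: str = "tenderqtl_run"
    analysis_set: str = "all"      # breed name or "all"
    snp_call_rate_min: float = 0.89
    animal_call_rate_min: float = 0.85
    maf_min: float = 0.01
    top_k: int = TOP_K
    rank_threshold: int = RANK_THRESHOLD
    alt_rank_threshold: int = ALT_RANK_THRESHOLD
    min_breeds: int = MIN_BREEDS
    gap_max: int = GAP_MAX
    max_span: int = MAX_SPAN
    window: int = 9
    pool_min_count: int = 5
    epsilon: float = 0.01
    tol_sigfigs: int = 4
    n_finemap_regions: int = 2
    phase_n_starts: int = 3
    seed: int = 1

    def to_json(self, path=None) -> str:
        s = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def _md5(path: Path) -> str:
    return hashlib.md5(path.read_bytes()).hexdigest()


def export_manhattan(ase: pd.DataFrame,
                     chrom_lengths: dict | None = None) -> pd.DataFrame:
    """Plot-ready table: chrom, pos, cumulative genome pos and t.

    Chromosome offsets come from ``chrom_lengths`` when given, else
    from the maximum observed position per chromosome.
    """
    from .reml import CHROM_ORDER
    chroms = sorted(ase["chrom"].unique(), key=lambda c: CHROM_ORDER[c])
    if chrom_lengths is None:
        chrom_lengths = {c: int(ase.loc[ase["chrom"] == c, "pos"].max())
                         for c in chroms}
    offset, cum = {}, 0
    for c in chroms:
        offset[c] = cum
        cum += int(chrom_lengths[c])
    out = ase[["snp_id", "chrom", "pos", "t_stat"]].copy()
    out["cum_pos"] = [offset[c] + p for c, p in zip(out["chrom"], out["pos"])]
    return out.sort_values("cum_pos").reset_index(drop=True)


def _load_genotypes(cfg: RunConfig) -> GenotypeMatrix:
    if cfg.genotypes.endswith(".ped"):
        return read_plink(cfg.genotypes, cfg.map_file)
    return read_genotypes_tsv(cfg.genotypes, cfg.animals_file, cfg.snps_file)


def _analysis(g, pheno, cfg, label, log):
    """QC'd genotypes -> GRM -> REML -> ASE table for one analysis set."""
    grm0 = build_grm(g)
    grm = regularize_grm(grm0, cfg.epsilon)
    spec, drop_log = build_model_spec(pheno, grm)
    fit = fit_reml(spec, tol_sigfigs=cfg.tol_sigfigs)
    design = marker_design(g)
    keep = [list(g.animal_ids).index(a) for a in spec.animal_ids]
    design.M = design.M[keep]
    design.animal_ids = spec.animal_ids
    ase = backsolve_ase(fit, design, spec.grm, g.snp_map)
    log[f"reml_{label}"] = {
        "var_a": fit.var_a, "var_e": fit.var_e, "h2": fit.h2,
        "n_iter": fit.n_iter, "converged": fit.converged,
        "records": len(spec.y), **drop_log,
    }
    return fit, spec, ase


def run_pipeline(cfg: RunConfig, genotypes: GenotypeMatrix | None = None,
                 phenotypes: pd.DataFrame | None = None) -> Path:
    """Execute all stages; returns the run directory.

    ``genotypes``/``phenotypes`` may be passed in memory (e.g. straight
    from the simulator); otherwise they are read from the configured
    paths. Re-running with the same config and inputs reproduces
    identical outputs.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"stages": []}

    def stage(name):
        log["stages"].append(name)

    try:
        stage("load")
        g = genotypes if genotypes is not None else _load_genotypes(cfg)
        pheno = (phenotypes if phenotypes is not None
                 else pd.read_csv(cfg.phenotypes, sep="\t", dtype={"cg": str}))

        stage("qc")
        g, qc_log = apply_qc(g, cfg.snp_call_rate_min,
                             cfg.animal_call_rate_min, cfg.maf_min)
        if g.n_snps == 0:
            raise RuntimeError("qc: no SNPs retained")
        if g.n_animals == 0:
            raise RuntimeError("qc: no animals retained")
        qc_log["snp_exclusions"].to_csv(out / "snp_exclusions.tsv", sep="\t",
                                        index=False)
        log["qc"] = {k: v for k, v in qc_log.items() if k != "snp_exclusions"}
        pheno = pheno[pheno["animal_id"].isin(set(g.animal_ids))]

        stage("phase")
        haps = phase_impute(g, window=cfg.window, n_starts=cfg.phase_n_starts,
                            seed=cfg.seed)
        g_imp = GenotypeMatrix(
            animal_ids=g.animal_ids, snp_ids=g.snp_ids,
            codes=haps.to_genotypes(), sex=g.sex, breed=g.breed,
            sire=g.sire, snp_map=g.snp_map)

        stage("grm_reml_ase")
        breeds = list(pd.unique(g_imp.breed))
        sets = ([("all", g_imp)] if cfg.analysis_set != "all"
                else [("all", g_imp)] + [
                    (b, g_imp.subset(animal_ids=list(
                        g_imp.animal_ids[g_imp.breed == b]))) for b in breeds])
        if cfg.analysis_set not in ("all",):
            sets = [(cfg.analysis_set, g_imp.subset(animal_ids=list(
                g_imp.animal_ids[g_imp.breed == cfg.analysis_set])))]
        fits, ases = {}, {}
        for label, gsub in sets:
            fit, spec, ase = _analysis(gsub, pheno, cfg, label, log)
            fits[label] = (fit, spec, gsub)
            ases[label] = ase
            ase.to_csv(out / f"ase_{label}.tsv", sep="\t", index=False)
        export_manhattan(ases[sets[0][0]]).to_csv(
            out / "manhattan.tsv", sep="\t", index=False)

        region_tbl = shared = None
        if cfg.analysis_set == "all" and len(breeds) > 1:
            stage("regions")
            across = rank_table(ases["all"]["t_stat"].to_numpy(), g_imp.snp_map)
            within = {b: rank_table(ases[b]["t_stat"].to_numpy(), g_imp.snp_map)
                      for b in breeds}
            region_tbl = build_regions(across, within, g_imp.snp_map,
                                       cfg.top_k, cfg.gap_max, cfg.max_span)
            shared = detect_shared_qtl(region_tbl, cfg.rank_threshold,
                                       cfg.min_breeds)
            region_tbl.to_csv(out / "regions.tsv", sep="\t", index=False)
            shared.to_csv(out / "shared_qtl.tsv", sep="\t", index=False)
            log["regions"] = summarize_support(shared, cfg.rank_threshold)

            stage("finemap")
            fit, spec, gsub = fits["all"]
            ctx = GlsContext.from_fit(spec.y, spec.X, spec.grm, fit)
            hsub = phase_impute(gsub.subset(animal_ids=list(spec.animal_ids)),
                                window=cfg.window,
                                n_starts=cfg.phase_n_starts, seed=cfg.seed)
            targets = (shared.sort_values("rank_all").head(cfg.n_finemap_regions)
                       if len(shared) else shared)
            fm_rows = []
            for _, reg in targets.iterrows():
                m = gsub.snp_map
                on_chrom = np.flatnonzero(
                    (m["chrom"] == reg["chrom"]).to_numpy())
                pos_c = m["pos"].to_numpy()[on_chrom]
                sel = (pos_c >= reg["start"]) & (pos_c <= reg["end"])
                # expand narrow regions symmetrically so haplotype
                # windows can slide, as the published analysis did
                want = max(cfg.window * 4, int(sel.sum()))
                lo, hi = np.flatnonzero(sel)[[0, -1]] if sel.any() else (0, -1)
                while hi - lo + 1 < want:
                    grow_lo = lo > 0 and (pos_c[hi] - pos_c[lo - 1]
                                          <= cfg.max_span)
                    grow_hi = hi < sel.size - 1 and (pos_c[hi + 1] - pos_c[lo]
                                                     <= cfg.max_span)
                    if not (grow_lo or grow_hi):
                        break
                    if grow_lo:
                        lo -= 1
                    if grow_hi:
                        hi += 1
                idx = on_chrom[lo: hi + 1]
                if idx.size < cfg.window:
                    continue
                res = window_scan(ctx, hsub, idx, cfg.window,
                                  cfg.pool_min_count)
                for r in res:
                    fm_rows.append({
                        "region": f"{reg['chrom']}:{reg['start']}-{reg['end']}",
                        "centre_snp": r.centre_snp, "pos": r.centre_pos,
                        "n_haplotypes": r.n_haplotypes, "F": r.f,
                        "df1": r.df1, "df2": r.df2,
                        "neglog10P": r.neglog10_p, "pct_var": r.pct_var})
            fm_cols = ["region", "centre_snp", "pos", "n_haplotypes", "F",
                       "df1", "df2", "neglog10P", "pct_var"]
            pd.DataFrame(fm_rows, columns=fm_cols).to_csv(
                out / "finemap_windows.tsv", sep="\t", index=False)
    except Exception as err:
        failed = log["stages"][-1] if log["stages"] else "init"
        raise RuntimeError(
            f"pipeline stage '{failed}' failed: {err}; "
            f"see {out / 'manifest.json'}") from err

    manifest = {
        "config_hash": cfg.config_hash(), "seed": cfg.seed,
        "version": __version__, "log": log,
        "outputs": {p.name: _md5(p) for p in sorted(out.glob("*.tsv"))},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True, default=str))
    cfg.to_json(out / "config.json")
    return out
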