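"""Single-SNP and sliding haplotype-window association within regions.

Tests are generalized least squares under the fixed covariance
V = G sigma2_A + I sigma2_E assembled from a previously fitted REML
analysis (variance components are frozen, not re-estimated per test).
All sums of squares are computed on the whitened scale (pre-multiply by
the inverse Cholesky factor of V), which reduces exactly to ordinary
least squares when V is proportional to the identity.

For a fitted effect, F = (delta SS / delta df) / (residual mean square
of the full model) with delta SS the gain in model sum of squares over
the contemporary-group-only model. The sliding window fits the
distinct phased haplotypes of ``window`` (default 9) contiguous SNPs as
a multi-allelic fixed effect, assigns each window's statistics to its
centre SNP, and also reports the percentage of phenotypic variation
explained: 100 * window SS / (total SS corrected for the mean and
contemporary groups). Because the haplotype count varies between
windows, the max-F and max-%VarP windows can differ; both maxima are
meaningful and both are reported by the scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cholesky, solve_triangular
from scipy.stats import f as f_dist

from .grm import Grm

POOL_MIN_COUNT = 5
POOLED_LABEL = "_POOLED"


@dataclass
class GlsContext:
    """Whitened phenotypes and contemporary-group design under fixed V."""

    yw: np.ndarray
    Xw: np.ndarray
    L: np.ndarray                # lower Cholesky factor of V
    var_a: float
    var_e: float

    @classmethod
    def from_components(cls, y, X, grm: Grm, var_a: float, var_e: float):
        V = var_a * grm.G + var_e * np.eye(len(y))
        L = cholesky(V, lower=True)
        return cls(
            yw=solve_triangular(L, np.asarray(y, float), lower=True),
            Xw=solve_triangular(L, np.asarray(X, float), lower=True),
            L=L, var_a=float(var_a), var_e=float(var_e),
        )

    @classmethod
    def from_fit(cls, y, X, grm: Grm, fit):
        return cls.from_components(y, X, grm, fit.var_a, fit.var_e)

    def whiten(self, cols: np.ndarray) -> np.ndarray:
        return solve_triangular(self.L, np.asarray(cols, float), lower=True)

    def model_ss(self, Xw_full: np.ndarray):
        """(model SS, rank) for a whitened design."""
        coef, rss, rank, _ = np.linalg.lstsq(Xw_full, self.yw, rcond=None)
        fitted = Xw_full @ coef
        return float(fitted @ fitted), int(rank), coef

    @property
    def total_ss(self) -> float:
        return float(self.yw @ self.yw)

    def baseline(self):
        """(cg model SS incl. mean, cg rank) — cached on first use."""
        if not hasattr(self, "_base"):
            ss, rank, _ = self.model_ss(self.Xw)
            self._base = (ss, rank)
        return self._base


@dataclass
class SnpTestResult:
    ase: float
    f: float
    df1: int
    df2: int
    neglog10_p: float
    ok: bool
    note: str = ""


@dataclass
class WindowResult:
    centre_snp: str
    centre_pos: int
    n_haplotypes: int
    f: float
    df1: int
    df2: int
    neglog10_p: float
    pct_var: float


def _f_test(ctx: GlsContext, Xw_full: np.ndarray):
    """F for the added columns of ``Xw_full`` over the CG-only model."""
    ss0, rank0 = ctx.baseline()
    ss1, rank1, coef = ctx.model_ss(Xw_full)
    df1 = rank1 - rank0
    n = len(ctx.yw)
    df2 = n - rank1
    if df1 <= 0 or df2 <= 0:
        return None
    delta = max(ss1 - ss0, 0.0)
    rms = (ctx.total_ss - ss1) / df2
    fstat = (delta / df1) / rms if rms > 0 else np.inf
    neglog10p = -f_dist.logsf(fstat, df1, df2) / np.log(10)
    return fstat, df1, df2, float(neglog10p), delta, coef


def single_snp_test(ctx: GlsContext, genotypes: np.ndarray) -> SnpTestResult:
    """GLS added-variable test of one SNP's allele effect.

    ``genotypes`` are A-allele counts for the analysis animals.
    Monomorphic or CG-collinear SNPs return a flagged NA result.
    """
    geno = np.asarray(genotypes, dtype=float)
    if np.all(geno == geno[0]):
        return SnpTestResult(np.nan, np.nan, 0, 0, np.nan, False, "monomorphic")
    gw = ctx.whiten(geno[:, None])
    full = np.hstack([ctx.Xw, gw])
    res = _f_test(ctx, full)
    if res is None:
        return SnpTestResult(np.nan, np.nan, 0, 0, np.nan, False,
                             "collinear with contemporary groups")
    fstat, df1, df2, nlp, _, coef = res
    return SnpTestResult(float(coef[-1]), float(fstat), df1, df2, nlp, True)


def pool_rare_haplotypes(counts: dict, min_count: int = POOL_MIN_COUNT) -> dict:
    """Map haplotypes with carrier count < ``min_count`` to one pooled level."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    return {h: (h if c >= min_count else POOLED_LABEL)
            for h, c in sorted(counts.items())}


def percent_variance(full_ss: float, reduced_ss: float, total_ss: float,
                     cg_ss: float) -> float:
    """Window share of phenotypic variation, in percent.

    ``cg_ss`` is the model SS of the mean-plus-contemporary-group fit,
    so the denominator is the total SS corrected for the mean and
    contemporary groups.
    """
    if full_ss < reduced_ss - 1e-9 * max(1.0, abs(reduced_ss)):
        raise ValueError("full-model SS cannot be below reduced-model SS")
    phen_ss = total_ss - cg_ss
    if phen_ss <= 0:
        raise ValueError("phenotypic SS must be positive")
    return 100.0 * max(full_ss - reduced_ss, 0.0) / phen_ss


def window_scan(ctx: GlsContext, haps, snp_indices,
                window: int = 9, min_count: int = POOL_MIN_COUNT) -> list:
    """Slide a ``window``-SNP haplotype effect through one region.

    ``snp_indices`` index the region's SNPs (genome order) inside
    ``haps``; windows never cross the region boundary. Each result is
    assigned to the centre SNP (the 5th of 9 by default).
    """
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3 for a unique centre")
    snp_indices = np.asarray(snp_indices)
    if snp_indices.size < window:
        raise ValueError("region has fewer SNPs than the window")
    pos = haps.snp_map["pos"].to_numpy()
    ids = haps.snp_map["snp_id"].to_numpy()
    ss_cg, _ = ctx.baseline()
    results = []
    for s in range(snp_indices.size - window + 1):
        idx = snp_indices[s: s + window]
        centre = idx[window // 2]
        diplos = haps.diplotypes(idx)
        counts: dict = {}
        for pair in diplos:
            for h in pair:
                counts[h] = counts.get(h, 0) + 1
        level_map = pool_rare_haplotypes(counts, min_count)
        levels = sorted(set(level_map.values()))
        dosage = np.zeros((len(diplos), len(levels)))
        lut = {lev: k for k, lev in enumerate(levels)}
        for i, pair in enumerate(diplos):
            for h in pair:
                dosage[i, lut[level_map[h]]] += 1.0
        if len(levels) < 2:
            results.append(WindowResult(ids[centre], int(pos[centre]),
                                        len(levels), np.nan, 0, 0, np.nan, 0.0))
            continue
        hw = ctx.whiten(dosage)
        res = _f_test(ctx, np.hstack([ctx.Xw, hw]))
        if res is None:
            results.append(WindowResult(ids[centre], int(pos[centre]),
                                        len(levels), np.nan, 0, 0, np.nan, 0.0))
            continue
        fstat, df1, df2, nlp, delta, _ = res
        ss1 = ss_cg + delta
        pct = percent_variance(ss1, ss_cg, ctx.total_ss, ss_cg)
        results.append(WindowResult(ids[centre], int(pos[centre]), len(levels),
                                    float(fstat), df1, df2, nlp, pct))
    return results


def best_windows(results: list) -> dict:
    """The two per-region maxima: max-F ("window_p") and max-%VarP
    ("window_vp"); NaN-F windows are ignored."""
    valid = [r for r in results if np.isfinite(r.f)]
    if not valid:
        return {"window_p": None, "window_vp": None}
    return {
        "window_p": max(valid, key=lambda r: r.f),
        "window_vp": max(valid, key=lambda r: r.pct_var),
    }
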