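"""REML variance components, GBLUP and back-solved SNP effects.

The single-trait animal model is

    y = X beta + Z u + e,   Var(u) = G sigma2_A,  Var(e) = I sigma2_E,

with X the contemporary-group design (breed x herd x sex x slaughter
date) and one record per genotyped animal (Z = I). The model is rotated
through the eigendecomposition G = U D U', which diagonalizes both
covariance structures, so each restricted-likelihood evaluation and
each EM update costs O(n p^2) instead of O(n^3). The heritability
profile of the restricted likelihood is first maximized by a scalar
search, then EM-REML iterations (monotone in the restricted
log-likelihood by construction) run until two successive heritability
iterates agree to the requested number of significant figures
(default 4).

At convergence the GBLUP breeding values are back-solved into SNP
allele substitution effects

    alpha_hat = c^-1 M' G^-1 u_hat,      c = 2 sum_i p_i q_i,

each normalized by sigma_M = sqrt(sigma2_A / c) into the t-like
statistic t_i = |alpha_i| / sigma_M, and ranked (1 = largest t_i, ties
broken by genome order). This back-solve is algebraically identical to
ridge-regression SNP-BLUP with Var(a) = I sigma2_M when G = MM'/c.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar

from .grm import Grm, MarkerDesign

BOUNDARY_FLOOR = 1e-12


@dataclass
class ModelSpec:
    """Aligned phenotypes, fixed design and GRM for one analysis."""

    y: np.ndarray
    X: np.ndarray
    grm: Grm
    animal_ids: np.ndarray
    fixed_levels: list = field(default_factory=list)

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=np.float64)
        self.X = np.asarray(self.X, dtype=np.float64)
        n = len(self.y)
        if self.X.shape[0] != n or self.grm.G.shape != (n, n):
            raise ValueError("y, X and G dimensions disagree")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("fixed-effect design is rank deficient")


@dataclass
class RemlFit:
    var_a: float
    var_e: float
    h2: float
    beta: np.ndarray
    u: np.ndarray                     # GBLUP breeding values (kg)
    fixed_levels: list
    animal_ids: np.ndarray
    loglik_trace: list
    n_iter: int
    converged: bool
    boundary: bool = False


def build_model_spec(pheno: pd.DataFrame, grm: Grm,
                     cg_column: str = "cg", y_column: str = "wbsf_kg",
                     min_cg_records: int = 2):
    """Assemble a ModelSpec from a phenotype table and a GRM.

    Contemporary-group levels with fewer than ``min_cg_records`` records
    are dropped (their records removed) and reported. Records are
    reordered to the GRM's animals; every GRM animal must have exactly
    one record.
    """
    counts = pheno[cg_column].value_counts()
    small = set(counts[counts < min_cg_records].index)
    kept = pheno[~pheno[cg_column].isin(small)]
    ids = list(grm.animal_ids)
    kept = kept.set_index("animal_id")
    present = [a for a in ids if a in kept.index]
    if kept.index.duplicated().any():
        raise ValueError("multiple records per animal")
    sub_idx = [ids.index(a) for a in present]
    G = grm.G[np.ix_(sub_idx, sub_idx)]
    sub = kept.loc[present]
    levels = sorted(sub[cg_column].unique())
    lut = {lab: k for k, lab in enumerate(levels)}
    X = np.zeros((len(sub), len(levels)))
    X[np.arange(len(sub)), [lut[v] for v in sub[cg_column]]] = 1.0
    spec = ModelSpec(
        y=sub[y_column].to_numpy(),
        X=X,
        grm=Grm(G=G, c=grm.c, epsilon=grm.epsilon,
                animal_ids=np.array(present, dtype=object)),
        animal_ids=np.array(present, dtype=object),
        fixed_levels=levels,
    )
    return spec, {"dropped_cg_levels": sorted(small),
                  "records_dropped": len(pheno) - len(sub)}


def _sigfig_str(x: float, k: int) -> str:
    return f"{x:.{k}g}"


class _Rotated:
    """Model quantities after the G = U D U' rotation."""

    def __init__(self, spec: ModelSpec):
        d, U = np.linalg.eigh(spec.grm.G)
        if d[0] <= 0:
            raise ValueError(
                "G is not positive definite; apply regularize_grm first")
        self.d = d
        self.U = U
        self.y = U.T @ spec.y
        self.X = U.T @ spec.X
        self.n, self.p = self.X.shape

    def core(self, var_a: float, var_e: float):
        """GLS pieces for V = diag(var_a * d + var_e)."""
        v = var_a * self.d + var_e
        w = 1.0 / v
        Xw = self.X * w[:, None]
        XtWX = self.X.T @ Xw
        cf = cho_factor(XtWX)
        beta = cho_solve(cf, Xw.T @ self.y)
        resid = self.y - self.X @ beta
        Py = w * resid
        return v, w, Xw, XtWX, cf, beta, resid, Py

    def reml_loglik(self, var_a: float, var_e: float) -> float:
        v, w, Xw, XtWX, cf, beta, resid, Py = self.core(var_a, var_e)
        _, logdet_xvx = np.linalg.slogdet(XtWX)
        return -0.5 * (np.sum(np.log(v)) + logdet_xvx + resid @ Py)

    def em_step(self, var_a: float, var_e: float):
        v, w, Xw, XtWX, cf, beta, resid, Py = self.core(var_a, var_e)
        # tr(PA) = tr(W A) - tr((X'WX)^-1 X'W A W X) for A in {G, I}
        B = cho_solve(cf, Xw.T)            # (p, n): (X'WX)^-1 X'W
        tr_PG = float(np.sum(w * self.d) - np.einsum("pn,n,np->", B, self.d * w,
                                                     self.X))
        tr_P = float(np.sum(w) - np.einsum("pn,n,np->", B, w, self.X))
        yPGPy = float(np.sum(self.d * Py * Py))
        yPPy = float(Py @ Py)
        var_a_new = var_a + var_a**2 * (yPGPy - tr_PG) / self.n
        var_e_new = var_e + var_e**2 * (yPPy - tr_P) / self.n
        return max(var_a_new, BOUNDARY_FLOOR), max(var_e_new, BOUNDARY_FLOOR)

    def blup(self, var_a: float, var_e: float):
        _, _, _, _, _, beta, _, Py = self.core(var_a, var_e)
        u_rot = var_a * self.d * Py
        return beta, self.U @ u_rot


def fit_reml(spec: ModelSpec, tol_sigfigs: int = 4,
             max_iter: int = 500) -> RemlFit:
    """Estimate variance components by REML and return the GBLUP fit.

    A profiled scalar search over the heritability locates the
    optimum, after which EM-REML iterations (restricted log-likelihood
    non-decreasing, asserted each step) refine the pair until two
    successive heritability iterates print identically at
    ``tol_sigfigs`` significant figures.
    """
    rot = _Rotated(spec)
    df = rot.n - rot.p

    def negll_profiled(h2):
        # V = s * (h2 G + (1-h2) I); the overall scale s is profiled out
        h2 = min(max(h2, 1e-6), 1 - 1e-6)
        v, w, Xw, XtWX, cf, beta, resid, Py = rot.core(h2, 1 - h2)
        s = float(resid @ Py) / df
        _, logdet_xvx = np.linalg.slogdet(XtWX)
        return 0.5 * (df * np.log(s) + np.sum(np.log(v)) + logdet_xvx + df)

    res = minimize_scalar(negll_profiled, bounds=(1e-6, 1 - 1e-6),
                          method="bounded", options={"xatol": 1e-8})
    h2_0 = float(res.x)
    v, w, Xw, XtWX, cf, beta, resid, Py = rot.core(h2_0, 1 - h2_0)
    scale = float(resid @ Py) / df
    var_a, var_e = h2_0 * scale, (1 - h2_0) * scale

    trace = [rot.reml_loglik(var_a, var_e)]
    h2 = var_a / (var_a + var_e)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        var_a_new, var_e_new = rot.em_step(var_a, var_e)
        ll = rot.reml_loglik(var_a_new, var_e_new)
        if ll < trace[-1] - 1e-8 * max(1.0, abs(trace[-1])):
            raise AssertionError("EM-REML restricted likelihood decreased")
        trace.append(ll)
        h2_new = var_a_new / (var_a_new + var_e_new)
        done = _sigfig_str(h2_new, tol_sigfigs) == _sigfig_str(h2, tol_sigfigs)
        var_a, var_e, h2 = var_a_new, var_e_new, h2_new
        if done:
            converged = True
            break
    beta, u = rot.blup(var_a, var_e)
    return RemlFit(
        var_a=float(var_a), var_e=float(var_e), h2=float(h2),
        beta=beta, u=u, fixed_levels=spec.fixed_levels,
        animal_ids=spec.animal_ids, loglik_trace=trace, n_iter=it,
        converged=converged, boundary=bool(var_a <= 10 * BOUNDARY_FLOOR),
    )


# -- allele substitution effects ------------------------------------------

CHROM_ORDER = {str(i): i for i in range(1, 30)} | {"X": 30, "XP": 31}


def genome_order(snp_map: pd.DataFrame) -> np.ndarray:
    """Index that sorts SNPs by (chromosome, position)."""
    key = np.array([CHROM_ORDER[c] for c in snp_map["chrom"]])
    return np.lexsort((snp_map["pos"].to_numpy(), key))


def backsolve_ase(fit: RemlFit, design: MarkerDesign, grm: Grm,
                  snp_map: pd.DataFrame) -> pd.DataFrame:
    """Back-solve GBLUP breeding values into per-SNP effects.

    Returns the ASE table: snp_id, chrom, pos, p_A, ase_kg, t_stat,
    rank, with rank 1 for the largest t and ties broken by genome
    order.
    """
    if design.M.shape[0] != grm.G.shape[0]:
        raise ValueError("marker design and G dimensions disagree")
    if len(fit.u) != grm.G.shape[0]:
        raise ValueError("fit and G dimensions disagree")
    cf = cho_factor(grm.G)
    alpha = design.M.T @ cho_solve(cf, fit.u) / design.c
    sigma_m = float(np.sqrt(fit.var_a / design.c))
    t = np.abs(alpha) / sigma_m if sigma_m > 0 else np.zeros_like(alpha)
    table = pd.DataFrame({
        "snp_id": design.snp_ids,
        "chrom": snp_map["chrom"].to_numpy(),
        "pos": snp_map["pos"].to_numpy(),
        "p_A": design.p,
        "ase_kg": alpha,
        "t_stat": t,
    })
    gorder = genome_order(snp_map)
    gpos = np.empty(len(table), dtype=int)
    gpos[gorder] = np.arange(len(table))
    order = np.lexsort((gpos, -t))
    rank = np.empty(len(table), dtype=int)
    rank[order] = np.arange(1, len(table) + 1)
    table["rank"] = rank
    return table


def genetic_sample_size(n_phenotypes: int, h2: float) -> float:
    """Cumulative additive information N * sqrt(h2), to one decimal."""
    if not 0 <= h2 <= 1:
        raise ValueError("h2 must be in [0, 1]")
    return round(n_phenotypes * float(np.sqrt(h2)), 1)
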