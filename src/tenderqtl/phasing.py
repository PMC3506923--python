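"""Phasing and imputation by overlapping-window haplotype EM.

Each chromosome is processed in overlapping windows (default width 9,
matching the haplotype-analysis window; stride = width // 2). Within a
window, every genotype-compatible haplotype pair is enumerated per
animal (single haplotypes for hemizygous males on the X), haplotype
frequencies are estimated by EM with random restarts, and each animal
is assigned its maximum-posterior pair. Overlapping windows are
stitched by choosing, per animal, the orientation of the new window's
pair that agrees with the already-assigned overlap at the most sites.

Observed genotypes are always preserved: the haplotype pair collapses
back to the unordered input genotype wherever it was non-missing.
Missing cells are imputed from the assigned pair, with the posterior
probability of the imputed allele count recorded. The procedure is
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, is_x_linked

_MAX_FREE_BITS = 12   # enumeration cap per window pattern


@dataclass
class PhasedHaplotypes:
    """Two phased allele sequences per animal (one on the male X).

    ``hap1``/``hap2`` hold A-allele indicators (0/1); hap2 is -1 where a
    male is hemizygous. ``posterior`` is 1 where the genotype was
    observed and the imputation posterior where it was missing.
    """

    animal_ids: np.ndarray
    snp_ids: np.ndarray
    snp_map: pd.DataFrame
    hap1: np.ndarray
    hap2: np.ndarray
    posterior: np.ndarray

    def to_genotypes(self) -> np.ndarray:
        """Collapse to unordered A-allele counts (no missing cells)."""
        return np.where(self.hap2 >= 0, self.hap1 + self.hap2,
                        self.hap1).astype(np.int8)

    def diplotypes(self, snp_idx) -> list:
        """Per-animal unordered pair of haplotype strings over ``snp_idx``.

        Hemizygous males contribute a single-haplotype tuple.
        """
        out = []
        h1 = self.hap1[:, snp_idx]
        h2 = self.hap2[:, snp_idx]
        for i in range(len(self.animal_ids)):
            a = "".join(map(str, h1[i]))
            if (h2[i] < 0).any():
                out.append((a,))
            else:
                b = "".join(map(str, h2[i]))
                out.append(tuple(sorted((a, b))))
        return out


def _enumerate_pairs(pattern: np.ndarray):
    """All unordered haplotype pairs (as bitmasks) compatible with a
    diploid genotype pattern; multiplicity 2 for heterozygous pairs."""
    w = len(pattern)
    base = 0
    for j in range(w):
        if pattern[j] == 2:
            base |= 1 << j
    het = [j for j in range(w) if pattern[j] == 1]
    mis = [j for j in range(w) if pattern[j] == -1]
    free = len(het) + 2 * len(mis)
    if free > _MAX_FREE_BITS:
        # keep the enumeration bounded: treat surplus missing cells as
        # heterozygous (the most permissive single-bit choice)
        surplus = free - _MAX_FREE_BITS
        demote = mis[-((surplus + 1) // 2):]
        het = het + demote
        mis = [j for j in mis if j not in demote]
    pairs = set()
    for hbits in range(1 << len(het)):
        h1h = base
        h2h = base
        for k, j in enumerate(het):
            if (hbits >> k) & 1:
                h1h |= 1 << j
            else:
                h2h |= 1 << j
        for mbits in range(1 << (2 * len(mis))):
            h1, h2 = h1h, h2h
            for k, j in enumerate(mis):
                if (mbits >> (2 * k)) & 1:
                    h1 |= 1 << j
                if (mbits >> (2 * k + 1)) & 1:
                    h2 |= 1 << j
            pairs.add((h1, h2) if h1 <= h2 else (h2, h1))
    return sorted(pairs)


def _enumerate_haploid(pattern: np.ndarray):
    w = len(pattern)
    base = 0
    mis = []
    for j in range(w):
        if pattern[j] == 1:
            base |= 1 << j
        elif pattern[j] == -1:
            mis.append(j)
    mis = mis[:_MAX_FREE_BITS]
    haps = []
    for mbits in range(1 << len(mis)):
        h = base
        for k, j in enumerate(mis):
            if (mbits >> k) & 1:
                h |= 1 << j
        haps.append(h)
    return haps


def _window_em(codes_w: np.ndarray, haploid_rows: np.ndarray,
               n_starts: int, rng: np.random.Generator, max_iter: int = 100):
    """EM over window haplotype frequencies; returns per-animal best
    (h1, h2) bitmask pairs (h2 = -1 for haploid rows) and the per-animal
    posterior table needed for imputation posteriors."""
    n, w = codes_w.shape
    dip = ~haploid_rows
    # candidate pairs per unique genotype pattern
    anim_entries_a, entries_h1, entries_h2, entries_mult = [], [], [], []
    dip_idx = np.flatnonzero(dip)
    if dip_idx.size:
        pats, inv = np.unique(codes_w[dip_idx], axis=0, return_inverse=True)
        pair_lists = [_enumerate_pairs(p) for p in pats]
        for k, row in zip(inv, dip_idx):
            for h1, h2 in pair_lists[k]:
                anim_entries_a.append(row)
                entries_h1.append(h1)
                entries_h2.append(h2)
                entries_mult.append(2.0 if h1 != h2 else 1.0)
    hap_idx = np.flatnonzero(haploid_rows)
    for row in hap_idx:
        for h in _enumerate_haploid(codes_w[row]):
            anim_entries_a.append(row)
            entries_h1.append(h)
            entries_h2.append(-1)
            entries_mult.append(1.0)
    a = np.asarray(anim_entries_a)
    h1 = np.asarray(entries_h1)
    h2 = np.asarray(entries_h2)
    mult = np.asarray(entries_mult)
    haps = np.unique(np.concatenate([h1, h2[h2 >= 0]])) if len(a) else np.array([0])
    lut = {h: i for i, h in enumerate(haps)}
    i1 = np.array([lut[h] for h in h1], dtype=np.intp)
    i2 = np.array([lut[h] if h >= 0 else -1 for h in h2], dtype=np.intp)
    is_dip_entry = h2 >= 0
    n_draws = 2 * dip_idx.size + hap_idx.size

    best = None
    for start in range(max(1, n_starts)):
        if start == 0:
            f = np.full(len(haps), 1.0 / len(haps))
        else:
            f = rng.dirichlet(np.ones(len(haps)))
            f = np.maximum(f, 1e-12)
            f /= f.sum()
        ll_prev = -np.inf
        for _ in range(max_iter):
            pf = np.where(is_dip_entry, f[i1] * f[np.maximum(i2, 0)] * mult,
                          f[i1])
            denom = np.bincount(a, weights=pf, minlength=n)
            denom_safe = np.where(denom > 0, denom, 1.0)
            post = pf / denom_safe[a]
            counts = np.bincount(i1, weights=post, minlength=len(haps))
            counts += np.bincount(np.maximum(i2, 0),
                                  weights=np.where(is_dip_entry, post, 0.0),
                                  minlength=len(haps))
            f = counts / max(n_draws, 1)
            f = np.maximum(f, 1e-15)
            f /= f.sum()
            ll = float(np.sum(np.log(denom_safe[denom > 0])))
            if ll - ll_prev < 1e-8:
                break
            ll_prev = ll
        if best is None or ll > best[0] + 1e-10:
            best = (ll, f.copy())
    f = best[1]
    pf = np.where(is_dip_entry, f[i1] * f[np.maximum(i2, 0)] * mult, f[i1])
    denom = np.bincount(a, weights=pf, minlength=n)
    post = pf / np.where(denom > 0, denom, 1.0)[a]

    # per-animal argmax pair, deterministic (first max in enumeration order)
    pair1 = np.zeros(n, dtype=np.int64)
    pair2 = np.full(n, -1, dtype=np.int64)
    best_post = np.full(n, -1.0)
    order = np.argsort(a, kind="stable")
    for e in order:
        row = a[e]
        if post[e] > best_post[row] + 1e-12:
            best_post[row] = post[e]
            pair1[row] = h1[e]
            pair2[row] = h2[e]
    return pair1, pair2, (a, h1, h2, post), f, dict(zip(haps, f))


def _bits_to_alleles(mask: np.ndarray, w: int) -> np.ndarray:
    return ((mask[:, None] >> np.arange(w)[None, :]) & 1).astype(np.int8)


def phase_impute(g: GenotypeMatrix, window: int = 9, n_starts: int = 3,
                 seed: int = 0, max_iter: int = 100) -> PhasedHaplotypes:
    """Phase all genotypes and impute missing cells.

    Raises ``ValueError`` when ``window`` < 2.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    rng = np.random.default_rng(seed)
    n, m = g.codes.shape
    hap1 = np.zeros((n, m), dtype=np.int8)
    hap2 = np.zeros((n, m), dtype=np.int8)
    posterior = np.ones((n, m), dtype=np.float64)
    missing = g.missing_mask()
    chrom_arr = g.snp_map["chrom"].to_numpy()

    for chrom in pd.unique(chrom_arr):
        cols = np.flatnonzero(chrom_arr == chrom)
        haploid_rows = (g.sex == "M") if is_x_linked(chrom) else np.zeros(n, bool)
        mc = cols.size
        w_eff = min(window, mc)
        stride = max(1, w_eff // 2)
        starts = list(range(0, mc - w_eff + 1, stride))
        if starts[-1] != mc - w_eff:
            starts.append(mc - w_eff)
        assigned_until = 0
        for s in starts:
            wcols = cols[s: s + w_eff]
            codes_w = g.codes[:, wcols].astype(np.int8)
            p1, p2, entry_tab, _, _ = _window_em(codes_w, haploid_rows,
                                                 n_starts, rng, max_iter)
            a1 = _bits_to_alleles(p1, w_eff)
            a2 = np.where(p2[:, None] >= 0,
                          _bits_to_alleles(np.maximum(p2, 0), w_eff), -1
                          ).astype(np.int8)
            ov = assigned_until - s     # columns already assigned in window
            if ov > 0:
                prev1 = hap1[:, wcols[:ov]]
                prev2 = hap2[:, wcols[:ov]]
                agree = ((a1[:, :ov] == prev1).sum(1)
                         + np.where((a2[:, :ov] >= 0).all(1),
                                    (a2[:, :ov] == prev2).sum(1), 0))
                swapped = ((a2[:, :ov] == prev1).sum(1)
                           + (a1[:, :ov] == prev2).sum(1))
                flip = (swapped > agree) & ~haploid_rows
                a1[flip], a2[flip] = a2[flip].copy(), a1[flip].copy()
            newcols = wcols[max(ov, 0):]
            sel = slice(max(ov, 0), w_eff)
            hap1[:, newcols] = a1[:, sel]
            hap2[:, newcols] = a2[:, sel]
            # imputation posteriors for originally-missing cells
            miss_w = missing[:, wcols]
            if miss_w.any():
                a_e, h1_e, h2_e, post_e = entry_tab
                chosen = np.where(a2 >= 0, a1 + np.maximum(a2, 0), a1)
                for row in np.flatnonzero(miss_w.any(axis=1)):
                    mask_e = a_e == row
                    if not mask_e.any():
                        continue
                    g1 = _bits_to_alleles(h1_e[mask_e], w_eff)
                    dip = h2_e[mask_e] >= 0
                    g2 = np.where(dip[:, None],
                                  _bits_to_alleles(np.maximum(h2_e[mask_e], 0),
                                                   w_eff), 0)
                    gc = g1 + g2
                    pp = post_e[mask_e]
                    for jloc in np.flatnonzero(miss_w[row]):
                        pr = float(pp[gc[:, jloc] == chosen[row, jloc]].sum())
                        posterior[row, wcols[jloc]] = min(pr, 1.0)
            assigned_until = s + w_eff

    # restore observed genotypes exactly where EM enumeration was capped
    ph = PhasedHaplotypes(
        animal_ids=g.animal_ids, snp_ids=g.snp_ids, snp_map=g.snp_map,
        hap1=hap1, hap2=hap2, posterior=posterior)
    collapsed = ph.to_genotypes()
    mismatch = (~missing) & (collapsed != g.codes)
    if mismatch.any():
        raise AssertionError("phasing altered an observed genotype")
    return ph
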