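"""Across-breed QTL-region concordance from ranked SNP effects.

SNP allele substitution effects are ranked by their normalized |t|
within each analysis (1 = strongest; ties broken by genome order).
SNPs ranking in the across-breed top ``top_k`` seed genomic regions;
nearby seeds merge, regions grow outward to highly-ranked within-breed
SNPs up to a span cap, and a region is declared a shared QTL when at
least ``min_breeds`` within-breed analyses rank a SNP inside it at or
under the threshold.

Coordinates are 1-based and a region's span is end - start in bp.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .reml import genome_order

TOP_K = 500
GAP_MAX = 1_000_000
MAX_SPAN = 5_700_000
RANK_THRESHOLD = 500
ALT_RANK_THRESHOLD = 999      # the "< 1000" variant
MIN_BREEDS = 3


def rank_table(t_values: np.ndarray, snp_map: pd.DataFrame) -> np.ndarray:
    """Dense ordinal ranks of |t| (1 = largest), ties broken by genome order."""
    t_values = np.asarray(t_values, dtype=float)
    gorder = genome_order(snp_map)
    gpos = np.empty(len(t_values), dtype=int)
    gpos[gorder] = np.arange(len(t_values))
    order = np.lexsort((gpos, -t_values))
    ranks = np.empty(len(t_values), dtype=int)
    ranks[order] = np.arange(1, len(t_values) + 1)
    return ranks


def build_regions(across_ranks: np.ndarray, within_ranks: dict,
                  snp_map: pd.DataFrame, top_k: int = TOP_K,
                  gap_max: int = GAP_MAX,
                  max_span: int = MAX_SPAN) -> pd.DataFrame:
    """Seed, merge and extend QTL regions; returns one row per region.

    Columns: chrom, start, end, tag_snp, tag_pos, n_snps, n_top_k,
    rank_<breed> (minimum within-breed rank over SNPs in the interval)
    and rank_all (minimum across-breed rank).
    """
    if max_span < gap_max:
        raise ValueError("max_span must be >= gap_max")
    across_ranks = np.asarray(across_ranks)
    chrom_arr = snp_map["chrom"].to_numpy()
    pos_arr = snp_map["pos"].to_numpy()
    snp_ids = snp_map["snp_id"].to_numpy()
    breeds = list(within_ranks)
    within = {b: np.asarray(r) for b, r in within_ranks.items()}

    rows = []
    for chrom in pd.unique(chrom_arr):
        idx = np.flatnonzero(chrom_arr == chrom)
        pos = pos_arr[idx]
        seeds = idx[across_ranks[idx] <= top_k]
        if seeds.size == 0:
            continue
        spos = pos_arr[seeds]
        # merge seeds separated by at most gap_max
        brk = np.flatnonzero(np.diff(spos) > gap_max)
        groups = np.split(np.arange(seeds.size), brk + 1)
        hits = idx[np.any([within[b][idx] <= top_k for b in breeds], axis=0)] \
            if breeds else np.array([], dtype=int)
        hpos = pos_arr[hits]
        for grp in groups:
            start = int(spos[grp[0]])
            end = int(spos[grp[-1]])
            # grow outward to within-breed hits, one nearest hit at a time
            while True:
                left = hits[(hpos < start) & (start - hpos <= gap_max)
                            & (end - hpos <= max_span)]
                right = hits[(hpos > end) & (hpos - end <= gap_max)
                             & (hpos - start <= max_span)]
                cand = []
                if left.size:
                    cand.append(("L", left[-1], start - pos_arr[left[-1]]))
                if right.size:
                    cand.append(("R", right[0], pos_arr[right[0]] - end))
                if not cand:
                    break
                side, j, _ = min(cand, key=lambda c: (c[2], c[0]))
                if side == "L":
                    start = int(pos_arr[j])
                else:
                    end = int(pos_arr[j])
            rows.append((chrom, start, end))

    # merge overlapping regions on a chromosome, then summarize
    out = []
    rows.sort(key=lambda r: (str(r[0]), r[1]))
    merged = []
    for chrom, start, end in rows:
        if merged and merged[-1][0] == chrom and start <= merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], end)
        else:
            merged.append([chrom, start, end])
    for chrom, start, end in merged:
        inside = np.flatnonzero((chrom_arr == chrom) & (pos_arr >= start)
                                & (pos_arr <= end))
        tag = inside[np.argmin(across_ranks[inside])]
        rec = {
            "chrom": chrom, "start": start, "end": end,
            "tag_snp": snp_ids[tag], "tag_pos": int(pos_arr[tag]),
            "n_snps": int(inside.size),
            "n_top_k": int((across_ranks[inside] <= top_k).sum()),
        }
        for b in breeds:
            rec[f"rank_{b}"] = int(within[b][inside].min())
        rec["rank_all"] = int(across_ranks[inside].min())
        out.append(rec)
    return pd.DataFrame(out)


def _breed_rank_columns(regions: pd.DataFrame) -> list:
    return [c for c in regions.columns
            if c.startswith("rank_") and c != "rank_all"]


def detect_shared_qtl(regions: pd.DataFrame, threshold: int = RANK_THRESHOLD,
                      min_breeds: int = MIN_BREEDS) -> pd.DataFrame:
    """Keep regions supported by >= ``min_breeds`` breeds at the rank
    threshold; adds n_breeds_supporting and the supporting breed set."""
    if len(regions) == 0:
        out = regions.copy()
        out["n_breeds_supporting"] = pd.Series(dtype=int)
        out["supporting_breeds"] = pd.Series(dtype=object)
        return out
    cols = _breed_rank_columns(regions)
    support = (regions[cols] <= threshold)
    out = regions.copy()
    out["n_breeds_supporting"] = support.sum(axis=1)
    out["supporting_breeds"] = [
        ",".join(c.removeprefix("rank_") for c in cols if row[c])
        for _, row in support.iterrows()
    ]
    return out[out["n_breeds_supporting"] >= min_breeds].reset_index(drop=True)


def summarize_support(regions: pd.DataFrame,
                      threshold: int = RANK_THRESHOLD) -> dict:
    """Histogram of supporting-breed counts plus the count and mean of
    within-breed rank entries exceeding the threshold."""
    cols = _breed_rank_columns(regions)
    ranks = regions[cols].to_numpy()
    support = (ranks <= threshold).sum(axis=1)
    hist = {k: int((support == k).sum()) for k in range(len(cols) + 1)}
    over = ranks[ranks > threshold]
    mean_over = int(round(float(over.mean()))) if over.size else 0
    return {
        "support_counts": hist,
        "n_regions": int(len(regions)),
        "instances_over_threshold": int(over.size),
        "mean_rank_over_threshold": mean_over,
    }


def interval_span(start: int, end: int) -> int:
    """Span in bp as end - start (1-based printed-coordinate arithmetic)."""
    if start > end:
        raise ValueError("start must be <= end")
    return int(end) - int(start)


def span_kb(start: int, end: int) -> float:
    """Span in kb, to the nearest kb (one decimal below 100 kb)."""
    bp = interval_span(start, end)
    return round(bp / 1000, 1) if bp < 100_000 else float(round(bp / 1000))
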