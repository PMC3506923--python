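import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tenderqtl as tq
from tenderqtl.regions import (build_regions, detect_shared_qtl,
                               interval_span, rank_table, span_kb,
                               summarize_support)


def _map(chroms, positions):
    return pd.DataFrame({
        "snp_id": [f"s{i}" for i in range(len(chroms))],
        "chrom": chroms, "pos": positions,
        "unique": True,
    })


class TestRankTable:
    def test_ties_break_by_genome_position(self):
        m = _map(["1"] * 4, [1, 2, 3, 4])
        ranks = rank_table(np.array([0.5, 3.1, 3.1, 0.2]), m)
        assert list(ranks) == [3, 1, 2, 4]

    def test_distinct_values_rank_by_descending_t(self):
        m = _map(["1"] * 5, [10, 20, 30, 40, 50])
        t = np.array([0.1, 5.0, 2.0, 4.0, 3.0])
        assert list(rank_table(t, m)) == [5, 1, 4, 2, 3]

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(0, 100, allow_nan=False), min_size=1,
                    max_size=400))
    def test_ranks_are_a_permutation(self, values):
        m = _map(["1"] * len(values), list(range(1, len(values) + 1)))
        ranks = rank_table(np.array(values), m)
        assert sorted(ranks) == list(range(1, len(values) + 1))


class TestBuildRegions:
    def _ranks(self, n, top_positions):
        r = np.arange(n) + 1000
        for i, pos in enumerate(top_positions):
            r[pos] = i + 1
        return r

    def test_isolated_seed_gives_single_snp_region(self):
        m = _map(["1"] * 5, [1_000_000 * i for i in range(1, 6)])
        across = self._ranks(5, [2])
        within = {"A": np.full(5, 9999)}
        regions = build_regions(across, within, m, top_k=500,
                                gap_max=500_000, max_span=5_700_000)
        assert len(regions) == 1
        assert regions.loc[0, "start"] == regions.loc[0, "end"] == 3_000_000
        assert regions.loc[0, "n_snps"] == 1

    def test_seeds_beyond_gap_stay_separate(self):
        m = _map(["1"] * 2, [1_000_000, 7_000_000])
        across = np.array([1, 2])
        regions = build_regions(across, {"A": np.array([9999, 9999])}, m,
                                top_k=500, gap_max=1_000_000,
                                max_span=5_700_000)
        assert len(regions) == 2

    def test_region_extends_to_within_breed_hits_up_to_span_cap(self):
        pos = [1_000_000, 1_500_000, 2_000_000, 2_500_000, 9_000_000]
        m = _map(["1"] * 5, pos)
        across = self._ranks(5, [2])               # seed at 2.0 Mb
        within = {"A": np.array([400, 9999, 9999, 450, 9999])}
        regions = build_regions(across, within, m, top_k=500,
                                gap_max=1_000_000, max_span=5_700_000)
        assert len(regions) == 1
        assert regions.loc[0, "start"] == 1_000_000
        assert regions.loc[0, "end"] == 2_500_000
        assert regions.loc[0, "rank_A"] == 400

    def test_max_span_below_gap_rejected(self):
        m = _map(["1"], [1])
        with pytest.raises(ValueError):
            build_regions(np.array([1]), {}, m, top_k=500,
                          gap_max=2_000_000, max_span=1_000_000)


class TestDetectSharedQtl:
    def test_five_breed_support_row(self):
        t = tq.table2_fixture()
        row = t[t["start"] == 97_861_341]
        out = detect_shared_qtl(row, threshold=500, min_breeds=3)
        assert out.loc[0, "n_breeds_supporting"] == 5

    def test_three_breed_support_row(self):
        t = tq.table2_fixture()
        row = t[t["start"] == 155_725_361]
        out = detect_shared_qtl(row, threshold=500, min_breeds=3)
        assert out.loc[0, "n_breeds_supporting"] == 3
        assert out.loc[0, "supporting_breeds"] == \
            "hereford,limousin,simmental"

    def test_empty_table_passes_through(self):
        t = tq.table2_fixture().iloc[0:0]
        assert len(detect_shared_qtl(t)) == 0


class TestSummaries:
    def test_support_monotone_in_threshold(self):
        t = tq.table2_fixture()
        s500 = summarize_support(t, 500)["support_counts"]
        s999 = summarize_support(t, 999)["support_counts"]
        cum500 = np.cumsum([s500[k] for k in range(5, -1, -1)])
        cum999 = np.cumsum([s999[k] for k in range(5, -1, -1)])
        assert np.all(cum999 >= cum500)          # support only grows

    def test_instance_partition_identity(self):
        t = tq.table2_fixture()
        s = summarize_support(t, 500)
        n_under = (t[[c for c in t.columns if c.startswith("rank_")
                      and c != "rank_all"]] <= 500).to_numpy().sum()
        assert 5 * len(t) == n_under + s["instances_over_threshold"]


class TestIntervalSpan:
    @pytest.mark.parametrize("start,end,bp", [
        (44_062_694, 44_070_881, 8187),
        (97_861_341, 98_538_952, 677_611),
        (5, 5, 0),
    ])
    def test_bp_spans(self, start, end, bp):
        assert interval_span(start, end) == bp

    def test_kb_rounding_rules(self):
        assert span_kb(97_861_341, 98_538_952) == 678       # nearest kb
        assert span_kb(98_495_888, 98_579_574) == 83.7      # <100 kb: 1 dp
        assert span_kb(44_062_694, 44_070_881) == 8.2

    def test_reversed_interval_rejected(self):
        with pytest.raises(ValueError):
            interval_span(10, 5)


class TestRegionRecovery:
    def test_planted_qtl_yields_region_containing_causal(self):
        """A strong planted QTL should produce a detected region on its
        chromosome that contains the causal position."""
        found = 0
        for seed in range(3):
            cfg = tq.SimConfig(
                n_breeds=2, sires_per_breed=12, progeny_per_sire=25,
                n_snps=3000, n_x_snps=100,
                dense_regions=(("7", 96_500_000, 99_360_000, 30),),
                qtl_spec=None, default_qtl_var_frac=(0.05,),
                h2_per_breed=(0.4, 0.4), var_a_per_breed=(0.3, 0.3),
                dam_breed_index=(0, 1),
                founder_haplotypes=40, pool_generations=20,
                missing_rate=0.0, cg_sd=0.3, seed=seed)
            g, pheno, truth = tq.simulate_cohort(cfg)
            causal = truth.qtl.iloc[0]
            g2, _ = tq.apply_qc(g)
            ases = {}
            for label in ("all", "b1", "b2"):
                if label == "all":
                    gsub, psub = g2, pheno
                else:
                    b = cfg.breeds[int(label[1]) - 1]
                    gsub = g2.subset(animal_ids=list(
                        g2.animal_ids[g2.breed == b]))
                    psub = pheno[pheno["breed"] == b]
                grm = tq.regularize_grm(tq.build_grm(gsub), 0.01)
                spec, _ = tq.build_model_spec(psub, grm)
                fit = tq.fit_reml(spec)
                design = tq.marker_design(gsub)
                keep = [list(gsub.animal_ids).index(a)
                        for a in spec.animal_ids]
                design.M = design.M[keep]
                ases[label] = tq.backsolve_ase(fit, design, spec.grm,
                                               gsub.snp_map)
            m = g2.snp_map
            across = tq.rank_table(ases["all"]["t_stat"].to_numpy(), m)
            within = {b: tq.rank_table(ases[b]["t_stat"].to_numpy(), m)
                      for b in ("b1", "b2")}
            regions = tq.build_regions(across, within, m, top_k=150,
                                       gap_max=1_000_000,
                                       max_span=5_700_000)
            on_chrom = regions[(regions["chrom"] == "7")
                               & (regions["start"] <= causal["pos"])
                               & (regions["end"] >= causal["pos"])]
            found += len(on_chrom) > 0
        assert found >= 2
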