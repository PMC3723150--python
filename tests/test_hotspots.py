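import numpy as np
import pytest

from mirtarnet.hotspots import (HotspotParams, find_hotspots, hotspot_summary,
                                hotspots_to_frame)

from _oracles import brute_force_hotspots
from conftest import make_site, make_table


def random_table(rng, n_sites=20, n_genes=2, n_mirnas=5, span=200):
    sites = []
    for _ in range(n_sites):
        start = int(rng.integers(1, span))
        sites.append(make_site(
            gene=f"g{rng.integers(n_genes)}",
            mirna=f"hsa-miR-{rng.integers(n_mirnas)}",
            start=start, end=start + 21,
            region=["utr5", "cds", "utr3"][rng.integers(3)]))
    return make_table(sites)


class TestFindHotspots:
    def test_textbook_cluster(self):
        table = make_table([
            make_site(mirna="hsa-miR-1", start=100, end=121),
            make_site(mirna="hsa-miR-2", start=105, end=126),
            make_site(mirna="hsa-miR-3", start=108, end=129)])
        hs = find_hotspots(table)
        assert len(hs) == 1
        assert hs[0].span[0] == 100
        assert len(hs[0].mirnas) == 3

    def test_distinct_mirna_requirement(self):
        table = make_table([
            make_site(mirna="hsa-miR-1", start=100, end=121),
            make_site(mirna="hsa-miR-2", start=105, end=126),
            make_site(mirna="hsa-miR-1", start=108, end=129)])
        assert find_hotspots(table) == []

    def test_window_break_splits_chains(self):
        table = make_table(
            [make_site(mirna=f"hsa-miR-{i}", start=100 + 5 * i, end=121 + 5 * i)
             for i in range(3)]
            + [make_site(mirna=f"hsa-miR-{i}", start=300 + 5 * i, end=321 + 5 * i)
               for i in range(3)])
        hs = find_hotspots(table)
        assert [h.span[0] for h in hs] == [100, 300]

    def test_region_boundaries_not_crossed(self):
        table = make_table([
            make_site(mirna="hsa-miR-1", start=95, end=116, region="utr5"),
            make_site(mirna="hsa-miR-2", start=101, end=122, region="cds"),
            make_site(mirna="hsa-miR-3", start=104, end=125, region="cds")])
        assert find_hotspots(table) == []

    def test_unannotated_rejected(self):
        with pytest.raises(ValueError, match="annotated"):
            find_hotspots(make_table([make_site(region="unassigned")]))

    def test_non_miranda_tiers_ignored_by_default(self):
        table = make_table([
            make_site(mirna=f"hsa-miR-{i}", tool="targetscan",
                      start=100 + i, end=106 + i) for i in range(3)])
        assert find_hotspots(table) == []
        assert len(find_hotspots(table, tool="targetscan")) == 1

    @pytest.mark.parametrize("seed", range(40))
    def test_oracle_equivalence_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        table = random_table(rng, n_sites=int(rng.integers(5, 31)))
        params = HotspotParams()
        found = {frozenset(s.key for s in h.sites)
                 for h in find_hotspots(table, params)}
        expected = brute_force_hotspots(list(table), params.min_mirnas,
                                        params.start_window)
        assert found == expected

    def test_monotone_in_window_and_min_mirnas(self):
        rng = np.random.default_rng(77)
        table = random_table(rng, n_sites=60, n_mirnas=8)
        for window_pair in [(20, 10), (10, 5), (5, 0)]:
            big = len(find_hotspots(table, HotspotParams(start_window=window_pair[0])))
            small = len(find_hotspots(table, HotspotParams(start_window=window_pair[1])))
            assert small <= big
        for k_pair in [(2, 3), (3, 4)]:
            low = len(find_hotspots(table, HotspotParams(min_mirnas=k_pair[0])))
            high = len(find_hotspots(table, HotspotParams(min_mirnas=k_pair[1])))
            assert high <= low

    def test_chains_are_disjoint(self):
        rng = np.random.default_rng(5)
        table = random_table(rng, n_sites=80, n_mirnas=10)
        seen = set()
        for h in find_hotspots(table, HotspotParams(min_mirnas=2)):
            keys = {(s.key, s.region) for s in h.sites}
            assert not keys & seen
            seen |= keys

    def test_interval_overlap_rule(self):
        # starts 30 apart never chain under the start rule but their long
        # intervals overlap by >= 10 nt
        table = make_table([
            make_site(mirna="hsa-miR-1", start=100, end=160),
            make_site(mirna="hsa-miR-2", start=130, end=190),
            make_site(mirna="hsa-miR-3", start=155, end=220)])
        assert find_hotspots(table) == []
        hs = find_hotspots(table, HotspotParams(rule="interval-overlap"))
        assert len(hs) == 1 and len(hs[0].sites) == 3


class TestSummary:
    def test_empty(self):
        df = hotspot_summary([])
        assert list(df["n_hotspots"]) == [0]

    def test_two_hotspots_one_gene(self):
        table = make_table(
            [make_site(mirna=f"hsa-miR-{i}", start=100 + 3 * i, end=121 + 3 * i,
                       region="cds") for i in range(3)]
            + [make_site(mirna=f"hsa-miR-{i}", start=450 + 3 * i, end=471 + 3 * i,
                         region="utr3") for i in range(3)])
        hs = find_hotspots(table)
        df = hotspot_summary(hs)
        per_gene = df[df["gene_id"] == "g1"]
        assert per_gene["n_hotspots"].sum() == 2
        assert set(per_gene["region"]) == {"cds", "utr3"}
        assert df[df["gene_id"] == "TOTAL"]["n_hotspots"].iloc[0] == len(hs) == 2

    def test_frame_columns(self):
        df = hotspots_to_frame([])
        assert list(df.columns)[:4] == ["gene_id", "region", "span_start", "span_end"]


class TestParams:
    def test_validation(self):
        with pytest.raises(ValueError):
            HotspotParams(min_mirnas=1)
        with pytest.raises(ValueError):
            HotspotParams(start_window=-1)
        with pytest.raises(ValueError):
            HotspotParams(rule="clique")
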