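import numpy as np
import pytest

from mirtarnet.io import load_fixture, site_table_to_frame
from mirtarnet.regions import annotate_table
from mirtarnet.scanner import scan_many
from mirtarnet.simulate import (HotspotSpec, SynthConfig, SynthConfigError,
                                generate_dataset, study_scale_config, revcomp)


def tiny_config(seed, **kw):
    defaults = dict(seed=seed, n_genes=2, site_count_lambda=0.3,
                    mirna_groups=[(("midbrain",), 3)], n_decoy_targetscan=0)
    defaults.update(kw)
    return SynthConfig(**defaults)


class TestGenerateDataset:
    def test_single_planted_site_recovered(self):
        cfg = SynthConfig(seed=1, n_genes=1, mirna_groups=[(("midbrain",), 1)],
                          site_counts={"SYNG01": {"syn-miR-001": 1}},
                          n_decoy_targetscan=0)
        ds = generate_dataset(cfg)
        assert len(ds.tables["miranda"]) == 1
        scanned = scan_many(ds.genes, ds.mirnas)
        assert [(s.start, s.end) for s in scanned] == \
            [(s.start, s.end) for s in ds.truth.sites]

    def test_same_seed_byte_identical(self):
        a = generate_dataset(tiny_config(9, n_two_way=1))
        b = generate_dataset(tiny_config(9, n_two_way=1))
        assert [g.sequence for g in a.genes] == [g.sequence for g in b.genes]
        for tool in a.tables:
            assert site_table_to_frame(a.tables[tool]).equals(
                site_table_to_frame(b.tables[tool]))

    def test_different_seeds_differ(self):
        a = generate_dataset(tiny_config(9))
        b = generate_dataset(tiny_config(10))
        assert [g.sequence for g in a.genes] != [g.sequence for g in b.genes]

    def test_planted_sites_are_exact_complements(self, small_dataset):
        ds = small_dataset
        seqs = {m.mirna_id: m.sequence for m in ds.mirnas}
        genes = {g.gene_id: g.sequence for g in ds.genes}
        for s in ds.truth.sites:
            assert genes[s.gene_id][s.start - 1:s.end] == revcomp(seqs[s.mirna_id])

    def test_fixture_counts_reproduced(self):
        fixture = load_fixture("table1_matrix")
        mirna_ids = [f"syn-miR-{i + 1:03d}" for i in range(11)]
        cfg = SynthConfig(
            seed=4, n_genes=35, utr5_len=300, cds_len=600, utr3_len=400,
            mirna_groups=[(("midbrain",), 11)],
            site_counts={f"SYNG{i + 1:02d}": dict(zip(mirna_ids, row))
                         for i, row in enumerate(fixture.counts.values)},
            n_decoy_targetscan=0)
        ds = generate_dataset(cfg)
        assert (ds.truth.matrix.counts.values == fixture.counts.values).all()
        assert ds.truth.matrix.grand_total() == 393
        # and the scanner recovers exactly the planted counts
        scanned = scan_many(ds.genes, ds.mirnas)
        from mirtarnet.stats import build_matrix
        m = build_matrix(scanned, list(ds.truth.matrix.counts.index),
                         list(ds.truth.matrix.counts.columns))
        assert m.counts.equals(ds.truth.matrix.counts)

    def test_infeasible_plant_rejected(self):
        with pytest.raises(SynthConfigError, match="exceed"):
            generate_dataset(SynthConfig(
                seed=2, n_genes=1, utr5_len=60, cds_len=60, utr3_len=60,
                mirna_groups=[(("midbrain",), 1)],
                site_counts={"SYNG01": {"syn-miR-001": 12}}))

    def test_too_many_consensus_rejected(self):
        with pytest.raises(SynthConfigError, match="consensus"):
            generate_dataset(tiny_config(3, site_count_lambda=0.0, n_two_way=5))

    def test_hotspot_members_derived_from_stretch(self, small_dataset):
        ds = small_dataset
        for truth in ds.truth.hotspots:
            starts = truth["starts"]
            assert all(0 < b - a <= 10 for a, b in zip(starts, starts[1:]))
            assert len(truth["mirnas"]) >= 3

    def test_background_has_no_extra_seed_hits(self, small_dataset):
        # by construction: a full rescan finds the planted sites and nothing else
        ds = small_dataset
        scanned = annotate_table(scan_many(ds.genes, ds.mirnas), ds.genes)
        got = {(s.gene_id, s.mirna_id, s.start, s.end) for s in scanned}
        want = {(s.gene_id, s.mirna_id, s.start, s.end) for s in ds.truth.sites}
        assert got == want


class TestConfig:
    def test_seed_mandatory(self):
        with pytest.raises(TypeError):
            SynthConfig()

    def test_validation(self):
        with pytest.raises(SynthConfigError):
            SynthConfig(seed=1, mirna_groups=[(("cortex",), 3)])
        with pytest.raises(SynthConfigError):
            SynthConfig(seed=1, mirna_length=40)
        with pytest.raises(SynthConfigError):
            HotspotSpec(gene=0, n_mirnas=1)
        with pytest.raises(SynthConfigError):
            HotspotSpec(gene=0, start_offsets=[3, 6])

    def test_yaml_round_trip(self, tmp_path):
        cfg = tiny_config(5, hotspot_specs=[HotspotSpec(gene=0, region="cds")],
                          n_two_way=1)
        p = tmp_path / "cfg.yaml"
        cfg.to_yaml(p)
        back = SynthConfig.from_yaml(p)
        assert back.seed == cfg.seed
        assert back.mirna_groups == cfg.mirna_groups
        assert back.hotspot_specs[0].region == "cds"
        assert generate_dataset(back).truth.matrix.counts.equals(
            generate_dataset(cfg).truth.matrix.counts)


class TestPaperScaleConfig:
    def test_gene_and_pool_counts(self):
        cfg = study_scale_config(seed=1)
        assert cfg.n_genes == 35
        totals = {r: 0 for r in ("midbrain", "cerebellum", "hippocampus",
                                 "frontal_cortex")}
        exclusive = {}
        for regions, count in cfg.mirna_groups:
            for r in regions:
                totals[r] += count
            if len(regions) == 1:
                exclusive[regions[0]] = count
        assert totals == {"cerebellum": 62, "hippocampus": 93,
                          "midbrain": 112, "frontal_cortex": 105}
        assert exclusive == {"midbrain": 23, "hippocampus": 17,
                             "frontal_cortex": 14, "cerebellum": 4}

    def test_planted_consensus_mirrors_study_counts(self):
        cfg = study_scale_config(seed=1)
        assert cfg.n_two_way + cfg.n_three_way == 48
        assert cfg.n_three_way == 11
        assert len(cfg.hotspot_specs) == 11


class TestPartialComplementPlants:
    def test_mismatched_plant_scores_lower(self):
        rng = np.random.default_rng(12)
        mir = "".join(rng.choice(list("ACGU"), size=22))
        site = list(revcomp(mir))
        # two non-seed mismatches (gene positions pairing miRNA 10 and 12)
        for mpos in (10, 12):
            gpos = 22 - mpos  # 0-based within site
            site[gpos] = {"A": "C", "C": "A", "G": "A", "U": "C"}[mir[mpos - 1]]
        from mirtarnet.scanner import align_duplex
        full = align_duplex(mir, revcomp(mir))
        partial = align_duplex(mir, "".join(site).replace("U", "T"))
        assert partial.raw_score < full.raw_score
        assert partial.raw_score >= full.raw_score - 2 * 8  # 2 x (match - mismatch)
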