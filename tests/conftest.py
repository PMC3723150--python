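import numpy as np
import pytest

from mirtarnet.models import GeneModel, SiteTable, TargetSite
from mirtarnet.simulate import HotspotSpec, SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def table1():
    from mirtarnet.io import load_fixture
    return load_fixture("table1_matrix")


@pytest.fixture(scope="session")
def table3():
    from mirtarnet.io import load_fixture
    return load_fixture("table3_sites")


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def toy_gene():
    rng = np.random.default_rng(7)
    seq = "".join(rng.choice(list("ACGT"), size=500))
    return GeneModel(gene_id="g1", symbol="G1", sequence=seq,
                     cds_start=101, cds_end=400)


@pytest.fixture(scope="session")
def small_dataset():
    """One seeded synthetic dataset exercised by several test modules."""
    cfg = SynthConfig(
        seed=42, n_genes=5, site_count_lambda=0.5,
        mirna_groups=[(("midbrain",), 4), (("midbrain", "cerebellum"), 3)],
        hotspot_specs=[HotspotSpec(gene=0, region="cds"),
                       HotspotSpec(gene=1, region="utr3", n_mirnas=4)],
        n_two_way=3, n_three_way=2)
    return generate_dataset(cfg)


def make_site(gene="g1", mirna="hsa-miR-1", tool="miranda", start=1, end=22,
              region="cds", **kw):
    return TargetSite(gene_id=gene, mirna_id=mirna, tool=tool, start=start,
                      end=end, region=region, **kw)


def make_table(sites, provenance="test"):
    return SiteTable(list(sites), provenance)
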