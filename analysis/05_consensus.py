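#!/usr/bin/env python
"""Cross-algorithm consensus, on the published coordinate pairs and on the
synthetic tool tables.

Every one of the 28 published miRanda/TargetScan coordinate pairs
satisfies the containment rule (the 7-mer seed interval lies inside the
alignment interval); on the synthetic side the planted 48 two-tool and 11
three-tool agreements are recovered from the scanned sites.
"""
from pathlib import Path

from mirtarnet import io as mio
from mirtarnet.consensus import (consensus_to_frame, intersect_tables,
                                 match_pair, venn_to_frame)

BASE = Path(__file__).resolve().parent.parent / "results"


def main():
    t3 = mio.load_fixture("table3_sites")
    recs = t3.records
    pairs = list(zip(recs[::2], recs[1::2]))
    n_match = sum(match_pair(a, b) for a, b in pairs)
    deduped, dropped = t3.deduplicate()
    records, _ = intersect_tables({"miranda": deduped.by_tool("miranda"),
                                   "targetscan": deduped.by_tool("targetscan")})
    consensus_to_frame(records).to_csv(BASE / "table3_consensus.tsv", sep="\t",
                                       index=False)
    print(f"published pairs: {n_match}/{len(pairs)} match by containment; "
          f"{dropped} duplicated rows dropped -> {len(records)} unique records")

    sim = BASE / "synthetic"
    tables = {"miranda": mio.read_site_table(BASE / "sites.annotated.tsv"),
              "targetscan": mio.read_site_table(sim / "sites.targetscan.tsv"),
              "pictar": mio.read_site_table(sim / "sites.pictar.tsv")}
    records, venn = intersect_tables(tables)
    consensus_to_frame(records).to_csv(BASE / "consensus.tsv", sep="\t",
                                       index=False)
    venn_to_frame(venn).to_csv(BASE / "venn.tsv", sep="\t", index=False)
    mt = sum(v for k, v in venn.items() if {"miranda", "targetscan"} <= k)
    three = venn[frozenset({"miranda", "targetscan", "pictar"})]
    print(f"synthetic: miranda-targetscan common {mt}, three-way {three} "
          f"(planted: 48 and 11)")


if __name__ == "__main__":
    main()
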