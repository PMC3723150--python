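"""Hotspot detection: stretches of a gene targeted by several distinct miRNAs.

A hotspot is a maximal single-linkage chain of sites (within one gene and
one region) whose consecutive sorted start positions differ by at most
``start_window`` nucleotides and which collects at least ``min_mirnas``
distinct miRNAs.  An alternate rule links sites by pairwise interval
overlap of at least ``start_window`` nucleotides.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .models import UNASSIGNED, SiteTable, TargetSite

RULES = ("start-window", "interval-overlap")


@dataclass
class HotspotParams:
    min_mirnas: int = 3
    start_window: int = 10
    rule: str = "start-window"

    def __post_init__(self):
        if self.min_mirnas < 2:
            raise ValueError("min_mirnas must be >= 2")
        if self.start_window < 0:
            raise ValueError("start_window must be >= 0")
        if self.rule not in RULES:
            raise ValueError(f"rule must be one of {RULES}")


@dataclass
class Hotspot:
    gene_id: str
    region: str
    sites: list[TargetSite] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        return (min(s.start for s in self.sites), max(s.end for s in self.sites))

    @property
    def mirnas(self) -> frozenset[str]:
        return frozenset(s.mirna_id for s in self.sites)


def _linked(a: TargetSite, b: TargetSite, params: HotspotParams) -> bool:
    if params.rule == "start-window":
        return abs(a.start - b.start) <= params.start_window
    inter = min(a.end, b.end) - max(a.start, b.start) + 1
    return inter >= params.start_window


def find_hotspots(table: SiteTable, params: HotspotParams | None = None,
                  tool: str = "miranda") -> list[Hotspot]:
    """Single-linkage chained hotspots per (gene, region) for one tool tier.

    Sites must be region-annotated.  Output is sorted by (gene, region,
    span start); chains with fewer than ``min_mirnas`` distinct miRNAs are
    discarded.
    """
    params = params or HotspotParams()
    sites = [s for s in table if s.tool == tool]
    if any(s.region == UNASSIGNED for s in sites):
        raise ValueError("sites must be region-annotated before hotspot detection")
    by_group: dict[tuple[str, str], list[TargetSite]] = {}
    for s in sites:
        by_group.setdefault((s.gene_id, s.region), []).append(s)
    hotspots = []
    for (gene_id, region), members in by_group.items():
        members.sort(key=lambda s: (s.start, s.end, s.mirna_id))
        # single-linkage components via union-find over linked pairs; for
        # the start-window rule on sorted starts this coincides with
        # consecutive-difference chaining
        parent = list(range(len(members)))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                if _linked(members[a], members[b], params):
                    ra, rb = find(a), find(b)
                    if ra != rb:
                        parent[rb] = ra
        chains: dict[int, list[TargetSite]] = {}
        for idx, s in enumerate(members):
            chains.setdefault(find(idx), []).append(s)
        for chain in chains.values():
            if len({c.mirna_id for c in chain}) >= params.min_mirnas:
                hotspots.append(Hotspot(gene_id, region, chain))
    hotspots.sort(key=lambda h: (h.gene_id, h.region, h.span[0]))
    return hotspots


def hotspot_summary(hotspots) -> pd.DataFrame:
    """Hotspot counts per (gene, region) with a grand-total row."""
    counts: dict[tuple[str, str], int] = {}
    for h in hotspots:
        counts[(h.gene_id, h.region)] = counts.get((h.gene_id, h.region), 0) + 1
    rows = [{"gene_id": g, "region": r, "n_hotspots": n}
            for (g, r), n in sorted(counts.items())]
    rows.append({"gene_id": "TOTAL", "region": "", "n_hotspots": len(list(hotspots))})
    return pd.DataFrame(rows, columns=["gene_id", "region", "n_hotspots"])


def hotspots_to_frame(hotspots) -> pd.DataFrame:
    rows = []
    for h in hotspots:
        rows.append({
            "gene_id": h.gene_id, "region": h.region,
            "span_start": h.span[0], "span_end": h.span[1],
            "n_sites": len(h.sites), "n_mirnas": len(h.mirnas),
            "mirnas": ";".join(sorted(h.mirnas)),
        })
    return pd.DataFrame(rows, columns=["gene_id", "region", "span_start", "span_end",
                                       "n_sites", "n_mirnas", "mirnas"])
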