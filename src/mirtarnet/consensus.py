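"""Cross-algorithm consensus of target predictions.

Two sites from different tools agree when they are for the same
(gene, miRNA) and their intervals are compatible: in ``containment`` mode
the shorter interval must lie inside the longer one (the typical
relationship between a seed-match 7-mer and a full alignment interval); in
``overlap`` mode the intersection must reach ``min_overlap`` nucleotides.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd

from .models import VALID_TOOLS, SiteTable, TargetSite

MODES = ("containment", "overlap")
#: default minimum overlap: the canonical seed-match length.
DEFAULT_MIN_OVERLAP = 7


@dataclass
class ConsensusRecord:
    gene_id: str
    mirna_id: str
    sites: dict[str, TargetSite]

    @property
    def tools_agreeing(self) -> frozenset[str]:
        return frozenset(self.sites)


def _overlap(a: TargetSite, b: TargetSite) -> int:
    return min(a.end, b.end) - max(a.start, b.start) + 1


def match_pair(a: TargetSite, b: TargetSite, mode: str = "containment",
               min_overlap: int = DEFAULT_MIN_OVERLAP) -> bool:
    """Do two sites from different tools report the same target site?"""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if a.tool == b.tool:
        raise ValueError("match_pair compares sites from different tools")
    if a.gene_id != b.gene_id or a.mirna_id != b.mirna_id:
        return False
    if mode == "containment":
        shorter, longer = sorted((a, b), key=lambda s: s.span)
        return longer.start <= shorter.start and shorter.end <= longer.end
    return _overlap(a, b) >= min_overlap


def intersect_tables(tables: dict[str, SiteTable], mode: str = "containment",
                     min_overlap: int = DEFAULT_MIN_OVERLAP,
                     region: str | None = "utr3",
                     ) -> tuple[list[ConsensusRecord], dict[frozenset, int]]:
    """Match sites across tools; return consensus records and Venn counts.

    ``tables`` maps tool name to its site table.  By default only
    3'UTR-region sites enter the comparison (``region=None`` widens to
    all).  Within each tool pair, matching is one-to-one: candidate pairs
    are ranked by intersection length (largest first, ties to the smaller
    start) and greedily accepted while both sites are unclaimed.  Matched
    sites merge into records via connected components; the Venn counts map
    each non-empty tool subset to its number of records (singleton subsets
    count each tool's unmatched sites).
    """
    if len(tables) < 2:
        raise ValueError("need site tables from at least two tools")
    for tool in tables:
        if tool not in VALID_TOOLS:
            raise ValueError(f"unknown tool {tool!r}")
    pool: list[tuple[str, TargetSite]] = []
    for tool, table in tables.items():
        for s in table:
            if s.tool != tool:
                raise ValueError(f"site with tool {s.tool!r} in the {tool!r} table")
            if region is None or s.region == region:
                pool.append((tool, s))
    index = {id(s): k for k, (_, s) in enumerate(pool)}
    parent = list(range(len(pool)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    matched: set[int] = set()
    for tool_a, tool_b in combinations(sorted(tables), 2):
        sites_a = [s for t, s in pool if t == tool_a]
        sites_b = [s for t, s in pool if t == tool_b]
        candidates = []
        for a in sites_a:
            for b in sites_b:
                if match_pair(a, b, mode, min_overlap):
                    candidates.append((-_overlap(a, b), a.start, b.start, a, b))
        candidates.sort(key=lambda c: c[:3])
        claimed_a: set[int] = set()
        claimed_b: set[int] = set()
        for _, _, _, a, b in candidates:
            if id(a) in claimed_a or id(b) in claimed_b:
                continue
            claimed_a.add(id(a))
            claimed_b.add(id(b))
            ka, kb = index[id(a)], index[id(b)]
            ra, rb = find(ka), find(kb)
            if ra != rb:
                parent[rb] = ra
            matched.update((ka, kb))
    components: dict[int, list[int]] = {}
    for k in range(len(pool)):
        components.setdefault(find(k), []).append(k)
    records: list[ConsensusRecord] = []
    venn: dict[frozenset, int] = {}
    for tool in tables:
        venn[frozenset([tool])] = 0
    for pair in combinations(sorted(tables), 2):
        venn[frozenset(pair)] = 0
    if len(tables) >= 3:
        for triple in combinations(sorted(tables), 3):
            venn[frozenset(triple)] = 0
    for comp in components.values():
        tools = frozenset(pool[k][0] for k in comp)
        if len(comp) == 1 and comp[0] not in matched:
            venn[tools] += 1
            continue
        sites: dict[str, TargetSite] = {}
        for k in sorted(comp, key=lambda k: (pool[k][1].start, pool[k][1].end)):
            sites.setdefault(pool[k][0], pool[k][1])
        first = pool[comp[0]][1]
        records.append(ConsensusRecord(first.gene_id, first.mirna_id, sites))
        venn[frozenset(sites)] += 1
    records.sort(key=lambda r: (r.gene_id, r.mirna_id,
                                min(s.start for s in r.sites.values())))
    return records, venn


def consensus_to_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"gene_id": r.gene_id, "mirna_id": r.mirna_id,
               "tools_agreeing": ";".join(sorted(r.tools_agreeing))}
        for tool in VALID_TOOLS:
            site = r.sites.get(tool)
            row[f"{tool}_start"] = site.start if site else None
            row[f"{tool}_end"] = site.end if site else None
        rows.append(row)
    cols = ["gene_id", "mirna_id", "tools_agreeing"]
    for tool in VALID_TOOLS:
        cols += [f"{tool}_start", f"{tool}_end"]
    return pd.DataFrame(rows, columns=cols)


def venn_to_frame(venn: dict[frozenset, int]) -> pd.DataFrame:
    rows = [{"tools": ";".join(sorted(k)), "n_tools": len(k), "count": v}
            for k, v in venn.items()]
    rows.sort(key=lambda r: (r["n_tools"], r["tools"]))
    return pd.DataFrame(rows, columns=["tools", "n_tools", "count"])
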