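"""Assign target sites to 5'UTR / CDS / 3'UTR and tabulate region distributions.

A site spanning a region boundary takes the region of its start coordinate,
which keeps per-region tallies a clean partition of the site table.
"""
from __future__ import annotations

import pandas as pd

from .models import REGIONS, UNASSIGNED, GeneModel, SiteTable, TargetSite


def assign_region(site: TargetSite, gene: GeneModel) -> TargetSite:
    """Return the site with its region set from the gene model (idempotent)."""
    if site.gene_id != gene.gene_id:
        raise ValueError(f"site gene {site.gene_id!r} != gene model {gene.gene_id!r}")
    if not (1 <= site.start and site.end <= gene.length):
        raise ValueError(f"site [{site.start}, {site.end}] outside gene "
                         f"{gene.gene_id} bounds [1, {gene.length}]")
    return site.with_region(gene.region_of(site.start))


def annotate_table(table: SiteTable, genes) -> SiteTable:
    """Assign regions to every site; genes may be a list or id->GeneModel dict."""
    gene_map = genes if isinstance(genes, dict) else {g.gene_id: g for g in genes}
    out = []
    for site in table:
        gene = gene_map.get(site.gene_id)
        if gene is None:
            raise KeyError(f"no gene model for {site.gene_id!r}")
        out.append(assign_region(site, gene))
    return SiteTable(out, table.provenance)


def region_distribution(table: SiteTable, mirnas=None,
                        group_by: str | None = None) -> pd.DataFrame:
    """Site counts per region, optionally stratified by miRNA expression region.

    With ``group_by='expression_region'`` a site is counted once for every
    brain region its miRNA is expressed in, so the stratified total can
    exceed the plain one; ``mirnas`` must then be provided.  Unannotated
    sites are an error: run :func:`annotate_table` first.
    """
    unassigned = sum(1 for s in table if s.region == UNASSIGNED)
    if unassigned:
        raise ValueError(f"{unassigned} site(s) have no region; run assign_region/"
                         "annotate_table first")
    if group_by is None:
        counts = {r: 0 for r in REGIONS}
        for s in table:
            counts[s.region] += 1
        return pd.DataFrame([{"group": "all", "region": r, "n_sites": counts[r]}
                             for r in REGIONS])
    if group_by != "expression_region":
        raise ValueError("group_by must be None or 'expression_region'")
    if mirnas is None:
        raise ValueError("stratified counts need the miRNA collection")
    expr = {m.mirna_id: m.expression_regions for m in mirnas}
    rows: dict[tuple[str, str], int] = {}
    for s in table:
        for grp in sorted(expr.get(s.mirna_id, frozenset())):
            rows[(grp, s.region)] = rows.get((grp, s.region), 0) + 1
    groups = sorted({g for g, _ in rows})
    return pd.DataFrame([{"group": g, "region": r, "n_sites": rows.get((g, r), 0)}
                         for g in groups for r in REGIONS])
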