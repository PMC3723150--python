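"""Gene x miRNA interaction counts: multiplicity, cooperativity, top-K ranking.

Multiplicity is the property of one miRNA targeting several genes (measured
as its total site count and the number of distinct genes hit); cooperativity
is the converse property of one gene being targeted by several miRNAs.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .models import SiteTable, normalize_mirna_id


@dataclass
class InteractionMatrix:
    """Non-negative integer site counts with genes as rows, miRNAs as columns.

    ``aliases`` maps alternate gene labels to the row label actually present
    (and vice versa), so lookups survive label drift between table sources.
    """
    counts: pd.DataFrame
    aliases: dict[str, str] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise ValueError("duplicate gene or miRNA identifiers in matrix")
        if (self.counts.values < 0).any():
            raise ValueError("interaction counts must be non-negative")
        self.counts = self.counts.astype(int)

    # -- label resolution ---------------------------------------------------
    def resolve_gene(self, gene_id: str) -> str:
        if gene_id in self.counts.index:
            return gene_id
        alias = self.aliases.get(gene_id)
        if alias is not None and alias in self.counts.index:
            return alias
        raise KeyError(f"gene {gene_id!r} not in matrix (and no alias matches)")

    def resolve_mirna(self, mirna_id: str) -> str:
        mid = normalize_mirna_id(mirna_id)
        if mid in self.counts.columns:
            return mid
        raise KeyError(f"miRNA {mirna_id!r} not in matrix")

    # -- statistics -----------------------------------------------------------
    def grand_total(self) -> int:
        return int(self.counts.values.sum())

    def multiplicity(self, mirna_id: str) -> tuple[int, int]:
        """(total sites, distinct genes hit) for one miRNA column."""
        col = self.counts[self.resolve_mirna(mirna_id)]
        return int(col.sum()), int((col > 0).sum())

    def cooperativity(self, gene_id: str, mirna_subset=None) -> tuple[int, int]:
        """(total sites, distinct miRNAs hitting) for one gene row.

        ``mirna_subset`` restricts the tally to the given columns; the
        default uses every column.
        """
        row = self.counts.loc[self.resolve_gene(gene_id)]
        if mirna_subset is not None:
            cols = [self.resolve_mirna(m) for m in mirna_subset]
            row = row[cols]
        return int(row.sum()), int((row > 0).sum())

    def top_k_mirnas(self, k: int) -> list[str]:
        """miRNAs ranked by total sites desc, genes hit desc, then id asc."""
        if k < 1:
            raise ValueError("k must be >= 1")
        ranking = sorted(
            self.counts.columns,
            key=lambda m: (-int(self.counts[m].sum()),
                           -int((self.counts[m] > 0).sum()), m))
        return ranking[: min(k, len(ranking))]

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path, aliases=None) -> "InteractionMatrix":
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        df.columns = [normalize_mirna_id(c) for c in df.columns]
        return cls(df, aliases=dict(aliases or {}))


def build_matrix(table: SiteTable, genes, mirnas) -> InteractionMatrix:
    """Count sites per (gene, miRNA) cell over the given row/column orders.

    Genes or miRNAs absent from the table get all-zero rows/columns; a site
    referencing an id outside the provided lists is an error (all offenders
    are listed).
    """
    genes = list(genes)
    mirnas = [normalize_mirna_id(m) for m in mirnas]
    gene_set, mirna_set = set(genes), set(mirnas)
    offenders = sorted(
        {f"gene {r.gene_id!r}" for r in table if r.gene_id not in gene_set}
        | {f"miRNA {r.mirna_id!r}" for r in table if r.mirna_id not in mirna_set})
    if offenders:
        raise ValueError("sites reference ids outside the provided lists: "
                         + ", ".join(offenders))
    counts = pd.DataFrame(0, index=pd.Index(genes, name="gene_id"), columns=mirnas)
    for rec in table:
        counts.loc[rec.gene_id, rec.mirna_id] += 1
    return InteractionMatrix(counts)


def multiplicity_table(matrix: InteractionMatrix) -> pd.DataFrame:
    """Per-miRNA summary (total_sites, genes_hit), ranked as top_k_mirnas."""
    order = matrix.top_k_mirnas(len(matrix.counts.columns))
    rows = []
    for m in order:
        total, hit = matrix.multiplicity(m)
        rows.append({"mirna_id": m, "total_sites": total, "genes_hit": hit})
    return pd.DataFrame(rows)


def cooperativity_table(matrix: InteractionMatrix, mirna_subset=None) -> pd.DataFrame:
    """Per-gene summary (total_sites, mirnas_hitting) in matrix row order."""
    rows = []
    for g in matrix.counts.index:
        total, hitting = matrix.cooperativity(g, mirna_subset)
        rows.append({"gene_id": g, "total_sites": total, "mirnas_hitting": hitting})
    return pd.DataFrame(rows)
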