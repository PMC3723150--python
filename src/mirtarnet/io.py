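"""Readers/writers for FASTA, gene-model and site-table TSVs, plus packaged fixtures.

All TSVs are UTF-8, tab-delimited, with a mandatory header row.  The site
table schema is: gene_id, mirna_id, tool, start, end and the optional
columns region, score, energy.
"""
from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (
    REGIONS, UNASSIGNED, VALID_TOOLS,
    GeneModel, MatureMiRNA, SiteTable, TargetSite, normalize_mirna_id,
)

log = logging.getLogger(__name__)

#: The transcribed interaction-count table prints one row as "SOD2" while the
#: accompanying gene list contains SOD1 only; statistics resolve either label.
GENE_ALIASES = {"SOD1": "SOD2", "SOD2": "SOD1"}

SITE_COLUMNS = ["gene_id", "mirna_id", "tool", "start", "end", "region", "score", "energy"]
_REQUIRED_SITE_COLUMNS = ["gene_id", "mirna_id", "tool", "start", "end"]


class FastaParseError(ValueError):
    pass


def _validate_fasta_text(path) -> None:
    """Reject FASTA files with headerless leading content or empty records."""
    last_header_line = None
    have_seq = False
    seen_any = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                if stripped == ">":
                    raise FastaParseError(f"{path}: empty FASTA header at line {lineno}")
                if last_header_line is not None and not have_seq:
                    raise FastaParseError(
                        f"{path}: record starting at line {last_header_line} has no sequence")
                last_header_line = lineno
                have_seq = False
                seen_any = True
            else:
                if last_header_line is None:
                    raise FastaParseError(
                        f"{path}: sequence data before any '>' header at line {lineno}")
                have_seq = True
    if seen_any and not have_seq:
        raise FastaParseError(
            f"{path}: record starting at line {last_header_line} has no sequence")


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file into (id, sequence) pairs; sequences upper-cased."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_fasta_text(path)
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records, path, width: int = 70) -> None:
    """Write (id, sequence) pairs as FASTA with fixed line wrapping."""
    seqrecs = [SeqRecord(Seq(seq), id=str(name), description="") for name, seq in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


def read_site_table(path, provenance: str | None = None,
                    deduplicate: bool = True) -> SiteTable:
    """Parse the normalised site-table TSV into a :class:`SiteTable`.

    Duplicate (gene, miRNA, tool, start, end) rows are collapsed with a
    logged count.  Row-level validation failures (inverted intervals,
    unknown tools) raise with the offending 1-based data row number.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "mirna_id": str, "tool": str})
    missing = [c for c in _REQUIRED_SITE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: site table missing required columns {missing}")
    records = []
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        region = getattr(row, "region", None)
        if region is None or pd.isna(region):
            region = UNASSIGNED
        score = getattr(row, "score", None)
        energy = getattr(row, "energy", None)
        try:
            records.append(TargetSite(
                gene_id=str(row.gene_id),
                mirna_id=str(row.mirna_id),
                tool=str(row.tool),
                start=int(row.start),
                end=int(row.end),
                region=str(region),
                score=None if score is None or pd.isna(score) else float(score),
                energy=None if energy is None or pd.isna(energy) else float(energy),
            ))
        except ValueError as exc:
            raise ValueError(f"{path}: row {idx}: {exc}") from exc
    table = SiteTable(records, provenance or str(path))
    if deduplicate:
        table, dropped = table.deduplicate()
        if dropped:
            log.warning("%s: dropped %d duplicate site row(s)", path, dropped)
    return table


def write_site_table(table: SiteTable, path) -> None:
    df = site_table_to_frame(table)
    df.to_csv(path, sep="\t", index=False)


def site_table_to_frame(table: SiteTable) -> pd.DataFrame:
    rows = [{
        "gene_id": r.gene_id, "mirna_id": r.mirna_id, "tool": r.tool,
        "start": r.start, "end": r.end, "region": r.region,
        "score": r.score, "energy": r.energy,
    } for r in table]
    return pd.DataFrame(rows, columns=SITE_COLUMNS)


def read_gene_models(path, sequences: dict[str, str] | None = None) -> list[GeneModel]:
    """Read the gene-model TSV (gene_id, symbol, chromosome, length, cds_start, cds_end).

    ``sequences`` (e.g. from :func:`read_fasta`) attaches sequences by gene_id.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    needed = {"gene_id", "length", "cds_start", "cds_end"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"{path}: gene-model table missing columns {sorted(missing)}")
    genes = []
    for row in df.itertuples(index=False):
        seq = sequences.get(str(row.gene_id)) if sequences else None
        genes.append(GeneModel(
            gene_id=str(row.gene_id),
            symbol=str(getattr(row, "symbol", row.gene_id)),
            chromosome=None if not hasattr(row, "chromosome") or pd.isna(row.chromosome)
            else str(row.chromosome),
            sequence=seq,
            cds_start=int(row.cds_start),
            cds_end=int(row.cds_end),
            length=int(row.length),
        ))
    return genes


def write_gene_models(genes, path) -> None:
    df = pd.DataFrame([{
        "gene_id": g.gene_id, "symbol": g.symbol,
        "chromosome": g.chromosome or "", "length": g.length,
        "cds_start": g.cds_start, "cds_end": g.cds_end,
    } for g in genes])
    df.to_csv(path, sep="\t", index=False)


def read_mirnas(fasta_path, metadata_path=None) -> list[MatureMiRNA]:
    """Read mature miRNAs from FASTA, optionally joining an expression-region TSV.

    The metadata TSV has columns mirna_id and expression_regions
    (semicolon-separated region names).
    """
    meta: dict[str, frozenset[str]] = {}
    if metadata_path is not None:
        mdf = pd.read_csv(metadata_path, sep="\t", dtype=str)
        for row in mdf.itertuples(index=False):
            raw = row.expression_regions
            regions = (frozenset() if raw is None or pd.isna(raw) else
                       frozenset(r.strip() for r in str(raw).split(";") if r.strip()))
            meta[normalize_mirna_id(str(row.mirna_id))] = regions
    out = []
    for name, seq in read_fasta(fasta_path):
        mid = normalize_mirna_id(name)
        out.append(MatureMiRNA(mid, seq, meta.get(mid, frozenset())))
    return out


def write_mirnas(mirnas, fasta_path, metadata_path=None) -> None:
    write_fasta([(m.mirna_id, m.sequence) for m in mirnas], fasta_path)
    if metadata_path is not None:
        df = pd.DataFrame([{
            "mirna_id": m.mirna_id,
            "expression_regions": ";".join(sorted(m.expression_regions)),
        } for m in mirnas])
        df.to_csv(metadata_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Packaged fixtures (transcribed published tables)
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("mirtarnet").joinpath("data", name)


def load_fixture(name: str):
    """Load a packaged fixture.

    ``table1_matrix``
        The 35-gene x 11-miRNA interaction count matrix ("--" transcribed as
        0) as an :class:`~mirtarnet.stats.InteractionMatrix`.  The printed
        per-gene totals and the printed grand total (392) ride along in
        ``matrix.meta``; note the printed DERL1 row total (4) disagrees with
        its own cells (5), so the cells sum to 393.
    ``table3_sites``
        The 28 printed miRanda/TargetScan coordinate pairs as a
        :class:`SiteTable` of 56 paired sites (all in the 3'UTR tier).
    """
    from .stats import InteractionMatrix  # local import avoids a cycle

    if name == "table1_matrix":
        with resources.as_file(_data_path("table1_interaction_counts.tsv")) as p:
            df = pd.read_csv(p, sep="\t", index_col="gene_id")
        printed_col_totals = df.loc["Total"].drop("printed_total").astype(int)
        printed_grand_total = int(df.loc["Total", "printed_total"])
        df = df.drop(index="Total")
        printed_row_totals = df["printed_total"].astype(int)
        counts = df.drop(columns="printed_total").astype(int)
        counts.columns = [normalize_mirna_id(c) for c in counts.columns]
        return InteractionMatrix(
            counts,
            aliases=dict(GENE_ALIASES),
            meta={
                "printed_row_totals": printed_row_totals,
                "printed_col_totals": printed_col_totals,
                "printed_grand_total": printed_grand_total,
            },
        )
    if name == "table3_sites":
        with resources.as_file(_data_path("table3_common_sites.tsv")) as p:
            df = pd.read_csv(p, sep="\t")
        records = []
        for row in df.itertuples(index=False):
            common = dict(gene_id=str(row.gene_id), mirna_id=str(row.mirna_id), region="utr3")
            records.append(TargetSite(tool="miranda", start=int(row.miranda_start),
                                      end=int(row.miranda_end), **common))
            records.append(TargetSite(tool="targetscan", start=int(row.targetscan_start),
                                      end=int(row.targetscan_end), **common))
        return SiteTable(records, provenance="table3_common_sites fixture")
    raise ValueError(f"unknown fixture {name!r}; available: table1_matrix, table3_sites")


def fixture_discrepancies() -> list[str]:
    """Internal-consistency report for the transcribed count-matrix fixture.

    Returns human-readable notes where the printed marginals disagree with
    the printed cells (the known case: DERL1 row prints 4, cells sum to 5,
    so the printed grand total 392 is one short of the cell total 393).
    """
    m = load_fixture("table1_matrix")
    notes = []
    row_sums = m.counts.sum(axis=1)
    for gene, printed in m.meta["printed_row_totals"].items():
        if row_sums[gene] != printed:
            notes.append(f"row {gene}: cells sum to {row_sums[gene]}, printed total {printed}")
    col_sums = m.counts.sum(axis=0)
    for mirna, printed in m.meta["printed_col_totals"].items():
        key = normalize_mirna_id(mirna)
        if col_sums[key] != printed:
            notes.append(f"column {key}: cells sum to {col_sums[key]}, printed total {printed}")
    if m.grand_total() != m.meta["printed_grand_total"]:
        notes.append(f"grand total: cells sum to {m.grand_total()}, "
                     f"printed {m.meta['printed_grand_total']}")
    return notes
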