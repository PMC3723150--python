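"""One-command pipeline: simulate/ingest -> scan -> annotate -> hotspots ->
stats -> consensus -> network, with a plain-text run log.

The YAML run config either points at existing inputs::

    inputs:
      genes_fasta: genes.fasta
      gene_models: genes.tsv
      mirnas_fasta: mirnas.fasta
      mirna_meta: mirnas.tsv        # optional
      sites_targetscan: ts.tsv      # optional, enables consensus
      sites_pictar: pt.tsv          # optional

or carries a ``simulate`` block (the synthetic-config YAML schema), in
which case the dataset is generated first and the planted companion tool
tables feed the consensus stage.  All randomness flows from the single
top-level ``seed``.
"""
from __future__ import annotations

import logging
from pathlib import Path

import yaml

from . import __version__, io as mio
from .consensus import consensus_to_frame, intersect_tables, venn_to_frame
from .hotspots import HotspotParams, find_hotspots, hotspot_summary, hotspots_to_frame
from .models import SiteTable
from .network import build_network, export_network
from .regions import annotate_table, region_distribution
from .scanner import ScannerParams, scan_many
from .simulate import SynthConfig, dataset_to_dir, generate_dataset
from .stats import (build_matrix, cooperativity_table, multiplicity_table)

log = logging.getLogger(__name__)


def _scanner_params(block: dict) -> ScannerParams:
    return ScannerParams(**block) if block else ScannerParams()


def run_pipeline(config_path, outdir, seed: int | None = None) -> dict:
    """Execute every stage; returns a summary dict (also logged to run.log)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("mirtarnet")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run(Path(config_path), outdir, seed, log)
    finally:
        handler.close()
        root.removeHandler(handler)


def _run(config_path, outdir, seed, log) -> dict:
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh) or {}
    summary: dict = {}
    log.info("mirtarnet %s run; config=%s", __version__, config_path)

    params = _scanner_params(cfg.get("scanner", {}))
    hparams = HotspotParams(**cfg.get("hotspots", {}))
    top_k = int(cfg.get("top_k", 11))
    extra_tables: dict[str, SiteTable] = {}

    if "simulate" in cfg:
        sim = dict(cfg["simulate"])
        if seed is not None:
            sim["seed"] = seed
        sim["mirna_groups"] = [(tuple(r), int(c)) for r, c in sim.get("mirna_groups", [])]
        if "region_weights" in sim:
            sim["region_weights"] = tuple(sim["region_weights"])
        if "hotspot_specs" in sim:
            from .simulate import HotspotSpec
            sim["hotspot_specs"] = [HotspotSpec(**h) for h in sim["hotspot_specs"]]
        sconfig = SynthConfig(**sim)
        log.info("simulate: seed=%d genes=%d miRNAs=%d", sconfig.seed,
                 sconfig.n_genes, sconfig.n_mirnas)
        dataset = generate_dataset(sconfig)
        dataset_to_dir(dataset, outdir / "inputs")
        genes = dataset.genes
        mirnas = dataset.mirnas
        for tool in ("targetscan", "pictar"):
            if len(dataset.tables[tool]):
                extra_tables[tool] = dataset.tables[tool]
        summary["seed"] = sconfig.seed
    else:
        inputs = cfg.get("inputs", {})
        for key in ("genes_fasta", "gene_models", "mirnas_fasta"):
            if key not in inputs:
                raise ValueError(f"run config must provide inputs.{key} or a "
                                 "simulate block")
            if not Path(inputs[key]).exists():
                raise FileNotFoundError(inputs[key])
        seqs = dict(mio.read_fasta(inputs["genes_fasta"]))
        genes = mio.read_gene_models(inputs["gene_models"], sequences=seqs)
        mirnas = mio.read_mirnas(inputs["mirnas_fasta"], inputs.get("mirna_meta"))
        for tool in ("targetscan", "pictar"):
            key = f"sites_{tool}"
            if key in inputs:
                extra_tables[tool] = mio.read_site_table(inputs[key])
        summary["seed"] = seed

    log.info("scan: %d genes x %d miRNAs", len(genes), len(mirnas))
    sites = scan_many(genes, mirnas, params)
    sites, dropped = sites.deduplicate()
    log.info("scan: %d sites (%d duplicates dropped)", len(sites), dropped)
    summary["n_sites"] = len(sites)

    sites = annotate_table(sites, genes)
    mio.write_site_table(sites, outdir / "sites.annotated.tsv")
    dist = region_distribution(sites)
    dist.to_csv(outdir / "region_counts.tsv", sep="\t", index=False)
    strat = region_distribution(sites, mirnas, group_by="expression_region")
    strat.to_csv(outdir / "region_counts_by_expression.tsv", sep="\t", index=False)
    log.info("annotate: region counts %s",
             dict(zip(dist["region"], dist["n_sites"])))

    hotspots = find_hotspots(sites, hparams)
    hotspots_to_frame(hotspots).to_csv(outdir / "hotspots.tsv", sep="\t", index=False)
    hotspot_summary(hotspots).to_csv(outdir / "hotspot_summary.tsv", sep="\t",
                                     index=False)
    log.info("hotspots: %d found", len(hotspots))
    summary["n_hotspots"] = len(hotspots)

    matrix = build_matrix(sites, [g.gene_id for g in genes],
                          [m.mirna_id for m in mirnas])
    matrix.to_tsv(outdir / "matrix.tsv")
    multiplicity_table(matrix).to_csv(outdir / "multiplicity.tsv", sep="\t",
                                      index=False)
    cooperativity_table(matrix).to_csv(outdir / "cooperativity.tsv", sep="\t",
                                       index=False)
    top = matrix.top_k_mirnas(top_k)
    summary["grand_total"] = matrix.grand_total()
    summary["top_mirnas"] = top
    log.info("stats: grand total %d sites; top miRNA %s", matrix.grand_total(),
             top[0] if top else None)

    if extra_tables:
        tables = {"miranda": sites, **extra_tables}
        records, venn = intersect_tables(tables)
        consensus_to_frame(records).to_csv(outdir / "consensus.tsv", sep="\t",
                                           index=False)
        venn_to_frame(venn).to_csv(outdir / "venn.tsv", sep="\t", index=False)
        summary["n_consensus"] = len(records)
        log.info("consensus: %d records across %s", len(records),
                 sorted(tables))

    net = build_network(matrix, top)
    export_network(net, outdir / "network.tsv", "edgelist")
    export_network(net, outdir / "network.graphml", "graphml")
    summary["n_edges"] = net.number_of_edges()
    log.info("network: %d nodes, %d edges", net.number_of_nodes(),
             net.number_of_edges())
    log.info("done")
    return summary
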