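"""Synthetic genes, miRNAs and per-tool site tables with known ground truth.

The generator plants exact reverse-complement target sites (maximal
alignment score, so recovery is threshold-robust) at controlled positions:
isolated sites drive the interaction-count matrix, clustered sites form
hotspots, and selected 3'UTR sites get matching TargetScan/PicTar seed
intervals for consensus tests.  Background sequence is rejection-sampled so
it contains no accidental site above the scanner thresholds: exact seed
complements are removed up front and a final verification scan repairs any
residual spurious hit.

Every random draw flows from the single mandatory ``seed``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .models import (EXPRESSION_REGIONS, REGIONS, GeneModel, MatureMiRNA,
                     SiteTable, TargetSite)
from .scanner import STACK_ENERGIES, ScannerParams, scan_gene
from .stats import InteractionMatrix, build_matrix

_DNA = "ACGT"
_COMP = str.maketrans("ACGTU", "TGCAA")


class SynthConfigError(ValueError):
    pass


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def perfect_site_score(mirna_len: int, params: ScannerParams) -> float:
    """Alignment score of a full-length exact-complement site."""
    n_seed = sum(1 for p in params.seed_positions if p <= mirna_len)
    return (n_seed * params.seed_scaling + (mirna_len - n_seed)) * params.match_score


def perfect_duplex_energy(mirna_seq: str) -> float:
    """Free energy of the fully paired duplex (closed form: sum of stacks)."""
    rna = mirna_seq.upper().replace("T", "U")
    return sum(STACK_ENERGIES[rna[i:i + 2]] for i in range(len(rna) - 1))


@dataclass
class HotspotSpec:
    """A planted cluster of distinct-miRNA sites with chained starts.

    Because planted sites are exact complements, clustered overlapping
    sites cannot all belong to independently drawn miRNAs: the generator
    samples one gene stretch and derives each member miRNA as the reverse
    complement of that stretch at its start offset, so all member sites
    coexist letter-for-letter.  ``start_offsets`` (first must be 0,
    consecutive differences within the chaining window) default to random
    gaps of 2..start_window nucleotides.
    """
    gene: str | int
    region: str = "cds"
    n_mirnas: int = 3
    start_offsets: list[int] | None = None

    def __post_init__(self):
        if self.region not in REGIONS:
            raise SynthConfigError(f"unknown region {self.region!r}")
        if self.start_offsets is not None:
            if self.start_offsets[0] != 0 or sorted(self.start_offsets) != list(
                    self.start_offsets):
                raise SynthConfigError("start_offsets must be sorted and begin at 0")
            self.n_mirnas = len(self.start_offsets)
        if self.n_mirnas < 2:
            raise SynthConfigError("a hotspot needs at least 2 miRNAs")


@dataclass
class SynthConfig:
    """Study conditions for one synthetic dataset (seed is mandatory)."""
    seed: int
    n_genes: int = 6
    utr5_len: int = 150
    cds_len: int = 300
    utr3_len: int = 250
    #: (expression-region subset, how many miRNAs carry exactly that subset)
    mirna_groups: list[tuple[tuple[str, ...], int]] = field(
        default_factory=lambda: [(("midbrain",), 4), (("midbrain", "cerebellum"), 2)])
    mirna_length: int = 22
    #: explicit per-pair counts (gene -> miRNA -> n sites); None samples Poisson
    site_counts: dict[str, dict[str, int]] | None = None
    site_count_lambda: float = 0.4
    region_weights: tuple[float, float, float] = (0.25, 0.5, 0.25)  # utr5, cds, utr3
    hotspot_specs: list[HotspotSpec] = field(default_factory=list)
    n_two_way: int = 0
    n_three_way: int = 0
    n_decoy_targetscan: int = 2
    gc_fraction: float = 0.5
    start_window: int = 10
    scanner_params: ScannerParams = field(default_factory=ScannerParams)
    verify_with_scanner: bool = True

    def __post_init__(self):
        if self.seed is None:
            raise SynthConfigError("a random seed is mandatory")
        for regions, count in self.mirna_groups:
            bad = set(regions) - set(EXPRESSION_REGIONS)
            if bad:
                raise SynthConfigError(f"unknown expression regions {sorted(bad)}")
            if count < 0:
                raise SynthConfigError("miRNA group counts must be >= 0")
        if not (16 <= self.mirna_length <= 28):
            raise SynthConfigError("mirna_length outside [16, 28]")
        if not 0 < self.gc_fraction < 1:
            raise SynthConfigError("gc_fraction must be in (0, 1)")

    @property
    def n_mirnas(self) -> int:
        return sum(c for _, c in self.mirna_groups)

    def gene_ids(self) -> list[str]:
        return [f"SYNG{i + 1:02d}" for i in range(self.n_genes)]

    def to_yaml(self, path) -> None:
        d = {
            "seed": self.seed, "n_genes": self.n_genes,
            "utr5_len": self.utr5_len, "cds_len": self.cds_len,
            "utr3_len": self.utr3_len,
            "mirna_groups": [[list(r), c] for r, c in self.mirna_groups],
            "mirna_length": self.mirna_length,
            "site_counts": self.site_counts,
            "site_count_lambda": self.site_count_lambda,
            "region_weights": list(self.region_weights),
            "hotspot_specs": [{"gene": h.gene, "region": h.region,
                               "n_mirnas": h.n_mirnas,
                               "start_offsets": h.start_offsets}
                              for h in self.hotspot_specs],
            "n_two_way": self.n_two_way, "n_three_way": self.n_three_way,
            "n_decoy_targetscan": self.n_decoy_targetscan,
            "gc_fraction": self.gc_fraction, "start_window": self.start_window,
            "verify_with_scanner": self.verify_with_scanner,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path, seed: int | None = None) -> "SynthConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if seed is not None:
            d["seed"] = seed
        d["mirna_groups"] = [(tuple(r), int(c)) for r, c in d.get("mirna_groups", [])]
        d["region_weights"] = tuple(d.get("region_weights", (0.25, 0.5, 0.25)))
        d["hotspot_specs"] = [HotspotSpec(**h) for h in d.get("hotspot_specs", [])]
        return cls(**d)


@dataclass
class GroundTruth:
    """Everything the generator planted, for exact-recovery tests."""
    sites: SiteTable                       # miranda tier, region-annotated
    hotspots: list[dict]                   # gene, region, span_start, mirnas
    matrix: InteractionMatrix              # planted counts, all genes x miRNAs
    consensus: list[dict]                  # gene, mirna, tools, intervals


@dataclass
class SynthDataset:
    config: SynthConfig
    genes: list[GeneModel]
    mirnas: list[MatureMiRNA]
    tables: dict[str, SiteTable]
    truth: GroundTruth


# ---------------------------------------------------------------------------

def _sample_mirnas(config: SynthConfig, rng) -> list[MatureMiRNA]:
    """Sample miRNA sequences: mutually distant, energetic enough to plant."""
    params = config.scanner_params
    seqs: list[str] = []
    out: list[MatureMiRNA] = []
    k = 0
    for regions, count in config.mirna_groups:
        for _ in range(count):
            k += 1
            for _ in range(200):
                cand = "".join(rng.choice(list("ACGU"), size=config.mirna_length))
                # planted exact-complement duplex must clear the energy
                # filter with margin, and miRNAs must be mutually distant so
                # one miRNA's planted site cannot satisfy another's threshold
                if perfect_duplex_energy(cand) > params.energy_threshold - 2.0:
                    continue
                if any(sum(a != b for a, b in zip(cand, s)) < 8 for s in seqs):
                    continue
                seqs.append(cand)
                out.append(MatureMiRNA(f"syn-miR-{k:03d}", cand, frozenset(regions)))
                break
            else:
                raise SynthConfigError("could not sample a usable miRNA sequence")
    return out


def _seed_site_pattern(mirna: MatureMiRNA, params: ScannerParams) -> str:
    """DNA 7-mer a gene carries where the miRNA seed pairs perfectly."""
    lo, hi = min(params.seed_positions), max(params.seed_positions)
    return revcomp(mirna.sequence[lo - 1:hi])


def _sample_counts(config: SynthConfig, gene_ids, mirnas, rng) -> pd.DataFrame:
    if config.site_counts is not None:
        counts = pd.DataFrame(0, index=gene_ids, columns=[m.mirna_id for m in mirnas])
        for g, row in config.site_counts.items():
            for m, c in row.items():
                if g not in counts.index or m not in counts.columns:
                    raise SynthConfigError(f"site_counts references unknown ({g}, {m})")
                counts.loc[g, m] = int(c)
        return counts
    draws = rng.poisson(config.site_count_lambda, size=(len(gene_ids), len(mirnas)))
    return pd.DataFrame(draws, index=gene_ids,
                        columns=[m.mirna_id for m in mirnas])


def generate_dataset(config: SynthConfig) -> SynthDataset:
    """Generate one dataset with planted sites, hotspots and consensus pairs."""
    rng = np.random.default_rng(config.seed)
    params = config.scanner_params
    mirnas = _sample_mirnas(config, rng)
    mirna_by_id = {m.mirna_id: m for m in mirnas}
    gene_ids = config.gene_ids()
    L = config.mirna_length
    gene_len = config.utr5_len + config.cds_len + config.utr3_len
    cds_start, cds_end = config.utr5_len + 1, config.utr5_len + config.cds_len
    region_bounds = {"utr5": (1, config.utr5_len), "cds": (cds_start, cds_end),
                     "utr3": (cds_end + 1, gene_len)}
    for region, (lo, hi) in region_bounds.items():
        if hi - lo + 1 < L:
            raise SynthConfigError(f"{region} shorter than one site ({L} nt)")
    counts = _sample_counts(config, gene_ids, mirnas, rng)
    gap = config.start_window + 1  # keeps independent plants from chaining

    # --- units: (gene, region, [(mirna_id, offset)]) -----------------------
    units: dict[str, dict[str, list[list[tuple[str, int]]]]] = {
        g: {r: [] for r in REGIONS} for g in gene_ids}

    # hotspot members: one random stretch per cluster, member miRNA k is the
    # reverse complement of the stretch at its offset, so the overlapping
    # member sites are mutually consistent
    hotspot_truth_units = []
    stretches: dict[int, str] = {}
    existing_seqs = {m.sequence for m in mirnas}
    for h, spec in enumerate(config.hotspot_specs):
        gene = gene_ids[spec.gene] if isinstance(spec.gene, int) else spec.gene
        if gene not in units:
            raise SynthConfigError(f"hotspot spec references unknown gene {spec.gene!r}")
        if spec.start_offsets is not None:
            offsets = list(spec.start_offsets)
            if any(b - a > config.start_window
                   for a, b in zip(offsets, offsets[1:])):
                raise SynthConfigError("hotspot start offsets exceed the chaining "
                                       "window")
        else:
            offsets = [0]
            for _ in range(spec.n_mirnas - 1):
                offsets.append(offsets[-1]
                               + int(rng.integers(2, config.start_window + 1)))
        stretch_len = offsets[-1] + L
        for _ in range(200):
            stretch = "".join(rng.choice(list(_DNA), size=stretch_len))
            cands = [revcomp(stretch[off:off + L]).replace("T", "U")
                     for off in offsets]
            if any(c in existing_seqs for c in cands) or len(set(cands)) != len(cands):
                continue
            if any(perfect_duplex_energy(c) > params.energy_threshold - 2.0
                   for c in cands):
                continue
            break
        else:
            raise SynthConfigError("could not sample a usable hotspot stretch")
        stretches[h] = stretch
        members = []
        for k, (off, cand) in enumerate(zip(offsets, cands)):
            # derived members carry no expression-region label so the
            # configured per-region pool sizes stay exact
            mid = f"syn-miR-hs{h + 1:02d}{chr(97 + k)}"
            mirna = MatureMiRNA(mid, cand, frozenset())
            mirnas.append(mirna)
            mirna_by_id[mirna.mirna_id] = mirna
            existing_seqs.add(cand)
            members.append((mirna.mirna_id, off))
        units[gene][spec.region].append(members)
        hotspot_truth_units.append((gene, spec.region, members))

    # singles from the count matrix; the first n_two+n_three go to the 3'UTR
    # so consensus pairs exist there
    singles = [(g, m) for g in gene_ids for m in counts.columns
               for _ in range(int(counts.loc[g, m]))]
    singles = [singles[i] for i in rng.permutation(len(singles))]
    n_consensus = config.n_two_way + config.n_three_way
    if n_consensus > len(singles):
        raise SynthConfigError(
            f"{n_consensus} consensus pairs requested but only {len(singles)} "
            "sites are planted; raise site counts")
    region_names = list(REGIONS)
    probs = np.asarray(config.region_weights, dtype=float)
    probs = probs / probs.sum()
    single_units: list[tuple[str, str, str]] = []  # gene, region, mirna
    for idx, (g, m) in enumerate(singles):
        region = "utr3" if idx < n_consensus else region_names[int(rng.choice(3, p=probs))]
        single_units.append((g, region, m))
    for g, region, m in single_units:
        units[g][region].append([(m, 0)])

    # --- placement: random non-overlapping layout, min gap between units ---
    explicit = config.site_counts is not None
    placements: dict[tuple[str, str, int], int] = {}  # (gene, region, unit idx) -> start
    dropped: list[tuple[str, str]] = []
    for g in gene_ids:
        for region in REGIONS:
            unit_list = units[g][region]
            if not unit_list:
                continue
            lo, hi = region_bounds[region]
            avail = hi - lo + 1

            def unit_len(u):
                return max(off for _, off in u) + L

            order = list(rng.permutation(len(unit_list)))
            while order:
                total = sum(unit_len(unit_list[i]) for i in order) + gap * (len(order) - 1)
                if total <= avail:
                    break
                # sampled singles may overflow a short region: drop extras;
                # explicitly requested plants must fit
                single_idx = [i for i in order if len(unit_list[i]) == 1]
                if explicit or not single_idx:
                    raise SynthConfigError(
                        f"planted sites exceed {region} length in gene {g}")
                victim = single_idx[-1]
                order.remove(victim)
                dropped.append((g, unit_list[victim][0][0]))
            if not order:
                continue
            lens = [unit_len(unit_list[i]) for i in order]
            slack = avail - sum(lens) - gap * (len(order) - 1)
            cuts = rng.multinomial(slack, np.ones(len(order) + 1) / (len(order) + 1))
            pos = lo
            for k, i in enumerate(order):
                pos += int(cuts[k])
                placements[(g, region, i)] = pos
                pos += lens[k] + gap
    for g, m in dropped:
        counts.loc[g, m] -= 1

    # --- planted site list --------------------------------------------------
    planted: list[TargetSite] = []
    planted_by_gene: dict[str, list[tuple[int, int, str]]] = {g: [] for g in gene_ids}
    hotspot_truth: list[dict] = []
    consensus_pool: list[TargetSite] = []
    for (g, region, i), start in sorted(placements.items()):
        for m, off in units[g][region][i]:
            s = start + off
            site = TargetSite(
                gene_id=g, mirna_id=m, tool="miranda", start=s, end=s + L - 1,
                region=region,
                score=round(perfect_site_score(L, params), 4),
                energy=round(perfect_duplex_energy(mirna_by_id[m].sequence), 4))
            planted.append(site)
            planted_by_gene[g].append((s, s + L - 1, m))
            if region == "utr3" and len(units[g][region][i]) == 1:
                consensus_pool.append(site)
    for (g, region, members) in hotspot_truth_units:
        idx = next(i for i, u in enumerate(units[g][region]) if u is members)
        start = placements[(g, region, idx)]
        hotspot_truth.append({
            "gene_id": g, "region": region, "span_start": start,
            "mirnas": frozenset(m for m, _ in members),
            "starts": sorted(start + off for _, off in members)})

    # --- gene sequences: background + plants + seed-complement cleanup ------
    base_p = np.array([(1 - config.gc_fraction) / 2, config.gc_fraction / 2,
                       config.gc_fraction / 2, (1 - config.gc_fraction) / 2])
    seed_patterns = {_seed_site_pattern(m, params) for m in mirnas}
    pat_len = len(next(iter(seed_patterns)))
    genes: list[GeneModel] = []
    for g in gene_ids:
        seq = rng.choice(list(_DNA), size=gene_len, p=base_p)
        protected = np.zeros(gene_len, dtype=bool)
        for s, e, m in planted_by_gene[g]:
            seq[s - 1:e] = list(revcomp(mirna_by_id[m].sequence))
            protected[s - 1:e] = True
        # remove accidental exact seed complements from the background
        for _ in range(50):
            dirty = False
            text = "".join(seq)
            for j in range(gene_len - pat_len + 1):
                if text[j:j + pat_len] in seed_patterns and not protected[j:j + pat_len].all():
                    free = [k for k in range(j, j + pat_len) if not protected[k]]
                    k = int(rng.choice(free))
                    seq[k] = rng.choice([b for b in _DNA if b != seq[k]])
                    dirty = True
            if not dirty:
                break
        genes.append(GeneModel(gene_id=g, symbol=g, sequence="".join(seq),
                               cds_start=cds_start, cds_end=cds_end))

    if config.verify_with_scanner:
        genes = _verify_and_repair(genes, mirnas, planted_by_gene, protected_cols={
            g: [(s, e) for s, e, _ in planted_by_gene[g]] for g in gene_ids},
            params=params, rng=rng)

    # --- companion tool tables ----------------------------------------------
    if n_consensus > len(consensus_pool):
        raise SynthConfigError("not enough isolated 3'UTR sites for the requested "
                               "consensus pairs")
    pool_idx = rng.permutation(len(consensus_pool))
    chosen = [consensus_pool[i] for i in pool_idx[:n_consensus]]
    three_way = chosen[:config.n_three_way]
    two_way = chosen[config.n_three_way:]
    ts_records, pictar_records, consensus_truth = [], [], []
    for site in three_way + two_way:
        ts = TargetSite(gene_id=site.gene_id, mirna_id=site.mirna_id,
                        tool="targetscan", start=site.end - 8, end=site.end - 2,
                        region="utr3")
        ts_records.append(ts)
        tools = {"miranda", "targetscan"}
        entry = {"gene_id": site.gene_id, "mirna_id": site.mirna_id,
                 "miranda": (site.start, site.end),
                 "targetscan": (ts.start, ts.end)}
        if site in three_way:
            pt = TargetSite(gene_id=site.gene_id, mirna_id=site.mirna_id,
                            tool="pictar", start=site.end - 7, end=site.end - 1,
                            region="utr3")
            pictar_records.append(pt)
            tools.add("pictar")
            entry["pictar"] = (pt.start, pt.end)
        entry["tools"] = frozenset(tools)
        consensus_truth.append(entry)
    # decoy TargetScan sites: 3'UTR intervals touching no planted site
    gene_map = {g.gene_id: g for g in genes}
    for _ in range(config.n_decoy_targetscan):
        for _ in range(100):
            g = gene_ids[int(rng.integers(len(gene_ids)))]
            m = mirnas[int(rng.integers(len(mirnas)))].mirna_id
            lo, hi = region_bounds["utr3"]
            s = int(rng.integers(lo, hi - 6))
            if any(s <= e and a <= s + 6 for a, e, _ in planted_by_gene[g]):
                continue
            if any(r.gene_id == g and r.start == s for r in ts_records):
                continue
            ts_records.append(TargetSite(gene_id=g, mirna_id=m, tool="targetscan",
                                         start=s, end=s + 6, region="utr3"))
            break

    planted.sort(key=lambda s: (s.gene_id, s.start, s.mirna_id))
    ts_records.sort(key=lambda s: (s.gene_id, s.start, s.mirna_id))
    pictar_records.sort(key=lambda s: (s.gene_id, s.start, s.mirna_id))
    miranda_table = SiteTable(planted, provenance="synthetic planted sites")
    tables = {"miranda": miranda_table,
              "targetscan": SiteTable(ts_records, provenance="synthetic targetscan"),
              "pictar": SiteTable(pictar_records, provenance="synthetic pictar")}
    truth = GroundTruth(
        sites=miranda_table,
        hotspots=sorted(hotspot_truth, key=lambda h: (h["gene_id"], h["region"],
                                                      h["span_start"])),
        matrix=build_matrix(miranda_table, gene_ids, [m.mirna_id for m in mirnas]),
        consensus=consensus_truth)
    return SynthDataset(config=config, genes=genes, mirnas=mirnas,
                        tables=tables, truth=truth)


def _verify_and_repair(genes, mirnas, planted_by_gene, protected_cols, params, rng):
    """Scan every gene and mutate background under any spurious hit."""
    out = []
    for gene in genes:
        seq = list(gene.sequence)
        protected = np.zeros(gene.length, dtype=bool)
        for s, e in protected_cols[gene.gene_id]:
            protected[s - 1:e] = True
        expected = {(s, e, m) for s, e, m in planted_by_gene[gene.gene_id]}
        for attempt in range(20):
            current = GeneModel(gene_id=gene.gene_id, symbol=gene.symbol,
                                sequence="".join(seq), cds_start=gene.cds_start,
                                cds_end=gene.cds_end)
            found = set()
            for m in mirnas:
                for site in scan_gene(current, m, params):
                    found.add((site.start, site.end, site.mirna_id))
            missing = expected - found
            if missing:
                raise SynthConfigError(
                    f"planted sites not recovered in {gene.gene_id}: {sorted(missing)}")
            spurious = found - expected
            if not spurious:
                out.append(current)
                break
            for s, e, _ in spurious:
                free = [k for k in range(s - 1, e) if not protected[k]]
                if not free:
                    raise SynthConfigError(
                        f"cannot repair spurious site at {gene.gene_id}:{s}-{e}")
                k = int(rng.choice(free))
                seq[k] = rng.choice([b for b in _DNA if b != seq[k]])
        else:
            raise SynthConfigError(f"background repair did not converge for "
                                   f"{gene.gene_id}")
    return out


def study_scale_config(seed: int) -> SynthConfig:
    """Study-scale conditions: 35 genes; brain-region miRNA pools of size
    62 (cerebellum), 93 (hippocampus), 112 (midbrain) and 105 (frontal
    cortex) with 23/17/14/4 region-exclusive members (midbrain /
    hippocampus / frontal cortex / cerebellum); desk-scale gene lengths.

    The shared-membership composition below is the unique-by-construction
    pairwise solution reproducing all eight printed pool counts with 215
    distinct miRNAs.
    """
    groups = [
        (("midbrain",), 23),
        (("hippocampus",), 17),
        (("frontal_cortex",), 14),
        (("cerebellum",), 4),
        (("frontal_cortex", "midbrain"), 43),
        (("hippocampus", "midbrain"), 26),
        (("cerebellum", "midbrain"), 20),
        (("frontal_cortex", "hippocampus"), 30),
        (("cerebellum", "hippocampus"), 20),
        (("cerebellum", "frontal_cortex"), 18),
    ]
    hotspots = [HotspotSpec(gene=0, region="utr3"), HotspotSpec(gene=1, region="utr3"),
                HotspotSpec(gene=2, region="utr5"), HotspotSpec(gene=3, region="utr5"),
                HotspotSpec(gene=4, region="utr5"), HotspotSpec(gene=5, region="utr5"),
                HotspotSpec(gene=6, region="cds"), HotspotSpec(gene=6, region="cds"),
                HotspotSpec(gene=7, region="cds"), HotspotSpec(gene=8, region="cds"),
                HotspotSpec(gene=9, region="cds")]
    return SynthConfig(
        seed=seed, n_genes=35, utr5_len=200, cds_len=500, utr3_len=300,
        mirna_groups=groups, site_count_lambda=0.1,
        hotspot_specs=hotspots, n_two_way=37, n_three_way=11)


def dataset_to_dir(dataset: SynthDataset, outdir) -> dict[str, str]:
    """Write genes, miRNAs and per-tool site tables under ``outdir``."""
    from pathlib import Path

    from . import io as mio
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    mio.write_fasta([(g.gene_id, g.sequence) for g in dataset.genes],
                    outdir / "genes.fasta")
    paths["genes_fasta"] = str(outdir / "genes.fasta")
    mio.write_gene_models(dataset.genes, outdir / "genes.tsv")
    paths["gene_models"] = str(outdir / "genes.tsv")
    mio.write_mirnas(dataset.mirnas, outdir / "mirnas.fasta", outdir / "mirnas.tsv")
    paths["mirnas_fasta"] = str(outdir / "mirnas.fasta")
    paths["mirna_meta"] = str(outdir / "mirnas.tsv")
    for tool, table in dataset.tables.items():
        p = outdir / f"sites.{tool}.tsv"
        mio.write_site_table(table, p)
        paths[f"sites_{tool}"] = str(p)
    return paths
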