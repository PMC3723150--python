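# Methods

## Scope and data model

The package analyses predicted miRNA target sites on a panel of genes,
each modelled as a sequence partitioned into 5′UTR, CDS and 3′UTR by its
CDS boundaries. All coordinates at external interfaces are 1-based with
inclusive intervals; T and U are interchangeable on the gene strand.
Mature miRNA identifiers are normalised to the `hsa-miR-<n>[-arm]`
convention on every ingestion path, collapsing the precursor/mature
capitalisation split that otherwise makes the same molecule appear under
two names in different tables. Site tables from the three prediction
tools (miranda, targetscan, pictar) share one TSV schema; duplicate
(gene, miRNA, tool, start, end) rows are dropped with a logged count.

## Target-site scanner

The scanner reimplements the classic seed-weighted complementarity
search. The miRNA (5′→3′) is aligned against the antiparallel gene strand
by Gotoh local dynamic programming. Per-column contributions are +5 for a
Watson–Crick pair, +1 for a G:U wobble and −3 for a mismatch, multiplied
by the seed scaling *w* (default 3.0) when the miRNA position lies in the
seed (positions 2–8 from the 5′ end — the standard seed convention,
encoding the extra weight of 5′-end pairing). The per-column scores are
not fixed by the study that set the thresholds; they follow the published
miRanda convention and are exposed in `ScannerParams`. Gap penalties are
applied exactly as specified — open 2.0, extend 8.0, a length-*L* gap
costing `open + L·extend` — even though open < extend is an unusual
affine regime (a warning is logged once). A 22-nt miRNA aligned to its
exact reverse complement therefore scores 7·5·3 + 15·5 = 180.

A full-gene DP is run once per (gene, miRNA); every cell at or above the
score threshold *S* (default 150) is traced back, the duplex energy is
evaluated, and candidates surviving both filters are merged so that
overlapping sites of the same miRNA keep only the best score (ties to the
smaller start). The inner kernel is JIT-compiled with numba; results are
identical to the pure-Python path, and the test suite checks the whole
aligner against an exhaustive enumeration oracle on small duplexes.

### Duplex energy model

Free energy is the sum of Turner-style nearest-neighbor stacking terms
over consecutive paired columns (16 Watson–Crick stack entries packaged
as `data/rna_stack_energies.tsv`, all negative), a fixed −0.5 kcal/mol
for stacks involving a wobble pair, and +0.5 kcal/mol per unpaired
nucleotide inside the duplex (a mismatch column counts two nucleotides, a
gap one). Full internal-loop thermodynamics is deliberately out of scope:
the model is deterministic, dependency-free and sufficient to exercise
the ΔG ≤ −25 kcal/mol filter — a single base pair scores 0 and fails it,
a perfect 22-mer helix of average composition reaches ≈ −45. It is not a
substitute for a folding package when absolute energies matter.

## Region annotation

A site takes the region containing its **start** coordinate. No rule for
boundary-spanning sites is implied by per-region tallies themselves, so
the start-position rule was chosen for determinism: every site maps to
exactly one region and region counts partition the table. Stratified
counts by brain region of miRNA expression count a site once per region
membership of its miRNA, so strata may sum to more than the table size.

## Hotspot detection

Two sites are linked when their start positions differ by at most
`start_window` (default 10 nt); single-linkage components per (gene,
region) with at least `min_mirnas` (default 3) distinct miRNAs are
hotspots. On sorted starts this is exactly consecutive-difference
chaining, which is how the independent test oracle states it; the
implementation uses pairwise union-find so the alternate
`interval-overlap` rule (link when intervals share ≥ `start_window` nt)
is handled by the same machinery. Transitive (single-linkage) and
clique-wise readings coincide on small clusters; single-linkage was
chosen as the deterministic, order-independent interpretation. Hotspots
never cross region boundaries, and distinct-miRNA counting uses
normalised identifiers.

## Interaction statistics

The interaction matrix counts deduplicated sites per (gene, miRNA).
Multiplicity of a miRNA is its column total and number of non-zero cells;
cooperativity of a gene is the row total and non-zero count over an
optional miRNA subset. Top-K ranking sorts by total sites, then genes
hit, then identifier — the printed table this reproduces has a three-way
tie at 21 sites and states no rule, so the tie-break is the package's own
choice. K defaults to 11 because the published ranking lists 11 miRNAs
even where the prose says "top 10".

### Known inconsistencies in the transcribed count table

The packaged fixture transcribes the published 35 × 11 table cell for
cell ("—" → 0). Two internal inconsistencies of the original are
preserved and flagged by `fixture_discrepancies()` rather than silently
corrected: the DERL1 row prints total 4 but its cells sum to 5, and
consequently the printed grand total 392 (the sum of printed row totals)
is one short of the cell sum 393, while the printed per-miRNA column
totals match the cells exactly. Computed statistics always come from the
cells. Similarly, the prose describes PRPH as hit by 10 miRNAs while its
printed row has 11 non-zero cells; the package reports the computed 11.
The row printed as "SOD2" conflicts with the gene panel (SOD1); the
fixture keeps the printed label and ships an alias so either name
resolves.

## Cross-algorithm consensus

Sites from different tools for the same (gene, miRNA) match in
`containment` mode when the shorter interval lies inside the longer one —
in all 28 published miRanda/TargetScan coordinate pairs the 7-mer seed
interval is enclosed by the alignment interval, so containment reproduces
that pairing — or in `overlap` mode when the intersection reaches
`min_overlap` (default 7 nt, the seed-match length), which also covers
seed-tool versus seed-tool comparisons where neither encloses the other.
Matching is one-to-one per tool pair (largest overlap first, ties to the
smaller start); matched sites merge into consensus records by connected
components, and Venn counts partition records by tool subset with
singleton entries counting unmatched sites. Consensus is restricted to
3′UTR sites by default because the seed-based tools only predict there.
The published common-site list has 12 CYCS rows of which two pairs are
exact duplicates; deduplicated counts are reported and the duplicates
logged.

## Bipartite network

Edges connect a miRNA to every gene with a positive count, carrying the
count as weight — the published interaction map draws unweighted arrows,
and thresholding the weights at ≥ 1 collapses to it. Gene nodes with no
edges are retained so the gene side always mirrors the panel. Export
(edge-list TSV, GraphML) uses a fixed node order (miRNAs then genes,
lexicographic), making output byte-reproducible.

## Synthetic data generator

The generator emulates the study's inputs with known ground truth:

* **Scale.** `study_scale_config` builds 35 genes (desk-scale lengths:
  200 nt 5′UTR, 500 nt CDS, 300 nt 3′UTR — long enough to hold realistic
  site loads while keeping a full scan in seconds) and brain-region miRNA
  pools of 62/93/112/105 with 23/17/14/4 region-exclusive members. The
  shared-membership composition (e.g. 43 miRNAs in frontal cortex +
  midbrain) is a fixed pairwise solution reproducing all eight published
  pool counts with 215 distinct miRNAs. Per-pair site counts are Poisson
  (λ = 0.1 per gene × miRNA, ≈ 750 sites — the same order as the ≈ 1500
  sites the original screen reported over a comparable pair count);
  region choice is weighted 25/50/25 (5′UTR/CDS/3′UTR), mirroring the
  reported CDS majority. Eleven hotspots and 48 cross-tool agreements (11
  three-way) are planted, matching the study's headline counts.
* **Plants.** Planted sites are exact reverse complements of their miRNA
  (maximal score 180 for 22-mers, so recovery is robust to the
  thresholds); partial-complementarity plants for sensitivity tests are
  obtained by mutating site bases. Independent plants are spaced more
  than the chaining window apart so no accidental hotspot forms.
* **Hotspot clusters.** Overlapping clustered sites cannot all be exact
  complements of independent miRNAs, so each cluster samples one gene
  stretch and derives its member miRNAs as reverse complements of the
  stretch at the chained offsets; members carry no expression-region
  label so the configured pool sizes stay exact.
* **Background hygiene.** miRNAs are drawn mutually distant (Hamming ≥ 8)
  with perfect-duplex energies clearing the filter by ≥ 2 kcal/mol;
  background sequence is rejection-sampled to remove exact seed
  complements, and a final verification scan repairs any residual
  spurious hit by mutating background bases (planted columns are never
  touched). The emitted miranda table therefore equals the scanner's
  output on the generated genes, including scores and energies.
* **Companion tool tables.** Each selected 3′UTR site gets a TargetScan
  7-mer at the seed-pairing interval `[end−8, end−2]` (the geometry seen
  in the published coordinate pairs) and, for three-way plants, a PicTar
  7-mer at `[end−7, end−1]`; decoy TargetScan-only sites are placed on
  clean background.

What passing recovery tests shows — and what it does not: the pipeline
recovers planted truth exactly because planted duplexes are perfect and
background is cleaned; real sequences have partial-complementarity sites,
conserved UTR structure and compositional bias the generator does not
emulate, so recovery rates here say nothing about sensitivity on real
transcripts.

## Reproducibility and numerical choices

All randomness flows from a single integer seed through one
`numpy.random.Generator`; identical configurations produce byte-identical
outputs. Score comparisons are exact floating-point sums of small
rationals (no tolerance needed at the thresholds used); scores and
energies are rounded to 4 decimals on output. Candidate ordering and all
exports use explicit deterministic tie-breaks (score descending, then
start ascending; lexicographic node order).

## Out-of-scope quantities

Site totals of the original screen (1456 miRanda sites, per-region and
per-tool totals, the published intersection table) depended on 2013-era
gene records, a specific miRNA database release and exact binaries of
three external tools, none of which are recoverable from the text; the
package does not claim to reproduce them numerically. Regression hooks
for the study's supplementary site lists exist in the test suite and
activate only when those files are placed under `data/supplementary/`.
Conservation-based filtering, statistical enrichment of hotspots, graph
layout and plotting are out of scope.
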