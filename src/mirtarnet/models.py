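"""Core domain types for the miRNA-target pipeline.

Coordinate convention: every position at an external interface is 1-based
and intervals are inclusive on both ends, matching how binding-site
coordinates are printed in the target-prediction literature.
"""
from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

VALID_TOOLS = ("miranda", "targetscan", "pictar")
REGIONS = ("utr5", "cds", "utr3")
UNASSIGNED = "unassigned"
EXPRESSION_REGIONS = ("midbrain", "cerebellum", "hippocampus", "frontal_cortex")

_NUC_RE = re.compile(r"^[ACGTUacgtu]+$")
_MIRNA_ID_RE = re.compile(r"^([A-Za-z]{3,4})-(mir|let)-(.+)$", re.IGNORECASE)


def normalize_mirna_id(raw: str) -> str:
    """Canonicalise a mature miRNA identifier to ``hsa-miR-<n>[-arm]`` form.

    Collapses the precursor/mature capitalisation split (``hsa-mir-323-5p``
    vs ``hsa-miR-323-5p``) so identifiers from different table sources
    compare equal.  Idempotent; unrecognised patterns pass through with a
    warning.
    """
    if not raw:
        raise ValueError("miRNA id must be a non-empty string")
    m = _MIRNA_ID_RE.match(raw.strip())
    if m is None:
        warnings.warn(f"miRNA id {raw!r} does not match the expected pattern; "
                      "left unchanged", stacklevel=2)
        return raw.strip()
    species, family, rest = m.group(1).lower(), m.group(2).lower(), m.group(3).lower()
    family = "miR" if family == "mir" else "let"
    return f"{species}-{family}-{rest}"


@dataclass(frozen=True)
class GeneModel:
    """A gene sequence partitioned into 5'UTR / CDS / 3'UTR.

    ``sequence`` may be omitted when only region annotation is needed, in
    which case ``length`` must be given explicitly.
    """
    gene_id: str
    symbol: str = ""
    chromosome: str | None = None
    sequence: str | None = None
    cds_start: int = 1
    cds_end: int = 1
    length: int | None = None

    def __post_init__(self):
        if self.sequence is not None:
            if not _NUC_RE.match(self.sequence):
                raise ValueError(f"gene {self.gene_id}: non-nucleotide characters in sequence")
            object.__setattr__(self, "sequence", self.sequence.upper())
            if self.length is None:
                object.__setattr__(self, "length", len(self.sequence))
            elif self.length != len(self.sequence):
                raise ValueError(f"gene {self.gene_id}: length {self.length} != sequence length")
        if self.length is None:
            raise ValueError(f"gene {self.gene_id}: need a sequence or an explicit length")
        if not (1 <= self.cds_start <= self.cds_end <= self.length):
            raise ValueError(
                f"gene {self.gene_id}: CDS [{self.cds_start}, {self.cds_end}] does not "
                f"respect 1 <= cds_start <= cds_end <= {self.length}")

    def region_of(self, pos: int) -> str:
        """Region (utr5 / cds / utr3) containing 1-based position ``pos``."""
        if not (1 <= pos <= self.length):
            raise ValueError(f"position {pos} outside gene {self.gene_id} [1, {self.length}]")
        if pos < self.cds_start:
            return "utr5"
        if pos <= self.cds_end:
            return "cds"
        return "utr3"

    def region_bounds(self, region: str) -> tuple[int, int] | None:
        """1-based inclusive bounds of a region, or None when it is empty."""
        if region == "utr5":
            return (1, self.cds_start - 1) if self.cds_start > 1 else None
        if region == "cds":
            return (self.cds_start, self.cds_end)
        if region == "utr3":
            return (self.cds_end + 1, self.length) if self.cds_end < self.length else None
        raise ValueError(f"unknown region {region!r}")


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA: id, 5'->3' RNA sequence, brain regions of expression."""
    mirna_id: str
    sequence: str
    expression_regions: frozenset[str] = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "mirna_id", normalize_mirna_id(self.mirna_id))
        if not _NUC_RE.match(self.sequence):
            raise ValueError(f"{self.mirna_id}: non-nucleotide characters in sequence")
        object.__setattr__(self, "sequence", self.sequence.upper().replace("T", "U"))
        if not (16 <= len(self.sequence) <= 28):
            raise ValueError(f"{self.mirna_id}: mature miRNA length {len(self.sequence)} "
                             "outside [16, 28]")
        regs = frozenset(self.expression_regions)
        bad = regs - set(EXPRESSION_REGIONS)
        if bad:
            raise ValueError(f"{self.mirna_id}: unknown expression regions {sorted(bad)}")
        object.__setattr__(self, "expression_regions", regs)


@dataclass(frozen=True)
class TargetSite:
    """One predicted miRNA binding interval on a gene, with tool provenance."""
    gene_id: str
    mirna_id: str
    tool: str
    start: int
    end: int
    region: str = UNASSIGNED
    score: float | None = None
    energy: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "mirna_id", normalize_mirna_id(self.mirna_id))
        if self.tool not in VALID_TOOLS:
            raise ValueError(f"unknown tool {self.tool!r}; allowed: {', '.join(VALID_TOOLS)}")
        if self.start > self.end:
            raise ValueError(f"site {self.gene_id}/{self.mirna_id}: start {self.start} > "
                             f"end {self.end}")
        if self.start < 1:
            raise ValueError(f"site {self.gene_id}/{self.mirna_id}: start must be >= 1")
        if self.region not in REGIONS and self.region != UNASSIGNED:
            raise ValueError(f"unknown region {self.region!r}")

    @property
    def key(self) -> tuple:
        return (self.gene_id, self.mirna_id, self.tool, self.start, self.end)

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    def with_region(self, region: str) -> "TargetSite":
        return replace(self, region=region)


@dataclass
class SiteTable:
    """An ordered collection of target sites with free-text provenance."""
    records: list[TargetSite] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def deduplicate(self) -> tuple["SiteTable", int]:
        """Drop duplicate (gene, miRNA, tool, start, end) rows.

        Returns the deduplicated table and the number of rows dropped; the
        first occurrence of each key is kept.
        """
        seen: set[tuple] = set()
        kept: list[TargetSite] = []
        for rec in self.records:
            if rec.key in seen:
                continue
            seen.add(rec.key)
            kept.append(rec)
        return SiteTable(kept, self.provenance), len(self.records) - len(kept)

    def by_tool(self, tool: str) -> "SiteTable":
        if tool not in VALID_TOOLS:
            raise ValueError(f"unknown tool {tool!r}")
        return SiteTable([r for r in self.records if r.tool == tool], self.provenance)
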