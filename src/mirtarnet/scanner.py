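"""Seed-weighted miRNA target-site scanner.

The scanner finds local complementarity alignments between a mature miRNA
(5'->3') and the antiparallel gene strand, Gotoh affine-gap dynamic
programming with per-position weighting: contributions at miRNA seed
positions (2-8 from the 5' end) are multiplied by a scaling factor, which
encodes the biological dominance of seed pairing in target recognition.
Candidate sites must clear both a raw alignment score threshold and a
duplex free-energy threshold computed from a nearest-neighbor stacking
model.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .models import GeneModel, MatureMiRNA, SiteTable, TargetSite

log = logging.getLogger(__name__)

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
_NEG = -1e30
_warned_gap_regime = False

#: kcal/mol charged per nucleotide left unpaired (mismatched or gapped)
#: inside the duplex; crude stand-in for internal loop/bulge costs.
UNPAIRED_PENALTY = 0.5
#: stacking contribution when one of the two stacked pairs is a G:U wobble.
WOBBLE_STACK = -0.5


def _load_stack_table() -> dict[str, float]:
    import pandas as pd
    with resources.as_file(
            resources.files("mirtarnet").joinpath("data", "rna_stack_energies.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    return dict(zip(df["dinucleotide"], df["delta_g"].astype(float)))


#: Turner-style nearest-neighbor free energies (kcal/mol) for two stacked
#: Watson-Crick pairs, keyed by the 5'->3' dinucleotide on the miRNA strand.
STACK_ENERGIES = _load_stack_table()


@dataclass
class ScannerParams:
    """Thresholds and scoring weights of the scanner.

    Defaults mirror the classic miRanda-style run: gap open 2.0 / extend
    8.0, minimum alignment score 150, maximum duplex energy -25 kcal/mol,
    seed scaling 3.0, and the conventional +5 / +1 / -3 per-position scores
    for Watson-Crick, G:U wobble and mismatched columns.
    """
    gap_open_penalty: float = 2.0
    gap_extend_penalty: float = 8.0
    score_threshold: float = 150.0
    energy_threshold: float = -25.0
    seed_scaling: float = 3.0
    match_score: float = 5.0
    gu_wobble_score: float = 1.0
    mismatch_score: float = -3.0
    seed_positions: tuple[int, ...] = tuple(range(2, 9))

    def __post_init__(self):
        for name in ("gap_open_penalty", "gap_extend_penalty"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("score_threshold", "energy_threshold", "seed_scaling",
                     "match_score", "gu_wobble_score", "mismatch_score"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.seed_scaling < 1:
            raise ValueError("seed_scaling must be >= 1")
        if any(p < 1 for p in self.seed_positions):
            raise ValueError("seed positions are 1-based from the miRNA 5' end")
        if self.gap_open_penalty < self.gap_extend_penalty:
            global _warned_gap_regime
            if not _warned_gap_regime:
                log.warning("gap open penalty (%.2f) < gap extend penalty (%.2f): "
                            "unusual affine-gap regime", self.gap_open_penalty,
                            self.gap_extend_penalty)
                _warned_gap_regime = True

    def substitution_matrix(self) -> np.ndarray:
        """4x4 per-column scores indexed by (miRNA base, gene base)."""
        s = np.full((4, 4), self.mismatch_score)
        for x in range(4):
            for y in range(4):
                if x + y == 3:           # A:U / C:G Watson-Crick
                    s[x, y] = self.match_score
                elif x + y == 5:         # G:U wobble
                    s[x, y] = self.gu_wobble_score
        return s

    def weight_vector(self, mirna_len: int) -> np.ndarray:
        w = np.ones(mirna_len)
        for p in self.seed_positions:
            if p <= mirna_len:
                w[p - 1] = self.seed_scaling
        return w


@dataclass
class DuplexAlignment:
    """One local miRNA:gene duplex.

    ``columns`` lists alignment columns 5'->3' on the miRNA as
    (mirna_pos, gene_pos, kind) with 1-based positions, ``None`` for a gap,
    and kind in {"wc", "wobble", "mismatch", "gap"}.  Gene positions are
    1-based within the scanned window, decreasing along the alignment
    because the duplex is antiparallel.
    """
    mirna_seq: str
    gene_window: str
    columns: list[tuple[int | None, int | None, str]]
    raw_score: float
    gene_start: int
    gene_end: int
    energy: float | None = None

    @property
    def paired(self) -> list[tuple[int, int]]:
        return [(i, j) for i, j, kind in self.columns if kind in ("wc", "wobble")]


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_ENC[c] for c in seq.upper()], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"non-nucleotide character {exc.args[0]!r} in sequence") from exc


def _gotoh(q, t, smat, wvec, open_pen, ext_pen):
    """Local affine-gap DP; returns score and pointer matrices."""
    m, n = q.shape[0], t.shape[0]
    M = np.full((m + 1, n + 1), _NEG)
    Ix = np.full((m + 1, n + 1), _NEG)
    Iy = np.full((m + 1, n + 1), _NEG)
    PM = np.zeros((m + 1, n + 1), dtype=np.int8)
    PIx = np.zeros((m + 1, n + 1), dtype=np.int8)
    PIy = np.zeros((m + 1, n + 1), dtype=np.int8)
    oe = open_pen + ext_pen
    for i in range(1, m + 1):
        wi = wvec[i - 1]
        qi = q[i - 1]
        for j in range(1, n + 1):
            # gap in the gene (consume miRNA base i)
            a = M[i - 1, j] - oe
            b = Ix[i - 1, j] - ext_pen
            if a >= b:
                Ix[i, j] = a
                PIx[i, j] = 1
            else:
                Ix[i, j] = b
                PIx[i, j] = 2
            # gap in the miRNA (consume gene base j)
            a = M[i, j - 1] - oe
            b = Iy[i, j - 1] - ext_pen
            if a >= b:
                Iy[i, j] = a
                PIy[i, j] = 1
            else:
                Iy[i, j] = b
                PIy[i, j] = 2
            # aligned column
            best = 0.0
            ptr = 0
            if M[i - 1, j - 1] > best:
                best = M[i - 1, j - 1]
                ptr = 1
            if Ix[i - 1, j - 1] > best:
                best = Ix[i - 1, j - 1]
                ptr = 2
            if Iy[i - 1, j - 1] > best:
                best = Iy[i - 1, j - 1]
                ptr = 3
            M[i, j] = best + wi * smat[qi, t[j - 1]]
            PM[i, j] = ptr
    return M, Ix, Iy, PM, PIx, PIy


try:  # JIT the kernel when numba is importable; the pure-Python path is identical
    from numba import njit

    _gotoh = njit(cache=True)(_gotoh)
except ImportError:  # pragma: no cover
    pass


def _traceback(i, j, PM, PIx, PIy):
    """Walk pointers back from aligned cell (i, j); returns columns in 5'->3' order."""
    cols = []
    state = 0  # 0=M, 1=Ix, 2=Iy
    while True:
        if state == 0:
            cols.append((i, j, "col"))
            ptr = PM[i, j]
            i, j = i - 1, j - 1
            if ptr == 0:
                break
            state = {1: 0, 2: 1, 3: 2}[ptr]
        elif state == 1:
            cols.append((i, None, "gap"))
            ptr = PIx[i, j]
            i -= 1
            state = 0 if ptr == 1 else 1
        else:
            cols.append((None, j, "gap"))
            ptr = PIy[i, j]
            j -= 1
            state = 0 if ptr == 1 else 2
    cols.reverse()
    return cols


def _column_kind(mx: str, gx: str) -> str:
    a, b = _ENC[mx], _ENC[gx]
    if a + b == 3:
        return "wc"
    if a + b == 5:
        return "wobble"
    return "mismatch"


def _build_alignment(mirna_seq, window, cols_rev, score) -> DuplexAlignment:
    """Convert reversed-window traceback columns into forward coordinates."""
    n = len(window)
    columns = []
    for i, jr, kind in cols_rev:
        j = None if jr is None else n - jr + 1  # reversed -> forward position
        if kind == "col":
            kind = _column_kind(mirna_seq[i - 1], window[j - 1])
        columns.append((i, j, kind))
    gene_positions = [j for _, j, _ in columns if j is not None]
    return DuplexAlignment(
        mirna_seq=mirna_seq, gene_window=window, columns=columns,
        raw_score=float(score), gene_start=min(gene_positions),
        gene_end=max(gene_positions))


def align_duplex(mirna, gene_window: str, params: ScannerParams | None = None) -> DuplexAlignment:
    """Best local duplex between a miRNA and one gene window.

    ``mirna`` may be a :class:`MatureMiRNA` or a plain 5'->3' sequence
    string.  The gene window is given 5'->3'; T and U are equivalent.
    """
    params = params or ScannerParams()
    seq = mirna.sequence if isinstance(mirna, MatureMiRNA) else str(mirna)
    if len(gene_window) < len(seq) - 5:
        raise ValueError("gene window shorter than miRNA length - 5")
    q = _encode(seq)
    t_rev = _encode(gene_window)[::-1].copy()
    M, _, _, PM, PIx, PIy = _gotoh(
        q, t_rev, params.substitution_matrix(), params.weight_vector(len(q)),
        params.gap_open_penalty, params.gap_extend_penalty)
    best = np.unravel_index(np.argmax(M), M.shape)
    score = M[best]
    if score <= 0:
        return DuplexAlignment(seq, gene_window, [], float(max(score, 0.0)),
                               gene_start=0, gene_end=0)
    cols_rev = _traceback(best[0], best[1], PM, PIx, PIy)
    aln = _build_alignment(seq, gene_window, cols_rev, score)
    aln.energy = duplex_energy(aln)
    return aln


def duplex_energy(alignment: DuplexAlignment) -> float:
    """Duplex free energy (kcal/mol) of an alignment.

    Sum of nearest-neighbor stack terms over consecutive paired columns
    (contiguous on both strands) plus a fixed penalty per unpaired
    nucleotide inside the duplex.  Watson-Crick stacks use the packaged
    table; stacks involving a wobble pair contribute ``WOBBLE_STACK``.
    """
    pairs = alignment.paired
    if not pairs:
        raise ValueError("alignment has no paired positions")
    kinds = {(i, j): kind for i, j, kind in alignment.columns if kind in ("wc", "wobble")}
    energy = 0.0
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        if i2 == i1 + 1 and j2 == j1 - 1:  # contiguous stack (antiparallel)
            if kinds[(i1, j1)] == "wc" and kinds[(i2, j2)] == "wc":
                energy += STACK_ENERGIES[alignment.mirna_seq[i1 - 1]
                                         + alignment.mirna_seq[i2 - 1]]
            else:
                energy += WOBBLE_STACK
    unpaired = 0
    for i, j, kind in alignment.columns:
        if kind == "mismatch":
            unpaired += 2
        elif kind == "gap":
            unpaired += 1
    return energy + UNPAIRED_PENALTY * unpaired


def scan_gene(gene: GeneModel, mirna: MatureMiRNA,
              params: ScannerParams | None = None) -> list[TargetSite]:
    """All target sites of one miRNA on one gene passing both thresholds.

    Runs one local DP over the whole gene, tracebacks every cell at or
    above the score threshold, keeps alignments that also satisfy the
    energy threshold, and merges overlapping candidates for the same miRNA
    to the best-scoring one (ties: smaller start).  Coordinates in the
    result are 1-based inclusive on the gene.
    """
    params = params or ScannerParams()
    if gene.sequence is None:
        raise ValueError(f"gene {gene.gene_id} has no sequence; cannot scan")
    q = _encode(mirna.sequence)
    t_rev = _encode(gene.sequence)[::-1].copy()
    M, _, _, PM, PIx, PIy = _gotoh(
        q, t_rev, params.substitution_matrix(), params.weight_vector(len(q)),
        params.gap_open_penalty, params.gap_extend_penalty)
    ii, jj = np.nonzero(M >= params.score_threshold)
    candidates = []
    for i, j in zip(ii.tolist(), jj.tolist()):
        cols_rev = _traceback(i, j, PM, PIx, PIy)
        aln = _build_alignment(mirna.sequence, gene.sequence, cols_rev, M[i, j])
        aln.energy = duplex_energy(aln)
        if aln.energy <= params.energy_threshold:
            candidates.append(aln)
    candidates.sort(key=lambda a: (-a.raw_score, a.gene_start))
    accepted: list[DuplexAlignment] = []
    for aln in candidates:
        if any(aln.gene_start <= kept.gene_end and kept.gene_start <= aln.gene_end
               for kept in accepted):
            continue
        accepted.append(aln)
    accepted.sort(key=lambda a: a.gene_start)
    return [TargetSite(gene_id=gene.gene_id, mirna_id=mirna.mirna_id, tool="miranda",
                       start=a.gene_start, end=a.gene_end,
                       score=round(a.raw_score, 4), energy=round(a.energy, 4))
            for a in accepted]


def scan_many(genes, mirnas, params: ScannerParams | None = None) -> SiteTable:
    """Scan every gene x miRNA combination into one site table (tool=miranda)."""
    params = params or ScannerParams()
    records: list[TargetSite] = []
    for gene in genes:
        for mirna in mirnas:
            records.extend(scan_gene(gene, mirna, params))
    return SiteTable(records, provenance="seed scanner")
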