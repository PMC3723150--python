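"""Independent brute-force oracles used by the test suite.

These deliberately avoid the production code paths: the alignment oracle
enumerates every monotone pairing between miRNA and antiparallel gene
positions, and the hotspot oracle transcribes the chaining rule literally
on sorted starts.
"""
from __future__ import annotations

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}


def _col_score(x: str, y: str, params) -> float:
    a, b = _ENC[x], _ENC[y]
    if a + b == 3:
        return params.match_score
    if a + b == 5:
        return params.gu_wobble_score
    return params.mismatch_score


def brute_force_best_score(mirna: str, window: str, params) -> float:
    """Optimal local duplex score by exhaustive enumeration.

    Enumerates every increasing pairing between miRNA positions (5'->3')
    and positions of the window read 3'->5'; unpaired stretches between
    consecutive paired columns cost one affine gap event per strand.
    Intended for tiny sequences only (cost ~ C(len_q + len_t, len_q)).
    """
    q = mirna.upper()
    t = window.upper()[::-1]
    nq, nt = len(q), len(t)
    weights = [params.seed_scaling if (i + 1) in params.seed_positions else 1.0
               for i in range(nq)]

    def gap_cost(length: int) -> float:
        return 0.0 if length == 0 else params.gap_open_penalty + \
            params.gap_extend_penalty * length

    best = 0.0

    def rec(last_i: int, last_j: int, score: float):
        nonlocal best
        if score > best:
            best = score
        for i in range(last_i + 1, nq):
            for j in range(last_j + 1, nt):
                add = weights[i] * _col_score(q[i], t[j], params)
                if last_i >= 0:
                    add -= gap_cost(i - last_i - 1) + gap_cost(j - last_j - 1)
                rec(i, j, score + add)

    rec(-1, -1, 0.0)
    return best


def brute_force_hotspots(sites, min_mirnas: int, start_window: int):
    """Literal transcription of the chaining rule on sorted starts.

    Returns a set of frozensets of site keys, one per qualifying chain.
    """
    groups: dict[tuple, list] = {}
    for s in sites:
        groups.setdefault((s.gene_id, s.region), []).append(s)
    result = set()
    for members in groups.values():
        members.sort(key=lambda s: (s.start, s.end, s.mirna_id))
        run = [members[0]]
        for s in members[1:]:
            if s.start - run[-1].start <= start_window:
                run.append(s)
            else:
                if len({x.mirna_id for x in run}) >= min_mirnas:
                    result.add(frozenset(x.key for x in run))
                run = [s]
        if len({x.mirna_id for x in run}) >= min_mirnas:
            result.add(frozenset(x.key for x in run))
    return result
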