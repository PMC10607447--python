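"""Low-level alignment kernels: Needleman-Wunsch DP, k-mer anchor
chaining for genome-scale alignment, and a seed-and-extend ungapped
protein HSP search (BLAST-style) used by the SG statistic.

Scoring conventions are deliberately explicit and deterministic:
nucleotide DP uses match +2 / mismatch -1 / gap -5 with tie-break
diagonal > up (gap in b) > left (gap in a), so that an independent
reimplementation of the same recurrence reproduces identity counts
exactly.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MATCH = 2
MISMATCH = -1
GAP = -5

_DNA_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _DNA_LUT[ord(_b)] = _i


def encode_dna(seq: str) -> np.ndarray:
    """A=0 C=1 G=2 T=3, anything else (N) = 4; N never matches."""
    return _DNA_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@njit(cache=True)
def _nw_fill(a, b):  # pragma: no cover - exercised via nw_stats
    n, m = a.shape[0], b.shape[0]
    H = np.empty((n + 1, m + 1), np.int32)
    P = np.empty((n + 1, m + 1), np.uint8)  # 0 diag, 1 up, 2 left
    H[0, 0] = 0
    P[0, 0] = 0
    for i in range(1, n + 1):
        H[i, 0] = GAP * i
        P[i, 0] = 1
    for j in range(1, m + 1):
        H[0, j] = GAP * j
        P[0, j] = 2
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = MATCH if (ai == b[j - 1] and ai < 4) else MISMATCH
            d = H[i - 1, j - 1] + s
            u = H[i - 1, j] + GAP
            l = H[i, j - 1] + GAP
            if d >= u and d >= l:
                H[i, j] = d
                P[i, j] = 0
            elif u >= l:
                H[i, j] = u
                P[i, j] = 1
            else:
                H[i, j] = l
                P[i, j] = 2
    return H, P


@njit(cache=True)
def _nw_traceback_stats(a, b, H, P):  # pragma: no cover
    n, m = a.shape[0], b.shape[0]
    cols = np.empty(n + m, np.uint8)  # 0 match, 1 mismatch, 2 gap
    k = 0
    i, j = n, m
    while i > 0 or j > 0:
        p = P[i, j]
        if p == 0 and i > 0 and j > 0:
            cols[k] = 0 if (a[i - 1] == b[j - 1] and a[i - 1] < 4) else 1
            i -= 1
            j -= 1
        elif p == 1 and i > 0:
            cols[k] = 2
            i -= 1
        else:
            cols[k] = 2
            j -= 1
        k += 1
    # cols is reversed; trim terminal gap runs from both ends
    start = 0
    while start < k and cols[k - 1 - start] == 2:
        start += 1
    end = k
    while end > start and cols[k - end] == 2:
        end -= 1
    matches = 0
    gaps_internal = 0
    for t in range(start, end):
        c = cols[k - 1 - t]
        if c == 0:
            matches += 1
        elif c == 2:
            gaps_internal += 1
    total = end - start
    return matches, gaps_internal, total, H[n, m]


def nw_stats(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int, int]:
    """Full global DP.  Returns (matches, internal_gap_columns,
    columns_after_terminal_trim, score); terminal gap runs (overhangs)
    are excluded from the column counts."""
    if a.shape[0] == 0 or b.shape[0] == 0:
        return 0, 0, 0, GAP * (a.shape[0] + b.shape[0])
    H, P = _nw_fill(a, b)
    return _nw_traceback_stats(a, b, H, P)


def edlib_stats(a_str: str, b_str: str) -> tuple[int, int, int]:
    """(matches, internal_gap_columns, trimmed_columns) from an edlib
    global alignment; used for segments too large for the score DP."""
    import edlib

    res = edlib.align(a_str, b_str, task="path", mode="NW")
    cigar = res["cigar"]
    matches = gaps = total = 0
    ai = bi = 0
    full_ops: list[tuple[int, str]] = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            full_ops.append((int(num), ch))
            num = ""
    lead = 0
    while lead < len(full_ops) and full_ops[lead][1] in "ID":
        ln, op = full_ops[lead]
        if op == "I":  # edlib: I consumes the query (first argument)
            ai += ln
        else:  # D consumes the target
            bi += ln
        lead += 1
    tail = len(full_ops)
    while tail > lead and full_ops[tail - 1][1] in "ID":
        tail -= 1
    for ln, op in full_ops[lead:tail]:
        if op in "=XM":
            if op == "=":
                matches += ln
            elif op == "M":
                for t in range(ln):
                    if a_str[ai + t] == b_str[bi + t] and a_str[ai + t] != "N":
                        matches += 1
            ai += ln
            bi += ln
            total += ln
        else:
            gaps += ln
            total += ln
            if op == "I":
                ai += ln
            else:
                bi += ln
    return matches, gaps, total


# ---------------------------------------------------------------------------
# k-mer anchor chaining


def _unique_kmers(seq: str, k: int) -> dict[str, int]:
    pos: dict[str, int] = {}
    dup: set[str] = set()
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if km in dup:
            continue
        if km in pos:
            del pos[km]
            dup.add(km)
        else:
            pos[km] = i
    return pos


def chain_anchors(a: str, b: str, k: int = 15) -> list[tuple[int, int, int]]:
    """Collinear chain of unique exact k-mer matches as (pos_a, pos_b, length)
    runs, non-overlapping and strictly increasing in both genomes.

    The chain is the longest increasing subsequence of unique-in-both
    k-mer matches ordered by position in ``a``; anchors stranded alone
    on their own diagonal are discarded as chance matches.
    """
    ka = _unique_kmers(a, k)
    if not ka:
        return []
    matches: list[tuple[int, int]] = []
    kb_seen: dict[str, int] = {}
    kb_dup: set[str] = set()
    for j in range(len(b) - k + 1):
        km = b[j : j + k]
        if km in kb_dup:
            continue
        if km in kb_seen:
            kb_dup.add(km)
            del kb_seen[km]
        else:
            kb_seen[km] = j
    for km, i in ka.items():
        j = kb_seen.get(km)
        if j is not None:
            matches.append((i, j))
    if not matches:
        return []
    matches.sort()
    # LIS on pos_b (strict) via patience sorting
    import bisect

    tails: list[int] = []
    tails_idx: list[int] = []
    back = [-1] * len(matches)
    for idx, (_, pb) in enumerate(matches):
        t = bisect.bisect_left(tails, pb)
        if t == len(tails):
            tails.append(pb)
            tails_idx.append(idx)
        else:
            tails[t] = pb
            tails_idx[t] = idx
        back[idx] = tails_idx[t - 1] if t > 0 else -1
    chain_rev = []
    cur = tails_idx[-1]
    while cur != -1:
        chain_rev.append(matches[cur])
        cur = back[cur]
    chain = chain_rev[::-1]
    # drop anchors sitting alone on their own diagonal: a chance k-mer
    # match agrees with neither neighbour, while anchors flanking a true
    # indel still agree with one side
    if len(chain) >= 3:
        diags = [pa - pb for pa, pb in chain]
        keep = [True] * len(chain)
        for t in range(1, len(chain) - 1):
            if diags[t] != diags[t - 1] and diags[t] != diags[t + 1]:
                keep[t] = False
        chain = [c for c, kp in zip(chain, keep) if kp]
    # merge same-diagonal overlaps, trim off-diagonal overlaps
    runs: list[list[int]] = []
    for pa, pb in chain:
        ln = k
        if runs:
            ra, rb, rl = runs[-1]
            if pa - pb == ra - rb and pa <= ra + rl:
                runs[-1][2] = pa + k - ra
                continue
            overlap = max(ra + rl - pa, rb + rl - pb)
            if overlap > 0:
                pa += overlap
                pb += overlap
                ln -= overlap
                if ln <= 0:
                    continue
        runs.append([pa, pb, ln])
    return [tuple(r) for r in runs]


# ---------------------------------------------------------------------------
# protein HSP search (seed-and-extend, ungapped, X-drop)

PROTEIN_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
_AA_LUT = np.full(256, PROTEIN_ALPHABET.index("X"), dtype=np.uint8)
for _i, _c in enumerate(PROTEIN_ALPHABET):
    _AA_LUT[ord(_c)] = _i

_BLOSUM: np.ndarray | None = None


def blosum62_matrix() -> np.ndarray:
    """BLOSUM62 as an int16 matrix over PROTEIN_ALPHABET (from Biopython)."""
    global _BLOSUM
    if _BLOSUM is None:
        from Bio.Align import substitution_matrices

        mat = substitution_matrices.load("BLOSUM62")
        n = len(PROTEIN_ALPHABET)
        arr = np.zeros((n, n), dtype=np.int16)
        for i, x in enumerate(PROTEIN_ALPHABET):
            for j, y in enumerate(PROTEIN_ALPHABET):
                arr[i, j] = int(mat[x][y])
        _BLOSUM = arr
    return _BLOSUM


def encode_protein(seq: str) -> np.ndarray:
    return _AA_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


_SEED_LEN = 4
_NAA = 24
_STAR = PROTEIN_ALPHABET.index("*")
_X = PROTEIN_ALPHABET.index("X")


@njit(cache=True)
def _hsp_search(qa, qb, blosum, xdrop, min_score, max_hsps):  # pragma: no cover
    """All ungapped HSPs between protein arrays qa (query) and qb.

    Returns (starts, ends, scores, n): HSP spans on qa coordinates.
    One extension per diagonal region (BLAST-style coverage skip).
    """
    la, lb = qa.shape[0], qb.shape[0]
    out_s = np.empty(max_hsps, np.int64)
    out_e = np.empty(max_hsps, np.int64)
    out_sc = np.empty(max_hsps, np.int64)
    n_out = 0
    if la < _SEED_LEN or lb < _SEED_LEN:
        return out_s, out_e, out_sc, 0
    nb = lb - _SEED_LEN + 1
    codes_b = np.empty(nb, np.int64)
    ok_b = np.empty(nb, np.uint8)
    for j in range(nb):
        c = 0
        ok = 1
        for t in range(_SEED_LEN):
            r = qb[j + t]
            if r >= 22:  # X or *
                ok = 0
            c = c * _NAA + r
        codes_b[j] = c
        ok_b[j] = ok
    order = np.argsort(codes_b, kind="mergesort")
    sorted_codes = codes_b[order]
    covered = np.full(la + lb + 1, -1, np.int64)  # a-end covered per diagonal
    na = la - _SEED_LEN + 1
    for i in range(na):
        c = 0
        ok = 1
        for t in range(_SEED_LEN):
            r = qa[i + t]
            if r >= 22:
                ok = 0
            c = c * _NAA + r
        if ok == 0:
            continue
        lo = np.searchsorted(sorted_codes, c, side="left")
        hi = np.searchsorted(sorted_codes, c, side="right")
        for h in range(lo, hi):
            j = order[h]
            if ok_b[j] == 0:
                continue
            diag = i - j + lb
            if covered[diag] >= i:
                continue
            # seed score
            sc = 0
            for t in range(_SEED_LEN):
                sc += blosum[qa[i + t], qb[j + t]]
            # extend right
            best_r = 0
            cur = 0
            t = 0
            ar, br = i + _SEED_LEN, j + _SEED_LEN
            ext_r = 0
            while ar + t < la and br + t < lb:
                cur += blosum[qa[ar + t], qb[br + t]]
                if cur > best_r:
                    best_r = cur
                    ext_r = t + 1
                if best_r - cur > xdrop:
                    break
                t += 1
            # extend left
            best_l = 0
            cur = 0
            t = 1
            ext_l = 0
            while i - t >= 0 and j - t >= 0:
                cur += blosum[qa[i - t], qb[j - t]]
                if cur > best_l:
                    best_l = cur
                    ext_l = t
                if best_l - cur > xdrop:
                    break
                t += 1
            total = sc + best_r + best_l
            hsp_s = i - ext_l
            hsp_e = i + _SEED_LEN + ext_r
            covered[diag] = hsp_e
            if total >= min_score and n_out < max_hsps:
                out_s[n_out] = hsp_s
                out_e[n_out] = hsp_e
                out_sc[n_out] = total
                n_out += 1
    return out_s, out_e, out_sc, n_out


def hsp_search(
    qa: np.ndarray,
    qb: np.ndarray,
    xdrop: int = 20,
    min_score: int = 50,
    max_hsps: int = 20000,
) -> list[tuple[int, int, int]]:
    """Ungapped BLOSUM62 HSPs (start, end, score) on query coordinates."""
    s, e, sc, n = _hsp_search(qa, qb, blosum62_matrix(), xdrop, min_score, max_hsps)
    return [(int(s[t]), int(e[t]), int(sc[t])) for t in range(n)]
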