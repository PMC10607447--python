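"""Deterministic six-frame ORF calling under a specified genetic code.

An ORF runs from a start codon to the next in-frame stop codon of the
code in use; with the default ``longest_per_stop`` policy only the
longest ORF ending at each stop is kept.  ORF coordinates include the
terminal stop codon, so the protein length is (end-start)/3 - 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seq_core import (
    STANDARD_STOPS,
    GeneticCode,
    GenomeRecord,
    reverse_complement,
    translate,
)

_BASE_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_LUT[ord(_b)] = _i

_START_CODONS_DEFAULT = frozenset({"ATG", "GTG", "TTG"})


def _codon_code(codon: str) -> int:
    return 16 * _BASE_LUT[ord(codon[0])] + 4 * _BASE_LUT[ord(codon[1])] + _BASE_LUT[ord(codon[2])]


@dataclass(frozen=True)
class OrfCallerParams:
    """Conventional prokaryotic-caller defaults; all exposed in config."""

    min_length_aa: int = 30
    start_codons: frozenset[str] = _START_CODONS_DEFAULT
    overlap_policy: str = "longest_per_stop"  # or "keep_all"

    def __post_init__(self) -> None:
        if self.min_length_aa < 10:
            raise ValueError("min_length_aa must be >= 10")
        if not self.start_codons <= {"ATG", "GTG", "TTG"}:
            raise ValueError("start codons limited to {ATG, GTG, TTG}")
        if self.overlap_policy not in ("longest_per_stop", "keep_all"):
            raise ValueError(f"unknown overlap_policy {self.overlap_policy!r}")


@dataclass
class OrfCall:
    """A predicted coding region (0-based half-open, forward-strand coords).

    ``internal_reassigned_stops`` holds the forward-strand leftmost
    coordinate of every internal codon that is a stop under the standard
    bacterial code (table 11) but a sense codon under ``table_id``; it is
    empty whenever table_id == 11.
    """

    genome_id: str
    start: int
    end: int
    strand: str
    frame: int
    table_id: int
    protein: str
    internal_reassigned_stops: list[int] = field(default_factory=list)
    wraps: bool = False

    @property
    def length_aa(self) -> int:
        return (self.end - self.start) // 3 - 1

    def coding_sequence(self, genome: GenomeRecord) -> str:
        seq = genome.seq
        if self.wraps:
            seq = seq + seq
        sub = seq[self.start : self.end]
        return sub if self.strand == "+" else reverse_complement(sub)


def _scan_strand(seq: str, code: GeneticCode, params: OrfCallerParams):
    """Yield (start, end, frame) ORF spans on the given strand sequence."""
    n = len(seq)
    if n < 6:
        return
    b = _BASE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    valid = (b[:-2] < 4) & (b[1:-1] < 4) & (b[2:] < 4)
    codes = (16 * b[:-2].astype(np.int16) + 4 * b[1:-1] + b[2:])
    codes[~valid] = 64  # N-containing codons never match start/stop
    stop_codes = np.array(sorted(_codon_code(c) for c in code.stop_codons), dtype=np.int16)
    start_codes = np.array(sorted(_codon_code(c) for c in params.start_codons), dtype=np.int16)
    for frame in range(3):
        ci = np.arange(frame, n - 2, 3)
        fcodes = codes[ci]
        stops = np.nonzero(np.isin(fcodes, stop_codes))[0]
        starts = np.nonzero(np.isin(fcodes, start_codes))[0]
        seg_begin = 0
        for s in stops:
            j = np.searchsorted(starts, seg_begin)
            if params.overlap_policy == "longest_per_stop":
                cand = starts[j : j + 1]
            else:
                cand = starts[j:]
            for st in cand:
                if st >= s:
                    break
                yield int(ci[st]), int(ci[s]) + 3, frame
            seg_begin = s + 1


def find_orfs(
    genome: GenomeRecord,
    code: GeneticCode,
    params: OrfCallerParams | None = None,
) -> list[OrfCall]:
    """Call ORFs on all six frames of ``genome`` under ``code``.

    On circular genomes the sequence is virtually doubled: ORFs starting
    in the first copy may run across the origin (flagged ``wraps``) but
    never exceed one genome length.  ORFs truncated by the end of a
    linear genome are discarded.
    """
    params = params or OrfCallerParams()
    L = len(genome)
    seq = genome.seq + genome.seq if genome.topology == "circular" else genome.seq
    reassigned = code.reassigned_stops
    orfs: list[OrfCall] = []

    def emit(start: int, end: int, frame: int, strand: str) -> None:
        if (end - start) // 3 - 1 < params.min_length_aa:
            return
        if genome.topology == "circular":
            if start >= L or end - start > L:
                return
            wraps = end > L
        else:
            wraps = False
        sub = seq[start:end] if strand == "+" else reverse_complement(seq[start:end])
        internal: list[int] = []
        if reassigned:
            for j in range(0, len(sub) - 3, 3):
                if sub[j : j + 3] in reassigned:
                    pos = start + j if strand == "+" else end - j - 3
                    internal.append(pos % L if genome.topology == "circular" else pos)
        protein = translate(sub[:-3], code)
        orfs.append(
            OrfCall(
                genome_id=genome.id, start=start, end=end, strand=strand,
                frame=frame, table_id=code.table_id, protein=protein,
                internal_reassigned_stops=sorted(internal), wraps=wraps,
            )
        )

    for s, e, f in _scan_strand(seq, code, params):
        emit(s, e, f, "+")
    rc = reverse_complement(seq)
    n = len(seq)
    for s, e, f in _scan_strand(rc, code, params):
        emit(n - e, n - s, f, "-")

    orfs.sort(key=lambda o: (o.start, o.end, o.strand))
    return orfs


class CodingModel:
    """Self-trained codon-usage model for coding-potential scoring.

    Trained on the codon counts of long ORFs (>= ``train_min_aa``),
    which are overwhelmingly real genes.  The directional score of an
    ORF is its mean per-codon log-likelihood minus that of reading its
    reverse complement with the same model; real genes score positive,
    antisense shadow ORFs negative.  This is a light-weight stand-in for
    the hexamer scoring real prokaryotic gene callers use.
    """

    def __init__(self, orfs: list[OrfCall], genome: GenomeRecord, train_min_aa: int = 100):
        counts = np.ones(64)  # add-one smoothing
        for o in orfs:
            if o.length_aa < train_min_aa:
                continue
            cds = o.coding_sequence(genome)
            b = _BASE_LUT[np.frombuffer(cds[:-3].encode("ascii"), dtype=np.uint8)]
            b = b[: 3 * (len(b) // 3)].reshape(-1, 3)
            ok = (b < 4).all(axis=1)
            codes = 16 * b[ok, 0] + 4 * b[ok, 1] + b[ok, 2]
            counts += np.bincount(codes, minlength=64)
        self._logf = np.log(counts / counts.sum())

    def _mean_llr(self, cds: str) -> float:
        b = _BASE_LUT[np.frombuffer(cds.encode("ascii"), dtype=np.uint8)]
        b = b[: 3 * (len(b) // 3)].reshape(-1, 3)
        ok = (b < 4).all(axis=1)
        if not ok.any():
            return 0.0
        codes = 16 * b[ok, 0] + 4 * b[ok, 1] + b[ok, 2]
        return float(self._logf[codes].mean())

    def directional_score(self, orf: OrfCall, genome: GenomeRecord) -> float:
        """Positive when the ORF reads better forward than reverse."""
        from .seq_core import reverse_complement

        cds = orf.coding_sequence(genome)[:-3]
        if len(cds) < 3:
            return 0.0
        return self._mean_llr(cds) - self._mean_llr(reverse_complement(cds))

    def frame_margin(self, orf: OrfCall, genome: GenomeRecord) -> float:
        """Own-frame mean log-likelihood minus the best of the other five
        reading frames over the same locus.

        A real gene reads best in its own frame; an antisense or
        frame-shifted shadow ORF is better explained by the frame of the
        gene it overlaps and scores negative.
        """
        from .seq_core import reverse_complement

        cds = orf.coding_sequence(genome)[:-3]
        if len(cds) < 9:
            return 0.0
        own = self._mean_llr(cds)
        rc = reverse_complement(cds)
        others = [self._mean_llr(cds[1:]), self._mean_llr(cds[2:])]
        others += [self._mean_llr(rc[off:]) for off in range(3)]
        return own - max(others)


def _cds_frame_margin(core: str, model: "CodingModel") -> float:
    from .seq_core import reverse_complement

    own = model._mean_llr(core)
    rc = reverse_complement(core)
    others = [model._mean_llr(core[1:]), model._mean_llr(core[2:])]
    others += [model._mean_llr(rc[off:]) for off in range(3)]
    return own - max(others)


def core3_margin(
    orf: OrfCall, genome: GenomeRecord, model: "CodingModel", window_aa: int = 200
) -> float:
    """Frame margin of the 3'-terminal portion of the ORF (coding strand).

    Anchoring at the 3' end (which sits at a genuine stop codon) spares
    genes whose start the caller over-extended upstream through
    non-coding sequence."""
    cds = orf.coding_sequence(genome)[:-3]
    core = cds[-3 * window_aa :]
    if len(core) < 30:
        return 0.0
    return _cds_frame_margin(core, model)


def trimmed_interval(
    orf: OrfCall,
    genome: GenomeRecord,
    model: "CodingModel",
    window_aa: int = 30,
    threshold: float = 0.0,
) -> tuple[int, int] | None:
    """ORF interval with its non-coding 5' prefix trimmed off.

    Walks 5'→3' in ``window_aa``-codon windows until a window's frame
    margin reaches ``threshold``; everything before it is treated as
    start over-extension.  Returns None when no window looks coding."""
    cds = orf.coding_sequence(genome)[:-3]
    n_cod = len(cds) // 3
    k = 0
    while k + window_aa <= n_cod:
        if _cds_frame_margin(cds[3 * k : 3 * (k + window_aa)], model) >= threshold:
            break
        k += window_aa
    else:
        if n_cod - k < 10 or _cds_frame_margin(cds[3 * k :], model) < threshold:
            return None
    off = 3 * k
    if orf.strand == "+":
        return (orf.start + off, orf.end)
    return (orf.start, orf.end - off)


def snap_orf_start(
    orf: OrfCall,
    genome: GenomeRecord,
    trim_codons: int,
    start_codons: frozenset[str] = _START_CODONS_DEFAULT,
) -> OrfCall:
    """Move the ORF start to the first start codon at or after the
    ``trim_codons``-th codon (coding strand), dropping a non-coding
    upstream extension.  Internal reassigned-stop positions outside the
    new span are removed.  Returns the original ORF when no start codon
    is found or fewer than 10 codons would remain."""
    if trim_codons <= 0:
        return orf
    cds = orf.coding_sequence(genome)
    n_cod = len(cds) // 3 - 1
    j = trim_codons
    while j <= n_cod - 10 and cds[3 * j : 3 * j + 3] not in start_codons:
        j += 1
    if j > n_cod - 10 or j == 0:
        return orf
    off = 3 * j
    if orf.strand == "+":
        new_start, new_end = orf.start + off, orf.end
    else:
        new_start, new_end = orf.start, orf.end - off
    internal = [p for p in orf.internal_reassigned_stops if new_start <= p < new_end - 2]
    return OrfCall(
        genome_id=orf.genome_id, start=new_start, end=new_end,
        strand=orf.strand, frame=orf.frame, table_id=orf.table_id,
        protein=orf.protein[j:], internal_reassigned_stops=internal,
        wraps=orf.wraps,
    )


def refined_orf_set(
    raw_orfs: list[OrfCall],
    genome: GenomeRecord,
    min_margin: float = 0.0,
    max_overlap_nt: int = 30,
    snap_starts: bool = False,
) -> tuple[list[OrfCall], float]:
    """Shadow-filtered, overlap-resolved annotation from six-frame calls.

    Three steps: (1) drop ORFs whose 3'-anchored core reads better in
    another frame (antisense/frame-shifted shadows of real genes, under
    the codon-bias model self-trained on the long calls); (2) trim each
    survivor's non-coding start over-extension to get its coding span;
    (3) greedily select ORFs by coding-span length with overlap between
    coding spans bounded by ``max_overlap_nt``.  Returns the selected
    ORFs (original, untrimmed coordinates) and the genome fraction
    covered by the union of all surviving coding spans.
    """
    if not raw_orfs:
        return [], 0.0
    model = CodingModel(raw_orfs, genome)
    kept: list[tuple[OrfCall, tuple[int, int]]] = []
    for o in raw_orfs:
        if core3_margin(o, genome, model) < min_margin:
            continue
        iv = trimmed_interval(o, genome, model)
        if iv is not None:
            kept.append((o, iv))
    spans = [iv for _, iv in kept]
    covered = 0.0
    if spans:
        ivs = sorted(spans)
        cs, ce = ivs[0]
        for s_, e_ in ivs[1:]:
            if s_ > ce:
                covered += ce - cs
                cs, ce = s_, e_
            else:
                ce = max(ce, e_)
        covered += ce - cs
    kept.sort(key=lambda t: (-(t[1][1] - t[1][0]), t[1][0], t[0].strand))
    accepted: list[tuple[OrfCall, tuple[int, int]]] = []
    for o, iv in kept:
        ok = True
        for _, aiv in accepted:
            if min(iv[1], aiv[1]) - max(iv[0], aiv[0]) > max_overlap_nt:
                ok = False
                break
        if ok:
            accepted.append((o, iv))
    if snap_starts:
        # snapping discards sequence, so it demands stronger evidence of
        # a non-coding prefix than overlap resolution does (a wrong snap
        # can drop genuine reassigned-stop positions)
        snapped = []
        for o, _ in accepted:
            iv_c = trimmed_interval(o, genome, model, threshold=-0.10)
            trim = 0
            if iv_c is not None:
                trim = (iv_c[0] - o.start) // 3 if o.strand == "+" else (o.end - iv_c[1]) // 3
            snapped.append(snap_orf_start(o, genome, trim))
        out = snapped
    else:
        out = [o for o, _ in accepted]
    out.sort(key=lambda o: (o.start, o.end, o.strand))
    return out, covered / len(genome)


def select_parsimonious(orfs: list[OrfCall], max_overlap_nt: int = 30) -> list[OrfCall]:
    """Greedy length-ranked selection of a non-redundant ORF set.

    Accepts ORFs longest-first, rejecting any that overlap an accepted
    ORF by more than ``max_overlap_nt`` (short prokaryotic gene overlaps
    are common; nested antisense ORFs are not).  This mimics the
    parsimonious gene sets real annotation pipelines emit and keeps
    genome-wide statistics from being dominated by spurious calls.
    """
    ranked = sorted(orfs, key=lambda o: (-(o.end - o.start), o.start, o.strand))
    accepted: list[OrfCall] = []
    for o in ranked:
        ok = True
        for a in accepted:
            ov = min(o.end, a.end) - max(o.start, a.start)
            if ov > max_overlap_nt:
                ok = False
                break
        if ok:
            accepted.append(o)
    accepted.sort(key=lambda o: (o.start, o.end, o.strand))
    return accepted


def max_coverage_selection(orfs: list[OrfCall]) -> list[OrfCall]:
    """Non-overlapping ORF subset maximizing total covered length.

    Classic weighted-interval-scheduling DP (weight = interval length),
    deterministic and order-independent; used for coverage statistics
    where greedy selection would be unstable.  Ties break toward the
    earlier, then lexicographically smaller interval.
    """
    if not orfs:
        return []
    import bisect

    ivs = sorted(orfs, key=lambda o: (o.end, o.start, o.strand))
    ends = [o.end for o in ivs]
    n = len(ivs)
    best = [0] * (n + 1)
    take = [False] * n
    for i, o in enumerate(ivs):
        p = bisect.bisect_right(ends, o.start, 0, i)
        with_i = best[p] + (o.end - o.start)
        if with_i > best[i]:
            best[i + 1] = with_i
            take[i] = True
        else:
            best[i + 1] = best[i]
    out: list[OrfCall] = []
    i = n
    while i > 0:
        if take[i - 1] and best[i] != best[i - 1]:
            o = ivs[i - 1]
            out.append(o)
            i = bisect.bisect_right(ends, o.start, 0, i - 1)
        else:
            i -= 1
    out.sort(key=lambda o: (o.start, o.end, o.strand))
    return out


def coding_fraction(orfs: list[OrfCall], genome_length: int) -> float:
    """Fraction of genome positions covered by >=1 ORF (union, both strands)."""
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    if not orfs:
        return 0.0
    intervals: list[tuple[int, int]] = []
    for o in orfs:
        if o.end <= genome_length:
            intervals.append((o.start, o.end))
        else:  # wrap-spanning feature on a circular genome
            intervals.append((o.start, genome_length))
            intervals.append((0, o.end - genome_length))
    intervals.sort()
    covered = 0
    cur_s, cur_e = intervals[0]
    for s, e in intervals[1:]:
        if s > cur_e:
            covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    covered += cur_e - cur_s
    return covered / genome_length


def orf_table(orfs: list[OrfCall]) -> pd.DataFrame:
    """TSV-ready summary of an ORF set."""
    return pd.DataFrame(
        {
            "genome_id": [o.genome_id for o in orfs],
            "start": [o.start for o in orfs],
            "end": [o.end for o in orfs],
            "strand": [o.strand for o in orfs],
            "frame": [o.frame for o in orfs],
            "length_aa": [o.length_aa for o in orfs],
            "n_internal_reassigned_stops": [len(o.internal_reassigned_stops) for o in orfs],
        }
    )
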