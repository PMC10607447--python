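"""tRNA gene detection and suppressor classification.

Detection uses a lightweight cloverleaf heuristic (stem complementarity
with G·U wobble, anticodon loop geometry, T-loop TTC motif) rather than
covariance models; users with tRNAscan-SE output can ingest it as GFF3
and get identical downstream classification.  Suppressor classification
from an anticodon is exact: a tRNA is a suppressor iff the codon it
decodes (the reverse complement of its anticodon) is one of the three
standard stop codons.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

from .seq_core import (
    GenomeRecord,
    SequenceError,
    read_gff3,
    reverse_complement,
)

#: Canonical cloverleaf template used by the synthetic generator and the
#: detector characterization tests.  Synthetic sequence: a 70-nt tRNA body
#: (acceptor 7 bp, D-arm 4 bp stem / 6-nt loop, anticodon 5 bp stem /
#: 7-nt loop, 5-bp T-stem with TTCGAAT loop, discriminator) plus CCA.
#: The anticodon placeholder NNN sits at loop positions 3-5.
TRNA_TEMPLATE = (
    "GCGGATT"      # acceptor stem 5'
    "TA"           # spacer
    "GCTC" "AGTTGG" "GAGC"   # D-arm: stem, loop, stem'
    "A"            # spacer
    "CGGAC" "CTNNNAA" "GTCCG"  # anticodon arm: stem, loop (anticodon at 3-5), stem'
    "A"            # variable loop
    "CGGGG" "TTCGAAT" "CCCCG"  # T-arm
    "AATCCGC"      # acceptor stem 3'
    "A"            # discriminator
    "CCA"
)

_STOP_BY_ANTICODON = {"CTA": "TAG", "TCA": "TGA", "TTA": "TAA"}

_PAIRS = {
    ("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"),
    ("G", "T"), ("T", "G"),  # G·U wobble
}


@dataclass
class TrnaGene:
    """A detected tRNA locus.  ``anticodon`` is read 5'→3' on the coding
    strand; ``decoded_codon`` is its reverse complement."""

    start: int
    end: int
    strand: str
    anticodon: str
    score: float = 0.0
    source: str = "builtin"

    @property
    def decoded_codon(self) -> str:
        return reverse_complement(self.anticodon)

    @property
    def is_suppressor(self) -> bool:
        return self.anticodon in _STOP_BY_ANTICODON

    @property
    def suppressed_stop(self) -> str:
        return _STOP_BY_ANTICODON.get(self.anticodon, "none")


def classify_suppressor(anticodon: str) -> tuple[bool, str]:
    """(is_suppressor, suppressed_stop) for a 3-nt DNA anticodon.

    CTA→TAG (amber), TCA→TGA (opal), TTA→TAA (ochre); anything else is
    a sense-codon tRNA.
    """
    ac = anticodon.upper()
    if len(ac) != 3 or re.search(r"[^ACGT]", ac):
        raise SequenceError(f"anticodon must be 3 nt over ACGT, got {anticodon!r}")
    stop = _STOP_BY_ANTICODON.get(ac)
    return (stop is not None, stop or "none")


def make_trna_gene_seq(anticodon: str) -> str:
    """The canonical template with ``anticodon`` substituted in."""
    ac = anticodon.upper()
    if len(ac) != 3 or re.search(r"[^ACGT]", ac):
        raise SequenceError(f"anticodon must be 3 nt over ACGT, got {anticodon!r}")
    return TRNA_TEMPLATE.replace("NNN", ac)


def _n_paired(a: str, b_rc_side: str) -> int:
    """Paired-base count between a stem and its partner (given 5'→3' on
    the same strand; partner is reversed for antiparallel pairing)."""
    return sum(1 for x, y in zip(a, b_rc_side[::-1]) if (x, y) in _PAIRS)


# Geometry derived from the canonical cloverleaf: distance from tRNA
# start to the anticodon-stem start, and T-loop anchoring on the TTC.
_AC_OFFSET_RANGE = range(18, 33)   # anticodon-stem start minus tRNA start
_TTC_WINDOW = 14                   # search span after the anticodon arm
_MIN_SCORE = 20.0


def _scan_one_strand(seq: str, min_score: float) -> list[tuple[int, int, str, float]]:
    """(start, end, anticodon, score) candidates on the forward reading."""
    out = []
    n = len(seq)
    for k in (5, 4):  # anticodon stem length
        arm = 2 * k + 7
        for i in range(0, n - arm):
            stem5 = seq[i : i + k]
            stem3 = seq[i + k + 7 : i + arm]
            if _n_paired(stem5, stem3) < k:
                continue
            loop = seq[i + k : i + k + 7]
            anticodon = loop[2:5]
            if "N" in anticodon:
                continue
            arm_end = i + arm
            for m in re.finditer("TTC", seq[arm_end : arm_end + _TTC_WINDOW]):
                ttc = arm_end + m.start()
                t_stem5 = seq[max(ttc - 5, 0) : ttc]
                t_stem3 = seq[ttc + 7 : ttc + 12]
                t_pairs = (
                    _n_paired(t_stem5, t_stem3)
                    if len(t_stem5) == 5 and len(t_stem3) == 5
                    else 0
                )
                if t_pairs < 4:
                    continue
                acc3 = seq[ttc + 12 : ttc + 19]
                if len(acc3) < 7:
                    continue
                best = None
                for off in _AC_OFFSET_RANGE:
                    a0 = i - off
                    if a0 < 0:
                        continue
                    acc_pairs = _n_paired(seq[a0 : a0 + 7], acc3)
                    if acc_pairs >= 6 and (best is None or acc_pairs > best[1]):
                        best = (a0, acc_pairs)
                if best is None:
                    continue
                a0, acc_pairs = best
                end = ttc + 20
                has_cca = seq[end : end + 3] == "CCA"
                if has_cca:
                    end += 3
                if not (60 <= end - a0 <= 120):
                    continue
                score = acc_pairs + k + t_pairs + 3.0 + (2.0 if has_cca else 0.0)
                if score >= min_score:
                    out.append((a0, end, anticodon, score))
    return out


def detect_trnas(genome: GenomeRecord, min_score: float = _MIN_SCORE) -> list[TrnaGene]:
    """Scan both strands for cloverleaf tRNA candidates.

    The detector requires a fully paired 4-5 bp anticodon stem enclosing
    a 7-nt loop, a TTC motif in a paired T-arm, and an acceptor stem with
    >=6 of 7 pairs (G·U allowed); overlapping candidates resolve to the
    best score.  Sensitivity on natural tRNAs is characterized, not
    guaranteed; classification given an anticodon is exact.
    """
    seq = genome.seq
    L = len(seq)
    cands: list[TrnaGene] = []
    for a0, end, anticodon, score in _scan_one_strand(seq, min_score):
        cands.append(TrnaGene(a0, end, "+", anticodon, score))
    for a0, end, anticodon, score in _scan_one_strand(reverse_complement(seq), min_score):
        cands.append(TrnaGene(L - end, L - a0, "-", anticodon, score))
    # non-maximum suppression of overlapping candidates
    cands.sort(key=lambda t: (-t.score, t.start, t.strand))
    kept: list[TrnaGene] = []
    for c in cands:
        if all(c.end <= k.start or c.start >= k.end for k in kept):
            kept.append(c)
    kept.sort(key=lambda t: (t.start, t.end))
    return kept


def ingest_external_trnas(gff3_path: str | Path, genome: GenomeRecord) -> list[TrnaGene]:
    """Load tRNA features from external GFF3 (e.g. tRNAscan-SE output).

    The anticodon is taken from an ``anticodon=`` attribute when present,
    otherwise from ``anticodon_start``/``anticodon_end`` coordinates
    (1-based inclusive on the forward strand, read from the reverse
    complement for minus-strand features).  Features without either are
    skipped with a warning; features beyond genome bounds are an error.
    """
    import warnings

    out: list[TrnaGene] = []
    for feat in read_gff3(gff3_path):
        if feat.ftype.lower() not in ("trna", "trna_gene"):
            continue
        if feat.start < 0 or feat.end > len(genome):
            raise SequenceError(
                f"tRNA feature [{feat.start + 1}, {feat.end}] beyond bounds of {genome.id}"
            )
        attrs = {k.lower(): v for k, v in feat.attributes.items()}
        anticodon = attrs.get("anticodon")
        if anticodon is None and "anticodon_start" in attrs and "anticodon_end" in attrs:
            s, e = int(attrs["anticodon_start"]) - 1, int(attrs["anticodon_end"])
            sub = genome.seq[s:e]
            anticodon = sub if feat.strand == "+" else reverse_complement(sub)
        if anticodon is None:
            warnings.warn(f"tRNA feature at {feat.start + 1} lacks an anticodon; skipped")
            continue
        anticodon = anticodon.upper().replace("U", "T")
        classify_suppressor(anticodon)  # validates the alphabet
        out.append(
            TrnaGene(feat.start, feat.end, feat.strand, anticodon, source="external")
        )
    return out


def trna_table(trnas: list[TrnaGene]):
    import pandas as pd

    return pd.DataFrame(
        {
            "start": [t.start for t in trnas],
            "end": [t.end for t in trnas],
            "strand": [t.strand for t in trnas],
            "anticodon": [t.anticodon for t in trnas],
            "decoded_codon": [t.decoded_codon for t in trnas],
            "is_suppressor": [t.is_suppressor for t in trnas],
            "suppressed_stop": [t.suppressed_stop for t in trnas],
            "source": [t.source for t in trnas],
        }
    )
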