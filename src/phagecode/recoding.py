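"""Stop-codon reassignment inference and re-annotation.

The signal for a reassigned stop codon is interrupted-ORF rescue:
genes that fragment into short same-frame pieces under the standard
bacterial code (table 11) but fuse into full-length ORFs when the
candidate stop codon is read as a sense codon.  Evidence is assessed
genome-wide (interruption candidates, coding-fraction gain, ORF-length
ratio), with suppressor tRNAs as corroborating — not required —
support, since recoded phage genomes without suppressor tRNA genes
are documented.

Reassignment of codon c is recommended iff

    coding_fraction_gain(c) >= g_min  AND  n_interruption_candidates(c) >= k_min

(defaults g_min = 0.02, k_min = 5); the recommended table is 15 for
TAG (→ Gln) and 4 for TGA (→ Trp).  TAA reassignment is scored for
completeness but never recommended: no standard NCBI table reassigns
TAA alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .orf_annotation import (
    CodingModel,
    OrfCall,
    OrfCallerParams,
    coding_fraction,
    find_orfs,
    refined_orf_set,
    select_parsimonious,
)
from .seq_core import Annotation, GeneticCode, GenomeRecord, reverse_complement
from .trna_scan import TrnaGene

#: Alternative table that makes each stop codon a sense codon; 0 is the
#: unofficial TAA pseudo-code (scored but never recommended).
ALT_TABLE_FOR_STOP = {"TAG": 15, "TGA": 4, "TAA": 0}


@dataclass(frozen=True)
class RecodingParams:
    g_min: float = 0.02          # minimum coding-fraction gain
    k_min: int = 5               # minimum interruption candidates
    min_continuation_aa: int = 10
    min_joined_aa: int = 60
    min_rescued_aa: int = 80     # gene-scale length for a rescued ORF
    min_fragment_aa: int = 30    # upstream fragment must itself be callable
    min_coding_score: float = 0.0  # directional codon-bias score floor
    interruption_min_orf_aa: int = 10
    max_overlap_nt: int = 30     # parsimonious-selection overlap allowance
    orf_params: OrfCallerParams = OrfCallerParams()


@dataclass
class InterruptionCandidate:
    """A table-11 ORF terminating in the candidate stop codon whose reading
    frame continues as an open stretch past it — the signature of one gene
    fragmented by a reassigned stop."""

    stop_codon: str
    upstream_orf: OrfCall
    downstream_orf: OrfCall
    joined_length_aa: int
    n_joining_stops: int


@dataclass
class CodonReport:
    """Evidence summary for one candidate stop codon on one genome."""

    genome_id: str
    stop_codon: str
    alt_table_id: int
    n_interruption_candidates: int
    coding_fraction_std: float
    coding_fraction_alt: float
    coding_fraction_gain: float
    mean_orf_length_ratio: float
    n_orfs_with_internal_stop: int
    n_internal_stops_total: int
    suppressor_trna_support: int
    passes_rule: bool
    notes: list[str] = field(default_factory=list)


@dataclass
class RecodingReport:
    """Per-genome verdict over all candidate stop codons."""

    genome_id: str
    reports: dict[str, CodonReport]
    verdict: str                  # "standard" or "reassigned"
    reassigned_codon: str = ""    # empty for standard
    recommended_table: int = 11
    notes: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "genome_id": self.genome_id,
            "verdict": self.verdict,
            "reassigned_codon": self.reassigned_codon,
            "recommended_table": self.recommended_table,
            "notes": self.notes,
            "codons": {
                c: {k: v for k, v in asdict(r).items()}
                for c, r in self.reports.items()
            },
        }
        return json.dumps(payload, indent=2, default=str)


def _codon_at(genome: GenomeRecord, orf_like_strand: str, pos: int, wrap: bool) -> str:
    seq = genome.seq + genome.seq if wrap else genome.seq
    codon = seq[pos : pos + 3]
    return codon if orf_like_strand == "+" else reverse_complement(codon)


def find_interruptions(
    orfs_table11: list[OrfCall],
    genome: GenomeRecord,
    stop_codon: str,
    min_continuation_aa: int = 10,
    min_joined_aa: int = 60,
) -> list[InterruptionCandidate]:
    """Find table-11 ORFs interrupted by ``stop_codon``.

    An ORF qualifies when its terminal stop is of the named type
    (possibly a run of consecutive same-type in-frame stops), the frame
    continues as an open reading stretch of at least
    ``min_continuation_aa`` codons before the next in-frame stop, and
    the joined product reaches gene scale (``min_joined_aa``): rescue of
    a real gene restores a long ORF, while chance stop-to-stop joins in
    non-coding frames stay short.  Genes holding several reassigned
    stops yield a chain of candidates, one per stop run.
    """
    if stop_codon not in ("TAG", "TGA", "TAA"):
        raise ValueError(f"not a stop codon: {stop_codon!r}")
    L = len(genome)
    circular = genome.topology == "circular"
    seq = genome.seq + genome.seq if circular else genome.seq
    stops_std = {"TAA", "TAG", "TGA"}
    out: list[InterruptionCandidate] = []
    for u in orfs_table11:
        if u.table_id != 11:
            raise ValueError("find_interruptions expects table-11 ORF calls")
        # position of the terminal stop codon on the coding strand
        if u.strand == "+":
            stop_pos = u.end - 3
            step = 3
        else:
            stop_pos = u.start
            step = -3
        if _codon_at(genome, u.strand, stop_pos, u.wraps) != stop_codon:
            continue
        # walk the run of consecutive same-type stops, then the open stretch
        n_joining = 1
        pos = stop_pos + step
        limit = len(seq) if circular else L

        def codon_fwd_at(p: int) -> str | None:
            if u.strand == "+":
                if p + 3 > limit:
                    return None
                return seq[p : p + 3]
            if p < 0:
                return None
            return reverse_complement(seq[p : p + 3])

        while True:
            c = codon_fwd_at(pos)
            if c == stop_codon:
                n_joining += 1
                pos += step
            else:
                break
        cont_start = pos
        cont_codons = 0
        terminal = None
        while True:
            c = codon_fwd_at(pos)
            if c is None:
                break
            if c in stops_std:
                terminal = c
                break
            cont_codons += 1
            pos += step
        if terminal is None or cont_codons < min_continuation_aa:
            continue
        if u.strand == "+":
            d_start, d_end = cont_start, pos + 3
        else:
            d_start, d_end = pos, cont_start + 3
        code11 = GeneticCode.from_table_id(11)
        sub = seq[d_start:d_end] if u.strand == "+" else reverse_complement(seq[d_start:d_end])
        from .seq_core import translate

        downstream = OrfCall(
            genome_id=genome.id,
            start=d_start % L if circular else d_start,
            end=d_end % L if (circular and d_end > L and d_start >= L) else d_end,
            strand=u.strand,
            frame=u.frame,
            table_id=11,
            protein=translate(sub[:-3], code11),
        )
        joined = u.length_aa + n_joining + cont_codons
        if joined < min_joined_aa:
            continue
        out.append(
            InterruptionCandidate(
                stop_codon=stop_codon,
                upstream_orf=u,
                downstream_orf=downstream,
                joined_length_aa=joined,
                n_joining_stops=n_joining,
            )
        )
    return out


class _TableArtifacts:
    """Per-genome, per-table intermediates shared across codon reports."""

    def __init__(self, genome: GenomeRecord, code: GeneticCode, params: RecodingParams):
        self.raw = find_orfs(genome, code, params.orf_params)
        # six-frame codon-bias model self-trained on the long ORFs
        self.model = CodingModel(self.raw, genome)
        # refined annotation: shadow-filtered, start-trimmed spans with
        # bounded overlap; the coding fraction is the union of the
        # surviving coding spans (start over-extensions would otherwise
        # inflate the coverage of any alternative table)
        self.parsimonious, self.coding_fraction = refined_orf_set(
            self.raw, genome,
            min_margin=params.min_coding_score,
            max_overlap_nt=params.max_overlap_nt,
        )
        # start-snapped view used for per-ORF reassigned-stop statistics
        self.annotation_view, _ = refined_orf_set(
            self.raw, genome,
            min_margin=params.min_coding_score,
            max_overlap_nt=params.max_overlap_nt,
            snap_starts=True,
        )


def recoding_score(
    genome: GenomeRecord,
    stop_codon: str,
    trnas: list[TrnaGene] | None = None,
    params: RecodingParams | None = None,
    _cache: dict | None = None,
) -> CodonReport:
    """Evidence statistics for reassigning one stop codon on one genome."""
    params = params or RecodingParams()
    trnas = trnas or []
    alt_id = ALT_TABLE_FOR_STOP[stop_codon]
    cache = _cache if _cache is not None else {}

    def table_artifacts(table_id: int) -> _TableArtifacts:
        if table_id not in cache:
            cache[table_id] = _TableArtifacts(
                genome, GeneticCode.from_table_id(table_id), params
            )
        return cache[table_id]

    std = table_artifacts(11)
    alt = table_artifacts(alt_id)
    orfs11, orfs_alt = std.parsimonious, alt.parsimonious

    # interrupted-gene candidates: the decisive evidence is that the
    # re-coded annotation composes a gene-scale ORF across >=1 internal
    # stop of this type, where table 11 reads a stop (the "destroyed"
    # gene is rescued).  One candidate per rescued gene keeps the count
    # specific.  Two guards reject the chance look-alikes:
    #  - upstream extension of an intact gene through an intergenic stop
    #    (the fragment before the first internal stop must itself reach
    #    the caller's minimum ORF length AND read as coding in its own
    #    frame - an extension prefix is non-coding), and
    #  - antisense / frame-shifted shadow ORFs (the rescued core, from
    #    the first internal stop onward, must read best in its own frame
    #    under the self-trained codon-bias model).
    candidates = [
        o for o in orfs_alt
        if o.length_aa >= params.min_rescued_aa
        and any(
            _reassigned_codon_fwd(genome, o, p) == stop_codon
            for p in o.internal_reassigned_stops
        )
        and _upstream_fragment_aa(o) >= params.min_fragment_aa
        and _rescued_core_margin(o, genome, alt.model) >= params.min_coding_score
        and _upstream_core_margin(o, genome, alt.model) >= params.min_coding_score
    ]

    cf_std = std.coding_fraction
    cf_alt = alt.coding_fraction
    mean11 = float(np.mean([o.length_aa for o in orfs11])) if orfs11 else 0.0
    mean_alt = float(np.mean([o.length_aa for o in orfs_alt])) if orfs_alt else 0.0
    ratio = mean_alt / mean11 if mean11 > 0 else float("nan")

    # internal stops of *this* type only (table 15 reassigns TAG, 4 TGA, ...),
    # counted on the start-snapped annotation view
    view = alt.annotation_view
    n_internal_total = sum(
        sum(1 for p in o.internal_reassigned_stops if _reassigned_codon_fwd(genome, o, p) == stop_codon)
        for o in view
    )
    n_orfs_internal = sum(
        1
        for o in view
        if any(_reassigned_codon_fwd(genome, o, p) == stop_codon for p in o.internal_reassigned_stops)
    )
    support = sum(1 for t in trnas if t.suppressed_stop == stop_codon)

    notes: list[str] = []
    if stop_codon == "TAA":
        notes.append("no supported translation table reassigns TAA alone; never recommended")
    gain = cf_alt - cf_std
    passes = gain >= params.g_min and len(candidates) >= params.k_min and stop_codon != "TAA"
    if passes and support == 0:
        notes.append("no suppressor tRNA support (recoded genomes without suppressor tRNAs are documented)")
    return CodonReport(
        genome_id=genome.id,
        stop_codon=stop_codon,
        alt_table_id=alt_id,
        n_interruption_candidates=len(candidates),
        coding_fraction_std=cf_std,
        coding_fraction_alt=cf_alt,
        coding_fraction_gain=gain,
        mean_orf_length_ratio=ratio,
        n_orfs_with_internal_stop=n_orfs_internal,
        n_internal_stops_total=n_internal_total,
        suppressor_trna_support=support,
        passes_rule=passes,
        notes=notes,
    )






def _rescued_core_margin(orf: OrfCall, genome: GenomeRecord, model: CodingModel) -> float:
    """Frame margin of the ORF portion downstream of the first internal
    reassigned stop (the rescued core), on the coding strand."""
    from .orf_annotation import _cds_frame_margin

    cds = orf.coding_sequence(genome)[:-3]
    core = cds[3 * _upstream_fragment_aa(orf) :]
    if len(core) < 30:
        return 0.0
    return _cds_frame_margin(core, model)


def _upstream_core_margin(orf: OrfCall, genome: GenomeRecord, model: CodingModel) -> float:
    """Frame margin of the ORF portion upstream of the first internal
    reassigned stop, on the coding strand."""
    from .orf_annotation import _cds_frame_margin

    cds = orf.coding_sequence(genome)[:-3]
    core = cds[: 3 * _upstream_fragment_aa(orf)]
    if len(core) < 30:
        return 0.0
    return _cds_frame_margin(core, model)


def _upstream_fragment_aa(orf: OrfCall) -> int:
    """Codons between the ORF start and its 5'-most internal reassigned
    stop on the coding strand."""
    if not orf.internal_reassigned_stops:
        return orf.length_aa
    if orf.strand == "+":
        return (min(orf.internal_reassigned_stops) - orf.start) // 3
    return (orf.end - (max(orf.internal_reassigned_stops) + 3)) // 3


def _reassigned_codon_fwd(genome: GenomeRecord, orf: OrfCall, pos: int) -> str:
    """The stop-type (coding-strand codon) at a reassigned-stop coordinate."""
    seq = genome.seq + genome.seq if orf.wraps else genome.seq
    codon = seq[pos : pos + 3]
    return codon if orf.strand == "+" else reverse_complement(codon)


def decide_code(
    reports: dict[str, CodonReport] | list[CodonReport],
    genome_id: str = "",
) -> RecodingReport:
    """Apply the decision rule over the per-codon reports.

    Ties between passing codons break toward the larger coding-fraction
    gain (with a warning: no standard table covers a double
    reassignment); no passing codon means the standard table 11.
    """
    if isinstance(reports, list):
        reports = {r.stop_codon: r for r in reports}
    gid = genome_id or next(iter(reports.values())).genome_id
    passing = [r for r in reports.values() if r.passes_rule]
    notes: list[str] = []
    if not passing:
        return RecodingReport(gid, reports, verdict="standard", recommended_table=11, notes=notes)
    passing.sort(key=lambda r: -r.coding_fraction_gain)
    if len(passing) > 1:
        notes.append(
            "multiple stop codons pass the reassignment rule; recommending the "
            "higher-gain codon (no supported double-reassignment table)"
        )
    best = passing[0]
    if best.suppressor_trna_support == 0:
        notes.append("no suppressor tRNA support for the recommended reassignment")
    return RecodingReport(
        gid,
        reports,
        verdict="reassigned",
        reassigned_codon=best.stop_codon,
        recommended_table=best.alt_table_id,
        notes=notes,
    )


def analyze_genome(
    genome: GenomeRecord,
    trnas: list[TrnaGene] | None = None,
    params: RecodingParams | None = None,
) -> RecodingReport:
    """Score all three stop codons and decide the genome's genetic code."""
    params = params or RecodingParams()
    cache: dict = {}
    reports = {
        c: recoding_score(genome, c, trnas, params, _cache=cache)
        for c in ("TAG", "TGA", "TAA")
    }
    return decide_code(reports, genome.id)


def annotate_recoded(
    genome: GenomeRecord,
    recommended_code: GeneticCode | int,
    params: OrfCallerParams | None = None,
    trnas: list[TrnaGene] | None = None,
    parsimonious: bool = True,
    coding_filter: bool = True,
    max_overlap_nt: int = 30,
) -> Annotation:
    """Final annotation under the recommended table.

    By default antisense/frame-shifted shadow ORFs are removed with the
    self-trained codon-bias model and the remaining six-frame calls are
    reduced to a parsimonious gene set (longest-first, bounded overlap).
    Each ORF carries the positions of its internal reassigned stops; the
    annotation summary reports how many ORFs contain at least one and
    what percentage of all ORFs that is.
    """
    code = (
        recommended_code
        if isinstance(recommended_code, GeneticCode)
        else GeneticCode.from_table_id(recommended_code)
    )
    orfs = find_orfs(genome, code, params or OrfCallerParams())
    if coding_filter and parsimonious:
        orfs, _ = refined_orf_set(
            orfs, genome, max_overlap_nt=max_overlap_nt, snap_starts=True
        )
    elif parsimonious:
        orfs = select_parsimonious(orfs, max_overlap_nt)
    return Annotation(
        genome_id=genome.id, orfs=orfs, trnas=list(trnas or []), table_id=code.table_id
    )


def report_table(reports: list[RecodingReport]) -> pd.DataFrame:
    """One row per genome x candidate codon, TSV-ready."""
    rows = []
    for rep in reports:
        for c, r in rep.reports.items():
            rows.append(
                {
                    "genome_id": rep.genome_id,
                    "stop_codon": c,
                    "alt_table_id": r.alt_table_id,
                    "n_interruption_candidates": r.n_interruption_candidates,
                    "coding_fraction_std": round(r.coding_fraction_std, 4),
                    "coding_fraction_alt": round(r.coding_fraction_alt, 4),
                    "coding_fraction_gain": round(r.coding_fraction_gain, 4),
                    "mean_orf_length_ratio": round(r.mean_orf_length_ratio, 3),
                    "n_orfs_with_internal_stop": r.n_orfs_with_internal_stop,
                    "n_internal_stops_total": r.n_internal_stops_total,
                    "suppressor_trna_support": r.suppressor_trna_support,
                    "passes_rule": r.passes_rule,
                    "verdict": rep.verdict,
                    "recommended_table": rep.recommended_table,
                }
            )
    return pd.DataFrame(rows)
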