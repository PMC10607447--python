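"""Sequence containers, genetic-code machinery, and FASTA/GFF3/GenBank IO.

Coordinates are 0-based half-open on the forward strand everywhere inside
the package; the GFF3/GenBank writers convert to 1-based inclusive at the
format boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TYPE_CHECKING

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

if TYPE_CHECKING:  # pragma: no cover
    from .orf_annotation import OrfCall
    from .trna_scan import TrnaGene

DNA_ALPHABET = set("ACGTN")
STANDARD_STOPS = frozenset({"TAA", "TAG", "TGA"})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SequenceError(ValueError):
    """Raised for malformed sequence input."""


def normalize_dna(seq: str, *, name: str = "sequence") -> str:
    """Uppercase, U→T, and reject characters outside {A,C,G,T,N}.

    Ambiguity codes other than N are rejected: assembled phage contigs
    rarely carry them and excluding them keeps codon logic unambiguous.
    """
    s = seq.upper().replace("U", "T")
    m = re.search(r"[^ACGTN]", s)
    if m:
        raise SequenceError(
            f"{name}: non-IUPAC or ambiguous character {s[m.start()]!r} at position {m.start()}"
        )
    return s


@dataclass
class GenomeRecord:
    """A named DNA sequence; the unit of all analyses.

    topology 'circular' marks pseudo-circular contigs: feature scans use a
    virtually doubled sequence and report coordinates modulo the length.
    """

    id: str
    seq: str
    topology: str = "linear"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("genome id must be non-empty")
        if self.topology not in ("linear", "circular"):
            raise SequenceError(f"unknown topology {self.topology!r}")
        self.seq = normalize_dna(self.seq, name=self.id)
        if len(self.seq) < 1:
            raise SequenceError(f"{self.id}: empty sequence")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def gc_content(self) -> float:
        """GC fraction over unambiguous positions."""
        acgt = sum(self.seq.count(b) for b in "ACGT")
        gc = self.seq.count("G") + self.seq.count("C")
        return gc / acgt if acgt else 0.0


def reverse_complement(seq: str) -> str:
    """Watson–Crick reverse complement; N maps to N; identity on ''."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneticCode:
    """An NCBI translation table restricted to what phage annotation needs.

    Supported ids: 11 (bacterial standard), 15 (TAG→Gln), 4 (TGA→Trp).
    ``codon_to_aa`` is total over the 64 codons, with stop codons mapped
    to '*'.  A table-less pseudo-code (id 0) covering TAA→Gln exists only
    so that TAA reassignment can be scored; it is never recommended.
    """

    table_id: int
    codon_to_aa: dict[str, str]
    stop_codons: frozenset[str]
    name: str = ""

    SUPPORTED = (11, 15, 4)

    @classmethod
    def from_table_id(cls, table_id: int) -> "GeneticCode":
        if table_id == 0:
            return cls._pseudo_taa()
        if table_id not in cls.SUPPORTED:
            raise ValueError(f"unsupported translation table {table_id}; supported: 11, 15, 4")
        tbl = CodonTable.unambiguous_dna_by_id[table_id]
        mapping = dict(tbl.forward_table)
        for stop in tbl.stop_codons:
            mapping[stop] = "*"
        return cls(
            table_id=table_id,
            codon_to_aa=mapping,
            stop_codons=frozenset(tbl.stop_codons),
            name=tbl.names[0] if tbl.names else str(table_id),
        )

    @classmethod
    def _pseudo_taa(cls) -> "GeneticCode":
        # No NCBI table reassigns only TAA; built for completeness scoring.
        base = cls.from_table_id(11)
        mapping = dict(base.codon_to_aa)
        mapping["TAA"] = "Q"
        return cls(
            table_id=0,
            codon_to_aa=mapping,
            stop_codons=frozenset({"TAG", "TGA"}),
            name="unofficial TAA->Gln pseudo-code",
        )

    @property
    def reassigned_stops(self) -> frozenset[str]:
        """Standard-code stops that are sense codons under this code."""
        return STANDARD_STOPS - self.stop_codons

    def aa(self, codon: str) -> str:
        """Amino acid (or '*') for a codon; 'X' when N is present."""
        if "N" in codon:
            return "X"
        return self.codon_to_aa[codon]


def translate(cds_seq: str, code: GeneticCode, to_first_stop: bool = False) -> str:
    """Translate a coding sequence.

    Internal stops are rendered '*' unless ``to_first_stop`` truncates
    there; codons containing N render 'X'.  A trailing partial codon is
    an error.
    """
    s = normalize_dna(cds_seq, name="cds")
    if len(s) % 3 != 0:
        raise SequenceError(f"CDS length {len(s)} not divisible by 3")
    out: list[str] = []
    for i in range(0, len(s), 3):
        aa = code.aa(s[i : i + 3])
        if aa == "*" and to_first_stop:
            break
        out.append(aa)
    return "".join(out)


@dataclass
class Annotation:
    """Final per-genome annotation: ORFs plus tRNA genes under one table."""

    genome_id: str
    orfs: list["OrfCall"] = field(default_factory=list)
    trnas: list["TrnaGene"] = field(default_factory=list)
    table_id: int = 11

    def __post_init__(self) -> None:
        self.orfs = sorted(self.orfs, key=lambda o: (o.start, o.end))
        self.trnas = sorted(self.trnas, key=lambda t: (t.start, t.end))

    @property
    def n_recoded_orfs(self) -> int:
        return sum(1 for o in self.orfs if o.internal_reassigned_stops)

    @property
    def pct_recoded_orfs(self) -> float:
        return 100.0 * self.n_recoded_orfs / len(self.orfs) if self.orfs else 0.0


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path, topology: str = "linear") -> list[GenomeRecord]:
    """Read genomes from FASTA; sequences normalized (uppercase, U→T).

    Errors on an empty file, duplicate ids, and non-{A,C,G,T,N} characters.
    """
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SequenceError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(
            GenomeRecord(id=rec.id, seq=str(rec.seq), topology=topology,
                         description=rec.description)
        )
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    return records


def write_fasta(genomes: Iterable[GenomeRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.id}" + (f" {g.description}" if g.description else "") + "\n")
            for i in range(0, len(g.seq), width):
                fh.write(g.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3

def _check_bounds(start: int, end: int, genome: GenomeRecord, what: str) -> None:
    wrap = genome.topology == "circular"
    limit = 2 * len(genome) if wrap else len(genome)
    if start < 0 or end > limit or start >= end:
        raise SequenceError(
            f"{what} [{start}, {end}) out of bounds for {genome.id} (len {len(genome)})"
        )


def _gff3_attrs(pairs: dict[str, str]) -> str:
    return ";".join(f"{k}={v}" for k, v in pairs.items() if v != "")


def write_gff3(annotation: Annotation, genome: GenomeRecord, path: str | Path) -> None:
    """Write CDS and tRNA features as GFF3 (1-based inclusive coordinates)."""
    lines = ["##gff-version 3", f"##sequence-region {genome.id} 1 {len(genome)}"]
    src = "phagecode"
    for i, orf in enumerate(annotation.orfs):
        _check_bounds(orf.start, orf.end, genome, "CDS")
        attrs = {
            "ID": f"{genome.id}_orf{i + 1:04d}",
            "transl_table": str(annotation.table_id),
            "frame": str(orf.frame),
        }
        if orf.internal_reassigned_stops:
            attrs["internal_reassigned_stops"] = ",".join(
                str(p + 1) for p in orf.internal_reassigned_stops
            )
        lines.append(
            "\t".join([
                genome.id, src, "CDS", str(orf.start + 1), str(orf.end),
                ".", orf.strand, "0", _gff3_attrs(attrs),
            ])
        )
    for i, trna in enumerate(annotation.trnas):
        _check_bounds(trna.start, trna.end, genome, "tRNA")
        attrs = {
            "ID": f"{genome.id}_trna{i + 1:03d}",
            "anticodon": trna.anticodon,
            "is_suppressor": str(trna.is_suppressor).lower(),
        }
        if trna.is_suppressor:
            attrs["suppressed_stop"] = trna.suppressed_stop
        lines.append(
            "\t".join([
                genome.id, src, "tRNA", str(trna.start + 1), str(trna.end),
                ".", trna.strand, ".", _gff3_attrs(attrs),
            ])
        )
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class Gff3Feature:
    """One parsed GFF3 feature line, coordinates converted to 0-based half-open."""

    seqid: str
    source: str
    ftype: str
    start: int
    end: int
    score: str
    strand: str
    phase: str
    attributes: dict[str, str]


def read_gff3(path: str | Path) -> list[Gff3Feature]:
    features: list[Gff3Feature] = []
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise SequenceError(f"{path}:{ln}: expected 9 tab-separated columns")
        attrs: dict[str, str] = {}
        for item in cols[8].split(";"):
            if item and "=" in item:
                k, v = item.split("=", 1)
                attrs[k.strip()] = v.strip()
        features.append(
            Gff3Feature(
                seqid=cols[0], source=cols[1], ftype=cols[2],
                start=int(cols[3]) - 1, end=int(cols[4]),
                score=cols[5], strand=cols[6], phase=cols[7], attributes=attrs,
            )
        )
    return features


# ---------------------------------------------------------------------------
# GenBank

def write_genbank(annotation: Annotation, genome: GenomeRecord, path: str | Path) -> None:
    """GenBank flat file with /transl_table on every CDS and a /note listing
    internal reassigned-stop positions (1-based) where present."""
    rec = SeqRecord(
        Seq(genome.seq), id=genome.id, name=genome.id[:16],
        description=genome.description or f"{genome.id} annotated by phagecode",
    )
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = genome.topology
    for orf in annotation.orfs:
        _check_bounds(orf.start, orf.end, genome, "CDS")
        quals: dict[str, list[str]] = {
            "transl_table": [str(annotation.table_id)],
            "translation": [orf.protein],
        }
        if orf.internal_reassigned_stops:
            pos = ",".join(str(p + 1) for p in orf.internal_reassigned_stops)
            quals["note"] = [f"internal reassigned stop codon(s) at {pos}"]
        rec.features.append(
            SeqFeature(
                SimpleLocation(orf.start, orf.end, strand=1 if orf.strand == "+" else -1),
                type="CDS", qualifiers=quals,
            )
        )
    for trna in annotation.trnas:
        _check_bounds(trna.start, trna.end, genome, "tRNA")
        quals = {"anticodon": [trna.anticodon]}
        if trna.is_suppressor:
            quals["note"] = [f"suppressor tRNA decoding {trna.suppressed_stop}"]
        rec.features.append(
            SeqFeature(
                SimpleLocation(trna.start, trna.end, strand=1 if trna.strand == "+" else -1),
                type="tRNA", qualifiers=quals,
            )
        )
    SeqIO.write([rec], str(path), "genbank")
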