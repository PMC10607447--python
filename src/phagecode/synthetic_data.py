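"""Phage-like genome simulator with exact ground truth.

Emulates gene-dense double-stranded DNA phage genomes: tightly packed
protein-coding genes with short intergenic spacers, a configurable
fraction of genes carrying internal amber (TAG) codons that are sense
codons under the phage's own code, suppressor tRNA genes with anticodon
CTA, and mutated relatives at dialed divergence.  Every emitted feature
is recorded in a TruthSet that is exactly consistent with the sequence.

Genes are drawn codon-wise from a GC-conditioned mixture over the 61
sense codons (stop codons excluded), so non-recoded genes contain no
in-frame TAG by construction and recoded genes contain TAG only at the
designed amber positions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .seq_core import GenomeRecord, reverse_complement
from .trna_scan import make_trna_gene_seq

_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]

#: Average proteome amino-acid composition (Swiss-Prot-style averages, %).
#: Real coding sequences have strongly non-uniform amino-acid usage; this
#: is what makes sense and antisense reading frames statistically
#: distinguishable, a property every real gene caller relies on.
_AA_FREQ = {
    "A": 8.2, "R": 5.5, "N": 4.0, "D": 5.4, "C": 1.4, "Q": 3.9, "E": 6.8,
    "G": 7.1, "H": 2.3, "I": 6.0, "L": 9.7, "K": 5.8, "M": 2.4, "F": 3.9,
    "P": 4.7, "S": 6.6, "T": 5.3, "W": 1.1, "Y": 2.9, "V": 6.9,
}

from Bio.Data.CodonTable import unambiguous_dna_by_id as _tables

_CODON_AA = {c: _tables[11].forward_table[c] for c in _SENSE_CODONS}


def _codon_distribution(gc_target: float) -> tuple[list[str], np.ndarray]:
    """Codon probabilities with realistic amino-acid composition and
    synonymous-codon weights exp(lambda * GC) tilted so the expected
    coding GC matches ``gc_target``."""
    aa_p = {a: f / 100.0 for a, f in _AA_FREQ.items()}
    norm = sum(aa_p.values())
    aa_p = {a: p / norm for a, p in aa_p.items()}
    gc_count = {c: sum(ch in "GC" for ch in c) for c in _SENSE_CODONS}

    def dist(lam: float) -> np.ndarray:
        weights = {}
        for aa in aa_p:
            syn = [c for c in _SENSE_CODONS if _CODON_AA[c] == aa]
            w = np.array([np.exp(lam * gc_count[c]) for c in syn])
            w /= w.sum()
            for c, wi in zip(syn, w):
                weights[c] = aa_p[aa] * wi
        return np.array([weights[c] for c in _SENSE_CODONS])

    def mean_gc(lam: float) -> float:
        p = dist(lam)
        return float(np.sum(p * np.array([gc_count[c] for c in _SENSE_CODONS])) / 3.0)

    from scipy.optimize import brentq

    lo, hi = -4.0, 4.0
    target = min(max(gc_target, mean_gc(lo) + 1e-3), mean_gc(hi) - 1e-3)
    lam = brentq(lambda x: mean_gc(x) - target, lo, hi, xtol=1e-6)
    return _SENSE_CODONS, dist(lam)


_DIST_CACHE: dict[float, tuple[list[str], np.ndarray]] = {}


def _cached_distribution(gc_target: float) -> tuple[list[str], np.ndarray]:
    key = round(gc_target, 4)
    if key not in _DIST_CACHE:
        _DIST_CACHE[key] = _codon_distribution(key)
    return _DIST_CACHE[key]


@dataclass(frozen=True)
class SyntheticSpec:
    """Study-condition defaults: a ~90 kb genome with ~100 tightly packed
    genes at phage-like GC (44.5%), 28% of genes recoded with 1-3 ambers
    each, and three suppressor tRNA genes."""

    n_genes: int = 100
    gene_length_aa: tuple[int, int] = (100, 400)
    intergenic_length: tuple[int, int] = (20, 120)
    gc_content: float = 0.445
    recoded_fraction: float = 0.28
    ambers_per_recoded_gene: tuple[int, int] = (1, 3)
    n_suppressor_trnas: int = 3
    strand_flip_prob: float = 0.3
    topology: str = "linear"
    seed: int = 0

    def __post_init__(self) -> None:
        for frac in (self.gc_content, self.recoded_fraction, self.strand_flip_prob):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        lo, hi = self.ambers_per_recoded_gene
        if lo < 1 or hi < lo:
            raise ValueError("ambers_per_recoded_gene must be a (min>=1, max>=min) pair")


@dataclass
class GeneTruth:
    start: int
    end: int
    strand: str
    recoded: bool
    amber_positions: list[int] = field(default_factory=list)  # fwd-strand codon starts


@dataclass
class TrnaTruth:
    start: int
    end: int
    strand: str
    anticodon: str


@dataclass
class TruthSet:
    """Ground truth exactly consistent with the emitted sequence."""

    genes: list[GeneTruth] = field(default_factory=list)
    trnas: list[TrnaTruth] = field(default_factory=list)
    mutations: list[dict] = field(default_factory=list)

    @property
    def recoded_genes(self) -> list[GeneTruth]:
        return [g for g in self.genes if g.recoded]

    @property
    def amber_positions(self) -> list[int]:
        return sorted(p for g in self.genes for p in g.amber_positions)

    @property
    def n_substitutions(self) -> int:
        return sum(1 for m in self.mutations if m["type"] == "sub")

    def to_json(self) -> str:
        return json.dumps(
            {
                "genes": [asdict(g) for g in self.genes],
                "trnas": [asdict(t) for t in self.trnas],
                "mutations": self.mutations,
            },
            indent=2,
        )


def _draw_codons(rng: np.random.Generator, n: int, gc: float) -> list[str]:
    codons, probs = _cached_distribution(gc)
    idx = rng.choice(len(codons), size=n, p=probs)
    return [codons[i] for i in idx]


def _intergenic(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def generate_genome(spec: SyntheticSpec) -> tuple[GenomeRecord, TruthSet]:
    """Build a genome and its TruthSet, deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n_recoded = int(round(spec.recoded_fraction * spec.n_genes))
    recoded_idx = set(
        rng.choice(spec.n_genes, size=n_recoded, replace=False).tolist()
    )
    # interleave suppressor tRNA genes at random gene boundaries
    trna_slots = set(
        rng.choice(spec.n_genes + 1, size=min(spec.n_suppressor_trnas, spec.n_genes + 1),
                   replace=False).tolist()
    )
    parts: list[str] = []
    truth = TruthSet()
    pos = 0

    def add_intergenic() -> None:
        nonlocal pos
        n = int(rng.integers(spec.intergenic_length[0], spec.intergenic_length[1] + 1))
        parts.append(_intergenic(rng, n, spec.gc_content))
        pos += n

    def add_trna() -> None:
        nonlocal pos
        body = make_trna_gene_seq("CTA")
        strand = "-" if rng.random() < spec.strand_flip_prob else "+"
        seq = body if strand == "+" else reverse_complement(body)
        truth.trnas.append(TrnaTruth(pos, pos + len(seq), strand, "CTA"))
        parts.append(seq)
        pos += len(seq)

    for gi in range(spec.n_genes):
        if gi in trna_slots:
            add_intergenic()
            add_trna()
        add_intergenic()
        n_aa = int(rng.integers(spec.gene_length_aa[0], spec.gene_length_aa[1] + 1))
        codons = _draw_codons(rng, n_aa, spec.gc_content)
        recoded = gi in recoded_idx
        amber_slots: list[int] = []
        if recoded:
            lo, hi = spec.ambers_per_recoded_gene
            k = int(rng.integers(lo, hi + 1))
            k = min(k, max(n_aa - 2, 1))
            # interior codon slots only (not the first codon after ATG, not
            # the codon before the terminal stop)
            slots = rng.choice(np.arange(1, n_aa - 1), size=k, replace=False)
            amber_slots = sorted(int(s) for s in slots)
            for s in amber_slots:
                codons[s] = "TAG"
        gene = "ATG" + "".join(codons) + "TAA"
        strand = "-" if rng.random() < spec.strand_flip_prob else "+"
        g_start, g_end = pos, pos + len(gene)
        if strand == "+":
            parts.append(gene)
            amber_pos = [g_start + 3 * (s + 1) for s in amber_slots]
        else:
            parts.append(reverse_complement(gene))
            amber_pos = [g_end - 3 * (s + 1) - 3 for s in amber_slots]
        truth.genes.append(
            GeneTruth(g_start, g_end, strand, recoded, sorted(amber_pos))
        )
        pos += len(gene)
    if spec.n_genes in trna_slots:
        add_intergenic()
        add_trna()
    add_intergenic()
    genome = GenomeRecord(
        id=f"synth_seed{spec.seed}",
        seq="".join(parts),
        topology=spec.topology,
        description="synthetic phage-like genome",
    )
    return genome, truth


def mutate_genome(
    genome: GenomeRecord,
    truth: TruthSet,
    sub_rate: float,
    indel_rate: float = 0.0,
    seed: int = 0,
    new_id: str | None = None,
) -> tuple[GenomeRecord, TruthSet]:
    """Apply per-site substitutions and short (1-6 nt) indels.

    Every event is logged; feature coordinates in the returned TruthSet
    are remapped through the indels.  Deterministic given ``seed``.
    """
    if not 0.0 <= sub_rate <= 0.5 or not 0.0 <= indel_rate <= 0.5:
        raise ValueError("rates must lie in [0, 0.5]")
    rng = np.random.default_rng(seed)
    bases = "ACGT"
    seq = list(genome.seq)
    log: list[dict] = []
    L = len(seq)
    # substitutions (positions with original base N are left untouched)
    if sub_rate > 0:
        hits = np.nonzero(rng.random(L) < sub_rate)[0]
        for p in hits:
            old = seq[p]
            if old not in bases:
                continue
            alt = bases.replace(old, "")
            new = alt[int(rng.integers(0, 3))]
            seq[p] = new
            log.append({"type": "sub", "pos": int(p), "old": old, "new": new})
    # indels, applied right-to-left so logged positions refer to the
    # substituted-but-not-yet-indeled coordinate system
    if indel_rate > 0:
        hits = np.nonzero(rng.random(L) < indel_rate)[0]
        events = []
        for p in hits:
            ln = int(rng.integers(1, 7))
            if rng.random() < 0.5:
                ins = "".join(bases[i] for i in rng.integers(0, 4, size=ln))
                events.append({"type": "ins", "pos": int(p), "seq": ins})
            else:
                events.append({"type": "del", "pos": int(p), "len": min(ln, L - int(p))})
        for ev in sorted(events, key=lambda e: -e["pos"]):
            if ev["type"] == "ins":
                seq[ev["pos"] : ev["pos"]] = list(ev["seq"])
            else:
                del seq[ev["pos"] : ev["pos"] + ev["len"]]
            log.append(ev)
    # coordinate remap through indels
    def remap(coord: int) -> int:
        delta = 0
        for ev in log:
            if ev["type"] == "ins" and ev["pos"] <= coord:
                delta += len(ev["seq"])
            elif ev["type"] == "del" and ev["pos"] < coord:
                delta -= min(ev["len"], max(coord - ev["pos"], 0))
        return coord + delta

    new_truth = TruthSet(
        genes=[
            GeneTruth(
                remap(g.start), remap(g.end), g.strand, g.recoded,
                [remap(p) for p in g.amber_positions],
            )
            for g in truth.genes
        ],
        trnas=[TrnaTruth(remap(t.start), remap(t.end), t.strand, t.anticodon) for t in truth.trnas],
        mutations=truth.mutations + log,
    )
    mutated = GenomeRecord(
        id=new_id or f"{genome.id}_mut{seed}",
        seq="".join(seq),
        topology=genome.topology,
        description=f"mutant of {genome.id} (sub={sub_rate}, indel={indel_rate}, seed={seed})",
    )
    return mutated, new_truth
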