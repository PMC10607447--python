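"""Reciprocal-best-hit orthologs between recoded proteomes and gene-order
(synteny) conservation.

Proteins must come from annotations under each genome's recommended
genetic code: on recoded genomes a standard-code annotation fragments
recoded genes and orthologs are missed.  RBH with global affine-gap
BLOSUM62 alignments and 30% identity / 50% coverage thresholds is the
declared ortholog criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import kendalltau

from .seq_core import Annotation


def _aligner():
    from Bio import Align

    al = Align.PairwiseAligner()
    al.substitution_matrix = _blosum_with_unknowns()
    al.open_gap_score = -11
    al.extend_gap_score = -1
    al.mode = "global"
    return al


_BLOSUM_EXT = None


def _blosum_with_unknowns():
    global _BLOSUM_EXT
    if _BLOSUM_EXT is None:
        from Bio.Align import substitution_matrices

        _BLOSUM_EXT = substitution_matrices.load("BLOSUM62")
    return _BLOSUM_EXT


def _sanitize(protein: str) -> str:
    # translations may carry X (from N codons); '*' never appears internally
    allowed = set("ARNDCQEGHILKMFPSTWYVBZX")
    return "".join(c if c in allowed else "X" for c in protein)


@dataclass
class OrthologPair:
    orf_a: int  # index into annotation a's ORF list
    orf_b: int
    identity_pct: float
    coverage_pct: float
    score: float


@dataclass
class OrthologTable:
    genome_a: str
    genome_b: str
    pairs: list[OrthologPair] = field(default_factory=list)

    @property
    def n_shared(self) -> int:
        return len(self.pairs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "orf_a": [p.orf_a for p in self.pairs],
                "orf_b": [p.orf_b for p in self.pairs],
                "identity_pct": [round(p.identity_pct, 1) for p in self.pairs],
                "coverage_pct": [round(p.coverage_pct, 1) for p in self.pairs],
                "score": [p.score for p in self.pairs],
            }
        )


def _identity_coverage(aln, la: int, lb: int) -> tuple[float, float]:
    a_row, b_row = str(aln[0]), str(aln[1])
    matches = aligned = 0
    for x, y in zip(a_row, b_row):
        if x != "-" and y != "-":
            aligned += 1
            if x == y:
                matches += 1
    ident = 100.0 * matches / aligned if aligned else 0.0
    cov = 100.0 * aligned / min(la, lb) if min(la, lb) else 0.0
    return ident, cov


def rbh_orthologs(
    annot_a: Annotation,
    annot_b: Annotation,
    min_identity: float = 30.0,
    min_coverage: float = 50.0,
) -> OrthologTable:
    """Reciprocal best hits between two proteomes.

    (x, y) is kept iff y is x's highest-scoring hit, x is y's, and the
    pair passes both identity and coverage thresholds.  Score ties break
    toward the lower ORF index, keeping the result deterministic.
    """
    table = OrthologTable(annot_a.genome_id, annot_b.genome_id)
    prot_a = [_sanitize(o.protein) for o in annot_a.orfs]
    prot_b = [_sanitize(o.protein) for o in annot_b.orfs]
    if not prot_a or not prot_b:
        return table
    al = _aligner()
    scores = np.full((len(prot_a), len(prot_b)), -np.inf)
    for i, pa in enumerate(prot_a):
        for j, pb in enumerate(prot_b):
            scores[i, j] = al.score(pa, pb)
    best_for_a = scores.argmax(axis=1)  # argmax takes the first on ties
    best_for_b = scores.argmax(axis=0)
    for i, j in enumerate(best_for_a):
        if best_for_b[j] != i:
            continue
        aln = next(iter(al.align(prot_a[i], prot_b[j])))
        ident, cov = _identity_coverage(aln, len(prot_a[i]), len(prot_b[j]))
        if ident >= min_identity and cov >= min_coverage:
            table.pairs.append(OrthologPair(i, int(j), ident, cov, float(scores[i, j])))
    return table


def shared_core(tables: list[OrthologTable]) -> int:
    """Count of core ORFs with orthologs in every genome of the set.

    Builds a graph of RBH pairs over (genome, orf) nodes; a core member
    is a connected component holding exactly one ORF per genome.
    """
    genomes: set[str] = set()
    for t in tables:
        genomes.update((t.genome_a, t.genome_b))
    expected = {frozenset(p) for p in combinations(sorted(genomes), 2)}
    present = {frozenset((t.genome_a, t.genome_b)) for t in tables}
    if expected - present:
        raise ValueError(f"missing pairwise tables for: {sorted(expected - present)}")
    parent: dict[tuple[str, int], tuple[str, int]] = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        parent.setdefault(x, x)
        parent.setdefault(y, y)
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[rx] = ry

    for t in tables:
        for p in t.pairs:
            union((t.genome_a, p.orf_a), (t.genome_b, p.orf_b))
    components: dict[tuple[str, int], list[tuple[str, int]]] = {}
    for node in parent:
        components.setdefault(find(node), []).append(node)
    n_core = 0
    for members in components.values():
        per_genome = [g for g, _ in members]
        if len(members) == len(genomes) and len(set(per_genome)) == len(genomes):
            n_core += 1
    return n_core


@dataclass
class SyntenyScore:
    genome_a: str
    genome_b: str
    tau: float
    adjacency_fraction: float
    inverted: bool
    n_pairs: int


def synteny_score(
    table: OrthologTable, annot_a: Annotation, annot_b: Annotation
) -> SyntenyScore:
    """Gene-order conservation between two genomes.

    tau is the Kendall rank correlation between ortholog order indices;
    if most ortholog pairs lie on opposite strands the order of b is
    reversed first (inversion flag), so a genome compared with its exact
    reverse complement still scores tau = 1.  ``adjacency_fraction`` is
    the fraction of orthologs consecutive in a that are also consecutive
    in b.
    """
    if table.n_shared < 2:
        raise ValueError("synteny undefined for fewer than 2 ortholog pairs")
    opposite = sum(
        1
        for p in table.pairs
        if annot_a.orfs[p.orf_a].strand != annot_b.orfs[p.orf_b].strand
    )
    inverted = opposite > table.n_shared / 2
    order_a = np.argsort(np.argsort([annot_a.orfs[p.orf_a].start for p in table.pairs]))
    starts_b = [annot_b.orfs[p.orf_b].start for p in table.pairs]
    if inverted:
        starts_b = [-s for s in starts_b]
    order_b = np.argsort(np.argsort(starts_b))
    tau = float(kendalltau(order_a, order_b).statistic)
    if abs(abs(tau) - 1.0) < 1e-9:  # permutation inputs: snap float noise
        tau = 1.0 if tau > 0 else -1.0
    by_a = np.argsort(order_a)
    adjacent = sum(
        1
        for t in range(len(by_a) - 1)
        if abs(int(order_b[by_a[t + 1]]) - int(order_b[by_a[t]])) == 1
    )
    return SyntenyScore(
        genome_a=table.genome_a,
        genome_b=table.genome_b,
        tau=tau,
        adjacency_fraction=adjacent / (table.n_shared - 1),
        inverted=inverted,
        n_pairs=table.n_shared,
    )
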