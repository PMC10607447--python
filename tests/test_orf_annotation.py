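import numpy as np
import pytest

from phagecode.seq_core import GeneticCode, GenomeRecord, reverse_complement
from phagecode.orf_annotation import (
    OrfCall,
    OrfCallerParams,
    coding_fraction,
    find_orfs,
    max_coverage_selection,
    select_parsimonious,
)

from conftest import random_dna

CODE11 = GeneticCode.from_table_id(11)
CODE15 = GeneticCode.from_table_id(15)


def brute_force_orfs(seq: str, stop_codons: set, start_codons: set, min_aa: int):
    """Independent six-frame scan: for every start codon, walk codon by
    codon to the next in-frame stop; longest ORF per stop kept."""
    found = {}
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        n = len(s)
        for i in range(n - 2):
            if s[i : i + 3] not in start_codons:
                continue
            j = i
            while j + 3 <= n:
                codon = s[j : j + 3]
                if j > i and codon in stop_codons:
                    break
                j += 3
            else:
                continue  # ran off the end: truncated, discard
            if s[j : j + 3] not in stop_codons:
                continue
            start, end = i, j + 3
            if (end - start) // 3 - 1 < min_aa:
                continue
            if strand == "-":
                start, end = n - end, n - start
            key = (end if strand == "+" else start, strand, i % 3)
            prev = found.get(key)
            if prev is None or (end - start) > (prev[1] - prev[0]):
                found[key] = (start, end, strand)
    return sorted(found.values())


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_caller_matches_brute_force_scan(seed):
    seq = random_dna(1500, seed + 77)
    genome = GenomeRecord(id="g", seq=seq)
    got = sorted(
        (o.start, o.end, o.strand)
        for o in find_orfs(genome, CODE11, OrfCallerParams(min_length_aa=10))
    )
    expected = brute_force_orfs(seq, {"TAA", "TAG", "TGA"}, {"ATG", "GTG", "TTG"}, 10)
    assert got == expected


def test_single_gene_in_inert_flanks():
    rng = np.random.default_rng(5)
    # 33-codon gene: ATG + 31 alanine codons (GCT) + TAA; flanks without
    # start or stop codons on either strand (C runs)
    gene = "ATG" + "GCT" * 31 + "TAA"
    genome = GenomeRecord(id="g", seq="C" * 99 + gene + "C" * 99)
    orfs = find_orfs(genome, CODE11, OrfCallerParams(min_length_aa=30))
    assert len(orfs) == 1
    o = orfs[0]
    assert (o.start, o.end, o.strand, o.length_aa) == (99, 99 + len(gene), "+", 32)
    assert o.protein == "M" + "A" * 31


def test_tables_identical_when_no_tag_present():
    # TAG-free on both strands (CTA is the reverse-strand TAG)
    seq = random_dna(3000, 9)
    while "TAG" in seq or "CTA" in seq:
        seq = seq.replace("TAG", "TTG").replace("CTA", "CCA")
    genome = GenomeRecord(id="g", seq=seq)
    a = find_orfs(genome, CODE11)
    b = find_orfs(genome, CODE15)
    assert [(o.start, o.end, o.strand) for o in a] == [(o.start, o.end, o.strand) for o in b]


def test_reverse_complement_reflects_coordinates():
    seq = random_dna(2000, 13)
    g1 = GenomeRecord(id="g", seq=seq)
    g2 = GenomeRecord(id="g", seq=reverse_complement(seq))
    L = len(seq)
    fwd = sorted((o.start, o.end, o.strand) for o in find_orfs(g1, CODE11))
    refl = sorted(
        (L - o.end, L - o.start, "+" if o.strand == "-" else "-")
        for o in find_orfs(g2, CODE11)
    )
    assert fwd == refl


@pytest.mark.parametrize("table", [11, 15, 4])
def test_no_internal_stops_in_any_reported_protein(table):
    genome = GenomeRecord(id="g", seq=random_dna(4000, table))
    for o in find_orfs(genome, GeneticCode.from_table_id(table)):
        assert "*" not in o.protein


def test_internal_reassigned_stop_positions():
    # gene with one TAG at codon 20 of 40
    gene = "ATG" + "GCT" * 19 + "TAG" + "GCT" * 19 + "TAA"
    genome = GenomeRecord(id="g", seq="C" * 60 + gene + "C" * 60)
    orfs15 = find_orfs(genome, CODE15)
    assert len(orfs15) == 1
    assert orfs15[0].internal_reassigned_stops == [60 + 20 * 3]
    # under table 11 the gene is truncated at the TAG and carries no marks
    orfs11 = find_orfs(genome, CODE11, OrfCallerParams(min_length_aa=10))
    assert all(o.internal_reassigned_stops == [] for o in orfs11)


def test_minus_strand_reassigned_stop_position():
    gene = "ATG" + "GCT" * 19 + "TAG" + "GCT" * 19 + "TAA"
    genome = GenomeRecord(id="g", seq="C" * 60 + reverse_complement(gene) + "C" * 60)
    orfs15 = [o for o in find_orfs(genome, CODE15) if o.strand == "-"]
    assert len(orfs15) == 1
    (pos,) = orfs15[0].internal_reassigned_stops
    assert genome.seq[pos : pos + 3] == reverse_complement("TAG")


def test_circular_genome_wraps_orf_across_origin():
    gene = "ATG" + "GCT" * 40 + "TAA"
    # place the gene across the origin: last 60 bases of gene at contig start
    full = "C" * 200 + gene
    rolled = full[-60:] + full[:-60]
    lin = GenomeRecord(id="lin", seq=rolled, topology="linear")
    circ = GenomeRecord(id="circ", seq=rolled, topology="circular")
    assert find_orfs(lin, CODE11) == []
    wrapped = [o for o in find_orfs(circ, CODE11) if o.wraps]
    assert len(wrapped) == 1
    assert wrapped[0].length_aa == 41


def test_coding_fraction_cases():
    mk = lambda s, e: OrfCall("g", s, e, "+", 0, 11, "M" * ((e - s) // 3 - 1))
    assert coding_fraction([], 1000) == 0.0
    assert coding_fraction([mk(0, 500)], 1000) == 0.5
    # two fully overlapping ORFs cover the same ground as one
    assert coding_fraction([mk(0, 300), mk(0, 300)], 1000) == 0.3
    with pytest.raises(ValueError):
        coding_fraction([mk(0, 300)], 0)


def test_max_coverage_selection_is_optimal_on_toy():
    mk = lambda s, e: OrfCall("g", s, e, "+", 0, 11, "M" * ((e - s) // 3 - 1))
    # one long interval beats two short ones it overlaps
    a, b, c = mk(0, 300), mk(240, 360), mk(330, 600)
    sel = max_coverage_selection([a, b, c])
    assert sel == [a, c]


def test_select_parsimonious_bounds_overlap():
    mk = lambda s, e: OrfCall("g", s, e, "+", 0, 11, "M" * ((e - s) // 3 - 1))
    sel = select_parsimonious([mk(0, 300), mk(270, 600), mk(290, 500)], max_overlap_nt=30)
    spans = [(o.start, o.end) for o in sel]
    assert (0, 300) in spans and (270, 600) in spans and (290, 500) not in spans
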