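import numpy as np
import pytest

from phagecode.seq_core import GeneticCode, GenomeRecord, reverse_complement
from phagecode.orf_annotation import OrfCallerParams, find_orfs
from phagecode.recoding import (
    CodonReport,
    RecodingParams,
    analyze_genome,
    annotate_recoded,
    decide_code,
    find_interruptions,
    recoding_score,
)
from phagecode.synthetic_data import SyntheticSpec, generate_genome
from phagecode.trna_scan import detect_trnas

from conftest import random_dna

CODE11 = GeneticCode.from_table_id(11)


def _codon_fill(n, seed):
    """n sense codons drawn from the generator's coding distribution."""
    from phagecode.synthetic_data import _cached_distribution

    rng = np.random.default_rng(seed)
    codons, probs = _cached_distribution(0.45)
    return [codons[i] for i in rng.choice(len(codons), n, p=probs)]


def _gene_with_stops(n_codons, stop_slots, stop="TAG", seed=0):
    """ATG + sense codons + TAA, with `stop` substituted at given slots."""
    cs = _codon_fill(n_codons - 2, seed)
    for slot in stop_slots:
        cs[slot - 1] = stop  # slot counts codons from gene start (ATG = 0)
    return "ATG" + "".join(cs) + "TAA"


def test_interruption_single_amber():
    """A 100-codon gene split by one TAG yields one candidate joining 99 aa."""
    gene = _gene_with_stops(100, [50])
    genome = GenomeRecord(id="g", seq="C" * 120 + gene + "C" * 120)
    orfs = find_orfs(genome, CODE11, OrfCallerParams(min_length_aa=10))
    cands = find_interruptions(orfs, genome, "TAG")
    assert len(cands) == 1
    c = cands[0]
    assert c.joined_length_aa == 99 and c.n_joining_stops == 1
    assert c.upstream_orf.length_aa == 50


def test_interruption_ignores_other_stop_types():
    gene = _gene_with_stops(100, [50], stop="TGA")
    genome = GenomeRecord(id="g", seq="C" * 120 + gene + "C" * 120)
    orfs = find_orfs(genome, CODE11, OrfCallerParams(min_length_aa=10))
    assert find_interruptions(orfs, genome, "TAG") == []
    assert len(find_interruptions(orfs, genome, "TGA")) == 1


def test_interruption_chain_spans_all_fragments():
    """Two TAGs with a start codon in the middle fragment chain together."""
    cs = _codon_fill(98, 3)
    cs[29] = "TAG"
    cs[34] = "ATG"  # makes the middle fragment a callable ORF
    cs[59] = "TAG"
    gene = "ATG" + "".join(cs) + "TAA"
    genome = GenomeRecord(id="g", seq="C" * 120 + gene + "C" * 120)
    orfs = find_orfs(genome, CODE11, OrfCallerParams(min_length_aa=10))
    cands = find_interruptions(orfs, genome, "TAG")
    assert len(cands) == 2
    # the union of joined regions covers the whole gene
    lo = min(min(c.upstream_orf.start, c.downstream_orf.start) for c in cands)
    hi = max(max(c.upstream_orf.end, c.downstream_orf.end) for c in cands)
    assert lo == 120 and hi == 120 + len(gene)


def test_consecutive_stop_run_counted_once():
    gene = _gene_with_stops(100, [50, 51])
    genome = GenomeRecord(id="g", seq="C" * 120 + gene + "C" * 120)
    orfs = find_orfs(genome, CODE11, OrfCallerParams(min_length_aa=10))
    cands = find_interruptions(orfs, genome, "TAG")
    assert len(cands) == 1 and cands[0].n_joining_stops == 2


def test_interruption_rejects_non_stop_codon():
    genome = GenomeRecord(id="g", seq=random_dna(500, 0))
    with pytest.raises(ValueError):
        find_interruptions([], genome, "AAA")


def _report(codon, gain, cands, table, support=0):
    return CodonReport(
        genome_id="g", stop_codon=codon, alt_table_id=table,
        n_interruption_candidates=cands, coding_fraction_std=0.8,
        coding_fraction_alt=0.8 + gain, coding_fraction_gain=gain,
        mean_orf_length_ratio=1.0, n_orfs_with_internal_stop=cands,
        n_internal_stops_total=cands, suppressor_trna_support=support,
        passes_rule=(gain >= 0.02 and cands >= 5 and codon != "TAA"),
    )


def test_decide_code_all_gains_near_zero_keeps_table_11():
    reports = {c: _report(c, 0.001, 0, t) for c, t in (("TAG", 15), ("TGA", 4), ("TAA", 0))}
    d = decide_code(reports)
    assert d.verdict == "standard" and d.recommended_table == 11


def test_decide_code_strong_tag_signal_recommends_table_15():
    reports = {
        "TAG": _report("TAG", 0.08, 12, 15, support=3),
        "TGA": _report("TGA", 0.0, 0, 4),
        "TAA": _report("TAA", 0.0, 0, 0),
    }
    d = decide_code(reports)
    assert d.verdict == "reassigned" and d.reassigned_codon == "TAG"
    assert d.recommended_table == 15


def test_decide_code_without_trna_support_still_recommends_with_note():
    reports = {
        "TAG": _report("TAG", 0.08, 12, 15, support=0),
        "TGA": _report("TGA", 0.0, 0, 4),
        "TAA": _report("TAA", 0.0, 0, 0),
    }
    d = decide_code(reports)
    assert d.recommended_table == 15
    assert any("no suppressor tRNA" in n for n in d.notes)


def test_decide_code_double_pass_breaks_tie_to_higher_gain():
    reports = {
        "TAG": _report("TAG", 0.08, 12, 15),
        "TGA": _report("TGA", 0.05, 9, 4),
        "TAA": _report("TAA", 0.0, 0, 0),
    }
    d = decide_code(reports)
    assert d.recommended_table == 15
    assert any("multiple stop codons" in n for n in d.notes)


def test_taa_reassignment_flagged_never_recommended(small_standard):
    genome, _ = small_standard
    r = recoding_score(genome, "TAA")
    assert r.alt_table_id == 0
    assert not r.passes_rule
    assert any("never recommended" in n for n in r.notes)


def test_recoded_genome_scores_and_verdict(small_recoded):
    genome, truth = small_recoded
    trnas = detect_trnas(genome)
    rep = analyze_genome(genome, trnas)
    assert rep.verdict == "reassigned"
    assert rep.reassigned_codon == "TAG" and rep.recommended_table == 15
    tag = rep.reports["TAG"]
    assert tag.suppressor_trna_support == 1
    assert tag.coding_fraction_gain >= 0.02
    assert tag.n_orfs_with_internal_stop >= len(truth.recoded_genes)


def test_standard_genome_verdict_and_zero_gain(small_standard):
    genome, _ = small_standard
    rep = analyze_genome(genome)
    assert rep.verdict == "standard" and rep.recommended_table == 11
    assert not rep.reports["TAG"].passes_rule
    assert not rep.reports["TGA"].passes_rule


def test_annotation_of_standard_genome_matches_table_11(small_standard):
    genome, _ = small_standard
    ann11 = annotate_recoded(genome, 11)
    ann15_on_std = annotate_recoded(genome, 11)
    assert [(o.start, o.end) for o in ann11.orfs] == [(o.start, o.end) for o in ann15_on_std.orfs]
    assert ann11.n_recoded_orfs == 0 and ann11.pct_recoded_orfs == 0.0


def test_annotation_recovers_every_recoded_gene_with_its_ambers(small_recoded):
    genome, truth = small_recoded
    ann = annotate_recoded(genome, 15)
    assert ann.table_id == 15
    found = set()
    for o in ann.orfs:
        found.update(o.internal_reassigned_stops)
    for gene in truth.recoded_genes:
        assert set(gene.amber_positions) <= found
    assert ann.n_recoded_orfs >= len(truth.recoded_genes)


def test_coding_fraction_gain_bounds(small_recoded, small_standard):
    for genome, _ in (small_recoded, small_standard):
        r = recoding_score(genome, "TAG")
        assert -1.0 <= r.coding_fraction_gain <= 1.0
        assert 0.0 <= r.coding_fraction_std <= 1.0
        assert 0.0 <= r.coding_fraction_alt <= 1.0
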