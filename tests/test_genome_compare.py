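import numpy as np
import pytest

from phagecode.genome_compare import (
    NiParams,
    SgParams,
    SimilarityMatrix,
    cluster_taxa,
    intergenomic_similarity,
    pairwise_ni,
    sg_score,
)
from phagecode.synthetic_data import SyntheticSpec, generate_genome, mutate_genome

from conftest import random_dna, substitute

MATCH, MISMATCH, GAP = 2, -1, -5


def nw_oracle(a: str, b: str):
    """Independent pure-Python Needleman-Wunsch with the package's declared
    scoring and tie-break (diagonal > up > left); returns (matches, columns
    after trimming terminal gap runs, score)."""
    n, m = len(a), len(b)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    P = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        H[i][0], P[i][0] = GAP * i, 1
    for j in range(1, m + 1):
        H[0][j], P[0][j] = GAP * j, 2
    for i in range(1, n + 1):
        ai = a[i - 1]
        Hi, Hi1, Pi = H[i], H[i - 1], P[i]
        for j in range(1, m + 1):
            d = Hi1[j - 1] + (MATCH if ai == b[j - 1] else MISMATCH)
            u = Hi1[j] + GAP
            l = Hi[j - 1] + GAP
            if d >= u and d >= l:
                Hi[j], Pi[j] = d, 0
            elif u >= l:
                Hi[j], Pi[j] = u, 1
            else:
                Hi[j], Pi[j] = l, 2
    cols = []
    i, j = n, m
    while i > 0 or j > 0:
        p = P[i][j]
        if p == 0 and i > 0 and j > 0:
            cols.append(0 if a[i - 1] == b[j - 1] else 1)
            i, j = i - 1, j - 1
        elif p == 1 and i > 0:
            cols.append(2)
            i -= 1
        else:
            cols.append(2)
            j -= 1
    cols.reverse()
    lo, hi = 0, len(cols)
    while lo < hi and cols[lo] == 2:
        lo += 1
    while hi > lo and cols[hi - 1] == 2:
        hi -= 1
    trimmed = cols[lo:hi]
    return trimmed.count(0), len(trimmed), H[n][m]


def _mutant_pair(seed, length):
    a = random_dna(length, seed)
    rng = np.random.default_rng(seed + 1)
    b = list(a)
    # substitutions and a couple of short indels
    for p in range(len(b) - 1, -1, -1):
        r = rng.random()
        if r < 0.05:
            b[p] = "ACGT".replace(b[p], "")[int(rng.integers(0, 3))]
        elif r < 0.055:
            del b[p : p + int(rng.integers(1, 4))]
    return a, "".join(b)


@pytest.mark.parametrize("seed", range(8))
def test_ni_matches_independent_dp_oracle(seed):
    a, b = _mutant_pair(seed, 300)
    matches, cols, _ = nw_oracle(*(sorted([a, b], key=lambda s: (len(s), s))))
    assert pairwise_ni(a, b) == matches / cols


def test_identical_genomes_have_unit_identity():
    s = random_dna(4000, 3)
    assert pairwise_ni(s, s) == 1.0


def test_ten_substitutions_in_a_kilobase():
    a = random_dna(1000, 11)
    b, n = substitute(a, 0.01, 11)
    # re-draw until exactly 10 substitutions realized, to pin the value
    seed = 11
    while n != 10:
        seed += 1
        b, n = substitute(a, 0.01, seed)
    assert pairwise_ni(a, b) == 0.990


def test_ni_equals_mutation_log_for_substitution_only_mutants():
    spec = SyntheticSpec(n_genes=20, gene_length_aa=(100, 200), seed=5)
    genome, truth = generate_genome(spec)
    for d, seed in ((0.02, 1), (0.10, 2)):
        mut, t2 = mutate_genome(genome, truth, d, 0.0, seed=seed)
        _, stats = pairwise_ni(genome.seq, mut.seq, return_stats=True)
        # integer-level identity: the alignment is the gap-free identity
        # alignment, so matches and columns are pinned by the log
        assert stats.gap_columns == 0
        assert stats.total_columns == len(genome)
        assert stats.matches == len(genome) - t2.n_substitutions


def test_ni_monotone_in_substitution_rate():
    spec = SyntheticSpec(n_genes=15, gene_length_aa=(100, 200), seed=6)
    genome, truth = generate_genome(spec)
    nis = []
    for d in (0.01, 0.05, 0.10, 0.20):
        vals = [
            pairwise_ni(genome.seq, mutate_genome(genome, truth, d, 0.0, seed=s)[0].seq)
            for s in range(3)
        ]
        nis.append(np.mean(vals))
    assert all(x > y for x, y in zip(nis, nis[1:]))


def test_ni_symmetry():
    a, b = _mutant_pair(21, 2000)
    assert pairwise_ni(a, b) == pairwise_ni(b, a)


def test_ni_gap_convention_switch():
    # one 3-nt internal deletion in 600 nt: default counts the gap columns
    # as mismatches, "exclude" drops them
    a = random_dna(600, 30)
    b = a[:300] + a[303:]
    ni_mismatch = pairwise_ni(a, b, NiParams(gap_mode="mismatch"))
    ni_exclude = pairwise_ni(a, b, NiParams(gap_mode="exclude"))
    assert ni_exclude > ni_mismatch
    assert ni_exclude == 1.0


def test_sg_self_normalization_and_range():
    genomes = [generate_genome(SyntheticSpec(n_genes=10, seed=s))[0] for s in range(3)]
    for g in genomes:
        assert sg_score(g, g) == 1.0
    v = sg_score(genomes[0], genomes[1])
    assert 0.0 <= v <= 1.0


def test_sg_symmetry():
    a = generate_genome(SyntheticSpec(n_genes=8, seed=1))[0]
    b = generate_genome(SyntheticSpec(n_genes=8, seed=2))[0]
    assert sg_score(a, b) == sg_score(b, a)


def test_sg_null_on_unrelated_random_genomes():
    for s in (0, 1, 2):
        a, b = random_dna(20000, 500 + s), random_dna(20000, 600 + s)
        assert sg_score(a, b) < 0.01


def test_sg_rejects_degenerate_input():
    with pytest.raises(ValueError):
        sg_score("ACGT" * 10, "ACGT" * 200)


def test_intergenomic_similarity_cases():
    g = random_dna(3000, 44)
    assert intergenomic_similarity(g, g) == 1.0
    assert intergenomic_similarity(g, g[:1500]) == pytest.approx(2 / 3, abs=1e-9)
    assert intergenomic_similarity(random_dna(5000, 1), random_dna(5000, 2)) < 0.05


def test_similarity_matrix_validation():
    with pytest.raises(ValueError, match="symmetric"):
        SimilarityMatrix(["a", "b"], "NI", np.array([[1, 0.5], [0.6, 1]]))
    with pytest.raises(ValueError, match="shape"):
        SimilarityMatrix(["a"], "NI", np.eye(2))


def test_clustering_reproduces_published_genus_species_partition():
    """Three genomes at NI 86.4/82.7/80.4% form one genus of three species."""
    ids = ["phAss-1", "ctckW2", "ct6IQ4"]
    v = np.array([
        [100.0, 86.4, 82.7],
        [86.4, 100.0, 80.4],
        [82.7, 80.4, 100.0],
    ]) / 100.0
    cl = cluster_taxa(SimilarityMatrix(ids, "NI", v))
    assert len(cl.genus_clusters) == 1 and sorted(cl.genus_clusters[0]) == sorted(ids)
    assert len(cl.species_clusters) == 3


@pytest.mark.parametrize("ni,n_species", [(88.1, 2), (96.0, 1)])
def test_clustering_pair_threshold_logic(ni, n_species):
    v = np.array([[100.0, ni], [ni, 100.0]]) / 100.0
    cl = cluster_taxa(SimilarityMatrix(["a", "b"], "NI", v))
    assert len(cl.genus_clusters) == 1
    assert len(cl.species_clusters) == n_species


def test_clustering_threshold_validation():
    m = SimilarityMatrix(["a", "b"], "NI", np.eye(2))
    with pytest.raises(ValueError):
        cluster_taxa(m, species_threshold=70, genus_threshold=95)
    with pytest.raises(ValueError):
        cluster_taxa(m, species_threshold=101)


@pytest.mark.parametrize("linkage", ["single", "complete"])
def test_species_partition_refines_genus_partition(linkage):
    rng = np.random.default_rng(7)
    for _ in range(10):
        n = int(rng.integers(3, 8))
        v = rng.uniform(0, 1, size=(n, n))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        ids = [f"g{i}" for i in range(n)]
        cl = cluster_taxa(SimilarityMatrix(ids, "NI", v), linkage_method=linkage)
        genus_of = {g: i for i, cluster in enumerate(cl.genus_clusters) for g in cluster}
        for sp in cl.species_clusters:
            assert len({genus_of[g] for g in sp}) == 1
        assert sorted(g for c in cl.species_clusters for g in c) == sorted(ids)
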