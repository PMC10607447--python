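"""Pairwise whole-genome comparison and species/genus clustering.

Three similarity statistics:

* **NI** (nucleotide identity): matches / aligned columns from a global
  genome alignment.  Small pairs get a full dynamic-programming
  alignment; genome-scale pairs are aligned by unique 15-mer anchor
  chaining with DP over the inter-anchor segments.  By the default gap
  convention internal gap columns count as mismatch columns and terminal
  overhangs are excluded (config-switchable to excluding gap columns).
* **SG**: summed scores of non-overlapping ungapped BLOSUM62 local
  alignments between all six-frame translations, normalized by the
  smaller self-score, so SG(self)=1 and 0 <= SG <= 1.
* **intergenomic similarity** (VIRIDIC-style): twice the aligned
  identities over the summed genome lengths, from the same anchor-chain
  machinery run in local mode (no terminal extension).

Clustering applies the ICTV-style thresholds (95% species, 70% genus);
species clusters are computed within each genus cluster, so the species
partition refines the genus partition by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from . import _align
from .seq_core import GenomeRecord, translate, GeneticCode, reverse_complement


@dataclass(frozen=True)
class NiParams:
    anchor_k: int = 15
    gap_mode: str = "mismatch"  # internal gap columns: "mismatch" or "exclude"
    full_dp_max_cells: int = 4_000_000
    segment_dp_max_cells: int = 25_000_000
    no_anchor_global_cap: int = 200_000  # combined length for full-global fallback

    def __post_init__(self) -> None:
        if self.gap_mode not in ("mismatch", "exclude"):
            raise ValueError(f"unknown gap_mode {self.gap_mode!r}")


@dataclass
class AlignmentStats:
    matches: int = 0
    gap_columns: int = 0
    total_columns: int = 0
    flag: str = ""

    def identity(self, gap_mode: str) -> float:
        cols = self.total_columns
        if gap_mode == "exclude":
            cols -= self.gap_columns
        return self.matches / cols if cols > 0 else 0.0


def _segment_stats(a_seg: str, b_seg: str, params: NiParams) -> tuple[int, int, int]:
    if not a_seg and not b_seg:
        return 0, 0, 0
    if not a_seg or not b_seg:
        g = len(a_seg) + len(b_seg)
        return 0, g, g
    if len(a_seg) * len(b_seg) <= params.segment_dp_max_cells:
        m, g, t, _ = _align.nw_stats(_align.encode_dna(a_seg), _align.encode_dna(b_seg))
        return m, g, t
    return _align.edlib_stats(a_seg, b_seg)


def _internal_segment_stats(a_seg: str, b_seg: str, params: NiParams) -> tuple[int, int, int]:
    """Stats for a between-anchor segment: terminal trimming must not
    apply here, so trimmed overhang columns are added back as gaps."""
    m, g, t = _segment_stats(a_seg, b_seg, params)
    # nw_stats/edlib_stats trim terminal gap runs, but between anchors the
    # whole segment is internal to the overall alignment, so the trimmed
    # columns are restored as gap columns.  For any global alignment,
    # untrimmed columns = len(a) + len(b) - (match + mismatch columns).
    both = t - g
    untrimmed = len(a_seg) + len(b_seg) - both
    extra = untrimmed - t
    return m, g + extra, t + extra


def _align_anchor_route(
    a: str, b: str, params: NiParams, local: bool
) -> AlignmentStats:
    chain = _align.chain_anchors(a, b, k=params.anchor_k)
    if not chain:
        if local:
            return AlignmentStats(flag="no_homology")
        if len(a) + len(b) <= params.no_anchor_global_cap:
            m, g, t = _align.edlib_stats(a, b)
            return AlignmentStats(m, g, t, flag="no_anchors_full_global")
        return AlignmentStats(flag="no_homology")
    stats = AlignmentStats()
    prev_a = prev_b = None
    for pa, pb, ln in chain:
        if prev_a is None:
            if not local:
                m, g, t = _segment_stats(a[:pa], b[:pb], params)
                stats.matches += m
                stats.gap_columns += g
                stats.total_columns += t
        else:
            m, g, t = _internal_segment_stats(a[prev_a:pa], b[prev_b:pb], params)
            stats.matches += m
            stats.gap_columns += g
            stats.total_columns += t
        stats.matches += ln
        stats.total_columns += ln
        prev_a, prev_b = pa + ln, pb + ln
    if not local:
        m, g, t = _segment_stats(a[prev_a:], b[prev_b:], params)
        stats.matches += m
        stats.gap_columns += g
        stats.total_columns += t
    return stats


def global_alignment_stats(a: str, b: str, params: NiParams | None = None) -> AlignmentStats:
    """Global alignment statistics under the declared conventions."""
    params = params or NiParams()
    if len(a) * len(b) <= params.full_dp_max_cells:
        m, g, t, _ = _align.nw_stats(_align.encode_dna(a), _align.encode_dna(b))
        return AlignmentStats(m, g, t)
    return _align_anchor_route(a, b, params, local=False)


def pairwise_ni(
    a: GenomeRecord | str,
    b: GenomeRecord | str,
    params: NiParams | None = None,
    return_stats: bool = False,
):
    """Whole-genome nucleotide identity in [0, 1].

    NI = matches / aligned columns; internal gap columns count as
    mismatches under the default convention, terminal overhangs are
    excluded.  Symmetric in its arguments.
    """
    params = params or NiParams()
    sa = a.seq if isinstance(a, GenomeRecord) else a
    sb = b.seq if isinstance(b, GenomeRecord) else b
    if not sa or not sb:
        raise ValueError("both genomes must be non-empty")
    # canonical orientation makes NI exactly symmetric in its arguments
    # (DP tie-breaks are not)
    if (len(sb), sb) < (len(sa), sa):
        sa, sb = sb, sa
    stats = global_alignment_stats(sa, sb, params)
    ni = stats.identity(params.gap_mode)
    return (ni, stats) if return_stats else ni


def intergenomic_similarity(
    a: GenomeRecord | str,
    b: GenomeRecord | str,
    params: NiParams | None = None,
    return_stats: bool = False,
):
    """VIRIDIC-style similarity: 2 * aligned identities / (len a + len b).

    Computed from the anchored alignment in local mode (the unaligned
    genome fraction dilutes the value, exactly as unalignable regions do
    in the reciprocal-BLASTN definition).
    """
    params = params or NiParams()
    sa = a.seq if isinstance(a, GenomeRecord) else a
    sb = b.seq if isinstance(b, GenomeRecord) else b
    if not sa or not sb:
        raise ValueError("both genomes must be non-empty")
    if (len(sb), sb) < (len(sa), sa):
        sa, sb = sb, sa
    stats = _align_anchor_route(sa, sb, params, local=True)
    sim = 2.0 * stats.matches / (len(sa) + len(sb))
    return (sim, stats) if return_stats else sim


# ---------------------------------------------------------------------------
# SG score


@dataclass(frozen=True)
class SgParams:
    xdrop: int = 20
    min_hsp_score: int = 50
    table_id: int = 11  # tBLASTx-style translation of both genomes


def _six_frame_proteins(seq: str, code: GeneticCode) -> list[str]:
    frames = []
    for s in (seq, reverse_complement(seq)):
        for f in range(3):
            sub = s[f:]
            sub = sub[: len(sub) - len(sub) % 3]
            frames.append(translate(sub, code) if sub else "")
    return frames


def _directional_sg_sum(
    frames_a: list[np.ndarray], frames_b: list[np.ndarray], params: SgParams
) -> float:
    hsps: list[tuple[int, int, int, int, int]] = []  # (-score, fa, fb, start, end)
    for fa, qa in enumerate(frames_a):
        for fb, qb in enumerate(frames_b):
            for s, e, sc in _align.hsp_search(qa, qb, params.xdrop, params.min_hsp_score):
                hsps.append((-sc, fa, fb, s, e))
    hsps.sort()
    chosen: dict[int, list[tuple[int, int]]] = {}
    total = 0.0
    for negsc, fa, _fb, s, e in hsps:
        ivs = chosen.setdefault(fa, [])
        if all(e <= cs or s >= ce for cs, ce in ivs):
            ivs.append((s, e))
            total += -negsc
    return total


def sg_score(
    a: GenomeRecord | str,
    b: GenomeRecord | str,
    params: SgParams | None = None,
    return_raw: bool = False,
):
    """Normalized translated similarity, 0 <= SG <= 1, SG(self) = 1.

    S(a,b) sums the scores of greedily chosen non-overlapping ungapped
    BLOSUM62 HSPs (4-aa exact seeds, X-drop 20, score >= 50) between all
    six-frame translations; the greedy selection runs on the query's
    coordinates, so S is symmetrized by averaging the two directions.
    SG = S_sym(a,b) / min(S(a,a), S(b,b)), clamped to [0, 1].
    """
    params = params or SgParams()
    sa = a.seq if isinstance(a, GenomeRecord) else a
    sb = b.seq if isinstance(b, GenomeRecord) else b
    if len(sa) < 100 or len(sb) < 100:
        raise ValueError("genomes shorter than 100 nt: translation frames degenerate")
    code = GeneticCode.from_table_id(params.table_id)
    fa = [_align.encode_protein(p) for p in _six_frame_proteins(sa, code)]
    fb = [_align.encode_protein(p) for p in _six_frame_proteins(sb, code)]
    s_aa = _directional_sg_sum(fa, fa, params)
    s_bb = _directional_sg_sum(fb, fb, params)
    s_ab = _directional_sg_sum(fa, fb, params)
    s_ba = _directional_sg_sum(fb, fa, params)
    s_sym = 0.5 * (s_ab + s_ba)
    denom = min(s_aa, s_bb)
    sg = min(max(s_sym / denom, 0.0), 1.0) if denom > 0 else 0.0
    return (sg, {"S_ab": s_ab, "S_ba": s_ba, "S_aa": s_aa, "S_bb": s_bb}) if return_raw else sg


# ---------------------------------------------------------------------------
# similarity matrices and clustering


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise similarity over a genome set (fractions in [0,1])."""

    genome_ids: list[str]
    metric: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.genome_ids), len(self.genome_ids)):
            raise ValueError("matrix shape does not match genome_ids")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("similarity matrix must be symmetric")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("similarity values must lie in [0, 1]")
        self.values = np.clip(v, 0.0, 1.0)

    def to_percent_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.round(self.values * 100.0, 1), index=self.genome_ids, columns=self.genome_ids
        )

    @classmethod
    def compute(
        cls,
        genomes: list[GenomeRecord],
        metric: str = "intergenomic_similarity",
        ni_params: NiParams | None = None,
        sg_params: SgParams | None = None,
    ) -> "SimilarityMatrix":
        fn = {
            "NI": lambda x, y: pairwise_ni(x, y, ni_params),
            "SG": lambda x, y: sg_score(x, y, sg_params),
            "intergenomic_similarity": lambda x, y: intergenomic_similarity(x, y, ni_params),
        }[metric]
        n = len(genomes)
        vals = np.eye(n)
        for i in range(n):
            for j in range(i + 1, n):
                vals[i, j] = vals[j, i] = fn(genomes[i], genomes[j])
        return cls([g.id for g in genomes], metric, vals)


@dataclass
class TaxonClustering:
    """Threshold clustering into putative species and genera."""

    genome_ids: list[str]
    species_threshold: float
    genus_threshold: float
    species_clusters: list[list[str]]
    genus_clusters: list[list[str]]
    linkage: str = "single"


def _threshold_partition(sim_pct: np.ndarray, ids: list[str], threshold: float, method: str):
    n = len(ids)
    if n == 1:
        return [[ids[0]]]
    dist = 100.0 - sim_pct
    iu = np.triu_indices(n, 1)
    Z = linkage(dist[iu], method=method)
    labels = fcluster(Z, t=100.0 - threshold, criterion="distance")
    clusters: dict[int, list[str]] = {}
    for lbl, gid in zip(labels, ids):
        clusters.setdefault(int(lbl), []).append(gid)
    return sorted(clusters.values(), key=lambda c: (-len(c), c[0]))


def cluster_taxa(
    matrix: SimilarityMatrix,
    species_threshold: float = 95.0,
    genus_threshold: float = 70.0,
    linkage_method: str = "single",
) -> TaxonClustering:
    """Cluster genomes at the species (>=95%) and genus (>=70%) thresholds.

    Species clustering is run within each genus cluster, so the species
    partition refines the genus partition for any linkage.
    """
    for t in (species_threshold, genus_threshold):
        if not 0.0 < t < 100.0:
            raise ValueError("thresholds must lie in (0, 100)")
    if species_threshold <= genus_threshold:
        raise ValueError("species threshold must exceed genus threshold")
    if linkage_method not in ("single", "complete"):
        raise ValueError("linkage must be 'single' or 'complete'")
    pct = matrix.values * 100.0
    ids = matrix.genome_ids
    genus_clusters = _threshold_partition(pct, ids, genus_threshold, linkage_method)
    species_clusters: list[list[str]] = []
    index = {g: i for i, g in enumerate(ids)}
    for gcl in genus_clusters:
        sub_idx = [index[g] for g in gcl]
        sub = pct[np.ix_(sub_idx, sub_idx)]
        species_clusters.extend(
            _threshold_partition(sub, gcl, species_threshold, linkage_method)
        )
    species_clusters.sort(key=lambda c: (-len(c), c[0]))
    return TaxonClustering(
        genome_ids=list(ids),
        species_threshold=species_threshold,
        genus_threshold=genus_threshold,
        species_clusters=species_clusters,
        genus_clusters=genus_clusters,
        linkage=linkage_method,
    )


def plot_heatmap(matrix: SimilarityMatrix, clustering: TaxonClustering, path: str) -> None:
    """Similarity heatmap with genomes ordered by cluster membership."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = [g for cl in clustering.genus_clusters for g in cl]
    idx = [matrix.genome_ids.index(g) for g in order]
    vals = matrix.values[np.ix_(idx, idx)] * 100.0
    fig, ax = plt.subplots(figsize=(0.5 * len(order) + 2,) * 2)
    im = ax.imshow(vals, vmin=0, vmax=100, cmap="viridis")
    ax.set_xticks(range(len(order)), order, rotation=90, fontsize=7)
    ax.set_yticks(range(len(order)), order, fontsize=7)
    fig.colorbar(im, label=f"{matrix.metric} (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
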