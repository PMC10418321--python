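"""Tests for QC filtering, ANI estimation, UPGMA, cluster cuts and NMDS."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr
from sklearn.metrics import adjusted_rand_score

from equomgs.genomics import (
    AniMatrix,
    GenomeRecord,
    build_ani_matrix,
    cut_clusters,
    metadata_association,
    nmds,
    pairwise_ani,
    qc_filter,
    symmetric_ani,
    upgma,
)
from equomgs.synthetic import make_base_genome, mutate_genome


def genome(gid, seq, **kw):
    return GenomeRecord(genome_id=gid, contigs=[seq], **kw)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def test_qc_boundaries_inclusive():
    g = genome("a", "ACGT" * 100, completeness=80.0, contamination=5.0)
    assert qc_filter([g]) == [g]


@pytest.mark.parametrize("completeness,contamination", [(79.9, 0.0), (95.0, 5.1)])
def test_qc_excludes_outside_thresholds(completeness, contamination):
    g = genome("a", "ACGT" * 100, completeness=completeness, contamination=contamination)
    assert qc_filter([g]) == []


def test_isolate_without_qc_passes_with_warning():
    g = genome("iso", "ACGT" * 100, source="isolate")
    with pytest.warns(UserWarning):
        assert qc_filter([g]) == [g]


def test_mag_without_qc_rejected():
    g = genome("mag", "ACGT" * 100)
    with pytest.raises(ValueError):
        qc_filter([g])


# ---------------------------------------------------------------------------
# ANI
# ---------------------------------------------------------------------------

def test_self_ani_is_100_all_fragments_mapped():
    seq = make_base_genome(50_000, 0.64, seed=0)
    est = pairwise_ani(genome("a", seq), genome("a2", seq))
    assert est.ani == pytest.approx(100.0)
    assert est.fragments_mapped == est.fragments_total > 0


def test_ani_tracks_realized_divergence():
    base = make_base_genome(100_000, 0.64, seed=1)
    for d, seed in [(0.01, 2), (0.05, 3)]:
        mut, realized = mutate_genome(base, d, seed=seed)
        ani = symmetric_ani(genome("a", base), genome("b", mut))
        assert abs(ani - 100 * (1 - realized)) <= 0.5


def test_kmer_ani_agrees_with_alignment_oracle():
    base = make_base_genome(30_000, 0.64, seed=4)
    mut, realized = mutate_genome(base, 0.03, seed=5)
    fast = pairwise_ani(genome("a", base), genome("b", mut), mode="kmer")
    oracle = pairwise_ani(genome("a", base), genome("b", mut), mode="alignment")
    assert fast.ani == pytest.approx(oracle.ani, abs=0.5)
    assert oracle.ani == pytest.approx(100 * (1 - realized), abs=0.5)


def test_symmetric_ani_is_mean_of_directions():
    base = make_base_genome(60_000, 0.64, seed=6)
    mut, _ = mutate_genome(base, 0.04, seed=7)
    a, b = genome("a", base), genome("b", mut)
    fwd = pairwise_ani(a, b).ani
    rev = pairwise_ani(b, a).ani
    assert symmetric_ani(a, b) == pytest.approx((fwd + rev) / 2)


def test_unrelated_genomes_hit_the_floor():
    a = genome("a", make_base_genome(60_000, 0.5, seed=8))
    b = genome("b", make_base_genome(60_000, 0.5, seed=9))
    assert symmetric_ani(a, b) == 70.0
    matrix = build_ani_matrix([a, b])
    assert matrix.floored_pairs == [("a", "b")]


def test_matrix_invariant_to_input_order(default_population):
    genomes = default_population.genomes[:6]
    m1 = build_ani_matrix(genomes)
    m2 = build_ani_matrix(genomes[::-1])
    perm = [m2.ids.index(g) for g in m1.ids]
    assert np.allclose(m1.values, m2.values[np.ix_(perm, perm)])


def test_duplicate_ids_rejected():
    g = genome("a", "ACGT" * 2000)
    with pytest.raises(ValueError):
        build_ani_matrix([g, g])


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

def upgma_from_definition(ids, dmat):
    """Brute-force reference: inter-cluster distance recomputed each step as
    the mean over all original member pairs."""
    index = {g: i for i, g in enumerate(ids)}
    clusters = {g: [g] for g in ids}
    merges = []
    while len(clusters) > 1:
        best = None
        labels = sorted(clusters)
        for i, la in enumerate(labels):
            for lb in labels[i + 1:]:
                d = float(
                    np.mean(
                        [dmat[index[x], index[y]] for x in clusters[la] for y in clusters[lb]]
                    )
                )
                if best is None or d < best[0] or (d == best[0] and (la, lb) < (best[1], best[2])):
                    best = (d, la, lb)
        d, la, lb = best
        members = clusters.pop(la) + clusters.pop(lb)
        merges.append((la, lb, d, len(members)))
        clusters[min(la, lb)] = members
    return merges


def ani_from_dist(ids, dmat):
    return AniMatrix(ids=ids, values=100.0 * (1 - dmat))


def test_two_genome_merge_height():
    ids = ["a", "b"]
    d = np.array([[0.0, 0.03], [0.03, 0.0]])
    dend = upgma(ani_from_dist(ids, d))
    assert dend.merges == [("a", "b", pytest.approx(0.03), 2)]


def test_three_genome_hand_example():
    ids = ["A", "B", "C"]
    d = np.array([[0, 0.02, 0.08], [0.02, 0, 0.08], [0.08, 0.08, 0]])
    dend = upgma(ani_from_dist(ids, d))
    (m1, m2) = dend.merges
    assert m1 == ("A", "B", pytest.approx(0.02), 2)
    assert m2[:2] == ("A", "C") and m2[2] == pytest.approx(0.08)


def test_upgma_matches_brute_force_oracle_on_random_matrices():
    rng = np.random.default_rng(12)
    for _ in range(30):
        n = int(rng.integers(4, 13))
        d = rng.uniform(0.01, 0.3, size=(n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        ids = [f"g{i:02d}" for i in range(n)]
        mine = upgma(ani_from_dist(ids, d)).merges
        oracle = upgma_from_definition(ids, d)
        assert len(mine) == len(oracle)
        for a, b in zip(mine, oracle):
            assert a[:2] == b[:2]
            assert a[2] == pytest.approx(b[2], abs=1e-12)
            assert a[3] == b[3]


def test_upgma_heights_match_scipy_average_linkage():
    rng = np.random.default_rng(13)
    for _ in range(10):
        n = 10
        d = rng.uniform(0.01, 0.3, size=(n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        ids = [f"g{i:02d}" for i in range(n)]
        mine = sorted(m[2] for m in upgma(ani_from_dist(ids, d)).merges)
        ref = sorted(linkage(squareform(d), method="average")[:, 2])
        assert np.allclose(mine, ref, atol=1e-10)


def test_merge_heights_non_decreasing(population_ani_matrix):
    heights = [m[2] for m in upgma(population_ani_matrix).merges]
    assert all(h2 >= h1 - 1e-12 for h1, h2 in zip(heights, heights[1:]))


def test_newick_roundtrip_parses():
    from io import StringIO
    from Bio import Phylo

    ids = ["a", "b", "c"]
    d = np.array([[0, 0.02, 0.08], [0.02, 0, 0.08], [0.08, 0.08, 0]])
    tree = Phylo.read(StringIO(upgma(ani_from_dist(ids, d)).to_newick()), "newick")
    assert sorted(t.name for t in tree.get_terminals()) == ids


# ---------------------------------------------------------------------------
# cluster cuts
# ---------------------------------------------------------------------------

def block_matrix(n1, n2, within_ani, between_ani):
    n = n1 + n2
    v = np.full((n, n), between_ani, dtype=float)
    v[:n1, :n1] = within_ani
    v[n1:, n1:] = within_ani
    np.fill_diagonal(v, 100.0)
    ids = [f"x{i:02d}" for i in range(n1)] + [f"y{i:02d}" for i in range(n2)]
    return AniMatrix(ids=ids, values=v)


def test_two_block_matrix_gives_two_clusters():
    m = block_matrix(5, 4, 97.0, 90.0)
    assign = cut_clusters(upgma(m))
    labels = assign.labels
    assert len(set(labels.values())) == 2
    assert len({labels[f"x{i:02d}"] for i in range(5)}) == 1
    assert len({labels[f"y{i:02d}"] for i in range(4)}) == 1
    # larger cluster gets label 0
    assert labels["x00"] == 0


def test_all_high_ani_single_cluster():
    m = block_matrix(3, 3, 97.0, 96.0)
    assert len(set(cut_clusters(upgma(m)).labels.values())) == 1


def test_all_low_ani_all_singletons():
    m = block_matrix(3, 3, 80.0, 80.0)
    assert len(set(cut_clusters(upgma(m)).labels.values())) == 6


def test_merge_exactly_at_cutoff_separates():
    m = block_matrix(2, 2, 97.0, 95.0)  # between-block merge exactly at 0.05
    assert len(set(cut_clusters(upgma(m), ani_cutoff=95.0).labels.values())) == 2


def test_planted_phylogroups_recovered(default_population, population_ani_matrix):
    assign = cut_clusters(upgma(population_ani_matrix))
    ids = list(population_ani_matrix.ids)
    ari = adjusted_rand_score(
        [default_population.truth_phylogroup[g] for g in ids],
        [assign.labels[g] for g in ids],
    )
    assert ari == 1.0


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------

def test_three_points_embed_exactly():
    pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.3, 0.8]])
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1)) / 10.0
    m = AniMatrix(ids=["a", "b", "c"], values=100.0 * (1 - d))
    emb = nmds(m, seed=0)
    assert emb.stress <= 1e-6


def test_nmds_preserves_rank_order_of_distances(default_population, population_ani_matrix):
    emb = nmds(population_ani_matrix, seed=1)
    coords = emb.coordinates
    d_in = population_ani_matrix.distances()
    d_out = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
    iu = np.triu_indices(len(coords), 1)
    rho = spearmanr(d_in[iu], d_out[iu]).statistic
    assert rho >= 0.9
    # between-phylogroup separation survives the embedding
    pg = default_population.truth_phylogroup
    ids = population_ani_matrix.ids
    same = np.array([pg[ids[i]] == pg[ids[j]] for i, j in zip(*iu)])
    assert d_out[iu][~same].min() > d_out[iu][same].max()


def test_nmds_dims_bound():
    m = block_matrix(2, 1, 97.0, 90.0)
    with pytest.raises(ValueError):
        nmds(m, dims=3)


# ---------------------------------------------------------------------------
# metadata association
# ---------------------------------------------------------------------------

def _assignment(labels):
    from equomgs.genomics import Dendrogram, PhylogroupAssignment

    return PhylogroupAssignment(labels=labels, dendrogram=Dendrogram(list(labels), []))


def test_balanced_independent_table_statistic_zero():
    labels = {f"g{i}": i % 2 for i in range(40)}
    meta = {f"g{i}": "Asia" if (i // 2) % 2 else "Europe" for i in range(40)}
    r = metadata_association(_assignment(labels), meta)
    assert r.statistic == pytest.approx(0.0)
    assert r.p_value == pytest.approx(1.0)


def test_perfectly_associated_table():
    labels = {f"g{i}": int(i >= 50) for i in range(100)}
    meta = {f"g{i}": "Asia" if i < 50 else "Europe" for i in range(100)}
    r = metadata_association(_assignment(labels), meta)
    assert r.statistic == pytest.approx(100.0)
    assert r.df == 1


def test_geography_association_significant_in_default_population(
    default_population, population_ani_matrix
):
    assign = cut_clusters(upgma(population_ani_matrix))
    geo = {g.genome_id: g.geography for g in default_population.genomes}
    r = metadata_association(assign, geo)
    assert r.p_value < 0.05
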