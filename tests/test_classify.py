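import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scritscreen import synthetic_data as sd
from scritscreen.classify import (
    DistanceMatrix,
    assign_groups,
    dendrogram_newick,
    distance_matrix,
    hierarchical_cluster,
    mds_embed,
    pearson_distance,
)
from scritscreen.errors import ContractError
from scritscreen.scrit import SCRITVector, component_index


def vec(values, compound="c", replicate="1"):
    values = np.asarray(values, float)
    doses = list(range(1, len(values) // 2 + 1))
    index = component_index(["p"], ("glu_plus", "glu_minus"), doses)
    return SCRITVector(compound, replicate, values, index)


class TestPearsonDistance:
    def test_self_distance_zero(self):
        u = np.array([1.0, 2.0, 5.0, 3.0])
        assert pearson_distance(u, u) == pytest.approx(0.0)

    def test_anticorrelated_distance_two(self):
        u = np.array([1.0, 2.0, 5.0, 3.0])
        assert pearson_distance(u, 4.0 - u) == pytest.approx(2.0)

    def test_zero_correlation_distance_one(self):
        u = np.array([1.0, -1.0, 1.0, -1.0])
        v = np.array([1.0, 1.0, -1.0, -1.0])
        assert pearson_distance(u, v) == pytest.approx(1.0)

    def test_matches_covariance_formula_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            u = rng.standard_normal(int(rng.integers(3, 40)))
            v = rng.standard_normal(len(u))
            num = np.mean(u * v) - u.mean() * v.mean()
            den = np.sqrt(
                (np.mean(u**2) - u.mean() ** 2) * (np.mean(v**2) - v.mean() ** 2)
            )
            assert pearson_distance(u, v) == pytest.approx(1 - num / den, abs=1e-12)

    @given(
        a=st.floats(0.01, 50),
        b=st.floats(-100, 100),
        seed=st.integers(0, 100),
    )
    @settings(max_examples=60, derandomize=True)
    def test_affine_invariance(self, a, b, seed):
        rng = np.random.default_rng(seed)
        u = rng.standard_normal(15)
        v = rng.standard_normal(15)
        assert pearson_distance(a * u + b, v) == pytest.approx(
            pearson_distance(u, v), abs=1e-9
        )

    def test_constant_vector_convention(self):
        with pytest.warns(UserWarning, match="near-constant"):
            d = pearson_distance(np.full(5, 0.3), np.arange(5.0))
        assert d == 1.0


class TestDistanceMatrix:
    def test_identical_vectors_all_zero(self):
        vs = [vec([0.1, 0.4, -0.2, 0.9], compound=c) for c in "abc"]
        D = distance_matrix(vs, metric="pearson")
        assert np.allclose(D.matrix, 0.0)

    def test_euclidean_pythagorean(self):
        a = vec([0.0, 0.0], compound="a")
        b = vec([3.0, 4.0], compound="b")
        D = distance_matrix([a, b], metric="euclidean")
        assert D.matrix[0, 1] == pytest.approx(5.0)

    def test_symmetry_and_zero_diagonal(self):
        rng = np.random.default_rng(1)
        vs = [vec(rng.uniform(-1, 1, 8), compound=f"c{i}") for i in range(6)]
        D = distance_matrix(vs)
        assert np.allclose(D.matrix, D.matrix.T)
        assert np.allclose(np.diag(D.matrix), 0.0)

    def test_mixed_shapes_rejected(self):
        with pytest.raises(ContractError):
            distance_matrix([vec([1.0, 2.0]), vec([1.0, 2.0, 3.0, 4.0], compound="b")])


def brute_force_average_linkage(matrix, ids):
    """Independent agglomeration trace used as the clustering oracle."""
    clusters = {i: [i] for i in range(len(ids))}
    D = {(i, j): matrix[i, j] for i in range(len(ids)) for j in range(len(ids)) if i < j}
    merges = []
    while len(clusters) > 1:
        (i, j), h = min(D.items(), key=lambda kv: kv[1])
        merges.append((sorted((ids[k] for k in clusters[i] + clusters[j])), h))
        new = max(clusters) + 1
        members = clusters.pop(i) + clusters.pop(j)
        dist_to = {}
        for k, mem in clusters.items():
            pairs = [matrix[a, b] for a in members for b in mem]
            dist_to[k] = float(np.mean(pairs))
        clusters[new] = members
        D = {
            (a, b): d
            for (a, b), d in D.items()
            if i not in (a, b) and j not in (a, b)
        }
        for k, d in dist_to.items():
            D[(min(k, new), max(k, new))] = d
    return merges


class TestHierarchicalCluster:
    def test_two_items_merge_at_their_distance(self):
        vs = [vec([0.1, 0.9, -0.5, 0.2]), vec([0.5, -0.3, 0.8, 0.1], compound="b")]
        D = distance_matrix(vs)
        res = hierarchical_cluster(D, n_clusters=1)
        assert res.linkage_matrix.shape == (1, 4)
        assert res.linkage_matrix[0, 2] == pytest.approx(D.matrix[0, 1])

    def test_duplicate_items_merge_first_at_zero(self):
        base = [0.3, -0.2, 0.7, 0.4]
        vs = [
            vec(base, compound="a"),
            vec([0.9, 0.1, -0.4, 0.6], compound="b"),
            vec(base, compound="a2"),
        ]
        res = hierarchical_cluster(distance_matrix(vs), n_clusters=1)
        assert res.linkage_matrix[0, 2] == pytest.approx(0.0)
        assert {int(res.linkage_matrix[0, 0]), int(res.linkage_matrix[0, 1])} == {0, 2}

    def test_matches_manual_average_linkage(self):
        rng = np.random.default_rng(5)
        m = rng.uniform(0.1, 1.0, (4, 4))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        ids = ["a", "b", "c", "d"]
        D = DistanceMatrix(ids=ids, matrix=m, metric="pearson")
        res = hierarchical_cluster(D, n_clusters=1)
        oracle = brute_force_average_linkage(m, ids)
        assert [h for _, h in oracle] == pytest.approx(
            list(res.linkage_matrix[:, 2])
        )

    def test_merge_heights_nondecreasing(self):
        rng = np.random.default_rng(6)
        vs = [vec(rng.uniform(-1, 1, 10), compound=f"c{i}") for i in range(12)]
        res = hierarchical_cluster(distance_matrix(vs))
        h = res.linkage_matrix[:, 2]
        assert np.all(np.diff(h) >= -1e-12)

    def test_flat_cut_produces_requested_clusters(self):
        rng = np.random.default_rng(7)
        centers = [np.zeros(10), np.ones(10) * 5, -np.ones(10) * 5]
        vs = [
            vec(c + rng.normal(0, 0.1, 10), compound=f"c{i}{j}")
            for i, c in enumerate(centers)
            for j in range(3)
        ]
        res = hierarchical_cluster(distance_matrix(vs, metric="euclidean"), n_clusters=3)
        assert res.n_flat_clusters == 3


class TestMDS:
    def test_collinear_points_recovered_in_one_dimension(self):
        m = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 1.0], [2.0, 1.0, 0.0]])
        D = DistanceMatrix(ids=["a", "b", "c"], matrix=m, metric="euclidean")
        coords = mds_embed(D, dims=1)
        got = np.abs(coords.values[:, 0] - coords.values[1, 0])
        assert got == pytest.approx([1.0, 0.0, 1.0], abs=1e-9)

    def test_round_trip_from_planar_points(self):
        rng = np.random.default_rng(8)
        pts = rng.uniform(-3, 3, (7, 2))
        m = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        D = DistanceMatrix(ids=[f"p{i}" for i in range(7)], matrix=m, metric="euclidean")
        coords = mds_embed(D, dims=2).values
        back = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        assert np.allclose(back, m, atol=1e-9)

    def test_duplicated_items_coincide(self):
        m = np.array(
            [[0.0, 0.0, 1.0], [0.0, 0.0, 1.0], [1.0, 1.0, 0.0]]
        )
        D = DistanceMatrix(ids=list("abc"), matrix=m, metric="euclidean")
        coords = mds_embed(D, dims=1).values
        assert coords[0] == pytest.approx(coords[1])

    def test_excess_dims_reduced_with_warning(self):
        m = np.array([[0.0, 2.0], [2.0, 0.0]])
        D = DistanceMatrix(ids=["a", "b"], matrix=m, metric="euclidean")
        with pytest.warns(UserWarning, match="positive eigenvalue"):
            coords = mds_embed(D, dims=3)
        assert coords.shape[1] == 1

    def test_deterministic_sign_convention(self):
        rng = np.random.default_rng(9)
        pts = rng.uniform(-3, 3, (6, 2))
        m = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        D = DistanceMatrix(ids=[f"p{i}" for i in range(6)], matrix=m, metric="euclidean")
        a = mds_embed(D, dims=2).values
        b = mds_embed(D, dims=2).values
        assert np.array_equal(a, b)
        for j in range(a.shape[1]):
            assert a[np.argmax(np.abs(a[:, j])), j] > 0


class TestAssignGroups:
    def test_references_label_their_own_fingerprints(self):
        doses = list(np.geomspace(0.005, 100, 10))
        params = ["tmrm_peripheral_integral", "hoechst_mean", "viability"]
        refs = sd.archetype_references(params, doses)
        rng = np.random.default_rng(10)
        items = []
        for arch, ref in refs.items():
            for r in range(2):
                items.append(
                    SCRITVector(
                        compound=f"x{arch}",
                        replicate=str(r),
                        values=ref.values + rng.normal(0, 0.01, len(ref.values)),
                        index=ref.index,
                    )
                )
        D = distance_matrix(items)
        cluster = hierarchical_cluster(D, n_clusters=5)
        labels = assign_groups(cluster, items, refs)
        for item, group in labels.items():
            assert group == item.split("/")[0][1:]

    def test_flat_fingerprint_goes_to_group_iv(self):
        doses = [1.0, 10.0]
        params = ["tmrm_peripheral_integral", "viability"]
        refs = sd.archetype_references(params, doses)
        flat = refs["IV"]
        items = [
            SCRITVector("flat", str(r), flat.values.copy(), flat.index) for r in range(2)
        ] + [
            SCRITVector("toxic", str(r), refs["II"].values.copy(), refs["II"].index)
            for r in range(2)
        ]
        cluster = hierarchical_cluster(distance_matrix(items), n_clusters=2)
        labels = assign_groups(cluster, items, refs)
        assert labels["flat/0"] == "IV"
        assert labels["toxic/0"] == "II"

    def test_missing_references_rejected(self):
        items = [vec([0.1, 0.5, 0.2, 0.8]), vec([0.3, 0.1, 0.9, 0.2], compound="b")]
        cluster = hierarchical_cluster(distance_matrix(items), n_clusters=2)
        with pytest.raises(ContractError):
            assign_groups(cluster, items, {})


class TestNewick:
    def test_dendrogram_parses_and_keeps_leaves(self):
        from Bio import Phylo

        rng = np.random.default_rng(11)
        vs = [vec(rng.uniform(-1, 1, 8), compound=f"c{i}") for i in range(5)]
        res = hierarchical_cluster(distance_matrix(vs))
        tree = Phylo.read(io.StringIO(dendrogram_newick(res)), "newick")
        leaves = {t.name for t in tree.get_terminals()}
        assert leaves == {f"c{i}/1" for i in range(5)}
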