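import numpy as np
import pytest

import biparclust as bp
from biparclust.hierclust import Dendrogram, average_linkage, hierarchical_cluster
from biparclust.io_metadata import ExpressionMatrix


def _matrix(values, prefix="g"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return ExpressionMatrix(
        values,
        [f"{prefix}{i}" for i in range(values.shape[0])],
        [f"s{j}" for j in range(values.shape[1])],
        nonnegative=False,
    )


def naive_upgma_cophenetic(dist):
    """Brute-force UPGMA: track clusters as member lists, size-weighted averages."""
    n = dist.shape[0]
    coph = np.zeros((n, n))
    active = list(range(n))
    d = {(i, j): dist[i, j] for i in range(n) for j in range(n) if i < j}

    def get(i, j):
        return d[(min(i, j), max(i, j))]

    next_id = n
    members = {i: [i] for i in range(n)}
    while len(active) > 1:
        pairs = [(get(a, b), a, b) for ai, a in enumerate(active) for b in active[ai + 1 :]]
        dist_ab, a, b = min(pairs)
        for x in members[a]:
            for y in members[b]:
                coph[x, y] = coph[y, x] = dist_ab
        members[next_id] = members[a] + members[b]
        for c in active:
            if c in (a, b):
                continue
            d[(min(c, next_id), max(c, next_id))] = (
                len(members[a]) * get(a, c) + len(members[b]) * get(b, c)
            ) / (len(members[a]) + len(members[b]))
        active = [c for c in active if c not in (a, b)] + [next_id]
        next_id += 1
    return coph


class TestZscaleRows:
    def test_two_point_row(self):
        out = bp.zscale_rows(_matrix([[1.0, 3.0]]))
        np.testing.assert_allclose(out.values[0], [-0.70710678, 0.70710678], atol=1e-6)

    def test_constant_row_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            out = bp.zscale_rows(_matrix([[2.0, 2.0], [1.0, 3.0]]))
        assert out.gene_ids == ["g1"]

    def test_normalization_contract(self):
        rng = np.random.default_rng(0)
        out = bp.zscale_rows(_matrix(rng.random((30, 8))))
        np.testing.assert_allclose(out.values.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.values.std(axis=1, ddof=1), 1.0, atol=1e-12)


class TestPearsonDistance:
    def test_perfect_correlation_extremes(self):
        mat = _matrix(np.array([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0], [3.0, 2.0, 1.0]]))
        dist = bp.pearson_distance(mat, axis="genes")
        assert dist[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert dist[0, 2] == pytest.approx(2.0, abs=1e-12)

    def test_covariance_formula_oracle(self):
        rng = np.random.default_rng(1)
        values = rng.random((6, 9))
        dist = bp.pearson_distance(_matrix(values), axis="genes")
        for i in range(6):
            for j in range(6):
                u, v = values[i], values[j]
                r = np.sum((u - u.mean()) * (v - v.mean())) / (
                    np.sqrt(np.sum((u - u.mean()) ** 2) * np.sum((v - v.mean()) ** 2))
                )
                assert dist[i, j] == pytest.approx(1 - r, abs=1e-9)

    def test_symmetry_zero_diagonal(self):
        rng = np.random.default_rng(2)
        dist = bp.pearson_distance(_matrix(rng.random((5, 7))), axis="genes")
        np.testing.assert_allclose(dist, dist.T)
        np.testing.assert_allclose(np.diag(dist), 0.0)

    def test_zero_variance_vector_named(self):
        mat = _matrix([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
        with pytest.raises(ValueError, match="g0"):
            bp.pearson_distance(mat, axis="genes")


class TestAverageLinkage:
    def test_two_points(self):
        dendro = average_linkage(np.array([[0.0, 3.0], [3.0, 0.0]]), ["a", "b"])
        assert dendro.n_leaves == 2
        assert dendro.heights[0] == pytest.approx(3.0)

    def test_hand_traced_four_points(self):
        # d(a,b)=1 merge first; d(ab,c) = (2+3)/2 = 2.5; then d(abc,d) = (4+5+6)/3 = 5
        dist = np.array(
            [
                [0.0, 1.0, 2.0, 4.0],
                [1.0, 0.0, 3.0, 5.0],
                [2.0, 3.0, 0.0, 6.0],
                [4.0, 5.0, 6.0, 0.0],
            ]
        )
        dendro = average_linkage(dist, ["a", "b", "c", "d"])
        np.testing.assert_allclose(dendro.heights, [1.0, 2.5, 5.0])

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_cophenetic_matches_naive_oracle(self, n):
        rng = np.random.default_rng(n)
        pts = rng.random((n, 3))
        dist = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        dendro = average_linkage(dist, [f"p{i}" for i in range(n)])
        np.testing.assert_allclose(
            dendro.cophenetic(), naive_upgma_cophenetic(dist), atol=1e-9
        )

    def test_merge_count_and_monotone_heights(self):
        rng = np.random.default_rng(3)
        pts = rng.random((7, 2))
        dist = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        dendro = average_linkage(dist, [f"p{i}" for i in range(7)])
        assert dendro.linkage_matrix.shape[0] == 6
        heights = dendro.heights
        assert all(a <= b + 1e-12 for a, b in zip(heights, heights[1:]))
        assert sorted(dendro.leaf_order()) == [f"p{i}" for i in range(7)]

    def test_invalid_distance_matrices(self):
        with pytest.raises(ValueError, match="symmetric"):
            average_linkage(np.array([[0.0, 1.0], [2.0, 0.0]]), ["a", "b"])
        with pytest.raises(ValueError, match="diagonal"):
            average_linkage(np.array([[1.0, 1.0], [1.0, 0.0]]), ["a", "b"])


class TestPipelineComposition:
    def test_affine_rescaling_invariance(self):
        """Per-gene affine rescaling of input leaves sample distances unchanged."""
        rng = np.random.default_rng(4)
        values = rng.random((12, 6)) + 0.5
        scale = rng.random(12)[:, None] * 3 + 0.5
        shift = rng.random(12)[:, None] * 2
        base = bp.pearson_distance(bp.zscale_rows(_matrix(values)))
        rescaled = bp.pearson_distance(bp.zscale_rows(_matrix(values * scale + shift)))
        np.testing.assert_allclose(base, rescaled, atol=1e-9)

    def test_newick_and_json_serialization(self, tmp_path):
        rng = np.random.default_rng(5)
        dendro = hierarchical_cluster(_matrix(rng.random((20, 6)) + 0.5))
        newick = dendro.to_newick()
        assert newick.endswith(";") and newick.count("s0") == 1
        from io import StringIO

        from Bio import Phylo

        tree = Phylo.read(StringIO(newick), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == sorted(
            f"s{j}" for j in range(6)
        )
        dendro.to_json(tmp_path / "d.json")
        assert (tmp_path / "d.json").exists()
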