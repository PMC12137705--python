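"""Network measures against independent brute-force oracles.

Each communication measure is checked against a structurally different
computation: communicability against its truncated power series, shortest
paths against exhaustive simple-path enumeration, search information against
explicit step-by-step transition-probability products along independently
found shortest paths, and cosine similarity against a per-pair dot-product
loop.
"""

import warnings
from itertools import permutations

import numpy as np
import pytest

from couplemap import (
    AnalysisConfig,
    StructuralConnectome,
    all_predictors,
    communicability_matrix,
    cosine_similarity_matrix,
    path_length_matrix,
    search_information_matrix,
    weight_to_length,
)
from couplemap.measures import search_information_raw

from conftest import random_sc


# ---------------------------------------------------------------------------
# oracles

def oracle_cosine(w: np.ndarray, exclude_direct: bool = True) -> np.ndarray:
    n = w.shape[0]
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            keep = [k for k in range(n) if not (exclude_direct and k in (i, j))]
            ci, cj = w[keep, i], w[keep, j]
            ni, nj = np.linalg.norm(ci), np.linalg.norm(cj)
            out[i, j] = ci @ cj / (ni * nj) if ni > 0 and nj > 0 else 0.0
    return out


def oracle_shortest_paths(lengths: np.ndarray) -> tuple[np.ndarray, dict]:
    """Exhaustive enumeration of all simple paths; feasible for n <= 7."""
    n = lengths.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    best_path: dict[tuple[int, int], tuple[int, ...]] = {}
    nodes = range(n)
    for i in nodes:
        for j in nodes:
            if i == j:
                continue
            for k in range(0, n - 1):
                for mid in permutations([v for v in nodes if v not in (i, j)], k):
                    path = (i, *mid, j)
                    length = sum(
                        lengths[a, b] for a, b in zip(path[:-1], path[1:])
                    )
                    if length < dist[i, j]:
                        dist[i, j] = length
                        best_path[(i, j)] = path
    return dist, best_path


def oracle_communicability(w: np.ndarray, k_terms: int = 60) -> np.ndarray:
    strength = w.sum(axis=0)
    d = np.where(strength > 0, strength, 1.0) ** -0.5
    d[strength == 0] = 0.0
    m = d[:, None] * w * d[None, :]
    out = np.eye(w.shape[0])
    term = np.eye(w.shape[0])
    for k in range(1, k_terms + 1):
        term = term @ m / k
        out = out + term
    return out


def oracle_search_information(w: np.ndarray) -> np.ndarray:
    """Raw directed SI via enumerated shortest paths and explicit probability
    products; requires unique shortest paths."""
    lengths = weight_to_length(w)
    _, paths = oracle_shortest_paths(lengths)
    strength = w.sum(axis=0)
    n = w.shape[0]
    si = np.full((n, n), np.inf)
    np.fill_diagonal(si, 0.0)
    for (i, j), path in paths.items():
        prob = 1.0
        for a, b in zip(path[:-1], path[1:]):
            prob *= w[a, b] / strength[a]
        si[i, j] = -np.log2(prob)
    return si


# ---------------------------------------------------------------------------
# cosine similarity

class TestCosineSimilarity:
    def test_identical_profiles_give_one(self):
        # regions 0 and 1 connect identically to regions 2 and 3
        w = np.zeros((4, 4))
        w[0, 2] = w[0, 3] = w[1, 2] = w[1, 3] = 1.0
        w += w.T
        sc = StructuralConnectome("s", w)
        assert cosine_similarity_matrix(sc).values[0, 1] == pytest.approx(1.0)

    def test_orthogonal_profiles_give_zero(self):
        # region 0 connects only to 2, region 1 only to 3: no shared neighbors
        w = np.zeros((4, 4))
        w[0, 2] = w[1, 3] = w[2, 3] = 1.0
        w += w.T
        sc = StructuralConnectome("s", w)
        assert cosine_similarity_matrix(sc).values[0, 1] == pytest.approx(0.0)

    @pytest.mark.parametrize("exclude_direct", [True, False])
    def test_matches_per_pair_oracle(self, rng, exclude_direct):
        for _ in range(10):
            sc = random_sc(7, rng)
            got = cosine_similarity_matrix(sc, exclude_direct).values
            np.testing.assert_allclose(
                got, oracle_cosine(sc.weights, exclude_direct), atol=1e-12
            )

    def test_zero_strength_region_warned_and_zeroed(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 2] = w[0, 2] = 1.0
        w += w.T  # region 3 isolated
        sc = StructuralConnectome("s", w)
        with pytest.warns(UserWarning, match="zero-strength"):
            cos = cosine_similarity_matrix(sc).values
        assert np.all(cos[3, :3] == 0) and np.all(cos[:3, 3] == 0)


# ---------------------------------------------------------------------------
# weight-to-length and shortest paths

@pytest.mark.parametrize(
    "w,rule,expected",
    [
        (2.0, "inverse", 0.5),
        (0.0, "inverse", np.inf),
        (4.0, "neglog", 0.0),  # max-weight edge
        (2.0, "neglog", np.log(2.0)),
        (0.0, "neglog", np.inf),
    ],
)
def test_weight_to_length_closed_forms(w, rule, expected):
    m = np.array([[0.0, w, 4.0], [w, 0.0, 0.1], [4.0, 0.1, 0.0]])
    lengths = weight_to_length(m, rule)
    assert lengths[0, 1] == pytest.approx(expected)


class TestPathLength:
    def test_chain_distance_sums(self):
        w = np.array([[0, 1.0, 0], [1.0, 0, 1.0], [0, 1.0, 0]])
        pl = path_length_matrix(StructuralConnectome("s", w)).values
        assert pl[0, 2] == pytest.approx(-2.0)  # negated sum of 1/w lengths

    def test_direct_edge_wins_when_shorter(self):
        w = np.array([[0, 10.0, 1.0], [10.0, 0, 1.0], [1.0, 1.0, 0]])
        pl = path_length_matrix(StructuralConnectome("s", w)).values
        assert pl[0, 1] == pytest.approx(-0.1)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(10):
            sc = random_sc(7, rng, density=0.4)
            dist, _ = oracle_shortest_paths(weight_to_length(sc.weights))
            got = path_length_matrix(sc).values
            np.testing.assert_allclose(got, -dist, atol=1e-10)

    def test_unreachable_pairs_get_sentinel(self):
        w = np.zeros((5, 5))
        w[0, 1] = w[1, 2] = 1.0
        w[3, 4] = 1.0
        w += w.T
        with pytest.warns(UserWarning, match="unreachable"):
            pl = path_length_matrix(StructuralConnectome("s", w)).values
        finite_max = 2.0  # longest finite distance: 0 -> 2 via two unit lengths
        assert pl[0, 3] == pytest.approx(-1.5 * finite_max)

    def test_reciprocal_inversion_option(self):
        w = np.array([[0, 2.0, 0], [2.0, 0, 2.0], [0, 2.0, 0]])
        pl = path_length_matrix(StructuralConnectome("s", w),
                                inversion="reciprocal").values
        assert pl[0, 1] == pytest.approx(2.0)  # 1 / (1/2)
        assert pl[0, 2] == pytest.approx(1.0)


class TestCommunicability:
    def test_empty_graph_gives_identity(self):
        sc = StructuralConnectome("s", np.zeros((4, 4)))
        np.testing.assert_allclose(communicability_matrix(sc).values, np.eye(4),
                                   atol=1e-12)

    def test_two_node_closed_form(self):
        # normalization maps any single edge weight to 1: offdiag sinh(1)
        w = np.array([[0, 0, 7.3], [0, 0, 0], [7.3, 0, 0.0]])
        g = communicability_matrix(StructuralConnectome("s", w)).values
        assert g[0, 2] == pytest.approx(np.sinh(1.0), abs=1e-12)
        assert g[0, 0] == pytest.approx(np.cosh(1.0), abs=1e-12)

    def test_matches_series_oracle(self, rng):
        for _ in range(10):
            sc = random_sc(int(rng.integers(5, 31)), rng)
            got = communicability_matrix(sc).values
            np.testing.assert_allclose(got, oracle_communicability(sc.weights),
                                       atol=1e-8)


class TestSearchInformation:
    def test_two_node_graph_is_zero(self):
        w = np.array([[0, 1.0, 1.0], [1.0, 0, 0], [1.0, 0, 0.0]])
        raw = search_information_raw(StructuralConnectome("s", w))
        # forced single step from a degree-1 leaf: probability 1, SI 0
        assert raw[1, 0] == pytest.approx(0.0)

    def test_star_center_to_leaf(self):
        k = 5
        w = np.zeros((k + 1, k + 1))
        w[0, 1:] = 1.0
        w += w.T
        raw = search_information_raw(StructuralConnectome("s", w))
        assert raw[0, 1] == pytest.approx(np.log2(k))
        assert raw[1, 0] == pytest.approx(0.0)  # leaf has a single exit

    def test_matches_step_by_step_oracle(self, rng):
        for _ in range(10):
            sc = random_sc(8, rng, density=0.5)
            raw = search_information_raw(sc)
            np.testing.assert_allclose(raw, oracle_search_information(sc.weights),
                                       atol=1e-10)

    def test_adjustment_symmetrizes_and_negates(self, rng):
        sc = random_sc(8, rng)
        raw = search_information_raw(sc)
        adj = search_information_matrix(sc).values
        np.testing.assert_allclose(adj, -(raw + raw.T) / 2.0, atol=1e-12)


# ---------------------------------------------------------------------------
# the full predictor set

class TestAllPredictors:
    def test_order_and_cardinality(self, small_sc):
        preds = all_predictors(small_sc)
        assert [p.measure for p in preds] == ["CoS", "PL", "G", "SI"]

    def test_all_outputs_symmetric(self, small_sc):
        for p in all_predictors(small_sc):
            np.testing.assert_allclose(p.values, p.values.T, atol=1e-10)

    def test_permutation_equivariance(self, rng):
        sc = random_sc(9, rng)
        perm = rng.permutation(9)
        sc_p = StructuralConnectome("s", sc.weights[np.ix_(perm, perm)])
        for a, b in zip(all_predictors(sc), all_predictors(sc_p)):
            np.testing.assert_allclose(
                a.values[np.ix_(perm, perm)], b.values, atol=1e-9
            )

    def test_adjustment_reverses_cost_ordering(self, rng):
        # negation is monotone decreasing: the regions ranked closest under
        # the raw cost are ranked highest under the adjusted matrix, so any
        # coupling correlation flips sign versus the raw values
        sc = random_sc(8, rng)
        pl = path_length_matrix(sc).values
        raw = -pl  # raw shortest-path cost
        off = ~np.eye(8, dtype=bool)
        assert np.array_equal(
            np.argsort(raw[0][off[0]]), np.argsort(-pl[0][off[0]])
        )
        v = rng.standard_normal(7)
        r_adj = np.corrcoef(v, pl[0][off[0]])[0, 1]
        r_raw = np.corrcoef(v, raw[0][off[0]])[0, 1]
        assert r_adj == pytest.approx(-r_raw)

    def test_config_alternatives_propagate(self, small_sc):
        cfg = AnalysisConfig(weight_to_length="neglog", inversion="reciprocal")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            preds = all_predictors(small_sc, cfg)
        pl = next(p for p in preds if p.measure == "PL")
        assert pl.meta == {"rule": "neglog", "inversion": "reciprocal"}
        assert np.all(pl.values >= 0)
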