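import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from braidkit import (
    Connectome,
    build_laplacian,
    build_weight_matrix,
    check_ficks_condition,
    check_mass_conservation,
    laplacian_condition_scan,
    threshold_disparity,
    threshold_naive,
)
from braidkit.connectome import (
    DegenerateDegreeError,
    InvalidInputError,
    apply_backbone_filter,
    register_backbone_filter,
)
from braidkit.fixtures import FixtureSpec, random_connectome


def admissible_grid(points_per_axis=5):
    axis = np.linspace(0.0, 1.0, points_per_axis)
    return [(a, b) for a in axis for b in axis if a + b <= 1 + 1e-12]


class TestWeightSchemes:
    @pytest.mark.parametrize(
        "scheme,expected",
        [("LW", 6.0), ("BW", 3.0), ("DW", 1.5)],
    )
    def test_single_edge_formulas(self, scheme, expected):
        conn = Connectome(["a", "b"], {(0, 1): (6.0, 2.0)})
        w = build_weight_matrix(conn, scheme)
        assert w.values[0, 1] == pytest.approx(expected)
        assert w.values[1, 0] == pytest.approx(expected)

    def test_diffusive_weight_matches_worked_example_entry(self):
        # n = 5e-4 fibers over length 40 under the diffusive scheme
        conn = Connectome(["a", "b"], {(0, 1): (5e-4, 40.0)})
        w = build_weight_matrix(conn, "DW")
        assert w.values[0, 1] == pytest.approx(3.125e-7, rel=1e-12)

    def test_zero_diagonal_and_symmetry(self, four_node):
        w = four_node[1]
        assert np.all(np.diag(w.values) == 0)
        assert np.max(np.abs(w.values - w.values.T)) <= 1e-12

    def test_unknown_scheme_rejected(self, four_node):
        with pytest.raises(InvalidInputError):
            build_weight_matrix(four_node[0], "XX")


class TestLaplacianFamily:
    def test_standard_laplacian_two_node(self):
        conn = Connectome(["a", "b"], {(0, 1): (1.0, 1.0)})
        lap = build_laplacian(build_weight_matrix(conn, "LW"))
        assert np.allclose(lap.values, [[1, -1], [-1, 1]])

    def test_standard_rows_sum_to_zero(self, four_node):
        lap = build_laplacian(four_node[1])
        assert np.max(np.abs(lap.values.sum(axis=1))) < 1e-18

    def test_symmetric_normalized_member_on_star(self):
        # K_{1,3}, unit weights: hub strength 3, leaves 1.  At (1/2, 1/2) the
        # family reduces to I - D^(-1/2) W D^(-1/2); hand-built comparison.
        edges = {(0, k): (1.0, 1.0) for k in (1, 2, 3)}
        conn = Connectome(list("hxyz"), edges)
        lap = build_laplacian(build_weight_matrix(conn, "LW"), 0.5, 0.5)
        s = -1.0 / np.sqrt(3.0)
        expected = np.array(
            [[1, s, s, s], [s, 1, 0, 0], [s, 0, 1, 0], [s, 0, 0, 1]]
        )
        assert np.allclose(lap.values, expected, atol=1e-14)

    def test_inadmissible_params_rejected(self, p3_weights):
        for a, b in [(-0.1, 0.0), (0.7, 0.7), (0.0, 1.2)]:
            with pytest.raises(InvalidInputError):
                build_laplacian(p3_weights, a, b)

    def test_isolated_node_degenerate_for_normalized_member(self):
        conn = Connectome(["a", "b", "c"], {(0, 1): (1.0, 1.0)})
        w = build_weight_matrix(conn, "LW")
        build_laplacian(w, 0.0, 0.0)  # standard form tolerates isolation
        with pytest.raises(DegenerateDegreeError):
            build_laplacian(w, 0.5, 0.5)


class TestTransportAxioms:
    def test_standard_form_passes_both(self, four_node_laplacian):
        assert check_mass_conservation(four_node_laplacian).ok
        assert check_ficks_condition(four_node_laplacian).ok

    def test_right_normalized_member_on_path(self, p3_weights):
        # (1, 0): L = I - D^(-1) W = [[1,-1,0],[-1/2,1,-1/2],[0,-1,1]] has
        # zero row sums but column sums (1/2, -1, 1/2); max|L| = 1, so the
        # scaled mass-conservation violation is exactly 1.
        lap = build_laplacian(p3_weights, 1.0, 0.0)
        assert check_ficks_condition(lap).ok
        mass = check_mass_conservation(lap)
        assert not mass.ok
        assert mass.max_violation == pytest.approx(1.0)

    def test_left_normalized_member_breaks_ficks_on_path(self, p3_weights):
        lap = build_laplacian(p3_weights, 0.0, 1.0)
        assert not check_ficks_condition(lap).ok

    def test_symmetric_member_fails_both_on_path(self, p3_weights):
        lap = build_laplacian(p3_weights, 0.5, 0.5)
        assert not check_mass_conservation(lap).ok
        assert not check_ficks_condition(lap).ok

    @pytest.mark.parametrize("seed", range(100))
    def test_standard_form_passes_on_random_connectomes(self, seed):
        conn = random_connectome(FixtureSpec(kind="random_geometric", size=12, seed=seed))
        lap = build_laplacian(build_weight_matrix(conn, "DW"))
        assert check_mass_conservation(lap).ok
        assert check_ficks_condition(lap).ok


class TestConditionScan:
    def test_path_graph_scan_returns_only_standard(self, p3_weights):
        passing = laplacian_condition_scan(p3_weights, admissible_grid())
        assert passing == [(0.0, 0.0)]

    def test_regular_ring_scan_passes_everywhere(self):
        conn = random_connectome(FixtureSpec(kind="regular_ring", size=20, degree=4))
        w = build_weight_matrix(conn, "LW")
        grid = admissible_grid()
        assert laplacian_condition_scan(w, grid) == grid

    def test_empty_grid(self, p3_weights):
        assert laplacian_condition_scan(p3_weights, []) == []


class TestThresholding:
    def test_naive_cutoff_counts(self):
        conn = Connectome(
            list("abcd"),
            {(0, 1): (1.0, 10.0), (1, 2): (2.0, 10.0), (2, 3): (3.0, 10.0)},
        )
        with pytest.warns(UserWarning, match="2 components"):
            kept = threshold_naive(conn, 2.0)
        assert kept.n_edges == 2
        assert all(n >= 2.0 for n, _ in kept.edges.values())

    def test_naive_zero_cutoff_is_identity(self, four_node):
        conn = four_node[0]
        assert threshold_naive(conn, 0.0).edges == conn.edges

    def test_naive_removes_all_with_warning(self, four_node):
        conn = four_node[0]
        with pytest.warns(UserWarning, match="4 components"):
            bare = threshold_naive(conn, 1.0)
        assert bare.n_edges == 0
        assert bare.n_nodes == 4

    def test_disparity_keeps_dominant_star_edge(self, star4):
        # hub p-value of the dominant edge: (1 - 100/103)^3 ~ 2.5e-5 < 0.05
        kept = threshold_disparity(star4, alpha=0.05)
        assert (0, 1) in kept.edges

    def test_disparity_degree_one_rule_keeps_uniform_star(self):
        edges = {(0, k): (1.0, 20.0) for k in range(1, 5)}
        conn = Connectome([f"n{k}" for k in range(5)], edges)
        kept = threshold_disparity(conn, alpha=0.05)
        assert kept.edges == conn.edges

    def test_disparity_near_one_alpha_is_identity(self, star4):
        assert threshold_disparity(star4, alpha=1 - 1e-12).edges == star4.edges

    def test_disparity_alpha_domain(self, star4):
        for alpha in (0.0, 1.0, -0.5, 2.0):
            with pytest.raises(InvalidInputError):
                threshold_disparity(star4, alpha=alpha)

    @pytest.mark.parametrize("seed", range(10))
    def test_filters_never_add_or_mutate_edges(self, seed):
        conn = random_connectome(FixtureSpec(kind="random_geometric", size=15, seed=seed))
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for result in (
                threshold_naive(conn, 10.0),
                threshold_disparity(conn, alpha=0.3),
            ):
                for key, nl in result.edges.items():
                    assert conn.edges[key] == nl

    def test_backbone_registry_hook(self, four_node):
        register_backbone_filter("keep-all", lambda c, **kw: c)
        assert apply_backbone_filter("keep-all", four_node[0]).edges == four_node[0].edges
        with pytest.raises(InvalidInputError):
            apply_backbone_filter("no-such-filter", four_node[0])


class TestConnectomeIO:
    def test_csv_round_trip(self, four_node, tmp_path):
        conn = four_node[0]
        conn.write_csv(tmp_path / "e.csv", tmp_path / "n.csv")
        back = Connectome.read_csv(tmp_path / "e.csv", tmp_path / "n.csv")
        assert back.node_labels == conn.node_labels
        assert back.edges == conn.edges

    def test_graphml_round_trip(self, tmp_path):
        conn = random_connectome(FixtureSpec(kind="random_geometric", size=10, seed=3))
        conn.write_graphml(tmp_path / "g.graphml")
        back = Connectome.read_graphml(tmp_path / "g.graphml")
        assert back.edges.keys() == conn.edges.keys()
        for key in conn.edges:
            assert back.edges[key] == pytest.approx(conn.edges[key])

    def test_self_loops_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="self-loop"):
            conn = Connectome.from_edge_records(["a", "b"], [(0, 0, 1.0, 1.0), (0, 1, 2.0, 3.0)])
        assert conn.edges == {(0, 1): (2.0, 3.0)}

    def test_asymmetric_records_averaged(self):
        conn = Connectome.from_edge_records(
            ["a", "b"], [(0, 1, 2.0, 10.0), (1, 0, 4.0, 30.0)]
        )
        assert conn.edges[(0, 1)] == (3.0, 20.0)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    n=st.integers(3, 8),
    seed=st.integers(0, 10_000),
    a=st.sampled_from([0.0, 0.25, 0.5]),
    b=st.sampled_from([0.0, 0.25, 0.5]),
)
def test_laplacian_symmetry_of_symmetric_members(n, seed, a, b):
    """L_{a,a} is symmetric for symmetric W; general members stay finite."""
    rng = np.random.default_rng(seed)
    w = rng.uniform(0.1, 2.0, size=(n, n))
    w = np.triu(w, 1)
    w = w + w.T
    from braidkit.connectome import WeightMatrix

    lap = build_laplacian(WeightMatrix(w, "LW"), a, b)
    assert np.all(np.isfinite(lap.values))
    if a == b:
        assert np.max(np.abs(lap.values - lap.values.T)) <= 1e-12
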