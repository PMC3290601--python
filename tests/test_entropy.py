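"""Information functionals, coefficient schemes, and graph entropies."""

import math
import random

import numpy as np
import pytest

from topodisc import (
    Graph,
    entropy_distance,
    entropy_from_functional,
    functional_fP,
    functional_fV,
    functional_frho,
    scheme_coefficients,
    vertex_orbits,
)
from topodisc.entropy import ENTROPY_INDICES, functional_frho_linear
from topodisc.graph import complete_graph, cycle_graph, path_graph, star_graph

from test_graph_core import random_connected_graph

VERTEX_TRANSITIVE = [cycle_graph(5), complete_graph(4), cycle_graph(6)]


class TestSchemes:
    def test_presets_for_diameter_2(self):
        assert scheme_coefficients("lin", 2).coefficients == (2.0, 1.0)
        assert scheme_coefficients("quad", 2).coefficients == (4.0, 1.0)
        exp = scheme_coefficients("exp", 2).coefficients
        assert exp == (math.e, 1.0)

    def test_presets_strictly_decreasing(self):
        for name in ("lin", "quad", "exp"):
            c = scheme_coefficients(name, 5).coefficients
            assert all(a > b for a, b in zip(c, c[1:]))

    def test_custom_all_equal_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            scheme_coefficients("custom", 2, [1.0, 1.0])

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            scheme_coefficients("custom", 2, [1.0, 0.0])

    def test_diameter_one_single_coefficient_allowed(self):
        # complete graphs: length-1 vector, entropy forced to log2 n anyway
        assert len(scheme_coefficients("lin", 1).coefficients) == 1

    def test_unknown_scheme(self):
        with pytest.raises(ValueError, match="unknown scheme"):
            scheme_coefficients("cubic", 3)


class TestSphereFunctional:
    def test_star_hand_values(self, star4):
        fv = functional_fV(star4, scheme_coefficients("custom", 2, [2.0, 1.0]))
        assert fv.values.tolist() == [6.0, 4.0, 4.0, 4.0]

    def test_p3_hand_values(self, p3):
        fv = functional_fV(p3, scheme_coefficients("custom", 2, [2.0, 1.0]))
        assert fv.values[0] == 3.0 and fv.values[1] == 4.0 and fv.values[2] == 3.0

    @pytest.mark.parametrize("g", VERTEX_TRANSITIVE)
    def test_uniform_on_vertex_transitive(self, g):
        fv = functional_fV(g, "lin")
        assert np.allclose(fv.values, fv.values[0])


class TestPathFunctional:
    @pytest.mark.parametrize("g", VERTEX_TRANSITIVE)
    def test_entropy_maximal_on_vertex_transitive(self, g):
        h = entropy_from_functional(functional_fP(g, "lin"))
        assert h == pytest.approx(math.log2(g.n), abs=1e-12)

    @pytest.mark.parametrize("scheme", ["lin", "quad", "exp"])
    def test_p3_end_differs_from_mid(self, p3, scheme):
        fp = functional_fP(p3, scheme)
        assert fp.values[0] != fp.values[1]

    def test_coincides_with_sphere_functional_on_trees(self):
        """Trees have a unique geodesic per pair, so path counts equal
        sphere sizes and f_P == f_V vertex by vertex."""
        rng = random.Random(2)
        for _ in range(10):
            import networkx as nx

            t = Graph.from_networkx(nx.random_labeled_tree(rng.randint(4, 12), seed=rng.randint(0, 10**6)))
            for scheme in ("lin", "exp"):
                assert np.allclose(
                    functional_fP(t, scheme).values, functional_fV(t, scheme).values
                )


class TestDegreeAssociationFunctional:
    @pytest.mark.parametrize("g", VERTEX_TRANSITIVE)
    def test_entropy_maximal_on_vertex_transitive(self, g):
        h = entropy_from_functional(functional_frho(g))
        assert h == pytest.approx(math.log2(g.n), abs=1e-12)

    def test_constant_on_automorphism_orbits(self):
        rng = random.Random(13)
        for _ in range(10):
            g = random_connected_graph(rng.randint(4, 8), rng)
            f = functional_frho(g).log_values
            for orbit in vertex_orbits(g):
                assert np.allclose(f[list(orbit)], f[orbit[0]], atol=1e-9)

    def test_strictly_positive_weights(self):
        rng = random.Random(17)
        for _ in range(10):
            g = random_connected_graph(rng.randint(3, 8), rng)
            assert np.all(np.isfinite(functional_frho(g).log_values))
            assert np.all(functional_frho_linear(g).values > 0)

    def test_alpha_validation(self, p4):
        with pytest.raises(ValueError, match="alpha"):
            functional_frho(p4, alpha=0.0)


class TestEntropy:
    def test_uniform_maximal(self, c4):
        h = entropy_from_functional(functional_fV(c4, "lin"))
        assert h == pytest.approx(2.0, abs=1e-12)

    def test_star_hand_value(self, star4):
        fv = functional_fV(star4, scheme_coefficients("custom", 2, [2.0, 1.0]))
        assert entropy_from_functional(fv) == pytest.approx(1.974938, abs=1e-6)

    def test_skewed_entropy_tends_to_zero(self):
        from topodisc.entropy import VertexFunctional

        f = np.array([1e9, 1.0, 1.0])
        fv = VertexFunctional("test", "custom", np.log(f), f)
        assert entropy_from_functional(fv) < 1e-6

    def test_probabilities_sum_to_one(self):
        rng = random.Random(19)
        for make in (functional_fV, functional_fP, functional_frho):
            for _ in range(5):
                g = random_connected_graph(rng.randint(3, 8), rng)
                assert make(g).probabilities().sum() == pytest.approx(1.0, abs=1e-12)

    def test_bounds_hold_for_all_registry_indices(self):
        rng = random.Random(23)
        for _ in range(8):
            g = random_connected_graph(rng.randint(3, 8), rng)
            for name, func in ENTROPY_INDICES.items():
                h = func(g)
                assert -1e-12 <= h <= math.log2(g.n) + 1e-12, name

    def test_scheme_scaling_invariance(self):
        """Multiplying all coefficients by a constant leaves the entropy
        unchanged: probabilities are ratios."""
        from topodisc import distance_matrix

        rng = random.Random(29)
        for _ in range(5):
            g = random_connected_graph(rng.randint(4, 8), rng)
            rho = int(distance_matrix(g).max())
            base = [float(rho - j + 1) for j in range(1, rho + 1)]
            if rho == 1:
                continue
            a = scheme_coefficients("custom", rho, base)
            b = scheme_coefficients("custom", rho, [7.5 * c for c in base])
            for make in (functional_fV, functional_fP):
                assert entropy_from_functional(make(g, a)) == pytest.approx(
                    entropy_from_functional(make(g, b)), abs=1e-10
                )

    def test_entropy_distance(self, c4, star4):
        assert entropy_distance(functional_fV(c4, "lin")) == pytest.approx(0.0, abs=1e-12)
        fv = functional_fV(star4, scheme_coefficients("custom", 2, [2.0, 1.0]))
        assert entropy_distance(fv) == pytest.approx(2 - 1.974938, abs=1e-6)
        with pytest.raises(ValueError):
            entropy_distance(fv, lam=-1.0)
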