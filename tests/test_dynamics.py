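import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hyperdyn import (
    Kernel,
    euler_integrate,
    full_kuramoto_f,
    generate_er_hypergraph,
    kernel_value,
    make_family,
    rhs,
    rhs_lifted,
    sample_initial_state,
    verify_decomposition,
)
from helpers import clique_rhs_kuramoto, rhs_bruteforce


class TestKernelValues:
    @pytest.mark.parametrize(
        "name,center,neighbors,expected",
        [
            ("diffusion", 0.0, [1.0], 1.0),
            ("diffusion", 0.5, [1.0, 0.0], 0.0),
            ("kuramoto", 0.0, [np.pi / 2], 1.0),
            ("si", 0.5, [1.0, 1.0], 0.5),
            ("si", 1.0, [0.3, 0.9], 0.0),
            # mcm, lam=-1, p=2: exp(-(0.5 - 0)) * (1 - 0)
            ("mcm", 0.0, [1.0], np.exp(-0.5)),
            ("log_product", 1.0, [np.e], 1.0),
        ],
    )
    def test_hand_computed_values(self, name, center, neighbors, expected):
        assert kernel_value(Kernel(name), center, neighbors) == pytest.approx(expected)

    def test_unknown_kernel_rejected(self):
        with pytest.raises(ValueError, match="unknown kernel"):
            Kernel("sir")

    def test_empty_neighbors_rejected(self):
        with pytest.raises(ValueError):
            Kernel("diffusion").evaluate(0.0, [])

    @given(
        name=st.sampled_from(["kuramoto", "si", "mcm", "diffusion", "log_product"]),
        values=st.lists(st.floats(0.05, 0.95), min_size=2, max_size=4),
        center=st.floats(0.05, 0.95),
    )
    @settings(max_examples=60, deadline=None)
    def test_neighbor_permutation_invariance(self, name, values, center):
        k = Kernel(name)
        base = k.evaluate(center, values)
        assert k.evaluate(center, values[::-1]) == pytest.approx(base, abs=1e-12)


class TestFullKuramoto:
    def test_hand_value_d3(self):
        f = full_kuramoto_f(3)
        assert f(0.0, [0.0, np.pi / 2]) == pytest.approx(1.0)

    def test_d2_matches_pairwise_kernel(self, rng):
        f = full_kuramoto_f(2)
        k = Kernel("kuramoto")
        for _ in range(20):
            a, b = rng.uniform(-np.pi, np.pi, 2)
            assert f(a, [b]) == pytest.approx(k.evaluate(a, [b]), abs=1e-14)

    def test_zero_at_synchrony(self):
        f = full_kuramoto_f(4)
        assert f(0.7, [0.7, 0.7, 0.7]) == pytest.approx(0.0, abs=1e-15)


class TestFamilyAssembly:
    def test_large_edge_update_sums_subsets(self):
        """For d > p the update is the kernel summed over (p-1)-subsets."""
        fam = make_family("diffusion", 2, 4)
        # d=3: f_3(y1, {y2, y3}) = (y2 - y1) + (y3 - y1)
        assert fam.f(3, 0.0, [1.0, 2.0]) == pytest.approx(3.0)

    def test_full_arity_below_cap(self):
        fam = make_family("si", 3, 4)
        assert fam.f(3, 0.0, [0.5, 0.5]) == pytest.approx(0.25)

    def test_permutation_invariance_exhaustive(self, rng):
        from itertools import permutations

        for name in ("kuramoto", "si", "mcm", "diffusion"):
            for p in (2, 3):
                fam = make_family(name, p, 4)
                for d in (2, 3, 4):
                    nb = rng.uniform(0.1, 0.9, d - 1)
                    vals = {round(fam.f(d, 0.4, list(pm)), 12) for pm in permutations(nb)}
                    assert len(vals) == 1


class TestRhs:
    def test_single_diffusion_edge(self):
        from hyperdyn import Hypergraph

        H = Hypergraph(2, {2: [(0, 1)]})
        fam = make_family("diffusion", 2, 2)
        np.testing.assert_allclose(rhs(H, fam, np.array([0.0, 1.0])), [1.0, -1.0])

    def test_full_kuramoto_three_edge(self):
        from hyperdyn import Hypergraph

        H = Hypergraph(3, {3: [(0, 1, 2)]})
        fam = make_family("full_kuramoto", 3, 3)
        x = np.array([0.0, 0.0, np.pi / 2])
        # node 0: sin((0-0)+(pi/2-0))=1; node 1 likewise; node 2: sin(-pi)=0
        np.testing.assert_allclose(rhs(H, fam, x), [1.0, 1.0, 0.0], atol=1e-12)

    def test_state_length_mismatch(self, small_hypergraph):
        fam = make_family("diffusion", 2, 4)
        with pytest.raises(ValueError, match="shape"):
            rhs(small_hypergraph, fam, np.zeros(4))

    @pytest.mark.parametrize("name,p", [("diffusion", 2), ("kuramoto", 2),
                                        ("si", 3), ("mcm", 3), ("full_kuramoto", 4)])
    def test_summation_equals_lifted_form(self, name, p, er_hypergraph, rng):
        """Per-node summation and lift-update-project give identical derivatives."""
        fam = make_family(name, p, 4)
        x = sample_initial_state(name, 20, rng)
        a = rhs(er_hypergraph, fam, x)
        b = rhs_lifted(er_hypergraph, fam, x)
        np.testing.assert_allclose(a, b, atol=1e-12)
        np.testing.assert_allclose(a, rhs_bruteforce(er_hypergraph, fam, x), atol=1e-12)

    def test_pairwise_kuramoto_equals_clique_expansion(self, small_hypergraph, rng):
        """Pairwise Kuramoto on a hypergraph is the clique-expanded graph dynamics."""
        fam = make_family("kuramoto", 2, 4)
        x = rng.uniform(-np.pi, np.pi, 5)
        np.testing.assert_allclose(
            rhs(small_hypergraph, fam, x), clique_rhs_kuramoto(small_hypergraph, x),
            atol=1e-12,
        )


class TestEuler:
    def test_one_step_diffusion(self):
        from hyperdyn import Hypergraph

        H = Hypergraph(2, {2: [(0, 1)]})
        fam = make_family("diffusion", 2, 2)
        traj = euler_integrate(H, fam, np.array([0.0, 1.0]), 0.01, 1)
        np.testing.assert_allclose(traj.states[1], [0.01, 0.99])
        assert traj.states.shape == (2, 2)

    def test_fixed_point_stays(self, er_hypergraph):
        fam = make_family("kuramoto", 2, 4)
        x0 = np.full(20, 0.3)
        traj = euler_integrate(er_hypergraph, fam, x0, 0.01, 10)
        np.testing.assert_allclose(traj.states, np.tile(x0, (11, 1)), atol=1e-14)

    def test_diffusion_conserves_state_sum(self, er_hypergraph, rng):
        for p in (2, 3, 4):
            fam = make_family("diffusion", p, 4)
            x0 = rng.uniform(-1, 1, 20)
            traj = euler_integrate(er_hypergraph, fam, x0, 0.01, 100)
            sums = traj.states.sum(axis=1)
            np.testing.assert_allclose(sums, sums[0], atol=1e-10)

    def test_si_all_ones_fixed_point_and_nonneg_derivatives(self, er_hypergraph, rng):
        fam = make_family("si", 3, 4)
        np.testing.assert_allclose(rhs(er_hypergraph, fam, np.ones(20)), 0.0, atol=1e-14)
        for _ in range(5):
            x = rng.uniform(0, 1, 20)
            assert (rhs(er_hypergraph, fam, x) >= 0).all()

    def test_nonfinite_aborts_with_diagnostic(self):
        from hyperdyn import Hypergraph

        H = Hypergraph(2, {2: [(0, 1)]})
        fam = make_family("si", 2, 2)
        with pytest.raises(FloatingPointError, match="non-finite"):
            # huge dt on an unstable direction blows up quickly
            euler_integrate(H, fam, np.array([-1e300, 1.0]), 1e6, 50)


class TestVerifyDecomposition:
    def test_log_product_is_order_two(self):
        """log(y1...yd) decomposes exactly into pairwise terms for d=3 and d=4."""
        for d in (3, 4):
            f = lambda y1, s: np.log(y1) + np.sum(np.log(s))
            phi = lambda y1, v: np.log(y1) / (d - 1) + np.log(v[0])
            res = verify_decomposition(f, phi, 2, d, n_samples=500, rng_seed=1,
                                       domain=(0.0, 1.0))
            assert res < 1e-10

    def test_pairwise_sine_sum_is_order_two(self):
        for d in (3, 4):
            f = lambda y1, s: np.sum(np.sin(np.asarray(s) - y1))
            phi = Kernel("kuramoto")
            res = verify_decomposition(f, phi, 2, d, n_samples=500, rng_seed=2,
                                       domain=(-np.pi, np.pi))
            assert res < 1e-10

    def test_full_sine_fails_pairwise_expansion(self):
        f3 = full_kuramoto_f(3)
        res = verify_decomposition(f3, Kernel("kuramoto"), 2, 3, n_samples=100,
                                   rng_seed=3, domain=(-np.pi, np.pi))
        assert res > 0.1

    def test_trivial_p_equals_d(self, rng):
        fam = make_family("mcm", 3, 3)
        f = lambda y1, s: fam.f(3, y1, s)
        res = verify_decomposition(f, Kernel("mcm"), 3, 3, n_samples=200, rng_seed=4)
        assert res < 1e-12

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            verify_decomposition(lambda a, b: 0.0, Kernel("diffusion"), 5, 3)


class TestInitialStates:
    def test_ranges(self, rng):
        k = sample_initial_state("kuramoto", 1000, rng)
        assert (k >= -np.pi).all() and (k <= np.pi).all()
        s = sample_initial_state("si", 1000, rng)
        assert (s >= 0).all() and (s <= 1).all()
        d = sample_initial_state("diffusion", 1000, rng)
        assert (d >= -1).all() and (d <= 1).all()

    def test_mcm_skewness_positive(self, rng):
        x = sample_initial_state("mcm", 10_000, rng)
        assert (x >= 0).all() and (x <= 1).all()
        centered = x - x.mean()
        skew = (centered**3).mean() / (centered**2).mean() ** 1.5
        assert skew > 0.2

    def test_unknown_name(self, rng):
        with pytest.raises(ValueError, match="unknown dynamics"):
            sample_initial_state("voter", 10, rng)
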