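import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import epilayers as ep
from epilayers.gf_core import (
    DegenerateLayerError,
    IncompleteTableError,
    InitialSusceptibility,
    NetworkEnsemble,
    eval_tilde_G,
    eval_tilde_G_i,
    eval_tilde_H_i,
    excess_joint_pmf,
    layer_excess_pmf,
    leading_eigen,
    r0,
    r0_layer,
    r_matrix,
    secondary_infection_pgf,
)


def single(dist, T=0.5):
    return NetworkEnsemble([(dist, T)])


def _grad_fd(f, x, h=1e-6):
    x = np.asarray(x, dtype=float)
    out = np.zeros(x.size)
    for j in range(x.size):
        xp, xm = x.copy(), x.copy()
        xp[j] = min(xp[j] + h, 1.0)
        xm[j] = max(xm[j] - h, 0.0)
        out[j] = (f(xp) - f(xm)) / (xp[j] - xm[j])
    return out


class TestExcessPMFs:
    def test_regular3_excess_is_point_mass_at_two(self, regular3):
        pt = excess_joint_pmf(single(regular3))
        marg = pt.marginal(0)
        assert marg[2] == pytest.approx(1.0)

    def test_regular2_excess_is_point_mass_at_one(self, regular2):
        pt = excess_joint_pmf(single(regular2))
        assert pt.marginal(0)[1] == pytest.approx(1.0)

    def test_poisson_excess_reproduces_itself(self):
        d = ep.make_degree_distribution("poisson", mean=3.0)
        pt = excess_joint_pmf(single(d))
        marg = pt.marginal(0)
        # oracle: (k+1)P(k+1)/E(k) equals the Poisson pmf again
        n = min(marg.size, d.pmf.size)
        np.testing.assert_allclose(marg[:n], d.pmf[:n], atol=1e-9)

    def test_two_regular2_layer_excess(self, two_regular2_ensemble):
        # following a layer-1 edge: excess degree (1, 2) with certainty
        pt = layer_excess_pmf(two_regular2_ensemble, 0)
        assert pt.probs[1, 2] == pytest.approx(1.0)

    def test_poisson_layer_excess_is_product_of_poissons(self, poisson_pair):
        e = NetworkEnsemble([(poisson_pair[0], 0.1), (poisson_pair[1], 0.6)])
        pt = layer_excess_pmf(e, 0)
        m0, m1 = pt.marginal(0), pt.marginal(1)
        n0 = min(m0.size, poisson_pair[0].pmf.size)
        n1 = min(m1.size, poisson_pair[1].pmf.size)
        np.testing.assert_allclose(m0[:n0], poisson_pair[0].pmf[:n0], atol=1e-8)
        np.testing.assert_allclose(m1[:n1], poisson_pair[1].pmf[:n1], atol=1e-8)

    def test_mixture_identity(self):
        # Gt equals the mean-degree-weighted mixture of the layer Gt_l
        e = NetworkEnsemble(
            [
                (ep.make_degree_distribution("regular", k=3), 0.3),
                (ep.make_degree_distribution("poisson", mean=2.0), 0.6),
            ]
        )
        Ek = [d.mean for d in e.distributions]
        for x in ([0.2, 0.9], [0.5, 0.5], [1.0, 0.3]):
            mix = sum(
                Ek[l] * eval_tilde_G_i(e, l, x) for l in range(2)
            ) / sum(Ek)
            assert eval_tilde_G(e, x) == pytest.approx(mix, abs=1e-10)

    def test_degenerate_layer_raises(self):
        e = NetworkEnsemble(
            [
                (ep.make_degree_distribution("regular", k=0), 0.5),
                (ep.make_degree_distribution("regular", k=2), 0.5),
            ]
        )
        with pytest.raises(DegenerateLayerError):
            layer_excess_pmf(e, 0)


class TestGeneratingFunctions:
    def test_tilde_G_matches_power_sum(self):
        e = NetworkEnsemble(
            [
                (ep.make_degree_distribution("geometric", a=0.4, tail_tol=1e-12), 0.3),
                (ep.make_degree_distribution("poisson", mean=2.0, tail_tol=1e-12), 0.6),
            ]
        )
        pt = excess_joint_pmf(e)
        for x in ([0.3, 0.7], [1.0, 1.0], [0.9, 0.1]):
            assert eval_tilde_G(e, x) == pytest.approx(pt.pgf(x), abs=1e-10)

    def test_normalisation_at_ones(self, poisson_pair):
        e = NetworkEnsemble([(poisson_pair[0], 0.1), (poisson_pair[1], 0.6)])
        assert e.eval_G([1.0, 1.0]) == pytest.approx(1.0, abs=1e-9)
        assert eval_tilde_G(e, [1.0, 1.0]) == pytest.approx(1.0, abs=1e-9)
        for i in range(2):
            assert eval_tilde_G_i(e, i, [1.0, 1.0]) == pytest.approx(1.0, abs=1e-9)

    def test_two_poisson_closed_form(self, poisson_pair):
        # Gt(x1, x2) = exp(-N1(1-x1) - N2(1-x2)) for two Poisson layers
        e = NetworkEnsemble([(poisson_pair[0], 0.1), (poisson_pair[1], 0.6)])
        x = [0.9, 0.4]
        assert eval_tilde_G(e, x) == pytest.approx(np.exp(-6.2), rel=1e-9)
        assert eval_tilde_G_i(e, 0, [1.0, 0.0]) == pytest.approx(np.exp(-2.0), rel=1e-8)

    def test_two_regular2_values(self, two_regular2_ensemble):
        # Gt_1(x) = x1 x2^2
        assert eval_tilde_G_i(two_regular2_ensemble, 0, [0.5, 0.5]) == pytest.approx(0.125)

    @pytest.mark.parametrize("i", [0, 1])
    def test_gradients_match_finite_differences(self, i):
        e = NetworkEnsemble(
            [
                (ep.make_degree_distribution("poisson", mean=3.0), 0.2),
                (ep.make_degree_distribution("geometric", a=0.3), 0.7),
            ]
        )
        for x in ([0.4, 0.8], [0.7, 0.2]):
            g = eval_tilde_G_i(e, i, x, grad=True)
            fd = _grad_fd(lambda y: eval_tilde_G_i(e, i, y), x)
            np.testing.assert_allclose(g, fd, atol=1e-6)
        g = eval_tilde_G(e, [0.4, 0.8], grad=True)
        fd = _grad_fd(lambda y: eval_tilde_G(e, y), [0.4, 0.8])
        np.testing.assert_allclose(g, fd, atol=1e-6)


class TestTildeH:
    def test_full_susceptibility_identity(self, two_regular2_ensemble, full_susceptibility):
        # Ht_i = x_i Gt_i on a grid when everyone starts susceptible
        e = two_regular2_ensemble
        for x in ([0.5, 0.5], [0.2, 0.9], [1.0, 1.0], [0.7, 0.3]):
            for i in range(2):
                assert eval_tilde_H_i(e, full_susceptibility, i, x) == pytest.approx(
                    x[i] * eval_tilde_G_i(e, i, x), abs=1e-10
                )
        assert eval_tilde_H_i(e, full_susceptibility, 0, [0.5, 0.5]) == pytest.approx(0.0625)

    def test_constant_s0_at_ones_gives_mean_susceptibility(self, two_regular2_ensemble):
        s0 = InitialSusceptibility(mode="constant", s0=0.9)
        for i in range(2):
            assert eval_tilde_H_i(two_regular2_ensemble, s0, i, [1.0, 1.0]) == pytest.approx(0.9)

    def test_per_degree_table_matches_constant(self, two_regular2_ensemble):
        e = two_regular2_ensemble
        table = {}
        for k1 in range(4):
            for k2 in range(4):
                table[(k1, k2)] = 0.7
        s_tab = InitialSusceptibility(mode="per_degree", table=table)
        s_c = InitialSusceptibility(mode="constant", s0=0.7)
        x = [0.6, 0.8]
        for i in range(2):
            assert eval_tilde_H_i(e, s_tab, i, x) == pytest.approx(
                eval_tilde_H_i(e, s_c, i, x), abs=1e-12
            )
            np.testing.assert_allclose(
                eval_tilde_H_i(e, s_tab, i, x, grad=True),
                eval_tilde_H_i(e, s_c, i, x, grad=True),
                atol=1e-10,
            )

    def test_missing_table_entry_raises(self, two_regular2_ensemble):
        s_tab = InitialSusceptibility(mode="per_degree", table={(0, 0): 1.0})
        with pytest.raises(IncompleteTableError):
            eval_tilde_H_i(two_regular2_ensemble, s_tab, 0, [0.5, 0.5])


class TestReproductionNumbers:
    def test_secondary_pgf_boundaries(self, regular3):
        e = single(regular3, T=0.5)
        assert secondary_infection_pgf(e, 1.0) == pytest.approx(1.0)
        # x = 0 gives the probability of zero onward infections:
        # binomial oracle sum over the excess degree 2: (1-T)^2 = 0.25
        assert secondary_infection_pgf(e, 0.0) == pytest.approx(0.25)

    def test_r0_single_layer(self, regular3):
        assert r0(single(regular3, T=0.5)) == pytest.approx(1.0)
        d = ep.make_degree_distribution("poisson", mean=4.0)
        assert r0(single(d, T=0.3)) == pytest.approx(1.2, abs=1e-9)

    def test_r0_two_poisson(self, poisson_pair):
        e = NetworkEnsemble([(poisson_pair[0], 0.1), (poisson_pair[1], 0.6)])
        assert r0(e) == pytest.approx(6.2, abs=1e-8)

    def test_r0_layer_two_regular2(self, two_regular2_ensemble):
        # layer 1 arrival: 1 onward layer-1 edge, 2 onward layer-2 edges
        assert r0_layer(two_regular2_ensemble, 0) == pytest.approx(0.25 + 2 * 0.5)

    def test_r0_weighted_sum_identity(self):
        e = NetworkEnsemble(
            [
                (ep.make_degree_distribution("poisson", mean=3.0), 0.2),
                (ep.make_degree_distribution("regular", k=4), 0.5),
            ]
        )
        Ek = [d.mean for d in e.distributions]
        weighted = sum(Ek[i] * r0_layer(e, i) for i in range(2)) / sum(Ek)
        assert r0(e) == pytest.approx(weighted, abs=1e-10)

    def test_single_layer_r0_equals_layer_r0(self, regular3):
        e = single(regular3, T=0.4)
        assert r0(e) == pytest.approx(r0_layer(e, 0), abs=1e-12)


class TestRMatrix:
    def test_two_regular2_entries(self, two_regular2_ensemble):
        R = r_matrix(two_regular2_ensemble)
        np.testing.assert_allclose(R.entries, [[0.25, 1.0], [0.5, 0.5]], atol=1e-12)
        np.testing.assert_allclose(R.row_sums(), [1.25, 1.0], atol=1e-12)

    def test_two_poisson_rank_one(self, poisson_pair):
        e = NetworkEnsemble([(poisson_pair[0], 0.1), (poisson_pair[1], 0.6)])
        R = r_matrix(e)
        np.testing.assert_allclose(R.entries, [[5.0, 1.2], [5.0, 1.2]], atol=1e-7)
        vals = np.sort(np.linalg.eigvals(R.entries).real)
        np.testing.assert_allclose(vals, [0.0, 6.2], atol=1e-7)

    def test_row_sums_are_layer_r0(self):
        e = NetworkEnsemble(
            [
                (ep.make_degree_distribution("geometric", a=0.4), 0.3),
                (ep.make_degree_distribution("poisson", mean=2.0), 0.6),
            ]
        )
        R = r_matrix(e)
        np.testing.assert_allclose(
            R.row_sums(), [r0_layer(e, i) for i in range(2)], atol=1e-10
        )

    def test_htilde_shift_identity(self, two_regular2_ensemble, full_susceptibility):
        # with everyone susceptible, the Ht-matrix is diag(T) + Gt-matrix
        RG = r_matrix(two_regular2_ensemble)
        RH = r_matrix(two_regular2_ensemble, kernel="Htilde", s0=full_susceptibility)
        np.testing.assert_allclose(
            RH.entries, np.diag(two_regular2_ensemble.T) + RG.entries, atol=1e-12
        )

    def test_entries_match_moment_formula(self):
        # two-layer entries vs the second-moment expression of the pgfs
        d1 = ep.make_degree_distribution("geometric", a=0.5)
        d2 = ep.make_degree_distribution("poisson", mean=2.5)
        e = NetworkEnsemble([(d1, 0.35), (d2, 0.55)])
        R = r_matrix(e).entries
        for i, d in enumerate((d1, d2)):
            kk = d.factorial_moment(2)
            assert R[i, i] == pytest.approx(e.T[i] * kk / d.mean, rel=1e-8)
        assert R[0, 1] == pytest.approx(e.T[1] * d2.mean, rel=1e-8)
        assert R[1, 0] == pytest.approx(e.T[0] * d1.mean, rel=1e-8)


class TestLeadingEigen:
    def test_two_regular2_radical_formula(self, two_regular2_ensemble):
        T1, T2 = 0.25, 0.5
        lam, vec = leading_eigen(r_matrix(two_regular2_ensemble))
        expected = (T1 + T2) / 2 + 0.5 * np.sqrt(T1**2 + T2**2 + 14 * T1 * T2)
        assert lam == pytest.approx(expected, abs=1e-12)
        assert np.all(vec >= -1e-12)

    def test_transpose_invariance(self, two_regular2_ensemble):
        R = r_matrix(two_regular2_ensemble)
        lam_t, _ = leading_eigen(R.entries.T)
        assert lam_t == pytest.approx(R.leading_eigenvalue, abs=1e-12)

    def test_scaled_identity(self):
        lam, _ = leading_eigen(np.diag([0.7, 0.7]))
        assert lam == pytest.approx(0.7)

    @given(st.floats(0.01, 0.99), st.floats(0.01, 0.99))
    def test_rank_one_poisson_eigenvalue(self, t1, t2):
        d1 = ep.make_degree_distribution("poisson", mean=5.0)
        d2 = ep.make_degree_distribution("poisson", mean=2.0)
        e = NetworkEnsemble([(d1, t1), (d2, t2)])
        R = r_matrix(e)
        assert R.leading_eigenvalue == pytest.approx(5 * t1 + 2 * t2, rel=1e-7)
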