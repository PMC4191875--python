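import itertools

import numpy as np
import pytest
from hypothesis import given, settings as hsettings, strategies as st

from gplmdca.alignment import EncodedMSA, find_gap_runs, msa_from_strings
from gplmdca.plm import (
    GapRunTable,
    OptimizerSettings,
    PottsParameters,
    RegularizationConfig,
    SiteParameters,
    SiteProblem,
    conditional_logprobs,
    fit_model,
    fit_site,
    load_fit,
    local_gap_energy,
    save_fit,
    site_objective_and_gradient,
    symmetrize_couplings,
    zero_sum_gauge,
)

Q = 21


def total_gap_energy(row, table):
    """Independent oracle: sum the table over the row's maximal runs."""
    return sum(table.get(r.start, r.length) for r in find_gap_runs(row))


class TestLocalGapEnergy:
    def test_isolated_gap_candidate(self):
        table = GapRunTable(entries={(3, 1): 0.7}, max_length_L=4)
        row = np.array([1, 2, 0, 4, 5])  # value at r ignored
        assert local_gap_energy(row, 3, 0, table) == pytest.approx(0.7)
        assert local_gap_energy(row, 3, 5, table) == 0.0

    def test_flanked_site_both_candidates(self):
        # lambda=1, rho=2 around column 3
        table = GapRunTable(
            entries={(2, 4): 1.0, (2, 1): 0.25, (4, 2): 0.5},
            max_length_L=4,
        )
        row = np.array([3, 0, 9, 0, 0, 7])
        assert local_gap_energy(row, 3, 0, table) == pytest.approx(1.0)
        assert local_gap_energy(row, 3, 5, table) == pytest.approx(0.75)

    def test_empty_table_is_zero(self):
        row = np.array([0, 0, 1, 0])
        table = GapRunTable()
        for s in (0, 3):
            assert local_gap_energy(row, 2, s, table) == 0.0

    def test_out_of_range_column(self):
        with pytest.raises(IndexError):
            local_gap_energy(np.array([1, 2]), 3, 0, GapRunTable())

    def test_energy_difference_matches_run_enumeration(self, rng):
        """local(gap) - local(non-gap) must equal the difference of full
        sequence gap energies computed by enumerating maximal runs."""
        N = 12
        keys = {(i, l): float(rng.normal())
                for i in range(1, N + 1) for l in range(1, N - i + 2)}
        table = GapRunTable(entries=keys, max_length_L=N)
        for _ in range(50):
            row = rng.integers(0, 3, size=N)
            r = int(rng.integers(1, N + 1))
            with_gap = row.copy()
            with_gap[r - 1] = 0
            without = row.copy()
            without[r - 1] = 5
            delta_local = (local_gap_energy(row, r, 0, table)
                           - local_gap_energy(row, r, 5, table))
            delta_full = (total_gap_energy(with_gap, table)
                          - total_gap_energy(without, table))
            assert delta_local == pytest.approx(delta_full, abs=1e-12)


class TestConditionalLogprobs:
    def test_uniform_when_all_zero(self):
        params = PottsParameters(fields_h=np.zeros((4, Q)))
        lp = conditional_logprobs(np.zeros(4, dtype=int), 2, params)
        assert np.allclose(lp, -np.log(Q))
        assert np.isclose(np.exp(lp).sum(), 1.0, atol=1e-12)

    def test_fields_only_is_log_softmax(self, rng):
        h = rng.normal(size=(3, Q))
        params = PottsParameters(fields_h=h)
        lp = conditional_logprobs(np.zeros(3, dtype=int), 1, params)
        expected = h[0] - np.log(np.exp(h[0]).sum())
        assert np.allclose(lp, expected)

    def test_matches_exact_enumeration_n2(self, rng):
        h = rng.normal(scale=0.7, size=(2, Q))
        J = rng.normal(scale=0.5, size=(Q, Q))
        params = PottsParameters(fields_h=h, couplings={(0, 1): J})
        energy = h[0][:, None] + h[1][None, :] + J
        joint = np.exp(energy - energy.max())
        joint /= joint.sum()
        for b in range(Q):
            cond = joint[:, b] / joint[:, b].sum()
            lp = conditional_logprobs(np.array([0, b]), 1, params)
            assert np.allclose(np.exp(lp), cond, atol=1e-12)
        for a in range(Q):
            cond = joint[a, :] / joint[a, :].sum()
            lp = conditional_logprobs(np.array([a, 0]), 2, params)
            assert np.allclose(np.exp(lp), cond, atol=1e-12)

    def test_nonfinite_parameters_rejected(self):
        h = np.zeros((2, Q))
        h[0, 0] = np.nan
        params = PottsParameters(fields_h=h)
        with pytest.raises(FloatingPointError):
            conditional_logprobs(np.zeros(2, dtype=int), 1, params)


class TestSiteObjective:
    def test_zero_params_zero_reg_gives_log_q(self, rng):
        msa = EncodedMSA(data=rng.integers(0, Q, size=(6, 4)))
        site = SiteParameters(h=np.zeros(Q))
        f, _ = site_objective_and_gradient(
            msa, 2, site, RegularizationConfig(0, 0, 0), use_gaps=False
        )
        assert f == pytest.approx(np.log(Q))

    def test_penalty_gradient_is_linear_in_parameters(self, rng):
        # the penalty contribution (gradient with reg minus gradient
        # without) is exactly 2*lambda*theta elementwise
        msa = EncodedMSA(data=rng.integers(0, Q, size=(5, 3)))
        reg = RegularizationConfig(0.5, 0.25, 0.0)
        with_pen = SiteProblem(msa, 1, reg, use_gaps=False)
        no_pen = SiteProblem(msa, 1, RegularizationConfig(0, 0, 0), False)
        theta = rng.normal(size=with_pen.n_params)
        _, g1 = with_pen.value_and_grad(theta)
        _, g0 = no_pen.value_and_grad(theta)
        q = Q
        assert np.allclose(g1[:q] - g0[:q], 2 * 0.5 * theta[:q])
        assert np.allclose(g1[q:] - g0[q:], 2 * 0.25 * theta[q:])

    @pytest.mark.parametrize("use_gaps", [False, True])
    def test_gradient_matches_finite_differences(self, use_gaps, rng):
        for _ in range(8):
            N, B = int(rng.integers(3, 7)), int(rng.integers(4, 11))
            msa = EncodedMSA(data=rng.integers(0, Q, size=(B, N)),
                             weights=rng.uniform(0.2, 1.0, B))
            problem = SiteProblem(msa, int(rng.integers(1, N + 1)),
                                  RegularizationConfig(), use_gaps)
            theta = rng.normal(scale=0.3, size=problem.n_params)
            _, grad = problem.value_and_grad(theta)
            eps = 1e-5
            for k in rng.choice(problem.n_params, size=15, replace=False):
                plus, minus = theta.copy(), theta.copy()
                plus[k] += eps
                minus[k] -= eps
                num = (problem.value_and_grad(plus)[0]
                       - problem.value_and_grad(minus)[0]) / (2 * eps)
                assert grad[k] == pytest.approx(num, rel=1e-4, abs=1e-9)

    def test_degenerate_weights_rejected(self):
        msa = EncodedMSA(data=np.zeros((2, 3), dtype=int),
                         weights=np.array([0.0, 0.0]))
        with pytest.raises(ValueError, match="b_eff"):
            SiteProblem(msa, 1, RegularizationConfig(), use_gaps=False)


class TestFitSite:
    def test_independent_sites_recover_column_frequencies(self, rng):
        # i.i.d. columns from a known categorical: fields match empirical
        # log-frequencies up to a constant and couplings stay near zero.
        # The field penalty is taken near zero; the coupling penalty must
        # stay finite because rare state pairs (expected counts ~10 over
        # 441 categories) quasi-separate the conditional otherwise.
        N, B = 5, 5000
        probs = rng.dirichlet(np.full(Q, 5.0), size=N)
        data = np.stack([rng.choice(Q, size=B, p=probs[i]) for i in range(N)],
                        axis=1)
        msa = EncodedMSA(data=data)
        reg = RegularizationConfig(1e-6, 0.05, 0.0)
        fit = fit_site(msa, 3, reg,
                       settings=OptimizerSettings(gtol=1e-6, max_iter=2000))
        emp = np.bincount(data[:, 2], minlength=Q) / B
        logf = np.log(emp + 1e-12)
        h_eff = fit.params.h + sum(block.mean(axis=1)
                                   for block in fit.params.J.values())
        centered = (h_eff - h_eff.mean()) - (logf - logf.mean())
        assert np.abs(centered).max() < 0.05
        j_max = max(np.abs(zero_sum_gauge(block)).max()
                    for block in fit.params.J.values())
        assert j_max < 0.05

    def test_huge_penalty_drives_parameters_to_zero(self, rng):
        msa = EncodedMSA(data=rng.integers(0, Q, size=(20, 4)))
        fit = fit_site(msa, 1, RegularizationConfig(1e6, 1e6, 1e6))
        assert np.abs(fit.params.h).max() < 1e-4
        assert all(np.abs(b).max() < 1e-4 for b in fit.params.J.values())

    def test_refit_from_optimum_is_stationary(self, rng):
        msa = EncodedMSA(data=rng.integers(0, Q, size=(30, 4)))
        fit = fit_site(msa, 2)
        problem = SiteProblem(msa, 2, RegularizationConfig(), False)
        refit = fit_site(msa, 2, x0=problem.pack(fit.params))
        assert abs(refit.objective - fit.objective) < 1e-9

    def test_objective_decreases_monotonically(self, rng):
        msa = EncodedMSA(data=rng.integers(0, Q, size=(40, 5)))
        fit = fit_site(msa, 1, settings=OptimizerSettings(record_history=True))
        hist = np.array(fit.objective_history)
        assert hist.size > 1
        assert np.all(np.diff(hist) <= 1e-12)


class TestFitModel:
    def test_population_pseudolikelihood_recovers_couplings_q3(self, rng):
        # weights = exact joint probabilities: consistency of the estimator
        q = 3
        J = zero_sum_gauge(rng.normal(scale=1.0, size=(q, q)))
        h = rng.normal(scale=0.5, size=(2, q))
        energy = h[0][:, None] + h[1][None, :] + J
        joint = np.exp(energy)
        joint /= joint.sum()
        patterns = np.array(list(itertools.product(range(q), repeat=2)))
        weights = np.array([joint[a, b] for a, b in patterns])
        msa = EncodedMSA(data=patterns, weights=weights, q=q)
        fit = fit_model(msa, RegularizationConfig(1e-8, 1e-8, 1e-8),
                        settings=OptimizerSettings(gtol=1e-9))
        assert np.abs(fit.params.couplings[(0, 1)] - J).max() < 1e-2

    def test_gap_free_alignment_gplm_equals_plm(self):
        msa = msa_from_strings([
            "ACDEFGHI", "ACDEFGHW", "MCDEFGHI", "ACDWFGHI",
            "ACDEFYHI", "TCDEFGHI",
        ])
        plain = fit_model(msa, use_gaps=False)
        gapped = fit_model(msa, use_gaps=True)
        for pair in plain.params.couplings:
            assert np.array_equal(plain.params.couplings[pair],
                                  gapped.params.couplings[pair])
        assert np.array_equal(plain.params.fields_h, gapped.params.fields_h)

    def test_serial_equals_parallel(self, rng):
        msa = EncodedMSA(data=rng.integers(0, Q, size=(30, 6)))
        serial = fit_model(msa, n_jobs=1)
        parallel = fit_model(msa, n_jobs=4)
        assert np.array_equal(serial.params.fields_h, parallel.params.fields_h)
        for pair in serial.params.couplings:
            assert np.array_equal(serial.params.couplings[pair],
                                  parallel.params.couplings[pair])

    def test_collapsing_duplicates_changes_nothing(self, rng):
        data = rng.integers(0, Q, size=(10, 4))
        data = np.vstack([data, data[:5]])
        msa = EncodedMSA(data=data)
        a = fit_model(msa, collapse_duplicates=True)
        b = fit_model(msa, collapse_duplicates=False)
        for pair in a.params.couplings:
            assert np.allclose(a.params.couplings[pair],
                               b.params.couplings[pair], atol=1e-6)

    def test_gauge_of_symmetrized_couplings(self, rng):
        msa = EncodedMSA(data=rng.integers(0, Q, size=(25, 5)))
        fit = fit_model(msa)
        for block in fit.params.couplings.values():
            assert np.abs(block.sum(axis=0)).max() < 1e-8
            assert np.abs(block.sum(axis=1)).max() < 1e-8

    def test_roundtrip_serialization(self, tmp_path, rng):
        msa = EncodedMSA(data=rng.integers(0, Q, size=(20, 4)))
        fit = fit_model(msa)
        path = tmp_path / "fit.npz"
        save_fit(fit, path)
        back = load_fit(path)
        assert np.array_equal(back.params.fields_h, fit.params.fields_h)
        for pair, block in fit.params.couplings.items():
            assert np.array_equal(back.params.couplings[pair], block)
        assert back.config == fit.config


class TestSymmetrizeAndGauge:
    def test_symmetrize_examples(self, rng):
        A = rng.normal(size=(Q, Q))
        B = rng.normal(size=(Q, Q))
        # both directed estimates equal (up to orientation) -> either one
        out = symmetrize_couplings({0: {1: A}, 1: {0: A.T}})
        assert np.allclose(out[(0, 1)], A)
        # one estimate zero -> half the other
        out = symmetrize_couplings({0: {1: A}, 1: {0: np.zeros((Q, Q))}})
        assert np.allclose(out[(0, 1)], A / 2)
        # general case: elementwise mean with the transpose
        out = symmetrize_couplings({0: {1: A}, 1: {0: B}})
        assert np.allclose(out[(0, 1)], (A + B.T) / 2)

    def test_gauge_constant_matrix_vanishes(self):
        assert np.allclose(zero_sum_gauge(np.full((Q, Q), 3.7)), 0.0)

    def test_gauge_single_entry_hand_expansion(self):
        c = 2.0
        J = np.zeros((Q, Q))
        J[0, 0] = Q * Q * c
        out = zero_sum_gauge(J)
        # J'(0,0) = q^2 c - qc - qc + c; J'(0,b) = -qc + c; J'(a,b) = c
        assert out[0, 0] == pytest.approx(Q * Q * c - 2 * Q * c + c)
        assert out[0, 1] == pytest.approx(-Q * c + c)
        assert out[1, 0] == pytest.approx(-Q * c + c)
        assert out[1, 2] == pytest.approx(c)

    @given(st.integers(0, 2 ** 32 - 1))
    @hsettings(deadline=None, max_examples=30)
    def test_gauge_idempotent_linear_projection(self, seed):
        r = np.random.default_rng(seed)
        A, B = r.normal(size=(2, 7, 7))
        once = zero_sum_gauge(A)
        assert np.allclose(zero_sum_gauge(once), once, atol=1e-12)
        assert np.allclose(
            zero_sum_gauge(2.0 * A + 3.0 * B),
            2.0 * zero_sum_gauge(A) + 3.0 * zero_sum_gauge(B),
            atol=1e-10,
        )
        assert np.abs(once.sum(axis=0)).max() < 1e-10
        assert np.abs(once.sum(axis=1)).max() < 1e-10

    def test_gauge_shift_invariance(self, rng):
        # adding per-site shifts c_i(b) to a block leaves the gauge fixed
        # projection unchanged: downstream scores cannot see the gauge
        J = rng.normal(size=(Q, Q))
        c_row = rng.normal(size=(Q, 1))
        c_col = rng.normal(size=(1, Q))
        shifted = J + c_row + c_col + 1.3
        assert np.allclose(zero_sum_gauge(shifted), zero_sum_gauge(J),
                           atol=1e-10)
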