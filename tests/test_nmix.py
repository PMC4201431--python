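"""N-mixture likelihood oracles, fitting, and derived abundance."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nmixtures import (
    CountDataset,
    DynamicNMixtureModel,
    SingleSeasonNMixtureModel,
    build_transition_matrix,
    project_abundance,
    simulate_study,
    transition_pmf,
    zip_pmf,
)


def brute_force_dynamic_loglik(counts, lam, psi, omega, gamma, p, K):
    """Exhaustive double enumeration over (N1, N2); the independent oracle."""
    total = 0.0
    for i in range(counts.shape[0]):
        s = 0.0
        for N1 in range(K + 1):
            a = psi * (N1 == 0) + (1 - psi) * stats.poisson.pmf(N1, lam[i])
            g1 = np.prod(
                [stats.binom.pmf(counts[i, 0, j], N1, p[i, 0, j]) for j in range(2)]
            )
            if a * g1 == 0.0:
                continue
            inner = 0.0
            for N2 in range(K + 1):
                tr = transition_pmf(N2, N1, omega, gamma[i])
                g2 = np.prod(
                    [stats.binom.pmf(counts[i, 1, j], N2, p[i, 1, j]) for j in range(2)]
                )
                inner += tr * g2
            s += a * g1 * inner
        total += np.log(s)
    return total


def single_site_dataset(counts_by_season):
    rows = [
        {"site": "a", "season": t + 1, "visit": j + 1, "count": c}
        for t, season in enumerate(counts_by_season)
        for j, c in enumerate(season)
    ]
    sites = pd.DataFrame({"site": ["a"], "snag_ba": [0.0], "conifer_ba": [0.0], "boxes": [0]})
    return CountDataset(pd.DataFrame(rows), sites)


class TestZipPmf:
    def test_reduces_to_poisson(self):
        assert zip_pmf(0, 2.0, 0.0) == pytest.approx(np.exp(-2.0), abs=1e-12)

    def test_zero_inflated_zero(self):
        # formula value, cross-checked by normalisation below
        assert zip_pmf(0, 2.0, 0.3) == pytest.approx(0.3 + 0.7 * np.exp(-2.0), abs=1e-12)

    def test_normalises(self):
        k = np.arange(0, 51)
        assert zip_pmf(k, 2.0, 0.3).sum() == pytest.approx(1.0, abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            zip_pmf(-1, 2.0, 0.3)
        with pytest.raises(ValueError):
            zip_pmf(0, 2.0, 1.0)


class TestTransition:
    def test_no_survivors_from_zero(self):
        assert transition_pmf(0, 0, 0.5, 1.0) == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_pure_survival(self):
        assert transition_pmf(1, 1, 0.5, 0.0) == pytest.approx(0.5)
        assert transition_pmf(0, 1, 0.5, 0.0) == pytest.approx(0.5)

    def test_survivor_enumeration(self):
        # two residents, omega=1/2, gamma=1: P(1|2) = 0.75 e^-1
        assert transition_pmf(1, 2, 0.5, 1.0) == pytest.approx(
            0.75 * np.exp(-1.0), abs=1e-12
        )

    def test_matrix_matches_pmf_entrywise(self):
        M = build_transition_matrix(0.3, 2.0, 12)
        for a in (0, 3, 7):
            for b in (0, 4, 11):
                assert M[a, b] == pytest.approx(transition_pmf(b, a, 0.3, 2.0), abs=1e-12)

    def test_absorbing_at_zero(self):
        M = build_transition_matrix(0.0, 0.0, 5)
        np.testing.assert_allclose(M[:, 0], 1.0)
        np.testing.assert_allclose(M[:, 1:], 0.0)

    def test_row_sums_near_one_for_adequate_K(self):
        gamma, n_prev = 4.0, 6
        K = int(gamma + 10 * np.sqrt(gamma) + n_prev)
        M = build_transition_matrix(0.7, gamma, K)
        assert np.all(M[: n_prev + 1].sum(axis=1) >= 1 - 1e-8)


class TestSingleSeasonLoglik:
    def test_closed_form_series(self):
        # one site, counts (0,0), lam=1, p=0.5:
        # log sum_N Pois(N;1) 0.25^N = lam (q^2 - 1) = -0.75
        ds = single_site_dataset([(0, 0)])
        m = SingleSeasonNMixtureModel(ds, mixture="P", K=200)
        assert m.loglik(np.array([0.0, 0.0])) == pytest.approx(-0.75, abs=1e-12)

    def test_perfect_detection_closure_logic(self):
        # counts (2,3) with p=1 cannot arise from a closed population
        ds = single_site_dataset([(2, 3)])
        m = SingleSeasonNMixtureModel(ds, mixture="P", K=50)
        assert m.loglik(np.array([0.0, 50.0])) == -np.inf

    def test_brute_force_enumeration(self):
        rng = np.random.default_rng(3)
        rows = []
        for i in range(5):
            for j in (1, 2):
                rows.append(
                    {"site": f"s{i}", "season": 1, "visit": j, "count": int(rng.integers(0, 4))}
                )
        sites = pd.DataFrame({"site": [f"s{i}" for i in range(5)], "snag_ba": rng.normal(size=5)})
        ds = CountDataset(pd.DataFrame(rows), sites)
        m = SingleSeasonNMixtureModel(ds, "snag_ba", "1", mixture="ZIP", K=200)
        params = np.array([0.4, 0.15, -1.2, -0.3])
        lam, psi, _, _, p = m._unpack(params)
        counts = ds.count_array()
        expected = 0.0
        for i in range(5):
            s = 0.0
            for N in range(201):
                a = psi * (N == 0) + (1 - psi) * stats.poisson.pmf(N, lam[i])
                g = stats.binom.pmf(counts[i, 0, 0], N, p[i, 0, 0]) * stats.binom.pmf(
                    counts[i, 0, 1], N, p[i, 0, 1]
                )
                s += a * g
            expected += np.log(s)
        assert m.loglik(params) == pytest.approx(expected, abs=1e-10)

    def test_k_below_max_count_is_config_error(self):
        ds = single_site_dataset([(0, 5)])
        with pytest.raises(ValueError, match="K"):
            SingleSeasonNMixtureModel(ds, mixture="P", K=3)


class TestDynamicLoglik:
    def test_matches_exhaustive_enumeration(self, tiny_dataset):
        m = DynamicNMixtureModel(
            tiny_dataset, "snag_ba", "boxes", "precip", mixture="ZIP", K=60
        )
        params = np.array([0.5, 0.2, -1.0, 0.3, -0.2, 0.1, -0.5, 0.15])
        lam, psi, gam, omega, p = m._unpack(params)
        oracle = brute_force_dynamic_loglik(
            tiny_dataset.count_array(), lam, psi, omega, gam, p, 60
        )
        assert m.loglik(params) == pytest.approx(oracle, abs=1e-10)

    def test_closure_limit_equals_single_season(self, tiny_dataset):
        """omega=1, gamma=0 freezes the population: the dynamic likelihood
        must equal a single-season likelihood over all pooled visits."""
        m = DynamicNMixtureModel(tiny_dataset, "1", "1", "1", mixture="P", K=60)
        # pooled: same site counts as one season with 4 visits
        pooled = tiny_dataset.visits.copy()
        pooled["visit"] = pooled["season"] * 10 + pooled["visit"]
        pooled["season"] = 1
        ds_pooled = CountDataset(pooled, tiny_dataset.sites)
        ss = SingleSeasonNMixtureModel(ds_pooled, "1", "1", mixture="P", K=60)
        lam0, p0 = 0.7, -0.4
        dyn = m.loglik(np.array([lam0, -40.0, 40.0, p0]))  # gamma ~ 0, omega ~ 1
        assert dyn == pytest.approx(ss.loglik(np.array([lam0, p0])), abs=1e-8)

    def test_zip_psi_zero_equals_poisson(self, tiny_dataset):
        mz = DynamicNMixtureModel(tiny_dataset, "1", "1", "1", mixture="ZIP", K=40)
        mp = DynamicNMixtureModel(tiny_dataset, "1", "1", "1", mixture="P", K=40)
        # psi on logit scale: -inf -> 0; use a large negative value
        zip_params = np.array([0.5, -745.0, 0.3, 0.1, -0.5])
        poi_params = np.array([0.5, 0.3, 0.1, -0.5])
        assert mz.loglik(zip_params) == pytest.approx(mp.loglik(poi_params), abs=1e-12)

    def test_invariance_under_site_and_visit_permutation(self, tiny_dataset):
        m = DynamicNMixtureModel(tiny_dataset, "snag_ba", "1", "precip", K=40)
        params = np.array([0.5, -1.0, 0.2, 0.3, 0.1, -0.5, 0.1])
        base = m.loglik(params)
        # permute site order
        order = [2, 0, 3, 1]
        sites_perm = tiny_dataset.sites.iloc[order].reset_index(drop=True)
        ds_perm = CountDataset(tiny_dataset.visits, sites_perm)
        m2 = DynamicNMixtureModel(ds_perm, "snag_ba", "1", "precip", K=40)
        assert m2.loglik(params) == pytest.approx(base, abs=1e-10)
        # swap visit labels within each season (visit covariates travel along)
        swapped = tiny_dataset.visits.copy()
        swapped["visit"] = 3 - swapped["visit"]
        m3 = DynamicNMixtureModel(
            CountDataset(swapped, tiny_dataset.sites), "snag_ba", "1", "precip", K=40
        )
        assert m3.loglik(params) == pytest.approx(base, abs=1e-10)


class TestFitting:
    def test_truncation_stability(self, intercept_scenario):
        out = simulate_study(intercept_scenario, seed=5)
        K = int(out["dataset"].count_array().max()) + 30
        m = DynamicNMixtureModel(out["dataset"], "1", "1", "1", mixture="P", K=K)
        fit = m.fit(starts=1, seed=0)
        assert fit.converged
        assert fit.truncation_stable(increment=50, tol=1e-6)

    def test_all_zero_counts_flagged_at_boundary(self):
        rows = [
            {"site": f"s{i}", "season": t, "visit": j, "count": 0}
            for i in range(6)
            for t in (1, 2)
            for j in (1, 2)
        ]
        sites = pd.DataFrame({"site": [f"s{i}" for i in range(6)]})
        ds = CountDataset(pd.DataFrame(rows), sites)
        m = DynamicNMixtureModel(ds, "1", "1", "1", mixture="P", K=30)
        fit = m.fit(starts=1, seed=0)
        # lambda driven to the zero boundary; SEs unavailable there
        lam = np.exp(fit.params[0])
        assert lam < 0.05
        assert not fit.se_available

    def test_expected_abundance_mixture_mean(self, tiny_dataset):
        m = DynamicNMixtureModel(tiny_dataset, "1", "1", "1", mixture="ZIP", K=40)
        fit = m.fit(starts=1, seed=0)
        lam, psi, gam, omega, _ = fit.natural_params()
        est, _ = fit.expected_site_abundance(0)
        np.testing.assert_allclose(est, (1 - psi) * lam, rtol=1e-10)
        est2, _ = fit.expected_site_abundance(1)
        np.testing.assert_allclose(est2, omega * (1 - psi) * lam + gam, rtol=1e-10)

    def test_nonconverged_refuses_derived_quantities(self, tiny_dataset):
        m = DynamicNMixtureModel(tiny_dataset, "1", "1", "1", K=40)
        fit = m.fit(starts=1, seed=0)
        fit.converged = False
        with pytest.raises(RuntimeError):
            fit.expected_site_abundance(0)


class TestProjection:
    def test_one_step(self):
        assert project_abundance(10, 0.5, 3.0, 2) == pytest.approx(8.0)

    def test_iterated_expectation(self):
        # two steps of E -> omega E + gamma
        assert project_abundance(10, 0.5, 3.0, 3) == pytest.approx(
            0.5 * (0.5 * 10 + 3) + 3
        )

    def test_equilibrium(self):
        assert project_abundance(10, 0.5, 3.0, 500) == pytest.approx(6.0)

    def test_omega_one_limit(self):
        assert project_abundance(10, 1.0, 3.0, 4) == pytest.approx(19.0)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            project_abundance(10, 0.5, 3.0, 0)
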