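"""Single-season and dynamic (open-population) N-mixture models.

The single-season model treats the count ``n_ij`` of unique individuals
detected at site ``i`` on visit ``j`` as a binomial draw from a latent
site abundance, ``n_ij ~ Binomial(N_i, p_ij)``, with ``N_i`` Poisson or
zero-inflated Poisson (ZIP).  The dynamic model links latent abundances
across primary seasons through apparent survival and recruitment:

    N_{i,1}   ~ ZIP(lambda_i, psi)
    N_{i,t+1} = Binomial(N_{i,t}, omega) + Poisson(gamma_i)

with detection ``p_itj`` on a logit link, ``lambda`` and ``gamma`` on a
log link, and ``omega`` and the zero-inflation weight ``psi`` on logit
links.  Likelihoods marginalise the latent chain by a forward pass over
abundances 0..K, where K is a truncation bound validated by a stability
check.  Sites are independent; abundance is assumed closed within a
season (visits are the secondary occasions of a robust design).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, gammaln, logit, logsumexp

from .data import CountDataset

__all__ = [
    "zip_pmf",
    "transition_pmf",
    "build_transition_matrix",
    "project_abundance",
    "DynamicNMixtureModel",
    "SingleSeasonNMixtureModel",
    "NMixtureResults",
]

# ----------------------------------------------------------------------
# elementary distributions
def zip_pmf(k, lam, psi):
    """Zero-inflated Poisson pmf: psi * 1{k=0} + (1 - psi) * Poisson(k; lam)."""
    k = np.asarray(k)
    if np.any(k < 0):
        raise ValueError("k must be non-negative")
    if np.any(np.asarray(lam) <= 0):
        raise ValueError("lam must be positive")
    if np.any((np.asarray(psi) < 0) | (np.asarray(psi) >= 1)):
        raise ValueError("psi must lie in [0, 1)")
    return psi * (k == 0) + (1.0 - psi) * stats.poisson.pmf(k, lam)


def transition_pmf(n_next, n_prev, omega, gamma):
    """P(N_{t+1} = n_next | N_t = n_prev) for survival-plus-recruitment dynamics.

    Survivors are Binomial(n_prev, omega); recruits are Poisson(gamma);
    the two are independent, so the pmf is the convolution

        sum_s Binom(s; n_prev, omega) * Poisson(n_next - s; gamma).
    """
    if not (0.0 <= omega <= 1.0):
        raise ValueError("omega must lie in [0, 1]")
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    s = np.arange(0, min(n_prev, n_next) + 1)
    return float(
        np.sum(stats.binom.pmf(s, n_prev, omega) * stats.poisson.pmf(n_next - s, gamma))
    )


def build_transition_matrix(omega: float, gamma: float, K: int) -> np.ndarray:
    """Tabulate the transition pmf as a (K+1)x(K+1) matrix.

    Row ``n_prev`` sums to 1 minus the Poisson tail mass beyond K; the
    deficit is negligible when K comfortably exceeds gamma + n_prev.
    """
    grid = np.arange(K + 1)
    # survivors: B[n_prev, s]; recruits: Toeplitz Poisson shift Q[s, n_next]
    B = stats.binom.pmf(grid[None, :], grid[:, None], omega)
    pois = stats.poisson.pmf(grid, gamma)
    Q = np.zeros((K + 1, K + 1))
    for s in grid:
        Q[s, s:] = pois[: K + 1 - s]
    return B @ Q


def project_abundance(n_start: float, omega: float, gamma: float, t: int) -> float:
    """Expected abundance after t-1 transitions from initial abundance.

    Iterating the one-step expectation E[N_{t}] = omega * E[N_{t-1}] + gamma
    gives the closed form N_1 * omega^(t-1) + gamma * (1 - omega^(t-1)) / (1 - omega),
    with the omega -> 1 limit N_1 + (t-1) * gamma.
    """
    if t < 1:
        raise ValueError("t must be >= 1")
    if not (0.0 <= omega <= 1.0):
        raise ValueError("omega must lie in [0, 1]")
    if omega == 1.0:
        return float(n_start + (t - 1) * gamma)
    w = omega ** (t - 1)
    return float(n_start * w + gamma * (1.0 - w) / (1.0 - omega))


# ----------------------------------------------------------------------
# parameter packing
@dataclass
class _Blocks:
    """Slices of the packed parameter vector for each link-scale block."""

    lam: slice
    psi: slice
    gam: slice
    omega: slice
    p: slice
    names: list[str] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.names)


def _detection_logpmf(counts, p, K):
    """log Binom(count; N, p) for N = 0..K, vectorised over observations.

    counts, p: 1-D arrays of equal length M.  Returns (M, K+1).
    """
    F = gammaln(np.arange(K + 2) + 1.0)  # F[n] = log n!
    N = np.arange(K + 1)
    n = counts[:, None]
    diff = N[None, :] - n
    valid = diff >= 0
    diffc = np.where(valid, diff, 0)
    hi = p == 1.0
    lo = p == 0.0
    pc = np.clip(p, 1e-300, 1.0 - 1e-16)[:, None]
    logC = F[N][None, :] - F[counts][:, None] - F[diffc.astype(int)]
    out = logC + n * np.log(pc) + diffc * np.log1p(-pc)
    out = np.where(valid, out, -np.inf)
    if hi.any():  # perfect detection: point mass at N = n
        out[hi] = np.where(N[None, :] == counts[hi][:, None], 0.0, -np.inf)
    if lo.any():  # no detection possible: count must be zero
        out[lo] = np.where(counts[lo][:, None] == 0, 0.0, -np.inf)
    return out


def _mixture_logpmf(lam, psi, K):
    """log ZIP(N; lam_i, psi) for N = 0..K; lam 1-D over sites -> (n_sites, K+1)."""
    N = np.arange(K + 1)
    logpois = N[None, :] * np.log(lam[:, None]) - lam[:, None] - gammaln(N + 1.0)[None, :]
    if psi <= 0.0:
        return logpois
    out = np.log1p(-psi) + logpois
    out[:, 0] = np.logaddexp(np.log(psi), out[:, 0])
    return out


class _NMixtureBase:
    """Shared machinery: design matrices, packing, optimisation."""

    def __init__(self, dataset: CountDataset, mixture: str, K: int | None):
        if mixture not in {"P", "ZIP"}:
            raise ValueError("mixture must be 'P' (Poisson) or 'ZIP'")
        self.dataset = dataset
        self.mixture = mixture
        self.counts = dataset.count_array()  # (n_sites, T, J)
        max_count = int(self.counts.max()) if self.counts.size else 0
        self.K = int(K) if K is not None else max_count + 100
        if self.K < max_count:
            raise ValueError(f"K={self.K} below the maximum observed count {max_count}")
        self.n_sites, self.n_seasons, self.n_visits = self.counts.shape

    def _design(self, lambda_formula, gamma_formula, p_formula):
        self.X_lam, lam_names = self.dataset.site_design(lambda_formula)
        self.X_p, p_names = self.dataset.visit_design(p_formula)
        names = [f"lam_{n}" for n in lam_names]
        i = len(names)
        sl_lam = slice(0, i)
        if self.mixture == "ZIP":
            names.append("psi_(Intercept)")
            sl_psi = slice(i, i + 1)
            i += 1
        else:
            sl_psi = slice(i, i)
        if gamma_formula is not None:
            self.X_gam, gam_names = self.dataset.site_design(gamma_formula)
            names += [f"gam_{n}" for n in gam_names]
            sl_gam = slice(i, i + len(gam_names))
            i += len(gam_names)
            names.append("omega_(Intercept)")
            sl_omega = slice(i, i + 1)
            i += 1
        else:
            self.X_gam = None
            sl_gam = slice(i, i)
            sl_omega = slice(i, i)
        names += [f"p_{n}" for n in p_names]
        sl_p = slice(i, i + len(p_names))
        self.blocks = _Blocks(sl_lam, sl_psi, sl_gam, sl_omega, sl_p, names)

    # -- natural-scale parameter fields ---------------------------------
    def _unpack(self, params):
        params = np.asarray(params, dtype=float)
        lam = np.exp(self.X_lam @ params[self.blocks.lam])
        psi = float(expit(params[self.blocks.psi][0])) if self.mixture == "ZIP" else 0.0
        if self.X_gam is not None:
            gam = np.exp(self.X_gam @ params[self.blocks.gam])
            omega = float(expit(params[self.blocks.omega][0]))
        else:
            gam, omega = None, None
        p = expit(self.X_p @ params[self.blocks.p]).reshape(
            self.n_sites, self.n_seasons, self.n_visits
        )
        return lam, psi, gam, omega, p

    def _season_detection_logliks(self, p):
        """log g_t(i, N) = sum_j log Binom(n_itj; N, p_itj), per season."""
        out = []
        for t in range(self.n_seasons):
            g = np.zeros((self.n_sites, self.K + 1))
            for j in range(self.n_visits):
                g += _detection_logpmf(self.counts[:, t, j], p[:, t, j], self.K)
            out.append(g)
        return out

    def loglik(self, params) -> float:
        raise NotImplementedError

    def _start_values(self):
        raise NotImplementedError

    def fit(
        self,
        starts: int = 5,
        seed: int = 0,
        maxiter: int = 1000,
        x0: np.ndarray | None = None,
        hessian: bool = True,
    ) -> "NMixtureResults":
        """Maximise the likelihood from ``starts`` jittered initialisations.

        The best converged optimum is kept; the covariance of the
        estimates is the inverse numerical Hessian of the negative
        log-likelihood at the optimum.  ``x0`` overrides the data-driven
        starting point (used to warm-start bootstrap refits).
        """
        rng = np.random.default_rng(seed)
        x0 = self._start_values() if x0 is None else np.asarray(x0, dtype=float)

        def nll(params):
            val = self.loglik(params)
            # large finite penalty keeps finite-difference gradients usable
            return 1e12 if not np.isfinite(val) else -val

        best = None
        for s in range(max(1, starts)):
            init = x0 if s == 0 else x0 + rng.normal(0.0, 0.3, size=x0.size)
            res = optimize.minimize(
                nll,
                init,
                method="L-BFGS-B",
                options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-8},
            )
            if best is None or res.fun < best.fun:
                best = res
        params = best.x
        llf = -best.fun
        success = bool(best.success)

        def _polish(x):
            return optimize.minimize(
                nll, x, method="Nelder-Mead",
                options={"xatol": 1e-8, "fatol": 1e-11,
                         "maxiter": 20000, "maxfev": 40000},
            )

        if not success and np.isfinite(llf):
            # quasi-Newton can crawl on the flat lambda-p ridge until the
            # iteration cap; a derivative-free polish settles the optimum
            polish = _polish(params)
            if polish.fun <= -llf:
                params, llf = polish.x, -polish.fun
                success = bool(polish.success)
        vcov = np.full((params.size, params.size), np.nan)
        se_ok = False
        if hessian:
            from statsmodels.tools.numdiff import approx_hess1

            def _try_vcov(x):
                with np.errstate(all="ignore"):
                    H = approx_hess1(x, nll)
                sym = (H + H.T) / 2.0
                try:
                    if np.isfinite(sym).all() and np.min(np.linalg.eigvalsh(sym)) > 0:
                        return np.linalg.inv(sym)
                except np.linalg.LinAlgError:
                    pass
                return None

            V = _try_vcov(params)
            if V is None and np.isfinite(llf):
                polish = _polish(params)
                if polish.fun <= -llf:
                    params, llf = polish.x, -polish.fun
                    success = success or bool(polish.success)
                    V = _try_vcov(params)
            if V is not None:
                vcov = V
                se_ok = True
        return NMixtureResults(
            model=self,
            params=params,
            llf=float(llf),
            vcov=vcov,
            converged=success,
            se_available=se_ok,
            optimizer_message=str(best.message),
        )


class DynamicNMixtureModel(_NMixtureBase):
    """Open-population N-mixture model for T >= 2 primary seasons.

    Parameters
    ----------
    dataset : CountDataset
    lambda_formula : str
        Log-linear model for initial (season-1) abundance over site
        covariates.
    gamma_formula : str
        Log-linear model for recruitment per transition.
    p_formula : str
        Logit-linear model for per-visit detection over visit and site
        covariates.
    mixture : {"ZIP", "P"}
        Season-1 abundance distribution.  ``psi`` (logit, intercept
        only) is the zero-inflation weight; the Poisson mixture fixes
        psi = 0.
    K : int, optional
        Latent-abundance truncation bound; defaults to the maximum
        observed count plus 100.

    Apparent survival ``omega`` is a single logit-scale constant per
    transition (putting covariates on survival is not supported: with
    two seasons it is weakly identified).
    """

    def __init__(
        self,
        dataset: CountDataset,
        lambda_formula: str = "1",
        gamma_formula: str = "1",
        p_formula: str = "1",
        mixture: str = "ZIP",
        K: int | None = None,
    ):
        super().__init__(dataset, mixture, K)
        if self.n_seasons < 2:
            raise ValueError("dynamic model needs at least two primary seasons")
        self.lambda_formula = lambda_formula
        self.gamma_formula = gamma_formula
        self.p_formula = p_formula
        self._design(lambda_formula, gamma_formula, p_formula)

    @property
    def name(self) -> str:
        return (
            f"lam({self.lambda_formula}) gam({self.gamma_formula}) omega(1) "
            f"p({self.p_formula}) [{self.mixture}]"
        )

    def loglik(self, params) -> float:
        """Marginal log-likelihood via a forward pass over the latent chain."""
        lam, psi, gam, omega, p = self._unpack(params)
        if not np.all(np.isfinite(lam)) or not np.all(np.isfinite(gam)):
            return -np.inf
        gdet = self._season_detection_logliks(p)
        log_a = _mixture_logpmf(lam, psi, self.K)

        # forward pass in scaled linear space
        log_phi = log_a + gdet[0]  # (n_sites, K+1)
        shift = np.max(log_phi, axis=1)
        if not np.all(np.isfinite(shift)):
            return -np.inf
        phi = np.exp(log_phi - shift[:, None])
        total_shift = shift

        grid = np.arange(self.K + 1)
        B = stats.binom.pmf(grid[None, :], grid[:, None], omega)  # survivors
        pois = stats.poisson.pmf(grid[:, None], gam[None, :]).T  # (n_sites, K+1)
        for t in range(1, self.n_seasons):
            m = phi @ B  # mass over survivor counts
            # add Poisson recruits: per-site convolution truncated at K
            z = np.empty_like(m)
            for i in range(self.n_sites):
                z[i] = np.convolve(m[i], pois[i])[: self.K + 1]
            log_phi = np.log(np.clip(z, 1e-300, None)) + gdet[t]
            shift = np.max(log_phi, axis=1)
            if not np.all(np.isfinite(shift)):
                return -np.inf
            phi = np.exp(log_phi - shift[:, None])
            total_shift = total_shift + shift
        site_ll = np.log(phi.sum(axis=1)) + total_shift
        return float(site_ll.sum())

    def _start_values(self):
        x0 = np.zeros(self.blocks.k)
        mean1 = max(float(self.counts[:, 0, :].max(axis=1).mean()), 0.1)
        meanT = max(float(self.counts[:, -1, :].max(axis=1).mean()), 0.1)
        x0[self.blocks.lam.start] = np.log(mean1 + 0.5)
        if self.mixture == "ZIP":
            x0[self.blocks.psi.start] = logit(0.1)
        x0[self.blocks.gam.start] = np.log(meanT + 0.5)
        x0[self.blocks.omega.start] = 0.0
        x0[self.blocks.p.start] = logit(0.3)
        return x0


class SingleSeasonNMixtureModel(_NMixtureBase):
    """Closed-population N-mixture model for a single primary season."""

    def __init__(
        self,
        dataset: CountDataset,
        lambda_formula: str = "1",
        p_formula: str = "1",
        mixture: str = "ZIP",
        K: int | None = None,
    ):
        super().__init__(dataset, mixture, K)
        if self.n_seasons != 1:
            raise ValueError(
                "single-season model requires one primary season; "
                "use dataset.season_subset(season)"
            )
        self.lambda_formula = lambda_formula
        self.p_formula = p_formula
        self._design(lambda_formula, None, p_formula)

    @property
    def name(self) -> str:
        return f"lam({self.lambda_formula}) p({self.p_formula}) [{self.mixture}]"

    def loglik(self, params) -> float:
        lam, psi, _, _, p = self._unpack(params)
        if not np.all(np.isfinite(lam)):
            return -np.inf
        gdet = self._season_detection_logliks(p)[0]
        log_a = _mixture_logpmf(lam, psi, self.K)
        site_ll = logsumexp(log_a + gdet, axis=1)
        return float(site_ll.sum())

    def _start_values(self):
        x0 = np.zeros(self.blocks.k)
        mean1 = max(float(self.counts[:, 0, :].max(axis=1).mean()), 0.1)
        x0[self.blocks.lam.start] = np.log(mean1 + 0.5)
        if self.mixture == "ZIP":
            x0[self.blocks.psi.start] = logit(0.1)
        x0[self.blocks.p.start] = logit(0.3)
        return x0


# ----------------------------------------------------------------------
@dataclass
class NMixtureResults:
    """Fit results: estimates on link scales, their covariance, AICc.

    ``params`` are ordered lambda block, psi (ZIP only), gamma block,
    omega, detection block; names carry the block prefix.
    """

    model: _NMixtureBase
    params: np.ndarray
    llf: float
    vcov: np.ndarray
    converged: bool
    se_available: bool
    optimizer_message: str = ""

    @property
    def param_names(self) -> list[str]:
        return self.model.blocks.names

    @property
    def k_params(self) -> int:
        return self.params.size

    @property
    def bse(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.sqrt(np.diag(self.vcov))

    @property
    def n_eff(self) -> int:
        """Effective sample size for AICc: the number of sites."""
        return self.model.n_sites

    @property
    def aicc(self) -> float:
        from .selection import aicc

        return aicc(self.llf, self.k_params, self.n_eff)

    def params_series(self) -> pd.Series:
        return pd.Series(self.params, index=self.param_names)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        return pd.DataFrame(
            {
                "lower": self.params - z * self.bse,
                "upper": self.params + z * self.bse,
            },
            index=self.param_names,
        )

    # ------------------------------------------------------------------
    def _require_converged(self):
        if not self.converged:
            raise RuntimeError("fit did not converge; refusing derived quantities")

    def natural_params(self):
        return self.model._unpack(self.params)

    def expected_site_abundance(self, season_position: int = 0):
        """Per-site expected abundance for a season with delta-method SE.

        Season 1: E[N] = (1 - psi) * lambda_i.  Later seasons iterate
        E[N_{t+1}] = omega * E[N_t] + gamma_i.
        """
        self._require_converged()

        def site_expectation(params):
            lam, psi, gam, omega, _ = self.model._unpack(params)
            e = (1.0 - psi) * lam
            for _t in range(season_position):
                e = omega * e + gam
            return e

        est = site_expectation(self.params)
        if not self.se_available:
            return est, np.full_like(est, np.nan)
        from statsmodels.tools.numdiff import approx_fprime

        G = approx_fprime(self.params, site_expectation)  # (n_sites, k)
        var = np.einsum("ik,kl,il->i", G, self.vcov, G)
        return est, np.sqrt(np.clip(var, 0.0, None))

    def mean_abundance(self, season_position: int = 0):
        """Expected abundance for an average site, with delta-method SE."""
        self._require_converged()

        def mean_expectation(params):
            lam, psi, gam, omega, _ = self.model._unpack(params)
            e = (1.0 - psi) * lam
            for _t in range(season_position):
                e = omega * e + gam
            return float(np.mean(e))

        est = mean_expectation(self.params)
        if not self.se_available:
            return est, np.nan
        from statsmodels.tools.numdiff import approx_fprime

        g = approx_fprime(np.asarray(self.params), mean_expectation).ravel()
        var = float(g @ self.vcov @ g)
        return est, float(np.sqrt(max(var, 0.0)))

    def detection_matrix(self) -> np.ndarray:
        """Fitted per-visit detection probabilities (n_sites, T, J)."""
        return self.model._unpack(self.params)[4]

    def expected_counts(self) -> np.ndarray:
        """E[n_itj] = E[N_it] * p_itj, used by the chi-square GOF statistic."""
        lam, psi, gam, omega, p = self.model._unpack(self.params)
        e = (1.0 - psi) * lam
        out = np.empty_like(p)
        for t in range(self.model.n_seasons):
            if t > 0:
                e = omega * e + gam
            out[:, t, :] = e[:, None] * p[:, t, :]
        return out

    # ------------------------------------------------------------------
    def simulate(self, rng: np.random.Generator) -> CountDataset:
        """Draw a replicate dataset from the fitted model (same covariates)."""
        lam, psi, gam, omega, p = self.model._unpack(self.params)
        n_sites = self.model.n_sites
        N = np.zeros((n_sites, self.model.n_seasons), dtype=int)
        nonzero = rng.random(n_sites) >= psi
        N[:, 0] = np.where(nonzero, rng.poisson(lam), 0)
        for t in range(1, self.model.n_seasons):
            N[:, t] = rng.binomial(N[:, t - 1], omega) + rng.poisson(gam)
        counts = rng.binomial(
            N[:, :, None], np.clip(p, 0.0, 1.0)
        )  # (n_sites, T, J)
        visits = self.model.dataset.merged_visit_table().copy()
        # canonical order matches count_array: site-major, then season, visit
        visits = visits[self.model.dataset.visits.columns]
        visits["count"] = counts.reshape(-1)
        return CountDataset(visits, self.model.dataset.sites.copy(),
                            dict(self.model.dataset.centering))

    def refit_to(self, dataset: CountDataset, starts: int = 1, seed: int = 0,
                 x0: np.ndarray | None = None, hessian: bool = True):
        """Fit the same model specification to another dataset."""
        if isinstance(self.model, DynamicNMixtureModel):
            m = DynamicNMixtureModel(
                dataset,
                self.model.lambda_formula,
                self.model.gamma_formula,
                self.model.p_formula,
                self.model.mixture,
                self.model.K,
            )
        else:
            m = SingleSeasonNMixtureModel(
                dataset,
                self.model.lambda_formula,
                self.model.p_formula,
                self.model.mixture,
                self.model.K,
            )
        return m.fit(starts=starts, seed=seed, x0=x0, hessian=hessian)

    def truncation_stable(self, increment: int = 50, tol: float = 1e-6) -> bool:
        """Check that enlarging K by ``increment`` moves the loglik < tol."""
        model = self.model
        if isinstance(model, DynamicNMixtureModel):
            bigger = DynamicNMixtureModel(
                model.dataset,
                model.lambda_formula,
                model.gamma_formula,
                model.p_formula,
                model.mixture,
                model.K + increment,
            )
        else:
            bigger = SingleSeasonNMixtureModel(
                model.dataset,
                model.lambda_formula,
                model.p_formula,
                model.mixture,
                model.K + increment,
            )
        return abs(bigger.loglik(self.params) - self.llf) < tol

    def summary(self) -> str:
        ci = self.conf_int()
        rows = []
        for i, name in enumerate(self.param_names):
            rows.append(
                f"{name:<28s} {self.params[i]:>9.4f} {self.bse[i]:>8.4f} "
                f"[{ci['lower'].iloc[i]:>8.4f}, {ci['upper'].iloc[i]:>8.4f}]"
            )
        head = (
            f"{self.model.name}\n"
            f"loglik = {self.llf:.3f}   K_par = {self.k_params}   "
            f"AICc = {self.aicc:.2f}   converged = {self.converged}\n"
            f"{'parameter':<28s} {'estimate':>9s} {'SE':>8s}  95% CI (link scale)"
        )
        return head + "\n" + "\n".join(rows)
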