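"""Capture–mark–recapture comparators: Huggins closed-population and
Cormack–Jolly–Seber (CJS) models on pooled encounter histories.

The Huggins estimator conditions on capture, so abundance drops out of
the likelihood and covariates can act on capture probability; abundance
is recovered by Horvitz–Thompson, ``N_hat = sum_i 1 / p*_i`` with
``p*_i`` the probability of being caught at least once.

The CJS model estimates apparent survival and recapture probability
conditional on first capture.  Unequal intervals between occasions are
handled by raising the per-unit (annual) survival to the interval
length, or by giving each distinct interval length its own survival
parameter ("interval-equal" structure).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit

from .data import CaptureHistorySet

__all__ = ["HugginsModel", "HugginsResults", "CJSModel", "CJSResults"]


def _polish(nll, best):
    """Derivative-free polish to push the optimum to ~1e-8 in the
    parameters (quasi-Newton stops earlier on these flat surfaces)."""
    res = optimize.minimize(
        nll, best.x, method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-13, "maxiter": 2000},
    )
    if res.fun <= best.fun:
        res.success = bool(best.success or res.success)
        return res
    return best


def _hessian_vcov(nll, params):
    from statsmodels.tools.numdiff import approx_hess1

    with np.errstate(all="ignore"):
        H = approx_hess1(np.asarray(params, dtype=float), nll)
    try:
        sym = (H + H.T) / 2.0
        if np.isfinite(sym).all() and np.min(np.linalg.eigvalsh(sym)) > 0:
            return np.linalg.inv(sym), True
    except np.linalg.LinAlgError:
        pass
    return np.full((len(params), len(params)), np.nan), False


# ----------------------------------------------------------------------
class HugginsModel:
    """Huggins conditional-likelihood closed-population model.

    Parameters
    ----------
    histories : CaptureHistorySet
        Encounter histories over the occasions of one closed period
        (two visits in this study's design).
    p_model : {"M0", "Mt"} or formula string
        "M0": one capture probability; "Mt": one per occasion; a
        formula is evaluated over site covariates carried by each
        individual (capture probability constant over occasions).
    site_covariates : DataFrame, optional
        Per-site covariate table, required for formula models.
    """

    def __init__(self, histories: CaptureHistorySet, p_model: str = "M0",
                 site_covariates: pd.DataFrame | None = None):
        self.histories = histories
        self.p_model = p_model
        self.y = histories.histories
        self.n_ind, self.n_occ = self.y.shape
        if p_model == "M0":
            self.X = None
            self.param_names = ["p_(Intercept)"]
            self.k_params = 1
        elif p_model == "Mt":
            self.X = None
            self.param_names = [f"p_occ{j + 1}" for j in range(self.n_occ)]
            self.k_params = self.n_occ
        else:
            if site_covariates is None:
                raise ValueError("formula p_model needs site_covariates")
            from .formula import build_design_matrix

            tbl = histories.individuals.merge(site_covariates, on="site", how="left")
            self.X, names = build_design_matrix(tbl, p_model)
            self.param_names = [f"p_{n}" for n in names]
            self.k_params = self.X.shape[1]

    def _capture_probs(self, params) -> np.ndarray:
        """(n_ind, n_occ) capture probabilities."""
        params = np.asarray(params, dtype=float)
        if self.p_model == "M0":
            return np.full((self.n_ind, self.n_occ), expit(params[0]))
        if self.p_model == "Mt":
            return np.tile(expit(params)[None, :], (self.n_ind, 1))
        p = expit(self.X @ params)
        return np.tile(p[:, None], (1, self.n_occ))

    def loglik(self, params) -> float:
        """Conditional-on-capture log-likelihood."""
        p = np.clip(self._capture_probs(params), 1e-12, 1 - 1e-12)
        ll = np.sum(self.y * np.log(p) + (1 - self.y) * np.log1p(-p))
        pstar = 1.0 - np.prod(1.0 - p, axis=1)
        return float(ll - np.sum(np.log(pstar)))

    def fit(self, starts: int = 1, seed: int = 0) -> "HugginsResults":
        rng = np.random.default_rng(seed)
        x0 = np.full(self.k_params, logit(np.clip(self.y.mean(), 0.05, 0.95)))
        if self.p_model not in {"M0", "Mt"}:
            x0 = np.zeros(self.k_params)
            x0[0] = logit(np.clip(self.y.mean(), 0.05, 0.95))

        def nll(b):
            v = self.loglik(b)
            return np.inf if not np.isfinite(v) else -v

        best = None
        for s in range(max(1, starts)):
            init = x0 if s == 0 else x0 + rng.normal(0, 0.3, x0.size)
            res = optimize.minimize(nll, init, method="L-BFGS-B",
                                    options={"ftol": 1e-14, "gtol": 1e-10})
            if best is None or res.fun < best.fun:
                best = res
        best = _polish(nll, best)
        vcov, se_ok = _hessian_vcov(nll, best.x)
        return HugginsResults(self, best.x, -best.fun, vcov, bool(best.success), se_ok)


@dataclass
class HugginsResults:
    """Huggins fit with Horvitz–Thompson abundance."""

    model: HugginsModel
    params: np.ndarray
    llf: float
    vcov: np.ndarray
    converged: bool
    se_available: bool

    @property
    def param_names(self):
        return self.model.param_names

    @property
    def k_params(self) -> int:
        return self.params.size

    @property
    def bse(self):
        with np.errstate(invalid="ignore"):
            return np.sqrt(np.diag(self.vcov))

    def pstar(self, params=None) -> np.ndarray:
        """Per-individual probability of at least one capture."""
        p = self.model._capture_probs(self.params if params is None else params)
        return 1.0 - np.prod(1.0 - p, axis=1)

    def abundance(self) -> tuple[float, float]:
        """Horvitz–Thompson abundance with its SE.

        Variance combines the HT component sum (1 - p*) / p*^2 with the
        delta-method contribution of the estimated capture parameters.
        """
        ps = self.pstar()
        if np.any(ps < 1e-8):
            raise RuntimeError("capture probability near zero: unstable estimate")
        n_hat = float(np.sum(1.0 / ps))
        var_ht = float(np.sum((1.0 - ps) / ps**2))
        from statsmodels.tools.numdiff import approx_fprime

        g = approx_fprime(
            np.asarray(self.params, dtype=float),
            lambda b: float(np.sum(1.0 / np.clip(self.pstar(b), 1e-12, 1.0))),
        ).ravel()
        var_par = float(g @ self.vcov @ g) if self.se_available else np.nan
        return n_hat, float(np.sqrt(var_ht + var_par))

    def abundance_per_site(self, n_sites: int) -> tuple[float, float]:
        n_hat, se = self.abundance()
        return n_hat / n_sites, se / n_sites

    def summary(self) -> str:
        n_hat, se = self.abundance()
        lines = [
            f"Huggins({self.model.p_model})  loglik = {self.llf:.3f}",
            f"N_hat = {n_hat:.2f} (SE {se:.2f}); "
            f"{self.model.n_ind} distinct individuals",
        ]
        for name, b, s in zip(self.param_names, self.params, self.bse):
            lines.append(f"  {name:<18s} {b:>9.4f} (SE {s:.4f})  p = {expit(b):.4f}")
        return "\n".join(lines)


# ----------------------------------------------------------------------
class CJSModel:
    """Cormack–Jolly–Seber model with unequal inter-occasion intervals.

    phi_structure:
        "constant" — one annual apparent-survival parameter phi; the
        survival over an interval of length d years is phi**d.
        "interval-equal" — one survival parameter per distinct interval
        length (intervals of the same length share a parameter).
    p_structure:
        "year-dependent" — one recapture probability per year group of
        occasions (occasions closer than one year are grouped);
        "constant" — a single recapture probability.
    """

    def __init__(self, histories: CaptureHistorySet,
                 phi_structure: str = "constant",
                 p_structure: str = "year-dependent"):
        if histories.n_occasions < 3:
            raise ValueError(
                "CJS with free survival and recapture needs >= 3 occasions"
            )
        if phi_structure not in {"constant", "interval-equal"}:
            raise ValueError(f"unknown phi_structure {phi_structure!r}")
        if p_structure not in {"year-dependent", "constant"}:
            raise ValueError(f"unknown p_structure {p_structure!r}")
        self.histories = histories
        self.phi_structure = phi_structure
        self.p_structure = p_structure
        self.intervals = histories.intervals
        # collapse identical histories for speed
        hist_strings = ["".join(map(str, row)) for row in histories.histories]
        uniq, counts = np.unique(hist_strings, return_counts=True)
        self.uniq_hist = np.array([[int(c) for c in h] for h in uniq])
        self.uniq_mult = counts.astype(float)

        if phi_structure == "interval-equal":
            levels = np.unique(np.round(self.intervals, 9))
            self._phi_map = np.searchsorted(levels, np.round(self.intervals, 9))
            self._n_phi = len(levels)
            self._phi_levels = levels
        else:
            self._phi_map = None
            self._n_phi = 1
            self._phi_levels = None
        if p_structure == "year-dependent":
            groups = np.zeros(histories.n_occasions, dtype=int)
            g = 0
            for t in range(1, histories.n_occasions):
                if self.intervals[t - 1] >= 1.0:
                    g += 1
                groups[t] = g
            # recapture applies to occasions 2..T; parameters indexed by
            # the year groups represented there
            recap_groups = groups[1:]
            levels = np.unique(recap_groups)
            self._p_map = np.searchsorted(levels, recap_groups)
            self._n_p = len(levels)
        else:
            self._p_map = np.zeros(histories.n_occasions - 1, dtype=int)
            self._n_p = 1
        self.param_names = [f"phi_{i + 1}" for i in range(self._n_phi)] + [
            f"p_{i + 1}" for i in range(self._n_p)
        ]
        self.k_params = self._n_phi + self._n_p

    def _interval_survival(self, params) -> np.ndarray:
        """Survival probability over each of the T-1 intervals."""
        if self.phi_structure == "constant":
            phi = expit(params[0])
            return phi ** self.intervals
        s = expit(np.asarray(params[: self._n_phi]))
        return s[self._phi_map]

    def _recapture_probs(self, params) -> np.ndarray:
        """Recapture probability at occasions 2..T."""
        p = expit(np.asarray(params[self._n_phi :]))
        return p[self._p_map]

    def loglik(self, params) -> float:
        """Conditional-on-first-capture log-likelihood."""
        params = np.asarray(params, dtype=float)
        s = np.clip(self._interval_survival(params), 1e-12, 1 - 1e-12)
        p = np.clip(self._recapture_probs(params), 1e-12, 1 - 1e-12)
        T = self.histories.n_occasions
        # chi[t] = P(never seen after occasion t | alive at t), 0-indexed
        chi = np.ones(T)
        for t in range(T - 2, -1, -1):
            chi[t] = (1.0 - s[t]) + s[t] * (1.0 - p[t]) * chi[t + 1]
        total = 0.0
        for h, mult in zip(self.uniq_hist, self.uniq_mult):
            ones = np.flatnonzero(h)
            f, last = ones[0], ones[-1]
            ll = 0.0
            for t in range(f, last):
                ll += np.log(s[t])
                ll += np.log(p[t]) if h[t + 1] else np.log1p(-p[t])
            ll += np.log(chi[last])
            total += mult * ll
        return float(total)

    def fit(self, starts: int = 1, seed: int = 0) -> "CJSResults":
        rng = np.random.default_rng(seed)
        x0 = np.zeros(self.k_params)

        def nll(b):
            v = self.loglik(b)
            return np.inf if not np.isfinite(v) else -v

        best = None
        for srt in range(max(1, starts)):
            init = x0 if srt == 0 else x0 + rng.normal(0, 0.5, x0.size)
            res = optimize.minimize(nll, init, method="L-BFGS-B",
                                    options={"ftol": 1e-14, "gtol": 1e-10})
            if best is None or res.fun < best.fun:
                best = res
        best = _polish(nll, best)
        vcov, se_ok = _hessian_vcov(nll, best.x)
        return CJSResults(self, best.x, -best.fun, vcov, bool(best.success), se_ok)


@dataclass
class CJSResults:
    """CJS fit: apparent survival and recapture probabilities."""

    model: CJSModel
    params: np.ndarray
    llf: float
    vcov: np.ndarray
    converged: bool
    se_available: bool

    @property
    def param_names(self):
        return self.model.param_names

    @property
    def k_params(self) -> int:
        return self.params.size

    @property
    def bse(self):
        with np.errstate(invalid="ignore"):
            return np.sqrt(np.diag(self.vcov))

    @property
    def annual_survival(self) -> float:
        """Per-unit-time apparent survival (constant structure only)."""
        if self.model.phi_structure != "constant":
            raise ValueError("annual survival defined for the constant structure")
        return float(expit(self.params[0]))

    def interval_survival(self) -> np.ndarray:
        """Apparent survival over each inter-occasion interval."""
        return self.model._interval_survival(self.params)

    def interval_survival_se(self) -> np.ndarray:
        """Delta-method SEs of the interval survivals."""
        from statsmodels.tools.numdiff import approx_fprime

        G = approx_fprime(
            np.asarray(self.params, dtype=float),
            lambda b: self.model._interval_survival(np.asarray(b)),
        )
        var = np.einsum("ik,kl,il->i", np.atleast_2d(G), self.vcov, np.atleast_2d(G))
        return np.sqrt(np.clip(var, 0.0, None))

    def recapture_probs(self) -> np.ndarray:
        return self.model._recapture_probs(self.params)

    def summary(self) -> str:
        lines = [
            f"CJS(phi={self.model.phi_structure}, p={self.model.p_structure})  "
            f"loglik = {self.llf:.3f}"
        ]
        for name, b, s in zip(self.param_names, self.params, self.bse):
            lines.append(
                f"  {name:<10s} {b:>9.4f} (SE {s:.4f})  prob = {expit(b):.4f}"
            )
        surv = ", ".join(f"{x:.4f}" for x in self.interval_survival())
        lines.append(f"  interval survival: {surv}")
        return "\n".join(lines)
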