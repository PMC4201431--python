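"""AICc multimodel inference and parametric-bootstrap goodness of fit.

Models are ranked by the small-sample Akaike criterion
``AICc = -2 loglik + 2K + 2K(K+1)/(n - K - 1)`` with the number of sites
as the effective sample size.  Akaike weights give the relative support
of each candidate; coefficients and predictions are model-averaged with
unconditional standard errors that add the between-model spread to the
within-model variance (Burnham–Anderson formula).

Goodness of fit uses the chi-square discrepancy between observed counts
and their fitted expectations ``E[n_itj] = E[N_it] p_itj``, calibrated
by a parametric bootstrap: replicate datasets are simulated from the
fitted model at its MLE, refitted (or evaluated plug-in), and the
p-value is the fraction of replicate statistics at least as large as
the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import CountDataset
from .formula import build_design_matrix
from .nmix import NMixtureResults

__all__ = [
    "aicc",
    "akaike_weights",
    "model_average_parameter",
    "AveragedEstimate",
    "ModelSet",
    "chisq_stat",
    "parametric_bootstrap_gof",
    "GofResult",
]

_Z95 = 1.959963984540054


def aicc(loglik: float, k_params: int, n_eff: int) -> float:
    """Second-order (small-sample corrected) Akaike information criterion."""
    if n_eff <= k_params + 1:
        raise ValueError(
            f"AICc undefined: effective sample size {n_eff} <= K + 1 = {k_params + 1}"
        )
    return -2.0 * loglik + 2.0 * k_params + 2.0 * k_params * (k_params + 1) / (
        n_eff - k_params - 1
    )


def akaike_weights(aicc_values) -> np.ndarray:
    """Akaike weights w_i = exp(-delta_i / 2) / sum_j exp(-delta_j / 2)."""
    a = np.asarray(aicc_values, dtype=float)
    if a.size < 1:
        raise ValueError("need at least one model")
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


@dataclass
class AveragedEstimate:
    """A model-averaged estimate with its unconditional SE and Wald 95% CI."""

    value: float
    se_unconditional: float
    ci95: tuple[float, float]

    @property
    def excludes_zero(self) -> bool:
        return self.ci95[0] > 0.0 or self.ci95[1] < 0.0


def model_average_parameter(estimates, ses, weights) -> AveragedEstimate:
    """Model-average aligned estimates with unconditional SE.

    ``SE_unc = sum_i w_i sqrt(se_i^2 + (theta_i - theta_bar)^2)``.
    With shrinkage averaging, models lacking the coefficient contribute
    estimate 0 with SE 0; callers align the inputs accordingly.
    """
    theta = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    w = np.asarray(weights, dtype=float)
    if not (theta.shape == se.shape == w.shape):
        raise ValueError("estimates, ses and weights must have equal length")
    w = w / w.sum()
    avg = float(np.sum(w * theta))
    se_unc = float(np.sum(w * np.sqrt(se**2 + (theta - avg) ** 2)))
    return AveragedEstimate(avg, se_unc, (avg - _Z95 * se_unc, avg + _Z95 * se_unc))


def _predict_response(fit: NMixtureResults, param: str, table: pd.DataFrame):
    """Response-scale prediction of lambda, gamma or p at new covariates.

    Returns (values, delta-method SEs).  Covariates must be on the same
    (centered) scale as the training data; use the dataset's
    ``centering`` offsets to convert raw values.
    """
    blocks = fit.model.blocks
    if param == "lambda":
        X, _ = build_design_matrix(table, fit.model.lambda_formula)
        sl = blocks.lam
        inv, dinv = np.exp, np.exp
    elif param == "gamma":
        X, _ = build_design_matrix(table, fit.model.gamma_formula)
        sl = blocks.gam
        inv, dinv = np.exp, np.exp
    elif param == "p":
        X, _ = build_design_matrix(table, fit.model.p_formula)
        sl = blocks.p
        inv = expit
        dinv = lambda eta: expit(eta) * (1.0 - expit(eta))  # noqa: E731
    else:
        raise ValueError(f"unknown parameter {param!r}")
    beta = fit.params[sl]
    V = fit.vcov[sl, sl]
    eta = X @ beta
    vals = inv(eta)
    grad = dinv(eta)[:, None] * X
    var = np.einsum("ik,kl,il->i", grad, V, grad)
    return vals, np.sqrt(np.clip(var, 0.0, None))


class ModelSet:
    """A ranked set of fitted candidate models sharing one dataset.

    Provides the AICc table (model, K, AICc, dAICc, w), model-averaged
    coefficients with unconditional SEs, and model-averaged
    response-scale predictions.
    """

    def __init__(self, fits: list[NMixtureResults], names: list[str] | None = None):
        if not fits:
            raise ValueError("empty model set")
        self.fits = list(fits)
        self.names = list(names) if names is not None else [f.model.name for f in fits]
        aiccs = np.array([f.aicc for f in self.fits])
        order = np.argsort(aiccs)
        self.fits = [self.fits[i] for i in order]
        self.names = [self.names[i] for i in order]
        self.aiccs = aiccs[order]
        self.weights = akaike_weights(self.aiccs)

    @property
    def best(self) -> NMixtureResults:
        return self.fits[0]

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Model": self.names,
                "K": [f.k_params for f in self.fits],
                "AICc": self.aiccs,
                "dAICc": self.aiccs - self.aiccs[0],
                "w": self.weights,
            }
        )

    def average_coefficient(self, name: str, shrinkage: bool = False) -> AveragedEstimate:
        """Model-average one named coefficient across the set.

        Without shrinkage (the default for inference on "variables in
        the supported models") weights are renormalised over the models
        that contain the coefficient; with shrinkage, absent models
        contribute zero.
        """
        est, se, w = [], [], []
        for fit, weight in zip(self.fits, self.weights):
            if name in fit.param_names:
                i = fit.param_names.index(name)
                est.append(fit.params[i])
                se.append(fit.bse[i])
                w.append(weight)
            elif shrinkage:
                est.append(0.0)
                se.append(0.0)
                w.append(weight)
        if not est:
            raise KeyError(f"coefficient {name!r} appears in no model")
        return model_average_parameter(est, se, w)

    def average_predictions(self, param: str, table: pd.DataFrame):
        """Model-averaged response-scale predictions with unconditional SE."""
        vals = []
        ses = []
        for fit in self.fits:
            v, s = _predict_response(fit, param, table)
            vals.append(v)
            ses.append(s)
        vals = np.array(vals)  # (n_models, n_rows)
        ses = np.array(ses)
        w = self.weights[:, None]
        avg = np.sum(w * vals, axis=0)
        se_unc = np.sum(w * np.sqrt(ses**2 + (vals - avg[None, :]) ** 2), axis=0)
        return avg, se_unc

    def average_mean_abundance(self, season_position: int = 0) -> AveragedEstimate:
        """Model-averaged expected abundance of an average site.

        The point estimate averages every model; the unconditional SE is
        computed over the models whose Hessian-based SEs are available
        (weights renormalised), since a boundary fit with a singular
        Hessian contributes an estimate but no within-model variance.
        If no model has an SE the uncertainty is reported as NaN.
        """
        est, se = [], []
        for fit in self.fits:
            e, s = fit.mean_abundance(season_position)
            est.append(e)
            se.append(s)
        est = np.asarray(est, dtype=float)
        se = np.asarray(se, dtype=float)
        value = float(np.sum(self.weights * est) / self.weights.sum())
        ok = np.isfinite(se)
        if not ok.any():
            return AveragedEstimate(value, np.nan, (np.nan, np.nan))
        w = self.weights[ok] / self.weights[ok].sum()
        se_unc = float(np.sum(w * np.sqrt(se[ok] ** 2 + (est[ok] - value) ** 2)))
        return AveragedEstimate(
            value, se_unc, (value - _Z95 * se_unc, value + _Z95 * se_unc)
        )


# ----------------------------------------------------------------------
def chisq_stat(dataset: CountDataset, fit: NMixtureResults, eps: float = 1e-8) -> float:
    """Chi-square discrepancy sum_(i,t,j) (n - E[n])^2 / max(E[n], eps)."""
    model_counts = dataset.count_array().astype(float)
    expected = fit.expected_counts()
    return float(np.sum((model_counts - expected) ** 2 / np.maximum(expected, eps)))


@dataclass
class GofResult:
    """Parametric-bootstrap goodness-of-fit summary."""

    t_obs: float
    t_boot: np.ndarray
    refit: bool

    @property
    def p_value(self) -> float:
        """Pr(T_b >= T_obs) across bootstrap replicates."""
        return float(np.mean(self.t_boot >= self.t_obs))

    @property
    def p_value_plus_one(self) -> float:
        """(1 + #{T_b >= T_obs}) / (1 + B) variant, never exactly 0."""
        return float((1 + np.sum(self.t_boot >= self.t_obs)) / (1 + self.t_boot.size))


def parametric_bootstrap_gof(
    fit: NMixtureResults,
    B: int = 5000,
    seed: int = 0,
    refit: bool = True,
    starts: int = 1,
) -> GofResult:
    """Parametric bootstrap of the chi-square statistic.

    Replicate datasets are simulated from the fitted model at its MLE.
    With ``refit=True`` (full parametric bootstrap) each replicate is
    refitted before computing its statistic; the plug-in mode skips the
    refit and evaluates the statistic at the generating MLE, which is
    much cheaper but conservative.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    t_obs = chisq_stat(fit.model.dataset, fit)
    t_boot = np.empty(B)
    for b in range(B):
        sim = fit.simulate(rng)
        if refit:
            fb = fit.refit_to(sim, starts=starts, seed=int(rng.integers(2**31 - 1)),
                              x0=fit.params, hessian=False)
            t_boot[b] = chisq_stat(sim, fb)
        else:
            plug = NMixtureResults(
                model=type(fit.model)(
                    sim,
                    **_model_kwargs(fit.model),
                ),
                params=fit.params,
                llf=np.nan,
                vcov=fit.vcov,
                converged=True,
                se_available=False,
            )
            t_boot[b] = chisq_stat(sim, plug)
    return GofResult(t_obs, t_boot, refit)


def _model_kwargs(model) -> dict:
    from .nmix import DynamicNMixtureModel

    kw = {
        "lambda_formula": model.lambda_formula,
        "p_formula": model.p_formula,
        "mixture": model.mixture,
        "K": model.K,
    }
    if isinstance(model, DynamicNMixtureModel):
        kw["gamma_formula"] = model.gamma_formula
    return kw
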