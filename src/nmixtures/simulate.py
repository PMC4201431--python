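"""Synthetic BACI trapping data with the structure the estimators assume.

The generator emulates a two-season (before/after) robust design: 56
forest sites, 29 of which receive a nest-box treatment between seasons,
two secondary visits per season, counts of unique individuals per
visit, and a matched individual-level capture-history simulation so the
capture–mark–recapture comparators can be tested against the same
latent truth.

Covariates are drawn from right-skewed gamma distributions calibrated
to the study's printed means and ranges (snag basal area mean 3.4
m²/ha, range ~0-13; conifer basal area mean 1.4 m²/ha, range ~0-6;
per-visit precipitation means 6.2/7.3 mm before and 5.4/12.2 mm after).
Truth coefficients act on covariates centered at their realised sample
means, mirroring the analysis pipeline, which centers before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import CaptureHistorySet, CountDataset
from .formula import build_design_matrix

__all__ = [
    "SimScenario",
    "simulate_covariates",
    "simulate_latent_dynamics",
    "simulate_counts",
    "simulate_capture_histories",
    "simulate_study",
    "study_scenario",
]


@dataclass
class SimScenario:
    """Generative truth for a before/after control-impact count study.

    Coefficient dictionaries map formula terms to link-scale values:
    log link for initial abundance ``lambda`` and recruitment ``gamma``,
    logit for detection ``p``; ``psi`` is the zero-inflation weight of
    the season-1 abundance distribution and ``omega`` the apparent
    survival over the single between-season transition.
    """

    n_sites: int = 56
    n_treated: int = 29
    n_seasons: int = 2
    n_visits: int = 2
    lambda_coefs: dict = field(default_factory=lambda: {"(Intercept)": 1.0})
    psi: float = 0.0
    gamma_coefs: dict = field(default_factory=lambda: {"(Intercept)": 1.0})
    omega: float = 0.5
    p_coefs: dict = field(default_factory=lambda: {"(Intercept)": 0.0})
    # covariate generators
    snag_shape: float = 2.0
    snag_scale: float = 1.7
    conifer_shape: float = 1.5
    conifer_scale: float = 14.0 / 15.0
    precip_means: tuple = ((6.2, 7.3), (5.4, 12.2))  # [season][visit] mm
    precip_shape: float = 2.0
    julian_ranges: tuple = ((250, 290), (291, 335))  # [visit] day-of-year
    occasion_times: tuple = (0.0, 0.08, 4.08, 4.16)  # years

    def __post_init__(self) -> None:
        if self.n_treated > self.n_sites:
            raise ValueError("n_treated must not exceed n_sites")
        if not (0.0 <= self.psi < 1.0):
            raise ValueError("psi must lie in [0, 1)")
        if not (0.0 <= self.omega <= 1.0):
            raise ValueError("omega must lie in [0, 1]")

    # ------------------------------------------------------------------
    def truth(self) -> dict:
        """Flat link-scale truth dictionary for recovery tests."""
        out = {f"lam_{k}": v for k, v in self.lambda_coefs.items()}
        out["psi"] = self.psi
        out.update({f"gam_{k}": v for k, v in self.gamma_coefs.items()})
        out["omega"] = self.omega
        out.update({f"p_{k}": v for k, v in self.p_coefs.items()})
        return out


def _coef_eta(table: pd.DataFrame, coefs: dict) -> np.ndarray:
    """Linear predictor from a term->value dict over a covariate table."""
    formula = " + ".join(k for k in coefs if k != "(Intercept)")
    X, names = build_design_matrix(table, formula if formula else "1")
    beta = np.array([coefs.get(n, 0.0) for n in names])
    return X @ beta


def _centered(table: pd.DataFrame, names: list[str]) -> pd.DataFrame:
    out = table.copy()
    for n in names:
        if n in out.columns:
            out[n] = out[n] - out[n].mean()
    return out


def simulate_covariates(scenario: SimScenario, rng: np.random.Generator):
    """Draw the site and visit covariate tables (no counts yet)."""
    n = scenario.n_sites
    snag = rng.gamma(scenario.snag_shape, scenario.snag_scale, size=n)
    conifer = rng.gamma(scenario.conifer_shape, scenario.conifer_scale, size=n)
    boxes = np.zeros(n, dtype=int)
    boxes[rng.choice(n, size=scenario.n_treated, replace=False)] = 1
    sites = pd.DataFrame(
        {
            "site": [f"S{i + 1:03d}" for i in range(n)],
            "snag_ba": snag,
            "conifer_ba": conifer,
            "boxes": boxes,
        }
    )
    rows = []
    for i in range(n):
        for t in range(scenario.n_seasons):
            for j in range(scenario.n_visits):
                mean_p = scenario.precip_means[min(t, len(scenario.precip_means) - 1)][
                    min(j, scenario.n_visits - 1)
                ]
                lo, hi = scenario.julian_ranges[min(j, len(scenario.julian_ranges) - 1)]
                rows.append(
                    {
                        "site": sites["site"].iloc[i],
                        "season": t + 1,
                        "visit": j + 1,
                        "precip": rng.gamma(
                            scenario.precip_shape, mean_p / scenario.precip_shape
                        ),
                        "julian_day": float(rng.integers(lo, hi + 1)),
                        # trap height alternates between visits (reversed layout)
                        "height": (i + j) % 2,
                        "year": t,
                    }
                )
    visits = pd.DataFrame(rows)
    return sites, visits


def simulate_latent_dynamics(
    scenario: SimScenario, sites: pd.DataFrame, rng: np.random.Generator
) -> np.ndarray:
    """Latent abundance per site × season under ZIP initial state and
    binomial-survival + Poisson-recruitment dynamics."""
    sites_c = _centered(sites, ["snag_ba", "conifer_ba"])
    lam = np.exp(_coef_eta(sites_c, scenario.lambda_coefs))
    gam = np.exp(_coef_eta(sites_c, scenario.gamma_coefs))
    n = scenario.n_sites
    N = np.zeros((n, scenario.n_seasons), dtype=int)
    occupied = rng.random(n) >= scenario.psi
    N[:, 0] = np.where(occupied, rng.poisson(lam), 0)
    for t in range(1, scenario.n_seasons):
        N[:, t] = rng.binomial(N[:, t - 1], scenario.omega) + rng.poisson(gam)
    return N


def detection_probs(
    scenario: SimScenario, sites: pd.DataFrame, visits: pd.DataFrame
) -> np.ndarray:
    """Per-visit detection probabilities, (n_sites, T, J), in table order."""
    merged = visits.merge(sites, on="site", how="left")
    merged = _centered(merged, ["precip", "julian_day", "snag_ba", "conifer_ba"])
    eta = _coef_eta(merged, scenario.p_coefs)
    return expit(eta).reshape(scenario.n_sites, scenario.n_seasons, scenario.n_visits)


def simulate_counts(
    scenario: SimScenario,
    latent: np.ndarray,
    sites: pd.DataFrame,
    visits: pd.DataFrame,
    rng: np.random.Generator,
) -> CountDataset:
    """Binomial thinning of latent abundance into per-visit counts."""
    p = detection_probs(scenario, sites, visits)
    counts = rng.binomial(latent[:, :, None], p)
    out = visits.copy()
    out["count"] = counts.reshape(-1)
    return CountDataset(out, sites)


def simulate_capture_histories(
    scenario: SimScenario,
    latent_n1: np.ndarray,
    sites: pd.DataFrame,
    visits: pd.DataFrame,
    rng: np.random.Generator,
) -> CaptureHistorySet:
    """Individual-level twin of the count simulation.

    Each season-1 resident gets Bernoulli(p) detections on the two 2008
    occasions, survives the transition with probability omega, and if
    surviving gets Bernoulli(p) detections on the two 2012 occasions.
    Recruits (Poisson per site, matching the recruitment rate) have
    all-zero 2008 history.  Only individuals captured at least once are
    returned, as in real trapping data.
    """
    sites_c = _centered(sites, ["snag_ba", "conifer_ba"])
    gam = np.exp(_coef_eta(sites_c, scenario.gamma_coefs))
    p = detection_probs(scenario, sites, visits)
    rows = []
    hists = []
    for i in range(scenario.n_sites):
        site = sites["site"].iloc[i]
        n_res = int(latent_n1[i])
        n_rec = int(rng.poisson(gam[i]))
        for _ in range(n_res):
            h = np.zeros(4, dtype=int)
            h[0] = rng.random() < p[i, 0, 0]
            h[1] = rng.random() < p[i, 0, 1]
            if rng.random() < scenario.omega:
                h[2] = rng.random() < p[i, 1, 0]
                h[3] = rng.random() < p[i, 1, 1]
            if h.any():
                rows.append(site)
                hists.append(h)
        for _ in range(n_rec):
            h = np.zeros(4, dtype=int)
            h[2] = rng.random() < p[i, 1, 0]
            h[3] = rng.random() < p[i, 1, 1]
            if h.any():
                rows.append(site)
                hists.append(h)
    individuals = pd.DataFrame(
        {"individual": [f"A{k + 1:05d}" for k in range(len(rows))], "site": rows}
    )
    return CaptureHistorySet(
        individuals, np.array(hists, dtype=int), np.array(scenario.occasion_times)
    )


def simulate_study(scenario: SimScenario, seed: int = 0):
    """Full draw: covariates, latent abundance, counts, capture histories.

    Returns a dict with keys ``dataset``, ``histories``, ``latent``,
    ``sites``, ``visits`` and ``truth``.
    """
    rng = np.random.default_rng(seed)
    sites, visits = simulate_covariates(scenario, rng)
    latent = simulate_latent_dynamics(scenario, sites, rng)
    dataset = simulate_counts(scenario, latent, sites, visits, rng)
    histories = simulate_capture_histories(scenario, latent[:, 0], sites, visits, rng)
    return {
        "dataset": dataset,
        "histories": histories,
        "latent": latent,
        "sites": sites,
        "visits": visits,
        "truth": scenario.truth(),
    }


def study_scenario() -> SimScenario:
    """Default scenario calibrated to the study's reported estimates.

    Targets: mean season-1 expected abundance ~2.7 individuals per site
    with zero inflation psi ~0.2, snag slope -0.19 and conifer slope
    +0.09 on log initial abundance; recruitment ~6 individuals per site
    per transition with the reported (all near-zero) treatment slopes;
    apparent survival 0.18 over the 4-year transition; mean per-visit
    detection ~0.17 with the reported precipitation, Julian-day, year
    and trap-height effects.  The intercepts below were solved
    numerically so that the realised design-averaged means hit those
    targets under the covariate generators.
    """
    return SimScenario(
        lambda_coefs={
            "(Intercept)": 1.1246,
            "snag_ba": -0.19,
            "conifer_ba": 0.09,
        },
        psi=0.2,
        gamma_coefs={
            "(Intercept)": 1.7512,
            "boxes": 0.06,
            "snag_ba": 0.05,
            "conifer_ba": -0.11,
            "boxes:snag_ba": -0.04,
            "boxes:conifer_ba": 0.18,
        },
        omega=0.18,
        p_coefs={
            "(Intercept)": -1.8782,
            "height": -0.28,
            "precip": -0.07,
            "year": 0.54,
            "julian_day": -0.02,
            "year:precip": 0.07,
            "year:height": 0.17,
            "year:julian_day": 0.02,
        },
    )
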