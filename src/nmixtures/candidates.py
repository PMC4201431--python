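"""Default candidate model set for the BACI count analysis.

The design varies one parameter at a time to avoid over-parameterising
relative to the number of sites: initial-abundance structures are
crossed with the detection structures while recruitment stays constant,
and recruitment structures are crossed with the detection structures
while initial abundance stays constant.  Apparent survival is constant
throughout.  Candidate sets can also be declared in YAML as a list of
{name, lambda, gamma, p} mappings.
"""

from __future__ import annotations

from .data import CountDataset
from .nmix import DynamicNMixtureModel

__all__ = [
    "LAMBDA_STRUCTURES",
    "GAMMA_STRUCTURES",
    "P_STRUCTURES",
    "default_candidates",
    "candidates_from_yaml",
    "build_models",
]

LAMBDA_STRUCTURES = ["1", "snag_ba", "conifer_ba", "snag_ba + conifer_ba"]
GAMMA_STRUCTURES = ["boxes", "boxes*snag_ba", "boxes*conifer_ba"]
P_STRUCTURES = [
    "year + height + precip + julian_day",
    "precip + julian_day + year*height",
    "year*precip + year*julian_day + height",
    "year*precip + year*julian_day + year*height",
    "snag_ba + conifer_ba",
]


def default_candidates() -> list[dict]:
    """The one-parameter-at-a-time candidate list (35 models incl. null)."""
    out = []
    for lam in LAMBDA_STRUCTURES:
        for p in P_STRUCTURES:
            out.append({"lambda": lam, "gamma": "1", "p": p})
    for gam in GAMMA_STRUCTURES:
        for p in P_STRUCTURES:
            out.append({"lambda": "1", "gamma": gam, "p": p})
    for m in out:
        m["name"] = _name(m)
    return out


def _name(m: dict) -> str:
    return f"lam({m['lambda']}) gam({m['gamma']}) p({m['p']})"


def candidates_from_yaml(path) -> list[dict]:
    import yaml

    with open(path) as fh:
        spec = yaml.safe_load(fh)
    out = []
    for m in spec:
        entry = {
            "lambda": str(m.get("lambda", "1")),
            "gamma": str(m.get("gamma", "1")),
            "p": str(m.get("p", "1")),
        }
        entry["name"] = m.get("name", _name(entry))
        out.append(entry)
    return out


def build_models(
    dataset: CountDataset,
    candidates: list[dict],
    mixture: str = "ZIP",
    K: int | None = None,
    veto_collinear: bool = True,
) -> list[tuple[str, DynamicNMixtureModel]]:
    """Instantiate candidate models, vetoing formulas that pair
    highly correlated covariates."""
    flagged = {
        frozenset((a, b)) for a, b, _ in dataset.screen_collinearity()
    } if veto_collinear else set()
    models = []
    for m in candidates:
        if flagged and _has_collinear_pair(m, flagged):
            continue
        models.append(
            (
                m["name"],
                DynamicNMixtureModel(
                    dataset,
                    lambda_formula=m["lambda"],
                    gamma_formula=m["gamma"],
                    p_formula=m["p"],
                    mixture=mixture,
                    K=K,
                ),
            )
        )
    return models


def _has_collinear_pair(m: dict, flagged: set) -> bool:
    import re

    for formula in (m["lambda"], m["gamma"], m["p"]):
        names = set(re.split(r"[+*:]", formula.replace(" ", ""))) - {"1", ""}
        for pair in flagged:
            if pair <= names:
                return True
    return False
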