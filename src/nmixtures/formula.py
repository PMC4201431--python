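"""Minimal additive/interaction formula language for design matrices.

Formulas are strings over named numeric covariates:

* ``"1"`` (or ``"."``, or ``""``) — intercept only;
* ``"a + b"`` — additive main effects;
* ``"a:b"`` — a product (interaction) term;
* ``"a*b"`` — shorthand for ``a + b + a:b``.

An intercept column is always included and always comes first.  All
covariates are numeric (binary design variables are coded 0/1 upstream),
so no contrast machinery is needed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["parse_formula", "build_design_matrix"]


def parse_formula(formula: str) -> list[tuple[str, ...]]:
    """Parse a formula string into an ordered list of terms.

    Each term is a tuple of covariate names whose columns are multiplied
    elementwise; the empty tuple denotes the intercept.  Duplicate terms
    are dropped, keeping first occurrence.
    """
    terms: list[tuple[str, ...]] = [()]
    text = formula.strip()
    if text in {"", "1", "."}:
        return terms
    for chunk in text.split("+"):
        chunk = chunk.strip()
        if not chunk:
            raise ValueError(f"empty term in formula {formula!r}")
        if chunk == "1":
            continue
        if "*" in chunk:
            factors = [f.strip() for f in chunk.split("*")]
            if any(not f for f in factors):
                raise ValueError(f"malformed term {chunk!r}")
            # a*b*c expands to all non-empty subsets, main effects first
            expanded: list[tuple[str, ...]] = []
            for size in range(1, len(factors) + 1):
                from itertools import combinations

                for combo in combinations(factors, size):
                    expanded.append(combo)
            for term in expanded:
                if term not in terms:
                    terms.append(term)
        elif ":" in chunk:
            term = tuple(f.strip() for f in chunk.split(":"))
            if term not in terms:
                terms.append(term)
        else:
            if (chunk,) not in terms:
                terms.append((chunk,))
    return terms


def term_name(term: tuple[str, ...]) -> str:
    return "(Intercept)" if not term else ":".join(term)


def build_design_matrix(
    table: pd.DataFrame, formula: str
) -> tuple[np.ndarray, list[str]]:
    """Build the design matrix for ``formula`` from covariate columns.

    Returns the matrix (one row per row of ``table``, intercept first) and
    the coefficient names.  Unknown covariates raise ``KeyError``.
    """
    terms = parse_formula(formula)
    n = len(table)
    cols = []
    names = []
    for term in terms:
        if not term:
            cols.append(np.ones(n))
        else:
            col = np.ones(n)
            for factor in term:
                if factor not in table.columns:
                    raise KeyError(f"unknown covariate {factor!r} in formula {formula!r}")
                col = col * np.asarray(table[factor], dtype=float)
            cols.append(col)
        names.append(term_name(term))
    X = np.column_stack(cols)
    if not np.all(np.isfinite(X)):
        raise ValueError(f"non-finite values in design matrix for {formula!r}")
    return X, names
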