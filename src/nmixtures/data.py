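"""Data containers and descriptive summaries for repeated-count surveys.

The sampling design is a robust design: sites are visited ``J`` times
(secondary visits) within each of ``T`` primary seasons, and the count
recorded at each visit is the number of *unique* individuals detected.
Site-level habitat covariates (snag and conifer basal area in m²/ha, a
0/1 nest-box treatment indicator) live in a separate per-site table;
visit-level covariates (total precipitation in mm, Julian day, trap
height class 0/1, year 0/1) live in the long count table.

For the capture–mark–recapture comparators, individual encounter
histories over ordered occasions (with possibly unequal inter-occasion
intervals, in years) are held in :class:`CaptureHistorySet`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formula import build_design_matrix

__all__ = [
    "CountDataset",
    "CaptureHistorySet",
    "CaptureSummary",
    "read_count_data",
    "read_capture_histories",
    "summarize_captures",
    "truncate2",
]

VISIT_COLUMNS = ["site", "season", "visit", "count"]
SITE_COLUMNS = ["site", "snag_ba", "conifer_ba", "boxes"]


@dataclass
class CountDataset:
    """Long-format site × season × visit counts with covariates.

    Parameters
    ----------
    visits : DataFrame
        One row per (site, season, visit) with the ``count`` column and
        any visit-level covariates.  Every combination must appear
        exactly once.
    sites : DataFrame
        One row per site with site-level covariates.
    centering : dict
        Covariate name -> subtracted mean, recorded by
        :meth:`center_covariates` so predictions can be made at raw
        covariate values.
    """

    visits: pd.DataFrame
    sites: pd.DataFrame
    centering: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.visits = self.visits.reset_index(drop=True)
        self.sites = self.sites.reset_index(drop=True)
        self._validate()

    def _validate(self) -> None:
        for col in VISIT_COLUMNS:
            if col not in self.visits.columns:
                raise ValueError(f"count table missing required column {col!r}")
        if "site" not in self.sites.columns:
            raise ValueError("site table missing required column 'site'")
        counts = self.visits["count"]
        arr = np.asarray(counts, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("counts must be finite")
        if np.any(arr < 0):
            raise ValueError("counts must be non-negative")
        if np.any(arr != np.floor(arr)):
            raise ValueError("counts must be integers")
        combos = self.visits[["site", "season", "visit"]]
        if combos.duplicated().any():
            raise ValueError("duplicate (site, season, visit) rows")
        # every site×season×visit cell present exactly once
        n_cells = (
            self.visits["site"].nunique()
            * self.visits["season"].nunique()
            * self.visits["visit"].nunique()
        )
        if len(self.visits) != n_cells:
            raise ValueError("missing (site, season, visit) combinations")
        missing = set(self.visits["site"]) - set(self.sites["site"])
        if missing:
            raise ValueError(f"sites {sorted(missing)!r} lack covariate rows")
        if "boxes" in self.sites.columns:
            if not set(np.unique(self.sites["boxes"])) <= {0, 1}:
                raise ValueError("boxes must be coded 0/1")
        for tbl in (self.visits, self.sites):
            num = tbl.select_dtypes(include=[np.number])
            if not np.all(np.isfinite(num.to_numpy(dtype=float))):
                raise ValueError("covariates must be finite")

    # ------------------------------------------------------------------
    # basic structure
    @property
    def site_ids(self) -> np.ndarray:
        return np.asarray(self.sites["site"])

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def seasons(self) -> np.ndarray:
        return np.sort(self.visits["season"].unique())

    @property
    def n_seasons(self) -> int:
        return self.visits["season"].nunique()

    @property
    def n_visits(self) -> int:
        return self.visits["visit"].nunique()

    def count_array(self) -> np.ndarray:
        """Counts as an (n_sites, n_seasons, n_visits) integer array."""
        ordered = self.visits.sort_values(["season", "visit"])
        site_order = pd.Categorical(ordered["site"], categories=self.site_ids)
        pivot = ordered.assign(_site=site_order).pivot_table(
            index="_site",
            columns=["season", "visit"],
            values="count",
            sort=True,
            observed=False,
        )
        arr = pivot.to_numpy(dtype=int)
        return arr.reshape(self.n_sites, self.n_seasons, self.n_visits)

    def season_subset(self, season) -> "CountDataset":
        """Restrict to a single primary season (for single-season fits)."""
        sub = self.visits[self.visits["season"] == season]
        if sub.empty:
            raise KeyError(f"season {season!r} not in dataset")
        return CountDataset(sub.copy(), self.sites.copy(), dict(self.centering))

    # ------------------------------------------------------------------
    # covariate handling
    def merged_visit_table(self) -> pd.DataFrame:
        """Visit rows joined with site covariates, in canonical order."""
        tbl = self.visits.sort_values(["season", "visit"]).copy()
        tbl["_site_order"] = pd.Categorical(tbl["site"], categories=self.site_ids).codes
        tbl = tbl.sort_values(["_site_order", "season", "visit"]).drop(columns="_site_order")
        return tbl.merge(self.sites, on="site", how="left").reset_index(drop=True)

    def center_covariates(self, names: list[str]) -> "CountDataset":
        """Return a copy with the named covariates centered to mean zero.

        Site covariates are centered across sites; visit covariates
        across visit rows.  The subtracted means accumulate in
        ``centering`` so predictions can be issued at raw values.
        """
        visits = self.visits.copy()
        sites = self.sites.copy()
        centering = dict(self.centering)
        for name in names:
            if name in sites.columns and name != "site":
                mu = float(np.mean(sites[name]))
                sites[name] = sites[name] - mu
            elif name in visits.columns and name not in VISIT_COLUMNS:
                mu = float(np.mean(visits[name]))
                visits[name] = visits[name] - mu
            else:
                raise KeyError(f"unknown covariate {name!r}")
            centering[name] = centering.get(name, 0.0) + mu
        return CountDataset(visits, sites, centering)

    def screen_collinearity(self, threshold: float = 0.7) -> list[tuple[str, str, float]]:
        """Flag covariate pairs with |Pearson r| above ``threshold``.

        Flagged pairs are meant to veto candidate formulas that contain
        both members.  Constant covariates (undefined r) are skipped
        with a warning.
        """
        import warnings

        tbl = self.merged_visit_table()
        names = [
            c
            for c in tbl.columns
            if c not in VISIT_COLUMNS and np.issubdtype(tbl[c].dtype, np.number)
        ]
        flagged = []
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                x = np.asarray(tbl[a], dtype=float)
                y = np.asarray(tbl[b], dtype=float)
                if np.std(x) == 0 or np.std(y) == 0:
                    warnings.warn(f"covariate pair ({a}, {b}) has a constant member; r undefined")
                    continue
                r = float(np.corrcoef(x, y)[0, 1])
                if abs(r) > threshold:
                    flagged.append((a, b, r))
        return flagged

    # ------------------------------------------------------------------
    # design matrices
    def site_design(self, formula: str) -> tuple[np.ndarray, list[str]]:
        """Design matrix at site resolution (initial abundance, recruitment)."""
        return build_design_matrix(self.sites, formula)

    def visit_design(self, formula: str) -> tuple[np.ndarray, list[str]]:
        """Design matrix at site × season × visit resolution (detection)."""
        return build_design_matrix(self.merged_visit_table(), formula)

    # ------------------------------------------------------------------
    # I/O
    def to_csv(self, count_path, site_path) -> None:
        self.visits.to_csv(count_path, index=False)
        self.sites.to_csv(site_path, index=False)

    @staticmethod
    def from_wide(wide: pd.DataFrame, sites: pd.DataFrame) -> "CountDataset":
        """Convenience converter from wide count columns ``count_s_v``."""
        rows = []
        count_cols = [c for c in wide.columns if c.startswith("count_")]
        for _, row in wide.iterrows():
            for col in count_cols:
                _, season, visit = col.split("_")
                rows.append(
                    {
                        "site": row["site"],
                        "season": int(season),
                        "visit": int(visit),
                        "count": row[col],
                    }
                )
        return CountDataset(pd.DataFrame(rows), sites)


def read_count_data(count_path, site_path) -> CountDataset:
    """Read and validate the long count CSV plus the site covariate CSV."""
    visits = pd.read_csv(count_path)
    sites = pd.read_csv(site_path)
    for col in VISIT_COLUMNS:
        if col not in visits.columns:
            raise ValueError(f"count file missing required column {col!r}")
    for col in ("site",):
        if col not in sites.columns:
            raise ValueError("site file missing required column 'site'")
    return CountDataset(visits, sites)


# ----------------------------------------------------------------------
@dataclass
class CaptureHistorySet:
    """Individual 0/1 encounter histories over ordered occasions.

    ``occasion_times`` are in years and strictly increasing; unequal
    spacing is how the 4-year gap between primary seasons enters the
    survival models.  Each individual carries its site so that
    site-level covariates can act as individual covariates.
    """

    individuals: pd.DataFrame  # columns: individual, site
    histories: np.ndarray  # (n_individuals, n_occasions) of 0/1
    occasion_times: np.ndarray  # (n_occasions,) years

    def __post_init__(self) -> None:
        self.histories = np.asarray(self.histories, dtype=int)
        self.occasion_times = np.asarray(self.occasion_times, dtype=float)
        if self.histories.ndim != 2:
            raise ValueError("histories must be 2-D")
        if len(self.individuals) != self.histories.shape[0]:
            raise ValueError("individual table and history matrix disagree")
        if self.histories.shape[1] != len(self.occasion_times):
            raise ValueError("occasion_times length must equal history length")
        if not set(np.unique(self.histories)) <= {0, 1}:
            raise ValueError("history entries must be 0/1")
        if np.any(self.histories.sum(axis=1) < 1):
            raise ValueError("every individual must be captured at least once")
        if np.any(np.diff(self.occasion_times) <= 0):
            raise ValueError("occasion_times must be strictly increasing")

    @property
    def n_individuals(self) -> int:
        return self.histories.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.histories.shape[1]

    @property
    def intervals(self) -> np.ndarray:
        """Inter-occasion intervals in years."""
        return np.diff(self.occasion_times)

    @property
    def total_captures(self) -> int:
        return int(self.histories.sum())

    def subset_occasions(self, occasions: list[int]) -> "CaptureHistorySet":
        """Restrict to the given occasion indices, dropping never-captured."""
        sub = self.histories[:, occasions]
        keep = sub.sum(axis=1) >= 1
        return CaptureHistorySet(
            self.individuals.loc[keep].reset_index(drop=True),
            sub[keep],
            self.occasion_times[occasions],
        )

    def to_csv(self, path) -> None:
        times = ";".join(f"{t:g}" for t in self.occasion_times)
        out = self.individuals.copy()
        out["history"] = ["".join(str(v) for v in row) for row in self.histories]
        out["occasion_times"] = times
        out.to_csv(path, index=False)


def read_capture_histories(path) -> CaptureHistorySet:
    """Read the encounter-history CSV (individual, site, history, occasion_times)."""
    tbl = pd.read_csv(path, dtype={"history": str})
    for col in ("individual", "site", "history", "occasion_times"):
        if col not in tbl.columns:
            raise ValueError(f"history file missing required column {col!r}")
    times_strs = tbl["occasion_times"].unique()
    if len(times_strs) != 1:
        raise ValueError("all individuals must share occasion_times")
    times = np.array([float(x) for x in times_strs[0].split(";")])
    hist = np.array([[int(ch) for ch in h] for h in tbl["history"]])
    return CaptureHistorySet(tbl[["individual", "site"]].copy(), hist, times)


# ----------------------------------------------------------------------
def truncate2(x: float) -> float:
    """Truncate (not round) to two decimals — the convention used for
    capture rates per 100 trap-nights."""
    return math.floor(x * 100.0) / 100.0


@dataclass
class CaptureSummary:
    """Descriptive capture summary per primary season.

    ``mean_unique_per_site`` is reported to one decimal and
    ``captures_per_100_trapnights`` to two decimals using truncation.
    """

    total_captures: int
    unique_individuals_per_year: dict
    mean_unique_per_site: dict
    captures_per_100_trapnights: dict
    trap_nights: dict

    def summary(self) -> str:
        lines = [f"Total captures: {self.total_captures}"]
        for year in self.unique_individuals_per_year:
            lines.append(
                f"  {year}: {self.unique_individuals_per_year[year]} unique individuals, "
                f"mean {self.mean_unique_per_site[year]:.1f} per site, "
                f"{self.captures_per_100_trapnights[year]:.2f} per 100 trap-nights "
                f"({self.trap_nights[year]} trap-nights)"
            )
        return "\n".join(lines)


def summarize_captures(
    unique_by_year: dict,
    n_sites: int,
    trap_nights_per_site: int = 48,
    total_captures: int | None = None,
) -> CaptureSummary:
    """Build a :class:`CaptureSummary` from per-year unique-individual tallies.

    Parameters
    ----------
    unique_by_year : dict
        Year -> total unique individuals that year (scalar) or a per-site
        array of unique individuals, which is summed.
    n_sites : int
        Number of trapping sites.
    trap_nights_per_site : int
        Effort per site per year; 48 corresponds to 8 stations × 2
        three-night trapping periods.
    total_captures : int, optional
        Total capture events (with recaptures) across all years, if known.
    """
    if trap_nights_per_site <= 0 or n_sites <= 0:
        raise ZeroDivisionError("trap nights and site count must be positive")
    uniques = {}
    for year, val in unique_by_year.items():
        arr = np.atleast_1d(np.asarray(val))
        uniques[year] = int(arr.sum())
    trap_nights = {year: n_sites * trap_nights_per_site for year in uniques}
    means = {year: round(uniques[year] / n_sites, 1) for year in uniques}
    rates = {
        year: truncate2(100.0 * uniques[year] / trap_nights[year]) for year in uniques
    }
    if total_captures is None:
        total_captures = sum(uniques.values())
    return CaptureSummary(int(total_captures), uniques, means, rates, trap_nights)
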