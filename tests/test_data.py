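"""Data containers, I/O, centering, collinearity and design matrices."""

import numpy as np
import pandas as pd
import pytest

from nmixtures import CountDataset, read_count_data, summarize_captures
from nmixtures.data import CaptureHistorySet, read_capture_histories, truncate2
from nmixtures.formula import build_design_matrix, parse_formula


class TestCountDataset:
    def test_roundtrip_io_lossless(self, tiny_dataset, tmp_path):
        tiny_dataset.to_csv(tmp_path / "c.csv", tmp_path / "s.csv")
        back = read_count_data(tmp_path / "c.csv", tmp_path / "s.csv")
        pd.testing.assert_frame_equal(
            back.visits.sort_values(["site", "season", "visit"]).reset_index(drop=True),
            tiny_dataset.visits.sort_values(["site", "season", "visit"]).reset_index(
                drop=True
            ),
            check_like=True,
        )
        pd.testing.assert_frame_equal(back.sites, tiny_dataset.sites, check_like=True)

    @pytest.mark.parametrize(
        "mutation, message",
        [
            (lambda v: v.assign(count=v["count"].where(v.index != 0, -1)), "negative"),
            (lambda v: v.assign(count=v["count"] + 0.5), "integer"),
            (lambda v: v.iloc[1:], "missing"),
        ],
    )
    def test_invalid_counts_rejected(self, tiny_dataset, mutation, message):
        with pytest.raises(ValueError):
            CountDataset(mutation(tiny_dataset.visits), tiny_dataset.sites)

    def test_missing_column_is_schema_error(self, tiny_dataset, tmp_path):
        tiny_dataset.visits.drop(columns=["count"]).to_csv(tmp_path / "c.csv", index=False)
        tiny_dataset.sites.to_csv(tmp_path / "s.csv", index=False)
        with pytest.raises(ValueError, match="count"):
            read_count_data(tmp_path / "c.csv", tmp_path / "s.csv")

    def test_count_array_matches_long_table(self, tiny_dataset):
        arr = tiny_dataset.count_array()
        assert arr.shape == (4, 2, 2)
        row = tiny_dataset.visits.query("site == 's2' and season == 2 and visit == 1")
        assert arr[2, 1, 0] == int(row["count"].iloc[0])

    def test_wide_converter(self, tiny_dataset):
        wide_rows = []
        for site, grp in tiny_dataset.visits.groupby("site", sort=False):
            entry = {"site": site}
            for _, r in grp.iterrows():
                entry[f"count_{r['season']}_{r['visit']}"] = r["count"]
            wide_rows.append(entry)
        ds = CountDataset.from_wide(pd.DataFrame(wide_rows), tiny_dataset.sites)
        a = ds.visits.set_index(["site", "season", "visit"])["count"].sort_index()
        b = tiny_dataset.visits.set_index(["site", "season", "visit"])["count"].sort_index()
        assert (a == b).all()


class TestCentering:
    def test_centered_mean_zero_and_offsets_recorded(self, tiny_dataset):
        ds = tiny_dataset.center_covariates(["snag_ba", "precip"])
        assert abs(ds.sites["snag_ba"].mean()) < 1e-12
        assert abs(ds.visits["precip"].mean()) < 1e-12
        assert ds.centering["snag_ba"] == pytest.approx(
            tiny_dataset.sites["snag_ba"].mean()
        )

    def test_idempotent_on_centered_input(self, tiny_dataset):
        once = tiny_dataset.center_covariates(["snag_ba"])
        twice = once.center_covariates(["snag_ba"])
        np.testing.assert_allclose(once.sites["snag_ba"], twice.sites["snag_ba"])

    def test_unknown_covariate_raises(self, tiny_dataset):
        with pytest.raises(KeyError):
            tiny_dataset.center_covariates(["nope"])

    def test_prediction_back_transform_consistency(self, tiny_dataset):
        # raw snag equal to the stored mean corresponds to centered zero
        ds = tiny_dataset.center_covariates(["snag_ba"])
        mu = ds.centering["snag_ba"]
        X_raw, _ = build_design_matrix(
            pd.DataFrame({"snag_ba": [mu - mu]}), "snag_ba"
        )
        X_zero, _ = build_design_matrix(pd.DataFrame({"snag_ba": [0.0]}), "snag_ba")
        np.testing.assert_allclose(X_raw, X_zero)


class TestCollinearity:
    def test_duplicated_covariate_flagged(self, tiny_dataset):
        sites = tiny_dataset.sites.assign(snag_copy=tiny_dataset.sites["snag_ba"])
        ds = CountDataset(tiny_dataset.visits, sites)
        flags = ds.screen_collinearity()
        pair = [f for f in flags if {"snag_ba", "snag_copy"} == {f[0], f[1]}]
        assert pair and pair[0][2] == pytest.approx(1.0)

    def test_orthogonal_pair_not_flagged(self):
        sites = pd.DataFrame(
            {
                "site": list("abcd"),
                "u": [1.0, 1.0, -1.0, -1.0],
                "v": [1.0, -1.0, 1.0, -1.0],
            }
        )
        rows = [
            {"site": s, "season": 1, "visit": j, "count": 0}
            for s in "abcd"
            for j in (1, 2)
        ]
        ds = CountDataset(pd.DataFrame(rows), sites)
        assert ds.screen_collinearity() == []

    def test_pearson_r_matches_direct_formula(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=5)
        y = 0.9 * x + 0.1 * rng.normal(size=5)
        sites = pd.DataFrame({"site": list("abcde"), "x": x, "y": y})
        rows = [
            {"site": s, "season": 1, "visit": j, "count": 0}
            for s in "abcde"
            for j in (1, 2)
        ]
        ds = CountDataset(pd.DataFrame(rows), sites)
        flags = ds.screen_collinearity(threshold=0.0)
        # direct Pearson on the visit-expanded rows
        xx = np.repeat(x, 2)
        yy = np.repeat(y, 2)
        r = np.sum((xx - xx.mean()) * (yy - yy.mean())) / np.sqrt(
            np.sum((xx - xx.mean()) ** 2) * np.sum((yy - yy.mean()) ** 2)
        )
        assert flags[0][2] == pytest.approx(r, abs=1e-12)

    def test_constant_covariate_warns_and_skips(self, tiny_dataset):
        sites = tiny_dataset.sites.assign(const=1.0)
        ds = CountDataset(tiny_dataset.visits, sites)
        with pytest.warns(UserWarning, match="constant"):
            flags = ds.screen_collinearity()
        assert all("const" not in f[:2] for f in flags)


class TestDesignMatrix:
    def test_intercept_only(self, tiny_dataset):
        X, names = tiny_dataset.site_design("1")
        assert names == ["(Intercept)"]
        np.testing.assert_array_equal(X, np.ones((4, 1)))

    def test_interaction_expansion(self, tiny_dataset):
        X, names = tiny_dataset.site_design("boxes*snag_ba")
        assert names == ["(Intercept)", "boxes", "snag_ba", "boxes:snag_ba"]
        np.testing.assert_allclose(X[:, 3], X[:, 1] * X[:, 2])

    def test_detection_structure_column_count(self, tiny_dataset):
        # year*precip + year*julian_day + height: intercept + 6 slopes
        X, names = tiny_dataset.visit_design(
            "year*precip + year*julian_day + height"
        )
        assert len(names) == 7
        assert set(names) == {
            "(Intercept)",
            "year",
            "precip",
            "year:precip",
            "julian_day",
            "year:julian_day",
            "height",
        }

    def test_unknown_covariate_raises(self, tiny_dataset):
        with pytest.raises(KeyError):
            tiny_dataset.site_design("unknown_cov")

    def test_parse_deduplicates_terms(self):
        assert parse_formula("a + a + a:b") == [(), ("a",), ("a", "b")]


class TestCaptureSummary:
    def test_study_tallies(self):
        s = summarize_captures(
            {2008: 83, 2012: 219}, n_sites=56, total_captures=383
        )
        assert s.mean_unique_per_site[2008] == 1.5
        assert s.mean_unique_per_site[2012] == 3.9
        assert s.captures_per_100_trapnights[2008] == 3.08
        assert s.captures_per_100_trapnights[2012] == 8.14
        assert s.trap_nights[2008] == 56 * 48
        assert s.total_captures == 383

    def test_truncation_not_rounding(self):
        assert truncate2(8.1473) == 8.14
        assert truncate2(8.149999) == 8.14

    def test_empty_case(self):
        s = summarize_captures({2008: 0}, n_sites=56)
        assert s.mean_unique_per_site[2008] == 0.0
        assert s.captures_per_100_trapnights[2008] == 0.0

    def test_zero_trap_nights_error(self):
        with pytest.raises(ZeroDivisionError):
            summarize_captures({2008: 5}, n_sites=56, trap_nights_per_site=0)


class TestCaptureHistories:
    def test_roundtrip(self, tmp_path):
        hs = CaptureHistorySet(
            pd.DataFrame({"individual": ["a", "b"], "site": ["s1", "s2"]}),
            np.array([[1, 0, 1, 0], [0, 1, 0, 0]]),
            np.array([0.0, 0.08, 4.0, 4.08]),
        )
        hs.to_csv(tmp_path / "h.csv")
        back = read_capture_histories(tmp_path / "h.csv")
        np.testing.assert_array_equal(back.histories, hs.histories)
        np.testing.assert_allclose(back.occasion_times, hs.occasion_times)

    def test_all_zero_history_rejected(self):
        with pytest.raises(ValueError, match="at least once"):
            CaptureHistorySet(
                pd.DataFrame({"individual": ["a"], "site": ["s1"]}),
                np.array([[0, 0]]),
                np.array([0.0, 1.0]),
            )

    def test_nonincreasing_times_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            CaptureHistorySet(
                pd.DataFrame({"individual": ["a"], "site": ["s1"]}),
                np.array([[1, 1]]),
                np.array([1.0, 1.0]),
            )
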