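"""Proximal-pressure statistic: diameter, neighborhoods, pressures, comparison."""

import numpy as np
import pandas as pd
import pytest

from conftest import brute_force_pressure, random_cell_table
from proxpress.pressure import (
    UnusableSampleError,
    cohort_pressure,
    compare_pressure,
    estimate_cell_diameter,
    neighborhood,
    proximal_pressure,
)


def _table_from_xy(xy, marker=None, area=None, sample_id="S"):
    xy = np.asarray(xy, dtype=float)
    t = pd.DataFrame(
        {"sample_id": sample_id, "cell_id": [f"c{i}" for i in range(len(xy))],
         "x": xy[:, 0], "y": xy[:, 1]}
    )
    if area is not None:
        t["area"] = area
    t["M"] = marker if marker is not None else 1.0
    return t


class TestEstimateCellDiameter:
    def test_area_equivalent_diameter(self):
        t = _table_from_xy([[0, 0], [5, 5], [9, 1]], area=np.pi)
        mask = pd.Series([True, True, False])
        assert estimate_cell_diameter(t, mask) == pytest.approx(2.0)

    def test_grid_nearest_neighbor_fallback(self):
        xy = [(i, j) for i in range(4) for j in range(4)]
        t = _table_from_xy(xy)
        assert estimate_cell_diameter(t, pd.Series([True] * 16)) == pytest.approx(1.0)

    def test_matches_definition_on_random_sample(self):
        rng = np.random.default_rng(0)
        t = random_cell_table(rng, 200)
        mask = pd.Series(rng.random(200) < 0.4)
        expected = np.median(2 * np.sqrt(t.loc[mask, "area"] / np.pi))
        assert estimate_cell_diameter(t, mask) == pytest.approx(expected, abs=1e-12)

    def test_single_cancer_cell_without_area_unusable(self):
        t = _table_from_xy([[0, 0], [1, 1]])
        with pytest.raises(UnusableSampleError):
            estimate_cell_diameter(t, pd.Series([True, False]))


class TestNeighborhood:
    def test_isolated_cell_has_empty_neighborhood(self):
        t = _table_from_xy([[0, 0], [100, 100]])
        assert neighborhood(t, "c0", 5.0) == []

    def test_boundary_distance_included_and_self_excluded(self):
        t = _table_from_xy([[0, 0], [3, 4], [0, 5.0001]])
        assert neighborhood(t, "c0", 5.0) == ["c1"]

    def test_missing_index_cell_rejected(self):
        t = _table_from_xy([[0, 0]])
        with pytest.raises(KeyError):
            neighborhood(t, "zzz", 1.0)

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(1)
        t = random_cell_table(rng, 1000)
        xy = t[["x", "y"]].to_numpy()
        for i in rng.choice(1000, size=50, replace=False):
            r = rng.uniform(5, 60)
            got = set(neighborhood(t, t.cell_id.iloc[i], r))
            d = np.sqrt(((xy - xy[i]) ** 2).sum(axis=1))
            want = set(t.cell_id.to_numpy()[(d <= r) & (np.arange(1000) != i)])
            assert got == want


class TestProximalPressure:
    def test_singleton_neighborhood_returns_its_value(self):
        t = _table_from_xy([[0, 0], [1, 0]], marker=[0.0, 7.25], area=np.pi)
        profs = proximal_pressure(t, ["M"], 2.0, pd.Series([True, False]))
        assert profs["M"].values.iloc[0] == pytest.approx(7.25)

    def test_linear_interpolation_convention(self):
        """Ten neighbors valued 1..10 give 9.1, not the nearest-rank 10."""
        xy = [[0.0, 0.0]] + [[np.cos(a), np.sin(a)] for a in np.linspace(0, 6, 10)]
        t = _table_from_xy(xy, marker=[0.0] + list(range(1, 11)), area=np.pi)
        mask = pd.Series([True] + [False] * 10)
        profs = proximal_pressure(t, ["M"], 2.0, mask)
        assert profs["M"].values.iloc[0] == pytest.approx(9.1)

    def test_empty_neighborhoods_missing_not_zero(self):
        t = _table_from_xy([[0, 0], [500, 500], [1, 0]], area=4.0)
        mask = pd.Series([True, True, False])
        profs = proximal_pressure(t, ["M"], 1.0, mask)
        p = profs["M"]
        assert np.isnan(p.values.loc["c1"])
        assert p.n_empty == 1

    def test_whole_field_radius_equals_global_percentile(self):
        """With a radius covering the field, each cancer cell's pressure is
        the 90th percentile of the marker over all other cells."""
        rng = np.random.default_rng(2)
        t = random_cell_table(rng, 300)
        mask = pd.Series(rng.random(300) < 0.3)
        profs = proximal_pressure(t, ["M0"], 1e6, mask)
        v = t["M0"].to_numpy()
        for i in np.flatnonzero(mask.to_numpy()):
            want = np.percentile(np.delete(v, i), 90)
            assert profs["M0"].values.iloc[mask[: i + 1].sum() - 1] == pytest.approx(
                want, abs=1e-9
            )

    def test_rigid_transform_invariance(self):
        rng = np.random.default_rng(3)
        t = random_cell_table(rng, 400)
        mask = pd.Series(rng.random(400) < 0.3)
        base = proximal_pressure(t, ["M0", "M1"], 2.0, mask)
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        moved = t.copy()
        xy = t[["x", "y"]].to_numpy() @ rot.T + np.array([123.4, -56.7])
        moved["x"], moved["y"] = xy[:, 0], xy[:, 1]
        out = proximal_pressure(moved, ["M0", "M1"], 2.0, mask)
        for m in ("M0", "M1"):
            pd.testing.assert_series_equal(
                base[m].values, out[m].values, atol=1e-9, rtol=0
            )

    def test_marker_order_invariance(self):
        rng = np.random.default_rng(4)
        t = random_cell_table(rng, 300)
        mask = pd.Series(rng.random(300) < 0.3)
        a = proximal_pressure(t, ["M0", "M2"], 2.0, mask)
        b = proximal_pressure(t, ["M2", "M0"], 2.0, mask)
        pd.testing.assert_series_equal(a["M0"].values, b["M0"].values)
        pd.testing.assert_series_equal(a["M2"].values, b["M2"].values)

    def test_raising_a_neighbor_value_cannot_lower_pressure(self):
        rng = np.random.default_rng(5)
        t = random_cell_table(rng, 200, n_markers=1)
        mask = pd.Series(rng.random(200) < 0.3)
        base = proximal_pressure(t, ["M0"], 2.0, mask)["M0"].values
        bumped = t.copy()
        j = int(rng.integers(200))
        bumped.loc[bumped.index[j], "M0"] += 50.0
        out = proximal_pressure(bumped, ["M0"], 2.0, mask)["M0"].values
        ok = base.notna()
        assert (out[ok] >= base[ok] - 1e-12).all()

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(6)
        t = random_cell_table(rng, 800, n_markers=2)
        mask = pd.Series(rng.random(800) < 0.35)
        profs = proximal_pressure(t, ["M0", "M1"], 2.0, mask)
        radius = profs["M0"].radius
        want = brute_force_pressure(t, ["M0", "M1"], radius, mask)
        for m in ("M0", "M1"):
            got = profs[m].values
            for cid, w in want[m].items():
                g = got.loc[cid]
                assert (np.isnan(w) and np.isnan(g)) or g == pytest.approx(w, abs=1e-9)


class TestCohortSummaries:
    def test_zscores_standardized_per_marker(self, small_cohort):
        (tables, _), _ = small_cohort
        masks = {s: t.cell_class == "cancer" for s, t in tables.items()}
        cp = cohort_pressure(tables, ["CD8", "CD4"], 2.0, masks)
        for m in ("CD8", "CD4"):
            z = cp.zscores[m].dropna().to_numpy()
            assert abs(z.mean()) < 1e-9
            assert abs(z.std(ddof=0) - 1.0) < 1e-9

    def test_pressures_within_sample_marker_range(self, small_cohort):
        (tables, _), _ = small_cohort
        sid, t = next(iter(tables.items()))
        profs = proximal_pressure(t, ["CD8"], 2.0, t.cell_class == "cancer")
        v = profs["CD8"].values.dropna()
        assert v.min() >= t["CD8"].min() - 1e-12
        assert v.max() <= t["CD8"].max() + 1e-12


class TestComparePressure:
    def _summaries(self, a, b):
        rows = {}
        for i, v in enumerate(a):
            rows[f"S{i}"] = {"M": v}
        for i, v in enumerate(b):
            rows[f"R{i}"] = {"M": v}
        df = pd.DataFrame.from_dict(rows, orient="index")
        groups = pd.Series(
            ["sensitive"] * len(a) + ["resistant"] * len(b), index=df.index
        )
        return df, groups

    def test_separated_groups_match_enumeration_oracle(self):
        """{1,2,3} vs {4,5,6}: the exact two-sided p equals the value from
        enumerating all 20 group assignments (2 extreme / 20 = 0.1)."""
        from itertools import combinations

        pooled = [1, 2, 3, 4, 5, 6]
        observed_u = 0  # U of {4,5,6} over {1,2,3}: all 9 pairs won
        count_extreme = 0
        total = 0
        for combo in combinations(range(6), 3):
            a = [pooled[i] for i in combo]
            b = [pooled[i] for i in range(6) if i not in combo]
            u = sum(x > y for x in b for y in a)
            dev = abs(u - 4.5)
            if dev >= abs(9 - 4.5):
                count_extreme += 1
            total += 1
        oracle_p = count_extreme / total
        df, groups = self._summaries([1, 2, 3], [4, 5, 6])
        out = compare_pressure(df, groups, ["M"])
        assert out.p_value.iloc[0] == pytest.approx(oracle_p)
        assert out.direction.iloc[0] == 1

    def test_identical_groups_no_discrimination(self):
        df, groups = self._summaries([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        out = compare_pressure(df, groups, ["M"])
        assert out.p_value.iloc[0] == 1.0
        assert out.direction.iloc[0] == 0

    def test_group_all_missing_reported_untestable(self):
        df, groups = self._summaries([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        df.loc[groups == "resistant", "M"] = np.nan
        out = compare_pressure(df, groups, ["M"])
        assert np.isnan(out.p_value.iloc[0])
        assert "untestable" in out.note.iloc[0]
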