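"""Effort correction, occurrence derivation, range and specialist classing."""

import math

import numpy as np
import pandas as pd
import pytest

from ecohurdle.errors import ValidationError
from ecohurdle.prep import (
    area_of_occupancy,
    cell_area_km2,
    classify_range,
    correct_effort,
    derive_occurrence,
    flag_specialists,
)


def records_table(rows):
    return pd.DataFrame(
        rows,
        columns=["study_id", "site_id", "taxon_id", "measure_type", "effort",
                 "value"],
    )


class TestCorrectEffort:
    def test_rescales_to_study_max_effort(self):
        rec = records_table(
            [
                ("s1", "a", "t1", "abundance", 2.0, 10.0),
                ("s1", "b", "t1", "abundance", 4.0, 10.0),
            ]
        )
        out = correct_effort(rec)
        assert out["value"].tolist() == [20.0, 10.0]

    def test_equal_efforts_unchanged(self):
        rec = records_table(
            [
                ("s1", "a", "t1", "abundance", 3.0, 7.0),
                ("s1", "b", "t2", "abundance", 3.0, 11.0),
            ]
        )
        assert correct_effort(rec)["value"].tolist() == [7.0, 11.0]

    def test_only_effort_sensitive_measures_touched(self):
        rec = records_table(
            [
                ("s1", "a", "t1", "relative_abundance", 2.0, 10.0),
                ("s1", "b", "t1", "density", 4.0, 10.0),
                ("s1", "c", "t1", "reporting_rate", 4.0, 0.5),
                ("s1", "d", "t1", "group_abundance", 2.0, 6.0),
            ]
        )
        out = correct_effort(rec)
        assert out["value"].tolist() == [10.0, 10.0, 0.5, 12.0]

    def test_zero_values_and_rank_order_preserved(self, rng):
        rows = []
        for site, effort in (("a", 1.0), ("b", 2.5)):
            vals = rng.lognormal(0, 1, 10)
            vals[3] = 0.0
            for i, v in enumerate(vals):
                rows.append(("s1", site, f"t{i}", "abundance", effort, v))
        rec = records_table(rows)
        out = correct_effort(rec)
        assert (out.loc[rec["value"] == 0, "value"] == 0).all()
        for site in ("a", "b"):
            before = rec[rec["site_id"] == site]["value"].rank()
            after = out[out["site_id"] == site]["value"].rank()
            assert (before == after).all()

    def test_double_correction_guard(self):
        rec = records_table([("s1", "a", "t1", "abundance", 2.0, 10.0)])
        out = correct_effort(rec)
        with pytest.raises(ValidationError, match="already"):
            correct_effort(out)

    def test_nonpositive_effort_rejected(self):
        rec = records_table([("s1", "a", "t1", "abundance", 0.0, 10.0)])
        with pytest.raises(ValidationError, match="effort"):
            correct_effort(rec)


class TestDeriveOccurrence:
    def test_direct_expansion(self):
        rec = records_table(
            [
                ("s1", "s1a", "A", "abundance", 1.0, 5.0),
                ("s1", "s1a", "B", "abundance", 1.0, 0.0),
                ("s1", "s1b", "A", "abundance", 1.0, 0.0),
                ("s1", "s1b", "B", "abundance", 1.0, 2.0),
            ]
        )
        out = derive_occurrence(rec)
        assert len(out) == 4
        present = out[out["present"] == 1][["site_id", "taxon_id"]]
        assert set(map(tuple, present.to_numpy())) == {("s1a", "A"), ("s1b", "B")}

    def test_taxon_never_positive_is_excluded(self):
        rec = records_table(
            [
                ("s1", "s1a", "A", "abundance", 1.0, 5.0),
                ("s1", "s1a", "B", "abundance", 1.0, 0.0),
                ("s1", "s1b", "B", "abundance", 1.0, 0.0),
                ("s1", "s1b", "A", "abundance", 1.0, 1.0),
            ]
        )
        out = derive_occurrence(rec)
        assert set(out["taxon_id"]) == {"A"}

    def test_single_site_study_all_present(self):
        rec = records_table(
            [
                ("s1", "only", "A", "abundance", 1.0, 5.0),
                ("s1", "only", "B", "abundance", 1.0, 3.0),
            ]
        )
        out = derive_occurrence(rec)
        assert (out["present"] == 1).all() and len(out) == 2

    def test_permutation_invariance(self, rng):
        rows = []
        for st in ("s1", "s2"):
            for site in ("x", "y", "z"):
                for tx in ("A", "B", "C", "D"):
                    rows.append(
                        (st, f"{st}{site}", tx, "abundance", 1.0,
                         float(rng.integers(0, 3)))
                    )
        rec = records_table(rows)
        out1 = derive_occurrence(rec)
        shuffled = rec.sample(frac=1.0, random_state=3).reset_index(drop=True)
        out2 = derive_occurrence(shuffled)
        key = ["study_id", "site_id", "taxon_id"]
        pd.testing.assert_frame_equal(
            out1.sort_values(key).reset_index(drop=True),
            out2.sort_values(key).reset_index(drop=True),
        )

    def test_duplicate_records_rejected(self):
        rec = records_table(
            [
                ("s1", "a", "A", "abundance", 1.0, 5.0),
                ("s1", "a", "A", "abundance", 1.0, 2.0),
            ]
        )
        with pytest.raises(ValidationError, match="duplicate"):
            derive_occurrence(rec)


class TestRangeClassification:
    def test_single_point_cell_area(self):
        # independent spherical-cap computation for the cell [0, 0.5) x [0, 0.5)
        R = 6371.0
        expected = (
            2 * math.pi * R**2
            * (math.sin(math.radians(0.5)) - math.sin(0.0))
            * (0.5 / 360.0)
        )
        got = area_of_occupancy(np.array([0.1]), np.array([0.1]))
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(3091, rel=2e-3)

    def test_same_cell_points_count_once(self):
        one = area_of_occupancy(np.array([0.1]), np.array([0.1]))
        two = area_of_occupancy(np.array([0.1, 0.3]), np.array([0.1, 0.4]))
        assert two == pytest.approx(one)

    def test_boundary_point_goes_north_east(self):
        a = area_of_occupancy(np.array([0.5]), np.array([0.5]))
        assert a == pytest.approx(cell_area_km2(0.5), rel=1e-12)

    def test_median_split_by_hand(self):
        points = pd.DataFrame(
            {
                "taxon_id": ["n"] + ["w"] * 5,
                "lon": [0.1, 1.1, 2.1, 3.1, 4.1, 5.1],
                "lat": [0.1] * 6,
            }
        )
        taxa = pd.DataFrame(
            {"taxon_id": ["n", "w"], "group": ["birds", "birds"]}
        )
        out = classify_range(points, taxa).set_index("taxon_id")
        assert out.loc["n", "range_class"] == "narrow"
        assert out.loc["w", "range_class"] == "wide"

    def test_tie_at_median_is_narrow(self):
        points = pd.DataFrame(
            {
                "taxon_id": ["a", "b", "b", "c", "c", "c"],
                "lon": [0.1, 1.1, 2.1, 3.1, 4.1, 5.1],
                "lat": [0.1] * 6,
            }
        )
        taxa = pd.DataFrame(
            {"taxon_id": ["a", "b", "c"], "group": ["birds"] * 3}
        )
        out = classify_range(points, taxa).set_index("taxon_id")
        # b sits exactly at the median AOO -> narrow ("exceeds" is strict)
        assert out.loc["b", "range_class"] == "narrow"
        assert out.loc["c", "range_class"] == "wide"

    def test_taxon_without_points_left_unset(self):
        points = pd.DataFrame(
            {"taxon_id": ["a"], "lon": [0.1], "lat": [0.1]}
        )
        taxa = pd.DataFrame(
            {"taxon_id": ["a", "ghost"], "group": ["birds", "birds"]}
        )
        out = classify_range(points, taxa).set_index("taxon_id")
        assert out.loc["ghost", "range_class"] == "unset"

    def test_split_partitions_groups_evenly(self, rng):
        taxa = pd.DataFrame(
            {"taxon_id": [f"t{i}" for i in range(30)], "group": ["birds"] * 30}
        )
        pts = []
        for i in range(30):
            k = int(rng.integers(1, 12))
            pts.append(
                pd.DataFrame(
                    {
                        "taxon_id": f"t{i}",
                        "lon": rng.uniform(-20, 20, k),
                        "lat": rng.uniform(-20, 20, k),
                    }
                )
            )
        out = classify_range(pd.concat(pts, ignore_index=True), taxa)
        counts = out["range_class"].value_counts()
        assert abs(counts.get("narrow", 0) - counts.get("wide", 0)) <= 1


class TestSpecialists:
    def test_rules(self):
        taxa = pd.DataFrame(
            {
                "taxon_id": ["b1", "b2", "m1", "m2", "i1"],
                "group": ["birds", "birds", "mammals", "mammals",
                          "invertebrates"],
            }
        )
        habitat = pd.DataFrame(
            {
                "taxon_id": ["b1", "b2", "m1", "m2"],
                "forest_importance": ["major", "suitable", None, None],
                "habitat_breadth": [None, None, 1, 3],
            }
        )
        out = flag_specialists(taxa, habitat).set_index("taxon_id")
        assert out.loc["b1", "specialist"] == "specialist"
        assert out.loc["b2", "specialist"] == "generalist"
        assert out.loc["m1", "specialist"] == "specialist"
        assert out.loc["m2", "specialist"] == "generalist"
        assert out.loc["i1", "specialist"] == "unknown"

    def test_missing_habitat_is_unknown(self):
        taxa = pd.DataFrame({"taxon_id": ["b1"], "group": ["birds"]})
        habitat = pd.DataFrame({"taxon_id": [], "forest_importance": []})
        out = flag_specialists(taxa, habitat)
        assert out["specialist"].tolist() == ["unknown"]
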