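"""Selection, group comparison, metaphase index and timing statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from kinetoquant.stats import (
    MetaphaseCounts,
    SelectionRule,
    TimingRecord,
    compare_groups,
    metaphase_index,
    select_kinetochores,
    significance_stars,
    summarize_cells,
    timing_summary,
)


def measurement_frame(n, cell_id="c0", condition="control", rng=None):
    rng = rng or np.random.default_rng(0)
    sac = rng.uniform(100, 1000, n)
    crest = rng.uniform(100, 1000, n)
    return pd.DataFrame(
        {
            "cell_id": cell_id,
            "condition": condition,
            "kt_id": np.arange(n),
            "corrected_sac": sac,
            "corrected_crest": crest,
            "ratio": sac / crest,
            "crest_nonpositive": False,
        }
    )


class TestSelection:
    def test_brightest_k_order_statistic(self):
        frame = measurement_frame(80)
        subset, under_k = select_kinetochores(frame, SelectionRule(k=20))
        assert len(subset) == 20 and not under_k
        threshold = np.sort(frame["corrected_sac"].to_numpy())[::-1][20]
        assert (subset["corrected_sac"] >= threshold).all()

    def test_all_mode_filters_invalid(self):
        frame = measurement_frame(80)
        frame.loc[frame.index[:2], "crest_nonpositive"] = True
        frame.loc[frame.index[:2], "ratio"] = np.nan
        subset, _ = select_kinetochores(frame, SelectionRule(mode="all"))
        assert len(subset) == 78

    def test_under_k_flag(self):
        subset, under_k = select_kinetochores(measurement_frame(15), SelectionRule(k=20))
        assert len(subset) == 15 and under_k

    def test_empty_valid_set_errors(self):
        frame = measurement_frame(3)
        frame["crest_nonpositive"] = True
        with pytest.raises(ValueError):
            select_kinetochores(frame)

    def test_idempotent_and_permutation_invariant(self):
        frame = measurement_frame(50)
        rule = SelectionRule(k=10)
        once, _ = select_kinetochores(frame, rule)
        twice, _ = select_kinetochores(once, rule)
        assert set(once["kt_id"]) == set(twice["kt_id"])
        shuffled = frame.sample(frac=1.0, random_state=1)
        again, _ = select_kinetochores(shuffled, rule)
        assert set(once["kt_id"]) == set(again["kt_id"])


class TestSummaries:
    def test_mean_over_all(self):
        frame = measurement_frame(3)
        frame["ratio"] = [1.0, 2.0, 3.0]
        out = summarize_cells(frame, SelectionRule(mode="all"))
        assert out.loc[0, "mean_ratio"] == pytest.approx(2.0)
        assert out.loc[0, "n_kts_used"] == 3

    def test_identical_cells_identical_summaries(self):
        a = measurement_frame(10, cell_id="a")
        b = a.copy()
        b["cell_id"] = "b"
        out = summarize_cells(pd.concat([a, b]), SelectionRule(mode="all"))
        assert out.loc[0, "mean_ratio"] == pytest.approx(out.loc[1, "mean_ratio"])


def cell_summary_frame(groups: dict[str, list[float]]) -> pd.DataFrame:
    rows = []
    for cond, means in groups.items():
        for i, m in enumerate(means):
            rows.append({"cell_id": f"{cond}_{i}", "condition": cond, "mean_ratio": m})
    return pd.DataFrame(rows)


class TestCompareGroups:
    def test_welch_closed_form_oracle(self):
        """{1,2,3} vs {2,3,4}: t = 1.2247, df = 4 (Welch-Satterthwaite).

        Closed form: means 2 and 3, both variances 1, n = 3, so
        t = 1 / sqrt(2/3) = 1.22474 and df = (2/3)^2 / (2 * (1/9)/2) = 4.
        """
        frame = cell_summary_frame({"control": [1, 2, 3], "test": [2, 3, 4]})
        (comp,) = compare_groups(frame, "control")
        assert abs(comp.statistic) == pytest.approx(1.224745, abs=1e-4)
        assert comp.df == pytest.approx(4.0, abs=1e-9)
        assert comp.fold_change == pytest.approx(1.5)

    def test_identical_groups(self):
        frame = cell_summary_frame({"control": [1, 2, 3], "test": [1, 2, 3]})
        (comp,) = compare_groups(frame, "control")
        assert comp.fold_change == pytest.approx(1.0)
        assert comp.p_value == pytest.approx(1.0)
        assert comp.stars == "ns"

    def test_f_equals_t_squared_two_groups(self):
        """For 2 equal-n groups, ANOVA F equals the pooled t^2 (here Welch
        coincides because the variances are equal)."""
        from scipy import stats as sps

        a, b = [1.0, 2.0, 3.0, 4.0], [2.5, 3.5, 4.5, 5.5]
        frame = cell_summary_frame({"control": a, "test": b})
        (comp,) = compare_groups(frame, "control")
        f_stat, _ = sps.f_oneway(a, b)
        assert comp.statistic**2 == pytest.approx(f_stat, abs=1e-6)

    def test_fold_change_equivariance(self):
        frame = cell_summary_frame({"control": [1, 2, 3], "test": [2, 3, 4]})
        (base,) = compare_groups(frame, "control")
        scaled = frame.copy()
        scaled.loc[scaled.condition == "test", "mean_ratio"] *= 2.0
        (doubled,) = compare_groups(scaled, "control")
        assert doubled.fold_change == pytest.approx(2.0 * base.fold_change)

    def test_anova_tukey_three_groups(self):
        rng = np.random.default_rng(0)
        frame = cell_summary_frame(
            {
                "control": list(rng.normal(1.0, 0.1, 10)),
                "LIC1": list(rng.normal(1.05, 0.1, 10)),
                "LIC2": list(rng.normal(2.0, 0.2, 10)),
            }
        )
        comps = compare_groups(frame, "control", test="anova_tukey")
        by_cond = {c.condition: c for c in comps}
        assert set(by_cond) == {"LIC1", "LIC2"}
        assert by_cond["LIC2"].p_value < 0.001
        assert by_cond["LIC2"].stars == "***"
        assert by_cond["LIC1"].p_value > 0.05

    def test_too_few_cells_errors(self):
        frame = cell_summary_frame({"control": [1.0], "test": [2.0, 3.0]})
        with pytest.raises(ValueError, match="fewer than 2"):
            compare_groups(frame, "control")


def test_significance_stars_thresholds():
    assert [significance_stars(p) for p in (0.0005, 0.005, 0.04, 0.2)] == [
        "***", "**", "*", "ns",
    ]


class TestMetaphaseIndex:
    def test_single_fraction(self):
        out = metaphase_index([MetaphaseCounts("r1", "control", 50, 500)])
        assert out.loc[0, "mean_percent"] == pytest.approx(10.0)
        assert not out.loc[0, "sd_available"]

    def test_replicate_mean_and_sd(self):
        counts = [
            MetaphaseCounts("r1", "LIC2", 10, 100),
            MetaphaseCounts("r2", "LIC2", 12, 100),
            MetaphaseCounts("r3", "LIC2", 14, 100),
        ]
        out = metaphase_index(counts)
        assert out.loc[0, "mean_percent"] == pytest.approx(12.0)
        assert out.loc[0, "sd_percent"] == pytest.approx(2.0)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            MetaphaseCounts("r", "c", 5, 0)
        with pytest.raises(ValueError):
            MetaphaseCounts("r", "c", 11, 10)


class TestTiming:
    def test_worked_five_cell_table(self):
        """Hand-counted oracle: mean 53.33 min, 60% arrested, 1/3 deaths."""
        records = [
            TimingRecord("c1", "LIC2", 0, 400, t_anaphase_min=30),
            TimingRecord("c2", "LIC2", 0, 400, t_anaphase_min=40),
            TimingRecord("c3", "LIC2", 0, 400, t_anaphase_min=90),
            TimingRecord("c4", "LIC2", 0, 400, t_death_min=260),
            TimingRecord("c5", "LIC2", 0, 720),  # no event by movie end
        ]
        out = timing_summary(records).iloc[0]
        assert out["mean_neb_to_anaphase_min"] == pytest.approx(160 / 3, abs=0.01)
        assert out["fraction_arrested"] == pytest.approx(0.6)
        assert out["fraction_death_after_arrest"] == pytest.approx(1 / 3)
        assert out["n_censored"] == 0

    def test_all_fast_anaphase(self):
        records = [
            TimingRecord(f"c{i}", "control", 0, 300, t_anaphase_min=25) for i in range(4)
        ]
        out = timing_summary(records).iloc[0]
        assert out["fraction_arrested"] == 0.0
        assert out["mean_neb_to_anaphase_min"] == pytest.approx(25.0)

    def test_all_die_late(self):
        records = [
            TimingRecord(f"c{i}", "LIC1+2", 0, 400, t_death_min=300) for i in range(3)
        ]
        out = timing_summary(records).iloc[0]
        assert out["fraction_arrested"] == 1.0
        assert out["fraction_death_after_arrest"] == 1.0
        assert math.isnan(out["mean_neb_to_anaphase_min"])

    def test_censored_cells_excluded_and_counted(self):
        """A movie ending before the threshold with no event is censored."""
        records = [
            TimingRecord("c1", "x", 0, 60),  # censored: observed only 60 min
            TimingRecord("c2", "x", 0, 400, t_anaphase_min=30),
        ]
        out = timing_summary(records).iloc[0]
        assert out["n_censored"] == 1
        assert out["n_assessable"] == 1
        assert out["fraction_arrested"] == 0.0

    def test_record_invariants(self):
        with pytest.raises(ValueError, match="at most one"):
            TimingRecord("c", "x", 0, 100, t_anaphase_min=30, t_death_min=50)
        with pytest.raises(ValueError, match="after NEB"):
            TimingRecord("c", "x", 50, 100, t_anaphase_min=40)

    def test_nonzero_neb_reference(self):
        """Times are on the movie clock; durations are relative to NEB."""
        records = [TimingRecord("c1", "x", 100, 500, t_anaphase_min=130)]
        out = timing_summary(records).iloc[0]
        assert out["mean_neb_to_anaphase_min"] == pytest.approx(30.0)
        assert out["fraction_arrested"] == 0.0
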