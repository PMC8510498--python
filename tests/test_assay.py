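"""Assay percentage formulas, replicate summaries, ratios, Dunnett codes."""

import numpy as np
import pytest

from damkit import (
    compare_to_control,
    dpph_percent_capture,
    frap_percent_reduction,
    ratio_table,
    summarize,
)
from damkit.assay import (
    AssayPanel,
    AssayReplicate,
    AssaySummary,
    analyze_panel,
    panel_percentages,
    significance_code,
)


def _panel(assay_type, groups, control_id):
    reps = [
        AssayReplicate(cid, j + 1, a)
        for cid, values in groups.items()
        for j, a in enumerate(values)
    ]
    return AssayPanel(assay_type=assay_type, replicates=tuple(reps), control_id=control_id)


class TestPercentFormulas:
    def test_dpph_endpoints(self):
        assert dpph_percent_capture(0.8, 0.8) == 0.0
        assert dpph_percent_capture(0.8, 0.0) == 100.0

    def test_dpph_direct_arithmetic(self):
        assert dpph_percent_capture(0.80, 0.27) == pytest.approx(66.25)

    def test_dpph_clamp_zero(self):
        assert dpph_percent_capture(0.8, 0.9) == pytest.approx(-12.5)
        assert dpph_percent_capture(0.8, 0.9, clamp_zero=True) == 0.0

    def test_dpph_zero_control_rejected(self):
        with pytest.raises(ValueError, match="control"):
            dpph_percent_capture(0.0, 0.5)

    def test_frap_control_reads_hundred_by_construction(self):
        assert frap_percent_reduction(0.52, 0.52) == 100.0
        assert frap_percent_reduction(0.0, 0.52) == 0.0

    def test_frap_scale(self):
        assert frap_percent_reduction(0.173 * 0.9, 0.9) == pytest.approx(17.3)

    def test_frap_blank_subtraction_variant(self):
        assert frap_percent_reduction(0.3, 0.5, blank=0.1) == pytest.approx(50.0)
        with pytest.raises(ValueError, match="blank"):
            frap_percent_reduction(0.3, 0.1, blank=0.1)


class TestSummaries:
    def test_triplicate_mean_and_sample_sd(self):
        # percentages {65.7, 66.2, 66.7} against control mean 0.80
        absorbances = [0.8 * (1 - p / 100) for p in (65.7, 66.2, 66.7)]
        panel = _panel("DPPH", {"blank": [0.8, 0.8, 0.8], "9": absorbances}, "blank")
        (summary,) = summarize(panel)
        assert summary.compound_id == "9"
        assert summary.mean_percent == pytest.approx(66.2, abs=1e-9)
        assert summary.sd_percent == pytest.approx(0.5, abs=1e-9)
        assert summary.n == 3

    def test_equal_replicates_give_zero_sd(self):
        panel = _panel("DPPH", {"blank": [0.8], "x": [0.4, 0.4, 0.4]}, "blank")
        (summary,) = summarize(panel)
        assert summary.sd_percent == 0.0

    def test_single_replicate_warns_sd_zero(self):
        panel = _panel("FRAP", {"AA": [0.5], "x": [0.25]}, "AA")
        with pytest.warns(UserWarning, match="single replicate"):
            summaries = summarize(panel)
        by_id = {s.compound_id: s for s in summaries}
        assert by_id["x"].sd_percent == 0.0
        assert by_id["x"].mean_percent == pytest.approx(50.0)

    def test_percentage_linearity_against_replicate_means(self):
        # summarize of DPPH percentages == percentage of the replicate means
        control = [0.8, 0.8, 0.8]
        sample = [0.3, 0.35, 0.4]
        panel = _panel("DPPH", {"blank": control, "x": sample}, "blank")
        (summary,) = summarize(panel)
        expected = dpph_percent_capture(np.mean(control), np.mean(sample))
        assert summary.mean_percent == pytest.approx(expected, abs=1e-9)

    def test_frap_control_row_kept_at_hundred(self):
        panel = _panel("FRAP", {"AA": [0.5, 0.5, 0.5], "x": [0.25, 0.25, 0.25]}, "AA")
        by_id = {s.compound_id: s for s in summarize(panel)}
        assert by_id["AA"].mean_percent == pytest.approx(100.0)


class TestRatioTable:
    def _summaries(self):
        return [
            AssaySummary("9", 66.2, 0.5, 3),
            AssaySummary("DDS", 2.5, 0.3, 3),
            AssaySummary("BHT", 90.7, 0.3, 3),
        ]

    def test_parent_self_ratio_is_one(self):
        rows = {r.compound_id: r for r in ratio_table(self._summaries(), "DDS", "BHT")}
        assert rows["DDS"].ratio_to_parent == 1.0
        assert rows["BHT"].ratio_to_standard == 1.0

    def test_published_scale_ratios(self):
        rows = {r.compound_id: r for r in ratio_table(self._summaries(), "DDS", "BHT")}
        assert rows["9"].ratio_to_parent == pytest.approx(26.48)
        assert rows["9"].ratio_to_standard == pytest.approx(0.730, abs=5e-4)

    def test_ratio_times_denominator_recovers_numerator(self):
        summaries = self._summaries()
        rows = ratio_table(summaries, "DDS", "BHT")
        means = {s.compound_id: s.mean_percent for s in summaries}
        for r in rows:
            assert r.ratio_to_parent * means["DDS"] == pytest.approx(
                means[r.compound_id], abs=1e-9
            )

    def test_zero_denominator_rejected(self):
        summaries = [AssaySummary("DDS", 0.0, 0.0, 3), AssaySummary("BHT", 90.7, 0.3, 3)]
        with pytest.raises(ValueError, match="zero mean"):
            ratio_table(summaries, "DDS", "BHT")

    def test_missing_standard_rejected(self):
        with pytest.raises(ValueError, match="standard"):
            ratio_table([AssaySummary("DDS", 2.5, 0.3, 3)], "DDS", "BHT")


class TestControlComparison:
    def test_identical_groups_not_significant(self):
        groups = {"ctrl": [10.0, 10.1, 9.9], "t": [10.0, 10.1, 9.9]}
        result = compare_to_control(groups, "ctrl", seed=7)
        assert result.codes == ("ns",)

    def test_huge_effect_flagged_three_stars(self):
        rng = np.random.default_rng(11)
        groups = {
            "ctrl": rng.normal(2.5, 0.3, 3),
            "t": rng.normal(66.2, 0.5, 3),
        }
        result = compare_to_control(groups, "ctrl", seed=7)
        assert result.codes == ("***",)
        assert result.anova_p < 0.001

    def test_requires_two_replicates_per_group(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            compare_to_control({"ctrl": [1.0], "t": [1.0, 2.0]}, "ctrl")

    def test_seeded_pvalues_reproducible(self):
        rng = np.random.default_rng(3)
        groups = {
            "ctrl": rng.normal(10, 1, 3),
            "a": rng.normal(11, 1, 3),
            "b": rng.normal(12, 1, 3),
        }
        p1 = compare_to_control(groups, "ctrl", seed=42).p_values
        p2 = compare_to_control(groups, "ctrl", seed=42).p_values
        assert p1 == p2

    def test_significance_code_thresholds(self):
        assert significance_code(0.2) == "ns"
        assert significance_code(0.04) == "*"
        assert significance_code(0.009) == "**"
        assert significance_code(0.0009) == "***"


class TestAnalyzePanel:
    def test_full_report_columns(self):
        rng = np.random.default_rng(5)
        groups = {
            "blank": [0.8, 0.8, 0.8],
            "DDS": list(0.8 * (1 - rng.normal(2.5, 0.3, 3) / 100)),
            "9": list(0.8 * (1 - rng.normal(66.2, 0.5, 3) / 100)),
            "BHT": list(0.8 * (1 - rng.normal(90.7, 0.3, 3) / 100)),
        }
        panel = _panel("DPPH", groups, "blank")
        report = analyze_panel(panel, parent_id="DDS", standard_id="BHT", seed=1)
        assert set(report["compound_id"]) == {"DDS", "9", "BHT"}
        row9 = report.set_index("compound_id").loc["9"]
        assert row9["ratio_to_parent"] == pytest.approx(
            row9["mean_percent"]
            / report.set_index("compound_id").loc["DDS", "mean_percent"]
        )
        assert row9["significance_code"] == "***"

    def test_control_absent_from_dpph_percentages(self):
        panel = _panel("DPPH", {"blank": [0.8, 0.8], "x": [0.4, 0.41]}, "blank")
        pct = panel_percentages(panel)
        assert set(pct["compound_id"]) == {"x"}
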