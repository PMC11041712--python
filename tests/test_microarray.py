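"""Two-channel array pipeline: parsing, normalization, filtering, calling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirmem.microarray import (
    ArrayInputError,
    ExpressionCall,
    ProbeMeasurement,
    average_replicates,
    call_expression,
    filter_flags,
    intensity_filter,
    normalize_slide,
    read_probe_table,
    retention_filter,
    run_pipeline,
    summarize_calls,
    write_probe_table,
)


def probe(name, hy3, hy5, flag="ok", is_control=False, slide="slide1", pid=None):
    return ProbeMeasurement(
        probe_id=pid or f"{slide}:{name}",
        mirna_name=name,
        intensity_hy3=hy3,
        intensity_hy5=hy5,
        flag=flag,
        is_control=is_control,
        slide_id=slide,
    )


def probe_log2(name, log_ratio, mean_intensity=10.0, **kw):
    """Probe whose raw log2(Hy3/Hy5) and mean log2 intensity are exact."""
    return probe(
        name,
        2.0 ** (mean_intensity + log_ratio / 2),
        2.0 ** (mean_intensity - log_ratio / 2),
        **kw,
    )


class TestReadProbeTable:
    def test_simplified_dialect_with_flagged_spot(self, tmp_path):
        path = tmp_path / "probes.csv"
        path.write_text(
            "probe_id,mirna_name,hy3,hy5,flag,is_control,slide_id\n"
            "p1,mir-a,1000,500,ok,False,s1\n"
            "p2,mir-b,800,800,ok,False,s1\n"
            "p3,mir-c,10,10,absent,False,s1\n"
            "p4,ctrl-1,600,600,ok,True,s1\n"
        )
        probes = read_probe_table(path)
        assert len(probes) == 4
        assert sum(p.flag == "absent" for p in probes) == 1
        assert sum(p.is_control for p in probes) == 1

    def test_gpr_dialect_flag_mapping(self, tmp_path):
        path = tmp_path / "slide.gpr.txt"
        path.write_text(
            "Block\tRow\tColumn\tName\tF635 Median\tF532 Median\tFlags\n"
            "1\t1\t1\tmir-a\t500\t1000\t0\n"
            "1\t1\t2\tmir-b\t400\t300\t-100\n"
            "1\t1\t3\tmir-c\t200\t250\t-50\n"
            "1\t1\t4\tcontrol-x\t600\t600\t100\n"
        )
        probes = read_probe_table(path, slide_id="s1")
        flags = {p.mirna_name: p.flag for p in probes}
        assert flags == {
            "mir-a": "ok", "mir-b": "absent", "mir-c": "marginal", "control-x": "ok",
        }
        # F532 is the green (Hy3) channel, F635 the red (Hy5)
        a = next(p for p in probes if p.mirna_name == "mir-a")
        assert (a.intensity_hy3, a.intensity_hy5) == (1000.0, 500.0)
        assert next(p for p in probes if p.mirna_name == "control-x").is_control

    def test_empty_data_section_warns(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("probe_id,mirna_name,hy3,hy5,flag\n")
        with pytest.warns(UserWarning, match="empty"):
            assert read_probe_table(path) == []

    def test_unknown_dialect_rejected(self, tmp_path):
        path = tmp_path / "weird.csv"
        path.write_text("foo,bar\n1,2\n")
        with pytest.raises(ArrayInputError, match="dialect"):
            read_probe_table(path)

    def test_duplicate_coordinates_rejected(self, tmp_path):
        path = tmp_path / "dup.gpr.txt"
        path.write_text(
            "Block\tRow\tColumn\tName\tF635 Median\tF532 Median\tFlags\n"
            "1\t1\t1\tmir-a\t500\t1000\t0\n"
            "1\t1\t1\tmir-b\t400\t300\t0\n"
        )
        with pytest.raises(ArrayInputError, match="duplicate"):
            read_probe_table(path)

    def test_round_trip_simplified(self, tmp_path):
        probes = [probe("mir-a", 1000, 500), probe("ctrl", 600, 600, is_control=True)]
        path = tmp_path / "rt.csv"
        write_probe_table(probes, path)
        assert read_probe_table(path) == probes


class TestFilterFlags:
    def test_counts(self):
        probes = (
            [probe(f"m{i}", 10, 10) for i in range(5)]
            + [probe(f"g{i}", 10, 10, flag="marginal") for i in range(3)]
            + [probe(f"a{i}", 10, 10, flag="absent") for i in range(2)]
        )
        assert len(filter_flags(probes)) == 5

    def test_all_ok_is_identity(self):
        probes = [probe(f"m{i}", 10, 10) for i in range(4)]
        assert filter_flags(probes) == probes

    def test_all_flagged_warns(self):
        probes = [probe("m", 10, 10, flag="absent")]
        with pytest.warns(UserWarning, match="flagged"):
            assert filter_flags(probes) == []


class TestNormalizeSlide:
    def test_control_median_subtracted(self):
        probes = [
            probe_log2("ctrl", 0.3, is_control=True),
            probe_log2("mir-a", 1.0),
        ]
        ratios = {r.mirna_name: r.log2_ratio for r in normalize_slide(probes)}
        assert ratios["mir-a"] == pytest.approx(0.7)
        assert ratios["ctrl"] == pytest.approx(0.0)

    def test_equal_channels_normalize_to_zero(self):
        probes = [probe("ctrl", 512, 512, is_control=True)] + [
            probe(f"m{i}", 2.0**v, 2.0**v) for i, v in enumerate((9.0, 10.0, 11.0))
        ]
        assert all(r.log2_ratio == pytest.approx(0.0) for r in normalize_slide(probes))

    def test_two_control_median(self):
        probes = [
            probe_log2("c1", 0.2, is_control=True),
            probe_log2("c2", 0.4, is_control=True),
            probe_log2("mir-a", 0.4),
        ]
        ratios = {r.mirna_name: r.log2_ratio for r in normalize_slide(probes)}
        assert ratios["mir-a"] == pytest.approx(0.1)

    def test_mean_log_intensity(self):
        r = normalize_slide([probe("m", 2.0**12, 2.0**8)], normalize=False)[0]
        assert r.mean_log_intensity == pytest.approx(10.0)
        assert r.log2_ratio == pytest.approx(4.0)

    def test_no_controls_is_error_unless_disabled(self):
        probes = [probe("m", 100, 100)]
        with pytest.raises(ArrayInputError, match="control"):
            normalize_slide(probes)
        assert len(normalize_slide(probes, normalize=False)) == 1

    def test_zero_intensity_probe_dropped_with_warning(self):
        probes = [probe("ctrl", 100, 100, is_control=True), probe("m", 0.0, 100)]
        with pytest.warns(UserWarning, match="dropped"):
            out = normalize_slide(probes)
        assert [r.mirna_name for r in out] == ["ctrl"]

    def test_mixed_slides_rejected(self):
        with pytest.raises(ArrayInputError, match="slides"):
            normalize_slide([probe("a", 1, 1, slide="s1"), probe("b", 1, 1, slide="s2")])

    def test_multiplicative_channel_bias_absorbed(self):
        """A constant dye bias on one channel cancels in control-centred ratios."""
        base = [
            probe_log2("ctrl", 0.0, is_control=True),
            probe_log2("mir-a", 1.2),
            probe_log2("mir-b", -0.4),
        ]
        biased = [
            probe(p.mirna_name, p.intensity_hy3, p.intensity_hy5 * 2.5,
                  is_control=p.is_control, pid=p.probe_id)
            for p in base
        ]
        r0 = {r.mirna_name: r.log2_ratio for r in normalize_slide(base)}
        r1 = {r.mirna_name: r.log2_ratio for r in normalize_slide(biased)}
        for name in r0:
            assert r1[name] == pytest.approx(r0[name], abs=1e-12)


class TestIntensityFilter:
    @pytest.mark.parametrize(
        "intensity, kept", [(7.9, False), (8.0, False), (10.0, True), (14.0, False)]
    )
    def test_strict_window(self, intensity, kept):
        ratios = normalize_slide([probe_log2("m", 0.0, intensity)], normalize=False)
        assert bool(intensity_filter(ratios)) is kept

    def test_invalid_window_rejected(self):
        with pytest.raises(ArrayInputError):
            intensity_filter([], lo=10, hi=10)


class TestRetentionFilter:
    def call(self, mean, sd):
        return ExpressionCall("m", mean, sd, 2, "unchanged")

    def test_as_printed_keeps_high_sd(self):
        assert retention_filter([self.call(0.6, 0.5)]) != []

    def test_reproducibility_mode_flips_comparator(self):
        assert retention_filter([self.call(0.6, 0.5)], sd_mode="reproducibility") == []
        assert retention_filter([self.call(0.6, 0.3)], sd_mode="reproducibility") != []

    def test_low_fold_change_always_dropped(self):
        for sd in (0.1, 0.9):
            assert retention_filter([self.call(0.3, sd)]) == []
            assert retention_filter([self.call(0.3, sd)], sd_mode="reproducibility") == []

    def test_negative_fold_change_magnitude(self):
        assert retention_filter([self.call(-0.6, 0.5)]) != []


class TestAverageReplicates:
    def ratios(self, name, values):
        return [
            normalize_slide([probe_log2(name, v, slide=f"s{i}")], normalize=False)[0]
            for i, v in enumerate(values)
        ]

    def test_two_replicates(self):
        (call,) = average_replicates(self.ratios("m", [0.9, 0.8]))
        assert call.mean_log2_fc == pytest.approx(0.85)
        assert call.sd_log2_fc == pytest.approx(abs(0.9 - 0.8) / math.sqrt(2))
        assert call.n_replicates == 2

    def test_single_replicate_sd_zero(self):
        (call,) = average_replicates(self.ratios("m", [0.5]))
        assert (call.mean_log2_fc, call.sd_log2_fc) == (pytest.approx(0.5), 0.0)

    def test_symmetric_replicates_average_to_zero(self):
        (call,) = average_replicates(self.ratios("m", [-0.2, 0.2]))
        assert call.mean_log2_fc == pytest.approx(0.0)


class TestCallExpression:
    @pytest.mark.parametrize(
        "fc, category",
        [(0.85, "up"), (-0.75, "down"), (0.0, "unchanged"),
         (0.7, "unchanged"), (-0.7, "unchanged")],
    )
    def test_rule(self, fc, category):
        assert call_expression(fc) == category

    def test_non_finite_rejected(self):
        with pytest.raises(ArrayInputError):
            call_expression(float("nan"))


class TestSummarizeCalls:
    def make_calls(self, n_up, n_down, n_unchanged):
        cats = ["up"] * n_up + ["down"] * n_down + ["unchanged"] * n_unchanged
        return [
            ExpressionCall(f"m{i}", 0.0, 0.0, 2, cat) for i, cat in enumerate(cats)
        ]

    def test_published_shape(self):
        s = summarize_calls(self.make_calls(38, 0, 141))
        assert (s.n_total, s.n_up, s.n_down, s.n_unchanged) == (179, 38, 0, 141)

    def test_empty(self):
        s = summarize_calls([])
        assert (s.n_total, s.n_up, s.n_down, s.n_unchanged) == (0, 0, 0, 0)

    def test_planted_mix(self):
        s = summarize_calls(self.make_calls(3, 2, 5))
        assert (s.n_total, s.n_up, s.n_down, s.n_unchanged) == (10, 3, 2, 5)

    @given(
        n_up=st.integers(0, 30), n_down=st.integers(0, 30), n_un=st.integers(0, 30)
    )
    @settings(max_examples=50, deadline=None)
    def test_partition_conserves_count(self, n_up, n_down, n_un):
        s = summarize_calls(self.make_calls(n_up, n_down, n_un))
        assert s.n_total == n_up + n_down + n_un
        assert s.n_up + s.n_down + s.n_unchanged == s.n_total


class TestPipelineProperties:
    def random_slide(self, rng, slide="s1", n=30):
        probes = [probe_log2("ctrl", 0.0, 10.0, is_control=True, slide=slide,
                             pid=f"{slide}:ctrl")]
        for i in range(n):
            probes.append(
                probe_log2(
                    f"m{i:03d}",
                    rng.normal(0, 1),
                    rng.uniform(6, 16),
                    slide=slide,
                    pid=f"{slide}:p{i}",
                    flag=rng.choice(["ok", "ok", "ok", "marginal", "absent"]),
                )
            )
        return probes

    def test_stages_are_monotone_filters(self, rng):
        for _ in range(20):
            probes = self.random_slide(rng)
            unflagged = filter_flags(probes)
            assert set(p.probe_id for p in unflagged) <= set(p.probe_id for p in probes)
            ratios = normalize_slide(unflagged)
            assert len(ratios) <= len(unflagged)
            windowed = intensity_filter(ratios)
            assert set(id(r) for r in windowed) <= set(id(r) for r in ratios)
            calls = average_replicates(windowed)
            retained = retention_filter(calls)
            assert set(c.mirna_name for c in retained) <= set(
                c.mirna_name for c in calls
            )

    def test_channel_swap_negates_ratios_and_swaps_calls(self, rng):
        probes = [p for p in self.random_slide(rng) if p.flag == "ok"]
        swapped = [
            probe(p.mirna_name, p.intensity_hy5, p.intensity_hy3,
                  is_control=p.is_control, pid=p.probe_id)
            for p in probes
        ]
        calls = {c.mirna_name: c for c in run_pipeline(probes)}
        anti = {c.mirna_name: c for c in run_pipeline(swapped)}
        assert set(calls) == set(anti)
        for name in calls:
            assert anti[name].mean_log2_fc == pytest.approx(
                -calls[name].mean_log2_fc, abs=1e-12
            )
            expected = {"up": "down", "down": "up", "unchanged": "unchanged"}
            assert anti[name].category == expected[calls[name].category]

    def test_controls_excluded_from_calls(self):
        probes = [
            probe_log2("ctrl", 0.0, is_control=True),
            probe_log2("mir-a", 1.0),
        ]
        calls = run_pipeline(probes)
        assert [c.mirna_name for c in calls] == ["mir-a"]
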