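"""Pipeline tests: I/O, thresholding, segmentation, statistics, reporting."""

import itertools

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from obtmon.circuit_models import DomainError
from obtmon.estimation import derive_rbulk
from obtmon.synthetic_data import NoiseSpec, simulate_study, write_fixture
from obtmon.timeseries_pipeline import (
    AmplitudeTrace,
    TraceFormatError,
    build_table2,
    detect_confluence_threshold,
    exact_rank_sum,
    group_compare,
    load_traces,
    run_study_pipeline,
    save_traces,
    segment_phases,
)


def make_trace(times, amps, well="W", condition="differentiated"):
    return AmplitudeTrace(well_id=well, times_h=np.asarray(times, float),
                          amplitudes_v=np.asarray(amps, float), condition=condition)


class TestLoadTraces:
    def test_well_formed_three_wells(self, tmp_path):
        rows = ["well,time_h,amplitude_v"]
        for w in ("A", "B", "C"):
            for t in range(30):
                rows.append(f"{w},{t},0.01")
        path = tmp_path / "t.csv"
        path.write_text("\n".join(rows) + "\n")
        traces = load_traces(path)
        assert len(traces) == 3
        assert all(tr.n == 30 for tr in traces)

    def test_duplicate_timestamp_is_format_error(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("well,time_h,amplitude_v\nA,0,0.01\nA,1,0.01\nA,1,0.01\n")
        with pytest.raises(TraceFormatError, match="row 2"):
            load_traces(path)

    def test_missing_column(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("well,time_h\nA,0\n")
        with pytest.raises(TraceFormatError, match="amplitude_v"):
            load_traces(path)

    def test_irregular_sampling_warns(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "well,time_h,amplitude_v\n" +
            "\n".join(f"A,{2 * t},0.01" for t in range(30)) + "\n"
        )
        with pytest.warns(UserWarning, match="deviates"):
            load_traces(path)

    def test_save_load_round_trip(self, tmp_path):
        study = simulate_study(seed=4)
        traces = load_traces(write_fixture(study, tmp_path / "fx")["traces"])
        out = tmp_path / "again.csv"
        save_traces(traces, out)
        back = load_traces(out)
        for a, b in zip(traces, back):
            assert a.well_id == b.well_id
            np.testing.assert_array_equal(a.times_h, b.times_h)
            np.testing.assert_array_equal(a.amplitudes_v, b.amplitudes_v)


class TestConfluenceThreshold:
    def test_never_crossing_returns_none(self, calibration):
        t = np.arange(48.0)
        a = np.full(48, float(calibration.a_osc[0]))
        assert detect_confluence_threshold(make_trace(t, a), calibration) is None

    def test_generator_truth_crossing(self, calibration):
        study = simulate_study(
            layout={"W2": "undifferentiated"},
            noise=NoiseSpec(multiplicative_sd=0.0), seed=5,
        )
        g = study.traces
        tr = make_trace(g.time_h, g.amplitude_v, "W2", "undifferentiated")
        from obtmon.synthetic_data import GrowthScenario

        truth_h = GrowthScenario().crossing_time_days(0.70) * 24.0
        got = detect_confluence_threshold(tr, calibration, 0.70)
        assert got == pytest.approx(truth_h, abs=1.0)

    def test_starting_above_threshold(self, calibration):
        t = np.arange(48.0)
        a = np.full(48, float(calibration.a_osc[-1]))
        assert detect_confluence_threshold(make_trace(t, a), calibration) == 0.0


class TestSegmentPhases:
    @staticmethod
    def piecewise_trace(plateau_days=0.8, mc_h=48.0, dt_h=1.0, total_h=192.0,
                        a0=1.0, slope1=0.05, slope2=0.08):
        """Linear rise, exactly flat plateau, linear rise."""
        t = np.arange(0.0, total_h + 0.5 * dt_h, dt_h)
        a_mc = a0 + slope1 * mc_h
        p_end = mc_h + plateau_days * 24.0
        a = np.where(
            t <= mc_h, a0 + slope1 * t,
            np.where(t <= p_end, a_mc, a_mc + slope2 * (t - p_end)),
        )
        return make_trace(t, a)

    def test_noiseless_piecewise_plateau(self):
        tr = self.piecewise_trace(plateau_days=0.8)
        seg = segment_phases(tr, 48.0, noise_sd=0.0)
        assert seg.plateau_duration_days == pytest.approx(0.8, abs=0.05)
        assert seg.diff_slope_v_per_day == pytest.approx(0.08 * 24.0, rel=0.05)

    def test_monotone_rise_has_no_plateau(self):
        t = np.arange(0.0, 192.0)
        tr = make_trace(t, 1.0 + 0.05 * t)
        seg = segment_phases(tr, 48.0, noise_sd=0.0)
        assert seg.plateau_duration_days == 0.0

    def test_deltas_on_raw_data(self):
        tr = self.piecewise_trace()
        seg = segment_phases(tr, 48.0, noise_sd=0.0)
        assert seg.delta_growth_v == pytest.approx(0.05 * 48.0)
        assert seg.delta_max_v == pytest.approx(tr.amplitudes_v[-1] - tr.amplitudes_v[0])
        assert seg.delta_max_v >= seg.delta_growth_v

    def test_affine_equivariance(self):
        tr = self.piecewise_trace()
        gain, offset = 3.7, 0.5
        scaled = make_trace(tr.times_h, gain * tr.amplitudes_v + offset)
        seg = segment_phases(tr, 48.0, noise_sd=0.0)
        seg2 = segment_phases(scaled, 48.0, noise_sd=0.0)
        assert seg2.plateau_duration_days == pytest.approx(seg.plateau_duration_days, abs=1e-9)
        assert seg2.delta_max_v == pytest.approx(gain * seg.delta_max_v, rel=1e-9)
        assert seg2.delta_growth_v == pytest.approx(gain * seg.delta_growth_v, rel=1e-9)

    def test_medium_change_outside_span(self):
        tr = self.piecewise_trace()
        with pytest.raises(DomainError):
            segment_phases(tr, 1e4, noise_sd=0.0)

    def test_too_short_trace(self):
        tr = make_trace(np.arange(10.0), np.ones(10))
        with pytest.raises(DomainError):
            segment_phases(tr, 5.0, noise_sd=0.0)


class TestExactRankSum:
    def test_identical_groups_p_one(self):
        _, p = exact_rank_sum([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
        assert p == 1.0

    def test_separated_3v3_p_is_point1(self):
        _, p = exact_rank_sum([10.0, 11.0, 12.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(17)
        for n1, n2 in [(3, 3), (4, 5), (6, 6), (2, 6)]:
            for _ in range(5):
                x = rng.normal(size=n1)
                y = rng.normal(0.5, size=n2)
                _, p = exact_rank_sum(x, y)
                ref = mannwhitneyu(x, y, alternative="two-sided", method="exact")
                assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_matches_brute_force_permutations_with_ties(self):
        rng = np.random.default_rng(23)
        for n1, n2 in [(3, 3), (4, 4), (3, 5)]:
            x = rng.integers(0, 4, size=n1).astype(float)
            y = rng.integers(0, 4, size=n2).astype(float)
            t_obs, p = exact_rank_sum(x, y)

            pooled = np.concatenate([x, y])
            # independent midrank computation via scipy
            from scipy.stats import rankdata

            ranks = rankdata(pooled)
            mean = n1 * (n1 + n2 + 1) / 2.0
            dev_obs = abs(np.sum(ranks[:n1]) - mean)
            count = total = 0
            for perm in itertools.permutations(range(n1 + n2)):
                total += 1
                dev = abs(np.sum(ranks[list(perm[:n1])]) - mean)
                if dev >= dev_obs - 1e-12:
                    count += 1
            assert p == pytest.approx(count / total, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(DomainError):
            exact_rank_sum([], [1.0])


class TestGroupCompare:
    def test_small_groups_rejected(self):
        with pytest.raises(DomainError):
            group_compare([1.0], [2.0, 3.0])

    def test_welch_option(self):
        rng = np.random.default_rng(2)
        x = rng.normal(1.0, 0.1, 8)
        y = rng.normal(0.0, 0.1, 8)
        res = group_compare(x, y, method="welch")
        assert res.p_value < 1e-6
        assert res.significant

    def test_exact_4v4_perfect_separation_significant(self):
        # the smallest attainable two-sided p at 4v4 is 2/70 < 0.05
        res = group_compare([10.0, 11.0, 12.0, 13.0], [1.0, 2.0, 3.0, 4.0])
        assert res.p_value == pytest.approx(2.0 / 70.0, abs=1e-12)
        assert res.significant

    def test_unknown_method(self):
        with pytest.raises(DomainError):
            group_compare([1.0, 2.0], [3.0, 4.0], method="bayes")


class TestBuildTable2:
    def test_experiment1_rbulk(self, params):
        table = build_table2({"W2": 1017.6, "W3": 1009.2}, {}, params)
        assert table["R_bulk_ohm"] == pytest.approx(1013.4, abs=1e-9)

    def test_experiment2_rbulk(self, params):
        table = build_table2({"W2": 845.3, "W3": 846.0}, {}, params)
        assert table["R_bulk_ohm"] == pytest.approx(845.65, abs=1e-9)

    def test_single_well_flagged(self, params):
        table = build_table2({"W2": 900.0}, {}, params)
        assert table["R_bulk_ohm"] == 900.0
        assert any("n=1" in f for f in table["flags"])

    def test_missing_wells_partial(self, params):
        table = build_table2({}, {"W6": [0.01]}, params)
        assert table["R_bulk_ohm"] is None
        assert any("skipped" in f for f in table["flags"])


@pytest.fixture(scope="module")
def study_dir(tmp_path_factory):
    path = tmp_path_factory.mktemp("study")
    study = simulate_study(seed=31)
    write_fixture(study, path)
    return path, study


class TestPipeline:
    def test_determinism_byte_identical(self, study_dir, calibration, params, bp, bio, comparator):
        path, study = study_dir
        reports = []
        for _ in range(2):
            traces = [t for t in load_traces(path / "traces.csv", condition_map=study.layout)
                      if t.condition != "unmonitored"]
            rep = run_study_pipeline(traces, calibration, interface=params,
                                     bp=bp, bio=bio, cmp=comparator)
            reports.append(rep.to_json())
        assert reports[0] == reports[1]

    def test_recovers_generator_resistances(self, study_dir, calibration, params, bp, bio, comparator):
        path, study = study_dir
        traces = [t for t in load_traces(path / "traces.csv", condition_map=study.layout)
                  if t.condition != "unmonitored"]
        rep = run_study_pipeline(traces, calibration, interface=params,
                                 bp=bp, bio=bio, cmp=comparator)
        # generator truth: R_gap = 1000 ohm, developing tissue resistance 150 ohm
        for rgap in rep.table["R_gap_ohm"].values():
            assert rgap == pytest.approx(1000.0, rel=0.05)
        assert rep.table["R_bulk_ohm"] == pytest.approx(
            derive_rbulk(list(rep.table["R_gap_ohm"].values()))
        )
        for rt in rep.table["R_tissue_ohm"].values():
            assert rt == pytest.approx(150.0, rel=0.25)

    def test_delta_max_dominates_growth_delta(self, study_dir, calibration, params, bp, bio, comparator):
        path, study = study_dir
        traces = [t for t in load_traces(path / "traces.csv", condition_map=study.layout)
                  if t.condition != "unmonitored"]
        rep = run_study_pipeline(traces, calibration, interface=params,
                                 bp=bp, bio=bio, cmp=comparator)
        for well, dmax in rep.deltas["delta_max_v"].items():
            assert dmax >= rep.deltas["delta_growth_v"][well] - 1e-12

    def test_power_with_four_wells_per_group(self, params, bp, bio, comparator):
        # at 4v4 the exact two-sided rank-sum can reach p = 2/70 < 0.05;
        # with generator defaults the groups separate essentially always
        from obtmon.synthetic_data import _AmplitudeForward

        layout = {f"D{i}": "differentiated" for i in range(4)}
        layout.update({f"U{i}": "undifferentiated" for i in range(4)})
        fwd = _AmplitudeForward(params, bp, bio, comparator)
        rng = np.random.default_rng(3131)
        hits = 0
        n_rep = 20
        for _ in range(n_rep):
            study = simulate_study(
                layout=layout, seed=int(rng.integers(2**31)), forward=fwd,
            )
            deltas = {}
            for well in layout:
                g = study.traces[study.traces.well == well]
                a = g.amplitude_v.to_numpy()
                deltas[well] = float(a.max() - a[0])
            res = group_compare(
                [deltas[w] for w in layout if w.startswith("D")],
                [deltas[w] for w in layout if w.startswith("U")],
            )
            hits += res.p_value < 0.05
        assert hits >= 0.9 * n_rep


class TestPlot:
    def test_plot_smoke(self, study_dir, tmp_path):
        from obtmon.timeseries_pipeline import plot_traces

        path, study = study_dir
        traces = [t for t in load_traces(path / "traces.csv", condition_map=study.layout)
                  if t.condition != "unmonitored"]
        out = tmp_path / "traces.png"
        plot_traces(traces, path=out)
        assert out.exists() and out.stat().st_size > 0
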