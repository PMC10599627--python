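"""Spike detection, bursts, network events, metric time series."""

import numpy as np
import pandas as pd
import pytest

from _oracles import bursts_oracle
from gbmcsf import mea


def _spikes(trains, window=(0.0, 420.0), wells=None):
    return mea.SpikeData(
        trains={k: np.asarray(v, float) for k, v in trains.items()},
        wells=wells or {},
        window=window,
    )


class TestDetectSpikes:
    def test_flat_trace_has_no_spikes(self):
        assert len(mea.detect_spikes(np.zeros(5000), 12_500.0)) == 0

    def test_injected_peaks_detected(self):
        rng = np.random.default_rng(12)
        fs = 12_500.0
        trace = rng.normal(0.0, 1.0, size=int(fs))
        peak_times = np.linspace(0.05, 0.95, 10)
        idx = (peak_times * fs).astype(int)
        trace[idx] = 12.0  # far above the 6-SD adaptive threshold
        detected = mea.detect_spikes(trace, fs)
        assert len(detected) == 10
        assert np.allclose(np.sort(detected), idx / fs, atol=1e-9)

    def test_amplitude_scale_invariance(self):
        rng = np.random.default_rng(3)
        trace = rng.normal(size=6000)
        trace[::700] = 15.0
        d1 = mea.detect_spikes(trace, 12_500.0)
        d2 = mea.detect_spikes(2.0 * trace, 12_500.0)
        assert np.allclose(d1, d2)

    def test_empty_trace(self):
        assert len(mea.detect_spikes(np.array([]), 12_500.0)) == 0


class TestFilterActive:
    def test_rate_boundary_is_strict(self):
        """35 spikes in 7 min = 5.0/min exactly -> removed; 36 -> kept."""
        sd = _spikes(
            {0: np.linspace(1, 400, 35), 1: np.linspace(1, 400, 36), 2: []},
            window=(0.0, 420.0),
        )
        kept = mea.filter_active(sd, min_rate_per_min=5.0)
        assert sorted(kept.trains) == [1]

    def test_zero_length_window_rejected(self):
        with pytest.raises(ValueError):
            _spikes({0: []}, window=(10.0, 10.0))


class TestDetectBursts:
    def test_five_spikes_at_50ms_is_one_burst(self):
        sd = _spikes({0: 10.0 + np.arange(5) * 0.05})
        bursts = mea.detect_bursts(sd)
        assert len(bursts[0]) == 1
        assert bursts[0][0].n_spikes == 5

    def test_four_spikes_is_no_burst(self):
        sd = _spikes({0: 10.0 + np.arange(4) * 0.05})
        assert mea.detect_bursts(sd)[0] == []

    def test_random_trains_match_sliding_scan_oracle(self):
        rng = np.random.default_rng(7)
        for rep in range(200):
            n = rng.integers(0, 60)
            ts = np.sort(rng.uniform(0, 20, size=n))
            ts = np.unique(ts)
            sd = _spikes({0: ts}, window=(0.0, 20.0))
            got = [(b.start, b.end, b.n_spikes) for b in mea.detect_bursts(sd)[0]]
            assert got == bursts_oracle(ts, 5, 0.100)

    def test_bursts_are_disjoint(self):
        rng = np.random.default_rng(1)
        ts = np.unique(np.sort(rng.uniform(0, 30, size=400)))
        bursts = mea.detect_bursts(_spikes({0: ts}, window=(0.0, 30.0)))[0]
        for a, b in zip(bursts, bursts[1:]):
            assert a.end < b.start

    def test_degenerate_thresholds_return_one_covering_run(self):
        ts = np.sort(np.random.default_rng(2).uniform(0, 100, size=50))
        sd = _spikes({0: np.unique(ts)}, window=(0.0, 100.0))
        bursts = mea.detect_bursts(sd, min_spikes=1, max_isi=np.inf)[0]
        assert len(bursts) == 1
        assert bursts[0].n_spikes == len(sd.trains[0])

    def test_time_rescaling_equivariance(self):
        rng = np.random.default_rng(5)
        ts = np.unique(np.sort(rng.uniform(0, 50, size=200)))
        b1 = mea.detect_bursts(_spikes({0: ts}, window=(0.0, 50.0)))[0]
        b2 = mea.detect_bursts(
            _spikes({0: ts * 2.0}, window=(0.0, 100.0)), max_isi=0.200
        )[0]
        assert [(2 * b.start, 2 * b.end, b.n_spikes) for b in b1] == [
            (b.start, b.end, b.n_spikes) for b in b2
        ]


class TestNetworkEvents:
    def test_50_pooled_spikes_is_one_event_49_is_none(self):
        trains = {i: 100.0 + np.arange(i, 50, 10) * 0.02 for i in range(10)}
        sd = _spikes(trains, wells={i: "W1" for i in range(10)})
        events = mea.detect_network_events(sd)
        assert len(events["W1"]) == 1
        assert events["W1"][0].n_spikes == 50
        assert len(events["W1"][0].neurons) == 10
        # remove one spike -> below the 50-spike minimum
        trains[0] = trains[0][:-1]
        sd49 = _spikes(trains, wells={i: "W1" for i in range(10)})
        assert mea.detect_network_events(sd49)["W1"] == []

    def test_matches_pooled_oracle_on_random_configs(self):
        rng = np.random.default_rng(9)
        for rep in range(100):
            trains = {
                i: np.unique(np.sort(rng.uniform(0, 10, size=rng.integers(0, 80))))
                for i in range(4)
            }
            sd = _spikes(trains, window=(0.0, 10.0),
                         wells={i: "W1" for i in range(4)})
            got = [
                (e.start, e.end, e.n_spikes)
                for e in mea.detect_network_events(sd, min_spikes=10, max_isi=0.05)["W1"]
            ]
            pooled = np.sort(np.concatenate(list(trains.values())))
            assert got == bursts_oracle(pooled, 10, 0.05)

    def test_single_neuron_well_with_burst_thresholds_equals_bursts(self):
        rng = np.random.default_rng(4)
        ts = np.unique(np.sort(rng.uniform(0, 60, size=300)))
        sd = _spikes({0: ts}, window=(0.0, 60.0))
        ev = mea.detect_network_events(sd, min_spikes=5, max_isi=0.100)["W1"]
        bursts = mea.detect_bursts(sd, min_spikes=5, max_isi=0.100)[0]
        assert [(e.start, e.end, e.n_spikes) for e in ev] == [
            (b.start, b.end, b.n_spikes) for b in bursts
        ]


class TestPopulationVector:
    def test_no_spikes_gives_zero_vector(self):
        sd = _spikes({0: [], 1: []}, window=(0.0, 1.0))
        _, pv = mea.population_vector(sd, frame=0.1, window=0.3)
        assert (pv == 0).all()

    def test_single_spike_spreads_unit_mass(self):
        sd = _spikes({0: [0.45]}, window=(0.0, 1.0))
        times, pv = mea.population_vector(sd, frame=0.1, window=0.3)
        # centered 3-frame rolling mean of a single binarized frame
        assert pv.sum() == pytest.approx(1.0)
        assert np.count_nonzero(pv) == 3

    def test_hand_computed_three_neuron_vector(self):
        # frames of 1 s, no smoothing beyond a 1-frame window
        sd = _spikes({0: [0.5, 2.5], 1: [0.6], 2: [3.5]}, window=(0.0, 4.0))
        _, pv = mea.population_vector(sd, frame=1.0, window=1.0)
        # frame 0: neurons 0 and 1 fire (binarized sum 2); frame 2: one;
        # frame 3: one
        assert pv.tolist() == [2.0, 0.0, 1.0, 1.0]


class TestMetricTimeSeries:
    def _ts(self):
        values = pd.DataFrame(
            {
                "w1": [10.0, 10.0, 8.0, 6.0, 9.0, 10.0],
                "ctrl": [10.0, 10.0, 10.0, 10.0, 10.0, 10.0],
            },
            index=[0.0, 1.0, 2.0, 3.0, 4.0, 5.0],
        )
        return mea.MetricTimeSeries(values=values, treatment=(2.0, 4.0))

    def test_constant_series_auc_is_value_times_span(self):
        ts = self._ts()
        auc = mea.treatment_auc(ts, phase="treatment")
        assert auc["ctrl"] == pytest.approx(10.0 * 2.0)

    def test_hand_trapezoid(self):
        auc = mea.treatment_auc(self._ts(), phase="treatment")
        # w1 over t=2..4: trapezoid of (8, 6, 9) -> 7 + 7.5
        assert auc["w1"] == pytest.approx(14.5)

    def test_time_reversal_symmetry(self):
        v = pd.DataFrame({"w": [3.0, 7.0, 2.0, 5.0]}, index=[0.0, 1.0, 2.0, 3.0])
        # phase values (7, 2, 5) mirrored within the window -> (5, 2, 7)
        vr = pd.DataFrame({"w": [3.0, 5.0, 2.0, 7.0]}, index=[0.0, 1.0, 2.0, 3.0])
        a1 = mea.treatment_auc(mea.MetricTimeSeries(v, (1.0, 3.0)), "treatment")
        a2 = mea.treatment_auc(mea.MetricTimeSeries(vr, (1.0, 3.0)), "treatment")
        assert a1["w"] == pytest.approx(
            np.trapezoid([7.0, 2.0, 5.0], [1.0, 2.0, 3.0])
        )
        assert a1["w"] == pytest.approx(a2["w"])

    def test_too_few_phase_points_rejected(self):
        v = pd.DataFrame({"w": [1.0, 2.0, 3.0]}, index=[0.0, 1.0, 2.0])
        ts = mea.MetricTimeSeries(v, (2.0, 2.5))
        with pytest.raises(ValueError, match="fewer than 2"):
            mea.treatment_auc(ts, "treatment")


class TestNormalizedPercentChange:
    def _ts(self, w1, ctrl):
        values = pd.DataFrame(
            {"w1": w1, "ctrl": ctrl}, index=[0.0, 1.0, 2.0]
        )
        return mea.MetricTimeSeries(values=values, treatment=(1.0, 2.0))

    def test_treated_equal_to_control_gives_zero(self):
        ts = self._ts([10.0, 8.0, 12.0], [10.0, 8.0, 12.0])
        for mode in ("ratio", "subtract"):
            out = mea.normalized_percent_change(ts, ["ctrl"], mode=mode)
            assert np.allclose(out["w1"], 0.0)

    def test_control_self_reference_is_exactly_zero(self):
        ts = self._ts([10.0, 5.0, 20.0], [10.0, 9.0, 11.0])
        out = mea.normalized_percent_change(ts, ["ctrl"])
        assert np.allclose(out["ctrl"], 0.0)

    def test_hand_computed_both_modes(self):
        ts = self._ts([10.0, 5.0, 15.0], [10.0, 8.0, 12.0])
        ratio = mea.normalized_percent_change(ts, ["ctrl"], mode="ratio")
        sub = mea.normalized_percent_change(ts, ["ctrl"], mode="subtract")
        # t=1: w1 rel 0.5, ctrl rel 0.8 -> ratio 100*(0.5/0.8-1) = -37.5
        assert ratio.loc[1.0, "w1"] == pytest.approx(-37.5)
        # subtract: (-50) - (-20) = -30
        assert sub.loc[1.0, "w1"] == pytest.approx(-30.0)
        # t=2: ratio 100*(1.5/1.2-1) = 25; subtract 50 - 20 = 30
        assert ratio.loc[2.0, "w1"] == pytest.approx(25.0)
        assert sub.loc[2.0, "w1"] == pytest.approx(30.0)

    def test_zero_baseline_reported_missing(self):
        ts = self._ts([0.0, 5.0, 5.0], [10.0, 10.0, 10.0])
        out = mea.normalized_percent_change(ts, ["ctrl"])
        assert out["w1"].isna().all()
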