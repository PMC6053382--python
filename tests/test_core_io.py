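"""Domain-type invariants and file-format round trips."""

import json

import numpy as np
import pandas as pd
import pytest

from meanet import (NetworkMetrics, RawRecording, SpikeTrain, StimulationSchedule,
                    WellRecording, signed_fold)
from meanet.core import Burst, QpcrSample
from meanet.io import (metrics_to_frame, read_metrics, read_qpcr_table,
                       read_raw_recording, read_spike_table, write_metrics,
                       write_qpcr_table, write_raw_recording, write_spike_table)


class TestSpikeTrain:
    def test_rejects_unsorted_nan_and_out_of_range_times(self):
        with pytest.raises(ValueError, match="not sorted"):
            SpikeTrain([2.0, 1.0], duration=10.0)
        with pytest.raises(ValueError, match="NaN"):
            SpikeTrain([1.0, np.nan], duration=10.0)
        with pytest.raises(ValueError, match="outside"):
            SpikeTrain([11.0], duration=10.0)

    def test_from_times_dedups_within_one_sample_period(self):
        period = 1.0 / 12500.0
        t = SpikeTrain.from_times([0.5, 0.5 + period / 3, 0.6], duration=1.0,
                                  sample_period=period)
        assert t.n_spikes == 2
        assert np.all(np.diff(t.times) >= period)

    def test_slice_is_half_open_and_rereferenced(self):
        t = SpikeTrain([0.0, 1.0, 2.0, 3.0], duration=4.0)
        sub = t.slice(1.0, 3.0)
        assert np.allclose(sub.times, [0.0, 1.0])
        assert sub.duration == 2.0


class TestDomainInvariants:
    def test_well_rejects_duplicate_electrode_keys(self):
        a = SpikeTrain([1.0], electrode_id="E00", duration=10.0)
        b = SpikeTrain([2.0], electrode_id="E00", duration=10.0)
        with pytest.raises(ValueError, match="duplicate"):
            WellRecording([a, b], duration=10.0)

    def test_unit_burst_needs_three_spikes(self):
        with pytest.raises(ValueError):
            Burst(start=0.0, stop=0.1, n_spikes=2, kind="unit")
        Burst(start=0.0, stop=0.1, n_spikes=2, kind="population")  # ok

    def test_raw_recording_rejects_nonfinite_voltage(self):
        with pytest.raises(ValueError):
            RawRecording(np.array([[0.0, np.inf]]))

    def test_network_metrics_bounds(self):
        with pytest.raises(ValueError):
            NetworkMetrics(event_sync=1.5)
        with pytest.raises(ValueError):
            NetworkMetrics(wmfr=-1.0)

    def test_signed_fold_convention(self):
        assert signed_fold(1.0) == 1.0
        assert signed_fold(2.0) == 2.0
        assert signed_fold(0.5) == -2.0
        with pytest.raises(ValueError):
            signed_fold(0.0)

    def test_lfs_schedule_is_0p1_hz(self):
        s = StimulationSchedule.lfs(start=10.0)
        assert s.n_pulses == 90
        assert np.allclose(np.diff(s.pulse_onsets), 10.0)
        assert s.pulse_duration == 0.2


class TestSpikeTable:
    def test_three_row_csv_parses_to_one_train(self, tmp_path):
        p = tmp_path / "spikes.csv"
        p.write_text("well,electrode,unit,time_s\nW01,E05,mua,1.0\n"
                     "W01,E05,mua,2.5\nW01,E05,mua,2.0\n")
        wells = read_spike_table(p, duration=300.0)
        assert len(wells) == 1
        (train,) = wells[0].trains
        assert np.allclose(train.times, [1.0, 2.0, 2.5])

    def test_empty_csv_with_header_gives_empty_collection(self, tmp_path):
        p = tmp_path / "spikes.csv"
        p.write_text("well,electrode,unit,time_s\n")
        assert read_spike_table(p) == []

    def test_round_trip_preserves_times_to_1e6(self, tmp_path, rng):
        wells = []
        for w in range(2):
            trains = [SpikeTrain(np.sort(rng.uniform(0, 300, 40)),
                                 electrode_id=f"E{e:02d}", duration=300.0)
                      for e in range(3)]
            trains.append(SpikeTrain(np.empty(0), electrode_id="E99",
                                     duration=300.0))  # silent electrode
            wells.append(WellRecording(trains, well_id=f"W{w:02d}",
                                       timepoint="week2", condition="glutamate"))
        p = tmp_path / "spikes.csv"
        write_spike_table(wells, p)
        back = read_spike_table(p)
        assert len(back) == 2
        for orig, rt in zip(wells, back):
            assert rt.well_id == orig.well_id
            assert rt.timepoint == "week2" and rt.condition == "glutamate"
            assert rt.n_trains == orig.n_trains  # silent electrode restored
            for a, b in zip(orig.trains, rt.trains):
                assert np.allclose(a.times, b.times, atol=1e-6)

    def test_missing_column_and_nan_time_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("well,electrode,time_s\nW01,E05,1.0\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_spike_table(p)
        p.write_text("well,electrode,unit,time_s\nW01,E05,mua,\n")
        with pytest.raises(ValueError, match="NaN"):
            read_spike_table(p)

    def test_time_outside_duration_names_row(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("well,electrode,unit,time_s\nW01,E05,mua,301.0\n")
        with pytest.raises(ValueError, match="row 0"):
            read_spike_table(p, duration=300.0)


class TestRawRecording:
    def test_zeros_round_trip(self, tmp_path):
        rec = RawRecording(np.zeros((2, 100), dtype=np.float32))
        write_raw_recording(rec, tmp_path / "raw.json")
        back = read_raw_recording(tmp_path / "raw.json")
        assert back.samples.shape == (2, 100)
        assert np.all(back.samples == 0)

    def test_seeded_trace_round_trip_bit_identical(self, tmp_path, rng):
        rec = RawRecording(rng.normal(0, 3, (4, 1000)).astype(np.float32),
                           well_id="W07")
        write_raw_recording(rec, tmp_path / "raw.json")
        back = read_raw_recording(tmp_path / "raw.json")
        assert back.well_id == "W07"
        assert np.array_equal(back.samples, rec.samples)

    def test_size_mismatch_is_corrupt_file_error(self, tmp_path):
        rec = RawRecording(np.zeros((2, 100), dtype=np.float32))
        write_raw_recording(rec, tmp_path / "raw.json")
        meta = json.loads((tmp_path / "raw.json").read_text())
        meta["n_channels"] = 3
        (tmp_path / "raw.json").write_text(json.dumps(meta))
        with pytest.raises(ValueError, match="corrupt"):
            read_raw_recording(tmp_path / "raw.json")

    def test_unsupported_dtype_rejected(self, tmp_path):
        rec = RawRecording(np.zeros((2, 10), dtype=np.float32))
        write_raw_recording(rec, tmp_path / "raw.json")
        meta = json.loads((tmp_path / "raw.json").read_text())
        meta["dtype"] = "int16"
        (tmp_path / "raw.json").write_text(json.dumps(meta))
        with pytest.raises(ValueError, match="dtype"):
            read_raw_recording(tmp_path / "raw.json")


class TestMetricsTable:
    KEY = ("W01", "week2", "control", "NoStim")

    def test_single_record_and_empty_table(self, tmp_path):
        m = NetworkMetrics(n_active_electrodes=5, wmfr=1.25, n_bursting_cells=3,
                           event_sync=0.4, cc_peak=0.6, mbfr=0.02,
                           mean_burst_duration=0.3)
        p = tmp_path / "metrics.csv"
        write_metrics([(self.KEY, m)], p)
        df = read_metrics(p)
        assert len(df) == 1
        write_metrics([], p)
        assert len(read_metrics(p)) == 0

    def test_round_trip_to_1e9(self, tmp_path):
        m = NetworkMetrics(n_active_electrodes=5, wmfr=1.2345678912, event_sync=0.25,
                           cc_peak=1.5, mbfr=0.0123456789, mean_burst_duration=0.31)
        p = tmp_path / "metrics.csv"
        write_metrics([(self.KEY, m)], p)
        row = read_metrics(p).iloc[0]
        assert abs(row["wmfr"] - m.wmfr) < 1e-9
        assert abs(row["mbfr"] - m.mbfr) < 1e-9

    def test_duplicate_key_rejected(self):
        m = NetworkMetrics()
        with pytest.raises(ValueError, match="W01"):
            metrics_to_frame([(self.KEY, m), (self.KEY, m)])


class TestQpcrTable:
    def test_round_trip(self, tmp_path):
        samples = [QpcrSample("S1", "control_NoStim", "NR2A", [25.0, 25.1, 24.9]),
                   QpcrSample("S1", "control_NoStim", "GAPDH", [18.0, 18.1, np.nan])]
        p = tmp_path / "ct.csv"
        write_qpcr_table(samples, p)
        back = read_qpcr_table(p)
        assert len(back) == 2
        assert np.allclose(back[0].ct_values, [25.0, 25.1, 24.9])

    def test_all_nan_row_rejected(self, tmp_path):
        p = tmp_path / "ct.csv"
        pd.DataFrame({"sample_id": ["S1"], "group": ["g"], "gene": ["NR2A"],
                      "ct1": [np.nan], "ct2": [np.nan], "ct3": [np.nan]}
                     ).to_csv(p, index=False)
        with pytest.raises(ValueError, match="finite CT"):
            read_qpcr_table(p)


class TestParamsConfig:
    def test_yaml_round_trip_and_overrides(self, tmp_path):
        from meanet import SimConfig
        from meanet.config import AnalysisParams, load_params, save_params

        sim = SimConfig(n_wells=3, qpcr_effects={("glutamate", "NoStim"):
                                                 {"NR2A": -1.0}})
        save_params(tmp_path / "p.yaml", AnalysisParams(threshold_k=5.5), sim)
        a, s = load_params(tmp_path / "p.yaml")
        assert a.threshold_k == 5.5
        assert s.n_wells == 3
        assert s.frac_active[2] == sim.frac_active[2]
        assert s.qpcr_effects[("glutamate", "NoStim")]["NR2A"] == -1.0
        a2, s2 = load_params(tmp_path / "p.yaml", threshold_k=7.0, n_wells=9)
        assert a2.threshold_k == 7.0 and s2.n_wells == 9

    def test_unknown_parameter_rejected(self):
        from meanet.config import load_params
        with pytest.raises(KeyError):
            load_params(None, not_a_parameter=1)
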