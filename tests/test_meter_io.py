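"""CSV ingestion, slot resampling, day segmentation, and report round trips."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from meterwatch.config import IOConfig
from meterwatch.meter_io import (
    read_meter_series,
    resample_to_slots,
    series_to_csv,
    split_complete_days,
    write_report,
    read_report,
)
from meterwatch.types import SLOTS_PER_DAY, DailyAssessment, MeterSeries, NormBand


def write_csv(path, rows, header="timestamp,energy_wh"):
    path.write_text("\n".join([header, *rows]) + "\n")


def quarter_hours(date="2024-01-01", n=96, start_slot=0):
    t0 = pd.Timestamp(date) + pd.Timedelta(minutes=15 * start_slot)
    return pd.date_range(t0, periods=n, freq="15min")


class TestRead:
    def test_header_only_file_gives_empty_series(self, tmp_path):
        p = tmp_path / "m.csv"
        write_csv(p, [])
        series = read_meter_series(p)
        assert len(series) == 0

    def test_full_day_at_quarter_hour_spacing(self, tmp_path):
        p = tmp_path / "m.csv"
        write_csv(p, [f"{t.isoformat()},{50.0}" for t in quarter_hours()])
        series = read_meter_series(p)
        assert len(series) == 96
        assert series.native_resolution == 900

    def test_duplicate_timestamp_named_in_error(self, tmp_path):
        p = tmp_path / "m.csv"
        write_csv(p, ["2024-01-01T00:00:00,5", "2024-01-01T00:00:00,6"])
        with pytest.raises(ValueError, match="duplicate timestamp.*2024-01-01 00:00"):
            read_meter_series(p)

    def test_bad_rows_report_line_numbers(self, tmp_path):
        p = tmp_path / "m.csv"
        write_csv(p, ["2024-01-01T00:00:00,5", "not-a-time,6"])
        with pytest.raises(ValueError, match=":3:"):
            read_meter_series(p)
        write_csv(p, ["2024-01-01T00:00:00,-5"])
        with pytest.raises(ValueError, match="negative energy"):
            read_meter_series(p)

    def test_kwh_column_converted_on_ingest(self, tmp_path):
        p = tmp_path / "m.csv"
        write_csv(p, ["2024-01-01T00:00:00,0.05", "2024-01-01T00:15:00,0.10"],
                  header="timestamp,energy_kwh")
        cfg = IOConfig(energy_column="energy_kwh", energy_unit="kwh")
        series = read_meter_series(p, cfg)
        assert series.frame["energy_wh"].tolist() == [50.0, 100.0]


class TestResample:
    def _series(self, stamps, energies, resolution):
        frame = pd.DataFrame({"timestamp": stamps, "energy_wh": energies})
        return MeterSeries("h", frame, resolution)

    def test_ninety_ten_second_readings_sum_into_slot(self):
        stamps = pd.date_range("2024-01-01", periods=90, freq="10s")
        out = resample_to_slots(self._series(stamps, [1.0] * 90, 10))
        assert out.frame["energy_wh"].tolist() == [90.0]

    def test_single_reading_passes_through(self):
        out = resample_to_slots(self._series([pd.Timestamp("2024-01-01 06:07")], [42.0], 60))
        assert out.frame["energy_wh"].tolist() == [42.0]
        assert out.frame["timestamp"].iloc[0] == pd.Timestamp("2024-01-01 06:00")

    def test_straddling_readings_conserve_total(self, rng):
        stamps = pd.date_range("2024-01-01 00:05", periods=500, freq="97s")
        energies = rng.uniform(0, 5, 500)
        out = resample_to_slots(self._series(stamps, energies, 97))
        assert out.frame["energy_wh"].sum() == pytest.approx(energies.sum(), rel=1e-12)

    def test_coarser_than_slot_rejected(self):
        with pytest.raises(ValueError, match="coarser"):
            resample_to_slots(self._series([pd.Timestamp("2024-01-01")], [1.0], 1800))


class TestSplitCompleteDays:
    def _series(self, stamps, value=10.0):
        frame = pd.DataFrame({"timestamp": stamps, "energy_wh": value})
        return MeterSeries("h", frame.reset_index(drop=True), 900)

    def test_one_complete_day(self):
        days, rejects = split_complete_days(self._series(quarter_hours()))
        assert len(days) == 1 and not rejects
        assert days[0].date == dt.date(2024, 1, 1)

    def test_missing_slot_is_rejected_with_index(self):
        stamps = quarter_hours().delete(40)
        days, rejects = split_complete_days(self._series(stamps))
        assert not days
        assert rejects == [(dt.date(2024, 1, 1), [40])]

    def test_middle_day_missing_slot_among_three(self):
        stamps = quarter_hours(n=3 * 96).delete(96 + 7)
        days, rejects = split_complete_days(self._series(stamps))
        assert len(days) == 2 and len(rejects) == 1
        # emitted + rejected covers every distinct date
        assert len(days) + len(rejects) == 3


class TestReports:
    def _assessment(self):
        return DailyAssessment(
            date=dt.date(2024, 1, 3),
            active_score=47.92,
            norm_band=NormBand(low=10.27, norm=42.26, high=73.36),
            cc=0.712,
            cc_defined=True,
            activity_level="normal",
            regularity_level="high",
            overall_status="normal",
            status_color="blue",
        )

    def test_round_trip_preserves_values(self, tmp_path):
        p = tmp_path / "report.json"
        write_report([self._assessment()], p)
        (rec,) = read_report(p)
        assert rec["active_score"] == 47.92
        assert (rec["norm_low"], rec["norm"], rec["norm_high"]) == (10.27, 42.26, 73.36)
        assert rec["cc"] == 0.712
        assert rec["status_color"] == "blue"

    def test_empty_report_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="empty"):
            write_report([], tmp_path / "r.json")

    def test_csv_round_trip_preserves_series(self, tmp_path, rng):
        stamps = quarter_hours(n=192)
        frame = pd.DataFrame(
            {"timestamp": stamps, "energy_wh": rng.uniform(0, 300, 192)}
        )
        series = MeterSeries("h", frame, 900)
        p = tmp_path / "trace.csv"
        series_to_csv(series, p)
        back = read_meter_series(p)
        assert np.allclose(
            back.frame["energy_wh"].to_numpy(), frame["energy_wh"].to_numpy()
        )
        assert (back.frame["timestamp"] == frame["timestamp"]).all()
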