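"""Independence filtering, occasion matrices, survey summaries."""

import numpy as np
import pandas as pd
import pytest

from occumap import build_history, filter_independent, summarize_sites, survey_summary


def _rec(station, *times):
    return pd.DataFrame({"station_id": station, "timestamp": list(times)})


class TestFilterIndependent:
    def test_sliding_rule_thirty_minute_boundary(self, toy_records):
        # 10:15 falls within 30 min of 10:00; 10:45 is exactly 30 min after
        # the (discarded) 10:15 raw record and therefore counts as independent
        kept = filter_independent(toy_records, 30)
        assert [t.strftime("%H:%M") for t in kept["timestamp"]] == ["10:00", "10:45"]

    def test_single_record_unchanged(self):
        rec = _rec("A", "2021-01-05T10:00")
        kept = filter_independent(rec, 30)
        assert len(kept) == 1

    def test_chain_of_close_records_collapses_to_first(self):
        rec = _rec("A", "2021-01-05T10:00", "2021-01-05T10:29", "2021-01-05T10:58")
        kept = filter_independent(rec, 30)
        assert len(kept) == 1

    def test_interleaved_stations_filtered_independently(self):
        rng = np.random.default_rng(5)
        frames = []
        for st in ["A", "B"]:
            minutes = np.sort(rng.integers(0, 5000, size=40))
            frames.append(
                pd.DataFrame(
                    {
                        "station_id": st,
                        "timestamp": [
                            (pd.Timestamp("2021-01-01") + pd.Timedelta(minutes=int(m))).isoformat()
                            for m in minutes
                        ],
                    }
                )
            )
        both = pd.concat(frames).sample(frac=1, random_state=0).reset_index(drop=True)
        kept = filter_independent(both, 30)
        # brute-force per-station enumeration
        for st, frame in zip(["A", "B"], frames):
            ts = sorted(pd.to_datetime(frame["timestamp"]))
            expect = [ts[0]]
            for prev, cur in zip(ts, ts[1:]):
                if (cur - prev) >= pd.Timedelta(minutes=30):
                    expect.append(cur)
            got = kept.loc[kept["station_id"] == st, "timestamp"].tolist()
            assert got == expect

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        minutes = np.sort(rng.integers(0, 3000, size=60))
        rec = _rec(
            "A",
            *[
                (pd.Timestamp("2021-02-01") + pd.Timedelta(minutes=int(m))).isoformat()
                for m in minutes
            ],
        )
        once = filter_independent(rec, 30)
        twice = filter_independent(once, 30)
        pd.testing.assert_frame_equal(once, twice)

    def test_unparseable_timestamp_names_row(self):
        rec = _rec("A", "2021-01-05T10:00", "not-a-time")
        with pytest.raises(ValueError, match="not-a-time"):
            filter_independent(rec, 30)


def _dep(station="A", site="s1", start="2021-01-01", days=30):
    end = (pd.Timestamp(start) + pd.Timedelta(days=days - 1)).date().isoformat()
    return pd.DataFrame(
        {
            "station_id": [station],
            "site": [site],
            "x": [0.0],
            "y": [0.0],
            "start_date": [start],
            "end_date": [end],
        }
    )


class TestBuildHistory:
    def test_thirty_day_deployment_gives_six_occasions(self):
        hist = build_history(pd.DataFrame(columns=["station_id", "timestamp"]), _dep(days=30), 5)
        assert hist.n_occasions == 6
        assert hist.occasions_observed()["A"] == 6

    def test_trailing_partial_window_retained(self):
        hist = build_history(pd.DataFrame(columns=["station_id", "timestamp"]), _dep(days=37), 5)
        assert hist.n_occasions == 8
        last_span = hist.occasion_spans["A"][-1]
        n_days = (pd.Timestamp(last_span[1]) - pd.Timestamp(last_span[0])).days + 1
        assert n_days == 2

    def test_trailing_partial_window_droppable(self):
        hist = build_history(
            pd.DataFrame(columns=["station_id", "timestamp"]), _dep(days=37), 5, drop_partial=True
        )
        assert hist.n_occasions == 7

    def test_detection_day_twelve_lands_in_occasion_three(self):
        rec = _rec("A", "2021-01-12T08:00")  # deployment day 12 (1-based)
        hist = build_history(rec, _dep(days=30), 5)
        row = hist.matrix.loc["A"]
        assert row["occ_3"] == 1.0
        assert row.drop("occ_3").sum() == 0.0

    def test_stations_padded_with_missing(self):
        dep = pd.concat([_dep("A", days=30), _dep("B", days=10)], ignore_index=True)
        hist = build_history(pd.DataFrame(columns=["station_id", "timestamp"]), dep, 5)
        assert hist.matrix.loc["B"].notna().sum() == 2
        assert hist.matrix.loc["B"].isna().sum() == 4

    def test_record_outside_deployment_fails(self):
        rec = _rec("A", "2021-03-01T08:00")
        with pytest.raises(ValueError, match="outside"):
            build_history(rec, _dep(days=30), 5)

    def test_roundtrip_csv(self, tmp_path):
        rec = _rec("A", "2021-01-12T08:00")
        hist = build_history(rec, _dep(days=30), 5)
        hist.to_csv(tmp_path / "h.csv", tmp_path / "h.json")
        from occumap import DetectionHistory

        back = DetectionHistory.from_csv(tmp_path / "h.csv", tmp_path / "h.json")
        pd.testing.assert_frame_equal(back.matrix, hist.matrix)
        assert back.window_days == 5


class TestSurveySummary:
    def test_encounter_rate_and_naive_occupancy_arithmetic(self):
        table = pd.DataFrame(
            {
                "site": ["a", "b"],
                "trap_nights": [1535, 230],
                "n_stations": [10, 10],
                "detections": [88, 0],
                "occupied_stations": [7, 0],
            }
        )
        out = summarize_sites(table)
        t = out["table"].set_index("site")
        assert t.loc["a", "encounter_rate"] == 5.7
        assert t.loc["a", "naive_occupancy"] == 0.70
        assert t.loc["b", "encounter_rate"] == 0.0
        assert t.loc["b", "naive_occupancy"] == 0.00
        assert out["total_trap_nights"] == 1765

    def test_totals_and_order_invariance(self):
        dep = pd.concat(
            [_dep("A", "s1", days=20), _dep("B", "s1", days=25), _dep("C", "s2", days=30)],
            ignore_index=True,
        )
        rec = pd.concat(
            [_rec("A", "2021-01-03T10:00"), _rec("C", "2021-01-07T09:00", "2021-01-20T09:00")],
            ignore_index=True,
        )
        out1 = survey_summary(rec, dep)
        out2 = survey_summary(rec.iloc[::-1].reset_index(drop=True), dep)
        assert out1["total_trap_nights"] == 75
        assert out1["total_detections"] == 3
        pd.testing.assert_frame_equal(out1["table"], out2["table"])
        assert out1["table"]["trap_nights"].sum() == out1["total_trap_nights"]

    def test_zero_trap_nights_site_rejected(self):
        table = pd.DataFrame(
            {
                "site": ["a"],
                "trap_nights": [0],
                "n_stations": [1],
                "detections": [0],
                "occupied_stations": [0],
            }
        )
        with pytest.raises(ValueError, match="zero trap nights"):
            summarize_sites(table)
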