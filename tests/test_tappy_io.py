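import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wavetap import (
    FeatureMatrix,
    KeystrokeEvent,
    SubjectLog,
    parse_log,
    read_feature_csv,
    write_feature_csv,
    write_log,
)
from wavetap.tappy_io import REGIONS, EmptyLogError, ParseReport


class TestKeystrokeEventInvariants:
    def test_rejects_bad_region(self):
        with pytest.raises(ValueError, match="region"):
            KeystrokeEvent("s", dt.date(2020, 1, 1), dt.time(9), "X", 1.0, "LL", 1.0, 1.0)

    def test_rejects_transition_region_mismatch(self):
        # transition must end in the event's region
        with pytest.raises(ValueError, match="transition"):
            KeystrokeEvent("s", dt.date(2020, 1, 1), dt.time(9), "L", 1.0, "LR", 1.0, 1.0)

    @pytest.mark.parametrize("field", ["hold_time", "latency", "flight"])
    @pytest.mark.parametrize("bad", [-1.0, float("nan"), float("inf")])
    def test_rejects_bad_timings(self, field, bad):
        kwargs = dict(
            subject_id="s", date=dt.date(2020, 1, 1), time=dt.time(9),
            region="L", hold_time=1.0, transition="LL", latency=1.0, flight=1.0,
        )
        kwargs[field] = bad
        with pytest.raises(ValueError):
            KeystrokeEvent(**kwargs)

    def test_log_rejects_time_travel(self):
        ev = lambda s: KeystrokeEvent(
            "s", dt.date(2020, 1, 1), dt.time(9, 0, s), "L", 1.0, "LL", 1.0, 1.0
        )
        with pytest.raises(ValueError, match="non-decreasing"):
            SubjectLog("s", "healthy", [ev(5), ev(3)])


class TestLogRoundTrip:
    def test_roundtrip_identity(self, tiny_log, tmp_path):
        path = write_log(tiny_log, tmp_path / "log.txt")
        back = parse_log(path, tiny_log.label)
        assert back.subject_id == tiny_log.subject_id
        assert back.events == tiny_log.events

    def test_one_event_one_line(self, tiny_log, tmp_path):
        log = SubjectLog(tiny_log.subject_id, tiny_log.label, tiny_log.events[:1])
        path = write_log(log, tmp_path / "one.txt")
        assert len(path.read_text().splitlines()) == 1

    def test_value_precision_preserved(self, tmp_path):
        ev = KeystrokeEvent(
            "s", dt.date(2020, 1, 1), dt.time(9), "L", 85.2, "LL", 10.0, 20.0
        )
        log = SubjectLog("s", "healthy", [ev])
        back = parse_log(write_log(log, tmp_path / "p.txt"), "healthy")
        assert back.events[0].hold_time == 85.2

    @settings(max_examples=25, deadline=None)
    @given(data=st.data())
    def test_roundtrip_property_random_logs(self, data, tmp_path_factory):
        """parse(write(log)) is the identity on randomly generated logs."""
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        n = int(rng.integers(1, 12))
        regions = rng.choice(list(REGIONS), size=n + 1)
        events = [
            KeystrokeEvent(
                "subj",
                dt.date(2020, 1, 6),
                dt.time(9, 0, i, int(rng.integers(0, 1000)) * 1000),
                str(regions[i + 1]),
                float(np.round(rng.uniform(0, 500), 6)),
                str(regions[i]) + str(regions[i + 1]),
                float(np.round(rng.uniform(0, 500), 6)),
                float(np.round(rng.uniform(0, 500), 6)),
            )
            for i in range(n)
        ]
        log = SubjectLog("subj", "parkinson", events)
        path = tmp_path_factory.mktemp("rt") / "log.txt"
        back = parse_log(write_log(log, path), "parkinson")
        assert back.events == log.events


class TestParserRobustness:
    def test_empty_file_raises(self, tmp_path):
        p = tmp_path / "empty.txt"
        p.write_text("")
        with pytest.raises(EmptyLogError):
            parse_log(p, "healthy")

    def test_malformed_lines_skipped_and_counted(self, tiny_log, tmp_path):
        path = write_log(tiny_log, tmp_path / "log.txt")
        lines = path.read_text().splitlines()
        lines.insert(2, "garbage line with wrong fields")
        lines.insert(4, "s1 2020-01-06 09:00:00.000 X 1.0 LL 1.0 1.0")  # bad region
        path.write_text("\n".join(lines) + "\n")
        report = ParseReport()
        with pytest.warns(UserWarning, match="skipped 2"):
            back = parse_log(path, "healthy", report=report)
        assert len(back.events) == len(tiny_log.events)
        assert report.n_skipped == 2 and report.n_valid == len(tiny_log.events)

    def test_strict_mode_aborts(self, tiny_log, tmp_path):
        path = write_log(tiny_log, tmp_path / "log.txt")
        path.write_text(path.read_text() + "bad\n")
        with pytest.raises(ValueError, match="expected 8 fields"):
            parse_log(path, "healthy", strict=True)

    def test_zero_padded_numerals_accepted(self, tmp_path):
        p = tmp_path / "z.txt"
        p.write_text("s1\t2020-01-06\t09:00:00.000\tL\t0085.2\tLL\t010\t020\n")
        log = parse_log(p, "healthy")
        assert log.events[0].hold_time == 85.2


class TestFeatureCsv:
    def test_shape_and_roundtrip(self, random_matrix, tmp_path):
        path = write_feature_csv(random_matrix, tmp_path / "m.csv")
        assert len(path.read_text().splitlines()) == random_matrix.n_subjects + 1
        back = read_feature_csv(path)
        assert back.column_names == random_matrix.column_names
        np.testing.assert_allclose(back.values, random_matrix.values, rtol=1e-10)
        assert list(back.labels) == list(random_matrix.labels)
        assert list(back.provenance) == list(random_matrix.provenance)

    def test_duplicate_columns_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            FeatureMatrix(
                np.zeros((2, 2)), ["a", "a"],
                np.array(["healthy", "healthy"], dtype=object),
                np.array(["s1", "s2"], dtype=object),
            )
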