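import numpy as np
import pandas as pd
import pytest

from riskseq.maze import PoseTrack, frame_features
from riskseq.sequences import (
    SEQ_CC,
    SEQ_CO,
    SEQ_GO,
    SEQ_NOGO,
    Sequence,
    SequenceTable,
    classify_sequence,
    counts_by_type,
    detect_sequences,
    make_event_table,
    risk_assessment_index,
    sequence_metrics,
)


def seq(type_, t_start=0.0, t_stop=1.0, **kw):
    defaults = dict(
        origin_arm="+y",
        terminal_arm="-y" if type_ in (SEQ_CC, SEQ_NOGO) else "+x",
        t_center=t_start + 0.4,
        t_first_risk=(t_start + 0.5) if type_ in (SEQ_NOGO, SEQ_GO) else None,
        n_risk_events=1 if type_ in (SEQ_NOGO, SEQ_GO) else 0,
    )
    defaults.update(kw)
    return Sequence(type=type_, t_start=t_start, t_stop=t_stop, **defaults)


def table_from_counts(counts: dict) -> SequenceTable:
    seqs, t = [], 0.0
    for tp, n in counts.items():
        for _ in range(n):
            seqs.append(seq(tp, t_start=t, t_stop=t + 1))
            t += 2.0
    return SequenceTable(sequences=seqs)


def track_from_waypoints(waypoints, fps=30.0, body=2.5):
    """Piecewise-linear path through (time, x, y) waypoints with heading
    along the direction of motion (outward when still)."""
    wt = np.array([w[0] for w in waypoints])
    wx = np.array([w[1] for w in waypoints])
    wy = np.array([w[2] for w in waypoints])
    n = int(round(wt[-1] * fps)) + 1
    t = np.arange(n) / fps
    pos = np.column_stack([np.interp(t, wt, wx), np.interp(t, wt, wy)])
    vel = np.zeros_like(pos)
    vel[1:] = np.diff(pos, axis=0) * fps
    vel[0] = vel[1]
    speed = np.linalg.norm(vel, axis=1)
    hu = np.zeros_like(pos)
    moving = speed > 1.0
    hu[moving] = vel[moving] / speed[moving, None]
    still = ~moving
    r = np.linalg.norm(pos, axis=1)
    out = still & (r > 1e-9)
    hu[out] = pos[out] / r[out, None]
    hu[still & ~out] = [1.0, 0.0]
    return PoseTrack(
        time=t,
        centroid=pos,
        head=pos + body * hu,
        tailbase=pos - body * hu,
        bbox_width=np.full(n, 3.0),
        bbox_height=np.full(n, 6.0),
    )


class TestClassify:
    @pytest.mark.parametrize(
        "terminal,n_risk,expected",
        [
            ("closed", 0, SEQ_CC),
            ("closed", 2, SEQ_NOGO),
            ("open", 2, SEQ_GO),
            ("open", 0, SEQ_CO),
        ],
    )
    def test_rule_table(self, terminal, n_risk, expected):
        assert classify_sequence(terminal, n_risk) == expected

    def test_bad_kind(self):
        with pytest.raises(ValueError):
            classify_sequence("sideways", 0)

    def test_exhaustive(self):
        # every terminal-kind x risk combination yields exactly one of
        # the four types
        seen = {
            classify_sequence(k, n)
            for k in ("closed", "open")
            for n in (0, 1, 5)
        }
        assert seen == {SEQ_CC, SEQ_NOGO, SEQ_GO, SEQ_CO}


class TestRiskIndex:
    def test_all_cc_zero(self):
        assert risk_assessment_index(table_from_counts({SEQ_CC: 7})) == 0.0

    def test_mixed_half(self):
        t = table_from_counts({SEQ_CC: 4, SEQ_NOGO: 3, SEQ_GO: 2, SEQ_CO: 1})
        assert risk_assessment_index(t) == 0.5

    def test_all_go_one(self):
        assert risk_assessment_index(table_from_counts({SEQ_GO: 5})) == 1.0

    def test_empty_rejected_with_message(self):
        with pytest.raises(ValueError, match="no sequences detected"):
            risk_assessment_index(SequenceTable())

    def test_monotonicity(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            counts = {tp: int(rng.integers(0, 6)) for tp in (SEQ_CC, SEQ_NOGO, SEQ_GO, SEQ_CO)}
            if sum(counts.values()) == 0:
                counts[SEQ_CC] = 1
            base = risk_assessment_index(table_from_counts(counts))
            plus_go = dict(counts)
            plus_go[SEQ_GO] += 1
            assert risk_assessment_index(table_from_counts(plus_go)) >= base
            plus_cc = dict(counts)
            plus_cc[SEQ_CC] += 1
            assert risk_assessment_index(table_from_counts(plus_cc)) <= base


class TestCounts:
    def test_empty_all_zero(self):
        assert counts_by_type(SequenceTable()) == {
            SEQ_CC: 0, SEQ_NOGO: 0, SEQ_GO: 0, SEQ_CO: 0
        }

    def test_counter_property(self):
        t = table_from_counts({SEQ_CC: 2, SEQ_GO: 1})
        before = counts_by_type(t)
        t.sequences.append(seq(SEQ_GO, t_start=100.0, t_stop=101.0))
        after = counts_by_type(t)
        assert after[SEQ_GO] == before[SEQ_GO] + 1
        assert after[SEQ_CC] == before[SEQ_CC]
        assert sum(after.values()) == len(t)


class TestSequenceInvariants:
    def test_nogo_requires_first_risk(self):
        with pytest.raises(ValueError, match="t_first_risk"):
            Sequence(
                type=SEQ_NOGO, origin_arm="+y", terminal_arm="-y",
                t_start=0.0, t_center=0.5, t_first_risk=None, t_stop=1.0,
            )

    def test_cc_must_not_carry_risk(self):
        with pytest.raises(ValueError, match="t_first_risk"):
            Sequence(
                type=SEQ_CC, origin_arm="+y", terminal_arm="-y",
                t_start=0.0, t_center=0.5, t_first_risk=0.6, t_stop=1.0,
            )

    def test_start_before_stop(self):
        with pytest.raises(ValueError, match="t_start"):
            seq(SEQ_CC, t_start=2.0, t_stop=1.0)


class TestDetection:
    def test_scripted_round_trip(self, scripted_session):
        table = detect_sequences(
            scripted_session["features"],
            scripted_session["events"],
            scripted_session["geometry"],
        )
        assert [s.type for s in table.sequences] == scripted_session["truth"].types()

    def test_idle_session_no_sequences(self, geometry):
        # animal parked in a closed-distal zone, heading outward
        n = 300
        pos = np.tile([0.0, 24.0], (n, 1))
        track = PoseTrack(
            time=np.arange(n) / 30,
            centroid=pos,
            head=pos + [0.0, 2.5],
            tailbase=pos - [0.0, 2.5],
            bbox_width=np.full(n, 3.0),
            bbox_height=np.full(n, 6.0),
        )
        features = frame_features(track, geometry)
        events = make_event_table([], [])
        table = detect_sequences(features, events, geometry)
        assert len(table) == 0

    def test_partial_open_excursion_is_nogo(self, geometry):
        # bout reaches only ~40% into the open arm (15 cm < 17.8 cm
        # threshold), one risk event while paused, returns to the other
        # closed arm -> NoGo, not Go
        waypoints = [
            (0.0, 0.0, 24.0),
            (2.0, 0.0, 24.0),
            (4.0, 0.0, 0.0),
            (5.0, 15.0, 0.0),
            (6.0, 15.0, 0.0),
            (7.0, 0.0, 0.0),
            (9.0, 0.0, -24.0),
            (10.0, 0.0, -24.0),
        ]
        track = track_from_waypoints(waypoints)
        features = frame_features(track, geometry)
        events = make_event_table([5.3], ["risk_assessment"])
        table = detect_sequences(features, events, geometry)
        assert [s.type for s in table.sequences] == [SEQ_NOGO]
        assert table.sequences[0].t_first_risk == 5.3

    def test_risk_event_outside_proximal_open_ignored_with_warning(self, geometry):
        # risk annotation while the animal is still in the closed arm:
        # ignored for classification -> C->C
        waypoints = [
            (0.0, 0.0, 24.0),
            (2.0, 0.0, 24.0),
            (4.0, 0.0, -24.0),
            (5.0, 0.0, -24.0),
        ]
        track = track_from_waypoints(waypoints)
        features = frame_features(track, geometry)
        events = make_event_table([2.2], ["risk_assessment"])
        with pytest.warns(UserWarning, match="proximal open arm"):
            table = detect_sequences(features, events, geometry)
        assert [s.type for s in table.sequences] == [SEQ_CC]

    def test_events_outside_session_rejected(self, scripted_session):
        events = make_event_table([1e6], ["risk_assessment"])
        with pytest.raises(ValueError, match="outside session"):
            detect_sequences(
                scripted_session["features"], events, scripted_session["geometry"]
            )

    def test_idempotence(self, scripted_session):
        args = (
            scripted_session["features"],
            scripted_session["events"],
            scripted_session["geometry"],
        )
        t1 = detect_sequences(*args)
        t2 = detect_sequences(*args)
        pd.testing.assert_frame_equal(t1.to_dataframe(), t2.to_dataframe())

    def test_unresolved_sequence_dropped(self, geometry, caplog):
        # bout that never crosses another arm's threshold before the
        # session ends is dropped
        waypoints = [
            (0.0, 0.0, 24.0),
            (1.0, 0.0, 24.0),
            (2.0, 0.0, 10.0),
            (3.0, 0.0, 10.0),
        ]
        track = track_from_waypoints(waypoints)
        features = frame_features(track, geometry)
        events = make_event_table([], [])
        import logging

        with caplog.at_level(logging.WARNING, logger="riskseq.sequences"):
            table = detect_sequences(features, events, geometry)
        assert len(table) == 0
        assert any("dropped" in r.message for r in caplog.records)


class TestMetrics:
    def make_features(self, n=100, speed=15.0, aspects=None):
        aspect = np.full(n, 2.0) if aspects is None else np.asarray(aspects)
        return pd.DataFrame(
            {
                "time": np.arange(n) / 30,
                "speed": np.full(n, speed),
                "aspect_ratio": aspect,
            }
        )

    def test_duration_subtraction(self):
        s = seq(SEQ_CC, t_start=10.0, t_stop=12.5)
        m = sequence_metrics(s, self.make_features(n=600))
        assert m["duration"] == 2.5

    def test_constant_speed_mean(self):
        s = seq(SEQ_CC, t_start=0.0, t_stop=1.0)
        m = sequence_metrics(s, self.make_features(speed=15.0))
        assert m["mean_speed"] == 15.0

    def test_aspect_mean(self):
        feats = self.make_features(n=2, aspects=[1.0, 2.0])
        s = seq(SEQ_CC, t_start=0.0, t_stop=0.5)
        m = sequence_metrics(s, feats)
        assert m["mean_aspect_ratio"] == 1.5

    def test_empty_slice_rejected(self):
        s = seq(SEQ_CC, t_start=50.0, t_stop=51.0)
        with pytest.raises(ValueError, match="no frames"):
            sequence_metrics(s, self.make_features(n=10))


def test_dataframe_round_trip():
    t = table_from_counts({SEQ_CC: 2, SEQ_NOGO: 1, SEQ_GO: 1})
    df = t.to_dataframe()
    back = SequenceTable.from_dataframe(df)
    pd.testing.assert_frame_equal(df, back.to_dataframe())
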