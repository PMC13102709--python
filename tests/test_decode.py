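"""Temporal decoding, event sequencing, amplitudes and benchmarks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from geminirec import decode, profiles, synth
from geminirec.decode import (
    CannotCalibrateError,
    RecordingProtocol,
    Stamp,
    benchmark_decoding,
    decode_events_sequence,
    decode_particle,
    decode_radii,
    normalized_halfmax_position,
    quantify_amplitude,
)
from geminirec.growth import GrowthModel
from geminirec.profiles import BandCall


def _call(channel, kind, radius, height=10.0):
    return BandCall(channel=channel, kind=kind, radius=radius, height=height,
                    prominence=height)


def _two_stamp_protocol(delay=0.0):
    return RecordingProtocol(
        stamps=[Stamp(0.0, "stamp1"), Stamp(11.0, "stamp2")], delay=delay
    )


class TestDecodeParticle:
    def test_closed_form_two_stamp_decoding(self):
        calls = [
            _call("stamp1", "onset", 1.0),
            _call("stamp2", "onset", 12.0 ** (1 / 3)),
            _call("signal", "onset", 6.0 ** (1 / 3)),
        ]
        events, model = decode_particle(calls, _two_stamp_protocol())
        assert model.K == pytest.approx(1.0)
        assert model.A == pytest.approx(1.0)
        assert events[0].raw_time == pytest.approx(5.0)
        assert events[0].kind == "activation-onset"

    def test_delay_correction_is_a_pure_shift(self):
        calls = [
            _call("stamp1", "onset", 1.0),
            _call("stamp2", "onset", 12.0 ** (1 / 3)),
            _call("signal", "onset", 6.0 ** (1 / 3)),
            _call("signal", "peak", 9.0 ** (1 / 3)),
        ]
        raw_events, _ = decode_particle(calls, _two_stamp_protocol(delay=0.0))
        cor_events, _ = decode_particle(calls, _two_stamp_protocol(delay=2.0))
        for r, c in zip(raw_events, cor_events):
            assert c.raw_time == pytest.approx(r.raw_time)
            assert c.time == pytest.approx(r.time - 2.0)

    def test_missing_stamp_band_cannot_calibrate(self):
        calls = [_call("stamp1", "onset", 1.0), _call("signal", "onset", 1.5)]
        with pytest.raises(CannotCalibrateError, match="stamp2"):
            decode_particle(calls, _two_stamp_protocol())

    def test_pulse_stamps_use_peak_calls(self):
        m = GrowthModel(K=2.0, A=5.0)
        proto = RecordingProtocol(
            stamps=[Stamp(0.0, "p1", "pulse"), Stamp(10.0, "p2", "pulse")]
        )
        calls = [
            _call("p1", "peak", m.radius_at_time(0.0)),
            _call("p2", "peak", m.radius_at_time(10.0)),
            _call("signal", "onset", m.radius_at_time(4.0)),
        ]
        events, cal = decode_particle(calls, proto)
        assert events[0].raw_time == pytest.approx(4.0)

    def test_out_of_window_and_pre_window_flags(self):
        m = GrowthModel(K=1.0, A=8.0)
        proto = _two_stamp_protocol()
        calls = [
            _call("stamp1", "onset", m.radius_at_time(0.0)),
            _call("stamp2", "onset", m.radius_at_time(11.0)),
            _call("signal", "onset", m.radius_at_time(-2.0)),
        ]
        events, _ = decode_particle(calls, proto)
        assert "out-of-window" in events[0].flags
        assert "pre-window" in events[0].flags

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        K=st.floats(0.01, 100.0),
        A=st.floats(0.0, 1e3),
        t1=st.floats(0.5, 4.0),
        t2=st.floats(5.0, 50.0),
        frac=st.floats(0.05, 0.95),
    )
    def test_noise_free_decoding_is_exact(self, K, A, t1, t2, frac):
        """Noise-free band radii decode to machine precision, any protocol."""
        m = GrowthModel(K=K, A=A)
        ts = t1 + frac * (t2 - t1)
        decoded = decode_radii(
            np.array([t1, t2]),
            np.array([m.radius_at_time(t1), m.radius_at_time(t2)]),
            np.array([m.radius_at_time(ts)]),
        )
        assert abs(decoded[0] - ts) <= 1e-9 * (ts + A / K + 1.0)


class TestEventSequence:
    def test_three_on_off_cycles_in_order(self):
        m = GrowthModel(K=3.0, A=2.0)
        times = [(1.0, "activation-onset"), (3.0, "peak"), (5.0, "activation-onset"),
                 (7.0, "peak"), (9.0, "activation-onset"), (11.0, "peak")]
        events = [
            decode.DecodedEvent(kind=k, time=t, raw_time=t, channel="signal",
                                radius=m.radius_at_time(t))
            for t, k in times
        ]
        seq = decode_events_sequence(events)
        kinds = [e.kind for e in seq]
        assert kinds == ["activation-onset", "deactivation-onset"] * 3
        assert [e.raw_time for e in seq] == sorted(e.raw_time for e in seq)

    def test_trailing_onset_still_on_at_fixation(self):
        ev = decode.DecodedEvent(kind="activation-onset", time=4.0, raw_time=4.0,
                                 channel="signal", radius=2.0)
        seq = decode_events_sequence([ev])
        assert [e.kind for e in seq] == ["activation-onset"]

    def test_empty_signal_channel(self):
        assert decode_events_sequence([]) == []

    def test_non_alternating_structure_warns(self):
        events = [
            decode.DecodedEvent(kind="activation-onset", time=t, raw_time=t,
                                channel="signal", radius=t)
            for t in (1.0, 2.0)
        ]
        with pytest.warns(UserWarning):
            decode_events_sequence(events)


class TestAmplitude:
    def test_ratio_and_scale_invariance(self):
        assert quantify_amplitude(10.0, 5.0) == pytest.approx(2.0)
        assert quantify_amplitude(20.0, 10.0) == pytest.approx(2.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            quantify_amplitude(10.0, 0.0)

    def test_dose_staircase_orders_plateaus(self):
        """Three rising doses write three signal plateaus in dose order."""
        spec = synth.ParticleSpec(
            model=GrowthModel(K=1000.0, A=0.0, units="px"),
            centre=(0.0, 0.0), nucleation_time=-8.0,
        )
        schedule = synth.DyeSchedule(switches=[(0.0, "a")])
        trace = synth.SignalTrace(
            events=[(0.0, 6.0, 0.2), (8.0, 14.0, 0.6), (16.0, 22.0, 1.0)],
            delay=0.0, tau_on=0.05, tau_off=0.1,
        )
        rec = synth.compose_radial_record(
            spec, schedule, trace, end_time=24.0, resolution=0.05, gain=100.0
        )
        peaks = profiles.call_peaks(rec, "signal", min_separation=1.0)
        heights = [p.height for p in peaks[:3]]
        assert len(heights) == 3
        assert heights == sorted(heights)


class TestHalfmaxPosition:
    def test_midway_and_edge_positions(self):
        y = np.zeros(100)
        y[50:] = 10.0
        prof = profiles.RadialProfile(
            ell=np.arange(100.0), channels={"signal": y}
        )
        frac, flags = normalized_halfmax_position(prof, "signal", (30.0, 70.0))
        assert frac == pytest.approx(0.5, abs=0.02)
        assert flags == []
        frac2, _ = normalized_halfmax_position(prof, "signal", (50.0, 90.0))
        assert frac2 == pytest.approx(0.0, abs=0.02)

    def test_outside_window_is_flagged(self):
        y = np.zeros(100)
        y[80:] = 10.0
        prof = profiles.RadialProfile(ell=np.arange(100.0), channels={"signal": y})
        _, flags = normalized_halfmax_position(prof, "signal", (10.0, 50.0))
        assert "out-of-window" in flags

    def test_group_medians_increase_with_induction_time(self):
        """Signals induced at 0/12/24 h map to increasing window fractions."""
        rng = np.random.default_rng(6)
        stamps = (0.0, 24.0)
        medians = []
        for t_sig in (0.0, 12.0, 24.0):
            df = synth.jittered_band_set(
                list(stamps), [t_sig], n_particles=60, radial_jitter_sd=0.02,
                k_mean=0.3, nucleation_time=-8.0, seed=int(rng.integers(2**31)),
            )
            fracs = []
            for _, sub in df.groupby("particle"):
                st_ = sub[sub["role"] == "stamp"]["radius_obs"].to_numpy()
                ev = sub[sub["role"] == "event"]["radius_obs"].to_numpy()
                r1, r2 = sorted(st_)
                fracs.append((ev[0] - r1) / (r2 - r1))
            medians.append(np.median(fracs))
        assert medians[0] < medians[1] < medians[2]


class TestBenchmark:
    def test_zero_jitter_decodes_perfectly(self):
        res = benchmark_decoding(
            [0.0, 11.0], [3.0, 6.0], 30, radial_jitter_sd=0.0, seed=1
        )
        assert np.allclose(res.table["error"], 0.0, atol=1e-8)
        assert res.fractions[1.0] == 1.0

    def test_fractions_monotone_and_confusion_consistent(self):
        res = benchmark_decoding(
            [0.0, 11.0], [2.0, 5.0, 8.0], 80, sigma_t_target=0.75, seed=2
        )
        vals = [res.fractions[w] for w in sorted(res.fractions)]
        assert vals == sorted(vals)
        col_sums = res.confusion.sum(axis=0)
        for g in (2.0, 5.0, 8.0):
            assert col_sums[g] == (res.table["group"] == g).sum()

    def test_same_seed_reproduces_statistics(self):
        kw = dict(stamp_times=[0.0, 11.0], group_times=[4.0], n_per_group=50,
                  sigma_t_target=0.75, seed=9)
        a, b = benchmark_decoding(**kw), benchmark_decoding(**kw)
        assert a.table.equals(b.table)

    def test_timing_error_scales_with_t_to_two_thirds(self):
        """Monte-Carlo group s.d. follows the delta-method t^(2/3) curve."""
        k, sigma_r = 0.3, 0.01
        groups = [10.0, 30.0, 60.0]
        sds = []
        for t in groups:
            m = GrowthModel(K=k, A=0.0)
            rng = np.random.default_rng(int(t))
            r = m.radius_at_time(t)
            decoded = m.time_at_radius(r + rng.normal(0, sigma_r, 10_000))
            sds.append(decoded.std(ddof=1))
        analytic = [3 * (k * t) ** (2 / 3) * sigma_r / k for t in groups]
        np.testing.assert_allclose(sds, analytic, rtol=0.10)


class TestResolutionLimit:
    def test_well_separated_events_always_resolve(self):
        limit, counts = decode.resolution_limit([3.0], boost=True, seed=4)
        assert counts[3.0] == 2
        assert limit == 3.0

    def test_slow_kinetics_resolve_one_hour_but_merge_finer(self):
        """Without fast turnover, bands stay distinct at 1 h but fuse at 15 min."""
        limit, counts = decode.resolution_limit([1.0, 0.25], boost=False, seed=4)
        assert counts[1.0] == 2
        assert counts[0.25] < 2
        assert limit == 1.0
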