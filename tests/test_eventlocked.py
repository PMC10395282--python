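"""Epoching, baselines, component measures, jackknife, and lateralized
(contra-minus-ipsi) waveforms."""

import numpy as np
import pandas as pd
import pytest

from driveload.datatypes import (
    ComponentMeasure,
    ContinuousRecording,
    EventLockedSet,
    MONTAGE_32,
    OcularEvent,
)
from driveload.synthetic import GeneratorConfig, simulate_recording
from driveload import eventlocked as el

FS = 500.0


def _make_els(data, lock_kind="fixation", metadata=None, fs=FS):
    n_ev, n_ch, n_t = data.shape
    times = (np.arange(n_t) - n_t // 3) * 1000.0 / fs
    meta = metadata if metadata is not None else pd.DataFrame(
        dict(load=["low"] * n_ev, direction=["right"] * n_ev,
             sacc_type=["outward"] * n_ev, subject=[0] * n_ev))
    return EventLockedSet(data=data, times=times, lock_kind=lock_kind,
                          channel_names=MONTAGE_32[:n_ch], metadata=meta,
                          sample_rate=fs)


class TestEpoching:
    def _rec_and_events(self, rng, n=30000):
        rec = ContinuousRecording(rng.normal(size=(32, n)), FS, MONTAGE_32)
        events = [OcularEvent("fixation_onset", s, "right", "outward",
                              load_level="low")
                  for s in (100, 5000, 15000, n - 100)]
        return rec, events

    def test_constant_offset_removed_by_baseline(self):
        rec = ContinuousRecording(np.full((32, 10000), 4.2), FS, MONTAGE_32)
        ev = [OcularEvent("fixation_onset", 5000, "left", "inward",
                          load_level="low")]
        els = el.epoch_events(rec, ev, "fixation")
        b0, b1 = el.BASELINES["fixation"]
        mask = (els.times >= b0) & (els.times < b1)
        assert np.abs(els.data[0][:, mask].mean()) < 1e-12

    def test_out_of_bounds_events_dropped(self, rng):
        rec, events = self._rec_and_events(rng)
        els = el.epoch_events(rec, events, "fixation")
        assert els.n_events == 2
        assert els.n_dropped == 2

    def test_event_without_load_label_excluded(self, rng):
        rec, _ = self._rec_and_events(rng)
        events = [OcularEvent("fixation_onset", 5000, "left", "inward"),
                  OcularEvent("fixation_onset", 9000, "left", "inward",
                              load_level="high")]
        els = el.epoch_events(rec, events, "fixation")
        assert els.n_events == 1
        assert els.metadata["load"].tolist() == ["high"]

    def test_baseline_idempotent(self, rng):
        rec, events = self._rec_and_events(rng)
        els = el.epoch_events(rec, events, "fixation")
        before = els.data.copy()
        el.apply_baseline(els)
        np.testing.assert_allclose(els.data, before, atol=1e-12)


class TestGrandAverage:
    def test_two_identical_events(self, rng):
        x = rng.normal(size=(1, 4, 100))
        data = np.repeat(x, 2, axis=0)
        els = _make_els(data)
        avg, n = el.grand_average(els, ("load",))[("low",)]
        assert n == 2
        np.testing.assert_allclose(avg, x[0], atol=1e-12)

    def test_noise_shrinks_as_sqrt_n(self, rng):
        n_ev = 64
        data = rng.normal(size=(n_ev, 2, 200))
        els = _make_els(data)
        avg, _ = el.grand_average(els, ("load",))[("low",)]
        rms_one = np.sqrt((data[0] ** 2).mean())
        rms_avg = np.sqrt((avg ** 2).mean())
        assert rms_avg == pytest.approx(rms_one / np.sqrt(n_ev), rel=0.25)

    def test_cell_counts_conserve_events(self, rng):
        n_ev = 30
        meta = pd.DataFrame(dict(
            load=rng.choice(["low", "medium", "high"], n_ev),
            direction=["left"] * n_ev, sacc_type=["inward"] * n_ev,
            subject=[0] * n_ev))
        els = _make_els(rng.normal(size=(n_ev, 2, 50)), metadata=meta)
        cells = el.grand_average(els, ("load",))
        assert sum(n for _, n in cells.values()) == n_ev


class TestMeasures:
    def test_negative_peak_recovered(self):
        times = np.arange(-500, 1000, 2.0)
        trace = -3.0 * np.exp(-0.5 * ((times - 100) / 20) ** 2)
        spec = ComponentMeasure("N1", "fixation", (20, 200),
                                ("O1", "Oz", "O2"), "negative")
        assert el.measure_component(trace, times, spec) == pytest.approx(-3.0)

    def test_flat_waveform_all_zero(self):
        times = np.arange(-500, 1000, 2.0)
        for spec in el.component_table():
            if spec.lock_kind == "saccade":
                times_s = np.arange(-1000, 500, 2.0)
                assert el.measure_component(np.zeros_like(times_s), times_s,
                                            spec) == 0.0
            else:
                assert el.measure_component(np.zeros_like(times), times,
                                            spec) == 0.0

    def test_cnv_window_mean_on_ramp(self):
        times = np.arange(-1000, 500, 2.0)
        a = 0.01
        trace = a * times
        spec = el.get_measure("CNV", "saccade")
        # mean of a*t over [-200, -50] = a * midpoint
        assert el.measure_component(trace, times, spec) == pytest.approx(
            a * (-125.0), rel=1e-6)

    def test_window_outside_epoch_rejected(self):
        times = np.arange(0, 100, 2.0)
        spec = el.get_measure("CNV", "saccade")
        with pytest.raises(ValueError, match="outside"):
            el.measure_component(np.zeros_like(times), times, spec)


class TestJackknife:
    def _averages(self, rng, n_sub=15, effect=0.0):
        times = np.arange(-500, 1000, 2.0)
        out = {}
        for s in range(n_sub):
            data = rng.normal(0, 0.5, size=(32, len(times)))
            bump = (2.0 + effect * s / n_sub) * np.exp(
                -0.5 * ((times - 150) / 25) ** 2)
            for ch in ("CP1", "CP2", "P3", "Pz", "P4"):
                data[MONTAGE_32.index(ch)] += bump
            out[s] = data
        return out, times

    def test_two_subjects_rejected(self, rng):
        avgs, times = self._averages(rng, n_sub=2)
        spec = el.get_measure("P2_parietal", "fixation")
        with pytest.raises(ValueError, match="3"):
            el.jackknife_peaks(avgs, times, MONTAGE_32, spec)

    def test_identical_subjects_degenerate(self, rng):
        avgs, times = self._averages(rng, n_sub=1)
        same = {s: avgs[0] for s in range(5)}
        spec = el.get_measure("P2_parietal", "fixation")
        loo = el.jackknife_peaks(same, times, MONTAGE_32, spec)
        full = el.measure_on_average(avgs[0], MONTAGE_32, times, spec)
        assert all(v == pytest.approx(full) for v in loo.values())

    def test_jackknife_f_equals_conventional_for_window_means(self, rng):
        """For a linear (window-mean) measure the (n-1)^2-rescaled jackknife
        F is algebraically the conventional F; checked by brute force."""
        from driveload.anova import rm_anova

        n_sub, k = 15, 3
        spec = el.get_measure("CNV", "saccade")
        times = np.arange(-1000, 500, 2.0)
        conv = np.empty((n_sub, k))
        per_subject = {}
        for cond in range(k):
            for s in range(n_sub):
                data = rng.normal(0, 0.4, size=(32, len(times)))
                data[MONTAGE_32.index("Cz")] -= 0.5 * cond
                per_subject[s] = data
                conv[s, cond] = el.measure_on_average(data, MONTAGE_32,
                                                      times, spec)
            loo = el.jackknife_peaks(per_subject, times, MONTAGE_32, spec)
            if cond == 0:
                jk = np.empty((n_sub, k))
            jk[:, cond] = [loo[s] for s in sorted(loo)]
        f_conv = rm_anova(conv)[0].F
        f_jk = rm_anova(jk, jackknife=True)[0].F
        assert f_jk == pytest.approx(f_conv, rel=0.01)


class TestContraIpsi:
    def test_symmetric_data_zero(self, rng):
        data = rng.normal(size=(6, 32, 100))
        for left, right in (("P7", "P8"), ("PO9", "PO10"), ("O1", "O2")):
            data[:, MONTAGE_32.index(right)] = data[:, MONTAGE_32.index(left)]
        els = _make_els(data)
        np.testing.assert_allclose(el.contra_ipsi(els), 0.0, atol=1e-12)

    def test_direction_flip_negates(self, rng):
        data = rng.normal(size=(8, 32, 100))
        meta = pd.DataFrame(dict(load=["low"] * 8,
                                 direction=["right"] * 4 + ["left"] * 4,
                                 sacc_type=["outward"] * 8, subject=[0] * 8))
        els = _make_els(data, metadata=meta)
        wave = el.contra_ipsi(els)
        flipped_meta = meta.copy()
        flipped_meta["direction"] = ["left"] * 4 + ["right"] * 4
        els2 = _make_els(data, metadata=flipped_meta)
        np.testing.assert_allclose(el.contra_ipsi(els2), -wave, atol=1e-12)

    def test_direction_none_excluded(self, rng):
        data = np.zeros((2, 32, 100))
        data[0, MONTAGE_32.index("O1")] = 5.0  # would dominate if included
        meta = pd.DataFrame(dict(load=["low"] * 2,
                                 direction=["none", "right"],
                                 sacc_type=["none", "outward"],
                                 subject=[0, 0]))
        els = _make_els(data, metadata=meta)
        np.testing.assert_allclose(el.contra_ipsi(els), 0.0, atol=1e-12)

    def test_injected_contralateral_deflection_recovered(self):
        """-1 uV on the contralateral pair members at 100 ms -> ERL -1."""
        n_t = 750
        times = (np.arange(n_t) - 250) * 1000.0 / FS
        data = np.zeros((2, 32, n_t))
        bump = -1.0 * ((times >= 80) & (times <= 120))
        for i, d in enumerate(("right", "left")):
            for left, right in (("P7", "P8"), ("PO9", "PO10"), ("O1", "O2")):
                contra = left if d == "right" else right
                data[i, MONTAGE_32.index(contra)] = bump
        meta = pd.DataFrame(dict(load=["low"] * 2,
                                 direction=["right", "left"],
                                 sacc_type=["outward"] * 2, subject=[0] * 2))
        els = EventLockedSet(data=data, times=times, lock_kind="fixation",
                             channel_names=MONTAGE_32, metadata=meta,
                             sample_rate=FS)
        wave = el.contra_ipsi(els)
        spec = el.get_measure("phasic_ERL", "fixation")
        assert el.measure_component(wave, times, spec) == pytest.approx(-1.0)


def test_lateralized_measures_inward_tonic_exceeds_outward(short_route,
                                                           short_telemetry):
    """Generator injects pre-saccadic contralateral negativity mainly before
    inward saccades; tonic lateralization must reflect that."""
    cfg = GeneratorConfig(snr=None, include_oscillations=False,
                          include_eog=False)
    rec, gt = simulate_recording(short_route, short_telemetry, cfg, seed=17)
    els_f = el.epoch_events(rec, gt.events, "fixation")
    els_s = el.epoch_events(rec, gt.events, "saccade")
    df = el.lateralized_measures(els_f, els_s)
    tonic = df[df.measure.isin(["tonic_ERL1", "tonic_ERL2"])]
    by_type = tonic.groupby("sacc_type").value.mean()
    assert by_type["inward"] < by_type["outward"]
    cnv = df[df.measure == "CNV"].groupby("sacc_type").value.mean()
    assert cnv["inward"] < cnv["outward"]
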