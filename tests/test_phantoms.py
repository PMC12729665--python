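"""Phantom grid construction, excitation synthesis and train simulation."""

import numpy as np
import pytest

from myofat.features import CalibrationRecord, detect_arrival_time, extract_criteria
from myofat.phantoms import (
    AcousticModel,
    DatasetManifest,
    ExcitationSpec,
    PhantomSpec,
    build_phantom_grid,
    default_excitations,
    generate_dataset,
    simulate_train,
    synth_excitation,
    total_fat_fraction,
)


class TestGrid:
    @pytest.mark.parametrize("levels, expected", [
        (None, 25),                       # default 5x5
        ((0.0,), 1),
        ((0.0, 25.0, 50.0), 9),
    ])
    def test_grid_size(self, levels, expected):
        specs = build_phantom_grid() if levels is None \
            else build_phantom_grid(levels)
        assert len(specs) == expected
        pairs = {(s.sat_pct, s.imat_pct) for s in specs}
        assert len(pairs) == expected

    def test_rejects_bad_levels(self):
        with pytest.raises(ValueError):
            build_phantom_grid(())
        with pytest.raises(ValueError):
            build_phantom_grid((25.0, 12.5))
        with pytest.raises(ValueError):
            build_phantom_grid((0.0, 60.0))


class TestTotalFat:
    @pytest.mark.parametrize("sat, imat, expected", [
        (0.0, 0.0, 0.0),
        (50.0, 50.0, 75.0),       # IMAT counts only in the muscle remainder
        (25.0, 25.0, 43.75),
        (50.0, 0.0, 50.0),
        (0.0, 50.0, 50.0),
    ])
    def test_compositing(self, sat, imat, expected):
        assert total_fat_fraction(sat, imat) == pytest.approx(expected)

    def test_range_check(self):
        with pytest.raises(ValueError):
            total_fat_fraction(-1.0, 0.0)
        with pytest.raises(ValueError):
            total_fat_fraction(0.0, 101.0)


class TestExcitation:
    def test_burst_duration_and_length(self):
        ex = ExcitationSpec("tone_burst", 0.8)
        assert ex.duration_us == pytest.approx(2.5)     # 2 cycles / 0.8 MHz
        w = synth_excitation(ex)
        assert abs(w.size - 313) <= 1
        # continuous-time peak is normalised to 1; the sampled maximum can
        # fall between samples
        assert np.max(np.abs(w)) == pytest.approx(1.0, abs=1e-4)

    def test_envelope_endpoints_are_zero(self):
        ex = ExcitationSpec("tone_burst", 2.2)
        w = ex.evaluate(np.array([0.0, ex.duration_us]))
        assert w == pytest.approx([0.0, 0.0], abs=1e-12)

    def test_sweep_energy_in_band(self):
        ex = ExcitationSpec("sweep", (0.5, 2.5))
        w = synth_excitation(ex)
        spec = np.abs(np.fft.rfft(w)) ** 2
        freq = np.fft.rfftfreq(w.size, 1.0 / ex.sample_rate_msps)
        in_band = spec[(freq >= 0.4) & (freq <= 2.6)].sum()
        assert in_band / spec.sum() > 0.90

    def test_sample_rate_guard(self):
        with pytest.raises(ValueError):
            ExcitationSpec("tone_burst", 2.2, sample_rate_msps=20.0)


class TestSimulateTrain:
    def test_noise_free_arrival_matches_closed_form(self):
        model = AcousticModel().noiseless()
        train = simulate_train(PhantomSpec(0.0, 0.0), model, 1, 0)
        t = detect_arrival_time(train.waveform_08, train.sample_rate_msps)
        offset = CalibrationRecord.from_excitations().detection_offset_us[
            "burst_08"]
        expected = 80.0 / 1589.0 * 1000.0          # us
        assert t - offset == pytest.approx(expected, rel=1e-4)

    def test_noise_free_velocity_at_full_fat(self):
        model = AcousticModel().noiseless()
        train = simulate_train(PhantomSpec(50.0, 50.0), model, 1, 0)
        calib = CalibrationRecord.from_excitations()
        cv = extract_criteria(train, calib)
        assert cv.cr1 == pytest.approx(1589.0 - 155.9 * 0.75, rel=1e-3)

    def test_determinism_and_substreams(self):
        a = simulate_train(PhantomSpec(12.5, 25.0), repeat_index=3, seed=9)
        b = simulate_train(PhantomSpec(12.5, 25.0), repeat_index=3, seed=9)
        assert np.array_equal(a.waveform_sweep, b.waveform_sweep)
        assert np.array_equal(a.waveform_08, b.waveform_08)
        c = simulate_train(PhantomSpec(12.5, 25.0), repeat_index=4, seed=9)
        assert not np.array_equal(a.waveform_08, c.waveform_08)

    def test_triple_pass_must_fit_record(self):
        with pytest.raises(ValueError):
            simulate_train(PhantomSpec(0.0, 0.0), sweep_record_us=100.0)

    def test_dataset_size(self):
        manifest = DatasetManifest(build_phantom_grid(), repeats=15, seed=0)
        assert manifest.n_records == 375
        tiny = DatasetManifest([PhantomSpec(0.0, 0.0)], repeats=1, seed=0)
        assert len(generate_dataset(tiny)) == 1

    def test_attenuation_surfaces_monotone(self):
        model = AcousticModel()
        for which in ("08", "22", "sweep", "triple"):
            grid = np.array([[model.attenuation(which, s, i)
                              for i in (0, 12.5, 25, 37.5, 50)]
                             for s in (0, 12.5, 25, 37.5, 50)])
            assert np.all(np.diff(grid, axis=0) >= 0)
            assert np.all(np.diff(grid, axis=1) >= 0)


class TestCalibrationConsistency:
    """Whole-chain statistics of the default model against its calibration."""

    def test_cr1_grid_moments(self, grid_records):
        cr1 = grid_records["cr1"]
        assert cr1.mean() == pytest.approx(1520.0, abs=2.0)
        assert cr1.std(ddof=1) == pytest.approx(30.3, abs=2.0)

    def test_noise_free_extraction_matches_model(self, noisefree_records):
        model = AcousticModel()
        for _, row in noisefree_records.iterrows():
            at = total_fat_fraction(row["sat"], row["imat"]) / 100.0
            assert row["cr1"] == pytest.approx(model.velocity(at), rel=1e-3)

    def test_noise_free_attenuations_monotone_along_axes(self, noisefree_records):
        one = noisefree_records[noisefree_records["repeat"] == 1]
        for crit in ("cr2", "cr3"):
            piv = one.pivot(index="sat", columns="imat", values=crit)
            assert np.all(np.diff(piv.to_numpy(), axis=0) > -1e-9)
            assert np.all(np.diff(piv.to_numpy(), axis=1) > -1e-9)
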