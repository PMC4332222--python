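"""Constant-phase forward model, lung sampling and record simulation."""

import math

import numpy as np
import pytest

from lungfot.presets import load_presets
from lungfot.protocol import build_protocol
from lungfot.simulate import (
    CompartmentParams,
    LungModel,
    UnmeasurableLungError,
    compartment_impedance,
    generate_cohort,
    lung_impedance,
    sample_lung,
    simulate_record,
    read_record_csv,
    write_record_csv,
    read_record_hdf5,
    write_record_hdf5,
)

SQRT_PI = math.sqrt(math.pi)


def one_compartment(g, h, raw=0.0, iaw=0.0, pc=-5.0, rc=0.0, ic=0.0):
    comp = CompartmentParams(raw=raw, iaw=iaw, g=g, h=h, pc=pc)
    return LungModel(rc=rc, ic=ic, compartments=(comp,),
                     raw_peep_slope=0.0, h_peep_slope=0.0)


class TestCompartmentImpedance:
    def test_equal_g_h_gives_alpha_half(self):
        c = CompartmentParams(raw=0.0, iaw=0.0, g=3.611, h=3.611, pc=0.0)
        assert c.alpha == pytest.approx(0.5, abs=1e-15)

    def test_closed_form_at_half_hertz(self):
        # G = H = 3.611, alpha = 1/2, omega = pi:
        # Re Z = Raw + G/sqrt(pi), E = -omega Im Z = H*sqrt(pi)
        c = CompartmentParams(raw=0.3, iaw=0.0, g=3.611, h=3.611, pc=0.0)
        z = compartment_impedance(c, 0.5)
        assert z.real == pytest.approx(0.3 + 3.611 / SQRT_PI, rel=1e-12)
        assert -math.pi * z.imag == pytest.approx(3.611 * SQRT_PI, rel=1e-12)

    def test_alpha_consistency_with_g_h(self):
        c = CompartmentParams(raw=0.1, iaw=0.0, g=1.7, h=9.3, pc=0.0)
        assert c.alpha == pytest.approx((2 / math.pi) * math.atan(9.3 / 1.7), abs=1e-12)

    def test_high_frequency_limit_is_resistive(self):
        c = CompartmentParams(raw=0.4, iaw=0.0, g=2.0, h=2.0, pc=0.0)
        z = compartment_impedance(c, 1e7)
        assert z.real == pytest.approx(0.4, abs=1e-3)
        assert -1e-3 < z.imag < 0

    def test_nonpositive_frequency_rejected(self):
        c = CompartmentParams(raw=0.0, iaw=0.0, g=1.0, h=1.0, pc=0.0)
        with pytest.raises(ValueError):
            compartment_impedance(c, 0.0)

    def test_nonpositive_tissue_constants_rejected(self):
        with pytest.raises(ValueError):
            CompartmentParams(raw=0.0, iaw=0.0, g=0.0, h=1.0, pc=0.0)


class TestLungImpedance:
    def test_identical_parallel_compartments_scale_as_one_over_n(self):
        comp = CompartmentParams(raw=0.5, iaw=0.0, g=4.0, h=8.0, pc=-5.0)
        f = np.array([0.5, 2.0, 19.625])
        z1 = compartment_impedance(comp, f)
        for n in (2, 5):
            model = LungModel(rc=0.1, ic=2e-4, compartments=(comp,) * n,
                              raw_peep_slope=0.0, h_peep_slope=0.0)
            z = lung_impedance(model, f, peep_cmh2o=0.0)
            expected = 0.1 + 1j * 2 * np.pi * f * 2e-4 + z1 / n
            assert np.allclose(z, expected, rtol=1e-12)

    def test_single_compartment_identity(self):
        model = one_compartment(g=3.0, h=6.0, raw=0.2)
        f = np.array([0.5, 5.0])
        assert np.allclose(
            lung_impedance(model, f, 0.0),
            compartment_impedance(model.compartments[0], f),
        )

    def test_unequal_raw_raises_elastance_with_frequency(self):
        # parallel heterogeneity of airway resistance produces a positive
        # frequency dependence of E beyond the intrinsic constant-phase rise
        f = np.linspace(0.5, 19.625, 40)
        omega = 2 * np.pi * f
        base = CompartmentParams(raw=0.5, iaw=0.0, g=3.0, h=10.0, pc=-5.0)
        homo = LungModel(rc=0.0, ic=0.0, compartments=(base, base),
                         raw_peep_slope=0.0, h_peep_slope=0.0)
        hetero = LungModel(
            rc=0.0, ic=0.0,
            compartments=(
                CompartmentParams(raw=0.1, iaw=0.0, g=3.0, h=10.0, pc=-5.0),
                CompartmentParams(raw=2.5, iaw=0.0, g=3.0, h=10.0, pc=-5.0),
            ),
            raw_peep_slope=0.0, h_peep_slope=0.0,
        )
        e_homo = -omega * lung_impedance(homo, f, 0.0).imag
        e_het = -omega * lung_impedance(hetero, f, 0.0).imag
        rise_homo = e_homo[-1] / e_homo[0]
        rise_het = e_het[-1] / e_het[0]
        assert rise_het > rise_homo

    def test_all_closed_is_unmeasurable(self):
        model = one_compartment(g=1.0, h=1.0, pc=10.0)
        with pytest.raises(UnmeasurableLungError):
            lung_impedance(model, np.array([0.5]), peep_cmh2o=0.0)

    def test_recruitment_monotone_in_peep(self):
        comps = tuple(
            CompartmentParams(raw=0.5, iaw=0.0, g=2.0, h=6.0, pc=pc)
            for pc in (-2.0, 1.0, 3.0, 5.0, 7.0)
        )
        model = LungModel(rc=0.05, ic=0.0, compartments=comps)
        n_open = [model.n_open(p) for p in (0, 2, 4, 6, 8)]
        assert n_open == sorted(n_open)
        assert n_open[0] >= 1


class TestSampleLung:
    def test_deterministic_given_seed(self):
        lib = load_presets()
        m1 = sample_lung(lib, "A2", np.random.default_rng(5))
        m2 = sample_lung(lib, "A2", np.random.default_rng(5))
        assert m1 == m2

    def test_isograft_never_derecruits(self):
        lib = load_presets()
        m = sample_lung(lib, "A0_iso", np.random.default_rng(1))
        assert all(c.pc < 0 for c in m.compartments)

    def test_severe_grade_more_heterogeneous_than_mild(self):
        lib = load_presets()
        cv = {}
        for grade in ("A1", "A3"):
            m = sample_lung(lib, grade, np.random.default_rng(1))
            h = np.array([c.h for c in m.compartments])
            cv[grade] = h.std() / h.mean()
        assert cv["A3"] > cv["A1"]

    def test_unknown_grade_rejected(self):
        with pytest.raises(ValueError, match="unknown grade"):
            sample_lung(load_presets(), "A4", np.random.default_rng(0))

    def test_measurable_at_zero_peep_for_every_grade(self):
        lib = load_presets()
        for grade in lib.grades:
            for seed in range(5):
                m = sample_lung(lib, grade, np.random.default_rng(seed))
                assert m.is_measurable(0.0)


class TestSimulateRecord:
    def test_noiseless_record_matches_closed_form(self, default_protocol):
        model = one_compartment(g=3.0, h=9.0, raw=0.4, rc=0.05, ic=2e-4)
        rec = simulate_record(model, default_protocol, peep_cmh2o=0.0)
        kbins = np.asarray(default_protocol.k_indices)
        qf = np.fft.rfft(rec.q)[kbins]
        pf = np.fft.rfft(rec.p)[kbins]
        z_true = lung_impedance(model, default_protocol.freqs_hz, 0.0)
        assert np.max(np.abs(pf / qf - z_true) / np.abs(z_true)) < 1e-9

    def test_resistive_limit_pointwise(self, default_protocol):
        model = one_compartment(g=1e-9, h=1e-9, raw=0.8)
        rec = simulate_record(model, default_protocol, peep_cmh2o=0.0)
        assert np.allclose(rec.p, 0.8 * rec.q, atol=1e-6 * np.max(np.abs(rec.p)))

    def test_noise_only_on_pressure(self, default_protocol):
        model = one_compartment(g=3.0, h=9.0, raw=0.4)
        r1 = simulate_record(model, default_protocol, 0.0, snr_db=40,
                             rng=np.random.default_rng(1))
        r2 = simulate_record(model, default_protocol, 0.0, snr_db=40,
                             rng=np.random.default_rng(2))
        assert np.array_equal(r1.q, r2.q)
        assert not np.array_equal(r1.p, r2.p)

    def test_snr_level_is_respected(self, default_protocol):
        model = one_compartment(g=3.0, h=9.0, raw=0.4)
        clean = simulate_record(model, default_protocol, 0.0)
        noisy = simulate_record(model, default_protocol, 0.0, snr_db=40,
                                rng=np.random.default_rng(0), n_windows=8)
        resid = noisy.p - np.tile(clean.p, 8)
        snr = 10 * np.log10(np.mean(clean.p**2) / np.mean(resid**2))
        assert snr == pytest.approx(40.0, abs=1.0)


class TestGenerateCohort:
    def test_default_cohort_shape(self, cohort):
        assert len(cohort.models) == 29            # 6+6+4+7+6 animals
        assert len(cohort.records) == 29 * 5       # five PEEP levels each

    def test_metadata_reproducible(self, cohort, preset_library):
        again = generate_cohort(library=preset_library, seed=0)
        assert again.metadata.equals(cohort.metadata)

    def test_single_animal_per_group(self, preset_library):
        from lungfot.simulate import CohortDesign

        design = CohortDesign(group_sizes={g: 1 for g in preset_library.grades},
                              snr_db=None)
        c = generate_cohort(design, preset_library, seed=3)
        assert len(c.models) == 5
        assert len(c.records) == 25


class TestRecordIO:
    def test_csv_round_trip(self, default_protocol, tmp_path):
        model = one_compartment(g=3.0, h=9.0, raw=0.4)
        rec = simulate_record(model, default_protocol, 2.0, animal_id="x-01")
        path = tmp_path / "rec.csv"
        write_record_csv(rec, path)
        back = read_record_csv(path)
        assert back.peep_cmh2o == 2.0
        assert back.animal_id == "x-01"
        assert np.allclose(back.p, rec.p)

    def test_hdf5_round_trip(self, default_protocol, tmp_path):
        model = one_compartment(g=3.0, h=9.0, raw=0.4)
        rec = simulate_record(model, default_protocol, 4.0, animal_id="y-02")
        path = tmp_path / "rec.h5"
        write_record_hdf5(rec, path)
        back = read_record_hdf5(path)
        assert np.array_equal(back.q, rec.q)
        assert back.snr_db is None
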