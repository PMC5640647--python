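"""Fluorescence summaries, mixture detection, iron index and calibrations."""

import math

import numpy as np
import pytest

import magflow as mf
from magflow.errors import (
    FitError,
    MetadataError,
    SampleSizeError,
    ValidationError,
)
from magflow.events_io import AcquisitionMeta, ChannelMap, EventTable
from magflow.quantify import FluorescenceSummary
from magflow.synthetic import PopulationSpec, QuenchModel, ScenarioSpec


def _fl1_table(values):
    values = np.asarray(values, dtype=float)
    n = len(values)
    data = np.column_stack([np.ones(n), np.ones(n), values, np.ones(n), np.ones(n)])
    return EventTable(data)


class TestSummarizeFluorescence:
    def test_constant_events(self):
        s = mf.summarize_fluorescence(_fl1_table([100, 100, 100]), "FL1_A")
        assert s.mfi == 100.0 and s.cv == 0.0 and s.n_events == 3

    def test_two_point_hand_computation(self):
        # sample sd of {50,150} is 70.711 (n-1 denominator)
        s = mf.summarize_fluorescence(_fl1_table([50, 150]), "FL1_A")
        assert s.mfi == 100.0
        assert s.cv == pytest.approx(0.70711, abs=1e-4)

    def test_matches_lognormal_mean_closed_form(self):
        mu, sigma = 2.0, 0.2
        spec = PopulationSpec("p", 1.0, {"FL1_A": mu}, {"FL1_A": sigma})
        table = mf.sample_population(
            spec, 100_000, seed=11, channel_map=ChannelMap(("FSC_A", "SSC_A", "FL1_A"))
        )
        expected = 10**mu * math.exp((sigma * math.log(10)) ** 2 / 2.0)
        s = mf.summarize_fluorescence(table, "FL1_A")
        assert s.mfi == pytest.approx(expected, rel=0.02)

    def test_scaling_behaviour(self):
        """MFI scales linearly under intensity rescaling; CV is scale-invariant."""
        base = _fl1_table([50, 100, 200, 400])
        scaled = _fl1_table([500, 1000, 2000, 4000])
        a = mf.summarize_fluorescence(base, "FL1_A")
        b = mf.summarize_fluorescence(scaled, "FL1_A")
        assert b.mfi == pytest.approx(10 * a.mfi, rel=1e-12)
        assert b.cv == pytest.approx(a.cv, rel=1e-12)

    def test_empty_table_rejected(self):
        with pytest.raises(SampleSizeError):
            mf.summarize_fluorescence(_fl1_table([]), "FL1_A")


class TestFitSubpopulations:
    def test_single_mode_selects_one_component(self):
        spec = PopulationSpec("p", 1.0, {"FL1_A": 2.5}, {"FL1_A": 0.25})
        table = mf.sample_population(
            spec, 5000, seed=12, channel_map=ChannelMap(("FSC_A", "SSC_A", "FL1_A"))
        )
        fit = mf.fit_subpopulations(table, "FL1_A")
        assert fit.k == 1

    def test_two_mode_parameter_recovery(self):
        """40/60 mixture at log10 means 1.5/3.5 (sd 0.2), n=25 000."""
        spec = ScenarioSpec(
            "mix",
            (
                PopulationSpec("lo", 0.4, {"FL1_A": 1.5}, {"FL1_A": 0.2}),
                PopulationSpec("hi", 0.6, {"FL1_A": 3.5}, {"FL1_A": 0.2}),
            ),
            n_events=25_000,
            seed=13,
        )
        table = mf.generate_scenario(spec, channel_map=ChannelMap(("FSC_A", "SSC_A", "FL1_A")))
        fit = mf.fit_subpopulations(table, "FL1_A")
        assert fit.k == 2
        assert fit.weights[0] == pytest.approx(0.4, abs=0.03)
        assert fit.means[0] == pytest.approx(1.5, abs=0.05)
        assert fit.means[1] == pytest.approx(3.5, abs=0.05)

    def test_packaged_pha_scenarios_split_as_expected(self):
        """Magnetic culture shows two PHA modes; non-magnetic only one."""
        magnetic = mf.generate_scenario(mf.load_scenario("magnetic_pha"))
        nonmagnetic = mf.generate_scenario(mf.load_scenario("nonmagnetic_pha"))
        assert mf.fit_subpopulations(magnetic, "FL1_A").k == 2
        assert mf.fit_subpopulations(nonmagnetic, "FL1_A").k == 1

    def test_too_few_events_rejected(self):
        with pytest.raises(SampleSizeError):
            mf.fit_subpopulations(_fl1_table(np.ones(100)), "FL1_A")


class TestIronIndex:
    def test_identity_when_sample_equals_reference(self):
        s = FluorescenceSummary("FL1_A", 1000.0, 0.1, 100)
        idx = mf.iron_index(s, s, QuenchModel(f0=1000.0, K_sv=0.1))
        assert idx.fold_quench == 1.0
        assert idx.iron_uM == pytest.approx(0.0, abs=1e-12)

    def test_inverts_quench_closed_form(self):
        ref = FluorescenceSummary("FL1_A", 1000.0, 0.1, 100)
        smp = FluorescenceSummary("FL1_A", 500.0, 0.1, 100)
        idx = mf.iron_index(smp, ref, QuenchModel(f0=1000.0, K_sv=0.1))
        assert idx.fold_quench == pytest.approx(2.0, rel=1e-12)
        assert idx.iron_uM == pytest.approx(10.0, rel=1e-12)

    def test_without_model_no_iron_estimate(self):
        ref = FluorescenceSummary("FL1_A", 1000.0, 0.1, 100)
        smp = FluorescenceSummary("FL1_A", 500.0, 0.1, 100)
        assert mf.iron_index(smp, ref).iron_uM is None

    def test_zero_sample_mfi_rejected(self):
        ref = FluorescenceSummary("FL1_A", 1000.0, 0.1, 100)
        smp = FluorescenceSummary("FL1_A", 0.0, 0.0, 100)
        with pytest.raises(ValidationError):
            mf.iron_index(smp, ref)

    @pytest.mark.parametrize("iron_true", [10.0, 50.0])
    def test_round_trip_through_simulated_events(self, iron_true):
        """Simulated PG-SK samples at known iron recover it within 10%."""
        model = QuenchModel(f0=3000.0, K_sv=0.1)
        cm = ChannelMap(("FSC_A", "SSC_A", "FL1_A"))

        def sample(iron, seed):
            mu = math.log10(mf.pgsk_expected_mfi(iron, model))
            spec = PopulationSpec("p", 1.0, {"FL1_A": mu}, {"FL1_A": 0.25})
            table = mf.sample_population(spec, 25_000, seed=seed, channel_map=cm)
            return mf.summarize_fluorescence(table, "FL1_A")

        idx = mf.iron_index(sample(iron_true, seed=21), sample(0.0, seed=22), model)
        assert idx.iron_uM == pytest.approx(iron_true, rel=0.10)


class TestCountCalibration:
    def test_exact_proportional_pairs(self):
        pairs = [(0.1, 1.16e8), (0.5, 5.8e8), (1.0, 1.16e9)]
        cal = mf.fit_count_calibration(pairs)
        assert cal.slope == pytest.approx(1.16e9, rel=1e-10)
        assert cal.r2 == pytest.approx(1.0, abs=1e-10)

    def test_degenerate_designs_rejected(self):
        with pytest.raises(FitError):
            mf.fit_count_calibration([(0.5, 1e8), (0.5, 1.1e8), (0.5, 0.9e8)])
        with pytest.raises(FitError):
            mf.fit_count_calibration([(0.5, 1e8), (1.0, 2e8)])
        with pytest.raises(ValidationError):
            mf.fit_count_calibration([(0.5, 1e8), (1.0, 2e8), (-0.1, 1e7)])

    def test_recovers_generator_slope(self):
        od = np.linspace(0.05, 1.0, 8)
        pairs = mf.generate_dilution_series(1.16e9, od, cv=0.05, seed=42)
        cal = mf.fit_count_calibration(pairs)
        assert cal.slope == pytest.approx(1.16e9, rel=0.05)
        assert cal.r2 >= 0.95

    def test_od_to_concentration_with_packaged_constants(self):
        assert mf.od_to_concentration(1.0, mf.packaged_calibration("fcm_unstained")) == 1.16e9
        assert mf.od_to_concentration(1.0, mf.packaged_calibration("fcm_syto62")) == 1.03e9
        assert mf.od_to_concentration(1.0, mf.packaged_calibration("cfu")) == 3.3e8
        assert mf.od_to_concentration(0.0, mf.packaged_calibration("cfu")) == 0.0

    def test_negative_od_rejected(self):
        with pytest.raises(ValidationError):
            mf.od_to_concentration(-0.1, mf.packaged_calibration("fcm_unstained"))


class TestEventsToConcentration:
    def test_volumetric_arithmetic(self):
        # 70 000 events in 35 uL/min x 120 s = 70 uL = 0.07 mL
        meta = AcquisitionMeta(n_events=70_000, flow_rate=35.0, duration=120.0)
        assert mf.events_to_concentration(meta) == pytest.approx(1.0e6, rel=1e-12)

    def test_zero_events(self):
        meta = AcquisitionMeta(n_events=0, flow_rate=35.0, duration=120.0)
        assert mf.events_to_concentration(meta) == 0.0

    def test_linear_in_dilution_factor(self):
        meta = AcquisitionMeta(
            n_events=70_000, flow_rate=35.0, duration=120.0, dilution_factor=100.0
        )
        assert mf.events_to_concentration(meta) == pytest.approx(1.0e8, rel=1e-12)

    def test_sentinel_metadata_rejected(self):
        meta = AcquisitionMeta(n_events=100, flow_rate=35.0, duration=None)
        with pytest.raises(MetadataError):
            mf.events_to_concentration(meta)
        assumed = AcquisitionMeta(
            n_events=100, flow_rate=35.0, duration=60.0, assumed=("duration",)
        )
        with pytest.raises(MetadataError):
            mf.events_to_concentration(assumed)
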