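"""Noise gating, threshold placement and quadrant viability classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import magflow as mf
from magflow.errors import ChannelError, SampleSizeError, ValidationError
from magflow.events_io import ChannelMap, EventTable
from magflow.gating import _nearest_rank_percentile


def _fl_table(fl1, fl3):
    """5-channel table with given FL1/FL3 values and unit scatter."""
    fl1 = np.asarray(fl1, dtype=float)
    fl3 = np.asarray(fl3, dtype=float)
    n = len(fl1)
    data = np.column_stack([np.ones(n), np.ones(n), fl1, fl3, np.ones(n)])
    return EventTable(data)


class TestLogDisplay:
    def test_clips_at_one(self):
        assert mf.log_display([0.0])[0] == 0.0

    def test_exact_powers_of_ten(self):
        np.testing.assert_allclose(mf.log_display([1, 10, 100, 1000]), [0, 1, 2, 3])

    def test_rejects_negative(self):
        with pytest.raises(ValidationError):
            mf.log_display([-1.0])

    @given(st.lists(st.floats(0, 1e6), min_size=2, max_size=20))
    @settings(deadline=None, max_examples=50)
    def test_monotone_nondecreasing(self, values):
        values = sorted(values)
        out = mf.log_display(values)
        assert np.all(np.diff(out) >= 0)


class TestNoiseGate:
    def test_zero_cut_retains_everything(self):
        table = mf.generate_scenario(mf.load_scenario("cells_with_debris", n_events=1000))
        gated = mf.noise_gate(table, mode="syto62", cut=0.0)
        assert gated.n_events == table.n_events

    def test_syto62_gate_recovers_cell_fraction(self):
        """FL4 cut at 100 separates DNA-stained cells (mu=3) from debris (mu=1)."""
        table = mf.generate_scenario(mf.load_scenario("cells_with_debris"))
        gated = mf.noise_gate(table, mode="syto62", cut=100.0)
        sd = math.sqrt(0.8 * 0.2 / table.n_events)
        assert abs(gated.meta.retained_fraction - 0.80) < 3 * sd
        # and the retained events are overwhelmingly true cells
        assert np.mean(gated.true_label == "cell") > 0.99

    def test_cut_above_all_values_gives_valid_empty_table(self):
        table = mf.generate_scenario(mf.load_scenario("cells_with_debris", n_events=200))
        gated = mf.noise_gate(table, mode="syto62", cut=1e12)
        assert gated.n_events == 0

    def test_missing_channel_raises(self):
        table = EventTable(np.ones((5, 2)), ChannelMap(("FSC_A", "SSC_A")))
        with pytest.raises(ChannelError):
            mf.noise_gate(table, mode="syto62", cut=1.0)
        # scatter mode still works
        assert mf.noise_gate(table, mode="scatter", cut=0.5).n_events == 5


class TestEstimateThresholds:
    def test_constant_control_pins_both_cuts(self):
        table = _fl_table([10.0] * 200, [10.0] * 200)
        thr = mf.estimate_thresholds(table)
        assert thr.fl1_cut == 10.0 and thr.fl3_cut == 10.0

    def test_nearest_rank_on_enumerated_uniform(self):
        values = np.arange(1, 1001, dtype=float)
        table = _fl_table(values, values)
        thr = mf.estimate_thresholds(table, percentile=99.5)
        assert thr.fl1_cut == 995.0

    def test_small_control_rejected(self):
        table = _fl_table([10.0] * 50, [10.0] * 50)
        with pytest.raises(SampleSizeError):
            mf.estimate_thresholds(table)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("percentile", [50.0, 90.0, 99.5, 100.0])
    def test_agrees_with_brute_force_oracle(self, seed, percentile):
        """Nearest-rank: smallest v in the sample with #(x<=v) >= ceil(p*n/100)."""
        rng = np.random.default_rng(seed)
        values = rng.lognormal(3, 1, size=1000)

        def oracle(x, p):
            target = math.ceil(p * len(x) / 100.0)
            for v in sorted(x):
                if np.sum(x <= v) >= target:
                    return v
            return max(x)

        assert _nearest_rank_percentile(values, percentile) == oracle(values, percentile)

    def test_provenance_recorded(self, unstained_control):
        thr = mf.estimate_thresholds(unstained_control, control_id="ctrl-1")
        assert thr.control_id == "ctrl-1"
        assert thr.percentile == 99.5


class TestClassifyViability:
    def test_hand_placed_events_around_cuts(self):
        """Six events around cuts (10,10); boundary values count negative."""
        table = _fl_table([5, 20, 20, 5, 10, 10], [5, 5, 20, 20, 10, 20])
        labels, fr = mf.classify_viability(table, mf.QuadrantThresholds(10, 10))
        assert list(labels) == [
            "healthy", "injured", "dead", "anomalous", "healthy", "anomalous",
        ]
        assert fr.healthy == pytest.approx(1 / 3)
        assert fr.injured == pytest.approx(1 / 6)
        assert fr.dead == pytest.approx(1 / 6)
        assert fr.anomalous == pytest.approx(1 / 3)

    def test_all_negative_events_are_healthy(self):
        table = _fl_table([0.0] * 10, [0.0] * 10)
        _, fr = mf.classify_viability(table, mf.QuadrantThresholds(10, 10))
        assert fr.healthy == 1.0

    def test_empty_table_warns_instead_of_raising(self):
        table = _fl_table([], [])
        labels, fr = mf.classify_viability(table, mf.QuadrantThresholds(10, 10))
        assert fr.n_events == 0 and fr.warning

    def test_fractions_sum_to_one(self, growing_magnetic, thresholds):
        _, fr = mf.classify_viability(growing_magnetic, thresholds)
        total = fr.healthy + fr.injured + fr.dead + fr.anomalous
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_permutation_invariance(self, thresholds):
        table = mf.generate_scenario(mf.load_scenario("starving_magnetic", n_events=2000))
        rng = np.random.default_rng(0)
        perm = rng.permutation(table.n_events)
        shuffled = EventTable(table.data[perm], table.channel_map)
        _, a = mf.classify_viability(table, thresholds)
        _, b = mf.classify_viability(shuffled, thresholds)
        assert a.to_dict() == b.to_dict()

    def test_raising_fl1_cut_never_decreases_healthy(self, growing_magnetic):
        cuts = [10.0, 50.0, 100.0, 500.0, 1e4, 1e6]
        healthy = []
        for c in cuts:
            _, fr = mf.classify_viability(growing_magnetic, mf.QuadrantThresholds(c, 100.0))
            healthy.append(fr.healthy)
        assert all(b >= a for a, b in zip(healthy, healthy[1:]))

    def test_recovers_generating_fractions_with_midpoint_cuts(self):
        """Populations 2 log-decades apart: midpoint cuts recover the spec
        fractions within 3 binomial standard deviations at n=25 000."""
        table = mf.generate_scenario(mf.load_scenario("starving_magnetic"))
        mid = 10 ** 2.5  # geometric midpoint of the 1.5 / 3.5 locations
        _, fr = mf.classify_viability(table, mf.QuadrantThresholds(mid, mid))
        n = table.n_events
        for name, expected in [
            ("healthy", 0.35), ("injured", 0.40), ("dead", 0.225), ("anomalous", 0.025),
        ]:
            sd = math.sqrt(expected * (1 - expected) / n)
            assert abs(getattr(fr, name) - expected) < 3 * sd, name


class TestScatterSummary:
    def test_constant_channel(self):
        data = np.column_stack([np.full(50, 100.0), np.full(50, 100.0)])
        table = EventTable(data, ChannelMap(("FSC_A", "SSC_A")))
        s = mf.scatter_summary(table)
        assert s.fsc_mean == 100.0 and s.fsc_cv == 0.0

    def test_plate_grown_larger_and_more_heterogeneous_than_liquid(self):
        liquid = mf.scatter_summary(mf.generate_scenario(mf.load_scenario("liquid_grown")))
        plate = mf.scatter_summary(mf.generate_scenario(mf.load_scenario("plate_grown")))
        assert plate.fsc_mean > liquid.fsc_mean
        assert plate.heterogeneity > liquid.heterogeneity

    def test_cv_matches_lognormal_closed_form(self):
        mu, sigma = 2.0, 0.25
        spec = mf.PopulationSpec(
            "p", 1.0,
            mu={"FSC_A": mu, "SSC_A": mu},
            sigma={"FSC_A": sigma, "SSC_A": sigma},
        )
        table = mf.sample_population(spec, 100_000, seed=8, channel_map=ChannelMap(("FSC_A", "SSC_A")))
        expected_cv = math.sqrt(math.exp((sigma * math.log(10)) ** 2) - 1.0)
        assert mf.scatter_summary(table).fsc_cv == pytest.approx(expected_cv, rel=0.02)

    def test_empty_table_rejected(self):
        table = EventTable(np.empty((0, 2)), ChannelMap(("FSC_A", "SSC_A")))
        with pytest.raises(SampleSizeError):
            mf.scatter_summary(table)
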