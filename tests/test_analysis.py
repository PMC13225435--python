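"""Analysis metrics on synthetic traces and on the shared sweep."""

import numpy as np
import pandas as pd
import pytest

import rgc_mg as rm
from rgc_mg import analysis
from rgc_mg.analysis import (
    TherapeuticCriteria,
    ca_progress,
    detect_spikes,
    find_window,
    mean_unblock,
    nmda_charge,
    peak_calcium,
    protection_efficacy,
    threshold_sensitivity,
)


def synthetic_spike_trace(n_spikes, t_end=1000.0, dt=0.02):
    """Sawtooth-like voltage with a known number of threshold crossings."""
    t = np.arange(0.0, t_end + dt / 2, dt)
    v = np.full_like(t, -65.0)
    for k in range(n_spikes):
        onset = 50.0 + k * (t_end - 100.0) / max(n_spikes, 1)
        v[(t >= onset) & (t < onset + 1.0)] = 20.0
    return t, v


class TestDetectSpikes:
    def test_known_crossing_count(self):
        for k in (0, 1, 7, 40):
            t, v = synthetic_spike_trace(k)
            m = detect_spikes((t, v), (0.0, 1000.0), n_expected=50)
            assert m.n_spikes == k

    def test_loss_identity(self):
        t, v = synthetic_spike_trace(160)
        m = detect_spikes((t, v), (0.0, 1000.0), n_expected=200)
        assert m.spike_probability == pytest.approx(0.8)
        assert m.spike_loss_pct == pytest.approx(20.0)
        assert m.spike_loss_pct == pytest.approx(100.0 * (1.0 - m.spike_probability))

    def test_flat_subthreshold_trace(self):
        t = np.arange(0.0, 100.0 + 1e-9, 0.02)
        m = detect_spikes((t, np.full_like(t, -65.0)), (0.0, 100.0), n_expected=8)
        assert m.n_spikes == 0
        assert m.spike_loss_pct == 100.0

    def test_debounce_single_count_per_excursion(self):
        t = np.arange(0.0, 10.0 + 1e-9, 0.02)
        v = np.where((t > 2) & (t < 4), 10.0, -65.0)  # one 2 ms excursion
        m = detect_spikes((t, v), (0.0, 10.0), n_expected=1)
        assert m.n_spikes == 1

    def test_probability_capped_at_one(self):
        t, v = synthetic_spike_trace(30)
        m = detect_spikes((t, v), (0.0, 1000.0), n_expected=10)
        assert m.spike_probability == 1.0
        assert m.spike_loss_pct == 0.0

    def test_window_outside_trace_rejected(self):
        t, v = synthetic_spike_trace(3)
        with pytest.raises(ValueError, match="window"):
            detect_spikes((t, v), (500.0, 2000.0), n_expected=10)

    def test_loss_identity_holds_on_every_sweep_cell(self, sweep):
        tab = sweep.table
        np.testing.assert_allclose(
            tab["spike_loss_pct"], 100.0 * (1.0 - tab["spike_prob"]), atol=1e-9
        )
        assert ((tab["spike_prob"] >= 0) & (tab["spike_prob"] <= 1)).all()


class TestPeakCalcium:
    def test_constant_trace(self):
        t = np.arange(0.0, 100.0, 1.0)
        assert peak_calcium((t, np.full_like(t, 0.37)), (0.0, 99.0)) == 0.37

    def test_window_restriction(self):
        t = np.arange(0.0, 100.0, 1.0)
        ca = np.where(t < 50, 2.0, 1.0)
        assert peak_calcium((t, ca), (60.0, 99.0)) == 1.0

    def test_no_stimulus_run_stays_at_rest(self, quiet_trace):
        assert peak_calcium(quiet_trace, (500.0, 3000.0)) == pytest.approx(0.05, rel=1e-4)


def window_row(mg, ca, loss):
    return pd.DataFrame(
        {"frequency_hz": 80.0, "mg_mM": mg, "peak_ca_uM": ca, "spike_loss_vs_baseline_pct": loss}
    )


class TestFindWindow:
    def test_interior_window(self):
        row = window_row(
            [1.0, 1.2, 1.4, 1.6, 1.8], [1.5, 1.2, 0.9, 0.8, 0.7], [0.0, 10.0, 15.0, 20.0, 30.0]
        )
        w = find_window(row, TherapeuticCriteria())
        assert (w.lower, w.upper) == (1.4, 1.6)
        assert w.width == pytest.approx(0.2)

    def test_all_cells_pass_gives_full_span(self):
        row = window_row([0.2, 0.4, 0.6], [0.5, 0.5, 0.5], [0.0, 0.0, 0.0])
        w = find_window(row)
        assert (w.lower, w.upper) == (0.2, 0.6)

    def test_empty_window(self):
        row = window_row([1.0, 1.5], [2.0, 1.5], [30.0, 40.0])
        w = find_window(row)
        assert not w.exists
        assert w.width == 0.0

    def test_unsorted_grid_rejected(self):
        row = window_row([1.5, 1.0], [0.5, 0.5], [0.0, 0.0])
        with pytest.raises(ValueError, match="sorted"):
            find_window(row)

    def test_membership_consistency_on_sweep(self, sweep):
        """Every concentration inside a reported window satisfies both
        criteria; the neighbours just outside violate at least one."""
        crit = sweep.criteria
        for freq, w in sweep.windows.items():
            row = sweep.table[sweep.table.frequency_hz == freq].reset_index(drop=True)
            ok = (row["peak_ca_uM"] < crit.ca_toxicity_threshold) & (
                row["spike_loss_vs_baseline_pct"] <= crit.max_spike_loss_pct + 1e-9
            )
            if not w.exists:
                continue
            inside = (row["mg_mM"] >= w.lower) & (row["mg_mM"] <= w.upper)
            assert ok[inside].all()
            idx = np.flatnonzero(inside.to_numpy())
            for j in (idx[0] - 1, idx[-1] + 1):
                if 0 <= j < len(row):
                    assert not ok.iloc[j]


class TestThresholdSensitivity:
    def test_width_monotone_in_threshold(self, sweep):
        row = sweep.table[sweep.table.frequency_hz == 80.0]
        sens = threshold_sensitivity(row, [0.6, 0.8, 1.0, 1.2, 1.4])
        widths = sens["width_mM"].to_numpy()
        assert np.all(np.diff(widths) >= 0)

    def test_infinite_threshold_limited_by_spike_loss_only(self, sweep):
        row = sweep.table[sweep.table.frequency_hz == 80.0]
        sens = threshold_sensitivity(row, [np.inf])
        loss_ok = row[row["spike_loss_vs_baseline_pct"] <= 20.0 + 1e-9]["mg_mM"]
        assert sens.iloc[0]["lower_mM"] == loss_ok.min()
        assert sens.iloc[0]["upper_mM"] == loss_ok.max()

    def test_unsorted_thresholds_rejected(self, sweep):
        row = sweep.table[sweep.table.frequency_hz == 80.0]
        with pytest.raises(ValueError, match="sorted"):
            threshold_sensitivity(row, [1.2, 0.8])


class TestProtectionEfficacy:
    def test_midpoint_linearity(self):
        assert protection_efficacy(4.0, 1.0, 2.5) == pytest.approx(50.0)

    def test_matching_pretreated_reference(self):
        assert protection_efficacy(4.0, 1.0, 1.0) == pytest.approx(100.0)

    def test_matching_untreated_reference(self):
        assert protection_efficacy(4.0, 1.0, 4.0) == pytest.approx(0.0)

    def test_degenerate_denominator_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            protection_efficacy(1.0, 1.0, 0.5)

    def test_simulated_efficacies_bounded(self, timing_table):
        eff = timing_table["efficacy_pct"].to_numpy()
        assert np.all(eff >= -1e-6) and np.all(eff <= 100.0 + 1e-6)


class TestCaProgress:
    def test_resting_start_maps_to_zero(self, mech_pair):
        assert ca_progress(mech_pair.cell(0), 0.0, (500.0, 3000.0)) == pytest.approx(0.0, abs=1e-6)

    def test_untreated_peak_maps_to_one(self, mech_pair):
        cell = mech_pair.cell(0)
        t_peak = cell.t[np.argmax(cell["Ca"])]
        assert ca_progress(cell, float(t_peak), (500.0, 3000.0)) == pytest.approx(1.0, rel=1e-9)

    def test_monotone_up_to_peak(self, mech_pair):
        """The Ca2+ envelope rises monotonically toward the untreated peak;
        per-pulse clearance puts a small ripple (~Ca * dt_pulse / tau_Ca)
        on top of it, which bounds the allowed local decrease."""
        cell = mech_pair.cell(0)
        i_peak = int(np.argmax(cell["Ca"]))
        ts = cell.t[: i_peak + 1 : 500]
        vals = np.array([ca_progress(cell, float(t), (500.0, 3000.0)) for t in ts])
        ripple = 1.0 * 12.5 / 200.0 / 4.5  # peak-normalised inter-pulse decay
        assert np.all(np.diff(vals) >= -ripple)
        assert vals[-1] > 0.99

    def test_time_before_trace_rejected(self, mech_pair):
        with pytest.raises(ValueError):
            ca_progress(mech_pair.cell(0), -5.0, (500.0, 3000.0))


class TestNmdaChargeAndUnblock:
    def test_zero_current_zero_charge(self):
        t = np.arange(0.0, 100.0, 0.02)
        assert nmda_charge(np.zeros_like(t), (0.0, 99.0), t=t) == 0.0

    def test_constant_current_charge(self):
        t = np.arange(0.0, 101.0, 1.0)
        q = nmda_charge(np.full_like(t, -3.0), (0.0, 100.0), t=t)
        assert q == pytest.approx(300.0)

    def test_mean_unblock_equals_block_factor_for_clamped_voltage(self, params):
        t = np.arange(0.0, 100.0, 1.0)

        class Clamped:
            def __init__(self):
                self.t = t
                self.data = {"V": np.full_like(t, -65.0)}
                self.mg = np.full_like(t, 0.2)
                self.params = params

            def __getitem__(self, k):
                return self.data[k]

        b = mean_unblock(Clamped(), (0.0, 99.0))
        assert b == pytest.approx(float(rm.mg_block_factor(-65.0, 0.2, params)), rel=1e-12)

    def test_mean_unblock_unity_without_mg(self, params):
        t = np.arange(0.0, 100.0, 1.0)

        class Clamped:
            t_ = t

            def __init__(self):
                self.t = t
                self.data = {"V": np.linspace(-80, 40, t.size)}
                self.mg = np.zeros_like(t)
                self.params = params

            def __getitem__(self, k):
                return self.data[k]

        assert mean_unblock(Clamped(), (0.0, 99.0)) == 1.0
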