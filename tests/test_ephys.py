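import numpy as np
import pandas as pd
import pytest

from septodg import ephys as ep
from septodg import synthetic_data as synth


class TestAccessResistanceQC:
    def _sweeps(self, ra):
        return ep.SweepSet(sweeps=[], mode="voltage_clamp", access_resistance_mohm=ra)

    def test_ten_percent_passes(self):
        assert ep.qc_access_resistance(self._sweeps([10.0, 11.0]))["status"] == "pass"

    def test_thirty_percent_fails(self):
        assert ep.qc_access_resistance(self._sweeps([10.0, 13.0]))["status"] == "fail"

    def test_exactly_twenty_percent_passes(self):
        assert ep.qc_access_resistance(self._sweeps([10.0, 12.0]))["status"] == "pass"

    def test_missing_checkpoints_unverifiable(self):
        assert ep.qc_access_resistance(self._sweeps([10.0]))["status"] == "unverifiable"


class TestDetectSipscs:
    def test_zero_trace_zero_events(self):
        sweep = ep.Sweep(time=np.arange(10000) / 1e4, signal=np.zeros(10000))
        table = ep.detect_sipscs(sweep)
        assert len(table.times) == 0

    def test_false_positive_rate_on_noise(self):
        rates = []
        for seed in range(5):
            cfg = synth.SimConfig(
                seed=seed,
                ephys=synth.EphysParams(sipsc_rate_hz=0.0, noise_sd_pa=2.0, duration_s=60.0),
            )
            sweeps, _ = synth.simulate_sipsc_trace(cfg)
            rates.append(len(ep.detect_sipscs(sweeps.sweeps[0]).times) / 60.0)
        assert np.mean(rates) < 0.2

    def test_injected_events_recovered(self):
        cfg = synth.SimConfig(
            seed=8, ephys=synth.EphysParams(sipsc_rate_hz=0.0, noise_sd_pa=2.0, duration_s=60.0)
        )
        sweeps, _ = synth.simulate_sipsc_trace(cfg)
        sweep = sweeps.sweeps[0]
        fs = 10_000.0
        kernel = synth._biexp_kernel(fs, 0.0005, 0.008)
        times = 2.0 + np.arange(10) * 5.0
        synth._add_events(sweep.signal, fs, times, -50.0 * np.ones(10), kernel)
        table = ep.detect_sipscs(sweep)
        assert len(table.times) == 10
        assert np.mean(table.amplitudes) == pytest.approx(50.0, abs=2.0)

    def test_count_non_increasing_in_k(self):
        cfg = synth.SimConfig(seed=2, ephys=synth.EphysParams(duration_s=30.0))
        sweeps, _ = synth.simulate_sipsc_trace(cfg)
        counts = [len(ep.detect_sipscs(sweeps.sweeps[0], k=k).times) for k in (2.5, 3.5, 5.0, 8.0)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_frequency_times_duration_is_count(self):
        cfg = synth.SimConfig(seed=4, ephys=synth.EphysParams(duration_s=30.0))
        sweeps, _ = synth.simulate_sipsc_trace(cfg)
        table = ep.detect_sipscs(sweeps.sweeps[0])
        assert table.frequency_hz * table.duration_s == pytest.approx(len(table.times))


class TestGroupStats:
    def _tables(self, rng, n_cells, mu):
        out = []
        for c in range(n_cells):
            n = 40
            times = np.sort(rng.uniform(0, 60, n))
            amps = rng.lognormal(mu, 0.3, n)
            out.append(ep.SynapticEventTable(times=times, amplitudes=amps, duration_s=60.0))
        return out

    def test_identical_pooled_samples_ks_zero(self, rng):
        a = self._tables(np.random.default_rng(0), 3, np.log(50))
        b = self._tables(np.random.default_rng(0), 3, np.log(50))
        out = ep.sipsc_group_stats({"WT": a, "AD": b})
        assert out["amplitude_ks"]["D"] == 0.0

    def test_ks_power_on_shifted_normals(self, rng):
        hits = 0
        for _ in range(20):
            a = rng.standard_normal(500)
            b = rng.standard_normal(500) + 1.0
            from scipy.stats import ks_2samp

            hits += ks_2samp(a, b).pvalue < 0.05
        assert hits == 20

    def test_group_means_and_sem_present(self, rng):
        out = ep.sipsc_group_stats(
            {"WT": self._tables(rng, 4, np.log(40)), "AD": self._tables(rng, 4, np.log(60))}
        )
        for g in ("WT", "AD"):
            assert out["per_group"][g]["amplitude_sem"] is not None
        assert out["amplitude_ttest"]["p"] < 0.05

    def test_zero_event_group_raises(self):
        empty = [
            ep.SynapticEventTable(times=np.array([]), amplitudes=np.array([]), duration_s=60.0)
            for _ in range(2)
        ]
        good = self._tables(np.random.default_rng(1), 2, np.log(50))
        with pytest.raises(ValueError, match="zero events"):
            ep.sipsc_group_stats({"WT": good, "AD": empty})


class TestOptoEpochs:
    def test_null_modulation_no_difference(self):
        cells = []
        for c in range(8):
            cfg = synth.SimConfig(
                seed=c,
                ephys=synth.EphysParams(duration_s=60.0, opto_rate_modulation=1.0),
            )
            epochs = synth.default_light_epochs(60.0)
            sweeps, truth = synth.simulate_sipsc_trace(cfg, light_epochs=epochs)
            table = ep.SynapticEventTable(
                times=truth.event_times_s, amplitudes=truth.event_amplitudes, duration_s=60.0
            )
            cells.append((table, epochs))
        out = ep.opto_epoch_compare(cells)
        diff = out["frequency_paired_t"]["mean_pre"] - out["frequency_paired_t"]["mean_light"]
        assert abs(diff) < 1.5  # ~0 up to Poisson noise

    def test_boundary_event_assigned_to_light(self):
        table = ep.SynapticEventTable(
            times=np.array([20.0]), amplitudes=np.array([50.0]), duration_s=60.0
        )
        out = ep.epoch_event_stats(table, [(20.0, 40.0)])
        assert out["light_frequency"] > 0
        assert out["pre_frequency"] == 0.0

    def test_modulated_decrease_detected(self):
        sig = 0
        n_rep = 10
        for rep in range(n_rep):
            cells = []
            for c in range(8):
                cfg = synth.SimConfig(
                    seed=rep * 50 + c,
                    ephys=synth.EphysParams(
                        duration_s=60.0, sipsc_rate_hz=5.0, opto_rate_modulation=0.5
                    ),
                )
                epochs = synth.default_light_epochs(60.0)
                sweeps, _ = synth.simulate_sipsc_trace(cfg, light_epochs=epochs)
                cells.append((ep.detect_sipscs(sweeps.sweeps[0]), epochs))
            out = ep.opto_epoch_compare(cells)
            ft = out["frequency_paired_t"]
            sig += ft["p"] < 0.05 and ft["mean_light"] < ft["mean_pre"]
        assert sig >= 0.8 * n_rep


class TestIntrinsicProperties:
    def test_ohms_law_forced(self):
        # constructed sweep: -2 mV steady-state deflection at -20 pA
        fs = 10_000.0
        t = np.arange(int(0.4 * fs)) / fs
        v = np.full(len(t), -70.0)
        in_step = (t >= 0.1) & (t < 0.3)
        tau = 0.01
        v[in_step] = -70.0 - 2.0 * (1 - np.exp(-(t[in_step] - 0.1) / tau))
        sweep = ep.Sweep(time=t, signal=v, injected_pa=-20.0, step_start_s=0.1,
                         step_duration_s=0.2, label="rin_pulse")
        props = ep.intrinsic_properties(
            ep.SweepSet(sweeps=[sweep], mode="current_clamp")
        )
        assert props.input_resistance_mohm == pytest.approx(100.0, rel=0.01)

    def test_rc_recovery_noiseless(self):
        cfg = synth.SimConfig(
            seed=1, ephys=synth.EphysParams(r_mohm=150.0, tau_ms=20.0, noise_sd_mv=0.0)
        )
        sweeps, truth = synth.simulate_current_steps(cfg)
        props = ep.intrinsic_properties(sweeps)
        assert props.input_resistance_mohm == pytest.approx(150.0, rel=0.01)
        assert props.tau_ms == pytest.approx(20.0, rel=0.05)
        assert props.capacitance_pf == pytest.approx(20.0 / 150.0 * 1000, rel=0.06)
        assert props.rmp_mv == pytest.approx(truth.rmp_mv, abs=0.5)

    def test_lif_rheobase(self):
        cfg = synth.SimConfig(seed=1, ephys=synth.EphysParams(rheobase_pa=110.0))
        sweeps, truth = synth.simulate_current_steps(cfg)
        props = ep.intrinsic_properties(sweeps)
        fi = props.fi_table
        assert all(fi[fi.current_pa <= 100].spike_count == 0)
        assert all(fi[fi.current_pa >= 120].spike_count > 0)
        assert props.rheobase_pa == truth.rheobase_pa == 120.0

    def test_fi_ladder_16_steps_monotone(self):
        cfg = synth.SimConfig(seed=1)
        sweeps, truth = synth.simulate_current_steps(cfg)
        props = ep.intrinsic_properties(sweeps)
        assert len(props.fi_table) == 16
        counts = props.fi_table.spike_count.to_numpy()
        assert all(a <= b for a, b in zip(counts, counts[1:]))
        # detector agrees with the generator's own spike rule
        for _, row in props.fi_table.iterrows():
            assert row.spike_count == truth.spike_counts[row.current_pa]

    def test_recovery_error_shrinks_with_noise(self):
        errs = []
        for noise in (0.5, 0.05):
            cfg = synth.SimConfig(
                seed=3, ephys=synth.EphysParams(r_mohm=120.0, noise_sd_mv=noise)
            )
            sweeps, _ = synth.simulate_current_steps(cfg)
            props = ep.intrinsic_properties(sweeps)
            errs.append(abs(props.input_resistance_mohm - 120.0))
        assert errs[1] <= errs[0]


class TestFiGroupCompare:
    def _table(self, rng, gain):
        currents = np.array(ep.STEP_LADDER_PA, dtype=float)
        base = np.clip((currents - 100.0) / 20.0, 0, None) * gain
        counts = np.clip(np.round(base + rng.normal(0, 1.0, len(currents))), 0, None)
        return pd.DataFrame({"current_pa": currents, "spike_count": counts})

    def test_reduced_gain_detected(self, rng):
        hits = 0
        n_rep = 10
        for _ in range(n_rep):
            wt = [self._table(rng, 1.0) for _ in range(9)]
            ad = [self._table(rng, 0.7) for _ in range(9)]
            out = ep.fi_group_compare({"WT": wt, "AD": ad})
            hits += out["genotype_p"] < 0.05
        assert hits >= 0.8 * n_rep

    def test_similar_groups_small_effect(self, rng):
        wt = [self._table(rng, 1.0) for _ in range(6)]
        ad = [self._table(rng, 1.0) for _ in range(6)]
        out = ep.fi_group_compare({"WT": wt, "AD": ad})
        assert out["genotype_F"] < 5.0

    def test_single_current_level_rejected(self):
        tbl = pd.DataFrame({"current_pa": [100.0], "spike_count": [2]})
        with pytest.raises(ValueError, match="two common current levels"):
            ep.fi_group_compare({"WT": [tbl, tbl], "AD": [tbl, tbl]})

    def test_missing_steps_excluded_listwise(self, rng):
        wt = [self._table(rng, 1.0) for _ in range(4)]
        ad = [self._table(rng, 0.7) for _ in range(4)]
        ad[0] = ad[0][ad[0].current_pa > 0]  # drop two steps from one cell
        out = ep.fi_group_compare({"WT": wt, "AD": ad})
        assert np.isfinite(out["genotype_p"])


class TestSweepSetValidation:
    def test_overlapping_epochs_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ep.SweepSet(sweeps=[], mode="voltage_clamp",
                        light_epochs=[(0.0, 20.0), (10.0, 30.0)])

    def test_epoch_outside_trace_rejected(self):
        sweep = ep.Sweep(time=np.arange(100) / 1e4, signal=np.zeros(100))
        with pytest.raises(ValueError, match="outside"):
            ep.SweepSet(sweeps=[sweep], mode="voltage_clamp", light_epochs=[(0.0, 5.0)])
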