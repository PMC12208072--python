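"""Tests for the Langevin integrators and the synthetic barcode generator."""

import numpy as np
import pytest
from numpy.random import default_rng

from browaug.simulate import (
    BarcodeSpec,
    LangevinParams,
    Trace,
    UnravelingSchedule,
    decode_bits,
    integrate_langevin,
    integrate_unraveling,
    stack_traces,
    synthesize_dataset,
    synthesize_trace,
)


class TestLangevin:
    def test_overdamped_noiseless_steady_state(self):
        # v = F / alpha exactly at every step
        p = LangevinParams(drag=4.0, bias_voltage=2.0, charge_density=1.0)
        traj = integrate_langevin(p, 50, seed=0)
        np.testing.assert_array_equal(traj.velocities, np.full(51, 0.5))

    def test_zero_drift_symmetry(self):
        p = LangevinParams(drag=2.0, bias_voltage=0.0, thermal_intensity=1.0)
        traj = integrate_langevin(p, 20_000, seed=1)
        v = traj.velocities[1:]
        se = v.std(ddof=1) / np.sqrt(len(v))
        assert abs(v.mean()) < 4 * se

    def test_integration_identity(self):
        p = LangevinParams(drag=3.0, mass=1.0, thermal_intensity=0.5, dt=0.05)
        traj = integrate_langevin(p, 200, seed=2)
        np.testing.assert_allclose(np.diff(traj.positions),
                                   traj.velocities[1:] * traj.dt, rtol=1e-12)

    def test_position_variance_grows_linearly(self):
        # Brownian scaling: Var[x_k] = k * (thermal/drag)^2 * dt^2
        p = LangevinParams(drag=2.0, bias_voltage=0.0, thermal_intensity=1.5, dt=0.1)
        n_rep, n_steps = 3000, 60
        pos = np.stack([integrate_langevin(p, n_steps, seed=s).positions
                        for s in range(n_rep)])
        var = pos.var(axis=0, ddof=1)
        k = np.arange(n_steps + 1)
        slope, r2 = np.polyfit(k, var, 1)[0], np.corrcoef(k, var)[0, 1] ** 2
        expected = (p.thermal_intensity / p.drag) ** 2 * p.dt**2
        assert r2 > 0.99
        assert abs(slope - expected) / expected < 0.1

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            LangevinParams(drag=0.0)
        with pytest.raises(ValueError):
            LangevinParams(drag=-1.0)
        with pytest.raises(ValueError):
            LangevinParams(drag=np.inf)
        with pytest.raises(ValueError):
            LangevinParams(drag=1.0, dt=0.0)

    def test_deterministic_under_seed(self):
        p = LangevinParams(drag=1.0, thermal_intensity=0.3)
        a = integrate_langevin(p, 100, seed=3)
        b = integrate_langevin(p, 100, seed=3)
        np.testing.assert_array_equal(a.velocities, b.velocities)


class TestUnraveling:
    def test_constant_schedule_reduces_to_langevin(self):
        # noiseless: bit-identical dynamics to the constant-coefficient model
        p = LangevinParams(drag=4.0, bias_voltage=2.0, dt=0.01)
        sched = UnravelingSchedule.constant(0.0, 4.0)
        traj = integrate_unraveling(p, sched, chain_length=1.0, seed=0)
        ref = integrate_langevin(p, traj.n_steps, seed=0)
        np.testing.assert_allclose(traj.velocities, ref.velocities, rtol=1e-12)

    def test_increasing_drag_decreases_velocity(self):
        p = LangevinParams(drag=1.0, bias_voltage=1.0, dt=0.01)
        sched = UnravelingSchedule.affine_drag(1.0, 5.0)
        traj = integrate_unraveling(p, sched, chain_length=2.0, seed=0)
        v = traj.velocities
        assert np.all(np.diff(v) < 1e-12)
        assert v[-1] < v[0]

    def test_translocation_time_closed_form(self):
        # constant drag, noiseless: time = chain_length * alpha / F, to one dt
        p = LangevinParams(drag=4.0, bias_voltage=2.0, dt=0.01)
        sched = UnravelingSchedule.constant(0.0, 4.0)
        traj = integrate_unraveling(p, sched, chain_length=1.5, seed=0)
        assert abs(traj.duration - 1.5 * 4.0 / 2.0) <= p.dt + 1e-12

    def test_invalid_chain_length(self):
        p = LangevinParams(drag=1.0)
        with pytest.raises(ValueError):
            integrate_unraveling(p, UnravelingSchedule.constant(0, 1.0), 0.0)

    def test_invalid_schedule_rejected(self):
        p = LangevinParams(drag=1.0)
        bad = UnravelingSchedule(mass_fn=lambda f: 0.0, drag_fn=lambda f: -1.0)
        with pytest.raises(ValueError):
            integrate_unraveling(p, bad, 1.0)


class TestSynthesizeTrace:
    def test_no_bits_gives_two_indicator_dips(self, clean_spec):
        spec = clean_spec((0, 0, 0))
        tr = synthesize_trace(spec, L=700, seed=0)
        assert decode_bits(tr.samples, spec) == (0, 0, 0)
        # exactly 2 regions below the dip threshold
        thresh = -(spec.base_drop + spec.dip_depth / 2)
        below = (tr.samples < thresh).astype(int)
        assert (np.diff(below) == 1).sum() + below[0] == 2

    def test_all_bits_gives_five_dips(self, clean_spec):
        spec = clean_spec((1, 1, 1))
        tr = synthesize_trace(spec, L=700, seed=0)
        thresh = -(spec.base_drop + spec.dip_depth / 2)
        below = (tr.samples < thresh).astype(int)
        assert (np.diff(below) == 1).sum() + below[0] == 5

    @pytest.mark.parametrize("code", range(8))
    @pytest.mark.parametrize("reverse", [False, True])
    def test_bit_pattern_bijection_both_orientations(self, clean_spec, code, reverse):
        bits = ((code >> 2) & 1, (code >> 1) & 1, code & 1)
        spec = BarcodeSpec(bits=bits, noise_std=0.0, fold_prob=0.0,
                           reverse_prob=1.0 if reverse else 0.0)
        tr = synthesize_trace(spec, L=700, seed=5)
        assert tr.label == code  # label stays defined on the forward read
        read = decode_bits(tr.samples, spec)
        assert read == (bits[::-1] if reverse else bits)

    def test_baseline_zero_outside_event(self, clean_spec):
        tr = synthesize_trace(clean_spec((1, 0, 1)), L=700, seed=1)
        s, e = tr.event_span
        outside = np.r_[tr.samples[:s], tr.samples[e:]]
        np.testing.assert_array_equal(outside, 0.0)

    def test_overlapping_dips_rejected(self):
        with pytest.raises(ValueError):
            synthesize_trace(BarcodeSpec(bits=(1, 1, 1), event_length=100,
                                         dip_width=40, indicator_width=10), L=700, seed=0)

    def test_event_too_long_rejected(self, clean_spec):
        with pytest.raises(ValueError):
            synthesize_trace(clean_spec((0, 0, 0), event_length=800), L=700, seed=0)

    def test_deterministic_under_seed(self):
        spec = BarcodeSpec(bits=(0, 1, 1))
        a = synthesize_trace(spec, seed=9)
        b = synthesize_trace(spec, seed=9)
        np.testing.assert_array_equal(a.samples, b.samples)


class TestSynthesizeDataset:
    def test_bookkeeping(self, small_dataset):
        traces, X, labels, exps = small_dataset
        assert len(traces) == 80
        assert sorted(set(labels.tolist())) == list(range(8))
        assert len(set(exps.tolist())) == 4
        assert X.shape == (80, 700)

    def test_zero_jitter_removes_confound(self):
        tmpl = BarcodeSpec(bits=(0, 0, 0), fold_prob=0.0)
        traces = synthesize_dataset([20] * 8, 4, spec_template=tmpl,
                                    experiment_jitter=0.0, seed=3)
        _, _, exps = stack_traces(traces)
        # dip floor should not differ systematically by experiment
        mins = np.array([t.samples.min() for t in traces])
        means = [mins[exps == e].mean() for e in range(4)]
        assert np.ptp(means) < 0.05

    def test_jitter_creates_detectable_confound(self):
        tmpl = BarcodeSpec(bits=(0, 0, 0), fold_prob=0.0)
        traces = synthesize_dataset([30] * 8, 3, spec_template=tmpl,
                                    experiment_jitter=0.15, seed=4)
        _, _, exps = stack_traces(traces)
        depth = np.array([t.samples.min() for t in traces])
        means = [depth[exps == e].mean() for e in range(3)]
        assert np.ptp(means) > 0.05

    def test_byte_identical_under_seed(self):
        a = synthesize_dataset([5] * 8, 2, seed=8)
        b = synthesize_dataset([5] * 8, 2, seed=8)
        Xa, la, ea = stack_traces(a)
        Xb, lb, eb = stack_traces(b)
        assert Xa.tobytes() == Xb.tobytes()
        np.testing.assert_array_equal(la, lb)
        np.testing.assert_array_equal(ea, eb)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            synthesize_dataset([5] * 7 + [-1], 2, seed=0)

    def test_single_experiment_rejected(self):
        with pytest.raises(ValueError):
            synthesize_dataset([5] * 8, 1, seed=0)
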