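import numpy as np
import pytest

from fishposture.eigenshape import decompose
from fishposture.neuro import (
    NeuroParams,
    NoiseConfig,
    ResolutionWarningError,
    StiffnessProfile,
    biexp_kernel,
    force_to_angles,
    generate_spike_train,
    neuromuscular_filter,
    perturb_params,
    simulate_bout,
)
from fishposture.spine import InvalidInputError
from fishposture.synthetic import EnsembleSpec, generate_ensemble, scoot_params, turn_params


def simple_params(n_c=2, d=0.0, a=1.0, burst=0.0):
    return NeuroParams(
        tau_f_ms=np.array([10.0, 30.0])[:n_c],
        a=np.full(n_c, a),
        d_ms=d,
        n_c=n_c,
        burst_ms=burst,
    )


class TestSpikeTrain:
    def test_zero_delay_fires_all_segments_simultaneously(self):
        drive = generate_spike_train(simple_params(d=0.0), dt_ms=2.0, duration_ms=60.0)
        left = drive.F_osc["left"]
        cols = np.nonzero(left.any(axis=0))[0]
        assert cols.size == 1  # one firing instant for the left side
        assert np.all(left[:, cols[0]] == 1.0)
        assert drive.F_osc["right"].any(axis=0).sum() == 1

    def test_segment_delay_accumulates_down_the_body(self):
        p = NeuroParams(
            tau_f_ms=np.array([10.0, 40.0]), a=np.ones(2), d_ms=4.0, n_c=2, burst_ms=0.0
        )
        drive = generate_spike_train(p, dt_ms=2.0, duration_ms=120.0)
        left = drive.F_osc["left"]
        t1 = drive.time_ms[np.argmax(left[1])]
        t9 = drive.time_ms[np.argmax(left[9])]
        assert t9 - t1 == pytest.approx(32.0, abs=2.0)

    def test_zero_amplitude_gives_zero_drive(self):
        drive = generate_spike_train(simple_params(a=0.0), dt_ms=2.0, duration_ms=60.0)
        assert not drive.F_osc["left"].any()
        assert not drive.F_osc["right"].any()

    def test_unresolvable_delay_raises(self):
        with pytest.raises(ResolutionWarningError):
            generate_spike_train(simple_params(d=1.0), dt_ms=2.0, duration_ms=60.0)


class TestNeuromuscularFilter:
    def test_impulse_response_peak_matches_closed_form(self):
        tr, td, dt = 4.0, 12.0, 0.1
        p = NeuroParams(
            tau_f_ms=np.array([10.0, 200.0]),
            a=np.array([2.0, 0.0]),
            d_ms=0.0,
            n_c=2,
            tau_rise_ms=tr,
            tau_decay_ms=td,
            burst_ms=0.0,
        )
        drive = generate_spike_train(p, dt_ms=dt, duration_ms=300.0)
        drive = neuromuscular_filter(drive, tr, td, dt)
        Fm = drive.F_m["left"][0]
        t_peak = tr * td / (td - tr) * np.log(td / tr)
        assert Fm.max() == pytest.approx(2.0, rel=1e-3)
        assert drive.time_ms[np.argmax(Fm)] == pytest.approx(10.0 + t_peak, abs=2 * dt)

    def test_zero_drive_stays_zero(self):
        drive = generate_spike_train(simple_params(a=0.0), dt_ms=2.0, duration_ms=60.0)
        drive = neuromuscular_filter(drive, 3.0, 8.5, 2.0)
        assert not drive.F_m["left"].any()

    def test_linearity_in_amplitude(self):
        d1 = neuromuscular_filter(
            generate_spike_train(simple_params(a=1.0), 2.0, 80.0), 3.0, 8.5, 2.0
        )
        d2 = neuromuscular_filter(
            generate_spike_train(simple_params(a=2.0), 2.0, 80.0), 3.0, 8.5, 2.0
        )
        assert np.allclose(d2.F_m["left"], 2 * d1.F_m["left"], atol=1e-12)

    def test_invalid_time_constants_rejected(self):
        with pytest.raises(InvalidInputError):
            biexp_kernel(10.0, 5.0, 1.0)


class TestForceToAngles:
    def test_balanced_forces_cancel(self):
        drive = neuromuscular_filter(
            generate_spike_train(simple_params(a=1.0), 2.0, 80.0), 3.0, 8.5, 2.0
        )
        drive.F_m["right"] = drive.F_m["left"].copy()
        sp = force_to_angles(drive, StiffnessProfile())
        assert np.allclose(sp.dtheta, 0.0)

    def test_constant_force_uniform_stiffness_gives_linear_profile(self):
        drive = generate_spike_train(simple_params(a=0.0), 2.0, 40.0)
        T = drive.time_ms.size
        drive.F_m = {
            "left": np.zeros((10, T)),
            "right": np.full((10, T), 0.9),
        }
        sp = force_to_angles(drive, StiffnessProfile(W=np.ones(9)))
        expected = 0.9 / 9.0 * np.arange(10)
        assert np.allclose(sp.dtheta[5], expected)

    def test_left_right_swap_negates_angles(self, turn_bout):
        mirrored = simulate_bout(turn_params().mirrored(), duration_ms=280)
        assert np.allclose(mirrored.dtheta, -turn_bout.dtheta, atol=1e-12)


class TestSimulateBout:
    def test_rest_fixed_point(self, rest_bout):
        assert np.all(rest_bout.dtheta == 0.0)

    def test_six_half_cycles_of_tail_oscillation(self, scoot_bout):
        tail = scoot_bout.tail_angle()
        thr = 0.1 * np.abs(tail).max()
        s = np.sign(tail)
        s[np.abs(tail) < 1e-12] = 0
        for i in range(1, s.size):
            if s[i] == 0:
                s[i] = s[i - 1]
        crossings = np.sum(s[:-1] * s[1:] < 0)
        assert 4 <= crossings <= 7  # 6 half cycles up to edge effects

    def test_turn_has_dominant_cycle_one_excursion(self, archetype_trajs, turn_bout):
        from fishposture.trajectory import detect_cycles

        tr = archetype_trajs["turn"]
        ann = detect_cycles(tr)
        a, b = ann.cycle_bounds_ms[0]
        inside = (tr.time_ms >= a) & (tr.time_ms <= b)
        assert np.abs(tr.U[inside, 0]).max() > np.abs(tr.U[~inside, 0]).max()
        # and the bend itself exceeds the classical turn threshold
        assert np.degrees(np.abs(turn_bout.tail_angle()).max()) > 40.0

    def test_archetype_ensembles_concentrate_in_three_modes(self):
        recs = generate_ensemble(EnsembleSpec(n_scoot=6, n_turn=4, n_rest=1, seed=5))
        basis, _ = decompose([r.spine for r in recs])
        assert basis.S[:3].sum() >= 0.96


class TestPerturbParams:
    def test_infinite_snr_is_identity(self):
        p = scoot_params()
        q = perturb_params(p, NoiseConfig(seed=1))
        assert np.allclose(q.a, p.a)
        assert np.allclose(q.tau_f_ms, p.tau_f_ms)
        assert np.allclose(q.d_ms, p.d_ms)

    def test_reproducible_for_fixed_seed(self):
        p = scoot_params()
        q1 = perturb_params(p, NoiseConfig(snr_a=2.0, seed=42))
        q2 = perturb_params(p, NoiseConfig(snr_a=2.0, seed=42))
        assert np.allclose(q1.a, q2.a)

    def test_noise_scale_matches_snr_definition(self):
        """At snr=1 the amplitude noise s.d. approximates mean(|a|)."""
        p = scoot_params()
        devs = []
        for seed in range(1000):
            q = perturb_params(p, NoiseConfig(snr_a=1.0, seed=seed))
            devs.append(q.a - p.a)
        # clipping at zero truncates part of the low tail, so compare the
        # pooled spread with a generous margin
        devs = np.array(devs)
        target = np.mean(np.abs(p.a))
        pooled_sd = np.sqrt(np.mean(devs[np.abs(devs) > 0] ** 2))
        assert pooled_sd == pytest.approx(target, rel=0.25)

    def test_firing_order_preserved_after_noise(self):
        p = scoot_params()
        q = perturb_params(p, NoiseConfig(snr_tau_f=1.0, seed=3))
        for phase in (0, 1):
            assert np.all(np.diff(q.tau_f_ms[phase::2]) > 0)


def test_noise_response_zero_against_itself(collective_basis, turn_bout):
    from fishposture.neuro import noise_response

    basis, _ = collective_basis
    assert noise_response(turn_bout, turn_bout, basis) == pytest.approx(0.0, abs=1e-12)
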