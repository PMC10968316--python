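import numpy as np
import pytest

from mrmotionsim.kspace import (KSpace, acquisition_line_order, compose_kspace,
                                kspace_to_image, simulate_artifact_slice,
                                simulate_artifact_volume, slice_to_kspace)
from mrmotionsim.motion import (MotionEvent, MotionSchedule, SimulationParams,
                                sample_motion_schedule, generate_motion_states)
from mrmotionsim.metrics import rmse


def naive_compose(clean, states, schedule, ordering="linear"):
    """Independent per-line walk: the oracle for compose_kspace."""
    n = clean.data.shape[0]
    order = acquisition_line_order(n, ordering)
    out = clean.data.copy()
    prov = np.zeros(n, dtype=int)
    for t in range(n):
        line = order[t]
        active = 0
        for k, ev in enumerate(schedule.events, start=1):
            if ev.onset_line <= t:
                active = k
        prov[line] = active
        if active > 0:
            out[line, :] = states[active - 1].data[line, :]
    return out, prov


class TestTransforms:
    def test_zero_slice_zero_kspace(self):
        k = slice_to_kspace(np.zeros((8, 8)))
        assert np.all(k.data == 0)

    def test_center_impulse_has_flat_magnitude(self):
        s = np.zeros((8, 8))
        s[4, 4] = 1.0  # centre of the centred layout
        k = slice_to_kspace(s)
        np.testing.assert_allclose(np.abs(k.data), 1.0, atol=1e-12)

    def test_parseval_identity(self, small_phantom):
        s = small_phantom.volume.get_slice(4)
        k = slice_to_kspace(s)
        np.testing.assert_allclose(np.sum(s**2),
                                   np.sum(np.abs(k.data) ** 2) / s.size,
                                   rtol=1e-10)

    def test_round_trip_identity(self, small_phantom):
        s = small_phantom.volume.get_slice(3)
        assert np.max(np.abs(kspace_to_image(slice_to_kspace(s)) - s)) < 1e-9

    def test_zero_kspace_zero_image(self):
        assert np.all(kspace_to_image(KSpace(np.zeros((8, 8), complex))) == 0)

    def test_output_real_nonnegative_for_asymmetric_kspace(self):
        rng = np.random.default_rng(0)
        k = KSpace(rng.normal(size=(8, 8)) + 1j * rng.normal(size=(8, 8)))
        img = kspace_to_image(k)
        assert np.isrealobj(img) and np.all(img >= 0)

    def test_non_2d_rejected(self):
        with pytest.raises(ValueError):
            slice_to_kspace(np.zeros((4, 4, 4)))


class TestAcquisitionOrder:
    def test_linear_is_identity(self):
        np.testing.assert_array_equal(acquisition_line_order(4, "linear"),
                                      [0, 1, 2, 3])

    def test_centric_small_cases(self):
        np.testing.assert_array_equal(acquisition_line_order(4, "centric"),
                                      [2, 1, 3, 0])
        np.testing.assert_array_equal(acquisition_line_order(5, "centric"),
                                      [2, 1, 3, 0, 4])

    @pytest.mark.parametrize("ordering", ["linear", "centric"])
    @pytest.mark.parametrize("n", [1, 2, 7, 16])
    def test_always_a_permutation(self, ordering, n):
        order = acquisition_line_order(n, ordering)
        assert sorted(order.tolist()) == list(range(n))

    def test_unknown_ordering_rejected(self):
        with pytest.raises(ValueError):
            acquisition_line_order(8, "spiral")


class TestCompose:
    def _random_instance(self, rng, n_lines, n_states):
        clean = KSpace(rng.normal(size=(n_lines, n_lines))
                       + 1j * rng.normal(size=(n_lines, n_lines)))
        states = [KSpace(rng.normal(size=(n_lines, n_lines))
                         + 1j * rng.normal(size=(n_lines, n_lines)))
                  for _ in range(n_states)]
        onsets = np.sort(rng.choice(np.arange(1, n_lines), size=n_states,
                                    replace=False))
        events = [MotionEvent(int(o), (0, 0, 0), (0, 0, 0)) for o in onsets]
        return clean, states, MotionSchedule(events=events, n_lines=n_lines)

    def test_empty_schedule_is_identity(self):
        rng = np.random.default_rng(1)
        clean, _, _ = self._random_instance(rng, 8, 1)
        sched = MotionSchedule(events=[], n_lines=8)
        out, prov = compose_kspace(clean, [], sched)
        np.testing.assert_array_equal(out.data, clean.data)
        assert np.all(prov == 0)

    def test_single_event_provenance(self):
        rng = np.random.default_rng(2)
        clean, states, _ = self._random_instance(rng, 8, 1)
        sched = MotionSchedule(events=[MotionEvent(5, (0, 0, 0), (0, 0, 0))],
                               n_lines=8)
        _, prov = compose_kspace(clean, states[:1], sched)
        np.testing.assert_array_equal(prov, [0, 0, 0, 0, 0, 1, 1, 1])

    @pytest.mark.parametrize("ordering", ["linear", "centric"])
    def test_matches_naive_oracle(self, ordering):
        rng = np.random.default_rng(3)
        for trial in range(100):
            n_lines = int(rng.integers(4, 17))
            n_states = int(rng.integers(1, min(4, n_lines - 1) + 1))
            clean, states, sched = self._random_instance(rng, n_lines, n_states)
            got, prov = compose_kspace(clean, states, sched, ordering)
            want, want_prov = naive_compose(clean, states, sched, ordering)
            np.testing.assert_array_equal(got.data, want)
            np.testing.assert_array_equal(prov, want_prov)

    def test_provenance_nondecreasing_in_acquisition_order(self, default_params):
        rng = np.random.default_rng(4)
        for seed in range(50):
            sched = sample_motion_schedule(default_params, 32,
                                           np.random.default_rng(seed))
            clean = KSpace(rng.normal(size=(32, 32)) + 0j)
            states = [KSpace(rng.normal(size=(32, 32)) + 0j)
                      for _ in range(sched.n_events)]
            _, prov = compose_kspace(clean, states, sched)
            order = acquisition_line_order(32)
            assert np.all(np.diff(prov[order]) >= 0)

    def test_center_and_first_half_stay_motion_free_under_defaults(
            self, default_params):
        # the first movement strikes only after more than half of k-space is
        # acquired, so with linear ordering the DC line and everything up to
        # it always carry motion-free data
        n = 64
        clean = KSpace(np.zeros((n, n), complex))
        for seed in range(100):
            sched = sample_motion_schedule(default_params, n,
                                           np.random.default_rng(seed))
            states = [KSpace(np.ones((n, n), complex))] * sched.n_events
            _, prov = compose_kspace(clean, states, sched)
            assert np.all(prov[: n // 2 + 1] == 0)
            assert np.mean(prov == 0) > 0.5

    def test_shape_mismatch_rejected(self):
        clean = KSpace(np.zeros((8, 8), complex))
        state = KSpace(np.zeros((6, 6), complex))
        sched = MotionSchedule(events=[MotionEvent(5, (0, 0, 0), (0, 0, 0))],
                               n_lines=8)
        with pytest.raises(ValueError):
            compose_kspace(clean, [state], sched)
        with pytest.raises(ValueError):
            compose_kspace(clean, [], sched)


class TestSimulateSlice:
    def test_zero_movements_reproduce_input(self, small_phantom):
        params = SimulationParams(n_movements_range=(0, 0))
        clean = small_phantom.volume.get_slice(4)
        artifact, residual, sched = simulate_artifact_slice(
            small_phantom.volume, 4, params, np.random.default_rng(0))
        assert sched.n_events == 0
        assert np.max(np.abs(artifact - clean)) < 1e-6
        assert np.max(np.abs(residual)) < 1e-6

    def test_default_params_produce_artifact_and_exact_residual(self, small_phantom):
        v = small_phantom.volume
        artifact, residual, _ = simulate_artifact_slice(
            v, 4, SimulationParams(), np.random.default_rng(11))
        clean = v.get_slice(4)
        assert rmse(clean, artifact) > 0
        np.testing.assert_array_equal(clean + residual, artifact)

    def test_artifact_energy_within_2x_of_clean(self, small_phantom):
        v = small_phantom.volume
        clean_e = np.sum(v.get_slice(4) ** 2)
        for seed in range(20):
            artifact, _, _ = simulate_artifact_slice(
                v, 4, SimulationParams(), np.random.default_rng(seed))
            assert np.isfinite(artifact).all()
            assert np.sum(artifact**2) < 2 * clean_e


class TestSimulateVolume:
    def test_shapes_and_schedule_count(self, small_phantom, default_params):
        art, res, scheds = simulate_artifact_volume(small_phantom.volume,
                                                    default_params, seed=1)
        assert art.shape == small_phantom.volume.shape
        assert res.shape == small_phantom.volume.shape
        assert len(scheds) == small_phantom.volume.n_slices

    def test_shared_schedule_mode(self, small_phantom):
        params = SimulationParams(per_slice_independent=False)
        _, _, scheds = simulate_artifact_volume(small_phantom.volume, params, seed=1)
        assert all(s is scheds[0] for s in scheds)

    def test_deterministic(self, small_phantom, default_params):
        a1, r1, _ = simulate_artifact_volume(small_phantom.volume, default_params, seed=9)
        a2, r2, _ = simulate_artifact_volume(small_phantom.volume, default_params, seed=9)
        assert np.array_equal(a1.data, a2.data)
        assert np.array_equal(r1.data, r2.data)

    def test_single_slice_run_agrees_with_volume_run(self, small_phantom,
                                                     default_params):
        v = small_phantom.volume
        art, _, scheds = simulate_artifact_volume(v, default_params, seed=21)
        z = 5
        a, _, sched = simulate_artifact_slice(v, z, default_params,
                                              np.random.default_rng((21, z)))
        np.testing.assert_array_equal(art.data[:, :, z], a)
        assert sched.events == scheds[z].events
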