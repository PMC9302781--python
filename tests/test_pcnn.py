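import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import brute_linking, scalar_pcnn, flood_fill_components

from mwbreast.pcnn import (
    DegenerateInputWarning,
    LesionRegion,
    PCNNParams,
    PCNNState,
    assign_zone,
    default_linking_kernel,
    extract_regions,
    linking_field,
    normalize_input,
    pcnn_step,
    run_pcnn,
    select_mask,
)


class TestNormalizeInput:
    def test_min_max_maps_to_unit_interval(self):
        s = normalize_input(np.array([[10.0, 20.0, 30.0]]))
        assert np.allclose(s, [[0.0, 0.5, 1.0]])

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        a = rng.random((8, 8))
        assert np.allclose(normalize_input(a), normalize_input(37.0 * a))

    def test_constant_input_warns_and_zeroes(self):
        with pytest.warns(DegenerateInputWarning):
            s = normalize_input(np.full((4, 4), 3.0))
        assert np.all(s == 0)

    def test_out_of_mask_pixels_zero(self):
        a = np.array([[5.0, 9.0], [1.0, 2.0]])
        mask = np.array([[True, True], [True, False]])
        s = normalize_input(a, mask)
        assert s[1, 1] == 0.0
        assert s[0, 1] == 1.0 and s[1, 0] == 0.0


class TestLinkingField:
    def test_silent_network_has_zero_linking(self):
        p = PCNNParams()
        assert np.all(linking_field(np.zeros((5, 5)), p) == 0)

    def test_impulse_response_is_the_kernel(self):
        p = PCNNParams()
        o = np.zeros((5, 5))
        o[2, 2] = 1.0
        l = linking_field(o, p)
        assert np.allclose(l[1:4, 1:4], default_linking_kernel())
        assert l[2, 2] == 0.0  # no self-linking

    def test_matches_brute_force_on_random_lattice(self):
        rng = np.random.default_rng(5)
        o = (rng.random((6, 6)) > 0.5).astype(float)
        p = PCNNParams()
        assert np.allclose(linking_field(o, p), brute_linking(o, p.weights))


class TestPCNNStep:
    def test_zero_initial_threshold_fires_all_positive_neurons(self):
        s = np.array([[0.0, 0.3], [0.7, 1.0]]) * 255
        state = pcnn_step(PCNNState.initial(s, PCNNParams()), PCNNParams())
        assert np.array_equal(state.o, (s > 0).astype(float))

    def test_huge_threshold_silences_and_decays_exactly(self):
        p = PCNNParams()
        s = np.random.default_rng(0).random((4, 4)) * 255
        state = PCNNState.initial(s, p)
        state.t = np.full_like(s, 1e9)
        nxt = pcnn_step(state, p)
        assert np.all(nxt.o == 0)
        assert np.allclose(nxt.t, 1e9 * np.exp(-0.2), rtol=1e-12)

    def test_three_step_sequence_matches_scalar_reference(self):
        s = np.array([[0.1, 0.9, 0.1], [0.9, 1.0, 0.9], [0.1, 0.9, 0.1]])
        p = PCNNParams()
        history = scalar_pcnn(s.tolist(), p.beta, p.alpha_t, p.v_t,
                              p.weights.tolist(), n_iter=3, t0=p.t0)
        state = PCNNState.initial(s, p)
        for f, l, u, t, o in history:
            state = pcnn_step(state, p)
            assert np.allclose(state.l, l, atol=0, rtol=0)
            assert np.allclose(state.u, u, atol=0, rtol=0)
            assert np.array_equal(state.t, np.array(t))
            assert np.array_equal(state.o, np.array(o))


class TestRunPCNN:
    def test_default_budget_is_32_masks(self):
        stack = run_pcnn(np.random.default_rng(1).random((10, 10)))
        assert len(stack.masks) == 32

    def test_deterministic(self):
        a = np.random.default_rng(2).random((12, 12))
        s1, s2 = run_pcnn(a), run_pcnn(a)
        for m1, m2 in zip(s1.masks, s2.masks):
            assert np.array_equal(m1, m2)

    def test_uniform_stimulus_fires_uniformly(self):
        # a uniform positive stimulus must stay spatially uniform: every
        # iteration's output is all-fire or all-quiet
        p = PCNNParams()
        state = PCNNState.initial(np.full((9, 9), 204.0), p)
        for _ in range(32):
            state = pcnn_step(state, p)
            assert state.o.all() or not state.o.any()

    def test_binary_outputs_and_threshold_recurrence(self):
        """Wherever the previous output was 0 the threshold decays by
        exactly exp(-alpha_t); wherever it fired, it gains V_T."""
        p = PCNNParams()
        s = normalize_input(np.random.default_rng(3).random((15, 15))) * p.stimulus_scale
        state = PCNNState.initial(s, p)
        for _ in range(12):
            prev_t, prev_o = state.t.copy(), state.o.copy()
            state = pcnn_step(state, p)
            assert set(np.unique(state.o)) <= {0.0, 1.0}
            quiet = prev_o == 0
            assert np.array_equal(state.t[quiet], np.exp(-p.alpha_t) * prev_t[quiet])
            assert np.all(state.t[~quiet] >= p.v_t)

    def test_every_positive_neuron_eventually_refires(self):
        # geometric threshold decay guarantees refiring of positive stimuli
        a = np.random.default_rng(4).random((8, 8)) + 0.1
        a[0, 0] = 0.0
        stack = run_pcnn(a, PCNNParams(n_iter=64))
        fired = np.zeros((8, 8), dtype=bool)
        for m in stack.masks[1:]:  # after the initial global flash
            fired |= m
        assert fired[a > 0].all()


class TestMaskSelection:
    def test_selected_iteration_is_one_based(self):
        stack = run_pcnn(np.random.default_rng(5).random((8, 8)))
        assert np.array_equal(select_mask(stack, 5), stack.masks[4])
        assert np.array_equal(select_mask(stack), stack.masks[4])
        assert np.array_equal(select_mask(stack, 32), stack.masks[-1])

    def test_first_iteration_fires_positive_pixels(self):
        a = np.random.default_rng(6).random((8, 8)) + 0.5
        a[3, 3] = 0.0
        stack = run_pcnn(a)
        m1 = select_mask(stack, 1)
        assert not m1[3, 3] and m1.sum() == 63

    def test_out_of_range_selection_rejected(self):
        stack = run_pcnn(np.random.default_rng(7).random((6, 6)))
        with pytest.raises(IndexError):
            select_mask(stack, 0)
        with pytest.raises(IndexError):
            select_mask(stack, 33)


class TestRegions:
    def test_two_disjoint_squares(self):
        m = np.zeros((12, 12), dtype=bool)
        m[1:4, 1:4] = True
        m[7:10, 7:10] = True
        regions = extract_regions(m, min_area=1)
        assert len(regions) == 2
        assert all(r.area == 9 for r in regions)

    def test_diagonal_touch_merges_under_8_connectivity(self):
        m = np.zeros((6, 6), dtype=bool)
        m[1, 1] = m[2, 2] = m[3, 3] = True
        assert len(extract_regions(m, min_area=1)) == 1

    def test_matches_flood_fill_oracle(self):
        rng = np.random.default_rng(8)
        m = rng.random((20, 20)) > 0.6
        regions = extract_regions(m, min_area=1)
        oracle = flood_fill_components(m)
        assert len(regions) == len(oracle)
        assert sorted(r.area for r in regions) == sorted(len(c) for c in oracle)

    def test_min_area_filters_speckle(self):
        m = np.zeros((10, 10), dtype=bool)
        m[0, 0] = True  # single-pixel speckle
        m[4:7, 4:7] = True
        regions = extract_regions(m, min_area=5)
        assert len(regions) == 1 and regions[0].area == 9

    def test_empty_mask_gives_no_regions(self):
        assert extract_regions(np.zeros((5, 5), dtype=bool)) == []


class TestZones:
    @pytest.mark.parametrize("row,expected", [(10.0, "upper"), (100.0, "lower"),
                                              (70.0, "upper")])  # tie -> upper
    def test_centroid_halfplane_rule(self, row, expected):
        region = LesionRegion(pixels=np.array([[int(row), 70]]),
                              centroid=(row, 70.0), area=1)
        assert assign_zone(region, (141, 141)) == expected


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_vectorized_pcnn_matches_scalar_reference(seed):
    """Full-state oracle equivalence on random lattices (exact)."""
    rng = np.random.default_rng(seed)
    shape = (int(rng.integers(3, 13)), int(rng.integers(3, 13)))
    s = np.round(rng.random(shape) * 255, 6)
    p = PCNNParams()
    history = scalar_pcnn(s.tolist(), p.beta, p.alpha_t, p.v_t,
                          p.weights.tolist(), n_iter=8, t0=p.t0)
    state = PCNNState.initial(s, p)
    for f, l, u, t, o in history:
        state = pcnn_step(state, p)
        assert np.array_equal(state.f, np.array(f))
        assert np.allclose(state.l, l, rtol=1e-12, atol=1e-12)
        assert np.allclose(state.u, u, rtol=1e-12, atol=1e-12)
        assert np.allclose(state.t, t, rtol=1e-12, atol=1e-12)
        assert np.array_equal(state.o, np.array(o))
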