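import numpy as np
import pytest

from dualbind.interaction import (
    build_interaction_map,
    compress,
    concat_refine,
    outer_interaction,
)
from dualbind.kan import KanLayer, KanLayerSpec, KanStack


def linear_stack(weight_rows, rng=None):
    """A KAN stack reduced to a pure linear map (amplitudes zeroed)."""
    weight_rows = np.atleast_2d(np.asarray(weight_rows, dtype=float))
    out_w, in_w = weight_rows.shape
    layer = KanLayer(KanLayerSpec(in_w, out_w), rng or np.random.default_rng(0))
    layer.amp[...] = 0.0
    layer.weight[...] = weight_rows
    layer.bias[...] = 0.0
    return KanStack([layer])


class TestCompress:
    def test_shape(self, rng):
        stack = KanStack.from_widths((6, 1), rng=rng)
        v = compress(rng.standard_normal((5, 6)), stack)
        assert v.shape == (5,)

    def test_identical_rows_identical_scalars(self, rng):
        stack = KanStack.from_widths((4, 1), rng=rng)
        row = rng.standard_normal(4)
        x = np.vstack([row, rng.standard_normal(4), row])
        v = compress(x, stack)
        # same parameters applied position-wise; BLAS blocking may differ by
        # row position, so equality is to float accumulation tolerance
        assert v[0] == pytest.approx(v[2], rel=1e-12, abs=1e-12)

    def test_linear_stack_matches_matrix_oracle(self):
        w = np.array([[1.0, -2.0, 0.5]])
        x = np.array([[1.0, 1.0, 2.0], [0.0, 3.0, -1.0]])
        np.testing.assert_allclose(compress(x, linear_stack(w)), x @ w[0], atol=1e-12)


class TestOuterInteraction:
    def test_zero_vector_gives_zero_matrix(self):
        m = outer_interaction(np.zeros(3), np.array([1.0, 2.0]))
        np.testing.assert_array_equal(m, np.zeros((3, 2)))

    def test_direct_example(self):
        m = outer_interaction(np.array([1.0, 2.0]), np.array([3.0, 4.0, 5.0]))
        np.testing.assert_array_equal(m, [[3, 4, 5], [6, 8, 10]])

    def test_matches_nested_loop_oracle(self, rng):
        v_ab = rng.standard_normal(4)
        v_ag = rng.standard_normal(6)
        m = outer_interaction(v_ab, v_ag)
        for i in range(4):
            for j in range(6):
                assert m[i, j] == v_ab[i] * v_ag[j]

    def test_rank_at_most_one(self, rng):
        """All 2x2 minors vanish (to relative float tolerance)."""
        for _ in range(100):
            v_ab = rng.standard_normal(int(rng.integers(2, 8)))
            v_ag = rng.standard_normal(int(rng.integers(2, 8)))
            m = outer_interaction(v_ab, v_ag)
            minors = m[:-1, :-1] * m[1:, 1:] - m[:-1, 1:] * m[1:, :-1]
            scale = max(1.0, np.abs(m).max() ** 2)
            assert np.abs(minors).max() <= 1e-9 * scale

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            outer_interaction(np.array([]), np.array([1.0]))

    def test_permutation_equivariance(self, rng):
        v_ab = rng.standard_normal(5)
        v_ag = rng.standard_normal(7)
        m = outer_interaction(v_ab, v_ag)
        p_ab = rng.permutation(5)
        p_ag = rng.permutation(7)
        np.testing.assert_array_equal(outer_interaction(v_ab[p_ab], v_ag), m[p_ab, :])
        np.testing.assert_array_equal(outer_interaction(v_ab, v_ag[p_ag]), m[:, p_ag])


class TestConcatRefine:
    def test_projection_recovery(self, rng):
        """Refinement weighting only the antibody-potential column returns v_ab."""
        l_ag_max = 6
        w = np.zeros((1, l_ag_max + 1))
        w[0, -1] = 1.0
        stack = linear_stack(w)
        v_ab = rng.standard_normal(4)
        v_ag = rng.standard_normal(5)
        m = outer_interaction(v_ab, v_ag)
        h = concat_refine(m, v_ab, stack, l_ag_max=l_ag_max)
        np.testing.assert_allclose(h, v_ab, atol=1e-12)

    def test_zero_input_gives_bias_response(self, rng):
        l_ag_max = 5
        stack = KanStack.from_widths((l_ag_max + 1, 1), rng=rng)
        stack.layers[0].bias[...] = 2.5
        m = np.zeros((3, 4))
        h = concat_refine(m, np.zeros(3), stack, l_ag_max=l_ag_max)
        np.testing.assert_allclose(h, 2.5, atol=1e-12)

    def test_linear_refinement_matches_matrix_oracle(self):
        m_inter = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        v_ab = np.array([0.5, -0.5])
        w = np.array([[1.0, 0.5, -1.0, 2.0]])  # 3 antigen cols + v_ab col
        h = concat_refine(m_inter, v_ab, linear_stack(w), l_ag_max=3)
        expected = m_inter @ w[0, :3] + v_ab * w[0, 3]
        np.testing.assert_allclose(h, expected, atol=1e-12)

    def test_padding_extension_never_changes_output(self, rng):
        """Growing the padded antigen width leaves h_aa unchanged, even with
        trained phases (nonzero edge response at zero input)."""
        v_ab = rng.standard_normal(4)
        v_ag = rng.standard_normal(5)
        m = outer_interaction(v_ab, v_ag)
        outputs = []
        for l_ag_max in (5, 8, 12):
            stack = KanStack.from_widths((l_ag_max + 1, 1), rng=np.random.default_rng(3))
            stack.layers[0].phase[...] = 0.7  # would leak through unmasked padding
            # identical parameters on the shared (valid) columns
            base = KanStack.from_widths((6, 1), rng=np.random.default_rng(3))
            base.layers[0].phase[...] = 0.7
            stack.layers[0].weight[...] = 0.0
            stack.layers[0].amp[...] = 0.0
            stack.layers[0].weight[0, :5] = base.layers[0].weight[0, :5]
            stack.layers[0].weight[0, -1] = base.layers[0].weight[0, -1]
            stack.layers[0].amp[0, :5] = base.layers[0].amp[0, :5]
            stack.layers[0].amp[0, -1] = base.layers[0].amp[0, -1]
            outputs.append(concat_refine(m, v_ab, stack, l_ag_max=l_ag_max))
        np.testing.assert_allclose(outputs[0], outputs[1], atol=1e-12)
        np.testing.assert_allclose(outputs[0], outputs[2], atol=1e-12)

    def test_mask_length_mismatch(self, rng):
        stack = KanStack.from_widths((6, 1), rng=rng)
        m = outer_interaction(rng.standard_normal(3), rng.standard_normal(4))
        with pytest.raises(ValueError, match="mask length"):
            concat_refine(m, rng.standard_normal(3), stack, mask_ag=np.ones(9, bool), l_ag_max=5)


class TestFullPipelinePermutations:
    def test_antibody_permutation_permutes_rows_and_h_aa(self, rng):
        comp_stack = KanStack.from_widths((6, 1), rng=np.random.default_rng(1))
        ref_stack = KanStack.from_widths((9, 1), rng=np.random.default_rng(2))
        x_ab = rng.standard_normal((5, 6))
        x_ag = rng.standard_normal((7, 6))
        base = build_interaction_map(x_ab, x_ag, comp_stack, ref_stack, l_ag_max=8)
        perm = rng.permutation(5)
        permuted = build_interaction_map(x_ab[perm], x_ag, comp_stack, ref_stack, l_ag_max=8)
        np.testing.assert_allclose(permuted.m_inter, base.m_inter[perm, :], atol=1e-12)
        np.testing.assert_allclose(permuted.h_aa, base.h_aa[perm], atol=1e-12)

    def test_antigen_permutation_permutes_columns(self, rng):
        comp_stack = KanStack.from_widths((6, 1), rng=np.random.default_rng(1))
        ref_stack = KanStack.from_widths((9, 1), rng=np.random.default_rng(2))
        x_ab = rng.standard_normal((5, 6))
        x_ag = rng.standard_normal((7, 6))
        base = build_interaction_map(x_ab, x_ag, comp_stack, ref_stack, l_ag_max=8)
        perm = rng.permutation(7)
        permuted = build_interaction_map(x_ab, x_ag[perm], comp_stack, ref_stack, l_ag_max=8)
        np.testing.assert_allclose(permuted.m_inter, base.m_inter[:, perm], atol=1e-12)
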