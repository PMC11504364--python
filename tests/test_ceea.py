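"""Covariance edge-enhanced attention: oracles, stochasticity, identity."""

import numpy as np
import pytest

from eenet import (
    CEEA,
    ceea_forward,
    center_and_flatten,
    channel_attention,
    channel_covariance,
    conv_lck,
    spatial_covariance_attention,
)
from eenet.ceea import CovMatrix, SpatialCapExceeded
from eenet.tensor import Tensor


def channel_cov_loop_oracle(a, b):
    """Double-loop channel covariance: (1/HW) sum_i a[c1,i] b[c2,i]."""
    c, hw = a.shape
    out = np.zeros((c, c))
    for c1 in range(c):
        for c2 in range(c):
            out[c1, c2] = sum(a[c1, i] * b[c2, i] for i in range(hw)) / hw
    return out


def spatial_cov_loop_oracle(e, f):
    """Triple-loop position covariance: (1/HW) sum_c e[c,i] f[c,j]."""
    c, hw = e.shape
    out = np.zeros((hw, hw))
    for i in range(hw):
        for j in range(hw):
            out[i, j] = sum(e[ch, i] * f[ch, j] for ch in range(c)) / hw
    return out


def row_softmax(m):
    e = np.exp(m - m.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


class TestCenterAndFlatten:
    def test_constant_channel_annihilated(self):
        out = center_and_flatten(np.full((1, 2, 2), 5.0))
        np.testing.assert_array_equal(out.values, [[0, 0, 0, 0]])

    def test_direct_arithmetic(self):
        out = center_and_flatten(np.array([[[1.0, 3.0], [5.0, 7.0]]]))
        np.testing.assert_array_equal(out.values, [[-3, -1, 1, 3]])

    def test_row_major_flattening(self):
        f = np.zeros((1, 2, 2))
        f[0, 1, 0] = 4.0  # (row=1, col=0) -> flat index 2
        out = center_and_flatten(f)
        assert out.values[0, 2] == 4.0 - 1.0  # value minus channel mean

    def test_rows_centred(self, rng):
        out = center_and_flatten(rng.normal(size=(4, 3, 5)))
        np.testing.assert_allclose(out.values.mean(axis=1), 0, atol=1e-12)
        assert out.source_dims == (4, 3, 5)


class TestChannelCovariance:
    def test_zero_maps(self):
        z = center_and_flatten(np.zeros((2, 2, 2)))
        np.testing.assert_array_equal(channel_covariance(z, z).values, np.zeros((2, 2)))

    def test_unit_variance(self):
        m = center_and_flatten(np.array([[[-1.0, 1.0]]]))
        np.testing.assert_allclose(channel_covariance(m, m).values, [[1.0]])

    def test_matrix_form_equals_loop_oracle(self, rng):
        for _ in range(100):
            a = center_and_flatten(rng.normal(size=(3, 2, 2)))
            b = center_and_flatten(rng.normal(size=(3, 2, 2)))
            np.testing.assert_allclose(
                channel_covariance(a, b).values,
                channel_cov_loop_oracle(a.values, b.values),
                atol=1e-6,
            )

    def test_dims_mismatch_rejected(self, rng):
        a = center_and_flatten(rng.normal(size=(2, 2, 2)))
        b = center_and_flatten(rng.normal(size=(2, 4, 1)))
        with pytest.raises(ValueError):
            channel_covariance(a, b)


class TestChannelAttention:
    def test_uniform_for_zero_covariance(self):
        attn = channel_attention(CovMatrix(np.zeros((4, 4))))
        np.testing.assert_allclose(attn.values, 1 / 4)

    def test_closed_form(self):
        attn = channel_attention(CovMatrix(np.array([[np.log(2.0), 0.0]])))
        np.testing.assert_allclose(attn.values, [[2 / 3, 1 / 3]], rtol=1e-12)

    def test_row_shift_invariance(self, rng):
        cov = rng.normal(size=(3, 3))
        shifted = cov.copy()
        shifted[1] += 7.5
        np.testing.assert_allclose(
            channel_attention(CovMatrix(cov)).values[1],
            channel_attention(CovMatrix(shifted)).values[1],
            rtol=1e-12,
        )

    def test_rows_sum_to_one(self, rng):
        for _ in range(20):
            attn = channel_attention(CovMatrix(rng.normal(size=(5, 5), scale=3)))
            np.testing.assert_allclose(attn.values.sum(axis=1), 1.0, atol=1e-6)
            assert np.all(attn.values > 0) and np.all(attn.values < 1)


class TestSpatialAttention:
    def test_zero_maps_uniform(self):
        z = center_and_flatten(np.zeros((1, 2, 2)))
        attn = spatial_covariance_attention(z, z)
        np.testing.assert_allclose(attn.values, 1 / 4)
        assert attn.grid_dims == (2, 2)

    def test_two_pixel_closed_form(self):
        m = center_and_flatten(np.array([[[1.0, -1.0]]]))  # already zero-mean
        attn = spatial_covariance_attention(m, m)
        sig = 1 / (1 + np.exp(-1.0))  # logistic of the 0.5 - (-0.5) gap
        np.testing.assert_allclose(attn.values, [[sig, 1 - sig], [1 - sig, sig]], rtol=1e-12)

    def test_matrix_form_equals_triple_loop(self, rng):
        for _ in range(100):
            e = center_and_flatten(rng.normal(size=(2, 2, 2)))
            f = center_and_flatten(rng.normal(size=(2, 2, 2)))
            got = spatial_covariance_attention(e, f).values
            np.testing.assert_allclose(
                got, row_softmax(spatial_cov_loop_oracle(e.values, f.values)), atol=1e-6
            )

    def test_cap_exceeded_raises_with_guidance(self, rng):
        e = center_and_flatten(rng.normal(size=(1, 40, 40)))
        with pytest.raises(SpatialCapExceeded, match="pool"):
            spatial_covariance_attention(e, e, spatial_cap=1024)


class TestCEEAForward:
    def test_identity_at_initialisation(self, rng):
        module = CEEA()
        f = rng.normal(size=(3, 6, 6))
        np.testing.assert_array_equal(ceea_forward(module, f), f)

    def test_compositional_oracle(self, rng):
        module = CEEA()
        module.gamma_c.data = np.array(0.7)
        module.gamma_p.data = np.array(-0.3)
        f = rng.normal(size=(2, 4, 4))
        got = ceea_forward(module, f)

        fe = conv_lck(module.lck.export_params(), f)
        fin = center_and_flatten(f)
        fec = center_and_flatten(fe)
        ac = channel_attention(channel_covariance(fin, fec)).values
        ap = spatial_covariance_attention(fec, fin).values
        expected = (
            f
            + 0.7 * (ac @ fin.values).reshape(f.shape)
            + (-0.3) * (fin.values @ ap.T).reshape(f.shape)
        )
        np.testing.assert_allclose(got, expected, rtol=1e-5, atol=1e-8)

    def test_pooled_spatial_branch_identity_and_shape(self, rng):
        module = CEEA(spatial_cap=64)  # forces pooling at 40x40
        f = rng.normal(size=(2, 40, 40))
        np.testing.assert_array_equal(ceea_forward(module, f), f)
        module.gamma_p.data = np.array(1.0)
        out = ceea_forward(module, f)
        assert out.shape == f.shape
        assert np.all(np.isfinite(out))

    def test_channel_permutation_consistency(self, rng):
        f = rng.normal(size=(4, 3, 3))
        perm = [3, 1, 0, 2]
        fin, fe = center_and_flatten(f), center_and_flatten(f * 0.5 + 1)
        cov = channel_covariance(fin, fe).values
        fin_p = center_and_flatten(f[perm])
        fe_p = center_and_flatten((f * 0.5 + 1)[perm])
        cov_p = channel_covariance(fin_p, fe_p).values
        np.testing.assert_allclose(cov_p, cov[np.ix_(perm, perm)], rtol=1e-12)
        ac, ac_p = row_softmax(cov), row_softmax(cov_p)
        np.testing.assert_allclose(ac_p, ac[np.ix_(perm, perm)], rtol=1e-12)

    def test_shape_preserved_on_batch(self, rng):
        module = CEEA()
        x = Tensor(rng.normal(size=(2, 3, 5, 7)))
        assert module(x).shape == (2, 3, 5, 7)
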