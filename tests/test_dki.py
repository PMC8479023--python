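"""Forward model, WLLS fit and scalar-map derivations.

Oracles here are deliberately independent of the implementation: signals are
checked against explicit index summation over the assembled 3x3 and 3x3x3x3
tensors, MK against a dense spherical average, and KFA against an explicit
81-component Frobenius-norm computation.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dkinet import dki, phantom
from dkinet.dki import (
    TensorFields,
    compute_fa,
    compute_kfa,
    compute_md,
    compute_mk,
    compute_scalars,
    fit_dki,
    predict_signal,
)
from dkinet.schemes import DWIDataset, build_scheme, fibonacci_sphere


def _fields_from(d6, w15, s0=1000.0):
    """Wrap bare per-voxel tensors into a (n,1,1) TensorFields."""
    d6 = np.atleast_2d(d6)
    w15 = np.atleast_2d(w15)
    n = d6.shape[0]
    return TensorFields(
        S0=np.full((n, 1, 1), s0),
        D=d6.reshape(n, 1, 1, 6),
        W=w15.reshape(n, 1, 1, 15),
        mask=np.ones((n, 1, 1), bool),
    )


def _signal_oracle(s0, d6, w15, scheme):
    """ln S via explicit index summation over full tensors."""
    D = dki.dt6_to_matrix(d6)
    W = dki.w15_to_tensor(w15)
    md = np.trace(D) / 3.0
    out = np.empty(scheme.n_volumes)
    for v in range(scheme.n_volumes):
        b = scheme.b_values[v]
        n = scheme.directions[v]
        d_app = sum(n[i] * n[j] * D[i, j] for i in range(3) for j in range(3))
        w_app = sum(n[i] * n[j] * n[k] * n[l] * W[i, j, k, l]
                    for i in range(3) for j in range(3)
                    for k in range(3) for l in range(3))
        out[v] = np.exp(np.log(s0) - b * d_app + b ** 2 / 6.0 * md ** 2 * w_app)
    return out


class TestPredictSignal:
    def test_isotropic_monoexponential(self, scheme_a):
        d6 = np.array([1e-3, 1e-3, 1e-3, 0, 0, 0])
        sig = predict_signal(1000.0, d6, np.zeros(15), scheme_a)
        b0 = scheme_a.b0_mask
        np.testing.assert_allclose(sig[b0], 1000.0, rtol=1e-12)
        shell1 = scheme_a.b_values == 1000
        np.testing.assert_allclose(sig[shell1], 1000.0 * np.exp(-1.0), rtol=1e-12)

    def test_b0_returns_s0_regardless_of_tensors(self, scheme_b):
        d6, w15 = phantom.random_tensor_pairs(1, seed=4)
        sig = predict_signal(123.0, d6[0], w15[0], scheme_b)
        np.testing.assert_allclose(sig[scheme_b.b0_mask], 123.0, rtol=1e-12)

    def test_matches_explicit_summation_oracle(self, scheme_b):
        d6, w15 = phantom.random_tensor_pairs(5, seed=5)
        sig = predict_signal(np.full(5, 700.0), d6, w15, scheme_b)
        for v in range(5):
            expected = _signal_oracle(700.0, d6[v], w15[v], scheme_b)
            np.testing.assert_allclose(sig[v], expected, rtol=1e-10)

    def test_invalid_inputs_rejected(self, scheme_a):
        d6 = np.array([1e-3, 1e-3, 1e-3, 0, 0, 0])
        with pytest.raises(ValueError, match="S0"):
            predict_signal(0.0, d6, np.zeros(15), scheme_a)
        # negative eigenvalue: D_app < 0 along directions near z
        indef = np.array([1e-3, 1e-3, -1e-3, 0, 0, 0])
        with pytest.raises(ValueError, match="diffusivity"):
            predict_signal(100.0, indef, np.zeros(15), scheme_a)


class TestFit:
    def test_noiseless_roundtrip(self, scheme_a):
        d6, w15 = phantom.random_tensor_pairs(100, seed=6)
        sig = predict_signal(np.full(100, 900.0), d6, w15, scheme_a)
        ds = DWIDataset(signal=sig.reshape(100, 1, 1, -1), scheme=scheme_a,
                        mask=np.ones((100, 1, 1), bool))
        fields = fit_dki(ds)
        scale_d = np.abs(d6).max(axis=1)
        scale_w = np.abs(w15).max(axis=1)
        assert (np.abs(fields.D.reshape(100, 6) - d6)
                / scale_d[:, None]).max() < 1e-6
        assert (np.abs(fields.W.reshape(100, 15) - w15)
                / scale_w[:, None]).max() < 1e-6

    def test_prolate_tensor_md_and_zero_w(self, scheme_a):
        d6 = np.array([1.7e-3, 0.3e-3, 0.3e-3, 0, 0, 0])
        sig = predict_signal(1000.0, d6, np.zeros(15), scheme_a)
        ds = DWIDataset(signal=np.tile(sig, (2, 1, 1, 1)), scheme=scheme_a,
                        mask=np.ones((2, 1, 1), bool))
        fields = fit_dki(ds)
        md = compute_md(fields)
        np.testing.assert_allclose(md[fields.mask], 0.76667e-3, rtol=1e-4)
        assert np.abs(fields.W[fields.mask]).max() < 1e-9

    def test_single_shell_not_identifiable(self):
        scheme = build_scheme([(1000, 30)], n_b0=1)
        sig = np.ones((2, 1, 1, scheme.n_volumes))
        ds = DWIDataset(signal=sig, scheme=scheme, mask=np.ones((2, 1, 1), bool))
        with pytest.raises(ValueError, match="not identifiable"):
            fit_dki(ds)

    def test_too_few_volumes(self):
        scheme = build_scheme([(1000, 8), (2000, 8)], n_b0=1)
        sig = np.ones((2, 1, 1, scheme.n_volumes))
        ds = DWIDataset(signal=sig, scheme=scheme, mask=np.ones((2, 1, 1), bool))
        with pytest.raises(ValueError, match="22"):
            fit_dki(ds)

    def test_voxels_outside_mask_untouched(self, scheme_a):
        d6, w15 = phantom.random_tensor_pairs(4, seed=8)
        sig = predict_signal(np.full(4, 500.0), d6, w15, scheme_a)
        mask = np.array([True, True, False, True]).reshape(4, 1, 1)
        ds = DWIDataset(signal=sig.reshape(4, 1, 1, -1), scheme=scheme_a, mask=mask)
        fields = fit_dki(ds)
        assert np.all(fields.D[2] == 0) and np.all(fields.W[2] == 0)
        assert fields.S0[2, 0, 0] == 0


class TestScalars:
    def test_md_equals_eigenvalue_mean(self, rng):
        d6, _ = phantom.random_tensor_pairs(20, seed=9)
        fields = _fields_from(d6, np.zeros((20, 15)))
        md = compute_md(fields).ravel()
        eig_mean = np.array([np.linalg.eigvalsh(dki.dt6_to_matrix(d)).mean()
                             for d in d6])
        np.testing.assert_allclose(md, eig_mean, rtol=1e-12)

    @pytest.mark.parametrize("lam,expected", [
        ((1.0, 1.0, 1.0), 0.0),
        ((1.0, 0.0, 0.0), 1.0),
    ])
    def test_fa_limits(self, lam, expected):
        d6 = np.array([lam[0], lam[1], lam[2], 0, 0, 0]) * 1e-3
        fields = _fields_from(d6, np.zeros(15))
        np.testing.assert_allclose(compute_fa(fields).ravel()[0], expected,
                                   atol=1e-12)

    def test_fa_prolate_closed_form(self):
        lam = np.array([1.7, 0.3, 0.3]) * 1e-3
        d6 = np.array([*lam, 0, 0, 0])
        fields = _fields_from(d6, np.zeros(15))
        expected = np.sqrt(1.5) * np.linalg.norm(lam - lam.mean()) \
            / np.linalg.norm(lam)
        np.testing.assert_allclose(compute_fa(fields).ravel()[0], expected,
                                   rtol=1e-12)
        assert abs(expected - 0.799) < 1e-3

    def test_mk_zero_w(self):
        d6, _ = phantom.random_tensor_pairs(5, seed=10)
        fields = _fields_from(d6, np.zeros((5, 15)))
        np.testing.assert_allclose(compute_mk(fields), 0.0, atol=1e-15)

    def test_mk_constant_kapp_construction(self):
        # isotropic D with W = K * I4 gives K_app(n) = K for every n
        k = 1.3
        d6 = np.array([1e-3, 1e-3, 1e-3, 0, 0, 0])
        w15 = k * dki.ISOTROPIC_W15
        fields = _fields_from(d6, w15)
        np.testing.assert_allclose(compute_mk(fields).ravel()[0], k, rtol=1e-12)

    def test_mk_matches_dense_spherical_oracle(self):
        d6, w15 = phantom.random_tensor_pairs(10, seed=11)
        fields = _fields_from(d6, w15)
        mk = compute_mk(fields).ravel()
        dense = fibonacci_sphere(10_000)
        md = d6[:, :3].mean(axis=1)
        d_app = d6 @ dki.design_d6(dense).T
        w_app = w15 @ dki.design_w15(dense).T
        k_app = np.clip((md ** 2)[:, None] * w_app / d_app ** 2,
                        dki.KAPP_MIN, dki.KAPP_MAX)
        oracle = k_app.mean(axis=1)
        assert np.abs(mk - oracle).max() / np.abs(oracle).max() < 5e-3

    def test_kfa_zero_conventions(self):
        d6 = np.array([1e-3, 1e-3, 1e-3, 0, 0, 0])
        fields = _fields_from(np.tile(d6, (2, 1)),
                              np.stack([np.zeros(15), 0.7 * dki.ISOTROPIC_W15]))
        kfa = compute_kfa(fields).ravel()
        np.testing.assert_allclose(kfa, 0.0, atol=1e-12)

    def test_kfa_explicit_81_component_oracle(self):
        w15 = np.zeros(15)
        w15[0] = 0.9  # only W1111 nonzero
        d6 = np.array([1e-3, 1e-3, 1e-3, 0, 0, 0])
        fields = _fields_from(d6, w15)
        kfa = compute_kfa(fields).ravel()[0]
        W = dki.w15_to_tensor(w15)
        wbar = sum(W[i, i, j, j] for i in range(3) for j in range(3)) / 5.0
        I4 = np.zeros((3, 3, 3, 3))
        delta = np.eye(3)
        for i, j, k, l in itertools.product(range(3), repeat=4):
            I4[i, j, k, l] = (delta[i, j] * delta[k, l]
                              + delta[i, k] * delta[j, l]
                              + delta[i, l] * delta[j, k]) / 3.0
        dev = W - wbar * I4
        expected = np.sqrt((dev ** 2).sum() / (W ** 2).sum())
        np.testing.assert_allclose(kfa, expected, rtol=1e-12)

    def test_compute_scalars_bundling(self, scheme_a):
        d6, w15 = phantom.random_tensor_pairs(6, seed=12)
        fields = _fields_from(d6, w15)
        fields.mask[3:] = False
        maps = compute_scalars(fields)
        assert maps.method == "model-fit"
        for name in ("FA", "MD", "MK", "KFA"):
            assert np.all(maps[name][~fields.mask] == 0)
        assert np.all((maps.FA >= 0) & (maps.FA <= 1))
        assert np.all((maps.KFA >= 0) & (maps.KFA <= 1))
        assert np.all(maps.MD >= 0)


def _rotate_d6(d6, R):
    return dki.matrix_to_dt6(R @ dki.dt6_to_matrix(d6) @ R.T)


def _rotate_w15(w15, R):
    W = dki.w15_to_tensor(w15)
    Wr = np.einsum("ia,jb,kc,ld,abcd->ijkl", R, R, R, R, W)
    return dki.tensor_to_w15(Wr)


def test_scalar_rotation_invariance():
    """FA, MD, MK, KFA are invariant under joint rotation of D and W."""
    d6, w15 = phantom.random_tensor_pairs(5, seed=13)
    rng = np.random.default_rng(14)
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    R = q * np.sign(np.diag(r))
    if np.linalg.det(R) < 0:
        R[:, 0] = -R[:, 0]
    base = _fields_from(d6, w15)
    rot = _fields_from(np.stack([_rotate_d6(d, R) for d in d6]),
                       np.stack([_rotate_w15(w, R) for w in w15]))
    np.testing.assert_allclose(compute_fa(base), compute_fa(rot), atol=1e-9)
    np.testing.assert_allclose(compute_md(base), compute_md(rot), rtol=1e-9)
    np.testing.assert_allclose(compute_kfa(base), compute_kfa(rot), atol=1e-9)
    # MK uses a fixed direction lattice; the spherical average converges, so
    # rotation changes it only at the lattice discretization level
    np.testing.assert_allclose(compute_mk(base), compute_mk(rot), atol=5e-3)


@settings(max_examples=25, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_scalar_bounds_random_tensors(seed):
    """FA and KFA stay in [0, 1] for arbitrary valid tensors."""
    d6, w15 = phantom.random_tensor_pairs(8, seed=seed)
    fields = _fields_from(d6, w15)
    fa = compute_fa(fields)
    kfa = compute_kfa(fields)
    assert np.all((fa >= 0) & (fa <= 1))
    assert np.all((kfa >= 0) & (kfa <= 1))
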