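import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from jard.model import (
    AcquisitionScheme,
    DTMParams,
    build_rotation,
    build_tensors,
    fractional_anisotropy,
    predict_signal,
    signal_and_jacobian,
)

angles = st.floats(-np.pi, np.pi, allow_nan=False)


def _elementary_product(a1, a2, a3):
    """Hand-coded Rx Ry Rz product, independent of the implementation."""
    rx = np.array(
        [[1, 0, 0], [0, np.cos(a1), -np.sin(a1)], [0, np.sin(a1), np.cos(a1)]]
    )
    ry = np.array(
        [[np.cos(a2), 0, np.sin(a2)], [0, 1, 0], [-np.sin(a2), 0, np.cos(a2)]]
    )
    rz = np.array(
        [[np.cos(a3), -np.sin(a3), 0], [np.sin(a3), np.cos(a3), 0], [0, 0, 1]]
    )
    return rx @ ry @ rz


class TestBuildRotation:
    def test_zero_angles_give_identity(self):
        assert np.allclose(build_rotation(0, 0, 0, 0, 1), np.eye(3))

    def test_alpha4_split_symmetric(self):
        # the +/- alpha4/2 split puts the in-plane rotations pi apart
        r1 = build_rotation(0, 0, 0, np.pi, 1)
        r2 = build_rotation(0, 0, 0, np.pi, 2)
        rel = r1 @ r2.T
        assert np.isclose(np.trace(rel), 2 * np.cos(np.pi) + 1, atol=1e-12)

    def test_matches_elementary_product(self):
        got = build_rotation(0.3, 0.7, 1.1, 0.5, 1)
        assert np.allclose(got, _elementary_product(0.3, 0.7, 1.1 + 0.25), atol=1e-12)
        got2 = build_rotation(0.3, 0.7, 1.1, 0.5, 2)
        assert np.allclose(got2, _elementary_product(0.3, 0.7, 1.1 - 0.25), atol=1e-12)

    @given(a1=angles, a2=angles, a3=angles, a4=angles)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_proper_rotation(self, a1, a2, a3, a4):
        r = build_rotation(a1, a2, a3, a4, 2)
        assert np.allclose(r @ r.T, np.eye(3), atol=1e-12)
        assert np.isclose(np.linalg.det(r), 1.0, atol=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            build_rotation(np.nan, 0, 0, 0, 1)
        with pytest.raises(ValueError):
            build_rotation(0, 0, 0, 0, 3)


class TestBuildTensors:
    def test_identity_rotation_diagonal(self):
        p = DTMParams(1.48e-3, 0.135e-3, 0.4e-3, 0, 0, 0, 0, 0.5, 0.4)
        t = build_tensors(p)
        assert np.allclose(t.D1, np.diag([1.48e-3, 0.135e-3, 0.135e-3]))

    @given(a1=angles, a2=angles, a3=angles, a4=angles)
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_spectrum_invariant_under_rotation(self, a1, a2, a3, a4):
        p = DTMParams(1.48e-3, 0.15e-3, 0.4e-3, a1, a2, a3, a4, 0.45, 0.45)
        t = build_tensors(p)
        ev1 = np.sort(np.linalg.eigvalsh(t.D1))
        assert np.allclose(ev1, [0.15e-3, 0.15e-3, 1.48e-3], atol=1e-12)
        ev2 = np.sort(np.linalg.eigvalsh(t.D2))
        assert np.allclose(ev2, [0.4e-3, 0.4e-3, 1.48e-3], atol=1e-12)

    def test_principal_axes_subtend_alpha4(self, crossing_params):
        p = dataclasses.replace(crossing_params, alpha3=0.8 * np.pi, alpha4=np.pi / 2)
        t = build_tensors(p)

        def principal(d):
            w, v = np.linalg.eigh(d)
            return v[:, np.argmax(w)]

        cosang = abs(principal(t.D1) @ principal(t.D2))
        assert np.isclose(np.arccos(np.clip(cosang, 0, 1)), np.pi / 2, atol=1e-9)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            DTMParams(-1e-3, 1e-4, 1e-4, 0, 0, 0, 0, 0.4, 0.4)
        with pytest.raises(ValueError):
            DTMParams(1e-3, 1e-4, 1e-4, 0, 0, 0, 0, 0.6, 0.6)


class TestPredictSignal:
    def test_b0_returns_s0(self, full_scheme, crossing_params):
        s = predict_signal(crossing_params, full_scheme)
        assert np.allclose(s[full_scheme.b0_mask], crossing_params.S0)
        assert np.all(s > 0) and np.all(s <= crossing_params.S0 + 1e-12)

    def test_pure_isotropic_closed_form(self):
        p = DTMParams(1e-3, 1e-4, 1e-4, 0, 0, 0, 0, 0.0, 0.0, S0=250.0)
        scheme = AcquisitionScheme([1000.0], [[1.0, 0.0, 0.0]])
        s = predict_signal(p, scheme)
        assert np.isclose(s[0], 250.0 * np.exp(-3.0), rtol=1e-12)

    def test_matches_explicit_matrix_oracle(self, crossing_params):
        # independent evaluation building the tensors as explicit matrices
        p = crossing_params
        t = build_tensors(p)
        w, v = np.linalg.eigh(t.D1)
        g = v[:, np.argmax(w)]  # gradient along D1's principal axis
        scheme = AcquisitionScheme([3000.0], [g])
        expected = p.S0 * (
            p.f1 * np.exp(-3000 * g @ t.D1 @ g)
            + p.f2 * np.exp(-3000 * g @ t.D2 @ g)
            + p.f_iso * np.exp(-3000 * p.D_iso)
        )
        assert np.isclose(predict_signal(p, scheme)[0], expected, rtol=1e-12)

    def test_label_exchange_invariance(self, full_scheme, crossing_params):
        p = dataclasses.replace(
            crossing_params, lambda_perp2=0.3e-3, f1=0.3, f2=0.55, alpha4=0.7
        )
        assert np.allclose(
            predict_signal(p, full_scheme),
            predict_signal(p.swap_labels(), full_scheme),
            rtol=1e-12,
        )

    def test_monotone_in_b(self, crossing_params):
        g = np.array([0.3, -0.5, 0.81])
        g /= np.linalg.norm(g)
        bs = np.linspace(0, 5000, 21)
        scheme = AcquisitionScheme(bs, np.tile(g, (21, 1)))
        s = predict_signal(crossing_params, scheme)
        assert np.all(np.diff(s) <= 1e-12)

    def test_f2_zero_equals_single_tensor_model(self, full_scheme, crossing_params):
        p = dataclasses.replace(crossing_params, f1=0.85, f2=0.0)
        t = build_tensors(p)
        g = full_scheme.directions
        b = full_scheme.b_values
        single = p.S0 * (
            p.f1 * np.exp(-b * np.einsum("ja,ab,jb->j", g, t.D1, g))
            + p.f_iso * np.exp(-b * p.D_iso)
        )
        assert np.allclose(predict_signal(p, full_scheme), single, rtol=1e-12)


class TestFractionalAnisotropy:
    def test_isotropic_is_zero(self):
        assert fractional_anisotropy([1e-3, 1e-3, 1e-3]) == 0

    def test_reference_tensor_two_decimals(self):
        fa = fractional_anisotropy(np.array([1.40, 0.40, 0.38]) * 1e-3)
        assert round(float(fa), 2) == 0.67

    def test_direct_formula_oracle(self):
        lam = np.array([1.48, 0.15, 0.12]) * 1e-3
        a, b, c = lam
        expected = np.sqrt(
            0.5 * ((a - b) ** 2 + (b - c) ** 2 + (a - c) ** 2)
            / (a**2 + b**2 + c**2)
        )
        assert np.isclose(fractional_anisotropy(lam), expected, rtol=1e-14)
        assert 0.89 < expected < 0.91

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            fractional_anisotropy([1e-3, 0.0, 1e-3])


class TestJacobian:
    def test_matches_finite_differences(self, small_scheme):
        theta = np.array([1.48e-3, 1.5e-4, 4.0e-4, 0.2, -0.4, 1.1, 0.8, 0.3, 0.5])
        s, jac = signal_and_jacobian(
            theta[None], small_scheme.b_values, small_scheme.directions, 250.0
        )
        eps = 1e-7
        for k in range(9):
            tp, tm = theta.copy(), theta.copy()
            tp[k] += eps
            tm[k] -= eps
            sp, _ = signal_and_jacobian(
                tp[None], small_scheme.b_values, small_scheme.directions, 250.0,
                want_jacobian=False,
            )
            sm, _ = signal_and_jacobian(
                tm[None], small_scheme.b_values, small_scheme.directions, 250.0,
                want_jacobian=False,
            )
            fd = (sp[0] - sm[0]) / (2 * eps)
            assert np.allclose(jac[0, :, k], fd, rtol=1e-5, atol=1e-4)

    def test_alpha1_column_vanishes_for_axially_symmetric_model(self, small_scheme):
        # the symmetric model's signal depends only on the principal axes,
        # which do not involve alpha1
        theta = np.array([1.48e-3, 1.5e-4, 4.0e-4, 0.2, -0.4, 1.1, 0.8, 0.3, 0.5])
        _, jac = signal_and_jacobian(
            theta[None], small_scheme.b_values, small_scheme.directions, 250.0
        )
        assert np.max(np.abs(jac[0, :, 3])) < 1e-12


class TestAcquisitionScheme:
    def test_rejects_non_unit_directions(self):
        with pytest.raises(ValueError):
            AcquisitionScheme([1000.0], [[1.0, 1.0, 0.0]])

    def test_b0_directions_unchecked(self):
        s = AcquisitionScheme([0.0], [[5.0, 0.0, 0.0]])
        assert s.n_measurements == 1

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            AcquisitionScheme([0.0, 1000.0], [[0.0, 0.0, 1.0]])
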