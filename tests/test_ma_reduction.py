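import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pulsetrack import (NLMSFilter, SignSignFilter,
                        count_weight_multiplications)


def nlms_oracle(u_seq, d_seq, taps, mu, eps):
    """Line-by-line recursion: w(n) = w(n-1) + mu*u/(u'u+eps)*e."""
    w = np.zeros(taps)
    u = np.zeros(taps)
    traj = []
    for u_new, d in zip(u_seq, d_seq):
        u = np.concatenate(([u_new], u[:-1]))
        y = u @ w
        e = d - y
        w = w + mu * u / (u @ u + eps) * e
        traj.append((w.copy(), e, y))
    return traj


def sign_sign_oracle(acc_seq, d_seq, taps, mu, order=("x", "y", "z")):
    """Brute-force recursion over the three sign-sign axis updates."""
    w = {a: np.zeros(taps) for a in "xyz"}
    u = {a: np.zeros(taps) for a in "xyz"}
    traj = []
    for (ax, ay, az), d in zip(acc_seq, d_seq):
        new = {"x": ax, "y": ay, "z": az}
        for a in "xyz":
            u[a] = np.concatenate(([new[a]], u[a][:-1]))
        s = {a: np.sign(u[a]) for a in "xyz"}
        y = sum(float(s[a] @ w[a]) for a in "xyz")
        e = d - y
        se = np.sign(e)
        for a in order:  # order immaterial: shared pre-update e
            c = np.count_nonzero(s[a])
            if c > 0:
                w[a] = w[a] + mu * s[a] / c * se
        traj.append(({a: w[a].copy() for a in "xyz"}, e, y))
    return traj


class TestNLMS:
    def test_zero_weight_identity(self):
        filt = NLMSFilter(taps=4, mu=0.1)
        e, y = filt.step(1.0, 3.5)
        assert y == 0.0 and e == 3.5

    def test_hand_example(self):
        # M=2, delay line (1,1), w=(0,0), d=1, mu=0.5: e=1, w=(0.25, 0.25)
        filt = NLMSFilter(taps=2, mu=0.5, eps=0.0)
        filt.step(1.0, 0.0)          # d=0 keeps weights at zero
        e, y = filt.step(1.0, 1.0)
        assert e == 1.0 and y == 0.0
        np.testing.assert_allclose(filt.w, [0.25, 0.25], atol=1e-15)

    def test_all_zero_input_with_eps_zero_raises(self):
        filt = NLMSFilter(taps=3, mu=0.1, eps=0.0)
        with pytest.raises(ZeroDivisionError):
            filt.step(0.0, 1.0)

    def test_non_finite_input_rejected(self):
        filt = NLMSFilter(taps=3)
        with pytest.raises(ValueError):
            filt.step(np.nan, 1.0)

    def test_matches_transliteration_oracle(self):
        rng = np.random.default_rng(11)
        u_seq = rng.normal(size=200)
        d_seq = rng.normal(size=200)
        filt = NLMSFilter(taps=8, mu=0.3, eps=1e-8)
        traj = nlms_oracle(u_seq, d_seq, taps=8, mu=0.3, eps=1e-8)
        for (u_new, d), (w_ref, e_ref, y_ref) in zip(zip(u_seq, d_seq), traj):
            e, y = filt.step(u_new, d)
            assert abs(e - e_ref) <= 1e-12 and abs(y - y_ref) <= 1e-12
            np.testing.assert_allclose(filt.w, w_ref, rtol=0, atol=1e-12)


class TestSignSign:
    def test_zero_error_freezes_weights(self):
        filt = SignSignFilter(taps=5, mu=0.01)
        for _ in range(10):
            filt.step(1.0, -1.0, 2.0, 0.0)   # y=0 so e=0 throughout
        assert np.all(filt.w_x == 0) and np.all(filt.w_y == 0) \
            and np.all(filt.w_z == 0)

    def test_all_positive_lines_increment_mu_over_m(self):
        M, mu = 21, 1e-4
        filt = SignSignFilter(taps=M, mu=mu)
        for _ in range(M):                    # fill delay lines, e stays 0
            filt.step(1.0, 2.0, 0.5, 0.0)
        e, y = filt.step(1.0, 1.0, 1.0, 0.7)
        assert e == 0.7 and y == 0.0
        for w in (filt.w_x, filt.w_y, filt.w_z):
            np.testing.assert_array_equal(w, np.full(M, mu / M))

    def test_matches_transliteration_oracle(self):
        rng = np.random.default_rng(12)
        acc = rng.choice([-1.0, 1.0], size=(500, 3))
        d = rng.normal(size=500)
        filt = SignSignFilter(taps=21, mu=1e-4)
        traj = sign_sign_oracle(acc, d, taps=21, mu=1e-4)
        for (ax, ay, az), dn, (w_ref, e_ref, y_ref) in zip(acc, d, traj):
            e, y = filt.step(ax, ay, az, dn)
            assert abs(e - e_ref) <= 1e-12 and abs(y - y_ref) <= 1e-12
            np.testing.assert_allclose(filt.w_x, w_ref["x"], atol=1e-12)
            np.testing.assert_allclose(filt.w_y, w_ref["y"], atol=1e-12)
            np.testing.assert_allclose(filt.w_z, w_ref["z"], atol=1e-12)

    def test_axis_update_order_immaterial(self):
        rng = np.random.default_rng(13)
        acc = rng.normal(size=(200, 3))
        d = rng.normal(size=200)
        a = sign_sign_oracle(acc, d, taps=7, mu=0.01, order=("x", "y", "z"))
        b = sign_sign_oracle(acc, d, taps=7, mu=0.01, order=("z", "y", "x"))
        for (wa, ea, _), (wb, eb, _) in zip(a, b):
            assert ea == eb
            for axis in "xyz":
                np.testing.assert_array_equal(wa[axis], wb[axis])

    @given(lam=st.floats(min_value=1e-6, max_value=1e6,
                         allow_nan=False, allow_infinity=False))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_positive_rescaling_invariance(self, lam):
        rng = np.random.default_rng(14)
        acc = rng.normal(size=(100, 3))
        d = rng.normal(size=100)
        f1 = SignSignFilter(taps=6, mu=0.02)
        f2 = SignSignFilter(taps=6, mu=0.02)
        for (ax, ay, az), dn in zip(acc, d):
            e1, _ = f1.step(ax, ay, az, dn)
            e2, _ = f2.step(lam * ax, lam * ay, lam * az, dn)
            assert e1 == e2
        np.testing.assert_array_equal(f1.w_x, f2.w_x)
        np.testing.assert_array_equal(f1.w_z, f2.w_z)

    def test_zero_reference_is_transparent(self):
        rng = np.random.default_rng(15)
        d = rng.normal(size=300)
        filt = SignSignFilter(taps=21)
        for dn in d:
            e, y = filt.step(0.0, 0.0, 0.0, dn)
            assert e == dn and y == 0.0
        assert np.all(filt.w_x == 0)

    def test_increments_in_three_level_set(self):
        rng = np.random.default_rng(16)
        filt = SignSignFilter(taps=9, mu=0.05)
        for _ in range(300):
            before = [w.copy() for w in (filt.w_x, filt.w_y, filt.w_z)]
            ax, ay, az, d = rng.normal(size=4)
            filt.step(ax, ay, az, d)
            for w0, w1, u in zip(before, (filt.w_x, filt.w_y, filt.w_z),
                                 (filt.u_x, filt.u_y, filt.u_z)):
                c = np.count_nonzero(np.sign(u))
                deltas = w1 - w0
                allowed = [0.0] if c == 0 else [-filt.mu / c, 0.0, filt.mu / c]
                # each increment equals a member of the three-level set
                # (up to the rounding of the in-place accumulation)
                dist = np.min(np.abs(deltas[:, None] - np.asarray(allowed)),
                              axis=1)
                assert np.all(dist <= 1e-15)


class TestComplexity:
    @pytest.mark.parametrize("taps,expected", [(21, (21, 64)), (1, (1, 4))])
    def test_multiplication_formulas(self, taps, expected):
        assert count_weight_multiplications(taps) == expected

    def test_instrumented_counts(self):
        rng = np.random.default_rng(17)
        M = 21
        ss = SignSignFilter(taps=M)
        nlms = NLMSFilter(taps=M)
        n = 200
        for _ in range(n):
            ss.step(*rng.normal(size=4))
            nlms.step(rng.normal(), rng.normal())
        assert ss.multiplications / n <= M
        assert nlms.multiplications == n * (3 * M + 1)


def test_weights_bounded_over_long_runs():
    rng = np.random.default_rng(18)
    n = 100_000
    acc = rng.uniform(-1, 1, size=(n, 3))
    d = rng.uniform(-1, 1, size=n)
    ss = SignSignFilter(taps=21, mu=1e-4)
    nlms = NLMSFilter(taps=21, mu=1e-4)
    for i in range(n):
        ss.step(acc[i, 0], acc[i, 1], acc[i, 2], d[i])
        nlms.step(acc[i, 0], d[i])
    for w in (ss.w_x, ss.w_y, ss.w_z, nlms.w):
        assert np.all(np.isfinite(w))
        assert np.max(np.abs(w)) < 10.0
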