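import numpy as np
import pytest
import scipy.linalg

from bcihier.io import NC, IC_CLASSES, Epoch, EpochSet, RawSession
from bcihier.preprocessing import (CSPModel, apply_csp, fit_csp_ovr,
                                   prefilter, subband_filter)

FS = 250.0


def sine(freq, seconds=12.0, fs=FS, n_channels=2):
    t = np.arange(int(seconds * fs)) / fs
    return np.tile(np.sin(2 * np.pi * freq * t), (n_channels, 1))


def as_session(signal):
    return RawSession(signal, FS, [f"c{i}" for i in range(signal.shape[0])],
                      events=[(0, "left")])


# steady-state window: the finite test signal switches on/off at its ends,
# and those broadband onset clicks legitimately pass any 1-50 Hz filter,
# so attenuation is measured away from the edges
CENTER = slice(int(2 * FS), -int(2 * FS))


def rms(x):
    return np.sqrt(np.mean(x ** 2))


class TestPrefilter:
    def test_mains_band_attenuated(self):
        s = sine(60.0)
        out = prefilter(as_session(s)).signal
        assert rms(out[:, CENTER]) < 0.05 * rms(s[:, CENTER])

    def test_passband_preserved(self):
        s = sine(10.0)
        out = prefilter(as_session(s)).signal
        assert abs(rms(out[:, CENTER]) - rms(s[:, CENTER])) \
            < 0.05 * rms(s[:, CENTER])

    def test_notch_kills_50hz(self):
        s = sine(50.0)
        out = prefilter(as_session(s)).signal
        assert rms(out[:, CENTER]) < 0.05 * rms(s[:, CENTER])

    def test_zero_in_zero_out(self):
        out = prefilter(as_session(np.zeros((2, 1000)))).signal
        np.testing.assert_array_equal(out, 0.0)

    def test_low_sampling_rate_rejected(self):
        sess = RawSession(np.zeros((2, 500)), 90.0, ["a", "b"],
                          events=[(0, "left")])
        with pytest.raises(ValueError, match="fs"):
            prefilter(sess)


class TestSubband:
    def test_energy_lands_in_own_band(self):
        for freq, idx in ((10.0, 0), (25.0, 2)):
            banded = subband_filter(sine(freq)[0], FS)
            energies = (banded ** 2).sum(axis=-1)
            assert energies[idx] / energies.sum() > 0.90

    def test_shape_contract(self):
        x = np.random.default_rng(0).standard_normal((5, 5, 750))
        assert subband_filter(x, FS).shape == (5, 5, 3, 750)

    def test_inband_idempotence(self):
        # noise limited to 9-11 Hz sits strictly inside the 8-12 band, so
        # re-filtering must leave it essentially untouched
        from bcihier.preprocessing import bandpass

        x = bandpass(np.random.default_rng(1).standard_normal(6000),
                     (9.0, 11.0), FS)
        again = subband_filter(x, FS)[0]
        a, b = again[CENTER], x[CENTER]
        assert abs(rms(a) - rms(b)) < 0.02 * rms(b)

    def test_invalid_band(self):
        with pytest.raises(ValueError, match="band"):
            subband_filter(sine(10.0)[0], FS, bands=((100.0, 130.0),))


def cov_epochs(cov, label, n_epochs=4, n_samples=64, seed=0):
    """Epochs whose per-epoch covariance is exactly ``cov``."""
    rng = np.random.default_rng(seed)
    root = scipy.linalg.sqrtm(cov).real
    out = []
    for i in range(n_epochs):
        q = scipy.linalg.qr(rng.standard_normal((n_samples, cov.shape[0])),
                            mode="economic")[0].T
        out.append(Epoch(root @ q, label, (0.0, n_samples / FS), i))
    return out


class TestCSP:
    def two_class_set(self, cov_a, cov_b):
        eps = (cov_epochs(cov_a, "left", seed=1)
               + cov_epochs(cov_b, NC, seed=2))
        return EpochSet(eps, FS)

    def test_axis_aligned_toy(self):
        # class A concentrates variance on channel 1, B on channel 2
        train = self.two_class_set(np.diag([10.0, 1.0]),
                                   np.diag([1.0, 10.0]))
        model = fit_csp_ovr(train, n_keep=1)
        w = model.filters["left"][0]
        cos = abs(w[0]) / np.linalg.norm(w)
        assert cos > 0.99
        assert model.eigenvalues["left"][0] > 0.85

    def test_identical_covariances_give_half_eigenvalues(self):
        train = self.two_class_set(np.eye(2), np.eye(2))
        model = fit_csp_ovr(train, n_keep=1)
        np.testing.assert_allclose(model.eigenvalues["left"], 0.5,
                                   atol=1e-9)

    def test_whitening_and_pairing(self, rng):
        cov_a = np.cov(rng.standard_normal((3, 200)))
        cov_b = np.cov(rng.standard_normal((3, 200)))
        eps = (cov_epochs(cov_a, "left", seed=3)
               + cov_epochs(cov_b, NC, seed=4))
        model = fit_csp_ovr(EpochSet(eps, FS), n_keep=2)
        for cls, other in (("left", NC), (NC, "left")):
            w = model.filters[cls]
            t = _norm_cov(cov_a if cls == "left" else cov_b)
            r = _norm_cov(cov_b if cls == "left" else cov_a)
            comp = t + r
            np.testing.assert_allclose(w @ comp @ w.T, np.eye(3), atol=1e-6)
            lam_t = np.diag(w @ t @ w.T)
            lam_r = np.diag(w @ r @ w.T)
            np.testing.assert_allclose(lam_t + lam_r, 1.0, atol=1e-6)

    def test_matches_brute_force_generalized_eigensolver(self, rng):
        # independent oracle: whiten the composite covariance explicitly,
        # then diagonalize the whitened target
        cov_a = np.cov(rng.standard_normal((2, 300))) + 0.1 * np.eye(2)
        cov_b = np.cov(rng.standard_normal((2, 300))) + 0.1 * np.eye(2)
        eps = (cov_epochs(cov_a, "left", seed=5)
               + cov_epochs(cov_b, NC, seed=6))
        model = fit_csp_ovr(EpochSet(eps, FS), n_keep=2, shrinkage=0.0)
        t, r = _norm_cov(cov_a), _norm_cov(cov_b)
        d, u = np.linalg.eigh(t + r)
        white = u @ np.diag(d ** -0.5) @ u.T
        lam, v = np.linalg.eigh(white @ t @ white.T)
        w_oracle = (white.T @ v).T[::-1]          # descending
        np.testing.assert_allclose(model.eigenvalues["left"], lam[::-1],
                                   atol=1e-9)
        for row, oracle_row in zip(model.filters["left"], w_oracle):
            cos = abs(row @ oracle_row) / (np.linalg.norm(row)
                                           * np.linalg.norm(oracle_row))
            assert cos > 1 - 1e-9

    def test_missing_class_data(self):
        eps = cov_epochs(np.eye(2), "left", n_epochs=1)
        with pytest.raises(ValueError):
            fit_csp_ovr(EpochSet(eps, FS))

    def test_save_load_round_trip(self, tmp_path, rng):
        train = self.two_class_set(np.diag([5.0, 1.0]), np.diag([1.0, 5.0]))
        model = fit_csp_ovr(train, n_keep=2)
        model.save(tmp_path / "csp.npz")
        back = CSPModel.load(tmp_path / "csp.npz")
        assert back.classes == model.classes and back.n_keep == 2
        np.testing.assert_allclose(back.filters["left"],
                                   model.filters["left"])


def _norm_cov(c):
    return c / np.trace(c)


class TestApplyCSP:
    def make_model(self, n_channels=2, n_keep=2):
        eye = np.eye(n_channels)
        return CSPModel(filters={c: eye.copy() for c in (NC,) + IC_CLASSES},
                        eigenvalues={c: np.ones(n_channels)
                                     for c in (NC,) + IC_CLASSES},
                        classes=(NC,) + IC_CLASSES, n_keep=n_keep)

    def test_identity_projection_returns_channels(self):
        model = self.make_model()
        seg = np.arange(20.0).reshape(2, 10)
        proj = apply_csp(model, Epoch(seg, "left", (0, 1), 0))
        np.testing.assert_allclose(proj[0], seg)

    def test_25_series(self, expert_epochs):
        from bcihier.preprocessing import fit_csp_ovr

        model = fit_csp_ovr(expert_epochs, n_keep=5)
        proj = apply_csp(model, expert_epochs.epochs[0])
        assert proj.shape[:2] == (5, 5)     # 5 classes x 5 projections

    def test_zero_epoch_zero_series(self):
        model = self.make_model()
        proj = apply_csp(model, Epoch(np.zeros((2, 16)), NC, (0, 1), 0))
        np.testing.assert_array_equal(proj, 0.0)

    def test_channel_mismatch(self):
        model = self.make_model()
        with pytest.raises(ValueError, match="channels"):
            apply_csp(model, Epoch(np.zeros((3, 16)), NC, (0, 1), 0))


def test_simulated_classes_are_csp_separable(expert_epochs):
    """On simulator output the first kept projection of each class carries
    more target-class variance than rest-class variance."""
    model = fit_csp_ovr(expert_epochs, n_keep=5)
    for cls in IC_CLASSES:
        lam = model.eigenvalues[cls][0]
        assert lam / (1 - lam) > 1.0
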