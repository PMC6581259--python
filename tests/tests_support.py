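"""Shared helpers for constructing exact-covariance epoch sets."""

import numpy as np
import scipy.linalg

from bcihier.io import NC, Epoch, EpochSet


def cov_epoch_set(rng, n_channels=2, n_epochs=4, n_samples=64):
    """Two-class epoch set whose per-epoch covariances are exact."""
    cov_a = np.cov(rng.standard_normal((n_channels, 300)))
    cov_a += 0.1 * np.eye(n_channels)
    cov_b = np.cov(rng.standard_normal((n_channels, 300)))
    cov_b += 0.1 * np.eye(n_channels)
    eps = []
    for label, cov, offset in (("left", cov_a, 0), (NC, cov_b, 100)):
        root = scipy.linalg.sqrtm(cov).real
        for i in range(n_epochs):
            q = scipy.linalg.qr(
                rng.standard_normal((n_samples, n_channels)),
                mode="economic")[0].T
            eps.append(Epoch(root @ q, label, (0.0, n_samples / 250.0),
                             offset + i))
    return EpochSet(eps, 250.0), cov_a, cov_b
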