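"""Broadband filtering, one-vs-rest common spatial patterns, sub-bands.

CSP finds spatial filters w maximising the variance ratio
w' C_target w / w' (C_target + C_rest) w between a target class and the rest.
Solving the generalized eigenproblem C_target v = lambda (C_target + C_rest) v
yields filters whitened against the composite covariance; eigenvalues near 1
mark projections where the target class carries most of the variance.  One
projection matrix is fitted per class (NC and the four imagery classes) and
only the leading ``n_keep`` rows of each are used downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.signal

from .io import ALL_CLASSES, Epoch, EpochSet, RawSession

DEFAULT_BANDS = ((8.0, 12.0), (12.0, 20.0), (20.0, 30.0))


@dataclass
class FilterSpec:
    kind: str                  # "bandpass" | "notch"
    band: tuple                # (low, high) Hz, or (center,) for notch
    order: int = 4
    zero_phase: bool = True

    def __post_init__(self):
        if self.kind == "bandpass" and not 0 < self.band[0] < self.band[1]:
            raise ValueError(f"bad bandpass spec {self.band}")


def _bandpass_sos(band, fs, order):
    if band[1] >= fs / 2:
        raise ValueError(f"band {band} reaches Nyquist for fs={fs}")
    return scipy.signal.butter(order, band, btype="bandpass", fs=fs,
                               output="sos")


def bandpass(x, band, fs, order=4, axis=-1):
    """Zero-phase Butterworth band-pass (forward-backward)."""
    return scipy.signal.sosfiltfilt(_bandpass_sos(band, fs, order), x,
                                    axis=axis)


def prefilter(session: RawSession, band=(1.0, 50.0), order: int = 10,
              notch: float = 50.0, notch_q: float = 30.0) -> RawSession:
    """Band-limit a session to 1-50 Hz and notch out the 50 Hz mains line.

    Both stages are applied forward-backward, so the output has no group
    delay.  Raises if the sampling rate cannot represent the notch.
    """
    fs = session.sfreq
    if fs <= 2 * notch:
        raise ValueError(f"fs={fs} too low for a {notch} Hz notch")
    sig = bandpass(session.signal, band, fs, order=order)
    b, a = scipy.signal.iirnotch(notch, notch_q, fs=fs)
    sig = scipy.signal.filtfilt(b, a, sig, axis=-1)
    return RawSession(signal=sig, sfreq=fs,
                      channel_names=list(session.channel_names),
                      events=list(session.events),
                      subject_id=session.subject_id)


# ---------------------------------------------------------------------------
# CSP


@dataclass
class CSPModel:
    """Per-class spatial projection matrices with eigenvalue ordering.

    ``filters[c]`` is (n_channels x n_channels); rows are sorted by the
    descending eigenvalue of class ``c`` against the composite covariance,
    so the first ``n_keep`` rows are the most target-class-specific
    projections.  Whitening holds per class: W Sigma_composite W' = I.
    """

    filters: dict                 # class -> (ch, ch), rows = spatial filters
    eigenvalues: dict             # class -> (ch,), descending
    classes: tuple
    n_keep: int = 5

    @property
    def n_channels(self) -> int:
        return next(iter(self.filters.values())).shape[1]

    def stacked_filters(self) -> np.ndarray:
        """(n_classes, n_keep, n_channels) array of the kept filter rows."""
        return np.stack([self.filters[c][: self.n_keep] for c in self.classes])

    def patterns(self, cls) -> np.ndarray:
        """Spatial patterns of class ``cls``: column j is the scalp
        topography whose activity filter row j extracts (the inverse of the
        filter matrix; patterns, not filters, are comparable to physical
        source topographies)."""
        return np.linalg.inv(self.filters[cls])

    def save(self, path) -> None:
        np.savez(path,
                 classes=np.array(self.classes), n_keep=self.n_keep,
                 **{f"W_{c}": self.filters[c] for c in self.classes},
                 **{f"eig_{c}": self.eigenvalues[c] for c in self.classes})

    @classmethod
    def load(cls, path) -> "CSPModel":
        z = np.load(path, allow_pickle=False)
        classes = tuple(str(c) for c in z["classes"])
        return cls(filters={c: z[f"W_{c}"] for c in classes},
                   eigenvalues={c: z[f"eig_{c}"] for c in classes},
                   classes=classes, n_keep=int(z["n_keep"]))


def _normalized_cov(segment: np.ndarray) -> np.ndarray:
    c = segment @ segment.T
    tr = np.trace(c)
    if tr <= 0:
        return np.eye(segment.shape[0])
    return c / tr


def _mean_cov(segments) -> np.ndarray:
    return np.mean([_normalized_cov(s) for s in segments], axis=0)


def _shrink(cov: np.ndarray, gamma: float) -> np.ndarray:
    ch = cov.shape[0]
    return (1 - gamma) * cov + gamma * (np.trace(cov) / ch) * np.eye(ch)


def fit_csp_ovr(train: EpochSet, n_keep: int = 5,
                shrinkage: float = 1e-5, classes=None) -> CSPModel:
    """Fit one-vs-rest CSP for every class present in ``train``.

    Per-epoch covariances are trace-normalized (epochs of different lengths
    contribute equally) and averaged within the target class and within the
    union of all other classes.  Rank-deficient covariances get shrinkage
    regularization toward a scaled identity.
    """
    if classes is None:
        classes = tuple(c for c in ALL_CLASSES if c in set(train.labels))
    labels = train.labels
    n_ch = train.epochs[0].segment.shape[0]
    if n_ch < n_keep:
        raise ValueError(f"n_keep={n_keep} exceeds {n_ch} channels")
    covs = np.array([_normalized_cov(e.segment) for e in train.epochs])
    filters, eigs = {}, {}
    for cls in classes:
        m = labels == cls
        if m.sum() < 2 or (~m).sum() < 2:
            raise ValueError(f"need >=2 epochs per side for class {cls!r}")
        target = _shrink(covs[m].mean(axis=0), shrinkage)
        rest = _shrink(covs[~m].mean(axis=0), shrinkage)
        composite = target + rest
        try:
            w, v = scipy.linalg.eigh(target, composite)
        except scipy.linalg.LinAlgError:
            warnings.warn(f"rank-deficient covariance for class {cls!r}; "
                          "raising shrinkage to 1e-3")
            target = _shrink(target, 1e-3)
            composite = target + _shrink(rest, 1e-3)
            w, v = scipy.linalg.eigh(target, composite)
        order = np.argsort(w)[::-1]
        filters[cls] = v[:, order].T        # rows = filters, desc eigenvalue
        eigs[cls] = w[order]
    return CSPModel(filters=filters, eigenvalues=eigs,
                    classes=tuple(classes), n_keep=n_keep)


def apply_csp(model: CSPModel, epoch: Epoch) -> np.ndarray:
    """Project one epoch: (n_classes, n_keep, n_samples) series."""
    seg = epoch.segment if isinstance(epoch, Epoch) else np.asarray(epoch)
    if seg.shape[0] != model.n_channels:
        raise ValueError(f"epoch has {seg.shape[0]} channels, "
                         f"model expects {model.n_channels}")
    return np.einsum("ckj,jt->ckt", model.stacked_filters(), seg)


def subband_filter(projections: np.ndarray, fs: float,
                   bands=DEFAULT_BANDS, order: int = 4) -> np.ndarray:
    """Band-filter projected series into the mu/low-beta/high-beta bands.

    Input (..., n_samples); output (..., n_bands, n_samples), zero phase.
    """
    for band in bands:
        if not 0 < band[0] < band[1] < fs / 2:
            raise ValueError(f"invalid band {band} for fs={fs}")
    out = np.stack([bandpass(projections, band, fs, order=order)
                    for band in bands], axis=-2)
    return out
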