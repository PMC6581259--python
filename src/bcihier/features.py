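"""Per-projection signal features and the 525-column instance matrix.

Seven time-domain statistics are computed for every (class, projection, band)
series: minimum, maximum and mean voltage, voltage range, average signal
power, rate of zero-voltage crossings and rate of non-negative samples.
With 5 classes x 5 projections x 3 bands that makes 5*5*3*7 = 525 features
per epoch, in a fixed lexicographic column order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import EpochSet
from .preprocessing import DEFAULT_BANDS, CSPModel, bandpass

FEATURE_NAMES = ("v_min", "v_max", "v_mean", "v_range",
                 "p_signal", "r_zero_cross", "r_positive")


def extract_features(series: np.ndarray, axis: int = -1) -> np.ndarray:
    """The 7 statistics of one (or a stack of) series, along ``axis``.

    sign(0) is treated as positive, consistently for both the zero-crossing
    rate and the non-negative-sample rate.
    """
    x = np.asarray(series, dtype=float)
    n = x.shape[axis]
    if n < 2:
        raise ValueError("need at least 2 samples (zero-crossing rate)")
    x = np.moveaxis(x, axis, -1)
    sgn = np.where(x >= 0, 1, -1)
    feats = np.stack([
        x.min(axis=-1),
        x.max(axis=-1),
        x.mean(axis=-1),
        x.max(axis=-1) - x.min(axis=-1),
        np.mean(x ** 2, axis=-1),
        np.mean(sgn[..., 1:] != sgn[..., :-1], axis=-1),  # 1/(N-1) * count
        np.mean(x >= 0, axis=-1),
    ], axis=-1)
    return feats


def feature_columns(classes, n_keep: int = 5, bands=DEFAULT_BANDS) -> list:
    """Column names in the fixed (class, projection, band, feature) order."""
    return [f"{c}/p{k + 1}/{int(b[0])}-{int(b[1])}/{f}"
            for c in classes
            for k in range(n_keep)
            for b in bands
            for f in FEATURE_NAMES]


@dataclass
class FeatureMatrix:
    """Instances x named-features matrix with per-row labels."""

    values: np.ndarray            # (n, d)
    columns: list
    labels: np.ndarray            # (n,) str
    trial_ids: np.ndarray = None  # (n,) int, optional

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[1] != len(self.columns):
            raise ValueError("column count mismatch")
        if self.values.shape[0] != len(self.labels):
            raise ValueError("label count mismatch")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def __len__(self):
        return self.values.shape[0]

    def rows(self, mask) -> "FeatureMatrix":
        mask = np.asarray(mask)
        return FeatureMatrix(self.values[mask], list(self.columns),
                             self.labels[mask],
                             None if self.trial_ids is None
                             else self.trial_ids[mask])

    def select_columns(self, indices) -> "FeatureMatrix":
        idx = np.asarray(indices, dtype=int)
        return FeatureMatrix(self.values[:, idx],
                             [self.columns[i] for i in idx],
                             self.labels, self.trial_ids)

    @staticmethod
    def concat(parts) -> "FeatureMatrix":
        cols = parts[0].columns
        for p in parts[1:]:
            if list(p.columns) != list(cols):
                raise ValueError("column mismatch in concat")
        tids = None
        if all(p.trial_ids is not None for p in parts):
            tids = np.concatenate([p.trial_ids for p in parts])
        return FeatureMatrix(np.vstack([p.values for p in parts]),
                             list(cols),
                             np.concatenate([p.labels for p in parts]), tids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.columns))
        df.insert(0, "label", self.labels)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        labels = df.pop("label").to_numpy()
        return cls(df.to_numpy(float), list(df.columns), labels)


def assemble_matrix(model: CSPModel, epochs: EpochSet,
                    bands=DEFAULT_BANDS, band_order: int = 4) -> FeatureMatrix:
    """Project, sub-band filter and featurise a whole epoch set.

    Epochs are grouped by length (IC and NC windows differ) so filtering and
    the statistics run vectorised; the row order follows ``epochs``.
    """
    n = len(epochs)
    if n == 0:
        raise ValueError("empty epoch set")
    cols = feature_columns(model.classes, model.n_keep, bands)
    out = np.empty((n, len(cols)))
    W = model.stacked_filters()           # (C, K, ch)
    lengths = np.array([e.n_samples for e in epochs])
    for L in np.unique(lengths):
        idx = np.nonzero(lengths == L)[0]
        seg = np.stack([epochs.epochs[i].segment for i in idx])  # (m, ch, L)
        if seg.shape[1] != model.n_channels:
            raise ValueError("epoch channel count does not match CSP model")
        proj = np.einsum("ckj,mjt->mckt", W, seg)                # (m, C, K, L)
        banded = np.stack([bandpass(proj, b, epochs.sfreq, order=band_order)
                           for b in bands], axis=-2)             # (m,C,K,B,L)
        out[idx] = extract_features(banded).reshape(len(idx), -1)
    return FeatureMatrix(out, cols, epochs.labels, epochs.trial_ids)
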