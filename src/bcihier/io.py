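"""Session I/O, epoch extraction and run partitioning.

A *session* is a continuous multichannel EEG recording with per-trial cue
annotations.  Trials follow a fixed template: the subject rests during the
first two seconds (non-intentional control, NC), a cue appears at t = 3 s and
motor imagery is sustained from t = 4 s to t = 7 s (intentional control, IC).
Epochs are cut from these two windows; each run of the evaluation protocol
partitions them into two training sets and a test set with the layout
(per IC class: one third to each set; NC: half to TrainingSet1, half to the
test set).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NC = "nc"
IC_CLASSES = ("left", "right", "tongue", "foot")
ALL_CLASSES = (NC,) + IC_CLASSES

#: BCI-competition-III style GDF annotation codes for the four imagery cues.
GDF_EVENT_MAP = {"769": "left", "770": "right", "771": "foot", "772": "tongue"}


class FormatError(ValueError):
    """The file is not in a recognised session format."""


class AnnotationError(ValueError):
    """The file carries no usable trial annotations."""


class PartitionError(ValueError):
    """The epochs cannot be partitioned with the requested layout."""


@dataclass
class RawSession:
    """Continuous EEG recording in microvolts.

    Parameters
    ----------
    signal : ndarray, shape (n_channels, n_samples)
    sfreq : float
        Sampling rate in Hz (250 for the supported competition recordings).
    channel_names : list of str
    events : list of (int, str)
        ``(onset_sample, trial_class)`` pairs, one per trial, sorted by onset.
    subject_id : str
    """

    signal: np.ndarray
    sfreq: float
    channel_names: list
    events: list
    subject_id: str = ""

    def __post_init__(self):
        self.signal = np.asarray(self.signal)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels x samples)")
        if self.signal.shape[0] < 2:
            raise ValueError("a session needs at least 2 channels")
        if not self.sfreq > 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_names) != self.signal.shape[0]:
            raise ValueError("channel_names length does not match signal")
        self.events = sorted(((int(o), str(c)) for o, c in self.events),
                             key=lambda e: e[0])

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


@dataclass
class Epoch:
    """A fixed-length labelled segment cut from one trial."""

    segment: np.ndarray          # (n_channels, n_samples)
    label: str                   # one of ALL_CLASSES
    window: tuple                # (start_s, end_s) relative to trial onset
    trial_id: int

    @property
    def n_samples(self) -> int:
        return self.segment.shape[1]


@dataclass
class EpochSet:
    """Ordered collection of epochs sharing a sampling rate."""

    epochs: list
    sfreq: float

    def __len__(self):
        return len(self.epochs)

    def __iter__(self):
        return iter(self.epochs)

    @property
    def labels(self) -> np.ndarray:
        return np.array([e.label for e in self.epochs])

    @property
    def trial_ids(self) -> np.ndarray:
        return np.array([e.trial_id for e in self.epochs])

    @property
    def class_counts(self) -> dict:
        out: dict = {}
        for e in self.epochs:
            out[e.label] = out.get(e.label, 0) + 1
        return out

    def subset(self, trial_ids, ic_only: bool = False) -> "EpochSet":
        wanted = set(int(t) for t in trial_ids)
        eps = [e for e in self.epochs
               if e.trial_id in wanted and not (ic_only and e.label == NC)]
        return EpochSet(eps, self.sfreq)

    def to_frame(self) -> pd.DataFrame:
        """Tabular index of the epochs (one row per epoch)."""
        return pd.DataFrame(
            {"trial_id": [e.trial_id for e in self.epochs],
             "label": [e.label for e in self.epochs],
             "start_s": [e.window[0] for e in self.epochs],
             "end_s": [e.window[1] for e in self.epochs],
             "n_samples": [e.n_samples for e in self.epochs]})


@dataclass
class RunSplit:
    """One random partition: level-1 training, level-2 training, test."""

    training_set_1: EpochSet     # IC + NC
    training_set_2: EpochSet     # IC only
    test_set: EpochSet           # IC + NC
    run_index: int = 0
    seed: int = 0

    def training_epochs(self) -> EpochSet:
        """Union of both training sets (used to fit CSP / feature selection)."""
        return EpochSet(list(self.training_set_1.epochs)
                        + list(self.training_set_2.epochs),
                        self.training_set_1.sfreq)


# ---------------------------------------------------------------------------
# session loading / saving


def load_session(path, fmt: str = None, event_map: dict = None) -> RawSession:
    """Load a session from a GDF file or the HDF5 matrix container.

    ``fmt`` is inferred from the extension when not given ("gdf" or
    "container").  GDF annotation codes are translated to class labels with
    ``event_map`` (default :data:`GDF_EVENT_MAP`); unmapped codes are ignored.
    """
    path = str(path)
    if fmt is None:
        low = path.lower()
        if low.endswith(".gdf"):
            fmt = "gdf"
        elif low.endswith((".h5", ".hdf5", ".hdf")):
            fmt = "container"
        else:
            raise FormatError(f"cannot infer session format from {path!r}")
    if fmt == "container":
        return _load_container(path)
    if fmt == "gdf":
        return _load_gdf(path, event_map or GDF_EVENT_MAP)
    raise FormatError(f"unknown session format {fmt!r}")


def _load_container(path) -> RawSession:
    with h5py.File(path, "r") as f:
        if "signal" not in f:
            raise FormatError(f"{path}: no 'signal' dataset")
        signal = f["signal"][()]
        if "events" not in f or f["events"].shape[0] == 0:
            raise AnnotationError(f"{path}: no trial annotations")
        onsets = f["events"]["onset"][()]
        labels = [lab.decode() if isinstance(lab, bytes) else str(lab)
                  for lab in f["events"]["label"][()]]
        names = [n.decode() if isinstance(n, bytes) else str(n)
                 for n in f["channel_names"][()]]
        return RawSession(signal=signal, sfreq=float(f.attrs["sfreq"]),
                          channel_names=names,
                          events=list(zip(onsets, labels)),
                          subject_id=str(f.attrs.get("subject_id", "")))


def _load_gdf(path, event_map) -> RawSession:
    import mne

    raw = mne.io.read_raw_gdf(path, preload=True, verbose="error")
    signal = raw.get_data() * 1e6  # volts -> microvolts
    ann = raw.annotations
    events = []
    for onset, desc in zip(ann.onset, ann.description):
        key = str(desc)
        if key in event_map:
            events.append((int(round(onset * raw.info["sfreq"])),
                           event_map[key]))
    if not events:
        raise AnnotationError(f"{path}: no mappable trial annotations")
    return RawSession(signal=signal, sfreq=float(raw.info["sfreq"]),
                      channel_names=list(raw.ch_names), events=events,
                      subject_id="")


def save_session(session: RawSession, path) -> None:
    """Write a session to the HDF5 matrix container."""
    ev = np.array([(o, c.encode()) for o, c in session.events],
                  dtype=[("onset", "i8"), ("label", "S16")])
    with h5py.File(path, "w") as f:
        f.create_dataset("signal", data=session.signal)
        f.create_dataset("events", data=ev)
        f.create_dataset(
            "channel_names",
            data=np.array([n.encode() for n in session.channel_names]))
        f.attrs["sfreq"] = session.sfreq
        f.attrs["subject_id"] = session.subject_id


# ---------------------------------------------------------------------------
# epoch extraction


def _window_slice(onset: int, window, sfreq: float):
    # half-open [start, end) in seconds, sample index = floor(t * fs), 0-based
    lo = onset + int(np.floor(window[0] * sfreq))
    hi = onset + int(np.floor(window[1] * sfreq))
    return lo, hi


def extract_epochs(session: RawSession, ic_window=(4.0, 7.0),
                   nc_window=(0.0, 2.0), nc_fraction: float = 2.0 / 3.0,
                   seed: int = 0) -> EpochSet:
    """Cut one IC epoch per trial and one NC epoch for a subset of trials.

    NC donor trials are drawn per class (exactly ``round(nc_fraction * n)``
    of each class's trials, seeded) so the downstream run partition can place
    every NC epoch without splitting a trial across train and test.
    """
    if not 0 < nc_fraction <= 1:
        raise ValueError("nc_fraction must be in (0, 1]")
    for w in (ic_window, nc_window):
        if not w[0] < w[1]:
            raise ValueError(f"bad window {w}")
    rng = np.random.default_rng(seed)
    sf = session.sfreq

    by_class: dict = {}
    for tid, (onset, cls) in enumerate(session.events):
        by_class.setdefault(cls, []).append(tid)
    donors = set()
    for cls in sorted(by_class):
        tids = by_class[cls]
        n_d = int(round(nc_fraction * len(tids)))
        donors.update(rng.choice(tids, size=n_d, replace=False).tolist())

    epochs = []
    for tid, (onset, cls) in enumerate(session.events):
        lo, hi = _window_slice(onset, ic_window, sf)
        if hi > session.n_samples or lo < 0:
            raise ValueError(
                f"trial {tid}: IC window {ic_window} exceeds the recording")
        epochs.append(Epoch(session.signal[:, lo:hi], cls,
                            tuple(ic_window), tid))
        if tid in donors:
            lo, hi = _window_slice(onset, nc_window, sf)
            if hi > session.n_samples or lo < 0:
                raise ValueError(
                    f"trial {tid}: NC window {nc_window} exceeds the recording")
            epochs.append(Epoch(session.signal[:, lo:hi], NC,
                                tuple(nc_window), tid))
    return EpochSet(epochs, sf)


# ---------------------------------------------------------------------------
# run partitioning


def partition_runs(epochs: EpochSet, n_runs: int = 5,
                   seed: int = 0) -> list:
    """Build ``n_runs`` independent random train1/train2/test partitions.

    Per IC class, trials are split into equal thirds across the three sets;
    NC epochs go half to TrainingSet1 and half to the test set.  Trials are
    assigned as wholes, so an IC epoch and the NC epoch cut from the same
    trial never straddle a train/test boundary.  At most 2 trials per class
    (and any NC epoch that cannot be placed) are dropped, with a log record,
    when counts do not divide evenly.
    """
    labels = epochs.labels
    ic_trials: dict = {}
    donor_trials = set(int(t) for t, l in zip(epochs.trial_ids, labels)
                       if l == NC)
    for e in epochs.epochs:
        if e.label != NC:
            ic_trials.setdefault(e.label, []).append(e.trial_id)
    if not ic_trials:
        raise PartitionError("no IC epochs to partition")
    for cls, tids in ic_trials.items():
        if len(tids) == 0:
            raise PartitionError(f"empty class {cls}")

    splits = []
    for run in range(n_runs):
        rng = np.random.default_rng(np.random.SeedSequence([seed, run]))
        t1, t2, te = [], [], []
        for cls in sorted(ic_trials):
            tids = list(ic_trials[cls])
            rng.shuffle(tids)
            n_drop = len(tids) % 3
            if n_drop:
                logger.info("run %d class %s: dropping %d trial(s) for "
                            "divisibility", run, cls, n_drop)
                tids = tids[:-n_drop]
            third = len(tids) // 3
            d = [t for t in tids if t in donor_trials]
            nd = [t for t in tids if t not in donor_trials]
            half = min(len(d) // 2, third)
            t1_cls = d[:half]
            te_cls = d[half:2 * half]
            # non-donors fill remaining slots first; leftover donors sink to
            # TrainingSet2 (their NC epoch is dropped) so NC stays 50/50
            pool = nd + d[2 * half:]
            t1_cls += pool[:third - half]
            pool = pool[third - half:]
            te_cls += pool[:third - half]
            pool = pool[third - half:]
            t2_cls = pool[:third]
            t1 += t1_cls
            te += te_cls
            t2 += t2_cls
        ts1 = epochs.subset(t1)
        ts2 = epochs.subset(t2, ic_only=True)
        n_lost = len(epochs.subset(t2)) - len(ts2)
        if n_lost:
            logger.info("run %d: %d NC epoch(s) of TrainingSet2 trials "
                        "dropped", run, n_lost)
        splits.append(RunSplit(ts1, ts2, epochs.subset(te),
                               run_index=run, seed=seed))
    return splits
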