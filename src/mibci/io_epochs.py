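"""Epoched-trial container and on-disk fixture formats.

The universal input to every stage of the package is a set of epoched,
labeled EEG trials: a stack of ``n_trials`` matrices of identical shape
``n_channels x n_samples`` plus a class label (1 or 2) per trial.

Two plain-text formats are supported:

``fixture``
    A single JSON file holding a manifest (labels, shapes, sampling rate,
    channel names) together with the trial matrices as nested lists.
    Doubles round-trip exactly through ``json``, so write/read is an
    identity, and writing the same object twice produces identical bytes.

``delimited``
    A directory with a ``manifest.json`` and one tab-separated matrix file
    per trial (rows = channels), for interop with tools that cannot parse
    the single-file fixture.

Neither format depends on any ecosystem-specific serialization; converting
BCI-competition ``.mat`` distributions into either format is left to
external tooling and documented in the README.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ParseError, ValidationError

FIXTURE_FORMAT = "mibci-epoched-trials"
DELIMITED_FORMAT = "mibci-epoched-trials-delimited"
FORMAT_VERSION = 1

VALID_LABELS = (1, 2)


@dataclass(frozen=True)
class EpochedTrials:
    """Labeled collection of multichannel trials.

    Parameters
    ----------
    data
        Array of shape ``(n_trials, n_channels, n_samples)``.
    labels
        Integer class labels in ``{1, 2}``, one per trial.
    channel_names
        Optional channel names, length ``n_channels``.
    sampling_rate_hz
        Sampling rate metadata (not used by any computation).
    """

    data: np.ndarray
    labels: np.ndarray
    channel_names: tuple[str, ...] | None = None
    sampling_rate_hz: float = 100.0

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "labels", labels)
        if data.ndim != 3:
            raise ValidationError(
                f"trial data must be 3-D (trials, channels, samples); got shape {data.shape}"
            )
        n, N, T = data.shape
        if n < 1:
            raise ValidationError("at least one trial is required")
        if N < 1 or T < 2:
            raise ValidationError(
                f"each trial needs >=1 channel and >=2 samples; got {N} x {T}"
            )
        if labels.shape != (n,):
            raise ValidationError(
                f"labels must have length {n}; got shape {labels.shape}"
            )
        bad = set(np.unique(labels)) - set(VALID_LABELS)
        if bad:
            raise ValidationError(f"labels must be in {{1, 2}}; found {sorted(bad)}")
        if not np.all(np.isfinite(data)):
            raise ValidationError("trial data contains non-finite values")
        if self.channel_names is not None:
            names = tuple(str(c) for c in self.channel_names)
            object.__setattr__(self, "channel_names", names)
            if len(names) != N:
                raise ValidationError(
                    f"{len(names)} channel names for {N} channels"
                )
        if not self.sampling_rate_hz > 0:
            raise ValidationError("sampling_rate_hz must be positive")

    # -- basic accessors -------------------------------------------------

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def class_data(self, label: int) -> np.ndarray:
        """All trials with the given label, shape (k, N, T)."""
        return self.data[self.labels == label]

    def subset(self, indices: Sequence[int]) -> "EpochedTrials":
        """New container restricted to the given trial indices (order kept)."""
        idx = np.asarray(indices, dtype=int)
        return EpochedTrials(
            data=self.data[idx],
            labels=self.labels[idx],
            channel_names=self.channel_names,
            sampling_rate_hz=self.sampling_rate_hz,
        )

    def __len__(self) -> int:
        return self.n_trials


def select_channels(
    trials: EpochedTrials, names_or_indices: Sequence[str | int]
) -> EpochedTrials:
    """Restrict trials to a subset of channels, in the requested order.

    Channels may be addressed by integer index or, when the container
    carries channel names, by name (e.g. ``["C3", "C4"]``).  Requesting the
    same channel twice duplicates the row and emits a warning.
    """
    if len(names_or_indices) == 0:
        raise ValidationError("at least one channel must be selected")
    idx: list[int] = []
    for item in names_or_indices:
        if isinstance(item, (int, np.integer)):
            i = int(item)
            if not 0 <= i < trials.n_channels:
                raise LookupError(
                    f"channel index {i} out of range for {trials.n_channels} channels"
                )
            idx.append(i)
        else:
            if trials.channel_names is None:
                raise LookupError(
                    "trials carry no channel names; select channels by index"
                )
            try:
                idx.append(trials.channel_names.index(str(item)))
            except ValueError:
                raise LookupError(
                    f"unknown channel {item!r}; available: "
                    f"{list(trials.channel_names)}"
                ) from None
    if len(set(idx)) < len(idx):
        warnings.warn("duplicate channels requested; rows will repeat", stacklevel=2)
    names = (
        tuple(trials.channel_names[i] for i in idx)
        if trials.channel_names is not None
        else None
    )
    return EpochedTrials(
        data=trials.data[:, idx, :],
        labels=trials.labels,
        channel_names=names,
        sampling_rate_hz=trials.sampling_rate_hz,
    )


# -- serialization -------------------------------------------------------


def _manifest(trials: EpochedTrials) -> dict:
    return {
        "version": FORMAT_VERSION,
        "n_trials": trials.n_trials,
        "n_channels": trials.n_channels,
        "n_samples": trials.n_samples,
        "sampling_rate_hz": trials.sampling_rate_hz,
        "channel_names": list(trials.channel_names)
        if trials.channel_names is not None
        else None,
        "labels": [int(v) for v in trials.labels],
    }


def write_trials(
    trials: EpochedTrials, path: str | Path, format: str = "fixture"
) -> Path:
    """Write trials to ``path`` in the requested format; returns the path.

    ``fixture`` writes a single JSON file; ``delimited`` writes a directory
    of TSV matrices plus a manifest.  Output is deterministic: the same
    container always produces byte-identical files.
    """
    path = Path(path)
    if format == "fixture":
        doc = {"format": FIXTURE_FORMAT, **_manifest(trials)}
        doc["trials"] = [t.tolist() for t in trials.data]
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(doc, fh, separators=(",", ":"))
            fh.write("\n")
        return path
    if format == "delimited":
        path.mkdir(parents=True, exist_ok=True)
        trial_files = [f"trial_{i:04d}.tsv" for i in range(trials.n_trials)]
        doc = {"format": DELIMITED_FORMAT, **_manifest(trials), "trials": trial_files}
        with open(path / "manifest.json", "w") as fh:
            json.dump(doc, fh, indent=2)
            fh.write("\n")
        for fname, mat in zip(trial_files, trials.data):
            np.savetxt(path / fname, mat, fmt="%.17g", delimiter="\t")
        return path
    raise ValidationError(f"unknown format {format!r}; expected 'fixture' or 'delimited'")


def _check_trial_shape(mat: np.ndarray, expected: tuple[int, int], index: int):
    if mat.ndim != 2 or mat.shape != expected:
        raise ParseError(
            f"trial {index + 1} has shape {mat.shape}; expected {expected}"
        )


def read_trials(path: str | Path, format: str = "fixture") -> EpochedTrials:
    """Read trials written by :func:`write_trials`.

    Raises :class:`~mibci.errors.ParseError` naming the offending trial
    (1-based) when shapes are inconsistent or labels unknown.
    """
    path = Path(path)
    if format == "fixture":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("format") != FIXTURE_FORMAT:
            raise ParseError(f"{path} is not a {FIXTURE_FORMAT} file")
        mats = [np.asarray(t, dtype=float) for t in doc["trials"]]
    elif format == "delimited":
        with open(path / "manifest.json") as fh:
            doc = json.load(fh)
        if doc.get("format") != DELIMITED_FORMAT:
            raise ParseError(f"{path} is not a {DELIMITED_FORMAT} directory")
        mats = [
            np.atleast_2d(np.loadtxt(path / fname, delimiter="\t"))
            for fname in doc["trials"]
        ]
    else:
        raise ValidationError(
            f"unknown format {format!r}; expected 'fixture' or 'delimited'"
        )

    if len(mats) == 0:
        raise ParseError(f"{path} contains no trials")
    expected = (int(doc["n_channels"]), int(doc["n_samples"]))
    for i, mat in enumerate(mats):
        _check_trial_shape(mat, expected, i)
    labels = doc["labels"]
    for i, lab in enumerate(labels):
        if lab not in VALID_LABELS:
            raise ParseError(f"trial {i + 1} has unknown label {lab!r}")
    names = doc.get("channel_names")
    try:
        return EpochedTrials(
            data=np.stack(mats),
            labels=np.asarray(labels, dtype=int),
            channel_names=tuple(names) if names is not None else None,
            sampling_rate_hz=float(doc["sampling_rate_hz"]),
        )
    except ValidationError as exc:
        raise ParseError(str(exc)) from exc
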