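"""In-memory and on-disk containers for epoched EEG and behavioral error tables.

The two units of analysis are:

* an *error table* — one row per retrieval trial with the signed angular
  error (degrees, in (-180, 180]) between the responded and the studied
  location on the circle; represented as a plain :class:`pandas.DataFrame`
  with columns ``participant, trial, error_deg, rt_ms``;
* an :class:`EpochSet` — stimulus-locked single-trial epochs
  (trials x channels x samples, microvolts) with their sampling rate, epoch
  start time and per-trial metadata.

On disk an :class:`EpochSet` is a directory holding ``data.npy``, a
``trials.csv`` metadata sidecar and a ``header.json`` (sampling rate, epoch
start, channel names).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EpochSet",
    "ERROR_TABLE_COLUMNS",
    "read_error_table",
    "write_error_table",
    "validate_error_table",
    "wrap_degrees",
]

ERROR_TABLE_COLUMNS = ("participant", "trial", "error_deg", "rt_ms")


def wrap_degrees(theta):
    """Wrap angles (degrees) into the half-open interval (-180, 180]."""
    theta = np.asarray(theta, dtype=float)
    wrapped = 180.0 - np.mod(180.0 - theta, 360.0)
    return wrapped if wrapped.ndim else float(wrapped)


def validate_error_table(errors: pd.DataFrame, wrap: bool = True) -> pd.DataFrame:
    """Check (and optionally wrap) an error table.

    Angles outside (-180, 180] are wrapped back onto the circle with a
    warning; missing error values are rejected.
    """
    missing = [c for c in ("participant", "trial", "error_deg") if c not in errors.columns]
    if missing:
        raise ValueError(f"error table missing required columns: {missing}")
    if errors["error_deg"].isna().any():
        raise ValueError("error table contains missing error_deg values")
    err = errors["error_deg"].to_numpy(dtype=float)
    outside = (err <= -180.0) | (err > 180.0)
    if outside.any():
        if not wrap:
            raise ValueError("error_deg outside (-180, 180]")
        import warnings

        warnings.warn(
            f"{int(outside.sum())} error_deg values outside (-180, 180] were wrapped",
            stacklevel=2,
        )
        errors = errors.copy()
        errors["error_deg"] = wrap_degrees(err)
    return errors


def read_error_table(path) -> pd.DataFrame:
    return validate_error_table(pd.read_csv(path))


def write_error_table(errors: pd.DataFrame, path) -> None:
    cols = [c for c in ERROR_TABLE_COLUMNS if c in errors.columns]
    errors.loc[:, cols].to_csv(path, index=False)


@dataclass
class EpochSet:
    """Epoched single-trial EEG data.

    Parameters
    ----------
    data:
        Array of shape ``(n_trials, n_channels, n_samples)`` in microvolts.
    sfreq:
        Sampling rate in Hz.
    tmin_ms:
        Time of the first sample relative to stimulus onset, in ms. Must
        place 0 ms exactly on a sample.
    channel_names:
        Unique channel labels (10/20 style, e.g. ``CP3``, ``P4``).
    trial_meta:
        One row per trial; typically ``participant, trial, error_deg, rt_ms``
        plus any derived columns (``bin`` labels and so on).
    """

    data: np.ndarray
    sfreq: float
    tmin_ms: float
    channel_names: list[str]
    trial_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_channels, n_samples)")
        n_trials, n_channels, _ = self.data.shape
        self.channel_names = list(self.channel_names)
        if len(self.channel_names) != n_channels:
            raise ValueError("channel_names length does not match data")
        if len(set(self.channel_names)) != n_channels:
            raise ValueError("channel_names must be unique")
        if self.trial_meta is None:
            self.trial_meta = pd.DataFrame({"trial": np.arange(n_trials)})
        if len(self.trial_meta) != n_trials:
            raise ValueError("trial_meta length does not match data")
        self.trial_meta = self.trial_meta.reset_index(drop=True)
        step = 1000.0 / self.sfreq
        if abs(round(self.tmin_ms / step) * step - self.tmin_ms) > 1e-9:
            raise ValueError("0 ms must fall exactly on a sample")

    # ------------------------------------------------------------------ #
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
    def times_ms(self) -> np.ndarray:
        return self.tmin_ms + np.arange(self.n_samples) * 1000.0 / self.sfreq

    def time_index(self, t_ms: float) -> int:
        """Index of the sample at time ``t_ms`` (must lie on a sample)."""
        idx = (t_ms - self.tmin_ms) * self.sfreq / 1000.0
        j = int(round(idx))
        if abs(idx - j) > 1e-6 or not 0 <= j < self.n_samples:
            raise ValueError(f"{t_ms} ms does not fall on a sample of this epoch")
        return j

    def window_slice(self, start_ms: float, end_ms: float) -> slice:
        """Inclusive sample slice covering [start_ms, end_ms]."""
        return slice(self.time_index(start_ms), self.time_index(end_ms) + 1)

    def channel_indices(self, names: Sequence[str]) -> np.ndarray:
        lut = {c: i for i, c in enumerate(self.channel_names)}
        try:
            return np.array([lut[n] for n in names], dtype=int)
        except KeyError as exc:
            raise KeyError(f"channel {exc} not present in EpochSet") from exc

    def subset(self, index) -> "EpochSet":
        """New EpochSet restricted to the given trial indices / boolean mask."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return EpochSet(
            data=self.data[index],
            sfreq=self.sfreq,
            tmin_ms=self.tmin_ms,
            channel_names=list(self.channel_names),
            trial_meta=self.trial_meta.iloc[index].reset_index(drop=True),
        )

    def copy(self) -> "EpochSet":
        return EpochSet(
            data=self.data.copy(),
            sfreq=self.sfreq,
            tmin_ms=self.tmin_ms,
            channel_names=list(self.channel_names),
            trial_meta=self.trial_meta.copy(),
        )

    # ------------------------------------------------------------------ #
    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.save(directory / "data.npy", self.data)
        self.trial_meta.to_csv(directory / "trials.csv", index=False)
        header = {
            "sfreq": self.sfreq,
            "tmin_ms": self.tmin_ms,
            "channel_names": self.channel_names,
        }
        (directory / "header.json").write_text(json.dumps(header, indent=2))

    @classmethod
    def load(cls, directory) -> "EpochSet":
        directory = Path(directory)
        header = json.loads((directory / "header.json").read_text())
        return cls(
            data=np.load(directory / "data.npy"),
            sfreq=header["sfreq"],
            tmin_ms=header["tmin_ms"],
            channel_names=header["channel_names"],
            trial_meta=pd.read_csv(directory / "trials.csv"),
        )

    @classmethod
    def from_mne(cls, epochs, trial_meta: pd.DataFrame | None = None) -> "EpochSet":
        """Adapter from an :class:`mne.Epochs` (data converted to microvolts)."""
        data = epochs.get_data() * 1e6
        meta = trial_meta
        if meta is None and getattr(epochs, "metadata", None) is not None:
            meta = epochs.metadata.reset_index(drop=True)
        return cls(
            data=data,
            sfreq=float(epochs.info["sfreq"]),
            tmin_ms=float(epochs.tmin) * 1000.0,
            channel_names=list(epochs.ch_names),
            trial_meta=meta,
        )
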