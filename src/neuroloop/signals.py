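"""Uniformly sampled single-channel signals and their plain-text round-trip.

The on-disk format is deliberately minimal: two ``#``-prefixed header lines
(sampling rate and units, with optional channel metadata), then one sample
per line.  Spike-time lists are one float (seconds) per line.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SampledSignal",
    "read_signal",
    "write_signal",
    "read_spike_times",
    "write_spike_times",
]


@dataclass
class SampledSignal:
    """A uniformly sampled single-channel series.

    Parameters
    ----------
    samples:
        Real-valued sample array (1-D).
    fs:
        Sampling rate in Hz, strictly positive.
    channel_meta:
        Free-form channel metadata, e.g. trajectory label, recording depth in
        mm, hemisphere.
    """

    samples: np.ndarray
    fs: float
    channel_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.size < 2:
            raise ValueError("signal must contain at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("signal contains NaN or infinite samples")

    @property
    def duration(self) -> float:
        """Signal duration in seconds."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs

    def __len__(self) -> int:
        return self.samples.size


def write_signal(sig: SampledSignal, path) -> None:
    """Write a :class:`SampledSignal` as delimited text.

    Header: ``# fs=<Hz>`` then ``# units=<units> [key=value ...]``, followed by
    one sample per line.
    """
    units = sig.channel_meta.get("units", "a.u.")
    extra = " ".join(
        f"{k}={v}" for k, v in sig.channel_meta.items() if k != "units"
    )
    with open(path, "w") as fh:
        fh.write(f"# fs={sig.fs!r}\n")
        fh.write(f"# units={units}" + (f" {extra}" if extra else "") + "\n")
        np.savetxt(fh, sig.samples, fmt="%.12g")


def read_signal(path) -> SampledSignal:
    """Read a :class:`SampledSignal` written by :func:`write_signal`."""
    meta: dict = {}
    fs = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for token in line.lstrip("# ").split():
                if "=" in token:
                    key, _, val = token.partition("=")
                    if key == "fs":
                        fs = float(val)
                    else:
                        meta[key] = val
    if fs is None:
        raise ValueError(f"{path}: missing '# fs=' header line")
    samples = np.loadtxt(path, comments="#")
    return SampledSignal(samples=samples, fs=fs, channel_meta=meta)


def write_spike_times(spike_times, path) -> None:
    """Write spike times (seconds) one float per line."""
    np.savetxt(path, np.asarray(spike_times, dtype=float), fmt="%.9f")


def read_spike_times(path) -> np.ndarray:
    """Read spike times (seconds), one float per line."""
    times = np.atleast_1d(np.loadtxt(path, comments="#"))
    return times.astype(float)
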