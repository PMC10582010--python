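"""Waveform container and 16-bit PCM WAV input/output.

All signal processing in :mod:`sonoscape` operates on :class:`Waveform`:
mono audio samples as floats in ``[-1, 1]`` plus a sampling rate, optionally
tagged with the plot that produced the recording and the recording start
time (seconds since local midnight).
"""

from __future__ import annotations

import wave
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["Waveform", "read_wav", "write_wav"]


@dataclass
class Waveform:
    """A mono audio recording.

    Parameters
    ----------
    samples:
        Float samples in ``[-1, 1]``.
    rate:
        Sampling rate in Hz.
    plot_id, start_time:
        Optional provenance: the plot the recorder stood on and the start
        of the recording in seconds since local midnight.
    """

    samples: np.ndarray
    rate: int
    plot_id: str | None = None
    start_time: float | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("Waveform requires mono (1-D) samples")
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("Waveform samples must be finite")

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return len(self.samples) / self.rate

    def slice(self, start_s: float, stop_s: float) -> "Waveform":
        i0 = int(round(start_s * self.rate))
        i1 = int(round(stop_s * self.rate))
        return replace(self, samples=self.samples[i0:i1])


def write_wav(path: str | Path, w: Waveform) -> None:
    """Write a waveform as 16-bit PCM mono WAV."""
    clipped = np.clip(w.samples, -1.0, 1.0)
    pcm = np.round(clipped * 32767.0).astype("<i2")
    with wave.open(str(path), "wb") as fh:
        fh.setnchannels(1)
        fh.setsampwidth(2)
        fh.setframerate(int(w.rate))
        fh.writeframes(pcm.tobytes())


def read_wav(path: str | Path, plot_id: str | None = None,
             start_time: float | None = None) -> Waveform:
    """Read a 16-bit PCM mono WAV file into a :class:`Waveform`."""
    with wave.open(str(path), "rb") as fh:
        if fh.getnchannels() != 1:
            raise ValueError(f"{path}: expected mono audio")
        if fh.getsampwidth() != 2:
            raise ValueError(f"{path}: expected 16-bit PCM")
        rate = fh.getframerate()
        raw = fh.readframes(fh.getnframes())
    samples = np.frombuffer(raw, dtype="<i2").astype(np.float64) / 32767.0
    return Waveform(samples=samples, rate=rate, plot_id=plot_id,
                    start_time=start_time)
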