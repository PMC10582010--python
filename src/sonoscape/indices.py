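"""Amplitude spectrograms with background-noise removal and the eight
acoustic indices used as biodiversity proxies.

The substrate for the spectral indices is a noise-reduced amplitude
spectrogram in the style of Towsey's amplitude spectrum: short Hamming
windows with no overlap, magnitudes scaled so a full-scale sine yields ~1
in its bin, and a per-frequency-bin background profile (the modal amplitude
of the quietest half of frames) subtracted and truncated at zero.

The indices:

* ``H_t`` — temporal entropy: Shannon entropy of the amplitude-envelope
  probability mass over frames, normalised by ``log(n_frames)``; 1 for a
  flat envelope, near 0 for a single click.
* ``ACI`` — acoustic complexity: per frequency bin, the sum of absolute
  frame-to-frame amplitude changes over the amplitude sum, summed across
  bins and averaged over temporal sub-windows.
* ``H_f`` — entropy of frequency: Shannon entropy of the normalised mean
  amplitude spectrum, normalised by ``log(n_bins)``.
* ``saturation`` — soundscape saturation: percentage of time-frequency
  cells whose amplitude exceeds the background profile by a dB threshold.
* ``events_per_second`` — upward crossings of the smoothed dB envelope
  through background + threshold, divided by duration.
* ``ADI`` / ``AEI`` — Shannon entropy / Gini coefficient over per-1-kHz-band
  active-cell proportions.
* ``BI`` — bioacoustic index: area under the mean dB spectrum above its
  minimum within a frequency band (dB·bins).

Silence conventions: digital silence yields ``H_t = H_f = 1`` (flat
envelope/spectrum) with a warning, and zeros for the activity-based
indices, so silent files cannot masquerade as biologically complex via NaN
propagation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .audio import Waveform

__all__ = [
    "AmplitudeSpectrogram",
    "AcousticIndexSet",
    "SilentRecordingWarning",
    "amplitude_spectrogram",
    "remove_background_noise",
    "temporal_entropy",
    "acoustic_complexity",
    "spectral_entropy",
    "soundscape_saturation",
    "events_per_second",
    "adi_aei_bi",
    "compute_indices",
    "summarize_plot_indices",
]

_EPS = 1e-12

INDEX_COLUMNS = ["H_t", "ACI", "H_f", "saturation", "events_per_second",
                 "ADI", "AEI", "BI"]

#: The five indices entering the regression models downstream.
MODEL_INDICES = ["H_t", "ACI", "H_f", "saturation", "events_per_second"]


class SilentRecordingWarning(UserWarning):
    """Raised when an index hits its digital-silence convention."""


@dataclass
class AmplitudeSpectrogram:
    """Time x frequency matrix of non-negative amplitudes.

    ``values[t, k]`` is the amplitude of frame ``t`` in frequency bin ``k``;
    bins span 0 Hz to Nyquist at ``freq_resolution`` Hz per bin. After
    noise removal, ``noise_profile`` holds the subtracted per-bin background
    amplitude.
    """

    values: np.ndarray
    frame_len: int
    frame_hop: int
    freq_resolution: float
    rate: int
    noise_profile: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def frame_duration(self) -> float:
        return self.frame_hop / self.rate

    def bin_freqs(self) -> np.ndarray:
        return np.arange(self.n_bins) * self.freq_resolution


def amplitude_spectrogram(w: Waveform, frame_len: int = 512,
                          overlap: float = 0.0) -> AmplitudeSpectrogram:
    """Hamming-windowed amplitude spectrogram, full-scale-sine calibrated.

    A full-scale sine at a bin centre yields amplitude ~1 in its bin
    (scaling ``2 / sum(window)``). Columns are the ``frame_len // 2``
    bins from 0 Hz up to (excluding) Nyquist.
    """
    if frame_len < 64:
        raise ValueError("frame_len must be >= 64")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    x = w.samples
    if len(x) < frame_len:
        raise ValueError(
            f"waveform ({len(x)} samples) shorter than one frame ({frame_len})")
    hop = max(int(round(frame_len * (1.0 - overlap))), 1)
    n_frames = 1 + (len(x) - frame_len) // hop
    window = np.hamming(frame_len)
    idx = np.arange(frame_len)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx] * window
    mag = np.abs(np.fft.rfft(frames, axis=1))[:, : frame_len // 2]
    values = mag * (2.0 / window.sum())
    return AmplitudeSpectrogram(
        values=values, frame_len=frame_len, frame_hop=hop,
        freq_resolution=w.rate / frame_len, rate=w.rate)


def remove_background_noise(spec: AmplitudeSpectrogram,
                            hist_bins: int = 100) -> AmplitudeSpectrogram:
    """Subtract the per-bin modal background amplitude.

    For every frequency bin, the quietest 50 % of frames are histogrammed
    (``hist_bins`` bins) and the histogram-peak amplitude is taken as the
    background level of that bin; it is subtracted and negatives truncated
    at zero. The profile is stored on the result for the saturation and
    activity computations.
    """
    if spec.n_frames < 60:
        raise ValueError("need >= 60 frames for a stable background estimate")
    v = spec.values
    half = spec.n_frames // 2
    quiet = np.sort(v, axis=0)[:half, :]
    profile = np.empty(spec.n_bins)
    for k in range(spec.n_bins):
        col = quiet[:, k]
        lo, hi = col[0], col[-1]
        if hi - lo < _EPS:
            profile[k] = col[0]
            continue
        counts, edges = np.histogram(col, bins=hist_bins, range=(lo, hi))
        # light smoothing stabilises the mode against bin-quantisation jitter
        smoothed = np.convolve(counts, np.ones(5) / 5, mode="same")
        peak = int(np.argmax(smoothed))
        profile[k] = 0.5 * (edges[peak] + edges[peak + 1])
    cleaned = np.clip(v - profile[None, :], 0.0, None)
    return replace(spec, values=cleaned, noise_profile=profile)


def _envelope(w: Waveform, frame_len: int = 512) -> np.ndarray:
    """Per-frame RMS amplitude envelope (non-overlapping frames)."""
    n = len(w.samples) // frame_len
    if n < 1:
        raise ValueError("waveform shorter than one envelope frame")
    frames = w.samples[: n * frame_len].reshape(n, frame_len)
    return np.sqrt(np.mean(frames ** 2, axis=1))


def _normalized_entropy(p: np.ndarray) -> float:
    total = p.sum()
    if total <= 0:
        return 1.0
    p = p / total
    nz = p > 0
    h = -(p[nz] * np.log(p[nz])).sum()
    return float(h / np.log(len(p)))


def temporal_entropy(w: Waveform, frame_len: int = 512) -> float:
    """Entropy of the amplitude envelope over time, in [0, 1]."""
    env = _envelope(w, frame_len)
    if env.sum() <= 0:
        warnings.warn("digital silence: temporal entropy defined as 1",
                      SilentRecordingWarning, stacklevel=2)
        return 1.0
    return _normalized_entropy(env)


def acoustic_complexity(spec: AmplitudeSpectrogram,
                        window_s: float = 60.0) -> float:
    """Acoustic Complexity Index, averaged over temporal sub-windows.

    Within each sub-window and frequency bin the index is
    ``sum |a[t+1] - a[t]| / sum a[t]``; bins with zero amplitude sum
    contribute 0. Bin values are summed per window and windows averaged.
    """
    frames_per_win = max(int(round(window_s / spec.frame_duration)), 2)
    v = spec.values
    wins = max(v.shape[0] // frames_per_win, 1)
    totals = []
    for i in range(wins):
        seg = v[i * frames_per_win: (i + 1) * frames_per_win]
        if seg.shape[0] < 2:
            continue
        num = np.abs(np.diff(seg, axis=0)).sum(axis=0)
        den = seg.sum(axis=0)
        ratio = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        totals.append(ratio.sum())
    return float(np.mean(totals)) if totals else 0.0


def spectral_entropy(spec: AmplitudeSpectrogram) -> float:
    """Entropy of the mean amplitude spectrum across bins, in [0, 1]."""
    s = spec.values.mean(axis=0)
    if s.sum() <= 0:
        warnings.warn("digital silence: spectral entropy defined as 1",
                      SilentRecordingWarning, stacklevel=2)
        return 1.0
    return _normalized_entropy(s)


def _active_cells(spec: AmplitudeSpectrogram, threshold_db: float) -> np.ndarray:
    """Boolean mask of noise-removed cells exceeding the background profile
    by ``threshold_db``."""
    if spec.noise_profile is None:
        raise ValueError("apply remove_background_noise first")
    gain = 10.0 ** (threshold_db / 20.0) - 1.0
    floor = np.maximum(spec.noise_profile, _EPS)
    return spec.values > gain * floor


def soundscape_saturation(spec: AmplitudeSpectrogram,
                          threshold_db: float = 12.0) -> float:
    """Percent of time-frequency cells above background + threshold_db."""
    active = _active_cells(spec, threshold_db)
    return float(100.0 * active.mean())


def events_per_second(w: Waveform, snr_threshold_db: float = 6.0,
                      frame_len: int = 512, smooth_frames: int = 5,
                      hist_bins: int = 100) -> float:
    """Acoustic event rate: upward crossings of the smoothed dB envelope
    through (modal background dB + ``snr_threshold_db``), per second."""
    env = _envelope(w, frame_len)
    if env.sum() <= 0:
        return 0.0
    db = 20.0 * np.log10(env + _EPS)
    if smooth_frames > 1:
        kernel = np.ones(smooth_frames) / smooth_frames
        pad = smooth_frames // 2
        padded = np.pad(db, pad, mode="edge")
        db = np.convolve(padded, kernel, mode="same")[pad: pad + len(db)]
    lo, hi = db.min(), db.max()
    if hi - lo < 1e-9:
        return 0.0
    counts, edges = np.histogram(db, bins=hist_bins, range=(lo, hi))
    peak = int(np.argmax(counts))
    background = 0.5 * (edges[peak] + edges[peak + 1])
    thr = background + snr_threshold_db
    above = db >= thr
    crossings = int(np.sum(~above[:-1] & above[1:]))
    if above[0]:
        crossings += 1
    return float(crossings / w.duration)


def _gini(x: np.ndarray) -> float:
    """Gini coefficient of non-negative values; 0 if all equal or all zero."""
    x = np.asarray(x, dtype=float)
    if x.sum() <= 0:
        return 0.0
    diffs = np.abs(x[:, None] - x[None, :]).sum()
    return float(diffs / (2.0 * len(x) * x.sum()))


def adi_aei_bi(spec: AmplitudeSpectrogram, band_width: float = 1000.0,
               bi_band: tuple[float, float] = (2000.0, 8000.0),
               activity_threshold_db: float = 12.0) -> tuple[float, float, float]:
    """Acoustic Diversity Index, Acoustic Evenness Index, Bioacoustic Index.

    ADI is the Shannon entropy (nats) of the normalised per-band
    active-cell proportions over consecutive ``band_width``-Hz bands; AEI
    is the Gini coefficient of the same proportions; BI is the area under
    the mean dB spectrum above its in-band minimum, within ``bi_band``.
    Requires a noise-removed spectrogram. Silence yields (0, 0, 0) with a
    warning.
    """
    nyq = spec.rate / 2.0
    if bi_band[1] > nyq + _EPS:
        raise ValueError(f"bi_band {bi_band} exceeds Nyquist {nyq:.0f} Hz")
    active = _active_cells(spec, activity_threshold_db)
    freqs = spec.bin_freqs()
    n_bands = max(int(nyq // band_width), 1)
    props = np.empty(n_bands)
    for b in range(n_bands):
        mask = (freqs >= b * band_width) & (freqs < (b + 1) * band_width)
        props[b] = active[:, mask].mean() if mask.any() else 0.0

    if props.sum() <= 0:
        warnings.warn("digital silence: ADI/AEI/BI defined as 0",
                      SilentRecordingWarning, stacklevel=2)
        return 0.0, 0.0, 0.0

    p = props / props.sum()
    nz = p > 0
    adi = float(-(p[nz] * np.log(p[nz])).sum())
    aei = _gini(props)

    band_mask = (freqs >= bi_band[0]) & (freqs <= bi_band[1])
    mean_db = 20.0 * np.log10(spec.values[:, band_mask].mean(axis=0) + _EPS)
    bi = float(np.sum(mean_db - mean_db.min()))
    return adi, aei, bi


@dataclass(frozen=True)
class AcousticIndexSet:
    """The eight per-recording index values."""

    H_t: float
    ACI: float
    H_f: float
    saturation: float
    events_per_second: float
    ADI: float
    AEI: float
    BI: float
    plot_id: str | None = None
    start_time: float | None = None

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in INDEX_COLUMNS}


def compute_indices(
    w: Waveform,
    frame_len: int = 512,
    overlap: float = 0.0,
    aci_window_s: float = 60.0,
    saturation_threshold_db: float = 12.0,
    events_threshold_db: float = 6.0,
    band_width: float = 1000.0,
    bi_band: tuple[float, float] | None = None,
) -> AcousticIndexSet:
    """All eight indices for one recording.

    The amplitude spectrogram is computed once; noise removal is applied
    for the activity-based indices (saturation, ADI, AEI, BI) while the
    entropies and ACI use the raw spectrum/waveform.
    """
    spec = amplitude_spectrogram(w, frame_len, overlap)
    cleaned = remove_background_noise(spec)
    if bi_band is None:
        bi_band = (2000.0, min(8000.0, w.rate / 2.0))
    adi, aei, bi = adi_aei_bi(cleaned, band_width, bi_band,
                              saturation_threshold_db)
    return AcousticIndexSet(
        H_t=temporal_entropy(w, frame_len),
        ACI=acoustic_complexity(spec, aci_window_s),
        H_f=spectral_entropy(spec),
        saturation=soundscape_saturation(cleaned, saturation_threshold_db),
        events_per_second=events_per_second(w, events_threshold_db, frame_len),
        ADI=adi, AEI=aei, BI=bi,
        plot_id=w.plot_id, start_time=w.start_time,
    )


def indices_frame(index_sets: list[AcousticIndexSet]) -> pd.DataFrame:
    """Per-recording index table (one row per recording)."""
    rows = []
    for s in index_sets:
        row = {"plot_id": s.plot_id, "start_time": s.start_time}
        row.update(s.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_plot_indices(per_recording: pd.DataFrame) -> pd.DataFrame:
    """Average indices over all recordings of each plot.

    Input is the per-recording table from :func:`indices_frame` (or any
    frame with a ``plot_id`` column and the eight index columns). Returns
    one row per plot with the arithmetic mean of each index plus
    ``n_recordings``. Raises if any plot has no recordings (empty input).
    """
    if per_recording.empty:
        raise ValueError("no recordings to summarise")
    missing = [c for c in INDEX_COLUMNS if c not in per_recording.columns]
    if missing:
        raise ValueError(f"missing index columns: {missing}")
    grouped = per_recording.groupby("plot_id")
    out = grouped[INDEX_COLUMNS].mean()
    out["n_recordings"] = grouped.size()
    return out
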