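"""Amplitude-envelope extraction from audio.

The acoustic feature tracked by low-frequency cortical activity is the
amplitude envelope of the stimulus.  It is computed the way auditory
neuroscience pipelines typically do:

1. decompose the waveform through a gammatone filter bank whose centre
   frequencies are equally spaced on the ERB-rate scale (a perceptual
   frequency axis approximating cochlear filter bandwidths),
2. take the magnitude of the analytic signal of each subband (the subband
   envelope) and average across subbands, giving a single nonnegative
   cochlear envelope,
3. band-pass the envelope 1-9 Hz with a zero-phase 4th-order Butterworth
   filter and resample to the EEG analysis rate (64 Hz),
4. cut into epochs on exactly the same grid as the EEG.

All functions are pure and operate on plain numpy arrays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal

__all__ = [
    "CochleagramSpec",
    "EnvelopeTrace",
    "erb_rate",
    "inverse_erb_rate",
    "erb_filterbank",
    "cochlear_envelope",
    "bandlimit_resample",
    "epoch_trace",
    "load_wav_mono",
]

#: Glasberg & Moore ERB-rate constants.
_ERB_A = 21.4
_ERB_B = 0.00437


def erb_rate(f):
    """Map frequency in Hz to the ERB-rate scale: 21.4*log10(1 + 0.00437 f)."""
    return _ERB_A * np.log10(1.0 + _ERB_B * np.asarray(f, dtype=float))


def inverse_erb_rate(e):
    """Inverse of :func:`erb_rate` (ERB-rate number back to Hz)."""
    return (10.0 ** (np.asarray(e, dtype=float) / _ERB_A) - 1.0) / _ERB_B


@dataclass(frozen=True)
class CochleagramSpec:
    """Configuration of the ERB-spaced gammatone filter bank.

    Defaults follow common cochleagram practice: 38 filters between 30 Hz
    and 7.5 kHz.  ``f_high`` must stay below the audio Nyquist frequency.
    """

    n_filters: int = 38
    f_low: float = 30.0
    f_high: float = 7500.0
    audio_fs: float = 44100.0

    def __post_init__(self):
        if self.n_filters < 1:
            raise ValueError("n_filters must be >= 1")
        if not (0.0 < self.f_low <= self.f_high):
            raise ValueError("need 0 < f_low <= f_high")
        if self.f_high > self.audio_fs / 2.0:
            raise ValueError("f_high above the audio Nyquist frequency")
        if self.audio_fs <= 0:
            raise ValueError("audio_fs must be positive")


@dataclass
class EnvelopeTrace:
    """A 1-D stimulus envelope at a stated sampling rate.

    The cochlear envelope (pre band-limiting) is nonnegative; after the
    1-9 Hz zero-phase band-pass the samples may dip below zero because of
    filter ringing — that is expected and harmless for correlation-based
    scoring.
    """

    samples: np.ndarray
    fs: float
    stimulus_id: object = None
    epoch_index: int | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("EnvelopeTrace.samples must be 1-D")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("EnvelopeTrace.samples must be finite")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    def __len__(self):
        return self.samples.size


@dataclass(frozen=True)
class FilterBank:
    """Gammatone FIR filter bank with ERB-rate-equidistant centres."""

    centers: np.ndarray
    taps: list = field(repr=False, default_factory=list)
    fs: float = 44100.0


def erb_filterbank(spec: CochleagramSpec) -> FilterBank:
    """Design ``spec.n_filters`` gammatone band-pass filters.

    Centre frequencies are equally spaced on the ERB-rate scale between
    ``f_low`` and ``f_high`` (inclusive).  A single-filter bank is centred
    at ``f_low`` (degenerate case, requires ``f_low == f_high``).
    """
    if spec.n_filters == 1:
        centers = np.array([0.5 * (spec.f_low + spec.f_high)])
    else:
        e = np.linspace(erb_rate(spec.f_low), erb_rate(spec.f_high), spec.n_filters)
        centers = inverse_erb_rate(e)
    taps = []
    for fc in centers:
        b, _ = signal.gammatone(float(fc), "fir", fs=spec.audio_fs)
        taps.append(np.asarray(b, dtype=float))
    return FilterBank(centers=centers, taps=taps, fs=spec.audio_fs)


def cochlear_envelope(audio: np.ndarray, spec: CochleagramSpec) -> EnvelopeTrace:
    """Subband-envelope cochleagram collapsed to a single envelope.

    Each subband envelope is the magnitude of the analytic signal of the
    gammatone-filtered waveform; the output is the arithmetic mean across
    subbands, still at the audio sampling rate.  Linear in amplitude:
    scaling the audio scales the envelope by the same factor.
    """
    audio = np.asarray(audio, dtype=float)
    if audio.ndim != 1:
        raise ValueError("audio must be a mono 1-D array")
    bank = erb_filterbank(spec)
    if audio.size <= max(len(t) for t in bank.taps):
        raise ValueError("audio shorter than the filter settling length")
    acc = np.zeros_like(audio)
    for b in bank.taps:
        sub = signal.lfilter(b, [1.0], audio)
        acc += np.abs(signal.hilbert(sub))
    env = acc / len(bank.taps)
    return EnvelopeTrace(samples=env, fs=spec.audio_fs)


def bandlimit_resample(
    x: np.ndarray,
    fs_in: float,
    fs_out: float,
    band: tuple[float, float] = (1.0, 9.0),
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass followed by rational resampling.

    The band-pass is a 4th-order Butterworth applied forward-backward
    (``sosfiltfilt``), so the net filter has zero phase and a squared
    magnitude response.  Resampling uses a polyphase FIR with its delay
    compensated, preserving the zero-phase property end to end.
    """
    x = np.asarray(x, dtype=float)
    if fs_out > fs_in:
        raise ValueError("fs_out must not exceed fs_in")
    if fs_in <= 2.0 * band[1]:
        raise ValueError("fs_in too low for the requested band")
    sos = signal.butter(order, band, btype="bandpass", fs=fs_in, output="sos")
    padlen = 3 * (2 * order + 1)
    if x.size <= padlen:
        raise ValueError("sequence shorter than the filter padding requirement")
    y = signal.sosfiltfilt(sos, x)
    if fs_out == fs_in:
        return y
    frac = Fraction(fs_out).limit_denominator(10**6) / Fraction(fs_in).limit_denominator(10**6)
    return signal.resample_poly(y, frac.numerator, frac.denominator)


def epoch_trace(
    x: np.ndarray,
    fs: float,
    epoch_seconds: float,
    discard_head_ms: float = 0.0,
    min_fragment: float = 0.5,
) -> list[np.ndarray]:
    """Cut a trace into consecutive non-overlapping epochs.

    The first ``discard_head_ms`` are dropped (stimulus-onset response),
    then full epochs of ``floor(epoch_seconds*fs)`` samples are emitted.
    A trailing fragment at least ``min_fragment`` of an epoch long is
    emitted as a final, shorter epoch: a 60 s trial at 64 Hz with 500 ms
    discarded yields one 30 s epoch and one 29.5 s epoch, keeping the
    printed two-epochs-per-trial count.  Audio and EEG cut with identical
    parameters land on identical boundaries, so the pairing stays aligned.
    """
    x = np.asarray(x)
    if fs <= 0 or epoch_seconds <= 0:
        raise ValueError("fs and epoch_seconds must be positive")
    n0 = int(round(discard_head_ms / 1000.0 * fs))
    body = x[..., n0:] if x.ndim > 1 else x[n0:]
    length = int(math.floor(epoch_seconds * fs))
    n = body.shape[-1]
    if n < length:
        raise ValueError("trace shorter than one epoch after discard")
    epochs = []
    full = n // length
    for i in range(full):
        epochs.append(body[..., i * length : (i + 1) * length])
    rem = body[..., full * length :]
    if rem.shape[-1] >= min_fragment * length:
        epochs.append(rem)
    return epochs


def load_wav_mono(path) -> tuple[np.ndarray, float]:
    """Read a WAV file as float mono; stereo is averaged with a warning."""
    import warnings

    from scipy.io import wavfile

    fs, data = wavfile.read(path)
    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(float)
    if data.ndim == 2:
        warnings.warn("stereo WAV averaged to mono", stacklevel=2)
        data = data.mean(axis=1)
    return data, float(fs)
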