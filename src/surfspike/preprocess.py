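"""Signal conditioning: zero-phase filtering, sync-tone onset detection, and
amplitude-envelope extraction.

High-frequency activity is isolated with a forward-backward (zero-phase)
3rd-order Butterworth high-pass at 300 Hz. Stimulus onsets are recovered from
a dedicated sync channel carrying a 1-5 kHz tone burst at each presentation.
The stimulus amplitude envelope is the magnitude of the analytic signal,
low-pass filtered and resampled to 200 Hz so it shares a time base with 5 ms
binned spike counts.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy import signal

from .types import Envelope, TimeSeries

__all__ = [
    "highpass_zero_phase",
    "detect_stimulus_onsets",
    "amplitude_envelope",
]


def highpass_zero_phase(x: TimeSeries, cutoff: float = 300.0, order: int = 3) -> TimeSeries:
    """Forward-backward Butterworth high-pass filter.

    Filtering in both directions cancels the filter's phase response, so
    spikes keep their shape and timing; the effective magnitude response is
    the squared single-pass response. Edges are handled by odd reflection
    padding of three filter orders.

    Raises
    ------
    ValueError
        If ``cutoff`` is at or above the Nyquist frequency.
    """
    nyq = x.sample_rate / 2.0
    if not 0 < cutoff < nyq:
        raise ValueError(f"cutoff {cutoff} Hz must lie in (0, {nyq}) Hz")
    b, a = signal.butter(order, cutoff, btype="highpass", fs=x.sample_rate)
    y = signal.filtfilt(b, a, x.samples, padtype="odd", padlen=3 * order)
    return TimeSeries(y, x.sample_rate, x.start_time)


def _lowpass_zero_phase(samples: np.ndarray, sample_rate: float, cutoff: float,
                        order: int = 4) -> np.ndarray:
    b, a = signal.butter(order, cutoff, btype="lowpass", fs=sample_rate)
    return signal.filtfilt(b, a, samples, padtype="odd", padlen=3 * order)


def detect_stimulus_onsets(sync: TimeSeries, band: tuple = (1000.0, 5000.0),
                           threshold_frac: float = 0.5,
                           refractory: float = 1.0) -> np.ndarray:
    """Detect tone-burst onsets on a sync channel.

    The channel is band-pass filtered to the tone band, rectified via the
    analytic-signal magnitude, and thresholded at ``threshold_frac`` times the
    95th percentile of the magnitude (robust to absolute level). Upward
    threshold crossings closer than ``refractory`` seconds to the previous
    detection are discarded; one onset is reported per burst.

    Returns
    -------
    ndarray
        Sorted onset times in seconds (empty on a silent channel).
    """
    lo, hi = band
    nyq = sync.sample_rate / 2.0
    hi = min(hi, 0.95 * nyq)
    sos = signal.butter(4, (lo, hi), btype="bandpass", fs=sync.sample_rate, output="sos")
    filtered = signal.sosfiltfilt(sos, sync.samples)
    mag = np.abs(signal.hilbert(filtered))
    scale = np.percentile(mag, 95)
    if scale <= 0:
        return np.empty(0)
    thr = threshold_frac * scale
    above = mag > thr
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above[0]:
        crossings = np.concatenate(([0], crossings))
    onsets = []
    last = -np.inf
    for i in crossings:
        t = sync.start_time + i / sync.sample_rate
        if t - last >= refractory:
            onsets.append(t)
            last = t
    return np.asarray(onsets)


def amplitude_envelope(audio: TimeSeries, lowpass_cutoff: float = 50.0,
                       target_rate: float = 200.0) -> Envelope:
    """Amplitude envelope of an audio stimulus.

    Hilbert-transform magnitude, zero-phase low-pass filtered at
    ``lowpass_cutoff`` (default 50 Hz, below the 100 Hz Nyquist of the target
    rate), then polyphase-resampled to ``target_rate`` and clipped at zero.
    """
    if audio.sample_rate <= 2 * target_rate:
        raise ValueError("audio sample rate must exceed twice the target envelope rate")
    if lowpass_cutoff >= target_rate / 2.0:
        raise ValueError(f"lowpass cutoff must be below {target_rate / 2.0} Hz")
    mag = np.abs(signal.hilbert(audio.samples))
    smooth = _lowpass_zero_phase(mag, audio.sample_rate, lowpass_cutoff)
    ratio = Fraction(target_rate / audio.sample_rate).limit_denominator(10**6)
    resampled = signal.resample_poly(smooth, ratio.numerator, ratio.denominator)
    return Envelope(np.clip(resampled, 0.0, None), target_rate, audio.start_time)
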