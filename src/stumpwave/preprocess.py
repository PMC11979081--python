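"""Signal conditioning for raw pressure recordings.

The chain is fixed: a 10 Hz low-pass first, then Savitzky-Golay polynomial
smoothing (order 2, 50 ms window). The low-pass is a 4th-order Butterworth
applied forward-backward (zero phase), so beat fiducials are not shifted in
time; the SG stage is likewise symmetric. Both stages are linear and
length-preserving.

Edge handling: the Butterworth stage uses scipy's odd-reflection padding,
the SG stage polynomial extrapolation at the ends, so quadratic signals are
reproduced exactly everywhere and 60-s traces keep usable first and last
beats.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .exceptions import ValidationError
from .io import PressureTrace

__all__ = ["FilterSettings", "lowpass_filter", "savgol_smooth", "condition_trace"]

#: Order of the Butterworth low-pass (applied twice via filtfilt).
BUTTER_ORDER = 4


@dataclass(frozen=True)
class FilterSettings:
    """Conditioning parameters.

    Attributes
    ----------
    lowpass_cutoff : float
        Low-pass corner frequency in Hz (default 10; must stay below the
        Nyquist frequency of the trace it is applied to).
    sg_window : float
        Savitzky-Golay window length in seconds (default 0.050). Converted
        to samples at the trace rate and rounded to the nearest odd count,
        never below 5 samples or ``sg_order + 1``.
    sg_order : int
        Savitzky-Golay polynomial order (default 2).
    """

    lowpass_cutoff: float = 10.0
    sg_window: float = 0.050
    sg_order: int = 2

    def __post_init__(self):
        if not self.lowpass_cutoff > 0:
            raise ValidationError("lowpass_cutoff must be positive")
        if not self.sg_window > 0:
            raise ValidationError("sg_window must be positive")
        if self.sg_order < 1:
            raise ValidationError("sg_order must be >= 1")

    def sg_window_samples(self, sampling_rate: float) -> int:
        """SG window in samples: nearest odd count, >= 5 and > sg_order."""
        w = int(round(self.sg_window * sampling_rate))
        if w % 2 == 0:
            w += 1
        w = max(w, 5)
        if w <= self.sg_order:
            w = self.sg_order + 1 if (self.sg_order + 1) % 2 == 1 else self.sg_order + 2
        return w


def lowpass_filter(trace: PressureTrace, settings: FilterSettings | None = None) -> PressureTrace:
    """Zero-phase Butterworth low-pass (default corner 10 Hz).

    Same length and sampling rate as the input; unit passband gain; applied
    forward and backward so fiducial timing is preserved.
    """
    settings = settings or FilterSettings()
    nyquist = trace.sampling_rate / 2.0
    if settings.lowpass_cutoff >= nyquist:
        raise ValidationError(
            f"lowpass_cutoff {settings.lowpass_cutoff} Hz must be below the "
            f"Nyquist frequency {nyquist} Hz"
        )
    sos = signal.butter(
        BUTTER_ORDER, settings.lowpass_cutoff, btype="low",
        fs=trace.sampling_rate, output="sos",
    )
    filtered = signal.sosfiltfilt(sos, trace.samples)
    return trace.with_samples(filtered)


def savgol_smooth(trace: PressureTrace, settings: FilterSettings | None = None) -> PressureTrace:
    """Savitzky-Golay smoothing (default order 2, 50 ms window).

    Reproduces polynomials up to ``sg_order`` exactly (including at the
    edges, where the fitted polynomial is extrapolated).
    """
    settings = settings or FilterSettings()
    w = settings.sg_window_samples(trace.sampling_rate)
    if w > trace.n:
        raise ValidationError(
            f"SG window of {w} samples exceeds trace length {trace.n}"
        )
    smoothed = signal.savgol_filter(
        trace.samples, window_length=w, polyorder=settings.sg_order, mode="interp"
    )
    return trace.with_samples(smoothed)


def condition_trace(trace: PressureTrace, settings: FilterSettings | None = None) -> PressureTrace:
    """Full conditioning chain: low-pass, then SG smoothing."""
    settings = settings or FilterSettings()
    return savgol_smooth(lowpass_filter(trace, settings), settings)
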