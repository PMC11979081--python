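"""Cardiac cycle mapping, fiducial location and two-step ensemble averaging.

Beat feet are detected as the local pressure minimum preceding each peak of
the first derivative (systolic upstroke), with an adaptive height threshold
at 50% of the median upstroke-slope peak and a 300 ms refractory period.
Fiducials follow the pressure-only convention used when no ECG is recorded:
the maximum of the discrete second derivative on the anacrotic (rising)
limb, i.e. the sharp acceleration at the start of the upstroke.

The representative beat is built in two passes: beats are aligned at their
fiducials and averaged into a "raw average"; each beat is then Pearson
correlated against that raw average over the common support, and only beats
with r above the gate (default 0.95) are re-averaged. Diagnostics (per-beat
correlations, retention flags) are carried on the result.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy import signal as _signal

from .exceptions import InsufficientBeatsError, InsufficientConcordantBeatsError, ValidationError
from .io import PressureTrace

__all__ = ["BeatSegment", "EnsembleBeat", "segment_beats", "locate_fiducial", "ensemble_average"]

#: Minimum peak-to-peak excursion (mmHg) for a trace to count as pulsatile.
MIN_PULSATILITY_MMHG = 5.0
#: Minimum systolic rise (mmHg) for a segment to have a usable anacrotic limb.
MIN_RISE_MMHG = 1.0


@dataclass
class BeatSegment:
    """One cardiac cycle cut from a trace, foot to next foot.

    Indices are absolute sample indices into the source trace; ``samples``
    is the cycle's pressure values. ``ok`` is False when no rising limb was
    found, in which case ``fiducial_index`` equals ``start_index`` and the
    beat is excluded from averaging.
    """

    start_index: int
    fiducial_index: int
    end_index: int
    samples: np.ndarray
    sampling_rate: float
    ok: bool = True

    def __post_init__(self):
        if not (self.start_index <= self.fiducial_index < self.end_index):
            raise ValidationError(
                "beat indices must satisfy start <= fiducial < end, got "
                f"({self.start_index}, {self.fiducial_index}, {self.end_index})"
            )

    @property
    def duration(self) -> float:
        return (self.end_index - self.start_index) / self.sampling_rate


@dataclass
class EnsembleBeat:
    """Representative averaged cardiac cycle plus retention diagnostics.

    ``fiducial_offset`` is the sample index of the alignment fiducial inside
    ``representative`` (a short pre-fiducial margin is kept so the beat foot
    survives averaging).
    """

    representative: np.ndarray
    sampling_rate: float
    n_detected: int
    n_retained: int
    correlations: np.ndarray
    retained_flags: np.ndarray
    heart_rate: float
    fiducial_offset: int = 0

    def __post_init__(self):
        self.representative = np.asarray(self.representative, dtype=float)
        self.correlations = np.asarray(self.correlations, dtype=float)
        self.retained_flags = np.asarray(self.retained_flags, dtype=bool)
        if self.n_retained > self.n_detected:
            raise ValidationError("n_retained cannot exceed n_detected")
        if int(self.retained_flags.sum()) != self.n_retained:
            raise ValidationError("retained_flags must mark exactly n_retained beats")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.representative.size) / self.sampling_rate


def _foot_before(p: np.ndarray, lo: int, hi: int) -> int:
    """Index of the pressure minimum in [lo, hi] (the beat foot)."""
    lo = max(lo, 0)
    return lo + int(np.argmin(p[lo : hi + 1]))


def segment_beats(
    trace: PressureTrace,
    min_cycle_s: float = 0.3,
    max_cycle_s: float = 2.0,
) -> List[BeatSegment]:
    """Map the cardiac cycles of a conditioned trace.

    Returns one segment per detected cycle, boundaries at successive beat
    feet, gated to physiological cycle lengths (0.3-2.0 s by default).
    An empty list (with a warning) is returned when the trace shows no
    pulsatility.
    """
    if trace.duration < 2.0:
        raise ValidationError("segment_beats needs at least 2 s of signal")
    p = trace.samples
    fs = trace.sampling_rate
    if float(np.ptp(p)) < MIN_PULSATILITY_MMHG:
        warnings.warn("no pulsatile beats detected (flat trace)", stacklevel=2)
        return []

    dp = np.gradient(p) * fs  # mmHg/s
    refractory = max(1, int(round(0.3 * fs)))
    cand, props = _signal.find_peaks(dp, distance=refractory, height=0.0)
    if cand.size == 0:
        warnings.warn("no upstroke candidates found", stacklevel=2)
        return []
    heights = props["peak_heights"]
    # Adaptive threshold: half the median upstroke-peak slope. The median is
    # taken over the strong-peak population (upper decile anchor) so that
    # small noise-induced dP/dt peaks between beats cannot drag it down.
    anchor = 0.5 * float(np.percentile(heights, 90))
    strong = heights[heights >= anchor]
    threshold = 0.5 * float(np.median(strong))
    upstrokes = cand[heights >= threshold]
    if upstrokes.size < 2:
        warnings.warn("fewer than 2 upstrokes detected", stacklevel=2)
        return []

    max_cycle = int(round(max_cycle_s * fs))
    feet = []
    prev = None
    for q in upstrokes:
        lo = prev if prev is not None else max(0, q - max_cycle)
        feet.append(_foot_before(p, lo, q))
        prev = q
    feet = np.unique(np.asarray(feet, dtype=int))

    segments: List[BeatSegment] = []
    for a, b in zip(feet[:-1], feet[1:]):
        length_s = (b - a) / fs
        if not (min_cycle_s <= length_s <= max_cycle_s):
            continue
        seg = BeatSegment(
            start_index=int(a),
            fiducial_index=int(a),
            end_index=int(b),
            samples=p[a:b].copy(),
            sampling_rate=fs,
        )
        try:
            seg.fiducial_index = locate_fiducial(seg)
        except ValidationError:
            seg.ok = False
        segments.append(seg)
    return segments


def locate_fiducial(segment: BeatSegment, trace: Optional[PressureTrace] = None) -> int:
    """Maximum of the discrete second derivative on the anacrotic limb.

    The search runs from the segment start to the systolic peak, using the
    centered second difference. Returns an absolute sample index into the
    source trace. Raises :class:`ValidationError` when the segment has no
    rising limb (systolic rise below 1 mmHg).
    """
    s = np.asarray(segment.samples, dtype=float)
    peak = int(np.argmax(s))
    if s[peak] - s[0] <= MIN_RISE_MMHG:
        raise ValidationError("segment has no usable rising limb")
    if peak < 2:
        return segment.start_index
    d2 = s[2 : peak + 1] - 2.0 * s[1:peak] + s[: peak - 1]
    if d2.size >= 3:
        # Mild binomial smoothing (edge-padded) stabilizes the argmax under
        # residual noise without moving a clean maximum.
        d2 = np.convolve(np.r_[d2[0], d2, d2[-1]], [0.25, 0.5, 0.25], mode="valid")
    rel = 1 + int(np.argmax(d2))
    return segment.start_index + rel


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = np.std(a), np.std(b)
    if sa == 0.0 or sb == 0.0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def ensemble_average(
    segments: Sequence[BeatSegment],
    r_threshold: float = 0.95,
    min_beats: int = 5,
    trace: Optional[PressureTrace] = None,
    pre_margin_s: float = 0.1,
) -> EnsembleBeat:
    """Two-step correlation-gated ensemble averaging.

    Step 1 aligns all usable beats at their fiducials (keeping up to
    ``pre_margin_s`` of pre-fiducial context when the source trace provides
    it) and averages them into a raw average. Step 2 Pearson-correlates each
    beat against the raw average over the common support and re-averages
    only beats with r strictly above ``r_threshold``.

    Raises
    ------
    InsufficientBeatsError
        Fewer than ``min_beats`` usable segments.
    InsufficientConcordantBeatsError
        Fewer than ``min_beats`` beats pass the correlation gate; carries
        the correlation vector for inspection.
    """
    if not 0.0 < r_threshold <= 1.0:
        raise ValidationError("r_threshold must be in (0, 1]")
    segments = list(segments)
    if not segments:
        raise InsufficientBeatsError("no beats to average")
    fs = segments[0].sampling_rate
    usable = [s for s in segments if s.ok]
    if len(usable) < min_beats:
        raise InsufficientBeatsError(
            f"only {len(usable)} usable beats, need at least {min_beats}"
        )
    # Beats far from the median cycle length (e.g. stubs cut around artifact
    # boundaries) would truncate every beat's common support; drop them
    # before alignment.
    median_dur = float(np.median([s.duration for s in usable]))
    usable = [s for s in usable if 0.75 * median_dur <= s.duration <= 1.25 * median_dur]
    if len(usable) < min_beats:
        raise InsufficientBeatsError(
            f"only {len(usable)} beats near the median cycle length "
            f"({median_dur:.2f} s), need at least {min_beats}"
        )

    pre_req = int(round(pre_margin_s * fs))
    if trace is not None:
        source = trace.samples
        pre_avail = [s.fiducial_index for s in usable]
    else:
        source = None
        pre_avail = [s.fiducial_index - s.start_index for s in usable]
    # Beats lacking the full pre-fiducial margin (typically the first beat
    # of the recording) are dropped rather than shortening everyone's window.
    pre = min(pre_req, int(np.median(pre_avail)))
    kept = [s for s, av in zip(usable, pre_avail) if av >= pre]
    if len(kept) < min_beats:
        pre = max(0, min(pre_avail))
        kept = usable
    # Beats whose post-fiducial span is an outlier (late fiducial) would
    # truncate the common support for everyone; they are still correlated
    # against the raw average over their available overlap, but cannot be
    # averaged at full support.
    spans = np.array([s.end_index - s.fiducial_index for s in kept])
    med_span = float(np.median(spans))
    core = [s for s, sp in zip(kept, spans) if sp >= 0.8 * med_span]
    if len(core) < min_beats:
        raise InsufficientBeatsError(
            f"only {len(core)} full-support beats, need at least {min_beats}"
        )
    post = min(s.end_index - s.fiducial_index for s in core)

    def window(seg: BeatSegment) -> np.ndarray:
        if source is not None:
            lo = max(0, seg.fiducial_index - pre)
            return source[lo : min(seg.fiducial_index + post, source.size)]
        rel = seg.fiducial_index - seg.start_index
        return seg.samples[max(0, rel - pre) : rel + post]

    core_windows = np.vstack([window(s) for s in core])
    raw_average = core_windows.mean(axis=0)

    min_overlap = max(8, raw_average.size // 4)
    corr_by_seg = {}
    for s in usable:
        w = window(s)
        n = min(w.size, raw_average.size)
        if n >= min_overlap:
            corr_by_seg[id(s)] = _pearson(w[:n], raw_average[:n])

    core_ids = {id(s) for s in core}
    correlations = np.array(
        [corr_by_seg.get(id(s), np.nan) for s in segments], dtype=float
    )
    retained_flags = np.zeros(len(segments), dtype=bool)
    for i, s in enumerate(segments):
        c = corr_by_seg.get(id(s))
        retained_flags[i] = c is not None and c > r_threshold and id(s) in core_ids

    n_retained = int(retained_flags.sum())
    if n_retained < min_beats:
        raise InsufficientConcordantBeatsError(
            f"only {n_retained} beats exceed the r > {r_threshold} gate "
            f"(need {min_beats})",
            correlations=correlations,
        )
    keep_rows = [
        i for i, s in enumerate(core) if corr_by_seg.get(id(s), -1.0) > r_threshold
    ]
    representative = core_windows[keep_rows].mean(axis=0)

    cycle_lengths = np.array([s.duration for s in kept])
    heart_rate = 60.0 / float(np.median(cycle_lengths))

    return EnsembleBeat(
        representative=representative,
        sampling_rate=fs,
        n_detected=len(segments),
        n_retained=n_retained,
        correlations=correlations,
        retained_flags=retained_flags,
        heart_rate=heart_rate,
        fiducial_offset=pre,
    )
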