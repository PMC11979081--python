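"""Morphometrics of the representative beat and the diastolic decay constant.

The panel extracted from one averaged cycle comprises systolic, diastolic,
pulse and mean pressures, the end-systolic (dicrotic notch, "incisura")
pressure, systolic/diastolic durations, areas under the pressure curve, the
heart rate, and the two-element Windkessel decay constant tau = R * C
estimated from the diastolic limb by the area method.

Area method
-----------
For an exponential decay P(t) = a + (P0 - a) exp(-t/tau) toward asymptote
``a``, the area above the asymptote over any window equals tau times the
pressure drop across it:  integral (P - a) dt = tau * (P_start - P_end).
Two variants are implemented:

* fixed asymptote (default 0 mmHg at the function level): tau is the
  integral divided by the pressure drop, exact when the true asymptote
  matches;
* ``asymptote="fit"``: the same area identity applied on the running
  integral. Writing S(t) = integral of P from the window start, the
  exponential satisfies P(t) = P(0) + (a/tau) t - (1/tau) S(t) for every t,
  so an ordinary least-squares fit of P on [1, t, S] recovers 1/tau (and
  the asymptote) without assuming it. Exact for a noise-free exponential
  with any asymptote -- but the joint (tau, asymptote) problem is poorly
  identified when tau exceeds the length of the diastolic window, so under
  measurement noise this variant can be very imprecise. The known-asymptote
  variant is therefore the default throughout.

The diastolic window starts a short guard (default 40 ms) after the notch
and stops a tail guard (default 100 ms) before cycle end: the zero-phase
conditioning filters ring over roughly 1/cutoff = 100 ms around the notch
shoulder and the next beat's foot, and both guards keep that ringing out of
the integral and its endpoint pressures.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Union

import numpy as np
from scipy import signal as _signal

from .beats import EnsembleBeat
from .exceptions import TauUndefinedError, ValidationError

__all__ = [
    "WaveformFeatures",
    "PressureRatios",
    "detect_dicrotic_notch",
    "extract_features",
    "estimate_tau_area",
    "compute_pressure_ratios",
]

#: Pressure drops below this (mmHg) do not support a tau estimate.
MIN_DECAY_MMHG = 0.5
#: Minimum diastolic window length in seconds.
MIN_DIASTOLE_S = 0.1
#: Default guard after the notch before the tau window opens (s).
DEFAULT_TAU_GUARD_S = 0.04
#: Default guard before cycle end closing the tau window (s).
DEFAULT_TAU_TAIL_S = 0.10


@dataclass
class WaveformFeatures:
    """The morphometric panel of one representative beat.

    Pressures in mmHg, durations in seconds, areas in mmHg*s, heart rate in
    beats/min. Duration/area/tau fields are NaN when the dicrotic notch was
    not found (``notch_found`` False); tau alone is NaN when the diastole
    does not decay (see ``flags``).
    """

    sbp: float
    dbp: float
    pp: float
    mbp: float
    inc_bp: float = math.nan
    t_sys: float = math.nan
    t_dia: float = math.nan
    area_total: float = math.nan
    area_sys: float = math.nan
    area_dia: float = math.nan
    tau: float = math.nan
    heart_rate: float = math.nan
    notch_found: bool = True
    flags: List[str] = field(default_factory=list)


@dataclass(frozen=True)
class PressureRatios:
    """ICA-stump / systemic (radial) ratios of like features."""

    sbp_ratio: float
    dbp_ratio: float
    pp_ratio: float
    mbp_ratio: float
    inc_ratio: float


def _foot_and_peak(beat: EnsembleBeat) -> tuple[int, int]:
    rep = beat.representative
    fs = beat.sampling_rate
    # Systolic peak: first look just after the fiducial (one cycle), then
    # global as fallback.
    peak = int(np.argmax(rep))
    if peak == 0:
        raise ValidationError("representative beat has its maximum at the start")
    foot = int(np.argmin(rep[:peak]))
    return foot, peak


def _cycle_end(beat: EnsembleBeat, foot: int) -> int:
    """Last sample index of the cycle starting at ``foot``."""
    rep = beat.representative
    if beat.heart_rate and beat.heart_rate > 0:
        n_cycle = int(round(beat.sampling_rate * 60.0 / beat.heart_rate))
        return min(foot + n_cycle, rep.size - 1)
    return rep.size - 1


def detect_dicrotic_notch(
    beat: EnsembleBeat,
    search_start_s: float = 0.05,
    search_end_frac: float = 0.8,
) -> Optional[int]:
    """Locate the dicrotic notch on the representative beat.

    The search window runs from 50 ms after the systolic peak to 80% of the
    cycle length. Primary rule: the most prominent local pressure minimum in
    the window. Fallback (for morphologies where the incisura appears as a
    shoulder rather than a dip): the most prominent interior maximum of the
    second derivative in the window. Returns the sample index into
    ``beat.representative``, or None when no candidate exists (e.g. a
    featureless monotone decay).
    """
    rep = beat.representative
    foot, peak = _foot_and_peak(beat)
    cend = _cycle_end(beat, foot)
    w0 = peak + int(round(search_start_s * beat.sampling_rate))
    w1 = foot + int(round(search_end_frac * (cend - foot)))
    if w1 - w0 < 3:
        return None
    win = rep[w0 : w1 + 1]
    # A real incisura dip is a few percent of the pulse height; smaller
    # local minima are residual noise on the averaged beat.
    min_prom = max(0.05, 0.02 * float(np.ptp(rep)))

    # Primary: local minimum (classic incisura dip).
    mins, props = _signal.find_peaks(-win, prominence=min_prom)
    if mins.size:
        best = mins[int(np.argmax(props["prominences"]))]
        return w0 + int(best)

    # Fallback: curvature shoulder -- interior peak of the second difference.
    d2 = win[2:] - 2.0 * win[1:-1] + win[:-2]
    if d2.size < 3:
        return None
    peaks, props = _signal.find_peaks(d2, prominence=0.1 * float(np.ptp(d2)))
    if peaks.size == 0:
        return None
    best = peaks[int(np.argmax(props["prominences"]))]
    return w0 + 1 + int(best)


def estimate_tau_area(
    beat: EnsembleBeat,
    notch_index: int,
    asymptote: Union[float, str] = 0.0,
    guard_s: float = DEFAULT_TAU_GUARD_S,
    tail_guard_s: float = DEFAULT_TAU_TAIL_S,
) -> float:
    """Diastolic decay constant tau (s) by the area method.

    Parameters
    ----------
    beat : EnsembleBeat
        Representative beat (any uniformly sampled decay works).
    notch_index : int
        Sample index of the dicrotic notch in the representative beat; the
        integration window opens ``guard_s`` later and closes
        ``tail_guard_s`` before cycle end.
    asymptote : float or "fit"
        Pressure toward which diastole decays. A number gives the one-area
        estimate integral(P - a)/(P_start - P_end); ``"fit"`` eliminates the
        asymptote by regressing the pressure on its own running integral
        (exact for an exponential with any asymptote).

    Raises
    ------
    TauUndefinedError
        Diastolic window shorter than 100 ms, a non-decaying diastole
        (pressure drop < 0.5 mmHg), or (for "fit") area differences
        inconsistent with an exponential decay.
    """
    rep = beat.representative
    fs = beat.sampling_rate
    try:
        foot, _peak = _foot_and_peak(beat)
    except ValidationError:
        foot = 0  # bare decay input (no systolic limb): window from the top
    cend = _cycle_end(beat, foot)
    w0 = int(notch_index) + int(round(guard_s * fs))
    w1 = cend - int(round(tail_guard_s * fs))
    if w1 - w0 < int(round(MIN_DIASTOLE_S * fs)):
        # Keep at least the minimum window by giving the tail guard back
        # before giving up entirely (short cycles at high heart rates).
        w1 = min(cend, w0 + int(round(MIN_DIASTOLE_S * fs)))
    if w1 - w0 < int(round(MIN_DIASTOLE_S * fs)):
        raise TauUndefinedError(
            f"diastolic window of {(w1 - w0) / fs:.3f} s is shorter than "
            f"{MIN_DIASTOLE_S} s"
        )
    p = rep[w0 : w1 + 1]
    dt = 1.0 / fs
    drop = float(p[0] - p[-1])
    if drop < MIN_DECAY_MMHG:
        raise TauUndefinedError(
            f"diastole does not decay (pressure drop {drop:.2f} mmHg "
            f"< {MIN_DECAY_MMHG} mmHg)"
        )

    if isinstance(asymptote, str):
        if asymptote != "fit":
            raise ValidationError(f"unknown asymptote mode {asymptote!r}")
        t = np.arange(p.size) * dt
        s = np.concatenate([[0.0], np.cumsum((p[1:] + p[:-1]) * 0.5 * dt)])
        design = np.column_stack([np.ones_like(t), t, s])
        coef, *_ = np.linalg.lstsq(design, p, rcond=None)
        if not coef[2] < 0:
            raise TauUndefinedError(
                "running-integral fit is not consistent with an exponential decay"
            )
        return -1.0 / float(coef[2])

    a = float(asymptote)
    if p[0] <= a:
        raise TauUndefinedError(
            f"diastole starts at {p[0]:.1f} mmHg, not above the asymptote {a:.1f}"
        )
    area = float(np.trapezoid(p - a, dx=dt))
    return area / drop


def extract_features(
    beat: EnsembleBeat,
    notch_index: Optional[int] = None,
    tau_asymptote: Union[float, str] = 0.0,
    tau_guard_s: float = DEFAULT_TAU_GUARD_S,
    tau_tail_guard_s: float = DEFAULT_TAU_TAIL_S,
) -> WaveformFeatures:
    """Extract the full morphometric panel from a representative beat.

    ``notch_index`` may be precomputed (``detect_dicrotic_notch``) or None,
    in which case detection is attempted here. When no notch is found the
    amplitude features are still returned and the duration/area/tau fields
    are NaN.
    """
    rep = beat.representative
    fs = beat.sampling_rate
    foot, peak = _foot_and_peak(beat)
    cend = _cycle_end(beat, foot)
    cycle = rep[foot : cend + 1]
    period = (cend - foot) / fs
    dt = 1.0 / fs

    sbp = float(np.max(cycle))
    dbp = float(rep[foot])
    feats = WaveformFeatures(
        sbp=sbp,
        dbp=dbp,
        pp=sbp - dbp,
        mbp=float(np.trapezoid(cycle, dx=dt)) / period,
        heart_rate=beat.heart_rate,
    )

    if notch_index is None:
        notch_index = detect_dicrotic_notch(beat)
    if notch_index is None or not (foot < notch_index < cend):
        feats.notch_found = False
        feats.flags.append("notch not found")
        return feats

    notch_index = int(notch_index)
    feats.inc_bp = float(rep[notch_index])
    feats.t_sys = (notch_index - foot) / fs
    feats.t_dia = (cend - notch_index) / fs
    feats.area_sys = float(np.trapezoid(rep[foot : notch_index + 1], dx=dt))
    feats.area_dia = float(np.trapezoid(rep[notch_index : cend + 1], dx=dt))
    feats.area_total = feats.area_sys + feats.area_dia

    try:
        feats.tau = estimate_tau_area(
            beat, notch_index, asymptote=tau_asymptote, guard_s=tau_guard_s,
            tail_guard_s=tau_tail_guard_s,
        )
    except TauUndefinedError as exc:
        feats.flags.append(f"tau undefined: {exc}")
    return feats


def compute_pressure_ratios(
    ica: WaveformFeatures, radial: WaveformFeatures
) -> PressureRatios:
    """Element-wise ICA / systemic ratios for paired same-subject features."""
    pairs = {
        "sbp_ratio": (ica.sbp, radial.sbp),
        "dbp_ratio": (ica.dbp, radial.dbp),
        "pp_ratio": (ica.pp, radial.pp),
        "mbp_ratio": (ica.mbp, radial.mbp),
        "inc_ratio": (ica.inc_bp, radial.inc_bp),
    }
    out = {}
    for name, (num, den) in pairs.items():
        if not den > 0:
            raise ValidationError(
                f"radial denominator for {name} must be positive, got {den}"
            )
        out[name] = float(num) / float(den)
    return PressureRatios(**out)
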