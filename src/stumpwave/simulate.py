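"""Synthetic pressure traces and cohorts with known ground truth.

Beat model
----------
One cardiac cycle of length T = 60/heart_rate is piecewise:

* anacrotic limb: raised-cosine rise from DBP to SBP over
  ``upstroke_fraction`` of the cycle (its second derivative is maximal at
  onset, which pins the detection fiducial analytically);
* systolic descent: a cosine arc from SBP (zero slope at the peak) down to
  the notch pressure at ``notch_fraction`` of the cycle, arriving steeper
  than the diastolic decay that follows -- the slope jumps up at the
  junction, the same end-systolic deceleration shoulder a real incisura
  leaves on the waveform, and the curvature spike it creates is what notch
  detection keys on;
* diastole: exponential decay toward an asymptote with time constant tau
  until cycle end, exactly the two-element Windkessel decay tau = R * C.

With the default ``asymptote=None`` the asymptote is derived per beat so
that the exponential lands exactly on DBP at cycle end: consecutive cycles
are then continuous at every foot and the foot value -- the DBP ground
truth -- equals the ``dbp`` parameter. The derived asymptote may be
negative for fast decays; it is a mathematical anchor, the samples
themselves never fall below DBP. An explicit numeric asymptote (e.g. 0)
instead truncates the exponential at cycle end and resets the next foot to
DBP, which leaves a step at the foot whenever the decay does not reach DBP
within one diastole.

Every published quantity of the morphometric panel (pressures, durations,
areas, mean pressure, tau) has a closed form under this model
(:func:`analytic_features`), so the whole downstream pipeline can be tested
against exact truth.

Traces add white measurement noise, a slow 0.05 Hz sinusoidal baseline
drift, and -- with probability ``artifact_rate`` per beat -- an artifact
beat (the time-reversed clean beat scaled by 0.6, which by construction
correlates far below the 0.95 retention gate with the clean template).

Cohorts
-------
:func:`default_cohort_params` encodes the study conditions: five
circle-of-Willis morphology groups with sizes (12, 12, 31, 18, 5),
group-specific ICA-stump pressure distributions (published group means and
between-subject SDs for DBP and pulse pressure), a shared systemic (radial)
distribution, a decay constant tau drawn from the same distribution in
every group (a true null), a backflow-grade assignment that weakens with
increasing CoW compromise, and a stenosis distribution unrelated to the
waveform parameters.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy import stats as sps

from .cow import CowSegment, SegState, classify_cow
from .exceptions import ValidationError
from .io import Channel, PressureTrace
from .metrics import PressureRatios, WaveformFeatures, compute_pressure_ratios
from .stats import CohortRecord

__all__ = [
    "BeatModelParams",
    "TraceTruth",
    "GroupPressureDist",
    "CohortSimParams",
    "generate_beat",
    "generate_trace",
    "generate_cohort",
    "analytic_features",
    "derived_asymptote",
    "sample_segments_for_group",
    "default_cohort_params",
    "DEFAULT_GROUP_SIZES",
]

#: Frequency of the slow baseline drift (Hz) -- below the beat frequency,
#: above DC, so it stresses foot detection realistically.
DRIFT_FREQ_HZ = 0.05
#: Amplitude scale of artifact beats relative to the clean template.
ARTIFACT_SCALE = 0.6

#: Cohort group sizes of the emulated study (CoW groups 1-5).
DEFAULT_GROUP_SIZES = (12, 12, 31, 18, 5)


@dataclass(frozen=True)
class BeatModelParams:
    """Parameters of the synthetic beat/trace generator.

    Pressures in mmHg, heart rate in beats/min, tau in seconds; fractions
    are of the cycle length. ``asymptote=None`` derives the diastolic
    asymptote for foot continuity (see module docstring); an explicit value
    must satisfy 0 <= asymptote < dbp.
    """

    heart_rate: float = 60.0
    sbp: float = 120.0
    dbp: float = 80.0
    notch_fraction: float = 0.35
    notch_pressure: float = 98.0
    tau: float = 2.0
    asymptote: Optional[float] = None
    upstroke_fraction: float = 0.15
    noise_sd: float = 1.0
    drift_amplitude: float = 2.0
    artifact_rate: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not self.heart_rate > 0:
            raise ValidationError("heart_rate must be > 0")
        if not self.tau > 0:
            raise ValidationError("tau must be > 0")
        if not self.sbp > self.notch_pressure > self.dbp:
            raise ValidationError(
                "pressures must satisfy sbp > notch_pressure > dbp, got "
                f"sbp={self.sbp}, notch_pressure={self.notch_pressure}, "
                f"dbp={self.dbp}"
            )
        if self.asymptote is not None:
            if not self.dbp > self.asymptote >= 0.0:
                raise ValidationError(
                    "explicit asymptote must satisfy dbp > asymptote >= 0, got "
                    f"{self.asymptote}"
                )
        if not 0.0 < self.upstroke_fraction < self.notch_fraction < 1.0:
            raise ValidationError(
                "fractions must satisfy 0 < upstroke_fraction < notch_fraction < 1"
            )
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.drift_amplitude < 0:
            raise ValidationError("drift_amplitude must be >= 0")
        if not 0.0 <= self.artifact_rate < 1.0:
            raise ValidationError("artifact_rate must be in [0, 1)")

    @property
    def period(self) -> float:
        return 60.0 / self.heart_rate


@dataclass
class TraceTruth:
    """Ground truth labels for a generated trace."""

    beat_start_indices: np.ndarray
    notch_indices: np.ndarray
    artifact_flags: np.ndarray
    params: BeatModelParams
    duration: float
    sampling_rate: float

    def __post_init__(self):
        self.beat_start_indices = np.asarray(self.beat_start_indices, dtype=int)
        self.notch_indices = np.asarray(self.notch_indices, dtype=int)
        self.artifact_flags = np.asarray(self.artifact_flags, dtype=bool)
        if np.any(np.diff(self.beat_start_indices) <= 0):
            raise ValidationError("beat_start_indices must be strictly increasing")
        n = self.beat_start_indices.size
        if self.notch_indices.size != n or self.artifact_flags.size != n:
            raise ValidationError(
                "one notch index and one artifact flag per beat required"
            )
        if np.any(self.notch_indices <= self.beat_start_indices):
            raise ValidationError("each notch must fall after its beat foot")

    @property
    def n_beats(self) -> int:
        return self.beat_start_indices.size


#: The descent reaches the notch this many times steeper than the initial
#: diastolic decay slope (bounded by feasibility of the cosine arc).
NOTCH_STEEPNESS = 2.0


def derived_asymptote(params: BeatModelParams) -> float:
    """Asymptote that makes the diastolic exponential land on DBP at cycle end."""
    if params.asymptote is not None:
        return float(params.asymptote)
    t_dia = (1.0 - params.notch_fraction) * params.period
    e = math.exp(-t_dia / params.tau)
    return (params.dbp - params.notch_pressure * e) / (1.0 - e)


def _descent_shape(params: BeatModelParams) -> Tuple[float, float, float]:
    """Cosine-arc descent coefficients (offset C, amplitude D, angular rate w).

    The descent is P(t) = C + D*cos(w*(t - t_up)) with P(t_up) = SBP (zero
    slope at the peak), P(t_notch) = notch pressure, and the notch-approach
    slope pinned to NOTCH_STEEPNESS times the initial diastolic decay slope
    (capped at 90% of the steepest slope the arc can deliver). The phase at
    the notch solves (1 - cos(phi)) / (phi * sin(phi)) = dP / (Td * |m|).
    """
    from scipy.optimize import brentq

    T = params.period
    td = (params.notch_fraction - params.upstroke_fraction) * T
    dp = params.sbp - params.notch_pressure
    a = derived_asymptote(params)
    m_dia = (params.notch_pressure - a) / params.tau  # |initial decay slope|
    m = min(NOTCH_STEEPNESS * m_dia, 1.8 * dp / td)
    ratio = dp / (td * m)  # in (0.5555.., inf) by the cap above

    f = lambda phi: (1.0 - math.cos(phi)) / (phi * math.sin(phi)) - ratio
    phi = brentq(f, 1e-6, math.pi - 1e-9)
    D = dp / (1.0 - math.cos(phi))
    C = params.sbp - D
    w = phi / td
    return C, D, w


def _beat_template(params: BeatModelParams, sampling_rate: float) -> np.ndarray:
    """Noise-free samples of one cycle."""
    T = params.period
    n = int(round(T * sampling_rate))
    if n < 8:
        raise ValidationError("cycle too short for the sampling rate")
    t = np.arange(n) / sampling_rate
    t_up = params.upstroke_fraction * T
    t_n = params.notch_fraction * T
    a = derived_asymptote(params)
    C, D, w = _descent_shape(params)

    p = np.empty(n)
    up = t < t_up
    p[up] = params.dbp + (params.sbp - params.dbp) * 0.5 * (
        1.0 - np.cos(np.pi * t[up] / t_up)
    )
    desc = (t >= t_up) & (t < t_n)
    p[desc] = C + D * np.cos(w * (t[desc] - t_up))
    dia = t >= t_n
    p[dia] = a + (params.notch_pressure - a) * np.exp(-(t[dia] - t_n) / params.tau)
    return p


def generate_beat(params: BeatModelParams, sampling_rate: float) -> np.ndarray:
    """Pressure samples for a single cycle (noise added when noise_sd > 0)."""
    if not sampling_rate > 0:
        raise ValidationError("sampling_rate must be > 0")
    p = _beat_template(params, sampling_rate)
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        p = p + rng.normal(0.0, params.noise_sd, p.size)
    return p


def _artifact_template(template: np.ndarray) -> np.ndarray:
    """Artifact morphology: time-reversed clean beat, scaled by 0.6.

    The amplitude scaling is taken about the beat's mean pressure so the
    artifact stays in the physiological range and joins its neighbours
    without large steps; time reversal guarantees a correlation with the
    clean template far below the 0.95 retention gate (affine rescaling does
    not change the correlation coefficient).
    """
    m = float(np.mean(template))
    return m + ARTIFACT_SCALE * (template[::-1] - m)


def generate_trace(
    params: BeatModelParams,
    duration: float = 60.0,
    sampling_rate: float = 100.0,
    channel: Channel = Channel.ICA_STUMP,
    subject_id: str = "",
) -> Tuple[PressureTrace, TraceTruth]:
    """Concatenated beats with noise, drift and artifact beats.

    Ground truth (every foot, notch and artifact flag) is returned
    alongside. Identical seeds give bitwise-identical output.
    """
    if not sampling_rate > 0:
        raise ValidationError("sampling_rate must be > 0")
    if duration <= params.period:
        raise ValidationError(
            f"duration {duration} s must exceed one cycle ({params.period:.2f} s)"
        )
    rng = np.random.default_rng(params.seed)
    template = _beat_template(params, sampling_rate)
    artifact = _artifact_template(template)
    n_beat = template.size
    notch_offset = int(round(params.notch_fraction * params.period * sampling_rate))

    n_total = int(round(duration * sampling_rate))
    out = np.empty(n_total)
    feet, notches, flags = [], [], []
    idx = 0
    while idx < n_total:
        is_artifact = bool(rng.random() < params.artifact_rate)
        beat = artifact if is_artifact else template
        end = min(idx + n_beat, n_total)
        out[idx:end] = beat[: end - idx]
        notch = idx + notch_offset
        if notch < n_total:
            feet.append(idx)
            notches.append(notch)
            flags.append(is_artifact)
        idx += n_beat

    t = np.arange(n_total) / sampling_rate
    if params.drift_amplitude > 0:
        out = out + params.drift_amplitude * np.sin(2.0 * np.pi * DRIFT_FREQ_HZ * t)
    if params.noise_sd > 0:
        out = out + rng.normal(0.0, params.noise_sd, n_total)

    trace = PressureTrace(
        samples=out,
        sampling_rate=float(sampling_rate),
        channel=channel,
        subject_id=subject_id,
    )
    truth = TraceTruth(
        beat_start_indices=np.array(feet),
        notch_indices=np.array(notches),
        artifact_flags=np.array(flags),
        params=params,
        duration=float(duration),
        sampling_rate=float(sampling_rate),
    )
    return trace, truth


def analytic_features(params: BeatModelParams) -> WaveformFeatures:
    """Closed-form morphometric panel of the noise-free beat model.

    Serves both as the feature generator for pre-drawn cohorts and as the
    exact oracle the measurement pipeline is tested against.
    """
    T = params.period
    t_up = params.upstroke_fraction * T
    t_n = params.notch_fraction * T
    t_dia = T - t_n
    a = derived_asymptote(params)
    e = math.exp(-t_dia / params.tau)
    p_end = a + (params.notch_pressure - a) * e

    # The upstroke is a full half-period raised cosine, so it integrates to
    # its endpoint mean; the descent arc has a closed-form integral.
    area_up = t_up * (params.dbp + params.sbp) / 2.0
    C, D, w = _descent_shape(params)
    phi = w * (t_n - t_up)
    area_desc = C * (t_n - t_up) + D * math.sin(phi) / w
    area_sys = area_up + area_desc
    area_dia = a * t_dia + params.tau * (params.notch_pressure - p_end)
    area_total = area_sys + area_dia

    return WaveformFeatures(
        sbp=params.sbp,
        dbp=params.dbp,
        pp=params.sbp - params.dbp,
        mbp=area_total / T,
        inc_bp=params.notch_pressure,
        t_sys=t_n,
        t_dia=t_dia,
        area_total=area_total,
        area_sys=area_sys,
        area_dia=area_dia,
        tau=params.tau,
        heart_rate=params.heart_rate,
    )


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupPressureDist:
    """Between-subject distribution of beat parameters for one channel/group.

    DBP and pulse pressure are truncated normals (DBP >= 15 mmHg, PP >= 2
    mmHg -- weak stump pulsation can genuinely be a few mmHg); SBP is their
    sum. The notch (end-systolic) pressure sits ``notch_rel`` of the way up
    the pulse pressure. Heart rate is truncated to 40-120 beats/min and tau
    to at least 0.3 s.
    """

    dbp_mean: float
    dbp_sd: float
    pp_mean: float
    pp_sd: float
    hr_mean: float = 68.0
    hr_sd: float = 13.0
    tau_mean: float = 2.0
    tau_sd: float = 0.3
    notch_rel_mean: float = 0.47
    notch_rel_sd: float = 0.03
    upstroke_fraction: float = 0.15
    notch_fraction: float = 0.35

    DBP_MIN = 15.0
    PP_MIN = 2.0
    HR_MIN, HR_MAX = 40.0, 120.0
    TAU_MIN = 0.3

    def _trunc(self, rng, mean, sd, lo, hi=np.inf):
        a, b = (lo - mean) / sd, (hi - mean) / sd
        return float(sps.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))

    def draw(self, rng: np.random.Generator, heart_rate: Optional[float] = None) -> dict:
        """Draw one subject's beat parameters (dict of scalars)."""
        dbp = self._trunc(rng, self.dbp_mean, self.dbp_sd, self.DBP_MIN)
        pp = self._trunc(rng, self.pp_mean, self.pp_sd, self.PP_MIN)
        if heart_rate is None:
            heart_rate = self._trunc(rng, self.hr_mean, self.hr_sd, self.HR_MIN, self.HR_MAX)
        tau = self._trunc(rng, self.tau_mean, self.tau_sd, self.TAU_MIN)
        notch_rel = float(np.clip(rng.normal(self.notch_rel_mean, self.notch_rel_sd),
                                  0.25, 0.70))
        return {
            "heart_rate": heart_rate,
            "dbp": dbp,
            "sbp": dbp + pp,
            "notch_pressure": dbp + notch_rel * pp,
            "tau": tau,
            "notch_fraction": self.notch_fraction,
            "upstroke_fraction": self.upstroke_fraction,
        }

    def expected_sbp_mean(self) -> float:
        """Exact mean of the drawn SBP (sum of the two truncated normals)."""
        def tmean(mean, sd, lo):
            a = (lo - mean) / sd
            return float(sps.truncnorm.mean(a, np.inf, loc=mean, scale=sd))

        return tmean(self.dbp_mean, self.dbp_sd, self.DBP_MIN) + tmean(
            self.pp_mean, self.pp_sd, self.PP_MIN
        )


@dataclass(frozen=True)
class CohortSimParams:
    """Cohort simulator configuration (defaults: the emulated study)."""

    group_sizes: Tuple[int, ...] = DEFAULT_GROUP_SIZES
    ica_groups: Tuple[GroupPressureDist, ...] = ()
    radial: GroupPressureDist = None  # type: ignore[assignment]
    backflow_probs: Tuple[Tuple[float, float, float], ...] = (
        (0.00, 0.10, 0.90),
        (0.05, 0.15, 0.80),
        (0.05, 0.30, 0.65),
        (0.15, 0.45, 0.40),
        (0.50, 0.30, 0.20),
    )
    stenosis_mean: float = 30.0
    stenosis_sd: float = 25.0
    mode: str = "features"
    noise_sd: float = 1.0
    drift_amplitude: float = 2.0
    artifact_rate: float = 0.05
    duration: float = 60.0
    sampling_rate: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if len(self.group_sizes) != 5:
            raise ValidationError("group_sizes must have 5 entries (CoW 1-5)")
        if any(n < 0 for n in self.group_sizes):
            raise ValidationError("group sizes must be >= 0")
        if self.ica_groups and len(self.ica_groups) != 5:
            raise ValidationError("ica_groups must have 5 entries")
        if len(self.backflow_probs) != 5:
            raise ValidationError("backflow_probs must have 5 rows")
        for row in self.backflow_probs:
            if len(row) != 3 or any(p < 0 for p in row) or abs(sum(row) - 1.0) > 1e-9:
                raise ValidationError(
                    "each backflow distribution must be 3 probabilities summing to 1"
                )
        if self.mode not in ("features", "traces"):
            raise ValidationError("mode must be 'features' or 'traces'")


#: ICA-stump DBP and pulse-pressure group means/SDs (mmHg) and per-group
#: heart rates (beats/min) of the emulated cohort; tau is identical across
#: groups by construction (the decay-constant null).
_ICA_GROUP_TABLE = (
    # (dbp_mean, dbp_sd, pp_mean, pp_sd, hr_mean, hr_sd)
    (51.5, 10.6, 23.4, 15.1, 63.4, 15.0),
    (50.7, 19.0, 27.7, 15.3, 66.0, 17.5),
    (40.7, 10.8, 18.9, 11.4, 70.2, 12.4),
    (38.9, 10.2, 12.2, 8.2, 70.3, 12.0),
    (35.0, 15.9, 11.7, 9.9, 68.4, 12.8),
)


def default_cohort_params(**overrides) -> CohortSimParams:
    """The study conditions: group structure and pressure distributions."""
    ica = tuple(
        GroupPressureDist(
            dbp_mean=d, dbp_sd=dsd, pp_mean=p, pp_sd=psd, hr_mean=h, hr_sd=hsd,
            tau_mean=2.0, tau_sd=0.3, notch_rel_mean=0.47,
        )
        for d, dsd, p, psd, h, hsd in _ICA_GROUP_TABLE
    )
    radial = GroupPressureDist(
        dbp_mean=62.0, dbp_sd=15.0, pp_mean=71.0, pp_sd=19.0,
        tau_mean=1.2, tau_sd=0.2, notch_rel_mean=0.37,
    )
    base = dict(ica_groups=ica, radial=radial)
    base.update(overrides)
    return CohortSimParams(**base)


def sample_segments_for_group(group: int, rng: np.random.Generator) -> dict:
    """Draw a random segment-state configuration classifying to ``group``."""
    anterior = [CowSegment.A1_CONTRA, CowSegment.ACOM, CowSegment.A1_IPSI]
    posterior = [
        CowSegment.P1_IPSI,
        CowSegment.PCOM_IPSI,
        CowSegment.P1_CONTRA,
        CowSegment.PCOM_CONTRA,
    ]
    post_ipsi = [CowSegment.P1_IPSI, CowSegment.PCOM_IPSI]
    for _ in range(100):
        states = {s: SegState.NORMAL for s in CowSegment}
        if group == 2:
            seg = anterior[rng.integers(len(anterior))]
            states[seg] = (SegState.HYPOPLASTIC, SegState.ABSENT)[rng.integers(2)]
        elif group == 3:
            seg = posterior[rng.integers(len(posterior))]
            states[seg] = (SegState.HYPOPLASTIC, SegState.ABSENT)[rng.integers(2)]
        elif group == 4:
            a_state, p_state = (
                (SegState.HYPOPLASTIC, SegState.HYPOPLASTIC),
                (SegState.HYPOPLASTIC, SegState.ABSENT),
                (SegState.ABSENT, SegState.HYPOPLASTIC),
            )[rng.integers(3)]
            states[anterior[rng.integers(len(anterior))]] = a_state
            states[posterior[rng.integers(len(posterior))]] = p_state
        elif group == 5:
            states[anterior[rng.integers(len(anterior))]] = SegState.ABSENT
            states[post_ipsi[rng.integers(len(post_ipsi))]] = SegState.ABSENT
        if classify_cow(states) == group:
            return states
    raise RuntimeError(f"could not sample a configuration for group {group}")


def generate_cohort(params: Optional[CohortSimParams] = None) -> List[CohortRecord]:
    """Generate one cohort of :class:`CohortRecord`.

    ``mode="features"`` draws per-subject beat parameters and fills the
    feature panels with their closed forms; ``mode="traces"`` additionally
    synthesizes the raw paired pressure recordings for each subject so the
    full measurement pipeline can be exercised. Reproducible under seed.
    """
    params = params or default_cohort_params()
    if not params.ica_groups or params.radial is None:
        params = default_cohort_params(
            **{
                k: getattr(params, k)
                for k in (
                    "group_sizes", "backflow_probs", "stenosis_mean", "stenosis_sd",
                    "mode", "noise_sd", "drift_amplitude", "artifact_rate",
                    "duration", "sampling_rate", "seed",
                )
            }
        )
    if sum(params.group_sizes) == 0:
        raise ValidationError("all group sizes are zero")

    rng = np.random.default_rng(params.seed)
    records: List[CohortRecord] = []
    counter = 0
    for g, n_g in enumerate(params.group_sizes, start=1):
        dist = params.ica_groups[g - 1]
        for _ in range(n_g):
            counter += 1
            sid = f"subj{counter:03d}"
            ica_draw = dist.draw(rng)
            radial_draw = params.radial.draw(rng, heart_rate=ica_draw["heart_rate"])

            common = dict(
                noise_sd=params.noise_sd,
                drift_amplitude=params.drift_amplitude,
                artifact_rate=params.artifact_rate,
            )
            p_ica = BeatModelParams(
                seed=int(rng.integers(2**31)), **ica_draw, **common
            )
            p_rad = BeatModelParams(
                seed=int(rng.integers(2**31)), **radial_draw, **common
            )

            ica_feats = analytic_features(p_ica)
            rad_feats = analytic_features(p_rad)
            backflow = int(rng.choice([1, 2, 3], p=params.backflow_probs[g - 1]))
            stenosis = float(
                np.clip(rng.normal(params.stenosis_mean, params.stenosis_sd), 0.0, 95.0)
            )
            segments = sample_segments_for_group(g, rng)

            rec = CohortRecord(
                subject_id=sid,
                cow_group=g,
                backflow_grade=backflow,
                contralateral_stenosis=stenosis,
                ica_features=ica_feats,
                radial_features=rad_feats,
                ratios=compute_pressure_ratios(ica_feats, rad_feats),
                cow_segments=segments,
            )
            if params.mode == "traces":
                rec.ica_trace, _ = generate_trace(
                    p_ica, params.duration, params.sampling_rate,
                    channel=Channel.ICA_STUMP, subject_id=sid,
                )
                rec.radial_trace, _ = generate_trace(
                    p_rad, params.duration, params.sampling_rate,
                    channel=Channel.RADIAL, subject_id=sid,
                )
            records.append(rec)
    return records
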