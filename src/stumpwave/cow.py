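"""Rule-based classification of circle-of-Willis (CoW) morphology.

The circle of Willis is scored from seven segments read off CT angiography:
the anterior communicating artery (A-com), the first segments of both
anterior cerebral arteries (A1), both posterior communicating arteries
(P-com) and the first segments of both posterior cerebral arteries (P1).
Laterality is expressed relative to the operated side. A segment is NORMAL
when its diameter is 0.8 mm or greater, HYPOPLASTIC when visible but
narrower, and ABSENT when not visualized.

Subjects fall into five morphology groups of increasing collateral
compromise:

1. complete circle — every segment normal;
2. compromised anterior semicircle only;
3. compromised posterior semicircle only;
4. both semicircles compromised;
5. isolated middle cerebral artery (MCA) — ABSENT segments interrupt every
   anterior collateral path (contralateral A1 -> A-com -> ipsilateral A1)
   and the ipsilateral posterior path (P1 -> P-com), so the operated-side
   MCA receives no primary collateral flow from the contralateral internal
   carotid or the vertebrobasilar system.

Group 5 takes precedence over group 4 (it is the extreme of group 4: any
isolated-MCA configuration also has both semicircles compromised).
"""
from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Optional

from .exceptions import ValidationError

__all__ = [
    "CowSegment",
    "SegState",
    "Side",
    "ANTERIOR_SEGMENTS",
    "POSTERIOR_SEGMENTS",
    "CowClassification",
    "state_from_diameter",
    "classify_cow",
    "classify_cow_detailed",
]

#: Diameter threshold (mm) separating normal from hypoplastic segments.
NORMAL_DIAMETER_MM = 0.8


class CowSegment(str, enum.Enum):
    """The seven CoW segments, sided relative to the operated hemisphere."""

    ACOM = "ACOM"
    A1_IPSI = "A1_IPSI"
    A1_CONTRA = "A1_CONTRA"
    PCOM_IPSI = "PCOM_IPSI"
    PCOM_CONTRA = "PCOM_CONTRA"
    P1_IPSI = "P1_IPSI"
    P1_CONTRA = "P1_CONTRA"


class SegState(str, enum.Enum):
    NORMAL = "NORMAL"
    HYPOPLASTIC = "HYPOPLASTIC"
    ABSENT = "ABSENT"


class Side(str, enum.Enum):
    LEFT = "LEFT"
    RIGHT = "RIGHT"


#: Anterior semicircle: contralateral A1, A-com, ipsilateral A1.
ANTERIOR_SEGMENTS = (CowSegment.A1_CONTRA, CowSegment.ACOM, CowSegment.A1_IPSI)
#: Posterior semicircle: P1 and P-com on each side.
POSTERIOR_SEGMENTS = (
    CowSegment.P1_IPSI,
    CowSegment.PCOM_IPSI,
    CowSegment.P1_CONTRA,
    CowSegment.PCOM_CONTRA,
)
#: The ipsilateral vertebrobasilar route to the operated MCA.
POSTERIOR_IPSI_PATH = (CowSegment.P1_IPSI, CowSegment.PCOM_IPSI)


def state_from_diameter(diameter_mm: Optional[float]) -> SegState:
    """Map a measured segment diameter to its categorical state.

    ``None`` means the segment was not visualized (ABSENT); a diameter of
    0.8 mm or greater is NORMAL, anything smaller but visible HYPOPLASTIC.
    """
    if diameter_mm is None:
        return SegState.ABSENT
    if diameter_mm < 0:
        raise ValidationError(f"diameter must be >= 0 mm, got {diameter_mm}")
    if diameter_mm >= NORMAL_DIAMETER_MM:
        return SegState.NORMAL
    if diameter_mm > 0:
        return SegState.HYPOPLASTIC
    return SegState.ABSENT


@dataclass(frozen=True)
class CowClassification:
    """Detailed classifier output.

    Attributes
    ----------
    group : int
        Morphology group 1-5.
    anterior_compromised, posterior_compromised : bool
        Any non-normal segment in the respective semicircle.
    multi_segment : bool
        More than one non-normal segment inside a single semicircle for
        groups 2/3 (the grouping scheme has no finer category; flagged for
        transparency).
    ambiguous_pair : bool
        Both semicircles compromised exclusively by ABSENT segments without
        meeting the isolated-MCA path-interruption test; labelled group 4 as
        the catch-all, flagged because the published rule list enumerates
        only pairs involving a hypoplastic segment.
    """

    group: int
    anterior_compromised: bool
    posterior_compromised: bool
    multi_segment: bool = False
    ambiguous_pair: bool = False


def _validate_segments(segments: Mapping) -> dict:
    states = {}
    for seg in CowSegment:
        key = seg
        if seg not in segments and seg.value in segments:
            key = seg.value
        if key not in segments:
            raise ValidationError(f"missing state for CoW segment {seg.value}")
        raw = segments[key]
        states[seg] = SegState(raw)
    return states


def classify_cow_detailed(
    segments: Mapping, operated_side: Side | str | None = None
) -> CowClassification:
    """Classify a full set of 7 segment states into CoW groups 1-5.

    ``segments`` maps :class:`CowSegment` (or its string value) to a
    :class:`SegState` (or its string value). ``operated_side`` is accepted
    for bookkeeping; segment labels are already expressed relative to the
    operated side so it does not enter the rules.
    """
    states = _validate_segments(segments)

    ant_states = [states[s] for s in ANTERIOR_SEGMENTS]
    post_states = [states[s] for s in POSTERIOR_SEGMENTS]
    ant_comp = any(s is not SegState.NORMAL for s in ant_states)
    post_comp = any(s is not SegState.NORMAL for s in post_states)

    # Isolated MCA: the anterior chain is a series path, so a single ABSENT
    # anterior segment interrupts it; likewise for the ipsilateral P1->P-com
    # route from the vertebrobasilar system.
    ant_interrupted = any(states[s] is SegState.ABSENT for s in ANTERIOR_SEGMENTS)
    post_ipsi_interrupted = any(
        states[s] is SegState.ABSENT for s in POSTERIOR_IPSI_PATH
    )

    multi = (
        sum(s is not SegState.NORMAL for s in ant_states) > 1 and not post_comp
    ) or (sum(s is not SegState.NORMAL for s in post_states) > 1 and not ant_comp)

    if ant_interrupted and post_ipsi_interrupted:
        return CowClassification(5, ant_comp, post_comp)
    if ant_comp and post_comp:
        ant_has_hypo = any(s is SegState.HYPOPLASTIC for s in ant_states)
        post_has_hypo = any(s is SegState.HYPOPLASTIC for s in post_states)
        ambiguous = not (ant_has_hypo or post_has_hypo)
        return CowClassification(4, True, True, ambiguous_pair=ambiguous)
    if ant_comp:
        return CowClassification(2, True, False, multi_segment=multi)
    if post_comp:
        return CowClassification(3, False, True, multi_segment=multi)
    return CowClassification(1, False, False)


def classify_cow(segments: Mapping, operated_side: Side | str | None = None) -> int:
    """Return the CoW morphology group (1-5) for a set of segment states."""
    return classify_cow_detailed(segments, operated_side).group
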