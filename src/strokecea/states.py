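"""Health-state enumeration shared by the decision tree and the Markov engine."""

from __future__ import annotations

from enum import IntEnum

__all__ = ["HealthState", "N_STATES", "ALIVE_STATES", "NO_MAJOR_STATES"]


class HealthState(IntEnum):
    """The seven health states of the long-term outcome model.

    ``*_Y1`` states are one-cycle tunnel states encoding the elevated
    major-stroke risk in the first year after the index minor stroke;
    ``*_POST`` states carry the lower later-year risks.  ``DEAD`` is
    absorbing.
    """

    WELL = 0
    UNDETECTED_Y1 = 1
    UNDETECTED_POST = 2
    DETECTED_Y1 = 3
    DETECTED_POST = 4
    POST_MAJOR = 5
    DEAD = 6


N_STATES = len(HealthState)

ALIVE_STATES = (
    HealthState.WELL,
    HealthState.UNDETECTED_Y1,
    HealthState.UNDETECTED_POST,
    HealthState.DETECTED_Y1,
    HealthState.DETECTED_POST,
    HealthState.POST_MAJOR,
)

#: Alive states without a prior major stroke (full utility; no yearly
#: post-major care costs).
NO_MAJOR_STATES = (
    HealthState.WELL,
    HealthState.UNDETECTED_Y1,
    HealthState.UNDETECTED_POST,
    HealthState.DETECTED_Y1,
    HealthState.DETECTED_POST,
)
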