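"""Test-phase vocabulary for the instrumented Timed-Up-and-Go assessment."""

from __future__ import annotations

from enum import IntEnum


class PhaseLabel(IntEnum):
    """The six per-timestamp activity categories of the segmenter.

    Codes are stable: they index the segmenter's softmax output and break
    majority-vote ties (lowest code wins).
    """

    BALANCE = 0
    WALK = 1
    TURN_AND_SIT = 2
    SIT = 3
    GET_UP = 4
    NOISE = 5


N_PHASES = len(PhaseLabel)

#: Scripted order of the modified TUG test as generated and segmented.
SCRIPTED_ORDER = (
    PhaseLabel.BALANCE,
    PhaseLabel.WALK,
    PhaseLabel.TURN_AND_SIT,
    PhaseLabel.SIT,
    PhaseLabel.GET_UP,
    PhaseLabel.WALK,
)
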