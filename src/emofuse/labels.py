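"""Label spaces shared by both recognition channels.

Four emotion states (regions of valence-arousal space) and three emotion
intensity levels. The integer codes are part of the on-disk contract:
state codes 1..4 and intensity codes -1/0/+1 appear verbatim in label CSVs
and serialized models.
"""

from __future__ import annotations

from enum import IntEnum


class EmotionState(IntEnum):
    """Emotion state label; the code order fixes score-vector ordering."""

    HAPPINESS = 1
    NEUTRAL = 2
    SADNESS = 3
    FEAR = 4


class IntensityLevel(IntEnum):
    """Emotion intensity label, predicted from the EEG channel only."""

    WEAK = -1
    MODERATE = 0
    STRONG = 1


#: Canonical orderings: index into a score vector <-> label.
STATE_ORDER: tuple[EmotionState, ...] = (
    EmotionState.HAPPINESS,
    EmotionState.NEUTRAL,
    EmotionState.SADNESS,
    EmotionState.FEAR,
)
INTENSITY_ORDER: tuple[IntensityLevel, ...] = (
    IntensityLevel.WEAK,
    IntensityLevel.MODERATE,
    IntensityLevel.STRONG,
)

N_STATES = len(STATE_ORDER)
N_INTENSITIES = len(INTENSITY_ORDER)


def state_from_index(i: int) -> EmotionState:
    return STATE_ORDER[i]


def intensity_from_index(i: int) -> IntensityLevel:
    return INTENSITY_ORDER[i]


def parse_state(token: "str | int | EmotionState") -> EmotionState:
    """Accept a state name ('happiness') or code (1..4)."""
    if isinstance(token, EmotionState):
        return token
    if isinstance(token, str) and not token.lstrip("-").isdigit():
        return EmotionState[token.strip().upper()]
    return EmotionState(int(token))


def parse_intensity(token: "str | int | IntensityLevel") -> IntensityLevel:
    """Accept an intensity name ('weak') or code (-1/0/1)."""
    if isinstance(token, IntensityLevel):
        return token
    if isinstance(token, str) and not token.lstrip("-").isdigit():
        return IntensityLevel[token.strip().upper()]
    return IntensityLevel(int(token))
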