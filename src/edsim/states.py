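"""Core state and sex enumerations shared across the package.

The disease process is a six-state annual-cycle Markov model: a healthy
state, four eating-disorder (ED) states — anorexia nervosa (AN), bulimia
nervosa (BN), binge-eating disorder (BED) and other specified feeding and
eating disorders (OSFED) — and an absorbing deceased state.
"""

from __future__ import annotations

from enum import IntEnum

#: number of transition ages; persons are followed from birth (age 0)
#: through the transition out of age 39, i.e. state arrays span ages 0..40.
N_AGES = 40


class EDState(IntEnum):
    """Model states. Integer codes double as kernel state codes."""

    HEALTHY = 0
    AN = 1
    BN = 2
    BED = 3
    OSFED = 4
    DECEASED = 5

    @property
    def is_ed(self) -> bool:
        return self in ED_STATES


class Sex(IntEnum):
    MALE = 0
    FEMALE = 1


#: the four ED states, in kernel index order (state code == index + 1)
ED_STATES = (EDState.AN, EDState.BN, EDState.BED, EDState.OSFED)

#: kernel array index of each ED state
ED_INDEX = {ed: ed.value - 1 for ed in ED_STATES}

SEXES = (Sex.MALE, Sex.FEMALE)

_SEX_LABEL = {Sex.MALE: "M", Sex.FEMALE: "F"}
_LABEL_SEX = {"M": Sex.MALE, "F": Sex.FEMALE,
              "MALE": Sex.MALE, "FEMALE": Sex.FEMALE}
_LABEL_ED = {ed.name: ed for ed in ED_STATES}


def sex_label(sex: Sex) -> str:
    return _SEX_LABEL[Sex(sex)]


def parse_sex(label: str | Sex) -> Sex:
    if isinstance(label, Sex):
        return label
    try:
        return _LABEL_SEX[str(label).strip().upper()]
    except KeyError:
        raise ValueError(f"unknown sex label: {label!r}") from None


def parse_ed(label: str | EDState) -> EDState:
    if isinstance(label, EDState):
        return label
    try:
        return _LABEL_ED[str(label).strip().upper()]
    except KeyError:
        raise ValueError(f"unknown ED label: {label!r}") from None


def is_any_ed(state: int) -> bool:
    """Membership in {AN, BN, BED, OSFED}."""
    return 1 <= int(state) <= 4
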