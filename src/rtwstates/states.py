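"""Six-state space for work-participation trajectories.

States follow the sickness-absence multistate model: individuals enter in
full-time sickness absence (FSA) and may move repeatedly between FSA, graded
sickness absence (GSA), work, non-employment and education; death is absorbing.
States are represented internally as small integer codes; CSV output uses the
short names.
"""

from __future__ import annotations

FSA, GSA, WORK, NONEMP, EDU, DEATH = range(6)

STATE_NAMES: tuple[str, ...] = ("FSA", "GSA", "WORK", "NONEMP", "EDU", "DEATH")
STATE_INDEX: dict[str, int] = {name: i for i, name in enumerate(STATE_NAMES)}

N_STATES = 6
TRANSIENT: tuple[int, ...] = (FSA, GSA, WORK, NONEMP, EDU)

#: ``to_state`` code for a censored final episode in counting-process records.
CENSORED = -1
CENSORED_LABEL = "CENSORED"


def state_label(code: int) -> str:
    return CENSORED_LABEL if code == CENSORED else STATE_NAMES[code]


def state_code(label: str) -> int:
    if label == CENSORED_LABEL:
        return CENSORED
    return STATE_INDEX[label]
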