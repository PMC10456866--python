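"""Markov health states for the PAH model.

Disease severity is graded by WHO functional class (FC I-IV, an adaptation
of the NYHA classification); death is the single absorbing state.
"""

from enum import IntEnum


class HealthState(IntEnum):
    """The five mutually exclusive Markov states, ordered by severity."""

    FC1 = 0
    FC2 = 1
    FC3 = 2
    FC4 = 3
    DEATH = 4


#: The four alive states, in model order.
FC_STATES = (HealthState.FC1, HealthState.FC2, HealthState.FC3, HealthState.FC4)

#: Column labels used by trace writers and summaries.
STATE_LABELS = ("FC1", "FC2", "FC3", "FC4", "DEATH")

N_STATES = len(STATE_LABELS)
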