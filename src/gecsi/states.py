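"""Chromatin-state alphabets and biologically motivated state groupings.

The default alphabet is the Roadmap Epigenomics 18-state ChromHMM model,
whose labels ("1_TssA" ... "18_Quies") are the prediction target throughout
this package. States are referred to internally by 0-based integer codes;
the label ``alphabet[code]`` is the external name.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The 18-state Roadmap ChromHMM alphabet, in model order.
DEFAULT_STATE_ALPHABET: tuple[str, ...] = (
    "1_TssA",
    "2_TssFlnk",
    "3_TssFlnkU",
    "4_TssFlnkD",
    "5_Tx",
    "6_TxWk",
    "7_EnhG1",
    "8_EnhG2",
    "9_EnhA1",
    "10_EnhA2",
    "11_EnhWk",
    "12_ZNF/Rpts",
    "13_Het",
    "14_TssBiv",
    "15_EnhBiv",
    "16_ReprPC",
    "17_ReprPCWk",
    "18_Quies",
)

#: Seven interpretive groups over the 18-state alphabet: TSS-related,
#: transcription, enhancer, H3K9me3-associated, bivalent, Polycomb-repressed,
#: and quiescent.  Keys are group names, values are 0-based state codes.
DEFAULT_STATE_GROUPS: dict[str, tuple[int, ...]] = {
    "TSS": (0, 1, 2, 3),
    "Transcription": (4, 5),
    "Enhancer": (6, 7, 8, 9, 10),
    "H3K9me3": (11, 12),
    "Bivalent": (13, 14),
    "Polycomb": (15, 16),
    "Quiescent": (17,),
}


@dataclass(frozen=True)
class StateGrouping:
    """A partition of a state alphabet into named interpretive groups.

    Parameters
    ----------
    groups
        Mapping of group name to the tuple of 0-based state codes it
        contains.  The groups must partition ``range(n_states)``.
    n_states
        Size of the state alphabet being partitioned.
    """

    groups: dict[str, tuple[int, ...]] = field(
        default_factory=lambda: dict(DEFAULT_STATE_GROUPS)
    )
    n_states: int = 18

    def __post_init__(self) -> None:
        seen = [s for members in self.groups.values() for s in members]
        if sorted(seen) != list(range(self.n_states)):
            raise ValueError(
                "state groups must partition the alphabet "
                f"(got codes {sorted(seen)} for {self.n_states} states)"
            )

    @property
    def group_of(self) -> np.ndarray:
        """Array mapping state code -> integer group id."""
        out = np.empty(self.n_states, dtype=np.int64)
        for gid, members in enumerate(self.groups.values()):
            for s in members:
                out[s] = gid
        return out

    def group_name(self, state: int) -> str:
        for name, members in self.groups.items():
            if state in members:
                return name
        raise KeyError(state)
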