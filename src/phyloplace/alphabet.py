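"""Amino-acid alphabet shared by every module.

Residues are indexed in the conventional order A R N D C Q E G H I L K M
F P S T W Y V (the order used by published empirical replacement
matrices).  Gap '-', unknown 'X' and stop '*' are treated as missing
data: they carry no information about the state at a tip.
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
N_STATES = 20
MISSING_CHARS = frozenset("-X*?.")

AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: -1 marks missing data.
MISSING = -1


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an amino-acid string as int8 state indices (missing = -1).

    Input is case-insensitive; any residue outside the 20-letter
    alphabet (ambiguity codes such as B/Z/J included) is treated as
    missing, matching the all-ones partial-likelihood convention.
    """
    out = np.full(len(seq), MISSING, dtype=np.int8)
    for i, ch in enumerate(seq.upper()):
        out[i] = AA_INDEX.get(ch, MISSING)
    return out


def decode_states(states: np.ndarray) -> str:
    return "".join(AMINO_ACIDS[s] if s >= 0 else "-" for s in states)
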