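"""Integer encoding of alignment characters.

Twenty standard amino acids are states 0..19 (alphabetical one-letter
order); the gap is the 21st state (index 20). Any character that is not
a standard residue — 'X', ambiguity codes, '.', '*' — is folded into the
gap state, so it never contributes a spurious amino-acid category to the
frequency tables.
"""
from __future__ import annotations

import numpy as np

AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"
GAP_STATE = 20
N_STATES = 21

_CODE = np.full(256, GAP_STATE, dtype=np.uint8)
for _i, _a in enumerate(AA_LETTERS):
    _CODE[ord(_a)] = _i
    _CODE[ord(_a.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Encode a (gapped) sequence string as uint8 states 0..20."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_rows(rows: list[str]) -> np.ndarray:
    """Encode equal-length strings into an (n_rows, n_cols) uint8 matrix."""
    if not rows:
        return np.zeros((0, 0), dtype=np.uint8)
    return np.vstack([encode(r) for r in rows])
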