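"""Amino-acid alphabets and physicochemical constants.

The twenty canonical residues are the validated vocabulary; the extended
letters (X, B, Z, U, O) are accepted by sequence validation and routed to a
dedicated "unknown" embedding by providers rather than rejected.
"""

from __future__ import annotations

CANONICAL_AA: str = "ACDEFGHIKLMNPQRSTVWY"
EXTENDED_AA: frozenset[str] = frozenset("XBZUO")
VALID_AA: frozenset[str] = frozenset(CANONICAL_AA) | EXTENDED_AA

# Kyte-Doolittle hydrophobic residues (positive hydropathy index).
HYDROPHOBIC_AA: frozenset[str] = frozenset("ACFILMV")

# Complementary electrostatic contact pairs (antibody residue, antigen residue):
# basic paratope residues paired with acidic epitope residues.
COMPLEMENTARY_PAIRS: frozenset[tuple[str, str]] = frozenset(
    {("K", "E"), ("K", "D"), ("R", "E"), ("R", "D")}
)

# MLM token vocabulary: canonical residues, one unknown token, one mask token.
UNK_TOKEN = "X"
MASK_TOKEN = "<mask>"
MLM_VOCAB: tuple[str, ...] = tuple(CANONICAL_AA) + (UNK_TOKEN, MASK_TOKEN)
MLM_TOKEN_INDEX: dict[str, int] = {tok: i for i, tok in enumerate(MLM_VOCAB)}
MASK_TOKEN_ID: int = MLM_TOKEN_INDEX[MASK_TOKEN]


def residue_token_id(residue: str) -> int:
    """Map a residue letter to its MLM vocabulary index (nonstandard -> unknown)."""
    if residue in MLM_TOKEN_INDEX and residue != MASK_TOKEN:
        return MLM_TOKEN_INDEX[residue]
    if residue in EXTENDED_AA:
        return MLM_TOKEN_INDEX[UNK_TOKEN]
    raise ValueError(f"residue {residue!r} is not in the amino-acid vocabulary")
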