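"""Fixed gene vocabulary of the frog mitogenome.

Tokens follow the single-letter tRNA convention used in gene-order
diagrams (L1 = tRNA-Leu(CUN), L2 = tRNA-Leu(UUR), S1 = tRNA-Ser(UCN),
S2 = tRNA-Ser(AGY), O = the short extra non-coding region between
tRNA-Asn and tRNA-Cys).  A signed token carries a leading ``-`` when the
feature lies on the light (L) strand.
"""

from __future__ import annotations

PCGS: tuple[str, ...] = (
    "ND1", "ND2", "COX1", "COX2", "ATP8", "ATP6", "COX3",
    "ND3", "ND4L", "ND4", "ND5", "ND6", "CYTB",
)

TRNAS: tuple[str, ...] = (
    "L1", "T", "P", "F", "V", "L2", "I", "Q", "M", "W", "A",
    "N", "C", "Y", "S1", "D", "K", "G", "R", "H", "S2", "E",
)

RRNAS: tuple[str, ...] = ("12S", "16S")

CR_TOKEN = "CR"
NCR_TOKEN = "O"

#: All 39 tokens that may appear in an annotation / gene order.
ALL_TOKENS: tuple[str, ...] = PCGS + TRNAS + RRNAS + (CR_TOKEN, NCR_TOKEN)

CATEGORIES = ("PCG", "tRNA", "rRNA", "CR", "NCR")

CATEGORY_OF: dict[str, str] = (
    {g: "PCG" for g in PCGS}
    | {t: "tRNA" for t in TRNAS}
    | {r: "rRNA" for r in RRNAS}
    | {CR_TOKEN: "CR", NCR_TOKEN: "NCR"}
)

#: Human-readable labels as printed in annotation tables.
LABEL_OF: dict[str, str] = {
    "L1": "tRNA-Leu(CUN)", "L2": "tRNA-Leu(UUR)",
    "S1": "tRNA-Ser(UCN)", "S2": "tRNA-Ser(AGY)",
    "T": "tRNA-Thr", "P": "tRNA-Pro", "F": "tRNA-Phe", "V": "tRNA-Val",
    "I": "tRNA-Ile", "Q": "tRNA-Gln", "M": "tRNA-Met", "W": "tRNA-Trp",
    "A": "tRNA-Ala", "N": "tRNA-Asn", "C": "tRNA-Cys", "Y": "tRNA-Tyr",
    "D": "tRNA-Asp", "K": "tRNA(Lys|Asn)", "G": "tRNA-Gly",
    "R": "tRNA-Arg", "H": "tRNA-His", "E": "tRNA-Glu",
    "12S": "12S rRNA", "16S": "16S rRNA",
    "CR": "D-loop", "O": "NCR",
}

# amino-acid letter -> order token, used when mapping GenBank tRNA products
_TRNA_BY_AA = {
    "Thr": "T", "Pro": "P", "Phe": "F", "Val": "V", "Ile": "I",
    "Gln": "Q", "Met": "M", "Trp": "W", "Ala": "A", "Asn": "N",
    "Cys": "C", "Tyr": "Y", "Asp": "D", "Lys": "K", "Gly": "G",
    "Arg": "R", "His": "H", "Glu": "E",
}


def token_sign(token: str) -> int:
    """+1 for an H-strand token, -1 for an L-strand (``-``-prefixed) one."""
    return -1 if token.startswith("-") else 1


def token_abs(token: str) -> str:
    """Token stripped of its strand sign."""
    return token[1:] if token.startswith("-") else token


def token_neg(token: str) -> str:
    """Token with its strand sign flipped."""
    return token[1:] if token.startswith("-") else "-" + token


def category_of(token: str) -> str:
    return CATEGORY_OF[token_abs(token)]
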