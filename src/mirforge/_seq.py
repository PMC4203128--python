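"""Small sequence utilities shared across modules.

On-disk alphabet is DNA (T); folding and display use RNA (U). Conversion
happens at module boundaries via :func:`to_dna` / :func:`to_rna`.
"""

from __future__ import annotations

_DNA_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def to_dna(seq: str) -> str:
    """Uppercase and convert U -> T."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    """Uppercase and convert T -> U."""
    return seq.upper().replace("T", "U")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA sequence (N-safe)."""
    return seq.translate(_DNA_COMP)[::-1]


def gc_fraction(seq: str) -> float:
    s = seq.upper()
    if not s:
        return 0.0
    return (s.count("G") + s.count("C")) / len(s)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))
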