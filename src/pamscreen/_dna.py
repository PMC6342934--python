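"""Small DNA helpers shared across the package.

Sequences are plain upper-case Python strings over ``ACGT`` (``N`` allowed
where stated).  Numeric code paths encode bases as the uint8 ASCII values of
the characters, so numpy comparisons against byte constants work directly.
"""

from __future__ import annotations

import numpy as np

DNA_BASES = "ACGT"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: IUPAC degenerate nucleotide codes -> the set of concrete bases they cover.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Base set -> smallest IUPAC code covering exactly that set.
_SET_TO_IUPAC = {bases: code for code, bases in IUPAC_CODES.items()}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-unaware, ACGTN only)."""
    return seq.translate(_COMPLEMENT)[::-1]


def revcomp_iupac(pattern: str) -> str:
    """Reverse complement of an IUPAC pattern (e.g. ``TTTV`` -> ``BAAA``)."""
    return pattern.translate(_IUPAC_COMPLEMENT)[::-1]


def iupac_code_for(bases: frozenset[str] | set[str]) -> str:
    """Smallest IUPAC code covering exactly the given base set."""
    code = _SET_TO_IUPAC.get(frozenset(bases))
    if code is None:
        raise ValueError(f"not a valid base set: {sorted(bases)}")
    return code


def check_dna(seq: str, name: str = "sequence", extra: str = "") -> str:
    """Validate *seq* over ACGT plus *extra* characters; returns *seq*."""
    allowed = set(DNA_BASES) | set(extra)
    bad = set(seq) - allowed
    if bad:
        raise ValueError(f"{name} contains invalid characters: {sorted(bad)}")
    return seq


def seq_to_u8(seq: str) -> np.ndarray:
    """ASCII uint8 view of a sequence string."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def u8_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def seqs_to_matrix(seqs: list[str], pad: str = "N") -> np.ndarray:
    """Stack sequences into an (n, max_len) uint8 matrix, right-padded."""
    if not seqs:
        return np.empty((0, 0), dtype=np.uint8)
    max_len = max(len(s) for s in seqs)
    padded = "".join(s.ljust(max_len, pad) for s in seqs)
    return seq_to_u8(padded).reshape(len(seqs), max_len)
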