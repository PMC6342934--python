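"""Anchored PAM extraction from depletion-screen reads.

Each library read carries a fixed protospacer "anchor" (by default the 31-nt
FnPSP1 target site) with the randomized PAM region immediately 5' of it.
This module locates the anchor in a read by substitution-only matching,
slices the ``k`` bases 5' of it (written 5'->3', position -1 adjacent to the
protospacer), optionally condenses the 8-mer to the 6 positions nearest the
protospacer, and tallies PAMs into per-sample count tables.

Counting is vectorised over equal-length read batches with numpy; a per-read
scalar path (:func:`locate_anchor`) defines the reference semantics.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._dna import DNA_BASES, check_dna, seq_to_u8, seqs_to_matrix

#: Default anchor: the FnPSP1 protospacer placed 3' of the randomized region.
FNPSP1_PROTOSPACER = "GAGAAGTCATTTAATAAGGCCACTGTTAAAA"


@dataclass(frozen=True)
class ReadRecord:
    """A single sequencing read (quality string optional)."""

    id: str
    seq: str
    qual: str | None = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError("read sequence must be non-empty")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError("quality string length must match sequence length")


@dataclass
class PamCountTable:
    """k-mer -> count map for one sample/replicate, with bookkeeping.

    ``total_reads`` counts every input read; ``valid_reads`` only those that
    yielded a PAM (anchor found, full window, no ambiguous base), and always
    equals the sum of ``counts``.
    """

    k: int
    counts: dict[str, int] = field(default_factory=dict)
    total_reads: int = 0
    valid_reads: int = 0
    sample_id: str = ""
    replicate_id: str = ""

    def validate(self) -> "PamCountTable":
        if self.valid_reads != sum(self.counts.values()):
            raise ValueError("sum of counts must equal valid_reads")
        if self.valid_reads > self.total_reads:
            raise ValueError("valid_reads cannot exceed total_reads")
        for kmer in self.counts:
            if len(kmer) != self.k or set(kmer) - set(DNA_BASES):
                raise ValueError(f"bad k-mer key: {kmer!r}")
        return self

    def frequencies(self) -> dict[str, float]:
        """Raw relative frequencies (no pseudocount); sum to 1."""
        if self.valid_reads == 0:
            raise ValueError("no valid reads")
        return {p: c / self.valid_reads for p, c in self.counts.items()}


def locate_anchor(read: ReadRecord | str, anchor: str, max_mismatches: int = 1) -> int | None:
    """0-based start of the best anchor occurrence, or ``None``.

    Matching is substitution-only (Hamming); among positions with equally few
    mismatches the leftmost wins, and hits with more than ``max_mismatches``
    substitutions are rejected.  ``N`` in the read never matches.
    """
    seq = read.seq if isinstance(read, ReadRecord) else read
    n, m = len(seq), len(anchor)
    if m == 0 or m > n:
        return None
    s = seq_to_u8(seq)
    a = seq_to_u8(anchor)
    windows = np.lib.stride_tricks.sliding_window_view(s, m)
    mismatches = (windows != a).sum(axis=1)
    best = int(mismatches.argmin())  # argmin returns the leftmost minimum
    if mismatches[best] > max_mismatches:
        return None
    return best


def extract_pam(read: ReadRecord | str, anchor_pos: int, k: int = 8) -> str | None:
    """The ``k`` bases ending immediately before ``anchor_pos``, 5'->3'.

    Returns ``None`` if fewer than ``k`` bases precede the anchor or the
    window contains a non-ACGT character.
    """
    seq = read.seq if isinstance(read, ReadRecord) else read
    if anchor_pos < k:
        return None
    window = seq[anchor_pos - k : anchor_pos]
    if set(window) - set(DNA_BASES):
        return None
    return window


def condense(pam8: str) -> str:
    """Drop the two most distal positions (-8, -7) of an 8-mer PAM.

    The screen showed no base preference 7-8 bp upstream of the protospacer,
    so tables are condensed to the 6 positions nearest it.
    """
    if len(pam8) != 8:
        raise ValueError(f"expected an 8-mer, got length {len(pam8)}")
    check_dna(pam8, "pam8")
    return pam8[2:]


def _count_batch(
    seqs: Sequence[str], anchor: str, tol: int, k: int
) -> Counter[str]:
    """Vectorised anchor scan + PAM slice for equal-length reads."""
    mat = seqs_to_matrix(list(seqs))
    n_reads, read_len = mat.shape
    m = len(anchor)
    counts: Counter[str] = Counter()
    if m > read_len or n_reads == 0:
        return counts
    a = seq_to_u8(anchor)
    n_offsets = read_len - m + 1
    mism = np.empty((n_reads, n_offsets), dtype=np.int32)
    for off in range(n_offsets):
        mism[:, off] = (mat[:, off : off + m] != a).sum(axis=1)
    best = mism.argmin(axis=1)
    ok = mism[np.arange(n_reads), best] <= tol
    ok &= best >= k  # need k upstream bases
    if not ok.any():
        return counts
    idx = np.nonzero(ok)[0]
    starts = best[idx] - k
    windows = mat[idx[:, None], starts[:, None] + np.arange(k)]
    acgt = seq_to_u8(DNA_BASES)
    clean = np.isin(windows, acgt).all(axis=1)
    for row in windows[clean]:
        counts[row.tobytes().decode("ascii")] += 1
    return counts


def count_pams(
    reads: Iterable[ReadRecord | str],
    anchor: str = FNPSP1_PROTOSPACER,
    tol: int = 1,
    k: int = 8,
    condense_pams: bool = False,
    sample_id: str = "",
    replicate_id: str = "",
) -> PamCountTable:
    """Count PAMs across reads into a :class:`PamCountTable`.

    Applies anchor location, PAM extraction and (optionally) condensation to
    each read; reads without a usable PAM window still count toward
    ``total_reads``.  The result is invariant to read order.
    """
    check_dna(anchor, "anchor")
    if not anchor:
        raise ValueError("anchor must be non-empty")
    by_len: dict[int, list[str]] = {}
    total = 0
    for read in reads:
        seq = read.seq if isinstance(read, ReadRecord) else read
        total += 1
        by_len.setdefault(len(seq), []).append(seq)
    counts: Counter[str] = Counter()
    for seqs in by_len.values():
        counts.update(_count_batch(seqs, anchor, tol, k))
    if condense_pams:
        condensed: Counter[str] = Counter()
        for pam, c in counts.items():
            condensed[condense(pam)] += c
        counts = condensed
        k_out = k - 2
    else:
        k_out = k
    table = PamCountTable(
        k=k_out,
        counts=dict(counts),
        total_reads=total,
        valid_reads=sum(counts.values()),
        sample_id=sample_id,
        replicate_id=replicate_id,
    )
    return table.validate()


def condense_table(table: PamCountTable) -> PamCountTable:
    """Marginalise an 8-mer count table over the two distal positions."""
    if table.k != 8:
        raise ValueError("condense_table expects an 8-mer table")
    condensed: Counter[str] = Counter()
    for pam, c in table.counts.items():
        condensed[condense(pam)] += c
    return PamCountTable(
        k=6,
        counts=dict(condensed),
        total_reads=table.total_reads,
        valid_reads=table.valid_reads,
        sample_id=table.sample_id,
        replicate_id=table.replicate_id,
    ).validate()
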