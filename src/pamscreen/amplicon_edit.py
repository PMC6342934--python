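"""Amplicon-sequencing edit-outcome calling: wild-type, indel, HDR.

Each read is globally aligned to the amplicon reference with an affine-gap
Gotoh DP (defaults: match +2, mismatch -3, gap open -6, gap extend -1 per
additional gap base).  Among co-optimal alignments, gaps are normalised to
their leftmost equivalent placement, so indel coordinates are deterministic.

Classification precedence for a read:

1. ``HDR_PERFECT``  — every donor edit present and the 36-nt HDR window
   matches the donor-edited reference exactly (no other change there);
2. ``HDR_CONVERTED`` — the key donor edit (the TG->CA conversion) is
   present, regardless of other events;
3. ``INDEL``        — nonzero net insertion/deletion length inside the cut
   window;
4. ``WT``           — otherwise.

Reads failing an alignment-score floor are ``AMBIGUOUS`` and excluded
from rate denominators.  Substitutions outside the HDR window never change a
read's class (sequencing-error tolerance).  Coordinates are 0-based
half-open throughout.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from numba import njit

from ._dna import check_dna, seq_to_u8
from .pam_extract import ReadRecord

NEG_INF = -1e18


@dataclass(frozen=True)
class AlignScoring:
    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -6.0  # cost of a length-1 gap
    gap_extend: float = -1.0  # per additional gap base


@dataclass(frozen=True)
class Interval:
    """0-based half-open interval on the reference."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"bad interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class AmpliconReference:
    """Amplicon reference with target annotation.

    ``donor_edits`` are same-length substitutions ``(pos, ref, alt)`` on
    reference coordinates; the edit at index ``key_edit`` is the conversion
    read out by HDR calling (by default the first, the TG->CA edit).
    """

    sequence: str
    pam: Interval
    spacer: Interval
    cut_window: Interval
    hdr_window: Interval
    donor_edits: list[tuple[int, str, str]] = field(default_factory=list)
    key_edit: int = 0
    name: str = "amplicon"

    def __post_init__(self) -> None:
        check_dna(self.sequence, "reference")
        n = len(self.sequence)
        for label, iv in (
            ("pam", self.pam),
            ("spacer", self.spacer),
            ("cut_window", self.cut_window),
            ("hdr_window", self.hdr_window),
        ):
            if iv.end > n:
                raise ValueError(f"{label} interval exceeds reference length")
        if len(self.hdr_window) != 36:
            raise ValueError("hdr_window must span exactly 36 nt")
        for pos, ref, alt in self.donor_edits:
            if len(ref) != len(alt):
                raise ValueError("donor edits must be same-length substitutions")
            if self.sequence[pos : pos + len(ref)] != ref:
                raise ValueError(
                    f"donor edit ref bases {ref!r} do not match reference at {pos}"
                )
        if self.donor_edits and not 0 <= self.key_edit < len(self.donor_edits):
            raise ValueError("key_edit out of range")

    def edited_sequence(self) -> str:
        """Reference with every donor edit applied (the perfect-HDR allele)."""
        seq = list(self.sequence)
        for pos, ref, alt in self.donor_edits:
            seq[pos : pos + len(ref)] = alt
        return "".join(seq)

    def to_row(self) -> dict[str, object]:
        """Flatten the annotation to one TSV row (coordinates 0-based
        half-open; edits encoded ``pos:ref>alt`` joined by ``;``)."""
        edits = ";".join(f"{p}:{r}>{a}" for p, r, a in self.donor_edits)
        return {
            "name": self.name,
            "pam_start": self.pam.start,
            "pam_end": self.pam.end,
            "spacer_start": self.spacer.start,
            "spacer_end": self.spacer.end,
            "cut_start": self.cut_window.start,
            "cut_end": self.cut_window.end,
            "hdr_start": self.hdr_window.start,
            "hdr_end": self.hdr_window.end,
            "donor_edits": edits,
            "key_edit": self.key_edit,
        }

    @classmethod
    def from_row(cls, sequence: str, row: dict[str, object]) -> "AmpliconReference":
        """Rebuild an annotated reference from a TSV row and its sequence."""
        edits = []
        spec = str(row.get("donor_edits", "") or "")
        for part in filter(None, spec.split(";")):
            pos, _, change = part.partition(":")
            ref, _, alt = change.partition(">")
            edits.append((int(pos), ref, alt))
        return cls(
            sequence=sequence,
            pam=Interval(int(row["pam_start"]), int(row["pam_end"])),
            spacer=Interval(int(row["spacer_start"]), int(row["spacer_end"])),
            cut_window=Interval(int(row["cut_start"]), int(row["cut_end"])),
            hdr_window=Interval(int(row["hdr_start"]), int(row["hdr_end"])),
            donor_edits=edits,
            key_edit=int(row.get("key_edit", 0) or 0),
            name=str(row.get("name", "amplicon")),
        )


class EditClass(str, Enum):
    WT = "WT"
    INDEL = "INDEL"
    HDR_CONVERTED = "HDR_CONVERTED"
    HDR_PERFECT = "HDR_PERFECT"
    AMBIGUOUS = "AMBIGUOUS"


@dataclass
class EditCall:
    read_id: str
    edit_class: EditClass
    net_indel_length: int = 0
    notes: str = ""


@dataclass
class ReadAlignment:
    """Gapped alignment of a read against the full reference."""

    aligned_read: str
    aligned_ref: str
    score: float
    events: list[tuple[int, int]]  # (ref position, net length; +ins / -del)
    substitutions: list[tuple[int, str, str]]  # (ref pos, ref base, read base)

    @property
    def identity(self) -> float:
        cols = [
            (a, b)
            for a, b in zip(self.aligned_read, self.aligned_ref)
            if a != "-" and b != "-"
        ]
        if not cols:
            return 0.0
        return sum(a == b for a, b in cols) / len(cols)


@njit(cache=True)
def _gotoh_fill(a, b, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    """Gotoh DP, global in the read ``a``, local in the reference ``b``
    (terminal reference gaps are free: amplicon-read semantics)."""
    n, m = a.shape[0], b.shape[0]
    M = np.full((n + 1, m + 1), NEG_INF)
    X = np.full((n + 1, m + 1), NEG_INF)  # gap in b (read consumed, insertion)
    Y = np.full((n + 1, m + 1), NEG_INF)  # gap in a (ref consumed, deletion)
    for j in range(m + 1):
        M[0, j] = 0.0  # free leading reference skip
    for i in range(1, n + 1):
        X[i, 0] = gap_open + gap_extend * (i - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            best_prev = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            M[i, j] = best_prev + s
            X[i, j] = max(
                M[i - 1, j] + gap_open,
                Y[i - 1, j] + gap_open,
                X[i - 1, j] + gap_extend,
            )
            Y[i, j] = max(
                M[i, j - 1] + gap_open,
                X[i, j - 1] + gap_open,
                Y[i, j - 1] + gap_extend,
            )
    return M, X, Y


def _traceback(a: str, b: str, M, X, Y, sc: AlignScoring) -> tuple[str, str, float]:
    """Recover one optimal alignment from the filled Gotoh matrices.

    Ties are broken M > X > Y; gap placement is made deterministic by the
    left-normalisation pass afterwards, not by this choice.
    """
    eps = 1e-6
    i = len(a)
    # free trailing reference skip: end at the best column of the last row
    ends = np.maximum(M[i, :], X[i, :])
    j = int(ends.argmax())
    finals = (M[i, j], X[i, j])
    score = max(finals)
    state = 0 if finals[0] >= score - eps else 1
    trail = len(b) - j
    rows_a: list[str] = []
    rows_b: list[str] = []
    while i > 0:
        if state == 0:
            s = sc.match if a[i - 1] == b[j - 1] else sc.mismatch
            rows_a.append(a[i - 1])
            rows_b.append(b[j - 1])
            target = M[i, j] - s
            srcs = (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            state = min(k for k in range(3) if abs(srcs[k] - target) < eps)
            i -= 1
            j -= 1
        elif state == 1:
            rows_a.append(a[i - 1])
            rows_b.append("-")
            target = X[i, j]
            if abs(M[i - 1, j] + sc.gap_open - target) < eps:
                state = 0
            elif abs(X[i - 1, j] + sc.gap_extend - target) < eps:
                state = 1
            else:
                state = 2
            i -= 1
        else:
            rows_a.append("-")
            rows_b.append(b[j - 1])
            target = Y[i, j]
            if abs(M[i, j - 1] + sc.gap_open - target) < eps:
                state = 0
            elif abs(Y[i, j - 1] + sc.gap_extend - target) < eps:
                state = 2
            else:
                state = 1
            j -= 1
    # render the free terminal reference skips as gap columns so that
    # removing gaps reproduces the full reference; they are never events
    row_a = "-" * j + "".join(reversed(rows_a)) + "-" * trail
    row_b = b[:j] + "".join(reversed(rows_b)) + b[len(b) - trail :]
    return row_a, row_b, float(score)


def _left_normalize(row_a: str, row_b: str) -> tuple[str, str]:
    """Shift every gap run to its leftmost score-equivalent placement.

    A gap run may swap with the aligned column just before it whenever the
    non-gap row carries the same character at both ends of the rotation, so
    the alignment score is unchanged.
    """
    A = list(row_a)
    B = list(row_b)

    def shift(gap_row: list[str], base_row: list[str]) -> bool:
        moved = False
        i = 0
        n = len(gap_row)
        while i < n:
            if gap_row[i] != "-":
                i += 1
                continue
            start = i
            while i < n and gap_row[i] == "-":
                i += 1
            end = i
            if end == n:  # terminal run (free reference skip): leave in place
                continue
            s = start
            while (
                s > 0
                and gap_row[s - 1] != "-"
                and base_row[s - 1] != "-"
                and base_row[s - 1] == base_row[end - 1]
            ):
                # slide the run left: the gap-row char hops over the run
                gap_row[end - 1] = gap_row[s - 1]
                gap_row[s - 1] = "-"
                s -= 1
                end -= 1
                moved = True
        return moved

    while shift(A, B) or shift(B, A):
        pass
    return "".join(A), "".join(B)


def _extract_events(
    row_read: str, row_ref: str
) -> tuple[list[tuple[int, int]], list[tuple[int, str, str]]]:
    events: list[tuple[int, int]] = []
    subs: list[tuple[int, str, str]] = []
    ref_pos = 0
    col = 0
    n = len(row_read)
    while col < n:
        r, q = row_ref[col], row_read[col]
        if r == "-":  # insertion relative to reference
            length = 0
            while col < n and row_ref[col] == "-":
                length += 1
                col += 1
            events.append((ref_pos, length))
        elif q == "-":  # deletion of reference bases
            run_start_col = col
            start = ref_pos
            length = 0
            while col < n and row_read[col] == "-":
                length += 1
                ref_pos += 1
                col += 1
            # gap runs touching either alignment end are free reference
            # skips (the read starts/ends inside the reference), not events
            if run_start_col > 0 and col < n:
                events.append((start, -length))
        else:
            if r != q:
                subs.append((ref_pos, r, q))
            ref_pos += 1
            col += 1
    return events, subs


def align_read(
    read: ReadRecord | str,
    ref: AmpliconReference | str,
    scoring: AlignScoring = AlignScoring(),
) -> ReadAlignment:
    """Global affine-gap alignment of a read against the reference.

    Returns the optimal-score alignment with leftmost gap placement among
    co-optimal alignments, plus its indel events and substitutions on
    reference coordinates.
    """
    read_seq = read.seq if isinstance(read, ReadRecord) else read
    ref_seq = ref.sequence if isinstance(ref, AmpliconReference) else ref
    if not read_seq:
        raise ValueError("read must be non-empty")
    a = seq_to_u8(read_seq)
    b = seq_to_u8(ref_seq)
    M, X, Y = _gotoh_fill(
        a, b, scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend
    )
    row_a, row_b, score = _traceback(read_seq, ref_seq, M, X, Y, scoring)
    row_a, row_b = _left_normalize(row_a, row_b)
    events, subs = _extract_events(row_a, row_b)
    aln = ReadAlignment(
        aligned_read=row_a,
        aligned_ref=row_b,
        score=score,
        events=events,
        substitutions=subs,
    )
    assert row_a.replace("-", "") == read_seq and row_b.replace("-", "") == ref_seq
    return aln


def _read_bases_at(aln: ReadAlignment, interval: Interval) -> str | None:
    """Read bases aligned across a reference interval, or None if an indel
    touches it (gap columns inside the interval or insertions at its
    interior boundaries)."""
    out: list[str] = []
    ref_pos = 0
    for r, q in zip(aln.aligned_ref, aln.aligned_read):
        if r == "-":
            if interval.start < ref_pos < interval.end:
                return None
            continue
        if interval.contains(ref_pos):
            if q == "-":
                return None
            out.append(q)
        ref_pos += 1
    if len(out) != len(interval):
        return None
    return "".join(out)


def _edit_present(aln: ReadAlignment, pos: int, alt: str) -> bool:
    window = Interval(pos, pos + len(alt))
    bases = _read_bases_at(aln, window)
    return bases == alt


def net_indel_in_window(aln: ReadAlignment, window: Interval) -> int:
    """Signed net indel length from events overlapping the cut window.

    A deletion counts if its deleted reference span intersects the window; an
    insertion if its insertion point lies in the closed window.  Overlap (not
    containment) semantics keep left-normalised gaps that straddle the window
    edge attributed to the cut site.
    """
    net = 0
    for pos, length in aln.events:
        if length < 0:
            if pos < window.end and pos - length > window.start:
                net += length
        else:
            if window.start <= pos <= window.end:
                net += length
    return net


def classify_read(
    aln: ReadAlignment,
    ref: AmpliconReference,
    read_id: str = "",
    min_score_frac: float = 0.5,
    scoring: AlignScoring = AlignScoring(),
) -> EditCall:
    """Classify one aligned read by the HDR > indel > WT precedence.

    Reads whose alignment score falls below ``min_score_frac`` of the
    perfect-match score for their length are AMBIGUOUS (unalignable or
    heavily damaged) and excluded from rate denominators downstream.
    """
    read_len = len(aln.aligned_read.replace("-", ""))
    if aln.score < min_score_frac * scoring.match * read_len:
        return EditCall(read_id, EditClass.AMBIGUOUS, notes="low alignment score")
    edited = ref.edited_sequence()
    if ref.donor_edits:
        all_present = all(
            _edit_present(aln, pos, alt) for pos, _, alt in ref.donor_edits
        )
        window_bases = _read_bases_at(aln, ref.hdr_window)
        window_target = edited[ref.hdr_window.start : ref.hdr_window.end]
        if all_present and window_bases == window_target:
            return EditCall(read_id, EditClass.HDR_PERFECT)
        key_pos, _, key_alt = ref.donor_edits[ref.key_edit]
        if _edit_present(aln, key_pos, key_alt):
            net = net_indel_in_window(aln, ref.cut_window)
            notes = f"conversion with net indel {net:+d}" if net else ""
            return EditCall(read_id, EditClass.HDR_CONVERTED, notes=notes)
    net = net_indel_in_window(aln, ref.cut_window)
    if net != 0:
        return EditCall(read_id, EditClass.INDEL, net_indel_length=net)
    return EditCall(read_id, EditClass.WT)


def classify_reads(
    reads: Iterable[ReadRecord | str],
    ref: AmpliconReference,
    scoring: AlignScoring = AlignScoring(),
    min_read_len: int = 40,
    min_score_frac: float = 0.5,
) -> tuple[list[EditCall], int]:
    """Align and classify a batch of reads.

    Reads shorter than ``min_read_len`` are excluded and counted in the
    returned filtered total.
    """
    calls: list[EditCall] = []
    n_filtered = 0
    for idx, read in enumerate(reads):
        seq = read.seq if isinstance(read, ReadRecord) else read
        rid = read.id if isinstance(read, ReadRecord) else f"read{idx}"
        if len(seq) < min_read_len:
            n_filtered += 1
            continue
        aln = align_read(seq, ref, scoring)
        calls.append(
            classify_read(
                aln, ref, read_id=rid, min_score_frac=min_score_frac, scoring=scoring
            )
        )
    return calls, n_filtered


@dataclass
class EditSummary:
    """Aggregate outcome rates; all rates are percentages of classified
    (non-ambiguous) reads.  ``hdr_converted_rate`` counts every read carrying
    the key conversion, including perfect edits; ``hdr_perfect_rate`` counts
    only donor-exact windows."""

    n_reads: int
    n_classified: int
    n_ambiguous: int
    indel_rate: float
    mean_abs_indel_length: float | None
    length_histogram: dict[int, int]
    hdr_converted_rate: float
    hdr_perfect_rate: float

    def to_dict(self) -> dict[str, object]:
        return {
            "n_reads": self.n_reads,
            "n_classified": self.n_classified,
            "n_ambiguous": self.n_ambiguous,
            "indel_rate": self.indel_rate,
            "mean_abs_indel_length": self.mean_abs_indel_length,
            "length_histogram": {str(k): v for k, v in sorted(self.length_histogram.items())},
            "hdr_converted_rate": self.hdr_converted_rate,
            "hdr_perfect_rate": self.hdr_perfect_rate,
        }


def summarize(calls: Sequence[EditCall]) -> EditSummary:
    """Aggregate per-read calls into the summary metrics."""
    n_reads = len(calls)
    classified = [c for c in calls if c.edit_class is not EditClass.AMBIGUOUS]
    n = len(classified)
    if n == 0:
        raise ValueError("no classifiable reads")
    indels = [c for c in classified if c.edit_class is EditClass.INDEL]
    perfect = sum(c.edit_class is EditClass.HDR_PERFECT for c in classified)
    converted = sum(c.edit_class is EditClass.HDR_CONVERTED for c in classified)
    hist = Counter(c.net_indel_length for c in indels)
    mean_len = (
        float(np.mean([abs(c.net_indel_length) for c in indels])) if indels else None
    )
    return EditSummary(
        n_reads=n_reads,
        n_classified=n,
        n_ambiguous=n_reads - n,
        indel_rate=100.0 * len(indels) / n,
        mean_abs_indel_length=mean_len,
        length_histogram=dict(hist),
        hdr_converted_rate=100.0 * (converted + perfect) / n,
        hdr_perfect_rate=100.0 * perfect / n,
    )
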