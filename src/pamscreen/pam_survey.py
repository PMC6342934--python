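"""Enumeration of PAM-compatible target sites on both strands.

Counts every position where an IUPAC PAM pattern (e.g. ``ATTN`` for
BhCas12b, ``TTTV`` for AsCas12a — both 5' of the protospacer) matches and a
full-length protospacer fits immediately 3' of it.  Reverse-strand sites are
found by matching the reverse-complement pattern on the forward sequence;
all coordinates are 0-based half-open on the forward axis, with the strand
flag giving the orientation.  Overlapping sites are all reported, and ``N``
in the subject never matches.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from ._dna import IUPAC_CODES, revcomp_iupac


@dataclass(frozen=True)
class PamPattern:
    """A 5'-of-protospacer PAM pattern plus the protospacer length."""

    iupac: str
    spacer_len: int = 23

    def __post_init__(self) -> None:
        if not self.iupac:
            raise ValueError("pattern must be non-empty")
        bad = set(self.iupac) - set(IUPAC_CODES)
        if bad:
            raise ValueError(f"invalid IUPAC codes in pattern: {sorted(bad)}")
        if self.spacer_len < 1:
            raise ValueError("spacer_len must be >= 1")

    def regex(self, reverse_complement: bool = False) -> re.Pattern[str]:
        pattern = revcomp_iupac(self.iupac) if reverse_complement else self.iupac
        # Explicit character classes: subject 'N' matches no code.
        return re.compile(
            "".join("[" + "".join(sorted(IUPAC_CODES[c])) + "]" for c in pattern)
        )


@dataclass
class Site:
    """One PAM site; coordinates 0-based half-open on the forward axis."""

    contig: str
    strand: str  # '+' or '-'
    pam_start: int
    protospacer_start: int


@dataclass
class SiteList:
    sites: list[Site] = field(default_factory=list)
    surveyed_length: int = 0

    def __len__(self) -> int:
        return len(self.sites)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "contig": s.contig,
                    "strand": s.strand,
                    "pam_start": s.pam_start,
                    "protospacer_start": s.protospacer_start,
                }
                for s in self.sites
            ],
            columns=["contig", "strand", "pam_start", "protospacer_start"],
        )


def scan_sites(
    sequence: str, pattern: PamPattern, contig: str = "seq"
) -> SiteList:
    """All PAM+protospacer sites on both strands of ``sequence``.

    Forward sites: the pattern matches at ``pam_start`` and the protospacer
    occupies ``[pam_start + len(pam), pam_start + len(pam) + spacer_len)``.
    Reverse sites: the reverse-complement pattern matches on the forward
    sequence with the protospacer immediately 5' of it on the forward axis.
    """
    seq = sequence.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains invalid characters: {sorted(bad)}")
    plen = len(pattern.iupac)
    slen = pattern.spacer_len
    sites: list[Site] = []

    fwd = pattern.regex()
    pos = 0
    while True:
        m = fwd.search(seq, pos)
        if m is None:
            break
        i = m.start()
        if i + plen + slen <= len(seq):
            sites.append(
                Site(contig=contig, strand="+", pam_start=i, protospacer_start=i + plen)
            )
        pos = i + 1  # overlapping matches

    rev = pattern.regex(reverse_complement=True)
    pos = 0
    while True:
        m = rev.search(seq, pos)
        if m is None:
            break
        j = m.start()
        if j - slen >= 0:
            sites.append(
                Site(contig=contig, strand="-", pam_start=j, protospacer_start=j - slen)
            )
        pos = j + 1

    sites.sort(key=lambda s: (s.pam_start, s.strand))
    return SiteList(sites=sites, surveyed_length=len(seq))


def scan_fasta(seqs: dict[str, str], pattern: PamPattern) -> SiteList:
    """Scan every contig of a FASTA mapping; lengths are summed."""
    merged = SiteList()
    for name, seq in seqs.items():
        part = scan_sites(seq, pattern, contig=name)
        merged.sites.extend(part.sites)
        merged.surveyed_length += part.surveyed_length
    return merged


def site_density(sites: SiteList, per_strand: bool = False) -> float | dict[str, float]:
    """Sites per kilobase of surveyed sequence (optionally per strand)."""
    if sites.surveyed_length <= 0:
        raise ValueError("surveyed length must be positive")
    scale = 1000.0 / sites.surveyed_length
    if not per_strand:
        return len(sites) * scale
    out = {"+": 0.0, "-": 0.0}
    for s in sites.sites:
        out[s.strand] += scale
    return out


def sites_to_bed(sites: SiteList, pattern: PamPattern) -> str:
    """BED6 rows covering PAM + protospacer for each site."""
    rows = []
    plen = len(pattern.iupac)
    slen = pattern.spacer_len
    for s in sites.sites:
        if s.strand == "+":
            start, end = s.pam_start, s.pam_start + plen + slen
        else:
            start, end = s.protospacer_start, s.pam_start + plen
        rows.append(f"{s.contig}\t{start}\t{end}\t{pattern.iupac}\t0\t{s.strand}")
    return "\n".join(rows) + ("\n" if rows else "")
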