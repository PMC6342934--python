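"""Closed-form gel quantitation of DNA cleavage and nicking.

A native gel of a double-cut substrate shows the undigested full-length band
(intensity ``a``) and two product bands (``b``, ``c``).  Under independent
per-strand cutting with equal probability ``p`` on both strands, the
full-length fraction is ``(1 - p)^2``, so the per-strand cleaved percentage
is recovered as

    percent = 100 * (1 - sqrt(a / (a + b + c)))
            = 100 * (1 - sqrt(1 - (b + c) / (a + b + c)))

which is what :func:`percent_cleaved` computes.  Denaturing gels resolve each
labelled strand separately; :func:`strand_fraction_cut` is the plain cut/total
ratio for one strand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class GelLane:
    """Integrated band intensities for one lane.

    ``a`` is the undigested full-length band; ``b`` and ``c`` are the two
    cleavage or nicking product bands.
    """

    a: float
    b: float
    c: float
    lane_id: str = ""

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) < 0:
            raise ValueError("band intensities must be non-negative")

    @property
    def total(self) -> float:
        return self.a + self.b + self.c


@dataclass(frozen=True)
class CleavageEstimate:
    percent: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent <= 100.0:
            raise ValueError("percent must lie in [0, 100]")


def percent_cleaved(lane: GelLane, background: float = 0.0) -> CleavageEstimate:
    """Per-strand cleavage/nicking percentage from one lane.

    ``background`` is an optional constant offset subtracted from every band
    before quantitation (floored at zero).  Scale-invariant in the bands.
    """
    a = max(lane.a - background, 0.0)
    b = max(lane.b - background, 0.0)
    c = max(lane.c - background, 0.0)
    total = a + b + c
    if total <= 0:
        raise ValueError("lane has no signal (a + b + c must be > 0)")
    return CleavageEstimate(percent=100.0 * (1.0 - math.sqrt(a / total)))


def strand_fraction_cut(uncut_intensity: float, cut_intensity: float) -> float:
    """Cut percentage for one labelled strand on a denaturing gel."""
    if uncut_intensity < 0 or cut_intensity < 0:
        raise ValueError("intensities must be non-negative")
    total = uncut_intensity + cut_intensity
    if total <= 0:
        raise ValueError("zero total intensity")
    return 100.0 * cut_intensity / total


def roundtrip_check(p: float, total_signal: float = 100.0) -> float:
    """Consistency oracle: noiseless lane at per-strand probability ``p``.

    Builds the lane a nuclease cutting both strands independently with
    probability ``p`` would produce and runs :func:`percent_cleaved`; the
    result equals ``100 * p`` identically.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    a = total_signal * (1.0 - p) ** 2
    cut_mass = total_signal - a
    lane = GelLane(a=a, b=cut_mass / 2.0, c=cut_mass / 2.0)
    if lane.total <= 0:
        return 0.0
    return percent_cleaved(lane).percent
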