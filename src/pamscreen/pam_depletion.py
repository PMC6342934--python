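"""Depletion scoring, depleted-PAM calling and motif summaries.

In the screen, bacteria whose plasmid carries a cleavable PAM are killed, so
active PAMs are *depleted* from the surviving library relative to an
empty-vector control.  The statistic is a pseudocounted log2 fold change

    log2_depletion = log2( freq_control / freq_sample ),

positive when the nuclease removed the PAM from the sample pool.  Scores are
computed per replicate and combined; calls require the score to clear a
threshold in every replicate (default) or on the replicate mean.

Motif summaries (position frequency matrix, per-position information content
in bits, IUPAC consensus) describe the called set, and count tables can be
flattened into Krona ``ImportText`` rows for PAM-wheel rendering.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._dna import DNA_BASES, iupac_code_for
from .pam_extract import PamCountTable

DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_THRESHOLD = 2.0  # log2 units: >= 4-fold depletion
DEFAULT_CONSENSUS_CUTOFF = 0.25


@dataclass
class DepletionTable:
    """Per-PAM depletion scores across replicates.

    ``frame`` is indexed by PAM with per-replicate columns
    ``count_control_<rep>``, ``count_sample_<rep>``, ``freq_control_<rep>``,
    ``freq_sample_<rep>``, ``log2_depletion_<rep>``, plus ``log2_depletion``
    (the replicate mean) and a ``depleted`` boolean once calls are made.
    """

    k: int
    frame: pd.DataFrame
    replicates: list[str]
    pseudocount: float

    @property
    def pams(self) -> list[str]:
        return list(self.frame.index)

    def replicate_scores(self) -> pd.DataFrame:
        cols = [f"log2_depletion_{rep}" for rep in self.replicates]
        return self.frame[cols]


def _frequencies(table: PamCountTable, pams: pd.Index, pseudocount: float) -> np.ndarray:
    if table.valid_reads == 0:
        raise ValueError("count table has zero valid reads")
    counts = np.array([table.counts.get(p, 0) for p in pams], dtype=float)
    denom = table.valid_reads + pseudocount * 4**table.k
    return (counts + pseudocount) / denom


def compute_depletion(
    sample: PamCountTable | list[PamCountTable],
    control: PamCountTable | list[PamCountTable],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    dense: bool = False,
) -> DepletionTable:
    """Score per-PAM depletion of sample libraries against controls.

    ``sample`` and ``control`` are matched per-replicate lists (or single
    tables).  Keys are the union of observed PAMs, or all ``4**k`` with
    ``dense=True``.  A pseudocount keeps scores finite at zero counts.
    """
    samples = sample if isinstance(sample, list) else [sample]
    controls = control if isinstance(control, list) else [control]
    if len(samples) != len(controls):
        raise ValueError("need one control table per sample table")
    if not samples:
        raise ValueError("need at least one replicate")
    k = samples[0].k
    for t in itertools.chain(samples, controls):
        if t.k != k:
            raise ValueError(f"k mismatch: {t.k} != {k}")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if dense:
        pams = pd.Index("".join(c) for c in itertools.product(DNA_BASES, repeat=k))
    else:
        keys: set[str] = set()
        for t in itertools.chain(samples, controls):
            keys.update(t.counts)
        pams = pd.Index(sorted(keys))
    data: dict[str, np.ndarray] = {}
    rep_ids = []
    score_cols = []
    for i, (s, c) in enumerate(zip(samples, controls)):
        rep = s.replicate_id or f"rep{i + 1}"
        rep_ids.append(rep)
        fc = _frequencies(c, pams, pseudocount)
        fs = _frequencies(s, pams, pseudocount)
        with np.errstate(divide="ignore"):
            score = np.log2(fc) - np.log2(fs)
        data[f"count_control_{rep}"] = np.array(
            [c.counts.get(p, 0) for p in pams], dtype=int
        )
        data[f"count_sample_{rep}"] = np.array(
            [s.counts.get(p, 0) for p in pams], dtype=int
        )
        data[f"freq_control_{rep}"] = fc
        data[f"freq_sample_{rep}"] = fs
        data[f"log2_depletion_{rep}"] = score
        score_cols.append(f"log2_depletion_{rep}")
    frame = pd.DataFrame(data, index=pams)
    frame.index.name = "pam"
    frame["log2_depletion"] = frame[score_cols].mean(axis=1)
    return DepletionTable(k=k, frame=frame, replicates=rep_ids, pseudocount=pseudocount)


def call_depleted(
    table: DepletionTable,
    threshold: float = DEFAULT_THRESHOLD,
    rule: str = "all-replicates",
) -> set[str]:
    """PAMs whose depletion score clears ``threshold`` (>= convention).

    ``rule='all-replicates'`` requires every replicate to clear it;
    ``rule='mean'`` tests the replicate mean.  Also sets the ``depleted``
    column on the table in place.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    scores = table.replicate_scores()
    if rule == "all-replicates":
        called = (scores >= threshold).all(axis=1)
    elif rule == "mean":
        called = table.frame["log2_depletion"] >= threshold
    else:
        raise ValueError(f"unknown rule: {rule!r}")
    table.frame["depleted"] = called
    return set(table.frame.index[called])


@dataclass
class PositionFrequencyMatrix:
    """Per-position base frequencies over a PAM set (columns sum to 1)."""

    freqs: pd.DataFrame  # rows: bases ACGT; columns: positions -k..-1
    n_pams: int
    weighting: str = "uniform"

    @property
    def k(self) -> int:
        return self.freqs.shape[1]

    def dominant_base(self, position: int) -> str:
        """Most frequent base at a position labelled -k..-1."""
        return str(self.freqs[position].idxmax())


@dataclass
class MotifSummary:
    consensus: str
    info_content: list[float] = field(default_factory=list)
    depleted_count: int = 0


def build_motif(
    depleted: set[str] | list[str],
    counts: dict[str, float] | None = None,
    consensus_cutoff: float = DEFAULT_CONSENSUS_CUTOFF,
) -> tuple[PositionFrequencyMatrix, MotifSummary]:
    """PFM, information content and IUPAC consensus of a PAM set.

    With ``counts`` the PFM is weighted (e.g. by depletion mass); otherwise
    each PAM contributes equally.  Information content per position is
    ``2 - H`` bits where ``H`` is the Shannon entropy of the base
    distribution; the consensus letter is the smallest IUPAC code covering
    all bases at frequency >= ``consensus_cutoff``.
    """
    pams = sorted(depleted)
    if not pams:
        raise ValueError("cannot build a motif from an empty PAM set")
    k = len(pams[0])
    if any(len(p) != k for p in pams):
        raise ValueError("all PAMs must have equal length")
    weights = np.array([1.0 if counts is None else counts[p] for p in pams])
    if weights.sum() <= 0:
        raise ValueError("weights must have positive total")
    weights = weights / weights.sum()
    positions = list(range(-k, 0))
    mat = np.zeros((4, k))
    base_idx = {b: i for i, b in enumerate(DNA_BASES)}
    for pam, w in zip(pams, weights):
        for j, base in enumerate(pam):
            mat[base_idx[base], j] += w
    freqs = pd.DataFrame(mat, index=list(DNA_BASES), columns=positions)
    info = []
    consensus = []
    for pos in positions:
        col = freqs[pos].to_numpy()
        nz = col[col > 0]
        entropy = float(-(nz * np.log2(nz)).sum())
        info.append(2.0 - entropy)
        covered = {b for b in DNA_BASES if freqs.loc[b, pos] >= consensus_cutoff}
        if not covered:
            covered = {str(freqs[pos].idxmax())}
        consensus.append(iupac_code_for(covered))
    pfm = PositionFrequencyMatrix(
        freqs=freqs, n_pams=len(pams), weighting="uniform" if counts is None else "count"
    )
    summary = MotifSummary(
        consensus="".join(consensus), info_content=info, depleted_count=len(pams)
    )
    return pfm, summary


@dataclass
class PamWheelNode:
    """One node of the hierarchical PAM wheel (a base at one position)."""

    label: str
    count: float
    children: dict[str, "PamWheelNode"] = field(default_factory=dict)

    def total_check(self) -> bool:
        if not self.children:
            return True
        ok = math.isclose(self.count, sum(c.count for c in self.children.values()))
        return ok and all(c.total_check() for c in self.children.values())


def pam_wheel_tree(
    counts: PamCountTable | dict[str, float], order: str = "inward"
) -> PamWheelNode:
    """Aggregate PAM counts position by position into a wheel tree.

    ``order='inward'`` walks from the most distal position toward the
    protospacer (root children are position -k); ``'outward'`` reverses the
    walk.  Node counts sum to the table total at every level.
    """
    if isinstance(counts, PamCountTable):
        mapping = {p: float(c) for p, c in counts.counts.items()}
    else:
        mapping = {p: float(c) for p, c in counts.items()}
    if not mapping:
        raise ValueError("empty table")
    if order not in ("inward", "outward"):
        raise ValueError(f"unknown order: {order!r}")
    root = PamWheelNode(label="", count=sum(mapping.values()))
    for pam, c in mapping.items():
        path = pam if order == "inward" else pam[::-1]
        node = root
        for base in path:
            child = node.children.get(base)
            if child is None:
                child = node.children[base] = PamWheelNode(label=base, count=0.0)
            child.count += c
            node = child
    return root


def krona_rows(node: PamWheelNode) -> list[str]:
    """Flatten a wheel tree to Krona ImportText rows: ``count<TAB>b1<TAB>b2...``."""
    rows: list[str] = []

    def walk(n: PamWheelNode, path: list[str]) -> None:
        if not n.children:
            count = n.count
            rows.append("\t".join([_fmt(count), *path]))
            return
        for base in sorted(n.children):
            walk(n.children[base], path + [base])

    def _fmt(x: float) -> str:
        return str(int(x)) if float(x).is_integer() else f"{x:.6g}"

    walk(node, [])
    return rows


def pfm_to_transfac(pfm: PositionFrequencyMatrix, name: str = "PAM") -> str:
    """Render a PFM as a transfac-style matrix block (Weblogo input)."""
    lines = [f"ID {name}", "BF unknown", "P0\tA\tC\tG\tT"]
    for i, pos in enumerate(pfm.freqs.columns, start=1):
        vals = "\t".join(f"{pfm.freqs.loc[b, pos]:.6f}" for b in DNA_BASES)
        lines.append(f"{i:02d}\t{vals}")
    lines.append("XX")
    lines.append("//")
    return "\n".join(lines) + "\n"
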