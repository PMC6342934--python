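"""Generators for every input the pipeline consumes, with ground truth.

Three experiment designs are emulated:

* **PAM depletion screen** — plasmids carry an 8-base randomized region 5'
  of a fixed protospacer; bacteria expressing the nuclease lose plasmids
  whose PAM supports cleavage, so active PAMs are depleted from the sample
  library relative to an empty-vector control.  The nuclease is a
  :class:`NucleasePamModel`: per-position, per-base activity factors whose
  product gives the cleavage activity of a PAM, and a ``depletion_strength``
  scaling the probability that an active plasmid is eliminated.
* **Amplicon editing** — reads from an edited locus are wild-type, carry one
  net indel inside the cut window (lengths default to the 5-15 bp deletions
  characteristic of Cas12b repair), or are converted by a 120-nt ssODN donor
  carrying a TG->CA edit plus a PAM-disrupting change.
* **Gel lanes** — band intensities under independent per-strand cutting,
  feeding the closed-form cleavage estimator.

Randomness: a single integer seed fans out through
``numpy.random.SeedSequence(seed).spawn(...)`` to one independent stream per
stage (pool construction, per-replicate selection/sampling/errors), in a
fixed documented order, so outputs are byte-identical across runs.
Sequencing errors are substitutions only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._dna import DNA_BASES, check_dna, seq_to_u8
from .amplicon_edit import AmpliconReference, Interval
from .cleavage_quant import GelLane
from .pam_extract import FNPSP1_PROTOSPACER, ReadRecord, condense

_BASE_U8 = seq_to_u8(DNA_BASES)  # codes 0..3 -> ASCII ACGT


@dataclass
class TruthTable:
    """Per-unit ground truth emitted alongside simulated data."""

    records: pd.DataFrame
    kind: str = ""

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class NucleasePamModel:
    """Multiplicative per-position PAM activity model.

    ``weights`` is (positions, 4) over bases ACGT, positions ordered from
    the most distal (-random_len) to -1 adjacent to the protospacer; the
    activity of a PAM is the product of its per-position weights, and an
    active plasmid is eliminated with probability
    ``depletion_strength * activity``.
    """

    weights: np.ndarray
    depletion_strength: float = 1.0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[1] != 4:
            raise ValueError("weights must be (positions, 4)")
        if (self.weights < 0).any() or (self.weights > 1).any():
            raise ValueError("weights must lie in [0, 1]")
        if not 0.0 <= self.depletion_strength <= 1.0:
            raise ValueError("depletion_strength must lie in [0, 1]")

    @property
    def random_len(self) -> int:
        return self.weights.shape[0]

    @classmethod
    def null(cls, random_len: int = 8) -> "NucleasePamModel":
        """No sequence preference and no killing (empty-vector control)."""
        return cls(weights=np.ones((random_len, 4)), depletion_strength=0.0)

    @classmethod
    def from_iupac(
        cls,
        motif: str,
        off_target_activity: float = 0.0,
        depletion_strength: float = 1.0,
    ) -> "NucleasePamModel":
        """Model active exactly on PAMs matching an IUPAC motif.

        Bases covered by the motif letter get weight 1, others
        ``off_target_activity``; e.g. ``"NNNNTTTN"`` is active iff positions
        -4..-2 are TTT.
        """
        from ._dna import IUPAC_CODES

        weights = np.full((len(motif), 4), off_target_activity, dtype=float)
        for i, code in enumerate(motif):
            for b in IUPAC_CODES[code]:
                weights[i, DNA_BASES.index(b)] = 1.0
        return cls(weights=weights, depletion_strength=depletion_strength)

    def activity_codes(self, pam_codes: np.ndarray) -> np.ndarray:
        """Activities for PAMs given as (n, random_len) base-code arrays."""
        pos = np.arange(self.random_len)
        return np.prod(self.weights[pos, pam_codes], axis=1)

    def activity(self, pam: str) -> float:
        codes = np.array([DNA_BASES.index(b) for b in pam])[None, :]
        if codes.shape[1] != self.random_len:
            raise ValueError("PAM length does not match model positions")
        return float(self.activity_codes(codes)[0])


@dataclass
class LibrarySimConfig:
    """Design of one PAM-library depletion experiment."""

    anchor: str = FNPSP1_PROTOSPACER
    random_len: int = 8
    upstream_pad: str = "GGATCC"
    downstream_pad: str = "GAATTC"
    n_plasmids: int = 1_000_000
    reads_per_sample: int = 100_000
    seq_error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        check_dna(self.anchor, "anchor")
        check_dna(self.upstream_pad, "upstream_pad")
        check_dna(self.downstream_pad, "downstream_pad")
        if not self.anchor:
            raise ValueError("anchor must be non-empty")
        if self.random_len < 1:
            raise ValueError("random_len must be >= 1")
        if self.n_plasmids < 1 or self.reads_per_sample < 1:
            raise ValueError("n_plasmids and reads_per_sample must be >= 1")
        if not 0.0 <= self.seq_error_rate < 1.0:
            raise ValueError("seq_error_rate must lie in [0, 1)")


def _apply_substitution_errors(
    codes: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Substitute each base (code 0..3) with a different one at ``rate``."""
    if rate <= 0:
        return codes
    mask = rng.random(codes.shape) < rate
    shifts = rng.integers(1, 4, size=codes.shape)
    return np.where(mask, (codes + shifts) % 4, codes)


def _codes_to_reads(codes: np.ndarray, prefix: str) -> list[ReadRecord]:
    ascii_mat = _BASE_U8[codes]
    seqs = ascii_mat.tobytes().decode("ascii")
    width = ascii_mat.shape[1]
    return [
        ReadRecord(id=f"{prefix}_{i:07d}", seq=seqs[i * width : (i + 1) * width])
        for i in range(ascii_mat.shape[0])
    ]


def _template_codes(cfg: LibrarySimConfig) -> tuple[np.ndarray, int]:
    """Constant read template as base codes; returns (codes, pam offset)."""
    layout = cfg.upstream_pad + "A" * cfg.random_len + cfg.anchor + cfg.downstream_pad
    codes = np.searchsorted(_BASE_U8, seq_to_u8(layout))
    return codes, len(cfg.upstream_pad)


def _emit_reads(
    pool_codes: np.ndarray,
    plasmid_idx: np.ndarray,
    cfg: LibrarySimConfig,
    rng: np.random.Generator,
    prefix: str,
) -> list[ReadRecord]:
    template, pam_off = _template_codes(cfg)
    reads = np.tile(template, (len(plasmid_idx), 1))
    reads[:, pam_off : pam_off + cfg.random_len] = pool_codes[plasmid_idx]
    reads = _apply_substitution_errors(reads, cfg.seq_error_rate, rng)
    return _codes_to_reads(reads, prefix)


def simulate_pam_library(
    model: NucleasePamModel,
    cfg: LibrarySimConfig,
    replicate_id: str = "rep1",
) -> tuple[list[ReadRecord], list[ReadRecord], TruthTable]:
    """One replicate of the depletion screen: (sample, control, truth).

    Control reads are resampled with replacement from the full plasmid pool;
    sample reads from the survivors after each plasmid is eliminated with
    probability ``depletion_strength * activity(PAM)`` (outgrowth after
    transformation).  The truth table records every plasmid's PAM, activity
    and survival.
    """
    if model.random_len != cfg.random_len:
        raise ValueError("model positions must match cfg.random_len")
    streams = np.random.SeedSequence(cfg.seed).spawn(5)
    pool_rng = np.random.Generator(np.random.PCG64(streams[0]))
    pool = pool_rng.integers(0, 4, size=(cfg.n_plasmids, cfg.random_len))
    return _simulate_replicate(pool, model, cfg, streams[1:5], replicate_id)


def _simulate_replicate(
    pool: np.ndarray,
    model: NucleasePamModel,
    cfg: LibrarySimConfig,
    streams: list[np.random.SeedSequence],
    replicate_id: str,
) -> tuple[list[ReadRecord], list[ReadRecord], TruthTable]:
    kill_rng, ctrl_rng, samp_rng, err_rng = (
        np.random.Generator(np.random.PCG64(s)) for s in streams
    )
    activity = model.activity_codes(pool)
    survived = kill_rng.random(len(pool)) >= model.depletion_strength * activity
    if not survived.any():
        raise ValueError("no plasmids survived selection; nothing to sequence")
    ctrl_idx = ctrl_rng.integers(0, len(pool), size=cfg.reads_per_sample)
    survivors = np.nonzero(survived)[0]
    samp_idx = survivors[samp_rng.integers(0, len(survivors), size=cfg.reads_per_sample)]
    sample_reads = _emit_reads(pool, samp_idx, cfg, err_rng, f"sample_{replicate_id}")
    control_reads = _emit_reads(pool, ctrl_idx, cfg, err_rng, f"control_{replicate_id}")
    pams = ["".join(DNA_BASES[c] for c in row) for row in pool]
    truth = TruthTable(
        records=pd.DataFrame(
            {
                "plasmid_id": np.arange(len(pool)),
                "pam": pams,
                "pam_condensed": [condense(p) if len(p) == 8 else p for p in pams],
                "activity": activity,
                "survived": survived,
            }
        ),
        kind="pam_library",
    )
    return sample_reads, control_reads, truth


@dataclass
class PamScreenData:
    """Replicated screen output: parallel sample/control read lists."""

    sample_reads: list[list[ReadRecord]]
    control_reads: list[list[ReadRecord]]
    truths: list[TruthTable]
    replicate_ids: list[str]


def simulate_pam_screen(
    model: NucleasePamModel, cfg: LibrarySimConfig, n_replicates: int = 2
) -> PamScreenData:
    """Replicated depletion screen sharing one plasmid library pool.

    The pool is drawn once; each replicate applies independent selection,
    resampling and sequencing error (independent transformations of the same
    library prep).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    root = np.random.SeedSequence(cfg.seed)
    streams = root.spawn(1 + 4 * n_replicates)
    pool_rng = np.random.Generator(np.random.PCG64(streams[0]))
    pool = pool_rng.integers(0, 4, size=(cfg.n_plasmids, cfg.random_len))
    data = PamScreenData([], [], [], [])
    for r in range(n_replicates):
        rep = f"rep{r + 1}"
        sample, control, truth = _simulate_replicate(
            pool, model, cfg, streams[1 + 4 * r : 5 + 4 * r], rep
        )
        data.sample_reads.append(sample)
        data.control_reads.append(control)
        data.truths.append(truth)
        data.replicate_ids.append(rep)
    return data


# ---------------------------------------------------------------------------
# Amplicon editing


@dataclass
class AmpliconSimConfig:
    """Design of one amplicon-sequencing editing experiment.

    ``indel_length_distribution`` maps signed net indel lengths to
    probabilities (negative = deletion); the default concentrates on the
    5-15 bp deletions typical of Cas12b end-joining outcomes.
    """

    reference: AmpliconReference
    indel_rate: float = 0.3
    hdr_rate: float = 0.0
    indel_length_distribution: dict[int, float] = field(
        default_factory=lambda: {-length: 1.0 / 11.0 for length in range(5, 16)}
    )
    donor_len: int = 120
    read_len: int | None = None
    seq_error_rate: float = 0.001
    n_reads: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.indel_rate < 0 or self.hdr_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.indel_rate + self.hdr_rate > 1.0 + 1e-12:
            raise ValueError("indel_rate + hdr_rate must be <= 1")
        total = sum(self.indel_length_distribution.values())
        if not np.isclose(total, 1.0):
            raise ValueError("indel length distribution must sum to 1")
        if 0 in self.indel_length_distribution:
            raise ValueError("net indel length 0 is not an indel")
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        if not 0.0 <= self.seq_error_rate < 1.0:
            raise ValueError("seq_error_rate must lie in [0, 1)")


def default_amplicon_reference(seed: int = 7) -> AmpliconReference:
    """A synthetic 180-nt amplicon emulating the ssODN-editing design.

    Plants an ATTC PAM, a 23-nt protospacer 3' of it, a 36-nt HDR window
    starting at the PAM with a TG dinucleotide at its centre, and donor
    edits: the TG->CA conversion plus a PAM-disrupting T->G change.
    """
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    seq = list("".join(DNA_BASES[c] for c in rng.integers(0, 4, size=180)))
    seq[60:64] = "ATTC"
    seq[77:79] = "TG"
    sequence = "".join(seq)
    return AmpliconReference(
        sequence=sequence,
        pam=Interval(60, 64),
        spacer=Interval(64, 87),
        cut_window=Interval(75, 95),
        hdr_window=Interval(60, 96),
        donor_edits=[(77, "TG", "CA"), (61, "T", "G")],
        key_edit=0,
        name="synthetic_locus",
    )


def make_donor(ref: AmpliconReference, length: int = 120) -> str:
    """The ssODN donor: edited reference, centred on the HDR window."""
    edited = ref.edited_sequence()
    center = (ref.hdr_window.start + ref.hdr_window.end) // 2
    start = max(0, min(center - length // 2, len(edited) - length))
    return edited[start : start + length]


def validate_donor(ref: AmpliconReference, donor: str) -> None:
    """Check donor homology arms match the reference outside the edits."""
    expected = make_donor(ref, len(donor))
    if donor != expected:
        raise ValueError("donor arms inconsistent with reference and edit list")


def simulate_amplicon_reads(
    cfg: AmpliconSimConfig,
) -> tuple[list[ReadRecord], TruthTable]:
    """Simulated amplicon reads with per-read truth.

    Each read is the full amplicon after its outcome: wild-type, one net
    indel (length from the configured distribution, placed uniformly inside
    the cut window), or the donor-converted allele; substitution sequencing
    errors are applied afterwards.
    """
    ref = cfg.reference
    streams = np.random.SeedSequence(cfg.seed).spawn(2)
    rng = np.random.Generator(np.random.PCG64(streams[0]))
    err_rng = np.random.Generator(np.random.PCG64(streams[1]))
    lengths = sorted(cfg.indel_length_distribution)
    probs = np.array([cfg.indel_length_distribution[k] for k in lengths])
    edited = ref.edited_sequence()
    u = rng.random(cfg.n_reads)
    reads: list[ReadRecord] = []
    rows = []
    for i in range(cfg.n_reads):
        if u[i] < cfg.indel_rate:
            net = int(rng.choice(lengths, p=probs))
            pos = int(rng.integers(ref.cut_window.start, ref.cut_window.end))
            if net < 0:
                seq = ref.sequence[:pos] + ref.sequence[pos - net :]
            else:
                ins = "".join(DNA_BASES[c] for c in rng.integers(0, 4, size=net))
                seq = ref.sequence[:pos] + ins + ref.sequence[pos:]
            outcome = "INDEL"
        elif u[i] < cfg.indel_rate + cfg.hdr_rate:
            seq = edited
            net = 0
            outcome = "HDR"
        else:
            seq = ref.sequence
            net = 0
            outcome = "WT"
        if cfg.read_len is not None and len(seq) > cfg.read_len:
            seq = seq[: cfg.read_len]
        codes = np.searchsorted(_BASE_U8, seq_to_u8(seq))
        codes = _apply_substitution_errors(codes[None, :], cfg.seq_error_rate, err_rng)
        seq = "".join(DNA_BASES[c] for c in codes[0])
        rid = f"amp_{i:06d}"
        reads.append(ReadRecord(id=rid, seq=seq))
        rows.append({"read_id": rid, "outcome": outcome, "net_indel_length": net})
    truth = TruthTable(records=pd.DataFrame(rows), kind="amplicon")
    return reads, truth


# ---------------------------------------------------------------------------
# Gel lanes


@dataclass
class GelSimConfig:
    """Independent per-strand cutting model behind one gel lane."""

    p_target: float
    p_nontarget: float
    total_signal: float = 100.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, p in (("p_target", self.p_target), ("p_nontarget", self.p_nontarget)):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.total_signal <= 0:
            raise ValueError("total_signal must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def simulate_gel_lanes(cfg: GelSimConfig, lane_id: str = "lane1") -> tuple[GelLane, TruthTable]:
    """One simulated lane plus its ground truth.

    Band masses under independent per-strand cuts with probabilities
    ``p_t``, ``p_nt``: the uncut band is ``(1-p_t)(1-p_nt)`` of the signal,
    the nicked/single-cut band carries the single-cut mass and the third
    band the double-cut mass.  Gaussian noise (sd ``noise_sd``) is added per
    band and truncated at zero.
    """
    pt, pnt, total = cfg.p_target, cfg.p_nontarget, cfg.total_signal
    a = total * (1 - pt) * (1 - pnt)
    b = total * (pt * (1 - pnt) + (1 - pt) * pnt)
    c = total * pt * pnt
    if cfg.noise_sd > 0:
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(cfg.seed)))
        a, b, c = (max(0.0, x + rng.normal(0, cfg.noise_sd)) for x in (a, b, c))
    uncut_frac = (1 - pt) * (1 - pnt)
    truth = TruthTable(
        records=pd.DataFrame(
            [
                {
                    "lane_id": lane_id,
                    "p_target": pt,
                    "p_nontarget": pnt,
                    "expected_percent": 100.0 * (1.0 - float(np.sqrt(uncut_frac))),
                }
            ]
        ),
        kind="gel",
    )
    return GelLane(a=a, b=b, c=c, lane_id=lane_id), truth
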