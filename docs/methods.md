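# Methods

This note documents the generative models, the analysis procedures, the
parameter choices that matter, and what the validation does and does not
establish.

## 1. Depletion-screen model

### Generative model

A plasmid library carries a fully randomized 8-base region immediately 5′
of a fixed 31-nt protospacer anchor (the FnPSP1 target site,
`GAGAAGTCATTTAATAAGGCCACTGTTAAAA`). The simulated nuclease is a
`NucleasePamModel`: an 8×4 matrix of per-position, per-base activity
factors in [0, 1], positions ordered −8..−1 with −1 adjacent to the
protospacer. A PAM's activity is the **product** of its per-position
factors; a plasmid is eliminated with probability
`depletion_strength × activity`. The multiplicative form was chosen over
additive alternatives because it is monotone in every position, spans
[0, 1] by construction, and makes "required" positions (factor 0 for
disallowed bases) compose naturally into IUPAC-style rules.

One replicate draws: elimination (Bernoulli per plasmid), a control read
set resampled with replacement from the **full** pool (empty-vector
control), a sample read set resampled with replacement from the
**survivors** (modelling overnight outgrowth after transformation, which
re-equilibrates plasmid abundances among survivors), and per-base
substitution sequencing errors. Replicates share one library pool but
apply independent selection/sampling/error draws, matching independent
transformations of a single library prep.

Reads are laid out `upstream_pad + PAM(8) + anchor + downstream_pad`. The
pads are short cloning-scar-like sequences (`GGATCC`, `GAATTC`); the true
plasmid backbone context is not part of the model and the pads are
arbitrary, configurable defaults.

### Defaults and why

| parameter | default | rationale |
|---|---|---|
| `random_len` | 8 nt | the library design; condensed to 6 downstream |
| `n_plasmids` | 1,000,000 | ≈15× coverage of the 65,536 8-mers; real screens transform 10⁶–10⁷ CFU, so count noise should be read-depth-limited, not library-granularity-limited. At ~10⁵ plasmids an active 6-mer would retain ~1 surviving plasmid and outgrowth resampling would amplify single-plasmid artifacts no real screen shows. |
| `reads_per_sample` | 100,000 | ≈24 reads per condensed 6-mer; enough to resolve ≥4-fold depletion at ~5σ |
| `seq_error_rate` | 0.001/base | Illumina-scale substitution rate; errors are substitutions only so the extraction-stage truth stays unambiguous |
| `depletion_strength` | model-level, swept in tests | the real per-PAM elimination probability is unknown; recovery is validated across 0.5–1.0 |

**Seed fan-out.** Every generator takes one integer seed and spawns
independent `numpy` `SeedSequence` child streams in a fixed order (library
pool; then per replicate: elimination, control sampling, sample sampling,
sequencing error). Identical configurations therefore produce
byte-identical output.

### Extraction and counting

The anchor is located per read by substitution-only (Hamming) matching,
best position wins, leftmost on ties, default tolerance 1 mismatch; gaps
are not allowed because the randomized region's offset relative to the
anchor must stay fixed. The 8 bases immediately 5′ of the anchor are the
PAM, written 5′→3′ (position −1 adjacent to the protospacer). Reads whose
window is truncated or contains a non-ACGT base are dropped from
`valid_reads` (no quality filtering is applied by default; the original
screen's filter rules are unpublished, so ours are declared, not
inferred). Counting is vectorised over equal-length read batches; a
per-read scalar path defines the reference semantics and the two are
cross-checked in tests.

Because the screen showed no base preference at positions −8/−7, count
tables are **condensed** to the 6 positions nearest the protospacer by
dropping the two distal bases; condensation commutes exactly with
counting (tested as an identity).

### Scoring and calling

Per 6-mer and replicate: `log2(f_control / f_sample)` with pseudocounted
frequencies `(count + 0.5) / (valid + 0.5·4^k)`. The pseudocount of 0.5
keeps scores finite at zero sample counts while perturbing well-covered
PAMs by <2%. The published screen's statistic and threshold are not
stated anywhere we could find, so the defaults are declared choices: call
depleted when **every** replicate reaches log2 ≥ 2 (4-fold). The
all-replicates rule trades a little sensitivity for strong null
specificity (a false call must survive two independent noise draws).

At the default depth the screen resolves strong depletion cleanly;
validation sweeps show the resolution limits: at 10⁴ reads (~2.4 reads
per 6-mer) the zero-count tail of inactive PAMs dominates rank-based
selection, and 2-fold depletion (strength 0.5) is below the noise floor
at that depth. This is a property of the experiment geometry, not the
estimator.

### Motif summaries

The position frequency matrix over a called PAM set is uniform-weighted
by default (optionally count/depletion-weighted; whether the original
figures weighted their wheels is unknown, so both are provided).
Information content per position is `2 − H` bits. The IUPAC consensus
letter covers all bases with frequency ≥ 0.25 (just above the uniform
background). Caveat: at uninformative positions the base frequencies
jitter around the cutoff, so the consensus letter there is sampling
noise — interpret consensus letters together with the information-content
track. PAM wheels are emitted as Krona `ImportText` rows
(`count<TAB>base…`), walking positions distal→proximal by default.

## 2. Amplicon edit calling

### Alignment

Reads are aligned with an affine-gap Gotoh DP (numba-compiled): match +2,
mismatch −3, gap open −6 (a length-1 gap), extend −1 per additional gap
base. The alignment is global in the read and free at the reference ends,
the standard geometry for an amplicon read laid on a longer reference —
a read that is an exact reference substring aligns with no events. Among
co-optimal alignments every internal gap run is shifted to its leftmost
score-equivalent placement, making indel coordinates deterministic; the
free terminal skips are rendered as gap columns but never counted as
events. The implementation is validated against Biopython's independent
`PairwiseAligner` on randomized pairs (score identity) and against
hand-enumerated co-optimal placements.

### Classification

Precedence per read: **HDR_PERFECT** if all donor edits are present and
the 36-nt HDR window matches the donor-edited reference exactly;
**HDR_CONVERTED** if the key TG→CA edit is present (other events,
including indels, may co-occur and are noted); **INDEL** if the net
signed indel length of events overlapping the cut window is nonzero;
otherwise **WT**. Overlap (not start-containment) semantics attribute
left-normalised deletions that straddle the window edge to the cut site,
as amplicon quantification windows conventionally do. Substitutions
outside the HDR window never change a read's class — this is the
sequencing-error tolerance. Reads scoring below half the perfect-match
score for their length are **AMBIGUOUS** and excluded from all rate
denominators; reads shorter than 40 nt are filtered before alignment.

Summary metrics: indel rate (% of classified reads), mean absolute net
indel length over indel reads with the full signed-length histogram, the
TG→CA conversion rate (converted + perfect reads — the conversion
frequency read off gray-bar style), and the perfect-edit rate (exact
36-nt window). All coordinates are 0-based half-open.

### Synthetic locus

The default reference is a 180-nt synthetic amplicon with a planted ATTC
PAM at 60, a 23-nt protospacer at 64–87, a 20-bp cut window centred on
the expected distal cleavage region (Cas12b-family nucleases cut
~17–24 nt from the PAM; the exact position for this enzyme is not
published, so the window is configurable per target), a 36-nt HDR window
starting at the PAM, and donor edits TG→CA at its centre plus a
PAM-disrupting T→G. The 120-nt donor is the edited reference centred on
the HDR window, and donor/reference arm consistency is validated.
Simulated indel reads carry one net indel placed uniformly in the cut
window with lengths defaulting to 5–15 bp deletions (equal weights), the
deletion range characteristic of this nuclease family's repair outcomes;
HDR reads are the fully converted allele. The simulation does not model
PCR bias, chimeras, paired-end overlap, quality-score-dependent errors,
or complex (multi-event) repair alleles — recovery tests therefore
establish estimator correctness under clean single-event outcomes, not
robustness to those artifacts.

## 3. Gel quantitation

Under independent per-strand cutting with probabilities `p_t`, `p_nt`,
the uncut band mass is proportional to `(1−p_t)(1−p_nt)`; the estimator
`100 × (1 − sqrt(a/(a+b+c)))` therefore returns
`100 × (1 − sqrt((1−p_t)(1−p_nt)))` — exactly `100p` when both strands
cut at `p` (verified to 1e-9 on a 101-point grid), and the geometric-mean
equivalent rate when they differ. No background subtraction is applied by
default (an optional constant offset is available); values of
`(b+c)/(a+b+c) > 1` are impossible for valid intensities and inputs are
validated rather than clamped. Lane noise is additive Gaussian per band,
truncated at zero.

## 4. PAM-site survey

IUPAC patterns are compiled to explicit character classes (subject `N`
matches nothing), scanned on the forward strand and, for minus-strand
sites, as the reverse-complement pattern on the same axis; a site
requires the full spacer (default 23 nt) to fit 3′ of the PAM in the
site's orientation. All overlapping sites are reported — "number of
targetable sites" semantics — with 0-based half-open coordinates, the
strand flag, and BED6 output. Density is sites per kilobase of surveyed
sequence; on i.i.d. uniform sequence the both-strand expectations are
31.25/kb (ATTN) and 23.44/kb (TTTV), used as analytic oracles.

## 5. Validation scales

The shipped tests run the full pipeline at reduced but statistically
adequate sizes chosen as the package's own validation budget: the
recovery screen at 10⁶ plasmids × 10⁵ reads × 2 replicates, the null
specificity over 20 seeded screens at 2×10⁵ plasmids (pool size is
irrelevant under the null because sample and control resample the same
pool), indel/HDR recovery on 2000 and 1000 reads, alignment
cross-checks on 500 random pairs ≤ 60 nt, and site-scan oracles on
100 × 200-nt sequences plus 10⁶ nt for density. `scripts/acceptance.py`
re-runs the same computations end-to-end from a single seed.

## 6. Known limitations

- The depletion statistic, call threshold, read filters and indel-window
  settings of the original analyses are unpublished; all defaults here
  are declared package choices, and numerical identity with published
  percentages is not claimed.
- Activity is multiplicative across positions; epistatic PAM preferences
  are out of scope.
- Sequencer indel errors are off by default; with them enabled the
  extraction-stage truth for reads with errors inside the PAM window
  becomes ambiguous.
- HDR simulation emits only perfect conversions; partial-tract
  conversion arises in the caller's vocabulary (HDR_CONVERTED) but not
  in the generator.
- The survey reports raw site counts: no uniqueness, chromatin or
  mismatch-tolerance filtering.
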