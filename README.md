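# pamscreen

Analysis pipeline for characterising Cas12b-family CRISPR nucleases from
sequencing and gel readouts: PAM discovery from randomized-library bacterial
depletion screens, amplicon-sequencing edit-outcome quantification (indels
and homology-directed repair), closed-form gel cleavage/nicking
quantitation, and genome surveys of PAM-compatible target sites. A
first-class synthetic-data module generates every input the pipeline
consumes — with machine-readable ground truth — so each stage can be
validated by parameter recovery.

## Who it is for

Groups running (or reanalysing) nuclease-characterisation experiments of
the depletion-screen design: bacteria expressing a candidate nuclease are
transformed with a plasmid library carrying a randomized region (here 8
bases) 5′ of a fixed protospacer; plasmids whose PAM supports cleavage are
lost, so sequencing the surviving library against an empty-vector control
reveals active PAMs as depleted k-mers. The same package quantifies the
downstream readouts of such projects: editing outcomes at amplicon-sequenced
loci and band-based cleavage fractions from in vitro assays.

## The statistics at the core

**Depletion score.** For each condensed 6-mer PAM *p*, with pseudocounted
relative frequencies in control and sample libraries,

    score(p) = log2( f_control(p) / f_sample(p) ),
    f_x(p) = (count_x(p) + c) / (valid_x + c·4^k),   c = 0.5

computed per replicate; a PAM is called depleted when every replicate's
score reaches the threshold (default log2 ≥ 2, i.e. 4-fold). Called sets
are summarised as a position frequency matrix, per-position information
content `2 − H` bits, an IUPAC consensus, and Krona-ready PAM-wheel trees.

**Edit calling.** Reads are aligned to the amplicon with an affine-gap
Gotoh DP (match +2, mismatch −3, gap open −6, gap extend −1; global in the
read, free terminal gaps on the reference; co-optimal gaps placed
leftmost), then classified with the precedence HDR-perfect (all donor
edits present and an exact 36-nt window match) → HDR-converted (the TG→CA
key edit present) → indel (nonzero net indel overlapping the cut window)
→ wild type.

**Gel quantitation.** With band intensities *a* (uncut full length) and
*b*, *c* (products), the per-strand cleavage/nicking percentage under
independent strand cutting is

    100 × (1 − sqrt(1 − (b + c)/(a + b + c)))

which exactly inverts the generative model in which the uncut fraction is
`(1 − p)²`.

## Worked example

`examples/` holds one narrative script per capability. Running
`python examples/pam_discovery.py` simulates a nuclease requiring TTT at
PAM positions −4..−2 (depletion strength 0.95, 300k-plasmid library,
50k reads × 2 replicates) and recovers it:

```
replicate 1: 49988/50000 reads usable
57 of 4096 observed 6-mers called depleted (>=4-fold)
consensus (positions -6..-1): YMTTTG
information content (bits): 0.02 0.01 2.00 2.00 2.00 0.00
most depleted PAMs:
  CATTTT  log2 depletion 5.00
  GGTTTG  log2 depletion 4.95
  ...
```

The three TTT positions carry the full 2 bits of information each, while
the unconstrained positions carry ~0 (their consensus letters are sampling
jitter around the 0.25 inclusion cutoff — read the information-content
track, not the letters, at uninformative positions).
`python examples/amplicon_editing.py` prints the recovered indel rate,
mean indel size, and TG→CA conversion/perfect-edit rates next to the
generative truth; `gel_quantitation.py` and `pam_site_survey.py` do the
same for the gel estimator and ATTN/TTTV site densities.

A thin CLI mirrors the pipeline for shell use
(`pamscreen simulate | pam-count | deplete | motif | wheel | indels | hdr |
gel | survey`); see `pamscreen --help`.

## Layout

- `src/pamscreen/synthetic_data.py` — generators with truth tables
- `src/pamscreen/pam_extract.py` — anchored PAM extraction and counting
- `src/pamscreen/pam_depletion.py` — depletion scores, calls, motifs, wheels
- `src/pamscreen/amplicon_edit.py` — alignment and WT/indel/HDR calling
- `src/pamscreen/cleavage_quant.py` — gel-band cleavage estimation
- `src/pamscreen/pam_survey.py` — IUPAC PAM-site enumeration (both strands)
- `docs/methods.md` — models, assumptions, parameter choices, limitations
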