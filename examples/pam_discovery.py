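"""PAM discovery from a simulated bacterial depletion screen.

Simulates a nuclease that cleaves only when the PAM carries TTT at
positions -4..-2, runs the screen through counting, depletion scoring and
calling, and prints the recovered motif.  A depletion score is
log2(control_freq / sample_freq): ~0 for inert PAMs, strongly positive for
PAMs the nuclease can use (those plasmids were eliminated).
"""

from pamscreen import (
    LibrarySimConfig,
    NucleasePamModel,
    build_motif,
    call_depleted,
    compute_depletion,
    count_pams,
    krona_rows,
    pam_wheel_tree,
    simulate_pam_screen,
)

model = NucleasePamModel.from_iupac("NNNNTTTN", depletion_strength=0.95)
cfg = LibrarySimConfig(n_plasmids=300_000, reads_per_sample=50_000, seed=42)
screen = simulate_pam_screen(model, cfg, n_replicates=2)

samples = [count_pams(r, condense_pams=True) for r in screen.sample_reads]
controls = [count_pams(r, condense_pams=True) for r in screen.control_reads]
print(f"replicate 1: {samples[0].valid_reads}/{samples[0].total_reads} reads usable")

table = compute_depletion(samples, controls, pseudocount=0.5)
called = call_depleted(table, threshold=2.0, rule="all-replicates")
print(f"{len(called)} of {len(table.pams)} observed 6-mers called depleted (>=4-fold)")

pfm, motif = build_motif(called)
print(f"consensus (positions -6..-1): {motif.consensus}")
print("information content (bits):",
      " ".join(f"{x:.2f}" for x in motif.info_content))

top = table.frame.loc[sorted(called)]["log2_depletion"].nlargest(5)
print("most depleted PAMs:")
for pam, score in top.items():
    print(f"  {pam}  log2 depletion {score:.2f}")

rows = krona_rows(pam_wheel_tree(controls[0]))
print(f"PAM wheel: {len(rows)} Krona rows (write to a file for Krona rendering)")
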