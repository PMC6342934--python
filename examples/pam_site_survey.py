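"""Survey PAM-compatible target sites on both strands of a sequence.

Compares the density of ATTN sites (Cas12b-style) against TTTV sites
(Cas12a-style) on uniform random sequence; on i.i.d. bases the analytic
expectations are 2 x (1/4)^3 x 1000 = 31.25/kb for ATTN and
2 x (1/4)^3 x (3/4) x 1000 = 23.44/kb for TTTV, both strands combined.
"""

import random

from pamscreen import PamPattern, scan_sites, site_density, sites_to_bed

rng = random.Random(1)
seq = "".join(rng.choice("ACGT") for _ in range(200_000))

for pam, analytic in (("ATTN", 31.25), ("TTTV", 23.44)):
    pattern = PamPattern(pam, spacer_len=23)
    sites = scan_sites(seq, pattern)
    density = site_density(sites)
    per_strand = site_density(sites, per_strand=True)
    print(f"{pam}: {len(sites)} sites in {len(seq)/1000:.0f} kb "
          f"-> {density:.2f}/kb (analytic {analytic:.2f}); "
          f"+ strand {per_strand['+']:.2f}, - strand {per_strand['-']:.2f}")

toy = "ATTC" + "G" * 23
sites = scan_sites(toy, PamPattern("ATTN", spacer_len=23))
print("\ntoy 27-nt sequence BED output:")
print(sites_to_bed(sites, PamPattern("ATTN", spacer_len=23)).strip())
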