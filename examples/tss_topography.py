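"""Positional STR enrichment around transcription start sites.

Builds a genome whose genes carry an STR planted just upstream of each
TSS, then profiles STR base occurrences over a +/-500 bp oriented window
and normalizes by the window mean.
"""

import numpy as np

from strscape import (
    SimConfig,
    find_strs,
    generate_genome,
    landmark_windows,
    positional_profile,
    pwm_estimate,
    relative_enrichment,
)
from strscape.topography import nucleotide_counts

rng = np.random.default_rng(6)
seq = list(generate_genome(SimConfig(length=120_000, gc=0.5, seed=6)))
genes = []
for g in range(40):
    start = 1500 + g * 2900
    genes.append(("seq", start, start + 1200, "+"))
    # plant a (CA)n array 60 bp upstream of each TSS
    seq[start - 90 : start - 60] = list("CA" * 15)
seq = "".join(seq)

strs = find_strs(seq)
lengths = {"seq": len(seq)}
windows = landmark_windows(genes, lengths, "TSS", flank=500)
prof = positional_profile(strs, windows, lengths, flank=500)
rel = relative_enrichment(prof)

print(f"profile length: {len(prof.counts)} offsets (-500..+500)")
peak = int(np.nanargmax(rel)) - 500
print(f"peak relative enrichment {np.nanmax(rel):.1f} at offset {peak:+d} bp")
print(f"mean relative enrichment across the window: {np.nanmean(rel):.3f}")

pwm = pwm_estimate(nucleotide_counts({"seq": seq}, strs, windows), alpha=1.0)
col = pwm.probabilities[:, 500 - 75]  # inside the planted arrays
print("PWM column near the planted array (A,C,G,T):", np.round(col, 3))
print(
    "\nThe enrichment peaks where the arrays were planted (~-60 to -90 bp\n"
    "upstream), and the probability matrix there is dominated by the A and\n"
    "C of the CA unit; the window mean is 1 by construction."
)
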