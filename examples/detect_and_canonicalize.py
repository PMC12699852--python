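"""Detect perfect STRs in a small synthetic genome and canonicalize units.

Plants three repeat arrays in a 20 kb random genome, runs the detector,
and groups the findings by canonical motif class (cyclic shifts and
reverse complements collapse to one representative).
"""

from strscape import (
    PlantSpec,
    SimConfig,
    canonical_motif,
    find_strs,
    generate_genome,
    plant_strs,
)

seq = generate_genome(SimConfig(length=20_000, gc=0.5, seed=1))
seq, truth = plant_strs(
    seq,
    [PlantSpec("CA", 15), PlantSpec("CCCTAA", 8), PlantSpec("GAA", 10)],
    seed=2,
)

records = find_strs(seq)
print(f"planted {len(truth)} arrays; detector found {len(records)} runs total")
for r in records:
    tag = "planted" if any(t.start == r.start for t in truth) else "chance"
    print(
        f"  [{r.start:>6}-{r.end:<6}) unit={r.unit:<6} period={r.period} "
        f"copies={r.copies:<3} class={canonical_motif(r.unit):<6} ({tag})"
    )
print(
    "\nEvery planted array is recovered at its exact coordinates; extra runs\n"
    "are chance repeats of the random background, all >= 10 bp with >= 3\n"
    "copies of a 1-9 bp unit. The class column shows that e.g. a CA run and\n"
    "a TG run belong to the same motif class (representative AC)."
)
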