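"""Fold-enrichment profile of STR density along a chromosome.

Partitions a synthetic 1 Mb chromosome into 100 kb bins, with a dense
satellite-like block of period-5 repeats planted in the middle — the
pattern centromeric satellite arrays produce in telomere-to-telomere
assemblies.
"""

from strscape import (
    PlantSpec,
    SimConfig,
    bin_profile,
    find_strs,
    generate_genome,
    genome_density,
    merge_intervals,
    plant_strs,
)

seq = generate_genome(SimConfig(length=1_000_000, gc=0.5, seed=8))
specs = [PlantSpec("AATGG", 60, count=1, position=450_000 + i * 400) for i in range(120)]
specs += [PlantSpec("AC", 20, count=40)]
seq, _ = plant_strs(seq, specs, seed=9)

strs = find_strs(seq)
density = genome_density(merge_intervals(strs), len(seq))
prof = bin_profile(strs, "seq", len(seq), density, bin_size=100_000, mode="overlap")

print(f"genome-wide STR density: {density:.2f} bp/kB")
print("bin  start      fold_enrichment  period-5 fraction")
for _, row in prof.table.iterrows():
    bar = "#" * int(round(4 * row["fold_enrichment"]))
    print(
        f"{int(row['bin']):>3}  {int(row['start']):>8}  "
        f"{row['fold_enrichment']:>6.2f} {bar:<12} {row['fraction_period_5']:.2f}"
    )
print(
    "\nThe bin containing the planted block shows a strong fold enrichment\n"
    "over the genome-wide density and is almost entirely period-5 repeat,\n"
    "mirroring how pericentromeric satellite stands out in binned profiles."
)
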