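"""Two-stage averaging of STR densities across an unbalanced taxonomy.

Densities (merged STR bp per kB) are averaged over assemblies within each
species, then over species within each phylum — so a species sequenced a
hundred times counts no more than one sequenced once.
"""

import numpy as np

from strscape import generate_taxonomy, rank_average_density, species_density

# one phylum with a heavily resequenced species, one with a single species
tax = generate_taxonomy(
    {"Bacteria": [2, 1]},
    assemblies_per_species={
        "Bacteria_phylum0_sp0": 100,  # 100 assemblies
        "Bacteria_phylum0_sp1": 1,
        "Bacteria_phylum1_sp0": 1,
    },
)
rng = np.random.default_rng(0)
asm_density = {
    a: (8.0 + rng.normal(0, 0.1) if sp == "Bacteria_phylum0_sp0" else 2.0)
    for a, sp in zip(tax["assembly_id"], tax["species"])
}

f_s = species_density(asm_density, tax)
f_r = rank_average_density(f_s, tax, "phylum")
print("F(S) per species (mean over its assemblies):")
for sp, d in sorted(f_s.items()):
    print(f"  {sp:<22} {d:6.2f} bp/kB")
print("F(R) per phylum (unweighted mean over species):")
for ph, d in sorted(f_r.items()):
    print(f"  {ph:<22} {d:6.2f} bp/kB")
print(
    "\nphylum0's mean sits midway between its two species (~5 bp/kB) even\n"
    "though one species contributes 100x more assemblies: the two-stage\n"
    "average removes sequencing-effort bias."
)
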