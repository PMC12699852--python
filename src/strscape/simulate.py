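"""Synthetic genomes, annotations, taxonomies and variant sets.

Every downstream stage of the pipeline can be exercised without any
download: genomes are first-order Markov (or i.i.d.) nucleotide sequences
with controllable GC / dinucleotide composition, STR arrays are planted at
known truth coordinates (buffered so the truth equals the detector's
maximal run), gene models are packed into valid GFF3, variants are placed
inside vs outside the STR union at controllable odds, and taxonomies can
be arbitrarily unbalanced.  All generators are deterministic given a seed
and emit standard formats the pipeline's own readers parse.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .repeats import StrRecord, reverse_complement

__all__ = [
    "PlantSpec",
    "SimConfig",
    "generate_genome",
    "plant_strs",
    "generate_annotation",
    "generate_variants",
    "generate_taxonomy",
]

_NUC = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantSpec:
    """One family of STR arrays to plant: ``count`` arrays of ``copies``
    copies of ``unit``, at a fixed position or at random positions."""

    unit: str
    copies: int
    count: int = 1
    position: int | str = "random"


@dataclass
class SimConfig:
    """Study conditions for one synthetic genome."""

    length: int = 100_000
    gc: float = 0.5
    transition: np.ndarray | None = None  # 4x4 row-stochastic, ACGT order
    seed: int = 0
    n_genes: int = 20
    gene_length: int = 1000
    n_variants: int = 0
    rho: float = 1.0  # indel rate inside STRs relative to outside
    class_mix: tuple[float, float, float] = (0.6, 0.2, 0.2)  # sub, ins, del

    def __post_init__(self):
        if self.length < 1000:
            raise ValueError("genome length must be >= 1000")
        if self.rho < 0:
            raise ValueError("rho must be >= 0")


def generate_genome(config: SimConfig) -> str:
    """Random nucleotide sequence at the requested composition.

    With a transition matrix: a first-order Markov chain started from its
    stationary distribution.  Without: i.i.d. draws with P(G) = P(C) =
    gc/2 and P(A) = P(T) = (1-gc)/2.
    """
    rng = np.random.default_rng(config.seed)
    n = config.length
    if config.transition is not None:
        T = np.asarray(config.transition, dtype=float)
        if T.shape != (4, 4) or (T < 0).any():
            raise ValueError("transition must be a non-negative 4x4 matrix")
        rowsums = T.sum(axis=1)
        if (rowsums == 0).any():
            raise ValueError("transition matrix has an empty row")
        T = T / rowsums[:, None]
        # stationary start
        vals, vecs = np.linalg.eig(T.T)
        pi = np.real(vecs[:, np.argmin(np.abs(vals - 1))])
        pi = np.abs(pi) / np.abs(pi).sum()
        states = np.empty(n, dtype=np.int8)
        states[0] = rng.choice(4, p=pi)
        # vectorized chain: inverse-CDF with one uniform per step
        cdf = np.cumsum(T, axis=1)
        u = rng.random(n)
        for i in range(1, n):
            states[i] = np.searchsorted(cdf[states[i - 1]], u[i])
        return "".join(_NUC[states])
    p = np.array([(1 - config.gc) / 2, config.gc / 2, config.gc / 2, (1 - config.gc) / 2])
    return "".join(rng.choice(_NUC, size=n, p=p))


def _buffer_base(unit: str) -> str:
    """A base differing from both the unit's first and last characters, so
    a planted array cannot extend by chance into its flanks."""
    for c in "ACGT":
        if c != unit[0] and c != unit[-1]:
            return c
    return "A"  # unreachable for |alphabet| = 4


def plant_strs(
    seq: str,
    specs: Sequence[PlantSpec],
    seed: int = 0,
    min_gap: int = 5,
) -> tuple[str, list[StrRecord]]:
    """Overwrite ``seq`` with STR arrays at known coordinates.

    Arrays are pairwise non-overlapping, separated by at least ``min_gap``
    bases, and flanked by a buffer base chosen so that the truth
    coordinates are exactly the detector's maximal run.  Returns the
    modified sequence and the truth records (sorted by start).
    """
    rng = np.random.default_rng(seed)
    chars = list(seq.upper())
    n = len(chars)
    total = sum((len(s.unit) * s.copies + 2) * s.count for s in specs)
    if total > n // 2:
        raise ValueError("total planted length exceeds half the genome")
    occupied: list[tuple[int, int]] = []
    truth: list[StrRecord] = []

    def free(a: int, b: int) -> bool:
        return all(b + min_gap <= s or a >= e + min_gap for s, e in occupied)

    for spec in specs:
        unit = spec.unit.upper()
        arr_len = len(unit) * spec.copies
        for k in range(spec.count):
            if spec.position != "random":
                start = int(spec.position) + k * (arr_len + min_gap + 2)
                if not (1 <= start and start + arr_len + 1 <= n) or not free(
                    start - 1, start + arr_len + 1
                ):
                    raise ValueError(f"cannot place array at position {start}")
            else:
                for _ in range(10_000):
                    start = int(rng.integers(1, n - arr_len - 1))
                    if free(start - 1, start + arr_len + 1):
                        break
                else:
                    raise ValueError("cannot place planted arrays without overlap")
            buf = _buffer_base(unit)
            chars[start - 1] = buf
            chars[start : start + arr_len] = list(unit * spec.copies)
            chars[start + arr_len] = buf
            occupied.append((start - 1, start + arr_len + 1))
            truth.append(
                StrRecord(
                    seq_id="seq",
                    start=start,
                    end=start + arr_len,
                    unit=unit,
                    period=len(unit),
                    copies=spec.copies,
                )
            )
    truth.sort(key=lambda r: r.start)
    return "".join(chars), truth


def generate_annotation(
    genome_length: int,
    n_genes: int,
    seed: int = 0,
    gene_length: int = 1000,
    allow_overlap: bool = False,
) -> list[tuple[str, int, int, str, str]]:
    """Random gene models as (seq_id, start, end, strand, feature_type).

    Each gene contributes a gene/exon/CDS triple over the same interval
    (single-exon models), with a random strand.  Genes are packed without
    overlap unless ``allow_overlap``; infeasible packing raises.
    """
    rng = np.random.default_rng(seed)
    feats: list[tuple[str, int, int, str, str]] = []
    if n_genes == 0:
        return feats
    if not allow_overlap and n_genes * (gene_length + 1) > genome_length:
        raise ValueError("genes do not fit without overlap")
    if allow_overlap:
        starts = sorted(int(rng.integers(0, genome_length - gene_length)) for _ in range(n_genes))
    else:
        # pack into the slack space: choose gaps by a random composition
        slack = genome_length - n_genes * gene_length
        cuts = np.sort(rng.integers(0, slack + 1, size=n_genes))
        starts = [int(cuts[i]) + i * gene_length for i in range(n_genes)]
    for s in starts:
        strand = "+" if rng.random() < 0.5 else "-"
        for ftype in ("gene", "exon", "CDS"):
            feats.append(("seq", s, s + gene_length, strand, ftype))
    return feats


def generate_variants(
    seq: str,
    str_union: Sequence[tuple[int, int]],
    n: int,
    rho: float = 1.0,
    class_mix: Sequence[float] = (0.6, 0.2, 0.2),
    seed: int = 0,
    seq_id: str = "seq",
) -> list[tuple[str, int, str, str]]:
    """Variants placed inside vs outside the STR union at odds ``rho``.

    Each anchor is drawn with relative density ``rho`` per base inside the
    union versus 1 outside; the class (substitution / small insertion /
    small deletion) is drawn from ``class_mix``.  Returns (seq_id, pos0,
    ref, alt) tuples; positions are unique.
    """
    rng = np.random.default_rng(seed)
    mix = np.asarray(class_mix, dtype=float)
    if mix.sum() <= 0 or (mix < 0).any():
        raise ValueError("class_mix must be non-negative and sum > 0")
    mix = mix / mix.sum()
    L = len(seq)
    inside = np.zeros(L, dtype=bool)
    for s, e in str_union:
        inside[s:e] = True
    # leave room for the deletion ref span and avoid position 0 anchors
    candidate = np.arange(1, L - 10)
    weights = np.where(inside[candidate], rho, 1.0)
    if weights.sum() == 0:
        raise ValueError("rho = 0 with an all-STR genome: nowhere to place variants")
    if n > len(candidate):
        raise ValueError("n exceeds available positions")
    weights = weights / weights.sum()
    pos = rng.choice(candidate, size=n, replace=False, p=weights)
    out: list[tuple[str, int, str, str]] = []
    alphabet = "ACGT"
    for p in np.sort(pos):
        p = int(p)
        ref_base = seq[p].upper()
        if ref_base not in alphabet:
            ref_base = "A"
        cls = rng.choice(3, p=mix)
        if cls == 0:  # substitution
            alt = alphabet[(alphabet.index(ref_base) + int(rng.integers(1, 4))) % 4]
            out.append((seq_id, p, ref_base, alt))
        elif cls == 1:  # small insertion
            ins = "".join(rng.choice(list(alphabet), size=int(rng.integers(1, 6))))
            out.append((seq_id, p, ref_base, ref_base + ins))
        else:  # small deletion
            dlen = int(rng.integers(1, 6))
            ref = seq[p : p + 1 + dlen].upper()
            out.append((seq_id, p, ref, ref_base))
    return out


def generate_taxonomy(
    species_per_domain: Mapping[str, Sequence[int]],
    assemblies_per_species: int | Mapping[str, int] = 1,
    seed: int = 0,
):
    """Nested lineage table with controllable imbalance.

    ``species_per_domain`` maps a domain name to a list of per-phylum
    species counts (one entry per phylum).  Families are assigned
    round-robin within each phylum (2 species per family).  Returns a
    pandas DataFrame with columns assembly_id, species, family, phylum,
    kingdom, domain.
    """
    import pandas as pd

    rows = []
    asm_counter = 0
    for dom, phylum_counts in species_per_domain.items():
        for pi, n_sp in enumerate(phylum_counts):
            phylum = f"{dom}_phylum{pi}"
            kingdom = f"{dom}_kingdom"
            for si in range(n_sp):
                species = f"{phylum}_sp{si}"
                family = f"{phylum}_fam{si // 2}"
                n_asm = (
                    assemblies_per_species[species]
                    if isinstance(assemblies_per_species, Mapping)
                    else assemblies_per_species
                )
                for _ in range(max(1, n_asm)):
                    rows.append(
                        {
                            "assembly_id": f"ASM{asm_counter:06d}",
                            "species": species,
                            "family": family,
                            "phylum": phylum,
                            "kingdom": kingdom,
                            "domain": dom,
                        }
                    )
                    asm_counter += 1
    return pd.DataFrame(rows)
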