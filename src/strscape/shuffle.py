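"""Dinucleotide-preserving sequence shuffling (Euler-path construction).

The null model for STR enrichment is a shuffled genome with the exact same
multiset of overlapping dinucleotides as the original.  We use the classic
Altschul-Erickson construction: view the sequence as an Eulerian path on
the 4-vertex nucleotide multigraph whose edges are the dinucleotides,
sample a uniformly random arborescence of last-exit edges toward the final
vertex by rejection, then shuffle the remaining out-edge orderings and walk
the path.  This samples uniformly among all sequences with the same
dinucleotide counts, first character and last character.

Genomes are shuffled in fixed-size chunks (5 Mb by default) and non-ACGT
characters (assembly gaps etc.) are frozen in place, each flanking ACGT
segment being shuffled independently.
"""

from __future__ import annotations

import re
import zlib
from dataclasses import dataclass

import numpy as np

__all__ = ["ShuffleConfig", "shuffle_dinucleotide", "shuffle_genome"]

_ACGT_SEGMENT = re.compile(r"[ACGT]+")


@dataclass(frozen=True)
class ShuffleConfig:
    chunk_size: int = 5_000_000
    seed: int = 0

    def __post_init__(self):
        if self.chunk_size < 2:
            raise ValueError("chunk_size must be >= 2")


def _dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Uniform dinucleotide-preserving shuffle of a pure-ACGT string."""
    n = len(seq)
    if n < 2:
        return seq
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    letters = "ACGT"
    s = [code[c] for c in seq]
    first, last = s[0], s[-1]

    # out-edge adjacency lists: edges[v] = multiset of targets
    edges: list[list[int]] = [[], [], [], []]
    for a, b in zip(s, s[1:]):
        edges[a].append(b)
    present = [v for v in range(4) if edges[v] or v == last]

    # Sample last-exit edges for every vertex except `last` by rejection:
    # accepted iff following last-exit edges from each vertex reaches `last`
    # (i.e. they form an arborescence into `last`).
    last_exit: dict[int, int] = {}
    for _ in range(10_000):
        last_exit = {
            v: edges[v][rng.integers(len(edges[v]))]
            for v in present
            if v != last and edges[v]
        }
        ok = True
        for v in present:
            if v == last:
                continue
            seen = set()
            u = v
            while u != last:
                if u in seen or u not in last_exit:
                    ok = False
                    break
                seen.add(u)
                u = last_exit[u]
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - rejection virtually never exhausts
        raise RuntimeError("failed to sample an Eulerian arrangement")

    # Shuffle the non-last-exit out-edges of each vertex, append last-exit.
    ordered: list[list[int]] = [[], [], [], []]
    for v in present:
        pool = list(edges[v])
        if v != last and pool:
            pool.remove(last_exit[v])
        rng.shuffle(pool)
        if v != last and edges[v]:
            pool.append(last_exit[v])
        ordered[v] = pool

    # Walk the Euler path from the first vertex.
    out = [first]
    ptr = [0, 0, 0, 0]
    u = first
    for _ in range(n - 1):
        v = ordered[u][ptr[u]]
        ptr[u] += 1
        out.append(v)
        u = v
    return "".join(letters[c] for c in out)


def shuffle_dinucleotide(seq: str, seed: int | np.random.Generator = 0) -> str:
    """Shuffle ``seq`` preserving its overlapping-dinucleotide counts.

    Deterministic given ``seed``; sequences shorter than 2 bp are returned
    unchanged.  Non-ACGT characters are frozen in place and each maximal
    ACGT segment is shuffled independently, so gap structure is preserved.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if len(seq) < 2:
        return seq
    seq = seq.upper()
    pieces: list[str] = []
    pos = 0
    for m in _ACGT_SEGMENT.finditer(seq):
        pieces.append(seq[pos : m.start()])
        pieces.append(_dinucleotide_shuffle(m.group(), rng))
        pos = m.end()
    pieces.append(seq[pos:])
    return "".join(pieces)


def shuffle_genome(
    records: dict[str, str] | list[tuple[str, str]],
    config: ShuffleConfig | None = None,
) -> dict[str, str]:
    """Shuffle every record of a genome chunk-wise.

    Each record is split into consecutive ``chunk_size`` windows; each
    window is dinucleotide-shuffled independently (the final, shorter chunk
    as-is).  Dinucleotides spanning chunk junctions are not preserved.
    Child seeds are derived per record and chunk so output is independent
    of processing order.
    """
    config = config or ShuffleConfig()
    items = records.items() if isinstance(records, dict) else records
    out: dict[str, str] = {}
    for rec_id, seq in items:
        chunks = []
        for ci, off in enumerate(range(0, len(seq), config.chunk_size)):
            child = np.random.default_rng(
                [config.seed, zlib.crc32(rec_id.encode()) & 0x7FFFFFFF, ci]
            )
            chunks.append(
                shuffle_dinucleotide(seq[off : off + config.chunk_size], child)
            )
        out[rec_id] = "".join(chunks)
    return out
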