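"""Detection and canonicalization of perfect short tandem repeats (STRs).

An STR here is a maximal perfect run of a 1-9 bp unit repeated at least
three full times and spanning at least 10 bp.  Runs never cross a non-ACGT
character, may end in a partial trailing copy, and are reported once, at
their smallest (primitive) period.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StrRecord",
    "MotifClass",
    "find_strs",
    "canonical_motif",
    "is_primitive",
    "motif_gc",
    "motif_classes",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGT")


@dataclass(frozen=True, order=True)
class StrRecord:
    """One maximal perfect tandem-repeat run.

    Coordinates are 0-based half-open.  ``copies`` counts complete units
    only; ``length`` may exceed ``period * copies`` by a partial trailing
    copy of fewer than ``period`` bases.
    """

    seq_id: str
    start: int
    end: int
    unit: str
    period: int = field(default=0)
    copies: int = field(default=0)

    def __post_init__(self):
        if self.period == 0:
            object.__setattr__(self, "period", len(self.unit))
        if self.copies == 0:
            object.__setattr__(self, "copies", self.length // self.period)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class MotifClass:
    """Equivalence class of repeat units under cyclic shift and reverse
    complement, named by its lexicographically minimal member."""

    representative: str
    members: frozenset[str]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def is_primitive(unit: str) -> bool:
    """True iff ``unit`` is not a whole-number repetition of a shorter string."""
    n = len(unit)
    for d in range(1, n):
        if n % d == 0 and unit == unit[:d] * (n // d):
            return False
    return True


def motif_gc(unit: str) -> float:
    """G+C fraction of a repeat unit."""
    if not unit:
        raise ValueError("empty unit")
    return (unit.count("G") + unit.count("C")) / len(unit)


def _check_unit(unit: str) -> str:
    if not isinstance(unit, str) or not unit:
        raise ValueError("unit must be a non-empty string")
    unit = unit.upper()
    if not set(unit) <= _VALID:
        raise ValueError(f"unit {unit!r} contains characters outside ACGT")
    return unit


def canonical_motif(unit: str) -> str:
    """Canonical representative of ``unit``'s shift/reverse-complement class.

    The representative is the lexicographic minimum (A < C < G < T) over all
    cyclic rotations of the unit and of its reverse complement.  Every
    member of a class maps to the same representative, and the map is
    idempotent.
    """
    unit = _check_unit(unit)
    rc = reverse_complement(unit)
    n = len(unit)
    doubled, rc_doubled = unit + unit, rc + rc
    return min(
        min(doubled[i : i + n] for i in range(n)),
        min(rc_doubled[i : i + n] for i in range(n)),
    )


def motif_classes(period: int) -> list[MotifClass]:
    """All shift/RC equivalence classes of primitive units of one period."""
    classes: dict[str, set[str]] = {}
    for tup in itertools.product("ACGT", repeat=period):
        u = "".join(tup)
        if not is_primitive(u):
            continue
        classes.setdefault(canonical_motif(u), set()).add(u)
    return [
        MotifClass(rep, frozenset(members))
        for rep, members in sorted(classes.items())
    ]


def find_strs(
    seq: str,
    seq_id: str = "seq",
    min_length: int = 10,
    min_copies: int = 3,
    max_period: int = 9,
) -> list[StrRecord]:
    """Detect every maximal perfect STR run in ``seq``.

    Parameters
    ----------
    seq
        Nucleotide sequence; case-insensitive.  Non-ACGT characters act as
        hard run terminators (runs never span them).
    min_length, min_copies, max_period
        Filtering thresholds: a run is kept when its length is at least
        ``min_length`` bp AND it contains at least ``min_copies`` complete
        units AND its primitive period is at most ``max_period``.

    Returns
    -------
    Records sorted by (start, period).  Each run appears once, at its
    primitive period: a run whose unit is itself periodic (e.g. ATAT) is
    reported only at the shorter period.
    """
    if not isinstance(seq, str):
        raise TypeError("seq must be a string")
    if min_length <= 0 or min_copies <= 0 or max_period <= 0:
        raise ValueError("thresholds must be positive")
    if not seq:
        return []
    seq = seq.upper()
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    valid = (
        (arr == ord("A")) | (arr == ord("C")) | (arr == ord("G")) | (arr == ord("T"))
    )

    records: list[StrRecord] = []
    # Maximal ACGT segments; each scanned independently.
    boundaries = np.flatnonzero(np.diff(valid.astype(np.int8)))
    seg_starts = [0] if valid[0] else []
    seg_ends: list[int] = []
    for b in boundaries:
        if valid[b]:
            seg_ends.append(int(b) + 1)
        else:
            seg_starts.append(int(b) + 1)
    if valid[-1]:
        seg_ends.append(len(arr))

    for s0, s1 in zip(seg_starts, seg_ends):
        seg = arr[s0:s1]
        n = s1 - s0
        for p in range(1, min(max_period, n - 1) + 1):
            match = seg[: n - p] == seg[p:]
            if not match.any():
                continue
            # maximal runs of True in `match`
            m = match.astype(np.int8)
            diffs = np.diff(m)
            starts = np.flatnonzero(diffs == 1) + 1
            ends = np.flatnonzero(diffs == -1) + 1
            if m[0]:
                starts = np.concatenate(([0], starts))
            if m[-1]:
                ends = np.concatenate((ends, [n - p]))
            for i, j in zip(starts, ends):
                length = int(j - i) + p  # periodic interval [i, j + p)
                if length < min_length or length < min_copies * p:
                    continue
                unit = seq[s0 + i : s0 + i + p]
                if not is_primitive(unit):
                    continue  # reported at the smaller period instead
                records.append(
                    StrRecord(
                        seq_id=seq_id,
                        start=s0 + int(i),
                        end=s0 + int(i) + length,
                        unit=unit,
                        period=p,
                        copies=length // p,
                    )
                )
    records.sort(key=lambda r: (r.start, r.period))
    return records
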