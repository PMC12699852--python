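"""Merged genomic interval sets — the unit of all density arithmetic.

All coordinates are 0-based half-open.  An :class:`IntervalSet` keeps, per
sequence, a sorted array of pairwise-disjoint intervals; construction
merges any overlapping or bookended input intervals.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Mapping

import numpy as np

__all__ = ["IntervalSet", "merge_intervals"]


def _merge_array(iv: np.ndarray) -> np.ndarray:
    """Union of possibly-overlapping intervals, as a sorted (n, 2) array."""
    if len(iv) == 0:
        return iv.reshape(0, 2)
    iv = iv[np.lexsort((iv[:, 1], iv[:, 0]))]
    merged = [iv[0].copy()]
    for s, e in iv[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append(np.array([s, e]))
    return np.array(merged, dtype=np.int64)


class IntervalSet:
    """Per-sequence sorted, disjoint genomic intervals."""

    def __init__(self, intervals: Mapping[str, Iterable[tuple[int, int]]] | None = None):
        self._data: dict[str, np.ndarray] = {}
        if intervals:
            for seq_id, ivs in intervals.items():
                arr = np.asarray(list(ivs), dtype=np.int64).reshape(-1, 2)
                if (arr[:, 0] >= arr[:, 1]).any():
                    raise ValueError("intervals require start < end")
                self._data[seq_id] = _merge_array(arr)

    def __getitem__(self, seq_id: str) -> np.ndarray:
        return self._data.get(seq_id, np.empty((0, 2), dtype=np.int64))

    def __iter__(self) -> Iterator[str]:
        return iter(self._data)

    def __len__(self) -> int:
        return sum(len(v) for v in self._data.values())

    def items(self):
        return self._data.items()

    @property
    def total_bp(self) -> int:
        return int(
            sum((arr[:, 1] - arr[:, 0]).sum() for arr in self._data.values())
        )

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        """Intervals covered by both sets."""
        out: dict[str, list[tuple[int, int]]] = {}
        for seq_id, a in self._data.items():
            b = other[seq_id]
            if len(b) == 0:
                continue
            hits = []
            i = j = 0
            while i < len(a) and j < len(b):
                s = max(a[i, 0], b[j, 0])
                e = min(a[i, 1], b[j, 1])
                if s < e:
                    hits.append((int(s), int(e)))
                if a[i, 1] < b[j, 1]:
                    i += 1
                else:
                    j += 1
            if hits:
                out[seq_id] = hits
        return IntervalSet(out)

    def contains(self, seq_id: str, pos: int) -> bool:
        """Membership test for a single position."""
        arr = self[seq_id]
        if len(arr) == 0:
            return False
        k = int(np.searchsorted(arr[:, 0], pos, side="right")) - 1
        return k >= 0 and pos < arr[k, 1]

    def to_records(self) -> list[tuple[str, int, int]]:
        return [
            (seq_id, int(s), int(e))
            for seq_id, arr in sorted(self._data.items())
            for s, e in arr
        ]


def merge_intervals(records: Iterable) -> IntervalSet:
    """Union of STR record intervals per sequence.

    Accepts any objects with ``seq_id``/``start``/``end`` attributes or
    ``(seq_id, start, end)`` tuples.
    """
    grouped: dict[str, list[tuple[int, int]]] = {}
    for r in records:
        if isinstance(r, tuple):
            seq_id, start, end = r[0], r[1], r[2]
        else:
            seq_id, start, end = r.seq_id, r.start, r.end
        grouped.setdefault(seq_id, []).append((start, end))
    return IntervalSet(grouped)
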