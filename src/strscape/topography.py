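"""STR positional topography around gene start/end landmarks.

For each annotated gene we take a window of ``flank`` bp on either side of
the transcription start site (TSS) or end site (TES), oriented in the
direction of transcription (mirrored for minus-strand genes), and count
STR base occurrences per offset, pooled over genes.  The per-offset counts
are normalized by the window mean to give a relative enrichment curve, and
uncertainty bands come from Monte-Carlo resampling of species (inner band)
or families (outer band) with replacement.

A companion 4 x (2*flank+1) nucleotide occurrence matrix, with repeat
bases translated to the gene strand, is turned into a probability matrix
with a Dirichlet-prior posterior-mean (pseudocount) estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import IntervalSet, merge_intervals
from .repeats import StrRecord

__all__ = [
    "Window",
    "PositionalProfile",
    "NucleotideProfile",
    "landmark_windows",
    "positional_profile",
    "relative_enrichment",
    "bootstrap_bands",
    "pwm_estimate",
    "nucleotide_counts",
]

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"
_COMP = {0: 3, 1: 2, 2: 1, 3: 0}


@dataclass(frozen=True)
class Window:
    """Oriented window around one gene landmark.

    Offset k maps to genomic position ``center + strand * k``; offsets run
    in the direction of transcription.
    """

    seq_id: str
    center: int
    strand: int  # +1 or -1


@dataclass
class PositionalProfile:
    """Pooled STR-base occurrence counts per offset in [-flank, +flank]."""

    counts: np.ndarray  # occurrences per offset
    n_valid: np.ndarray  # windows contributing at each offset
    landmark: str = "TSS"
    period: int | None = None

    @property
    def flank(self) -> int:
        return (len(self.counts) - 1) // 2

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.flank, self.flank + 1)


@dataclass(frozen=True)
class NucleotideProfile:
    """Column-stochastic 4 x W probability matrix over {A, C, G, T}."""

    probabilities: np.ndarray
    alpha: np.ndarray


def landmark_windows(
    genes: Iterable[tuple[str, int, int, str]],
    seq_lengths: Mapping[str, int],
    landmark: str = "TSS",
    flank: int = 500,
) -> list[Window]:
    """Oriented landmark windows for gene features.

    ``genes`` yields (seq_id, start, end, strand) with 0-based half-open
    coordinates.  For plus-strand genes TSS = start and TES = end - 1; for
    minus-strand genes the landmarks mirror (TSS = end - 1, TES = start).
    Strandless genes are skipped with a warning.  Windows are later clipped
    at sequence edges by the profiling step, which tracks per-offset
    validity.
    """
    if landmark not in ("TSS", "TES"):
        raise ValueError("landmark must be 'TSS' or 'TES'")
    windows: list[Window] = []
    skipped = 0
    for seq_id, start, end, strand in genes:
        if strand == "+":
            center = start if landmark == "TSS" else end - 1
            windows.append(Window(seq_id, center, +1))
        elif strand == "-":
            center = end - 1 if landmark == "TSS" else start
            windows.append(Window(seq_id, center, -1))
        else:
            skipped += 1
    if skipped:
        logger.warning("skipped %d strandless genes", skipped)
    return windows


def _coverage(intervals: np.ndarray, length: int) -> np.ndarray:
    cov = np.zeros(length, dtype=bool)
    for s, e in intervals:
        cov[max(0, s) : min(length, e)] = True
    return cov


def positional_profile(
    strs: Sequence[StrRecord],
    windows: Sequence[Window],
    seq_lengths: Mapping[str, int],
    flank: int = 500,
    period: int | None = None,
    landmark: str = "TSS",
) -> PositionalProfile:
    """Count (gene, STR-base) incidences at each offset around the windows.

    ``period`` restricts to one repeat-unit length; ``None`` pools all.
    Offsets falling outside the sequence are masked, not counted.
    """
    width = 2 * flank + 1
    counts = np.zeros(width, dtype=np.int64)
    n_valid = np.zeros(width, dtype=np.int64)
    selected = [r for r in strs if period is None or r.period == period]
    union = merge_intervals(selected)
    cov_cache: dict[str, np.ndarray] = {}
    for w in windows:
        length = seq_lengths[w.seq_id]
        if w.seq_id not in cov_cache:
            cov_cache[w.seq_id] = _coverage(union[w.seq_id], length)
        cov = cov_cache[w.seq_id]
        offs = np.arange(-flank, flank + 1)
        pos = w.center + w.strand * offs
        valid = (pos >= 0) & (pos < length)
        n_valid += valid
        counts[valid] += cov[pos[valid]]
    return PositionalProfile(counts, n_valid, landmark=landmark, period=period)


def relative_enrichment(profile: PositionalProfile | np.ndarray) -> np.ndarray:
    """Per-offset counts divided by the window-mean count.

    The mean is taken over offsets that received at least one valid window
    (truncation-masked offsets are excluded); over those offsets the output
    averages exactly 1.  An all-zero profile has no defined enrichment and
    raises.
    """
    if isinstance(profile, PositionalProfile):
        counts = profile.counts.astype(float)
        valid = profile.n_valid > 0
    else:
        counts = np.asarray(profile, dtype=float)
        valid = np.ones(len(counts), dtype=bool)
    if not valid.any() or counts[valid].sum() == 0:
        raise ValueError("all-zero profile: relative enrichment undefined")
    mean = counts[valid].mean()
    out = np.full(len(counts), np.nan)
    out[valid] = counts[valid] / mean
    return out


def bootstrap_bands(
    profiles: Mapping[str, np.ndarray],
    taxonomy: pd.DataFrame | None = None,
    level: str = "species",
    n_rep: int = 1000,
    seed: int = 0,
    ci: float = 0.95,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pointwise percentile band for the mean relative-enrichment curve.

    ``profiles`` maps species to their relative-enrichment vectors.  At
    ``level='species'`` the species themselves are resampled with
    replacement; at ``level='family'`` whole families (via the taxonomy's
    species -> family mapping) are resampled and all their species enter
    each replicate.  Returns (mean_curve, lower, upper); with a single
    resampling unit the band degenerates to the point estimate.
    """
    species = sorted(profiles)
    mat = np.vstack([profiles[s] for s in species])
    mean_curve = mat.mean(axis=0)
    if level == "species":
        unit_rows = [[i] for i in range(len(species))]
    elif level == "family":
        if taxonomy is None:
            raise ValueError("family-level bands require a taxonomy")
        fam = taxonomy.drop_duplicates("species").set_index("species")["family"]
        groups: dict[str, list[int]] = {}
        for i, sp in enumerate(species):
            groups.setdefault(str(fam.get(sp, "NA")), []).append(i)
        unit_rows = list(groups.values())
    else:
        raise ValueError("level must be 'species' or 'family'")
    if len(unit_rows) < 2:
        logger.warning("single resampling unit: degenerate band")
        return mean_curve, mean_curve.copy(), mean_curve.copy()
    rng = np.random.default_rng(seed)
    reps = np.empty((n_rep, mat.shape[1]))
    for r in range(n_rep):
        chosen = rng.integers(len(unit_rows), size=len(unit_rows))
        rows = np.concatenate([unit_rows[c] for c in chosen])
        reps[r] = mat[rows].mean(axis=0)
    tail = (1.0 - ci) / 2.0
    lower = np.percentile(reps, 100 * tail, axis=0)
    upper = np.percentile(reps, 100 * (1 - tail), axis=0)
    return mean_curve, lower, upper


def nucleotide_counts(
    sequences: Mapping[str, str],
    strs: Sequence[StrRecord],
    windows: Sequence[Window],
    flank: int = 500,
    period: int | None = None,
) -> np.ndarray:
    """4 x (2*flank+1) occurrence matrix of STR-base nucleotides per offset.

    Each STR base falling at an offset contributes its nucleotide,
    translated to the gene strand (complemented for minus-strand windows).
    """
    width = 2 * flank + 1
    counts = np.zeros((4, width), dtype=np.int64)
    code = np.full(256, -1, dtype=np.int8)
    for i, c in enumerate(ALPHABET):
        code[ord(c)] = i
    selected = [r for r in strs if period is None or r.period == period]
    union = merge_intervals(selected)
    for w in windows:
        seq = sequences[w.seq_id]
        length = len(seq)
        cov = _coverage(union[w.seq_id], length)
        offs = np.arange(-flank, flank + 1)
        pos = w.center + w.strand * offs
        valid = (pos >= 0) & (pos < length)
        for k in np.flatnonzero(valid):
            p = pos[k]
            if not cov[p]:
                continue
            ci = code[ord(seq[p])]
            if ci < 0:
                continue
            if w.strand < 0:
                ci = _COMP[int(ci)]
            counts[ci, k] += 1
    return counts


def pwm_estimate(
    counts: np.ndarray, alpha: Sequence[float] | float = 1.0
) -> NucleotideProfile:
    """Posterior-mean nucleotide probabilities under a Dirichlet prior.

    Column-wise: p_i = (n_i + alpha_i) / sum_j (n_j + alpha_j).  With the
    default Laplace prior (alpha = 1 per nucleotide) an all-zero column is
    uniform (0.25 each).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape[0] != 4:
        raise ValueError("counts must be a 4 x W matrix")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    alpha_vec = np.broadcast_to(np.asarray(alpha, dtype=float).reshape(-1), (4,)).copy()
    if (alpha_vec < 0).any():
        raise ValueError("alpha must be non-negative")
    post = counts + alpha_vec[:, None]
    colsums = post.sum(axis=0)
    if (colsums == 0).any():
        raise ValueError("all-zero column with zero pseudocounts: undefined")
    return NucleotideProfile(post / colsums, alpha_vec)
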