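"""STR-polymorphism overlap statistics.

Variants (assumed left-aligned and normalized upstream) are classified
into substitutions, small insertions and small deletions (indel size <=
50 bp; larger events are dropped).  The proportion of variants whose
anchor base falls inside the merged STR union is compared against
length-matched shuffled control regions, stratified into genic (>= 30% of
the STR overlapping CDS) and intergenic STRs, with a pseudocounted fold
enrichment and a one-tailed Fisher exact test.  Variant density is also
regressed on STR density across species, with Cook's distance flagging
influential species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .intervals import IntervalSet, merge_intervals
from .repeats import StrRecord

__all__ = [
    "VariantRecord",
    "OverlapStats",
    "classify_variants",
    "overlap_proportion",
    "stratify_genic",
    "matched_controls",
    "enrichment_and_fisher",
    "density_regression",
]

logger = logging.getLogger(__name__)

CLASSES = ("substitution", "small_insertion", "small_deletion")
MAX_INDEL = 50


@dataclass(frozen=True)
class VariantRecord:
    seq_id: str
    pos: int  # 0-based anchor base
    ref: str
    alt: str
    var_class: str


@dataclass
class OverlapStats:
    species: str
    var_class: str
    n_variants: int
    n_overlapping: int
    control_overlapping: int
    fold_enrichment: float
    fisher_p: float
    fisher_p_adj: float = float("nan")


def classify_variants(
    records: Sequence[tuple[str, int, str, str]],
    max_indel: int = MAX_INDEL,
) -> list[VariantRecord]:
    """Partition (seq_id, pos0, ref, alt) records into the three classes.

    Same-length single-base alleles are substitutions; longer alt is a
    small insertion, longer ref a small deletion, both only when the
    length difference is <= ``max_indel``.  Larger events are dropped;
    malformed alleles are skipped with a warning count.
    """
    out: list[VariantRecord] = []
    skipped = 0
    for seq_id, pos, ref, alt in records:
        if not ref or not alt or set(ref.upper()) - set("ACGTN") or set(alt.upper()) - set("ACGTN"):
            skipped += 1
            continue
        delta = len(alt) - len(ref)
        if delta == 0:
            if len(ref) != 1:
                skipped += 1  # MNVs are not one of the three classes
                continue
            cls = "substitution"
        elif delta > 0:
            if delta > max_indel:
                continue
            cls = "small_insertion"
        else:
            if -delta > max_indel:
                continue
            cls = "small_deletion"
        out.append(VariantRecord(seq_id, pos, ref.upper(), alt.upper(), cls))
    if skipped:
        logger.warning("skipped %d malformed/unclassifiable variant records", skipped)
    return out


def overlap_proportion(
    variants: Sequence[VariantRecord], strs: IntervalSet
) -> float:
    """Fraction of variants whose anchor position lies in the STR union."""
    if not variants:
        raise ValueError("no variants: overlap proportion undefined")
    hits = sum(strs.contains(v.seq_id, v.pos) for v in variants)
    return hits / len(variants)


def stratify_genic(
    strs: Sequence[StrRecord], cds: IntervalSet, genic_fraction: float = 0.3
) -> tuple[list[StrRecord], list[StrRecord]]:
    """Split STRs into genic (>= ``genic_fraction`` of the STR overlapping
    CDS) and intergenic strata."""
    genic: list[StrRecord] = []
    intergenic: list[StrRecord] = []
    for r in strs:
        piece = IntervalSet({r.seq_id: [(r.start, r.end)]})
        ov = piece.intersect(cds).total_bp
        (genic if ov >= genic_fraction * r.length else intergenic).append(r)
    return genic, intergenic


def _place_in_territory(
    length: int,
    territory: np.ndarray,
    forbidden: IntervalSet,
    seq_id: str,
    rng: np.random.Generator,
    max_tries: int = 1000,
) -> tuple[int, int]:
    fits = territory[(territory[:, 1] - territory[:, 0]) >= length]
    if len(fits) == 0:
        raise RuntimeError(f"no territory segment fits a {length} bp control")
    weights = (fits[:, 1] - fits[:, 0] - length + 1).astype(float)
    weights /= weights.sum()
    for _ in range(max_tries):
        seg = fits[rng.choice(len(fits), p=weights)]
        start = int(rng.integers(seg[0], seg[1] - length + 1))
        probe = IntervalSet({seq_id: [(start, start + length)]})
        if probe.intersect(forbidden).total_bp == 0:
            return start, start + length
    raise RuntimeError("control placement exhausted retries")


def matched_controls(
    strs: Sequence[StrRecord],
    seq_lengths: Mapping[str, int],
    cds: IntervalSet,
    seed: int = 0,
    genic_fraction: float = 0.3,
) -> list[tuple[str, int, int]]:
    """Length-matched random control regions complementary to the STRs.

    One control per STR, of identical length, placed uniformly at random
    outside the STR union.  STRs are first stratified into genic and
    intergenic, and controls are drawn from the corresponding stratum's
    territory (merged CDS vs its complement), so sequence-composition
    differences between genic and intergenic DNA are respected.
    Deterministic given ``seed``.  Returns raw (seq_id, start, end)
    intervals — controls may overlap one another, and the per-stratum
    length histogram matches the STRs' exactly; merge with
    :func:`strscape.intervals.merge_intervals` for overlap queries.
    """
    rng = np.random.default_rng(seed)
    union = merge_intervals(strs)
    genic, intergenic = stratify_genic(strs, cds, genic_fraction)

    # Per-sequence territory for each stratum, minus the STR union.
    def territory(seq_id: str, genic_stratum: bool) -> np.ndarray:
        L = seq_lengths[seq_id]
        cds_iv = cds[seq_id]
        if genic_stratum:
            base = cds_iv
        else:
            comp = []
            prev = 0
            for s, e in cds_iv:
                if prev < s:
                    comp.append((prev, int(s)))
                prev = int(e)
            if prev < L:
                comp.append((prev, L))
            base = np.array(comp, dtype=np.int64).reshape(-1, 2)
        # subtract STR union
        out = []
        for s, e in base:
            cur = int(s)
            for us, ue in union[seq_id]:
                if ue <= cur or us >= e:
                    continue
                if us > cur:
                    out.append((cur, int(us)))
                cur = max(cur, int(ue))
            if cur < e:
                out.append((cur, int(e)))
        return np.array(out, dtype=np.int64).reshape(-1, 2)

    placed: list[tuple[str, int, int]] = []
    for stratum, is_genic in ((genic, True), (intergenic, False)):
        terr_cache: dict[str, np.ndarray] = {}
        for r in stratum:
            if r.seq_id not in terr_cache:
                terr_cache[r.seq_id] = territory(r.seq_id, is_genic)
            try:
                s, e = _place_in_territory(
                    r.length, terr_cache[r.seq_id], union, r.seq_id, rng
                )
            except RuntimeError as err:
                name = "genic" if is_genic else "intergenic"
                raise RuntimeError(f"{name} stratum: {err}") from err
            placed.append((r.seq_id, s, e))
    return placed


def enrichment_and_fisher(
    n_obs: int, n_ctrl: int, n_total: int
) -> tuple[float, float]:
    """Pseudocounted fold enrichment and one-tailed Fisher p.

    FE = (n_obs / N) / ((n_ctrl + 1) / N): the pseudocount guards against
    control strata with zero overlapping variants.  The Fisher test is on
    [[n_obs, N - n_obs], [n_ctrl, N - n_ctrl]] with alternative='greater'.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not (0 <= n_obs <= n_total and 0 <= n_ctrl <= n_total):
        raise ValueError("overlap counts must lie in [0, n_total]")
    fe = n_obs / (n_ctrl + 1)
    table = [[n_obs, n_total - n_obs], [n_ctrl, n_total - n_ctrl]]
    _, p = stats.fisher_exact(table, alternative="greater")
    return float(fe), float(p)


def density_regression(
    str_density: Sequence[float], variant_density: Sequence[float]
) -> dict:
    """OLS of variant density on STR density, with influence diagnostics.

    Returns slope, intercept, slope standard error, Spearman rho and p,
    and per-point Cook's distances.  Requires >= 4 points and a
    non-constant predictor.
    """
    x = np.asarray(str_density, dtype=float)
    y = np.asarray(variant_density, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 species")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: regression undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    cooks = model.get_influence().cooks_distance[0]
    rho, rho_p = stats.spearmanr(x, y)
    return {
        "slope": float(model.params[1]),
        "intercept": float(model.params[0]),
        "slope_se": float(model.bse[1]),
        "spearman_rho": float(rho),
        "spearman_p": float(rho_p),
        "cooks_distance": cooks,
    }
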