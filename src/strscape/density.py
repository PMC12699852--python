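"""STR densities, two-stage taxonomic averaging, and motif composition.

Density is always merged STR base pairs per kilobase of the region
considered.  To keep heavily-sequenced species from dominating taxon
summaries, densities are averaged in two stages: over assemblies within a
species (F(S)), then over species within a taxonomic rank value (F(R)) —
an unweighted nested mean, so a species with 100 assemblies counts exactly
as much as a species with one.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import IntervalSet, merge_intervals
from .repeats import StrRecord, canonical_motif, motif_gc

__all__ = [
    "TAXONOMY_RANKS",
    "genome_density",
    "compartment_density",
    "species_density",
    "rank_average_density",
    "motif_prevalence",
    "rank_motif_prevalence",
    "composition_by_period",
    "at_content_by_period",
    "gc_threshold_curve",
    "density_size_correlation",
]

logger = logging.getLogger(__name__)

TAXONOMY_RANKS = ("species", "family", "phylum", "kingdom", "domain")


def genome_density(strs: IntervalSet, genome_size: int) -> float:
    """Merged STR bp per kB of genome: 1000 * total_bp / genome_size."""
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    return 1000.0 * strs.total_bp / genome_size


def compartment_density(strs: IntervalSet, compartment: IntervalSet) -> float | None:
    """STR bp per kB of a merged genomic compartment (genes, exons, CDS...).

    Returns ``None`` when the compartment is empty — the genome is skipped
    rather than crashed, mirroring how species without the relevant GFF
    features are dropped from compartment summaries.
    """
    comp_bp = compartment.total_bp
    if comp_bp == 0:
        return None
    return 1000.0 * strs.intersect(compartment).total_bp / comp_bp


def species_density(
    assembly_densities: Mapping[str, float],
    taxonomy: pd.DataFrame,
) -> dict[str, float]:
    """F(S): unweighted mean density over the assemblies of each species."""
    tax = taxonomy.set_index("assembly_id")["species"]
    per_species: dict[str, list[float]] = {}
    for asm, dens in assembly_densities.items():
        if asm not in tax.index:
            logger.warning("assembly %s absent from taxonomy; excluded", asm)
            continue
        per_species.setdefault(tax[asm], []).append(dens)
    return {sp: float(np.mean(v)) for sp, v in per_species.items()}


def rank_average_density(
    species_densities: Mapping[str, float],
    taxonomy: pd.DataFrame,
    rank: str,
) -> dict[str, float]:
    """F(R): unweighted mean of species densities per value of ``rank``.

    The per-kB scale is already inside each F(S); no further factor is
    applied.  Species missing from the taxonomy are excluded with a
    warning; species with zero STRs contribute 0 to the mean.
    """
    if rank not in TAXONOMY_RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    lineage = taxonomy.drop_duplicates("species").set_index("species")[rank]
    grouped: dict[str, list[float]] = {}
    for sp, dens in species_densities.items():
        if sp not in lineage.index or pd.isna(lineage[sp]):
            logger.warning("species %s absent from taxonomy rank %s; excluded", sp, rank)
            continue
        grouped.setdefault(str(lineage[sp]), []).append(dens)
    return {val: float(np.mean(v)) for val, v in grouped.items()}


def motif_prevalence(
    strs_per_species: Mapping[str, Sequence[StrRecord]],
    period: int,
) -> dict[str, float]:
    """Mean per-species proportion of STR bp in each canonical motif class.

    Within each species, the proportion of a class is the total length of
    STRs of that class divided by the total length of all STRs of the
    given period; proportions are then averaged unweighted across species.
    Species with no STRs of the period are excluded from the mean.
    """
    per_species_props: list[dict[str, float]] = []
    for sp, records in strs_per_species.items():
        by_class: dict[str, int] = {}
        total = 0
        for r in records:
            if r.period != period:
                continue
            by_class[canonical_motif(r.unit)] = by_class.get(canonical_motif(r.unit), 0) + r.length
            total += r.length
        if total == 0:
            continue
        per_species_props.append({c: bp / total for c, bp in by_class.items()})
    if not per_species_props:
        return {}
    classes = sorted({c for props in per_species_props for c in props})
    n = len(per_species_props)
    return {
        c: sum(props.get(c, 0.0) for props in per_species_props) / n for c in classes
    }


def rank_motif_prevalence(
    strs_per_species: Mapping[str, Sequence[StrRecord]],
    taxonomy: pd.DataFrame,
    rank: str,
    period: int,
) -> pd.DataFrame:
    """Prevalence matrix (rank value x canonical class) of mean per-species
    bp proportions — the table behind the motif-prevalence heatmaps."""
    lineage = taxonomy.drop_duplicates("species").set_index("species")[rank]
    groups: dict[str, dict[str, Sequence[StrRecord]]] = {}
    for sp, recs in strs_per_species.items():
        if sp not in lineage.index or pd.isna(lineage[sp]):
            continue
        groups.setdefault(str(lineage[sp]), {})[sp] = recs
    rows = {val: motif_prevalence(members, period) for val, members in groups.items()}
    return pd.DataFrame.from_dict(rows, orient="index").fillna(0.0).sort_index()


def composition_by_period(strs: Iterable[StrRecord]) -> pd.DataFrame:
    """Proportions of STR occurrences (record counts) and of STR bp,
    stratified by unit length 1-9.  Each proportion column sums to 1 over
    the periods present."""
    counts: dict[int, int] = {}
    bps: dict[int, int] = {}
    for r in strs:
        counts[r.period] = counts.get(r.period, 0) + 1
        bps[r.period] = bps.get(r.period, 0) + r.length
    periods = sorted(counts)
    n_tot = sum(counts.values())
    bp_tot = sum(bps.values())
    return pd.DataFrame(
        {
            "period": periods,
            "n_occurrences": [counts[p] for p in periods],
            "occurrence_proportion": [counts[p] / n_tot for p in periods] if n_tot else [],
            "str_bp": [bps[p] for p in periods],
            "bp_proportion": [bps[p] / bp_tot for p in periods] if bp_tot else [],
        }
    )


def at_content_by_period(
    strs: Iterable[StrRecord], per: str = "record"
) -> dict[int, float]:
    """Median AT fraction of repeat units per period.

    ``per='record'`` takes the median over records; with per-species input,
    callers can instead median over species-level means (``per`` only
    controls this module's own behaviour for a flat record list).
    """
    if per not in ("record",):
        raise ValueError("per must be 'record' for a flat record list")
    vals: dict[int, list[float]] = {}
    for r in strs:
        vals.setdefault(r.period, []).append(1.0 - motif_gc(r.unit))
    return {p: float(np.median(v)) for p, v in sorted(vals.items())}


def gc_threshold_curve(
    strs: Iterable[StrRecord], thresholds: Sequence[float]
) -> dict[float, int]:
    """Count of STR records whose unit GC content is >= t, for each t.

    Monotone non-increasing in t.
    """
    thresholds = list(thresholds)
    if any(t < 0 or t > 1 for t in thresholds):
        raise ValueError("thresholds must lie in [0, 1]")
    gcs = np.array([motif_gc(r.unit) for r in strs])
    return {float(t): int((gcs >= t).sum()) for t in thresholds}


def density_size_correlation(
    genome_sizes: Sequence[float], densities: Sequence[float]
) -> tuple[float, float]:
    """Spearman rank correlation of genome size vs STR density.

    Returns (rho, p).  Requires >= 3 points; a constant vector yields an
    undefined rho, returned as NaN with a warning.
    """
    sizes = np.asarray(genome_sizes, dtype=float)
    dens = np.asarray(densities, dtype=float)
    if len(sizes) < 3:
        raise ValueError("need at least 3 species")
    if np.ptp(sizes) == 0 or np.ptp(dens) == 0:
        logger.warning("constant vector: Spearman rho undefined")
        return float("nan"), float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, p = stats.spearmanr(sizes, dens)
    return float(rho), float(p)
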