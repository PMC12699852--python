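"""End-to-end pipeline: detect -> shuffle -> detect-on-shuffle -> enrich ->
density -> topography -> bins, with a manifest for resumability.

Each stage writes plain TSV/BED artifacts to the output directory and an
entry in ``manifest.json`` recording its parameters and input checksums.
Re-running with an identical configuration skips stages whose outputs
exist under a matching manifest entry; deleting a stage output forces just
that stage to recompute.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as sio
from .chromosome_bins import bin_profile
from .density import composition_by_period, genome_density
from .enrichment import compare_real_vs_shuffled
from .intervals import merge_intervals
from .repeats import find_strs
from .shuffle import ShuffleConfig, shuffle_genome
from .topography import landmark_windows, positional_profile, relative_enrichment

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    fasta: str
    out_dir: str
    gff: str | None = None
    min_length: int = 10
    min_copies: int = 3
    max_period: int = 9
    chunk_size: int = 5_000_000
    flank: int = 500
    bin_size: int = 100_000
    seed: int = 0

    def validate(self) -> None:
        if not Path(self.fasta).exists():
            raise FileNotFoundError(self.fasta)
        if self.gff and not Path(self.gff).exists():
            raise FileNotFoundError(self.gff)
        if min(self.min_length, self.min_copies, self.max_period) <= 0:
            raise ValueError("thresholds must be positive")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


class _Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.data = json.loads(path.read_text()) if path.exists() else {}

    def fresh(self, stage: str, entry: dict, outputs: list[Path]) -> bool:
        return self.data.get(stage) == entry and all(p.exists() for p in outputs)

    def record(self, stage: str, entry: dict) -> None:
        self.data[stage] = entry
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True))


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every applicable stage; returns the artifact directory.

    Deterministic given the config seed; a failing stage halts the run
    with its name, retaining the outputs of earlier stages.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out / "manifest.json")
    params = config.to_dict()
    base_entry = {"params": params, "fasta": _checksum(config.fasta)}

    genome = sio.read_fasta(config.fasta)

    def detect_stage(name: str, seqs: dict[str, str], bed: Path) -> None:
        records = []
        for seq_id, seq in seqs.items():
            records.extend(
                find_strs(
                    seq,
                    seq_id=seq_id,
                    min_length=config.min_length,
                    min_copies=config.min_copies,
                    max_period=config.max_period,
                )
            )
        sio.write_str_bed(records, bed)
        logger.info("%s: %d STRs detected", name, len(records))

    # --- detect on the real genome
    real_bed = out / "strs.bed"
    if not manifest.fresh("detect", base_entry, [real_bed]):
        detect_stage("detect", genome, real_bed)
        manifest.record("detect", base_entry)

    # --- shuffle + detect on the shuffle
    shuf_fa = out / "shuffled.fa"
    shuf_bed = out / "strs_shuffled.bed"
    if not manifest.fresh("shuffle", base_entry, [shuf_fa, shuf_bed]):
        shuffled = shuffle_genome(
            genome, ShuffleConfig(chunk_size=config.chunk_size, seed=config.seed)
        )
        sio.write_fasta(shuffled, shuf_fa)
        detect_stage("shuffle-detect", shuffled, shuf_bed)
        manifest.record("shuffle", base_entry)

    # --- enrichment + densities
    enrich_tsv = out / "enrichment.tsv"
    density_tsv = out / "density.tsv"
    comp_tsv = out / "composition.tsv"
    if not manifest.fresh("enrich", base_entry, [enrich_tsv, density_tsv, comp_tsv]):
        real = sio.read_str_bed(real_bed)
        shuf = sio.read_str_bed(shuf_bed)
        obs = {"genome": float(merge_intervals(real).total_bp)}
        exp = {"genome": float(merge_intervals(shuf).total_bp)}
        _, per_genome = compare_real_vs_shuffled(obs, exp)
        sio.write_tsv(
            pd.DataFrame(
                [
                    {
                        "genome_id": r.genome_id,
                        "observed_bp": r.observed_bp,
                        "expected_bp": r.expected_bp,
                        "fe": r.fe,
                    }
                    for r in per_genome
                ]
            ),
            enrich_tsv,
        )
        size = sum(len(s) for s in genome.values())
        dens = genome_density(merge_intervals(real), size)
        sio.write_tsv(
            pd.DataFrame([{"genome_id": "genome", "density_bp_per_kb": dens}]),
            density_tsv,
        )
        sio.write_tsv(composition_by_period(real), comp_tsv)
        manifest.record("enrich", base_entry)

    # --- bins
    bins_tsv = out / "bins.tsv"
    if not manifest.fresh("bins", base_entry, [bins_tsv]):
        real = sio.read_str_bed(real_bed)
        size = sum(len(s) for s in genome.values())
        dens = genome_density(merge_intervals(real), size)
        tables = []
        if dens > 0:
            for seq_id, seq in genome.items():
                prof = bin_profile(
                    real, seq_id, len(seq), dens, bin_size=config.bin_size
                )
                t = prof.table.copy()
                t.insert(0, "chrom", seq_id)
                tables.append(t)
        sio.write_tsv(
            pd.concat(tables, ignore_index=True) if tables else pd.DataFrame(),
            bins_tsv,
        )
        manifest.record("bins", base_entry)

    # --- topography (needs gene annotations)
    if config.gff:
        topo_tsv = out / "topography_tss.tsv"
        entry = dict(base_entry, gff=_checksum(config.gff))
        if not manifest.fresh("topography", entry, [topo_tsv]):
            real = sio.read_str_bed(real_bed)
            genes = [
                (c, s, e, st)
                for c, s, e, st, t in sio.read_gff3(config.gff)
                if t == "gene"
            ]
            seq_lengths = {k: len(v) for k, v in genome.items()}
            windows = landmark_windows(genes, seq_lengths, "TSS", config.flank)
            prof = positional_profile(
                real, windows, seq_lengths, flank=config.flank, landmark="TSS"
            )
            df = pd.DataFrame({"offset": prof.offsets, "count": prof.counts})
            try:
                df["relative_enrichment"] = relative_enrichment(prof)
            except ValueError:
                df["relative_enrichment"] = float("nan")
            sio.write_tsv(df, topo_tsv)
            manifest.record("topography", entry)

    return out
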