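"""Format readers and writers.

All coordinates are normalized to 0-based half-open on read and restored
to each format's native convention on write: GFF3 and VCF are 1-based
(GFF3 end-inclusive), BED is already 0-based half-open.  This module is
the only place 1-based arithmetic appears.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .repeats import StrRecord, canonical_motif

logger = logging.getLogger(__name__)

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_bed",
    "write_bed",
    "read_str_bed",
    "write_str_bed",
    "read_vcf",
    "write_vcf",
    "read_tsv",
    "write_tsv",
]

GFF_FEATURE_TYPES = ("gene", "exon", "CDS")


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Multi-record FASTA (gzip-transparent) as id -> uppercase sequence."""
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(records: dict[str, str], path: str | Path, width: int = 80) -> None:
    with _open_text(path, "wt") as fh:
        for rec_id, seq in records.items():
            fh.write(f">{rec_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_gff3(
    path: str | Path, feature_types: Sequence[str] = GFF_FEATURE_TYPES
) -> list[tuple[str, int, int, str, str]]:
    """GFF3 features as (seq_id, start0, end0, strand, type).

    GFF3 is 1-based end-inclusive; the returned intervals are 0-based
    half-open.  Unknown feature types are ignored (counted in the log);
    parent/child relations are not resolved — features are flat intervals.
    """
    wanted = set(feature_types)
    out = []
    ignored = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise ValueError(f"{path}:{lineno}: malformed GFF3 line")
            seq_id, _, ftype, start, end, _, strand = fields[:7]
            if ftype not in wanted:
                ignored += 1
                continue
            try:
                s, e = int(start) - 1, int(end)
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: bad coordinates") from err
            out.append((seq_id, s, e, strand, ftype))
    if ignored:
        logger.info("read_gff3: ignored %d features of other types", ignored)
    return out


def write_gff3(
    features: Iterable[tuple[str, int, int, str, str]], path: str | Path
) -> None:
    """Write (seq_id, start0, end0, strand, type) features as GFF3."""
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for i, (seq_id, s, e, strand, ftype) in enumerate(features):
            attrs = f"ID={ftype}{i}"
            fh.write(
                f"{seq_id}\tstrscape\t{ftype}\t{s + 1}\t{e}\t.\t{strand}\t.\t{attrs}\n"
            )


def read_bed(path: str | Path) -> list[tuple]:
    """BED as (seq_id, start, end[, name]) tuples (0-based half-open)."""
    out = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: malformed BED line")
            row = (fields[0], int(fields[1]), int(fields[2]), *fields[3:4])
            out.append(row)
    return out


def write_bed(intervals: Iterable[tuple], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for row in intervals:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_str_bed(records: Iterable[StrRecord], path: str | Path) -> None:
    """STR records as BED-like TSV: seq_id, start, end, unit, period,
    copies, canonical_motif."""
    with _open_text(path, "wt") as fh:
        for r in records:
            fh.write(
                f"{r.seq_id}\t{r.start}\t{r.end}\t{r.unit}\t{r.period}\t"
                f"{r.copies}\t{canonical_motif(r.unit)}\n"
            )


def read_str_bed(path: str | Path) -> list[StrRecord]:
    out = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{lineno}: malformed STR BED line")
            out.append(
                StrRecord(f[0], int(f[1]), int(f[2]), f[3], int(f[4]), int(f[5]))
            )
    return out


def read_vcf(path: str | Path) -> list[tuple[str, int, str, str]]:
    """VCF records as (seq_id, pos0, ref, alt); POS is converted from
    1-based.  Multi-allelic records yield one tuple per ALT.  Records
    failing FILTER (other than PASS/.) are skipped."""
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            if rec.filter.keys() and set(rec.filter.keys()) - {"PASS", "."}:
                continue
            for alt in rec.alts or ():
                out.append((rec.chrom, rec.pos - 1, rec.ref, alt))
    return out


def write_vcf(
    variants: Iterable[tuple[str, int, str, str]],
    contigs: dict[str, int],
    path: str | Path,
    qual: int = 100,
) -> None:
    """Minimal valid VCF 4.2 (plain text) from (seq_id, pos0, ref, alt)."""
    with _open_text(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=strscape-simulate\n")
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for seq_id, pos, ref, alt in variants:
            fh.write(f"{seq_id}\t{pos + 1}\t.\t{ref}\t{alt}\t{qual}\tPASS\t.\n")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
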