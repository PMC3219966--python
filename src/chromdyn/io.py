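"""Readers and writers for the plain-text formats the pipeline touches.

All genomic output is 0-based half-open BED dialect.  The annotation format
is GFF3-like (tab-separated, 1-based closed coordinates, converted on read);
cleavage tags travel as 4-column BED with single-base intervals; density
tracks as fixed-step bedGraph; configuration as YAML.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .annotate import CORE_PROMOTER_MOTIFS, GenomeAnnotation
from .density import DensityTrack, TagSet
from .genome import Genome


class ParseError(ValueError):
    """Malformed input line; the message names the file and line number."""


def _fail(path, lineno, msg):
    raise ParseError(f"{path}:{lineno}: {msg}")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def write_bed(df: pd.DataFrame, path, float_format: str = "%.6g") -> None:
    """Write intervals as BED: chrom, start, end, then any extra columns."""
    cols = ["chrom", "start", "end"] + [c for c in df.columns if c not in ("chrom", "start", "end")]
    df[cols].to_csv(path, sep="\t", header=False, index=False, float_format=float_format)


def read_bed(path, extra_columns: list[str] | None = None) -> pd.DataFrame:
    """Read a headerless BED file; extra columns get the supplied names (or
    ``col3``, ``col4``...)."""
    rows = []
    n_extra = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                _fail(path, lineno, f"expected >=3 tab-separated fields, got {len(parts)}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                _fail(path, lineno, f"non-integer coordinate in {parts[1]!r}/{parts[2]!r}")
            if n_extra is None:
                n_extra = len(parts) - 3
            rows.append([parts[0], start, end] + parts[3:])
    names = extra_columns or [f"col{i}" for i in range(3, 3 + (n_extra or 0))]
    cols = ["chrom", "start", "end"] + names[: (n_extra or 0)]
    df = pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)
    if len(df):
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
    return df


def write_tags_bed(tags: TagSet, path) -> None:
    """Tags as 4-column BED: chrom, pos, pos+1, "tag"."""
    with open(path, "w") as fh:
        for chrom, pos in tags.positions.items():
            for p in pos:
                fh.write(f"{chrom}\t{p}\t{p + 1}\ttag\n")


def read_tags_bed(path, stage: int = 0, replicate: int = 0) -> TagSet:
    df = read_bed(path)
    positions = {
        chrom: np.sort(sub["start"].to_numpy(dtype=np.int64))
        for chrom, sub in df.groupby("chrom", sort=False)
    }
    return TagSet(stage=stage, replicate=replicate, positions=positions)


# ---------------------------------------------------------------------------
# bedGraph (fixed-step density tracks)
# ---------------------------------------------------------------------------

def write_bedgraph(track: DensityTrack, path, float_format: str = "%.6g") -> None:
    with open(path, "w") as fh:
        for chrom in track.genome:
            vals = track.values[chrom]
            bs = track.bin_size
            clen = track.genome.length(chrom)
            for i, v in enumerate(vals):
                end = min((i + 1) * bs, clen)
                if float(v) == int(v):
                    fh.write(f"{chrom}\t{i * bs}\t{end}\t{int(v)}\n")
                else:
                    fh.write(f"{chrom}\t{i * bs}\t{end}\t{float_format % v}\n")


def read_bedgraph(path, genome: Genome, bin_size: int = 20, window: int = 150) -> DensityTrack:
    values = {
        chrom: np.zeros(-(-genome.length(chrom) // bin_size)) for chrom in genome
    }
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                _fail(path, lineno, "bedGraph needs 4 fields")
            chrom = parts[0]
            if chrom not in genome:
                _fail(path, lineno, f"unknown chromosome {chrom!r}")
            try:
                start = int(parts[1])
                value = float(parts[3])
            except ValueError:
                _fail(path, lineno, "malformed coordinate or value")
            if start % bin_size:
                _fail(path, lineno, f"start {start} not on the {bin_size}-bp grid")
            values[chrom][start // bin_size] = value
    for chrom in values:
        arr = values[chrom]
        if np.allclose(arr, np.round(arr)):
            values[chrom] = arr.astype(np.int64)
    return DensityTrack(genome=genome, bin_size=bin_size, window=window, values=values)


# ---------------------------------------------------------------------------
# GFF3-like annotation (1-based closed on disk, 0-based half-open in memory)
# ---------------------------------------------------------------------------

_GFF_TYPE = {"five_utr": "five_prime_UTR", "cds": "CDS", "intron": "intron",
             "three_utr": "three_prime_UTR"}
_GFF_TYPE_REV = {v: k for k, v in _GFF_TYPE.items()}


def write_gff(annot: GenomeAnnotation, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in annot.genome:
            fh.write(f"##sequence-region {chrom} 1 {annot.genome.length(chrom)}\n")
        for _, g in annot.genes.iterrows():
            attrs = f"ID={g['gene_id']};regulator={int(bool(g['regulator']))}"
            fh.write(
                f"{g['chrom']}\tchromdyn\tgene\t{g['start'] + 1}\t{g['end']}\t.\t"
                f"{g['strand']}\t.\t{attrs}\n"
            )
        for _, f in annot.features.iterrows():
            attrs = f"Parent={f['gene_id']}"
            fh.write(
                f"{f['chrom']}\tchromdyn\t{_GFF_TYPE[f['feature']]}\t{f['start'] + 1}\t"
                f"{f['end']}\t.\t{f['strand']}\t.\t{attrs}\n"
            )


def read_gff(path, genome: Genome) -> GenomeAnnotation:
    """Parse the documented GFF3-like dialect into a GenomeAnnotation.

    Coordinates are converted from 1-based closed to 0-based half-open; a
    coordinate outside the declared chromosome is an error.
    """
    gene_rows, feat_rows = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                _fail(path, lineno, f"expected 9 GFF fields, got {len(parts)}")
            chrom, _src, ftype, start_s, end_s, _score, strand, _frame, attrs = parts
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                _fail(path, lineno, f"non-integer coordinate {start_s!r}/{end_s!r}")
            if chrom not in genome:
                _fail(path, lineno, f"unknown chromosome {chrom!r}")
            start, end = start1 - 1, end1
            if start < 0 or end > genome.length(chrom) or end <= start:
                _fail(path, lineno, "coordinate outside chromosome bounds")
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "gene":
                gid = attr.get("ID")
                if gid is None:
                    _fail(path, lineno, "gene record without ID attribute")
                tss = start if strand == "+" else end - 1
                gene_rows.append(
                    (gid, chrom, strand, start, end, tss, bool(int(attr.get("regulator", "0"))))
                )
            elif ftype in _GFF_TYPE_REV:
                gid = attr.get("Parent")
                if gid is None:
                    _fail(path, lineno, "feature record without Parent attribute")
                feat_rows.append((gid, chrom, strand, _GFF_TYPE_REV[ftype], start, end))
            else:
                _fail(path, lineno, f"unsupported feature type {ftype!r}")
    genes = pd.DataFrame(
        gene_rows, columns=["gene_id", "chrom", "strand", "start", "end", "tss", "regulator"]
    )
    features = pd.DataFrame(
        feat_rows, columns=["gene_id", "chrom", "strand", "feature", "start", "end"]
    )
    return GenomeAnnotation(genome=genome, genes=genes, features=features)


# ---------------------------------------------------------------------------
# Config and tables
# ---------------------------------------------------------------------------

def write_config(params: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params, fh, sort_keys=True)


def read_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_table(df: pd.DataFrame, path, float_format: str = "%.6g") -> None:
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_motif_matrix(motifs: pd.DataFrame, path) -> None:
    out = motifs.astype(int)
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_motif_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    return df.astype(bool)[list(c for c in df.columns if c in CORE_PROMOTER_MOTIFS) or df.columns]
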