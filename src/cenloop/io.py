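"""Readers and writers for the text formats the pipeline consumes.

Formats: two-column chrom.sizes, BED4/BED6, GFF3 (genes; 1-based closed
converted to 0-based half-open on read), bedGraph aligned to a fixed bin
grid, plain-text COO triplets for contact matrices, and BEDPE for loops.
All round-trips are lossless on unmasked data.
"""

from __future__ import annotations

import io as _io
import math
import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core import BinnedTrack, ContactMap, GenomeAnnotation, GenomicInterval, Loop

BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def read_chrom_sizes(path: str | os.PathLike) -> dict[str, int]:
    df = pd.read_csv(path, sep=r"\s+", header=None, names=["chrom", "length"],
                     dtype={"chrom": str})
    if df["chrom"].duplicated().any():
        dup = df.loc[df["chrom"].duplicated(), "chrom"].iloc[0]
        raise ValueError(f"duplicate chromosome name {dup!r} in {path}")
    return dict(zip(df["chrom"], df["length"].astype(int)))


def write_chrom_sizes(sizes: dict[str, int], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")


def read_bed(path: str | os.PathLike) -> list[GenomicInterval]:
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype=str)
    df.columns = BED_COLS[: df.shape[1]]
    out = []
    for row in df.itertuples(index=False):
        strand = getattr(row, "strand", ".")
        name = getattr(row, "name", None)
        out.append(
            GenomicInterval(
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                strand=strand if strand in ("+", "-") else ".",
                name=None if name in (None, ".") else name,
            )
        )
    return out


def write_bed(intervals: list[GenomicInterval], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\n"
            )


def read_centromeres(path: str | os.PathLike) -> dict[str, int]:
    """Centromere BED -> per-chromosome midpoint of the CEN interval."""
    cens: dict[str, int] = {}
    for iv in read_bed(path):
        if iv.chrom in cens:
            raise ValueError(f"more than one centromere for {iv.chrom}")
        cens[iv.chrom] = iv.midpoint
    return cens


def read_gff3_genes(path: str | os.PathLike, feature: str = "gene") -> list[GenomicInterval]:
    """Gene models from GFF3 via gffutils (in-memory DB).

    GFF3 is 1-based closed; intervals come back 0-based half-open.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    out = []
    for feat in db.features_of_type(feature, order_by="start"):
        name = feat.attributes.get("Name", feat.attributes.get("ID", [None]))[0]
        out.append(
            GenomicInterval(
                chrom=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand if feat.strand in ("+", "-") else ".",
                name=name,
            )
        )
    return out


def read_annotation(paths: dict) -> GenomeAnnotation:
    """Assemble a validated GenomeAnnotation from a config of file paths.

    Keys: ``chrom_sizes`` (required), ``centromeres`` (required BED),
    ``genes`` (optional BED or GFF3, by extension), ``sites`` (optional
    mapping of collection name -> BED path).  Out-of-bounds intervals and
    missing centromeres raise; nothing is silently clipped.
    """
    sizes = read_chrom_sizes(paths["chrom_sizes"])
    cens = read_centromeres(paths["centromeres"])
    genes: list[GenomicInterval] = []
    if paths.get("genes"):
        gpath = Path(paths["genes"])
        if gpath.suffix.lower() in (".gff", ".gff3"):
            genes = read_gff3_genes(gpath)
        else:
            genes = read_bed(gpath)
    sites = {
        name: read_bed(p) for name, p in (paths.get("sites") or {}).items()
    }
    return GenomeAnnotation(
        chromosomes=sizes, centromeres=cens, genes=genes, sites=sites
    )


# ---------------------------------------------------------------------------
# bedGraph tracks
# ---------------------------------------------------------------------------

def read_track(
    path: str | os.PathLike, bin_size: int, chrom_sizes: dict[str, int],
    semantics: str = "raw",
) -> BinnedTrack:
    """Read a grid-aligned bedGraph into a BinnedTrack.

    Records absent from the file are masked; off-grid or overlapping records
    are errors.
    """
    values = {
        c: np.zeros(math.ceil(l / bin_size)) for c, l in chrom_sizes.items()
    }
    mask = {c: np.ones(v.shape, dtype=bool) for c, v in values.items()}
    df = pd.read_csv(
        path, sep=r"\s+", header=None, comment="#",
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": int, "end": int, "value": float},
    )
    for row in df.itertuples(index=False):
        if row.chrom not in values:
            raise ValueError(f"unknown chromosome {row.chrom!r}")
        length = chrom_sizes[row.chrom]
        expected_end = min(row.start + bin_size, length)
        if row.start % bin_size != 0 or row.end != expected_end:
            raise ValueError(
                f"off-grid bedGraph record {row.chrom}:{row.start}-{row.end} "
                f"for bin size {bin_size}"
            )
        b = row.start // bin_size
        if not mask[row.chrom][b]:
            raise ValueError(
                f"overlapping records at {row.chrom}:{row.start}-{row.end}"
            )
        values[row.chrom][b] = row.value
        mask[row.chrom][b] = False
    return BinnedTrack(bin_size=bin_size, values=values, mask=mask, semantics=semantics)


def write_track(
    track: BinnedTrack, path: str | os.PathLike, chrom_sizes: dict[str, int],
) -> None:
    """Write unmasked bins as bedGraph records; masked bins are omitted."""
    with open(path, "w") as fh:
        for chrom in track.values:
            v = track.values[chrom]
            m = track.mask[chrom]
            length = chrom_sizes[chrom]
            for b in np.flatnonzero(~m):
                start = int(b) * track.bin_size
                end = min(start + track.bin_size, length)
                fh.write(f"{chrom}\t{start}\t{end}\t{v[b]:.10g}\n")


# ---------------------------------------------------------------------------
# COO contact matrices
# ---------------------------------------------------------------------------

def read_matrix(path: str | os.PathLike) -> ContactMap:
    """Read a COO triplet text file (upper triangle sufficient).

    Header comment lines carry the grid: ``# chrom=<name> bin_size=<bp>
    n_bins=<n>``.  The stored matrix is symmetrized on read.
    """
    meta: dict[str, str] = {}
    body = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        meta[k] = v
            else:
                body.append(line)
    for key in ("chrom", "bin_size", "n_bins"):
        if key not in meta:
            raise ValueError(f"COO header missing {key}= in {path}")
    if body:
        arr = np.loadtxt(_io.StringIO("\n".join(body)), ndmin=2)
        rows, cols, vals = arr[:, 0].astype(int), arr[:, 1].astype(int), arr[:, 2]
    else:
        rows = cols = np.empty(0, dtype=int)
        vals = np.empty(0)
    return ContactMap.from_upper_triplets(
        chrom=meta["chrom"], bin_size=int(meta["bin_size"]),
        n_bins=int(meta["n_bins"]), rows=rows, cols=cols, vals=vals,
    )


def write_matrix(cmap: ContactMap, path: str | os.PathLike) -> None:
    """Write the upper triangle of a ContactMap as COO triplet text."""
    upper = sp.triu(cmap.counts).tocoo()
    with open(path, "w") as fh:
        fh.write(f"# chrom={cmap.chrom} bin_size={cmap.bin_size} n_bins={cmap.n_bins}\n")
        for i, j, v in zip(upper.row, upper.col, upper.data):
            fh.write(f"{i}\t{j}\t{v:.10g}\n")


# ---------------------------------------------------------------------------
# BEDPE loops
# ---------------------------------------------------------------------------

def write_loops(loops: list[Loop], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tobs_exp\tq_value\tcategory\n")
        for lp in loops:
            fh.write(
                f"{lp.anchor1.chrom}\t{lp.anchor1.start}\t{lp.anchor1.end}\t"
                f"{lp.anchor2.chrom}\t{lp.anchor2.start}\t{lp.anchor2.end}\t"
                f"{lp.obs_exp:.6g}\t{lp.q_value:.6g}\t{lp.category or '.'}\n"
            )


def read_loops(path: str | os.PathLike) -> list[Loop]:
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom1", "start1", "end1", "chrom2", "start2",
                            "end2", "obs_exp", "q_value", "category"])
    out = []
    for row in df.itertuples(index=False):
        out.append(
            Loop(
                anchor1=GenomicInterval(row.chrom1, int(row.start1), int(row.end1)),
                anchor2=GenomicInterval(row.chrom2, int(row.start2), int(row.end2)),
                obs_exp=float(row.obs_exp),
                q_value=float(row.q_value),
                category=None if row.category in (".", None) else str(row.category),
            )
        )
    return out
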