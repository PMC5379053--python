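"""Readers and writers for the standard formats the pipeline consumes.

FASTA via Biopython, tables via pandas; rmsk-style TE annotation is the
8-column TSV (chrom, genoStart [0-based], genoEnd [half-open], strand,
repName, repClass, repFamily, milliDiv); coverage is bedGraph plus a
library-size sidecar TSV.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .intervals import GenomicInterval, TEInstance, TFSite
from .profiles import CoverageTrack

RMSK_COLUMNS = [
    "chrom", "genoStart", "genoEnd", "strand", "repName", "repClass",
    "repFamily", "milliDiv",
]


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_rmsk(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation.to_csv(path, sep="\t", index=False, columns=RMSK_COLUMNS)


def read_rmsk(path: str | Path) -> list[TEInstance]:
    df = pd.read_csv(path, sep="\t")
    missing = set(RMSK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"rmsk table missing columns: {sorted(missing)}")
    out = []
    for r in df.itertuples():
        p = 0.0 if pd.isna(r.milliDiv) else float(r.milliDiv) / 1000.0
        out.append(
            TEInstance(
                interval=GenomicInterval(
                    r.chrom, int(r.genoStart), int(r.genoEnd), r.strand
                ),
                subfamily=str(r.repName),
                family=str(r.repFamily),
                te_class=str(r.repClass),
                divergence_p=p,
            )
        )
    return out


def write_peaks_bed(peaks: pd.DataFrame, path: str | Path) -> None:
    """BED6 with the TF name in the name column."""
    bed = peaks[["chrom", "start", "end", "tf"]].copy()
    bed["score"] = 0
    bed["strand"] = "."
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_peaks_bed(path: str | Path, tf: str | None = None) -> list[TFSite]:
    """Read a BED3/BED6 peak file into peak-kind TF sites.

    The TF name comes from the BED name column if present, else ``tf``.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    sites = []
    for r in df.itertuples(index=False):
        name = str(r[3]) if len(r) > 3 else tf
        if not name:
            raise ValueError("BED file lacks a name column; pass tf=")
        sites.append(
            TFSite(
                interval=GenomicInterval(str(r[0]), int(r[1]), int(r[2])),
                tf=name,
                kind="peak",
            )
        )
    return sites


def read_genes_bed(path: str | Path) -> list[tuple[str, GenomicInterval]]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    return [
        (str(r[3]), GenomicInterval(str(r[0]), int(r[1]), int(r[2])))
        for r in df.itertuples(index=False)
    ]


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Run-length-encoded per-base depth as bedGraph."""
    frames = []
    for chrom in sorted(track.depth):
        arr = track.depth[chrom]
        if arr.size == 0:
            continue
        change = np.flatnonzero(np.diff(arr)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [arr.size]))
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": ends, "value": arr[starts]}
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep="\t", index=False, header=False, float_format="%g"
    )


def read_bedgraph(
    path: str | Path,
    chrom_sizes: Mapping[str, int],
    library_size: float,
    mark: str = "",
    cell_type: str = "",
) -> CoverageTrack:
    depth = {c: np.zeros(n, dtype=np.float64) for c, n in chrom_sizes.items()}
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "value"])
    for r in df.itertuples():
        if r.chrom in depth:
            depth[r.chrom][int(r.start) : int(r.end)] = float(r.value)
    return CoverageTrack(
        depth=depth, library_size=library_size, mark=mark, cell_type=cell_type
    )


def write_library_sizes(tracks: Mapping[str, CoverageTrack], path: str | Path) -> None:
    pd.DataFrame(
        [{"mark": m, "library_size": t.library_size} for m, t in sorted(tracks.items())]
    ).to_csv(path, sep="\t", index=False)


def write_chrom_sizes(chrom_sizes: Mapping[str, int], path: str | Path) -> None:
    pd.DataFrame(
        [{"chrom": c, "size": n} for c, n in sorted(chrom_sizes.items())]
    ).to_csv(path, sep="\t", index=False)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["chrom"], df["size"].astype(int)))


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping of key: value pairs")
    return cfg


def write_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
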