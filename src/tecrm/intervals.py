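"""Genomic interval types and the site-clustering / TE-overlap procedures.

Coordinates are 0-based, half-open throughout (BED semantics), matching the
``intersectBed`` / ``closestBed`` conventions the analysis mirrors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "TEInstance",
    "TFSite",
    "TFCluster",
    "extend_to_length",
    "cluster_sites",
    "assign_clusters_to_tes",
    "closest_gene",
    "associate_genes",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        # deterministic integer midpoint; for even widths this is the
        # left-of-center base, the standard genomics convention
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def distance(self, other: "GenomicInterval") -> int | None:
        """bp between nearest ends; 0 if overlapping; None across chromosomes."""
        if self.chrom != other.chrom:
            return None
        if self.overlaps(other):
            return 0
        if self.end <= other.start:
            return other.start - self.end
        return self.start - other.end


@dataclass(frozen=True)
class TEInstance:
    """A RepeatMasker-annotated transposable-element copy.

    ``divergence_p`` is the proportion of substituted sites relative to the
    subfamily consensus (rmsk milliDiv / 1000), the observed divergence that
    feeds the Jukes-Cantor correction downstream.
    """

    interval: GenomicInterval
    subfamily: str
    family: str = ""
    te_class: str = ""
    divergence_p: float = 0.0

    def __post_init__(self) -> None:
        if not self.subfamily:
            raise ValueError("subfamily must be non-empty")
        if not (0.0 <= self.divergence_p < 0.75):
            raise ValueError(f"divergence_p must lie in [0, 0.75), got {self.divergence_p}")


@dataclass(frozen=True)
class TFSite:
    """A TF binding site: a ChIP-seq peak or a motif hit.

    Peaks use the peak center as reference point; motif hits use the motif
    start, mirroring how the clustering procedure anchors each site kind.
    """

    interval: GenomicInterval
    tf: str
    kind: str = "peak"  # {"peak", "motif"}
    reference_point: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("peak", "motif"):
            raise ValueError(f"kind must be 'peak' or 'motif', got {self.kind!r}")
        if self.reference_point is None:
            ref = self.interval.center if self.kind == "peak" else self.interval.start
            object.__setattr__(self, "reference_point", ref)
        if not (self.interval.start <= self.reference_point < self.interval.end):
            raise ValueError("reference_point must lie within the interval")


@dataclass(frozen=True)
class TFCluster:
    """A chain of TF sites whose sorted reference points are <= gap apart."""

    sites: tuple[TFSite, ...]
    span: GenomicInterval = field(init=False)
    n_tfs: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError("cluster must contain at least one site")
        chrom = self.sites[0].interval.chrom
        refs = sorted(s.reference_point for s in self.sites)
        object.__setattr__(
            self, "span", GenomicInterval(chrom, refs[0], refs[-1] + 1)
        )
        object.__setattr__(self, "n_tfs", len({s.tf for s in self.sites}))


def extend_to_length(site: TFSite, target_length: int = 200) -> TFSite:
    """Extend a site to ``target_length`` bp centered on its reference point.

    The left edge is clipped at the chromosome start without re-centering, so
    intervals near position 0 may come out shorter than requested. The
    reference point is unchanged.
    """
    if target_length <= 0 or target_length % 2:
        raise ValueError("target_length must be even and positive")
    half = target_length // 2
    center = site.reference_point
    start = max(0, center - half)
    end = center + half
    iv = GenomicInterval(site.interval.chrom, start, end, site.interval.strand)
    return replace(site, interval=iv)


def cluster_sites(sites: Sequence[TFSite], gap: int = 100) -> list[TFCluster]:
    """Single-linkage chaining of sites within ``gap`` bp of each other.

    Per chromosome, sites are sorted by reference point and consecutive points
    at distance <= gap (boundary inclusive) are chained into one cluster.
    Singletons are returned too; ``n_tfs`` counts distinct TF names.
    """
    if gap < 0:
        raise ValueError("gap must be non-negative")
    by_chrom: dict[str, list[TFSite]] = {}
    for s in sites:
        by_chrom.setdefault(s.interval.chrom, []).append(s)
    clusters: list[TFCluster] = []
    for chrom in sorted(by_chrom):
        ordered = sorted(
            by_chrom[chrom], key=lambda s: (s.reference_point, s.tf, s.interval.start)
        )
        chain: list[TFSite] = [ordered[0]]
        for s in ordered[1:]:
            if s.reference_point - chain[-1].reference_point <= gap:
                chain.append(s)
            else:
                clusters.append(TFCluster(tuple(chain)))
                chain = [s]
        clusters.append(TFCluster(tuple(chain)))
    return clusters


def assign_clusters_to_tes(
    tes: Sequence[TEInstance], clusters: Sequence[TFCluster]
) -> np.ndarray:
    """Count, per TE, the TFs bound via overlapping site clusters.

    A TE overlapping (>= 1 bp, half-open) a cluster with ``n_tfs = i`` is
    "bound by i TFs"; a TE hit by several clusters takes the maximum; TEs with
    no overlapping cluster get 0.  Returns an int array parallel to ``tes``.
    """
    out = np.zeros(len(tes), dtype=int)
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for c in clusters:
        by_chrom.setdefault(c.span.chrom, []).append((c.span.start, c.span.end, c.n_tfs))
    for spans in by_chrom.values():
        spans.sort()
    for idx, te in enumerate(tes):
        spans = by_chrom.get(te.interval.chrom, [])
        if not spans:
            continue
        starts = np.array([s[0] for s in spans])
        # candidate clusters cannot start at/after the TE end
        hi = int(np.searchsorted(starts, te.interval.end))
        best = 0
        for start, end, n in spans[:hi]:
            if end > te.interval.start and n > best:
                best = n
        out[idx] = best
    return out


def closest_gene(
    te: TEInstance,
    genes: Sequence[tuple[str, GenomicInterval]],
    max_dist: int = 50_000,
) -> tuple[str, int] | None:
    """Nearest gene within ``max_dist`` bp of a TE, or None.

    Distance is 0 for any overlap, else bp between nearest interval ends
    (closestBed semantics). Ties go to the gene with the smaller start.
    """
    if not genes:
        raise ValueError("gene list must be non-empty")
    best: tuple[int, int, str] | None = None
    for name, iv in genes:
        d = te.interval.distance(iv)
        if d is None or d > max_dist:
            continue
        key = (d, iv.start, name)
        if best is None or key < best:
            best = key
    if best is None:
        return None
    return best[2], best[0]


def associate_genes(
    tes: Sequence[TEInstance],
    genes: Sequence[tuple[str, GenomicInterval]],
    max_dist: int = 50_000,
) -> pd.DataFrame:
    """Tabulate each TE's nearest gene within the distance window."""
    rows = []
    for te in tes:
        hit = closest_gene(te, genes, max_dist) if genes else None
        rows.append(
            {
                "chrom": te.interval.chrom,
                "start": te.interval.start,
                "end": te.interval.end,
                "subfamily": te.subfamily,
                "nearest_gene": hit[0] if hit else "",
                "distance": hit[1] if hit else -1,
            }
        )
    return pd.DataFrame(rows)
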