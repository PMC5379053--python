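"""Binned, library-normalized coverage metaprofiles around TE centers.

Coverage for each epigenetic mark is averaged in fixed-width bins (default
50 bp) across a window (default 3 kb: 1.5 kb either side of the TE midpoint),
scaled to reads-per-million by the track's library size, and averaged per
TF-occupancy category (0 TFs, 1 TF, >= 2 TFs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import TEInstance

__all__ = ["CoverageTrack", "MetaProfile", "binned_profile", "category_profiles"]

CATEGORIES = ("0", "1", ">=2")


@dataclass
class CoverageTrack:
    """Per-base depth arrays keyed by chromosome, plus the library size."""

    depth: Mapping[str, np.ndarray]
    library_size: float
    mark: str = ""
    cell_type: str = ""
    normalize: bool = True  # False for ratio tracks (e.g. methylation)

    def scale(self) -> float:
        if not self.normalize:
            return 1.0
        if self.library_size <= 0:
            raise ValueError("library size must be positive for RPM scaling")
        return 1e6 / self.library_size


@dataclass
class MetaProfile:
    """Mean normalized read density per bin for one mark/cell-type/category."""

    mark: str
    cell_type: str
    category: str
    bins: np.ndarray
    n_elements: int


def binned_profile(
    track: CoverageTrack,
    chrom: str,
    center: int,
    flank: int = 1500,
    bin_size: int = 50,
) -> np.ndarray:
    """Mean RPM-scaled depth in each bin of the window around ``center``.

    Bin b covers [center - flank + b*bin, center - flank + (b+1)*bin). Bins
    truncated by a chromosome end are NaN so that category averaging can
    exclude them; a center outside the chromosome is an error.
    """
    if flank % bin_size:
        raise ValueError("flank must be a multiple of bin_size")
    if chrom not in track.depth:
        raise ValueError(f"unknown chromosome {chrom!r}")
    arr = track.depth[chrom]
    if not (0 <= center < arr.size):
        raise ValueError(f"center {center} outside chromosome {chrom}")
    n_bins = 2 * flank // bin_size
    out = np.full(n_bins, np.nan)
    scale = track.scale()
    for b in range(n_bins):
        lo = center - flank + b * bin_size
        hi = lo + bin_size
        if lo < 0 or hi > arr.size:
            continue  # truncated bin stays NaN
        out[b] = arr[lo:hi].mean() * scale
    return out


def category_profiles(
    tes: Sequence[TEInstance],
    n_tfs_per_te: Sequence[int],
    tracks: Sequence[CoverageTrack],
    flank: int = 1500,
    bin_size: int = 50,
) -> list[MetaProfile]:
    """Average binned profiles per TF-occupancy category, per track.

    Categories are 0 TFs, 1 TF and >= 2 TFs; the TE center is the integer
    midpoint of its interval. Empty categories are omitted with a warning.
    Missing (truncated) bins are excluded from the per-bin mean.
    """
    n_tfs = np.asarray(n_tfs_per_te, dtype=int)
    if len(tes) != n_tfs.size:
        raise ValueError("tes and n_tfs_per_te must be parallel")
    cat_members: dict[str, list[TEInstance]] = {c: [] for c in CATEGORIES}
    for te, n in zip(tes, n_tfs):
        cat = "0" if n == 0 else ("1" if n == 1 else ">=2")
        cat_members[cat].append(te)
    profiles: list[MetaProfile] = []
    for track in tracks:
        for cat in CATEGORIES:
            members = cat_members[cat]
            if not members:
                warnings.warn(
                    f"category {cat!r} has no elements for mark {track.mark!r}"
                )
                continue
            mat = np.vstack(
                [
                    binned_profile(
                        track, te.interval.chrom, te.interval.center, flank, bin_size
                    )
                    for te in members
                ]
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                mean = np.nanmean(mat, axis=0)
            profiles.append(
                MetaProfile(
                    mark=track.mark,
                    cell_type=track.cell_type,
                    category=cat,
                    bins=mean,
                    n_elements=len(members),
                )
            )
    return profiles


def profiles_to_frame(profiles: Sequence[MetaProfile]) -> pd.DataFrame:
    """Long-format table: mark, cell_type, category, bin, value, n_elements."""
    rows = []
    for p in profiles:
        for b, v in enumerate(p.bins):
            rows.append(
                {
                    "mark": p.mark,
                    "cell_type": p.cell_type,
                    "category": p.category,
                    "bin": b,
                    "value": v,
                    "n_elements": p.n_elements,
                }
            )
    return pd.DataFrame(rows)
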