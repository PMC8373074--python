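"""Strand-aware TSS/TES windows, repeat filtering and metagene profiles.

The TSS window of a gene is the 250 bp immediately upstream of (and
excluding) the transcription start base; the TES window is mirrored on the
downstream side of the transcription end.  All coordinates are 0-based
half-open, so on the + strand a gene starting at s has TSS window
[s - 250, s), and on the - strand a gene ending at e has TSS window
[e, e + 250).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GeneModel, GenomeAssembly, IntervalSet
from .simulate import FragmentSet
from .tracks import FRACTIONS, DepthTrack, ScoreTrack, _BaseTrack

__all__ = [
    "RegionWindow",
    "MetageneProfile",
    "anchor_window",
    "filter_repeat_overlap",
    "window_mean",
    "window_rcpm",
    "region_stats",
    "metagene_profile",
    "metagene_profiles",
]

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_BP = 250


@dataclass(frozen=True)
class RegionWindow:
    """A fixed-size window anchored at a gene's TSS or TES."""

    chrom: str
    start: int
    end: int
    gene_id: str
    kind: str  # "TSS" or "TES"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"window for {self.gene_id}: start must be < end")
        if self.kind not in ("TSS", "TES"):
            raise ValueError(f"window kind must be TSS or TES, got {self.kind!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def anchor_window(
    gene: GeneModel,
    kind: str = "TSS",
    upstream_bp: int = DEFAULT_WINDOW_BP,
    genome: GenomeAssembly | None = None,
) -> RegionWindow:
    """Window on the regulatory side of the anchor, oriented by strand.

    TSS: the ``upstream_bp`` bases upstream of transcription initiation.
    TES: the ``upstream_bp`` bases downstream of transcription termination.
    Windows extending past a chromosome edge are clipped with a warning
    (pass ``genome`` to clip at the right end too).
    """
    if kind not in ("TSS", "TES"):
        raise ValueError(f"kind must be TSS or TES, got {kind!r}")
    if upstream_bp <= 0:
        raise ValueError("upstream_bp must be > 0")
    if gene.strand not in ("+", "-"):  # unreachable via GeneModel, guards raw input
        raise ValueError(f"unknown strand {gene.strand!r}")
    upstream_side = (kind == "TSS") == (gene.strand == "+")
    if upstream_side:
        start, end = gene.start - upstream_bp, gene.start
    else:
        start, end = gene.end, gene.end + upstream_bp
    if start < 0:
        warnings.warn(f"window for {gene.gene_id} clipped at chromosome start")
        start = 0
    if genome is not None:
        L = genome.length(gene.chrom)
        if end > L:
            warnings.warn(f"window for {gene.gene_id} clipped at chromosome end")
            end = L
    if start >= end:
        raise ValueError(f"window for {gene.gene_id} is empty after clipping")
    return RegionWindow(gene.chrom, start, end, gene.gene_id, kind)


def filter_repeat_overlap(
    windows: list[RegionWindow], repeats: IntervalSet
) -> list[RegionWindow]:
    """Drop every window that overlaps any repeat by >= 1 bp.

    Half-open overlap test: a window [ws, we) and repeat [rs, re) overlap
    iff ws < re and rs < we; abutting intervals do not overlap.  Equivalent
    to intersect-with-inversion on the window list.
    """
    if len(repeats) == 0:
        return list(windows)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in repeats.frame.groupby("chrom"):
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy()
        # prefix-max of ends lets a single binary search answer the overlap query
        ends_cummax = np.maximum.accumulate(sub["end"].to_numpy())
        by_chrom[str(chrom)] = (starts, ends_cummax)
    kept = []
    for w in windows:
        if w.chrom not in by_chrom:
            kept.append(w)
            continue
        starts, ends_cummax = by_chrom[w.chrom]
        i = np.searchsorted(starts, w.end, side="left")  # repeats with start < w.end
        if i == 0 or ends_cummax[i - 1] <= w.start:
            kept.append(w)
    return kept


def window_mean(track: _BaseTrack, window: RegionWindow) -> float:
    """Arithmetic mean of the track over the window's bases."""
    if window.length <= 0:
        raise ValueError("zero-length window")
    v = track[window.chrom]
    if window.start < 0 or window.end > v.size:
        raise ValueError(f"window {window} outside track")
    return float(v[window.start : window.end].mean())


def window_rcpm(
    fragments: FragmentSet,
    window: RegionWindow,
    total_mapped: int | None = None,
) -> float:
    """Read count per million mapped within the window.

    Counts fragments overlapping the window by >= 1 bp, scaled by 1e6 /
    total mapped fragments (default: the size of the fragment set).
    """
    if window.length <= 0:
        raise ValueError("zero-length window")
    total = len(fragments) if total_mapped is None else int(total_mapped)
    if total <= 0:
        raise ValueError("total_mapped must be positive")
    sub = fragments.frame
    sub = sub[sub["chrom"] == window.chrom]
    n = int(((sub["start"] < window.end) & (sub["end"] > window.start)).sum())
    return n * 1e6 / total


def region_stats(
    window: RegionWindow,
    track: _BaseTrack | None = None,
    fragments: FragmentSet | None = None,
    total_mapped: int | None = None,
) -> tuple[float | None, float | None]:
    """(mean track value, rcpm) over one window; either half may be skipped."""
    mean = window_mean(track, window) if track is not None else None
    rcpm = (
        window_rcpm(fragments, window, total_mapped) if fragments is not None else None
    )
    return mean, rcpm


def _rcpm_table(
    fragments: FragmentSet,
    windows: list[RegionWindow],
    total_mapped: int | None = None,
) -> pd.Series:
    """Vectorized rcpm per window (indexed by gene_id), one fragment set."""
    total = len(fragments) if total_mapped is None else int(total_mapped)
    if total <= 0:
        raise ValueError("total_mapped must be positive")
    out = {}
    by_chrom = {str(c): sub for c, sub in fragments.frame.groupby("chrom")}
    sorted_cols: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in by_chrom.items():
        sorted_cols[chrom] = (
            np.sort(sub["start"].to_numpy()),
            np.sort(sub["end"].to_numpy()),
        )
    for w in windows:
        if w.chrom not in sorted_cols:
            out[w.gene_id] = 0.0
            continue
        starts, ends = sorted_cols[w.chrom]
        n_tot = starts.size
        n_right = n_tot - np.searchsorted(starts, w.end, side="left")  # start >= w.end
        n_left = np.searchsorted(ends, w.start, side="right")  # end <= w.start
        out[w.gene_id] = (n_tot - n_right - n_left) * 1e6 / total
    return pd.Series(out, name="rcpm")


@dataclass
class MetageneProfile:
    """Fractional proportions over (flank | scaled gene body | flank).

    ``proportions`` has one row per fraction (1..5) and one column per bin;
    each column with signal sums to 1.  ``bin_edges_label`` marks which bins
    are upstream flank / body / downstream flank.
    """

    proportions: np.ndarray  # (5, n_bins)
    mean_depth: np.ndarray  # (5, n_bins) mean normalized depth before ratios
    flank_bins: int
    body_bins: int
    n_genes: int

    @property
    def n_bins(self) -> int:
        return self.proportions.shape[1]

    @property
    def tss_bin(self) -> int:
        """Index of the first gene-body bin (the bin at the TSS)."""
        return self.flank_bins

    @property
    def tes_bin(self) -> int:
        """Index of the last gene-body bin (the bin at the TES)."""
        return self.flank_bins + self.body_bins - 1

    def as_frame(self) -> pd.DataFrame:
        cols = (
            [f"up{j}" for j in range(self.flank_bins)]
            + [f"body{j}" for j in range(self.body_bins)]
            + [f"down{j}" for j in range(self.flank_bins)]
        )
        return pd.DataFrame(self.proportions, index=[f"Fr-{f}" for f in FRACTIONS], columns=cols)


def _binned_means(cs: np.ndarray, bounds: np.ndarray) -> np.ndarray:
    """Mean of a per-base vector over [bounds[i], bounds[i+1]) via its cumsum."""
    widths = np.diff(bounds)
    return (cs[bounds[1:]] - cs[bounds[:-1]]) / widths


def metagene_profile(
    fraction_tracks: dict[int, DepthTrack],
    genes: list[GeneModel],
    flank_bp: int = 2000,
    body_bins: int = 100,
    flank_bins: int = 40,
) -> MetageneProfile:
    """Average fractional proportions over genes, TSS on the left.

    Each gene body is linearly rescaled to ``body_bins`` bins; the 5' and 3'
    flanks keep their native scale, split into ``flank_bins`` bins each.
    Minus-strand genes are reversed so transcription always runs left to
    right.  Genes shorter than ``body_bins`` bp, or whose flanks leave the
    chromosome, are skipped (count logged).  Per bin, the proportion of
    fraction f is its mean depth divided by the sum over the five fractions.
    """
    if set(fraction_tracks) != set(FRACTIONS):
        raise ValueError("need one track per fraction 1..5")
    genome = fraction_tracks[1].genome
    cumsums = {
        f: {c: np.concatenate(([0.0], np.cumsum(t[c]))) for c in genome}
        for f, t in fraction_tracks.items()
    }
    n_bins = 2 * flank_bins + body_bins
    sums = np.zeros((5, n_bins))
    used = 0
    skipped = 0
    for gene in genes:
        L = genome.length(gene.chrom)
        if gene.length < body_bins or gene.start - flank_bp < 0 or gene.end + flank_bp > L:
            skipped += 1
            continue
        up = np.linspace(gene.start - flank_bp, gene.start, flank_bins + 1).astype(np.int64)
        body = np.round(np.linspace(gene.start, gene.end, body_bins + 1)).astype(np.int64)
        down = np.linspace(gene.end, gene.end + flank_bp, flank_bins + 1).astype(np.int64)
        for fi, f in enumerate(FRACTIONS):
            cs = cumsums[f][gene.chrom]
            prof = np.concatenate(
                [_binned_means(cs, up), _binned_means(cs, body), _binned_means(cs, down)]
            )
            if gene.strand == "-":
                prof = prof[::-1]
            sums[fi] += prof
        used += 1
    if skipped:
        logger.info("metagene_profile: skipped %d genes (too short or flank off chromosome)", skipped)
    if used == 0:
        raise ValueError("no usable genes for metagene profile")
    mean_depth = sums / used
    col_tot = mean_depth.sum(axis=0)
    proportions = np.divide(
        mean_depth, col_tot, out=np.zeros_like(mean_depth), where=col_tot > 0
    )
    return MetageneProfile(proportions, mean_depth, flank_bins, body_bins, used)


def metagene_profiles(
    fraction_tracks: dict[int, DepthTrack],
    genes_by_class: dict[str, list[GeneModel]],
    flank_bp: int = 2000,
    body_bins: int = 100,
    flank_bins: int = 40,
) -> dict[str, MetageneProfile]:
    """One metagene profile per expression class; empty classes are skipped."""
    out = {}
    for cls, genes in genes_by_class.items():
        if not genes:
            logger.warning("metagene_profiles: class %r has no genes, skipped", cls)
            continue
        out[cls] = metagene_profile(fraction_tracks, genes, flank_bp, body_bins, flank_bins)
    return out
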