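"""Nucleosome occupancy summaries: NFR depth and TSS occupancy curves.

The nucleosome-free-region (NFR) depth of a gene is the distance between the
lowest and highest occupancy values inside its TSS window (the 250 bp
upstream of the start site): ``nfr_depth = max - min``.  No smoothing is
applied.  Occupancy units are arbitrary; downstream correlation analyses are
unit-free, and the statistic is invariant to adding a constant to the track.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import RegionWindow
from .genome import GeneModel, tss_position
from .tracks import DepthTrack

__all__ = ["OccupancySummary", "nfr_depth", "nfr_depth_table", "tss_occupancy_curve"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OccupancySummary:
    gene_id: str
    min_occ: float
    max_occ: float

    @property
    def nfr_depth(self) -> float:
        return self.max_occ - self.min_occ


def nfr_depth(occupancy: DepthTrack, tss_window: RegionWindow) -> OccupancySummary:
    """max - min occupancy over the TSS window's bases."""
    if tss_window.length <= 0:
        raise ValueError("zero-length window")
    v = occupancy[tss_window.chrom]
    if tss_window.start < 0 or tss_window.end > v.size:
        raise ValueError(f"window {tss_window} outside occupancy track")
    seg = v[tss_window.start : tss_window.end]
    return OccupancySummary(tss_window.gene_id, float(seg.min()), float(seg.max()))


def nfr_depth_table(
    occupancy: DepthTrack, windows: list[RegionWindow]
) -> pd.DataFrame:
    """One row per window: gene_id, min_occ, max_occ, nfr_depth."""
    rows = []
    for w in windows:
        s = nfr_depth(occupancy, w)
        rows.append((s.gene_id, s.min_occ, s.max_occ, s.nfr_depth))
    return pd.DataFrame(rows, columns=["gene_id", "min_occ", "max_occ", "nfr_depth"])


def tss_occupancy_curve(
    occupancy: DepthTrack,
    genes_by_class: dict[str, list[GeneModel]],
    flank_bp: int = 1000,
    n_bins: int = 100,
) -> dict[str, np.ndarray]:
    """Mean occupancy around the TSS (strand-aware), one curve per class.

    The curve covers [TSS - flank_bp, TSS + flank_bp) in ``n_bins`` equal
    bins, oriented so transcription runs left to right.  Genes whose window
    leaves the chromosome are skipped; classes with no usable genes are
    omitted with a warning.
    """
    genome = occupancy.genome
    cumsums = {c: np.concatenate(([0.0], np.cumsum(occupancy[c]))) for c in genome}
    out: dict[str, np.ndarray] = {}
    for cls, genes in genes_by_class.items():
        acc = np.zeros(n_bins)
        used = 0
        for gene in genes:
            center = tss_position(gene)
            lo, hi = center - flank_bp, center + flank_bp
            if lo < 0 or hi > genome.length(gene.chrom):
                continue
            bounds = np.round(np.linspace(lo, hi, n_bins + 1)).astype(np.int64)
            cs = cumsums[gene.chrom]
            prof = (cs[bounds[1:]] - cs[bounds[:-1]]) / np.diff(bounds)
            if gene.strand == "-":
                prof = prof[::-1]
            acc += prof
            used += 1
        if used == 0:
            logger.warning("tss_occupancy_curve: class %r has no usable genes, omitted", cls)
            continue
        out[cls] = acc / used
    return out
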