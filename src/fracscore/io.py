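"""Readers and writers for the plain-text formats the pipeline exchanges.

BED and bedGraph are written with 0-based half-open coordinates.  The
bedGraph writer run-length-compresses runs of equal adjacent values, so a
dense per-base track round-trips losslessly through a compact file.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GeneModel, GenomeAssembly, IntervalSet, genes_from_frame, genes_to_frame
from .simulate import FragmentSet
from .tracks import DepthTrack, ScoreTrack, _BaseTrack

__all__ = [
    "write_bed",
    "read_bed",
    "write_fragments_bed",
    "read_fragments_bed",
    "write_bedgraph",
    "read_bedgraph",
    "write_genes_tsv",
    "read_genes_tsv",
    "write_chrom_sizes",
    "read_chrom_sizes",
]


def write_bed(intervals: IntervalSet | pd.DataFrame, path: str | Path) -> None:
    frame = intervals.frame if isinstance(intervals, IntervalSet) else intervals
    frame[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> IntervalSet:
    frame = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2], names=["chrom", "start", "end"]
    )
    return IntervalSet(frame)


def write_fragments_bed(fragments: FragmentSet, path: str | Path, fraction: int | None = None) -> None:
    """Write fragments as 3-column BED, optionally one fraction only."""
    frame = fragments.frame
    if fraction is not None:
        frame = frame[frame["fraction"] == fraction]
    frame = frame.sort_values(["chrom", "start", "end"], kind="mergesort")
    frame[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def read_fragments_bed(path: str | Path, genome: GenomeAssembly, fraction: int) -> FragmentSet:
    frame = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2], names=["chrom", "start", "end"]
    )
    frame["fraction"] = np.int8(fraction)
    return FragmentSet(genome, frame)


def write_bedgraph(track: _BaseTrack, path: str | Path, fmt: str = "%.6g") -> None:
    """Run-length-compressed bedGraph; zero runs are kept for losslessness."""
    with open(path, "w") as fh:
        for chrom in track.genome:
            v = track[chrom]
            if v.size == 0:
                continue
            change = np.flatnonzero(np.diff(v)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [v.size]))
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\t{fmt % v[s]}\n")


def read_bedgraph(path: str | Path, genome: GenomeAssembly, kind: str = "depth"):
    """Expand a bedGraph into a dense per-base track (depth or score)."""
    frame = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"]
    )
    data = {c: np.zeros(genome.length(c)) for c in genome}
    for chrom, sub in frame.groupby("chrom"):
        if chrom not in genome:
            raise ValueError(f"bedGraph chromosome {chrom!r} not in genome")
        v = data[str(chrom)]
        for row in sub.itertuples(index=False):
            v[row.start : row.end] = row.value
    cls = DepthTrack if kind == "depth" else ScoreTrack
    return cls(genome, data)


def write_genes_tsv(genes: list[GeneModel], path: str | Path) -> None:
    genes_to_frame(genes).to_csv(path, sep="\t", index=False)


def read_genes_tsv(path: str | Path) -> list[GeneModel]:
    return genes_from_frame(pd.read_csv(path, sep="\t"))


def write_chrom_sizes(genome: GenomeAssembly, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in zip(genome.chrom_names, genome.chrom_lengths):
            fh.write(f"{name}\t{length}\n")


def read_chrom_sizes(path: str | Path) -> GenomeAssembly:
    frame = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return GenomeAssembly(tuple(frame["chrom"].astype(str)), tuple(int(x) for x in frame["length"]))
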