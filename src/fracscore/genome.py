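"""Genome assemblies, gene models and interval sets.

Coordinates are 0-based half-open (BED convention) throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomeAssembly",
    "GeneModel",
    "IntervalSet",
    "tss_position",
    "tes_position",
]


@dataclass(frozen=True)
class GenomeAssembly:
    """A set of named chromosomes with fixed lengths (in bp)."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("chromosome names must be unique")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")

    @property
    def total_length(self) -> int:
        return int(sum(self.chrom_lengths))

    def length(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[self.chrom_names.index(chrom)]
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_names

    def __iter__(self) -> Iterator[str]:
        return iter(self.chrom_names)


@dataclass(frozen=True)
class GeneModel:
    """One gene: a strand-oriented interval with an optional TPM value."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    tpm: float | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")
        if self.tpm is not None and self.tpm < 0:
            raise ValueError(f"gene {self.gene_id}: tpm must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start

    def with_tpm(self, tpm: float) -> "GeneModel":
        return replace(self, tpm=float(tpm))


def tss_position(gene: GeneModel) -> int:
    """Base index of the transcription start site (inside the gene)."""
    return gene.start if gene.strand == "+" else gene.end - 1


def tes_position(gene: GeneModel) -> int:
    """Base index of the transcription end site (inside the gene)."""
    return gene.end - 1 if gene.strand == "+" else gene.start


@dataclass
class IntervalSet:
    """A plain set of (chrom, start, end) intervals: repeats, TADs, ...

    Backed by a pandas frame with columns chrom/start/end.
    """

    frame: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["chrom", "start", "end"]))

    def __post_init__(self) -> None:
        missing = {"chrom", "start", "end"} - set(self.frame.columns)
        if missing:
            raise ValueError(f"interval frame missing columns {sorted(missing)}")
        if len(self.frame) and not (self.frame["start"] < self.frame["end"]).all():
            raise ValueError("intervals must satisfy start < end")

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, int, int]]) -> "IntervalSet":
        recs = list(records)
        return cls(pd.DataFrame(recs, columns=["chrom", "start", "end"]))

    def __len__(self) -> int:
        return len(self.frame)

    def for_chrom(self, chrom: str) -> pd.DataFrame:
        return self.frame[self.frame["chrom"] == chrom]

    def validate_bounds(self, genome: GenomeAssembly) -> None:
        for chrom, sub in self.frame.groupby("chrom"):
            if chrom not in genome:
                raise ValueError(f"interval on unknown chromosome {chrom!r}")
            L = genome.length(str(chrom))
            if (sub["start"] < 0).any() or (sub["end"] > L).any():
                raise ValueError(f"interval out of bounds on {chrom}")


def genes_to_frame(genes: Sequence[GeneModel]) -> pd.DataFrame:
    """Tabulate gene models (one row per gene, TSV-ready)."""
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "strand": [g.strand for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "tpm": [np.nan if g.tpm is None else g.tpm for g in genes],
        }
    )


def genes_from_frame(frame: pd.DataFrame) -> list[GeneModel]:
    genes = []
    for row in frame.itertuples(index=False):
        tpm = getattr(row, "tpm", None)
        if tpm is not None and np.isnan(tpm):
            tpm = None
        genes.append(
            GeneModel(
                gene_id=str(row.gene_id),
                chrom=str(row.chrom),
                strand=str(row.strand),
                start=int(row.start),
                end=int(row.end),
                tpm=tpm,
            )
        )
    return genes
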