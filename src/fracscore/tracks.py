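"""Per-base signal tracks over a genome assembly.

A track stores one float vector per chromosome, one value per base.  This is
the in-memory analogue of a (dense) wiggle/bedGraph file and is shared by
coverage depth, MNase occupancy, RNAP signal and the Fr-5/Fr-1 score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import GenomeAssembly

__all__ = ["DepthTrack", "ScoreTrack", "FRACTIONS"]

#: Valid sedimentation fraction labels, top (open) to bottom (compact).
FRACTIONS: tuple[int, ...] = (1, 2, 3, 4, 5)


@dataclass
class _BaseTrack:
    genome: GenomeAssembly
    data: dict[str, np.ndarray] = field(repr=False)

    def __post_init__(self) -> None:
        for chrom in self.genome:
            if chrom not in self.data:
                raise ValueError(f"track missing chromosome {chrom!r}")
            v = np.asarray(self.data[chrom], dtype=np.float64)
            if v.ndim != 1 or v.shape[0] != self.genome.length(chrom):
                raise ValueError(
                    f"track vector for {chrom} has length {v.shape[0]}, "
                    f"expected {self.genome.length(chrom)}"
                )
            self.data[chrom] = v

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.data[chrom]

    @property
    def total_signal(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))

    def copy(self):
        return type(self)(self.genome, {c: v.copy() for c, v in self.data.items()})

    def same_genome(self, other: "_BaseTrack") -> bool:
        return self.genome == other.genome

    @classmethod
    def zeros(cls, genome: GenomeAssembly):
        return cls(genome, {c: np.zeros(genome.length(c)) for c in genome})


class DepthTrack(_BaseTrack):
    """Nonnegative per-base signal (coverage depth, occupancy, ChIP level)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        for chrom, v in self.data.items():
            if (v < 0).any():
                raise ValueError(f"negative depth values on {chrom}")


class ScoreTrack(_BaseTrack):
    """Per-base log2 ratio track (may be negative); must be finite."""

    def __post_init__(self) -> None:
        super().__post_init__()
        for chrom, v in self.data.items():
            if not np.isfinite(v).all():
                raise ValueError(f"non-finite score values on {chrom}")
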