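"""Coverage depth, normalization and the Fr-5/Fr-1 compaction score.

The central statistic is, per base p,

    score(p) = log2( (d5(p) + eps) / (d1(p) + eps) )

where d1 and d5 are the normalized sequencing depths of the top (open,
Fr-1) and bottom (compact, Fr-5) gradient fractions and eps (default 0.001)
keeps the ratio finite where either depth is zero.  Very negative scores mark
locally open chromatin; scores near zero mark compact chromatin.

Normalization follows the fixed order: rescale each fraction's depth track to
a common target total signal (the "wigsum", default 8.5e9), then multiply by
that fraction's recovered-DNA factor.  Because the score is a ratio of two
tracks sharing the same wigsum, the wigsum cancels and the recovery factors
carry all inter-fraction asymmetry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .genome import GenomeAssembly
from .simulate import FragmentSet
from .tracks import FRACTIONS, DepthTrack, ScoreTrack

__all__ = [
    "NormalizationConfig",
    "CompactionBinConfig",
    "ClassificationResult",
    "coverage_from_fragments",
    "normalize_track",
    "compaction_score",
    "classify_compaction",
]

logger = logging.getLogger(__name__)

#: Default offset added to both depths before the ratio, and default wigsum.
DEFAULT_EPSILON = 0.001
DEFAULT_WIGSUM = 8.5e9


@dataclass(frozen=True)
class NormalizationConfig:
    """Target wigsum, per-fraction recovered-DNA factors, and ratio offset."""

    wigsum: float = DEFAULT_WIGSUM
    recovery_factors: tuple[float, float, float, float, float] = (1.0,) * 5
    epsilon: float = DEFAULT_EPSILON

    def __post_init__(self) -> None:
        if self.wigsum <= 0:
            raise ValueError("wigsum must be > 0")
        if len(self.recovery_factors) != 5 or any(f <= 0 for f in self.recovery_factors):
            raise ValueError("recovery_factors must be 5 positive values")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")

    def factor(self, fraction: int) -> float:
        if fraction not in FRACTIONS:
            raise ValueError(f"fraction must be in 1..5, got {fraction}")
        return self.recovery_factors[fraction - 1]


@dataclass(frozen=True)
class CompactionBinConfig:
    """Four ascending score edges splitting the genome into five classes.

    Class 0 (score below the first edge) is the most open, class 4 the most
    compact.  The default edges bracket the two thresholds used in practice:
    -3.5 (genome-wide compaction) and -2.5 (relatively open chromatin).
    """

    edges: tuple[float, float, float, float] = (-4.5, -3.5, -2.5, -1.5)
    labels: tuple[str, ...] = field(
        default=("very open", "open", "intermediate", "compact", "very compact")
    )

    def __post_init__(self) -> None:
        if len(self.edges) != 4 or any(
            self.edges[i] >= self.edges[i + 1] for i in range(3)
        ):
            raise ValueError("edges must be 4 strictly increasing values")
        if len(self.labels) != 5:
            raise ValueError("need 5 class labels")


@dataclass
class ClassificationResult:
    """Per-base class labels plus genome-wide percentages."""

    labels: dict[str, np.ndarray]
    percentages: np.ndarray  # (5,), sums to 100
    class_names: tuple[str, ...]
    threshold: float
    pct_above_threshold: float

    def as_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"compaction_class": self.class_names, "percent_of_genome": self.percentages}
        )


def coverage_from_fragments(
    fragments: FragmentSet,
    genome: GenomeAssembly,
    fraction: int | None = None,
) -> DepthTrack:
    """Per-base count of fragments covering each base (half-open intervals).

    Restrict to one sedimentation fraction with ``fraction=``; fragment
    bounds are validated by :class:`FragmentSet` on construction.
    """
    frame = fragments.frame
    if fraction is not None:
        if fraction not in FRACTIONS:
            raise ValueError(f"fraction must be in 1..5, got {fraction}")
        frame = frame[frame["fraction"] == fraction]
    data = {}
    for chrom in genome:
        L = genome.length(chrom)
        diff = np.zeros(L + 1)
        sub = frame[frame["chrom"] == chrom]
        if len(sub):
            np.add.at(diff, sub["start"].to_numpy(), 1.0)
            np.add.at(diff, sub["end"].to_numpy(), -1.0)
        data[chrom] = np.cumsum(diff[:-1])
    return DepthTrack(genome, data)


def normalize_track(
    track: DepthTrack,
    config: NormalizationConfig,
    fraction: int | None = None,
) -> DepthTrack:
    """Rescale to the wigsum, then apply the fraction's recovery factor.

    A track with zero total signal is returned unchanged with a warning (it
    cannot be rescaled).
    """
    total = track.total_signal
    if total <= 0:
        logger.warning("normalize_track: track has zero total signal; returned unchanged")
        return track.copy()
    scale = config.wigsum / total
    if fraction is not None:
        scale *= config.factor(fraction)
    return DepthTrack(track.genome, {c: v * scale for c, v in track.data.items()})


def compaction_score(
    track1: DepthTrack,
    track5: DepthTrack,
    epsilon: float = DEFAULT_EPSILON,
) -> ScoreTrack:
    """log2((Fr-5 depth + eps) / (Fr-1 depth + eps)) at every base."""
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    if not track1.same_genome(track5):
        raise ValueError("Fr-1 and Fr-5 tracks cover different genomes")
    data = {
        c: np.log2((track5[c] + epsilon) / (track1[c] + epsilon)) for c in track1.genome
    }
    return ScoreTrack(track1.genome, data)


def classify_compaction(
    score_track: ScoreTrack,
    bins: CompactionBinConfig | None = None,
    threshold: float = -3.5,
) -> ClassificationResult:
    """Assign every base one of five compaction classes and tally percentages.

    Also reports the percentage of bases scoring above ``threshold``
    (default -3.5), the conventional cut for "compacted" chromatin.
    """
    bins = bins or CompactionBinConfig()
    edges = np.asarray(bins.edges)
    labels = {}
    counts = np.zeros(5, dtype=np.int64)
    n_total = 0
    n_above = 0
    for chrom in score_track.genome:
        v = score_track[chrom]
        lab = np.searchsorted(edges, v, side="right").astype(np.uint8)
        labels[chrom] = lab
        counts += np.bincount(lab, minlength=5)
        n_total += v.size
        n_above += int((v > threshold).sum())
    pct = 100.0 * counts / max(n_total, 1)
    return ClassificationResult(
        labels=labels,
        percentages=pct,
        class_names=bins.labels,
        threshold=threshold,
        pct_above_threshold=100.0 * n_above / max(n_total, 1),
    )
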