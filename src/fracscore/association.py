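"""Gene-level association of compaction scores with expression, RNAP and TADs.

Expression classes follow the fixed cuts on the log10(TPM + 1) scale:
Low < 0.15, Mid in (0.5, 1.5], High > 2.0.  Values falling in the gaps
(0.15, 0.5] and (1.5, 2.0] belong to no class and are excluded from
class-grouped analyses but retained in scatter/correlation analyses.

Gene qualification requires a read count per million mapped (rcpm) strictly
above 0.05 at both the TSS and the TES window, which guards the log-ratio
score against zero-coverage windows.

Correlation coefficients are sample Pearson r with an ordinary
least-squares approximation line; r and the two-sided p-value are reported
per test with no multiple-testing adjustment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import IntervalSet
from .tracks import ScoreTrack, DepthTrack
from .annotation import RegionWindow, window_mean

__all__ = [
    "ExpressionCategoryConfig",
    "QualificationConfig",
    "FitResult",
    "TADSummary",
    "categorize_expression",
    "categorize_expression_array",
    "qualify_genes",
    "pearson_fit",
    "fraction_relative_abundance",
    "tad_summary",
    "rnap_association",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExpressionCategoryConfig:
    """Class cuts on the log10(TPM + 1) scale."""

    low_max: float = 0.15
    mid_min: float = 0.5
    mid_max: float = 1.5
    high_min: float = 2.0

    def __post_init__(self) -> None:
        if not self.low_max < self.mid_min < self.mid_max < self.high_min:
            raise ValueError("need low_max < mid_min < mid_max < high_min")


@dataclass(frozen=True)
class QualificationConfig:
    rcpm_min: float = 0.05

    def __post_init__(self) -> None:
        if self.rcpm_min < 0:
            raise ValueError("rcpm_min must be >= 0")


@dataclass(frozen=True)
class FitResult:
    """Pearson correlation with its least-squares approximation line."""

    r: float
    slope: float
    intercept: float
    pvalue: float
    n: int


def categorize_expression(
    tpm: float, config: ExpressionCategoryConfig | None = None
) -> str | None:
    """Map a TPM to Low / Mid / High, or None for the between-class gaps.

    Bounds are exactly: Low if y < low_max; Mid if mid_min < y <= mid_max;
    High if y > high_min, where y = log10(tpm + 1).
    """
    config = config or ExpressionCategoryConfig()
    if tpm < 0:
        raise ValueError("tpm must be >= 0")
    y = np.log10(tpm + 1.0)
    if y < config.low_max:
        return "Low"
    if config.mid_min < y <= config.mid_max:
        return "Mid"
    if y > config.high_min:
        return "High"
    return None


def categorize_expression_array(
    tpm: np.ndarray, config: ExpressionCategoryConfig | None = None
) -> np.ndarray:
    """Vectorized :func:`categorize_expression`; None encodes no class."""
    config = config or ExpressionCategoryConfig()
    tpm = np.asarray(tpm, dtype=float)
    if (tpm < 0).any():
        raise ValueError("tpm must be >= 0")
    y = np.log10(tpm + 1.0)
    out = np.full(y.shape, None, dtype=object)
    out[y < config.low_max] = "Low"
    out[(y > config.mid_min) & (y <= config.mid_max)] = "Mid"
    out[y > config.high_min] = "High"
    return out


def qualify_genes(
    records: pd.DataFrame, config: QualificationConfig | None = None
) -> pd.DataFrame:
    """Keep genes with rcpm strictly above the cut at both TSS and TES.

    ``records`` must carry columns ``rcpm_tss`` and ``rcpm_tes``; rows at
    exactly the cut are excluded (strict inequality).
    """
    config = config or QualificationConfig()
    need = {"rcpm_tss", "rcpm_tes"}
    if need - set(records.columns):
        raise ValueError(f"records must have columns {sorted(need)}")
    keep = (records["rcpm_tss"] > config.rcpm_min) & (records["rcpm_tes"] > config.rcpm_min)
    return records[keep].reset_index(drop=True)


def pearson_fit(x, y) -> FitResult:
    """Sample Pearson r plus the OLS line y = slope * x + intercept."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: x or y is constant")
    res = stats.linregress(x, y)
    return FitResult(
        r=float(res.rvalue),
        slope=float(res.slope),
        intercept=float(res.intercept),
        pvalue=float(res.pvalue),
        n=int(x.size),
    )


def fraction_relative_abundance(
    amounts, epsilon: float = 0.001
) -> np.ndarray:
    """log2 of each fraction's amount relative to the mean over fractions.

    Zero amounts would make the log diverge; when any amount is zero the
    ``epsilon`` offset is added to every amount first (with a warning), the
    same offset convention used by the compaction score.
    """
    a = np.asarray(amounts, dtype=float)
    if (a < 0).any():
        raise ValueError("amounts must be >= 0")
    if not (a > 0).any():
        raise ValueError("at least one amount must be positive")
    if (a == 0).any():
        warnings.warn(f"zero amounts offset by epsilon={epsilon}")
        a = a + epsilon
    return np.log2(a / a.mean())


@dataclass
class TADSummary:
    """Per-TAD score statistics and boundary openness classification."""

    tad_table: pd.DataFrame  # chrom, start, end, length, mean_score, sd_score
    boundary_table: pd.DataFrame  # chrom, position, mean_score, open
    open_threshold: float
    length_fit: FitResult | None  # TAD length vs TAD mean score

    @property
    def open_boundary_fraction(self) -> float:
        if len(self.boundary_table) == 0:
            return float("nan")
        return float(self.boundary_table["open"].mean())


def tad_summary(
    score_track: ScoreTrack,
    tads: IntervalSet,
    open_threshold: float = -2.5,
    boundary_window: int = 2000,
) -> TADSummary:
    """Mean/SD of the score inside each TAD, plus boundary openness.

    Each TAD contributes its start and end points as boundaries (shared
    points deduplicated per chromosome); a boundary's score is the mean over
    a symmetric window of ``boundary_window`` bp (clipped at chromosome
    edges), and it is called open iff that mean is below ``open_threshold``.
    Also reports the Pearson fit of TAD length vs TAD mean score (None when
    undefined, e.g. fewer than 3 TADs).
    """
    tad_rows = []
    boundary_rows = []
    genome = score_track.genome
    tads.validate_bounds(genome)
    half = boundary_window // 2
    for chrom, sub in tads.frame.groupby("chrom", sort=True):
        v = score_track[str(chrom)]
        for row in sub.itertuples(index=False):
            seg = v[row.start : row.end]
            tad_rows.append(
                (
                    chrom,
                    int(row.start),
                    int(row.end),
                    int(row.end - row.start),
                    float(seg.mean()),
                    float(seg.std(ddof=0)),
                )
            )
        for pos in sorted(set(sub["start"]).union(sub["end"])):
            lo = max(0, int(pos) - half)
            hi = min(v.size, int(pos) + half)
            mean = float(v[lo:hi].mean())
            boundary_rows.append((chrom, int(pos), mean, mean < open_threshold))
    tad_table = pd.DataFrame(
        tad_rows, columns=["chrom", "start", "end", "length", "mean_score", "sd_score"]
    )
    boundary_table = pd.DataFrame(
        boundary_rows, columns=["chrom", "position", "mean_score", "open"]
    )
    fit = None
    if len(tad_table) >= 3:
        try:
            fit = pearson_fit(tad_table["length"], tad_table["mean_score"])
        except ValueError:
            logger.warning("tad_summary: length-vs-score correlation undefined")
    return TADSummary(tad_table, boundary_table, open_threshold, fit)


def rnap_association(
    rnap_track: DepthTrack,
    tss_windows: list[RegionWindow],
    tss_scores: pd.Series,
) -> tuple[pd.DataFrame, FitResult | None]:
    """Per-gene RNAP level at the TSS joined with the Fr-5/Fr-1 TSS score.

    ``tss_scores`` is indexed by gene_id.  Returns the joined table and the
    Pearson fit of score vs RNAP level; the fit is None (with a warning)
    when the correlation is undefined, the table is emitted regardless.
    """
    rows = []
    for w in tss_windows:
        if w.gene_id not in tss_scores.index:
            continue
        rows.append((w.gene_id, window_mean(rnap_track, w), float(tss_scores[w.gene_id])))
    table = pd.DataFrame(rows, columns=["gene_id", "rnap_level", "tss_score"])
    fit = None
    if len(table) >= 3:
        try:
            fit = pearson_fit(table["tss_score"], table["rnap_level"])
        except ValueError:
            logger.warning("rnap_association: correlation undefined (constant input)")
    return table, fit
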