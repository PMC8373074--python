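"""Synthetic sedimentation-fractionation data with a planted compaction landscape.

The generator builds a toy genome whose local chromatin compaction ``c`` is
known exactly at every base (``c = 0`` fully open, ``c = 1`` fully compact).
Chromatin fragments sediment into one of five sucrose-gradient fractions
according to their mean compaction; gene expression, nucleosome occupancy and
RNAP binding are simulated with configurable coupling to the landscape.  Every
downstream statistic of the pipeline can therefore be checked against the
planted truth without any external data.

The sedimentation law is ``fraction = 1 + Binomial(4, c_bar)`` where ``c_bar``
is the mean compaction over the fragment.  This maps [0, 1] onto the five
fractions with the correct endpoints (fully open chromatin stays in Fr-1,
fully compact chromatin sediments to Fr-5), has a mean fraction index that is
strictly monotone in compaction, and admits closed-form oracles: the
maximum-likelihood compaction at a position is (mean fraction index - 1)/4.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GeneModel, GenomeAssembly, IntervalSet, tss_position
from .tracks import FRACTIONS, DepthTrack

__all__ = [
    "CapacityError",
    "CompactionLandscape",
    "FragmentSet",
    "BinomialSedimentationModel",
    "gen_genome_and_genes",
    "plant_compaction_landscape",
    "simulate_expression",
    "simulate_fraction_fragments",
    "simulate_mnase_occupancy",
    "simulate_rnap_track",
    "gen_repeats",
    "gen_tads",
    "uniform_depths",
]


class CapacityError(ValueError):
    """Raised when the requested genes cannot be placed on the genome."""


@dataclass
class CompactionLandscape:
    """Planted per-base compaction parameter c in [0, 1].

    ``tss_depths`` records the planted valley depth per gene (the ground
    truth that downstream scoring should recover) and ``tss_centers`` the
    base on which each valley is centred.
    """

    genome: GenomeAssembly
    values: dict[str, np.ndarray] = field(repr=False)
    baseline: float = 0.0
    valley_width: float = 0.0
    tss_depths: dict[str, float] = field(default_factory=dict)
    tss_centers: dict[str, tuple[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom in self.genome:
            v = np.asarray(self.values[chrom], dtype=np.float64)
            if v.shape[0] != self.genome.length(chrom):
                raise ValueError(f"landscape vector length mismatch on {chrom}")
            if (v < 0).any() or (v > 1).any():
                raise ValueError("compaction values must lie in [0, 1]")
            self.values[chrom] = v

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.values[chrom]

    def at(self, chrom: str, pos: int) -> float:
        return float(self.values[chrom][pos])

    def tss_compaction(self, gene: GeneModel) -> float:
        """Planted compaction at the gene's TSS base."""
        return self.at(gene.chrom, tss_position(gene))


@dataclass
class BinomialSedimentationModel:
    """fraction = 1 + Binomial(n_trials, c_bar); n_trials = 4 gives 5 fractions."""

    n_trials: int = 4

    def fraction_probs(self, c_bar: np.ndarray) -> np.ndarray:
        """(len(c_bar), n_trials+1) matrix of fraction probabilities."""
        from scipy.stats import binom

        c = np.atleast_1d(np.asarray(c_bar, dtype=float))
        k = np.arange(self.n_trials + 1)
        return binom.pmf(k[None, :], self.n_trials, c[:, None])

    def sample(self, c_bar: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        return 1 + rng.binomial(self.n_trials, np.asarray(c_bar, dtype=float))

    def expected_fraction(self, c_bar: np.ndarray) -> np.ndarray:
        return 1.0 + self.n_trials * np.asarray(c_bar, dtype=float)


@dataclass
class FragmentSet:
    """Sequenced chromatin fragments, each carrying one fraction label."""

    genome: GenomeAssembly
    frame: pd.DataFrame = field(repr=False)  # columns chrom, start, end, fraction

    def __post_init__(self) -> None:
        need = {"chrom", "start", "end", "fraction"}
        if need - set(self.frame.columns):
            raise ValueError(f"fragment frame must have columns {sorted(need)}")
        f = self.frame
        if len(f):
            if not f["fraction"].isin(FRACTIONS).all():
                raise ValueError("fraction labels must be in 1..5")
            for chrom, sub in f.groupby("chrom"):
                L = self.genome.length(str(chrom))
                bad = (sub["start"] < 0) | (sub["end"] > L) | (sub["start"] >= sub["end"])
                if bad.any():
                    i = sub.index[bad][0]
                    rec = f.loc[i]
                    raise ValueError(
                        f"fragment out of bounds: {rec['chrom']}:{rec['start']}-{rec['end']}"
                    )

    def __len__(self) -> int:
        return len(self.frame)

    def fraction_counts(self) -> pd.Series:
        return self.frame["fraction"].value_counts().reindex(FRACTIONS, fill_value=0)

    def subset(self, fraction: int) -> "FragmentSet":
        if fraction not in FRACTIONS:
            raise ValueError(f"fraction must be in 1..5, got {fraction}")
        return FragmentSet(self.genome, self.frame[self.frame["fraction"] == fraction].reset_index(drop=True))


def _spawn_seed(seed: int, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(salt)]))


def uniform_depths(n: int, low: float, high: float, seed: int) -> np.ndarray:
    """Draw n per-gene valley depths uniformly from [low, high]."""
    rng = _spawn_seed(seed, 101)
    return rng.uniform(low, high, size=n)


def gen_genome_and_genes(
    n_chroms: int,
    chrom_len: int,
    n_genes: int,
    min_spacing: int,
    seed: int,
    gene_len_range: tuple[int, int] = (1000, 3000),
) -> tuple[GenomeAssembly, list[GeneModel]]:
    """Build a toy assembly and place non-overlapping genes on it.

    Genes are distributed across chromosomes proportionally to length; on
    each chromosome, gene lengths are drawn uniformly from ``gene_len_range``
    and the remaining free space is split randomly among the inter-gene gaps,
    every interior gap being at least ``min_spacing``.  Raises
    :class:`CapacityError` when the genes cannot fit.
    """
    if n_chroms < 1 or chrom_len < 1 or n_genes < 0:
        raise ValueError("n_chroms, chrom_len must be positive; n_genes >= 0")
    lo, hi = gene_len_range
    if not (0 < lo <= hi):
        raise ValueError("invalid gene_len_range")
    rng = _spawn_seed(seed, 1)
    genome = GenomeAssembly(
        tuple(f"chr{i + 1}" for i in range(n_chroms)), tuple([chrom_len] * n_chroms)
    )
    # worst-case capacity check up front (pigeonhole on max gene length)
    if n_genes * (hi + min_spacing) > genome.total_length + min_spacing * n_chroms:
        raise CapacityError(
            f"{n_genes} genes of up to {hi} bp with {min_spacing} bp spacing "
            f"do not fit in {genome.total_length} bp"
        )
    per_chrom = [n_genes // n_chroms] * n_chroms
    for i in range(n_genes % n_chroms):
        per_chrom[i] += 1
    genes: list[GeneModel] = []
    gid = 0
    for chrom, k in zip(genome, per_chrom):
        if k == 0:
            continue
        lengths = rng.integers(lo, hi + 1, size=k)
        free = chrom_len - int(lengths.sum()) - (k - 1) * min_spacing
        if free < 0:
            raise CapacityError(f"genes do not fit on {chrom}")
        extra = rng.multinomial(free, np.full(k + 1, 1.0 / (k + 1)))
        strands = rng.choice(["+", "-"], size=k)
        pos = int(extra[0])
        for j in range(k):
            start = pos
            end = start + int(lengths[j])
            genes.append(GeneModel(f"gene{gid:04d}", chrom, str(strands[j]), start, end))
            gid += 1
            pos = end + min_spacing + int(extra[j + 1])
    return genome, genes


def plant_compaction_landscape(
    genome: GenomeAssembly,
    genes: list[GeneModel],
    baseline_c: float,
    tss_valley_depths: float | np.ndarray,
    valley_width: float,
    truncate_sigmas: float = 4.0,
) -> CompactionLandscape:
    """Constant-baseline landscape with Gaussian openness valleys at TSSs.

    ``c(x) = baseline - depth_g * exp(-(x - tss_g)^2 / (2 * width^2))`` near
    each gene's TSS; ``valley_width`` is the Gaussian sigma in bp.  Depths may
    be a scalar or one value per gene and must not exceed the baseline.
    Where valleys of neighbouring genes overlap the deficits add and the
    result is clipped into [0, 1].
    """
    if not 0.0 <= baseline_c <= 1.0:
        raise ValueError("baseline_c must lie in [0, 1]")
    depths = np.broadcast_to(np.asarray(tss_valley_depths, dtype=float), (len(genes),)).copy()
    if (depths < 0).any() or (depths > baseline_c + 1e-12).any():
        raise ValueError("valley depths must lie in [0, baseline_c]")
    if valley_width < 0:
        raise ValueError("valley_width must be >= 0")
    values = {c: np.full(genome.length(c), baseline_c) for c in genome}
    centers: dict[str, tuple[str, int]] = {}
    for gene, depth in zip(genes, depths):
        center = tss_position(gene)
        centers[gene.gene_id] = (gene.chrom, center)
        if depth == 0 or valley_width == 0:
            if depth > 0:
                values[gene.chrom][center] -= depth
            continue
        half = int(np.ceil(truncate_sigmas * valley_width))
        lo = max(0, center - half)
        hi = min(genome.length(gene.chrom), center + half + 1)
        x = np.arange(lo, hi)
        values[gene.chrom][lo:hi] -= depth * np.exp(-0.5 * ((x - center) / valley_width) ** 2)
    for chrom in values:
        np.clip(values[chrom], 0.0, 1.0, out=values[chrom])
    return CompactionLandscape(
        genome,
        values,
        baseline=baseline_c,
        valley_width=valley_width,
        tss_depths={g.gene_id: float(d) for g, d in zip(genes, depths)},
        tss_centers=centers,
    )


def simulate_expression(
    genes: list[GeneModel],
    landscape: CompactionLandscape,
    intercept_a: float,
    slope_b: float,
    noise_sd: float,
    seed: int,
) -> list[GeneModel]:
    """Couple expression negatively to TSS compaction.

    ``log10(TPM + 1) = max(0, a - b * c(TSS) + N(0, noise_sd))``; open TSSs
    (low c) get high expression.  Returns new gene models with tpm set.
    """
    if intercept_a < 0 or slope_b < 0 or noise_sd < 0:
        raise ValueError("intercept_a, slope_b and noise_sd must be >= 0")
    rng = _spawn_seed(seed, 2)
    noise = rng.normal(0.0, noise_sd, size=len(genes)) if noise_sd > 0 else np.zeros(len(genes))
    out = []
    for gene, eps in zip(genes, noise):
        y = max(0.0, intercept_a - slope_b * landscape.tss_compaction(gene) + eps)
        out.append(gene.with_tpm(10.0**y - 1.0))
    return out


def simulate_fraction_fragments(
    genome: GenomeAssembly,
    landscape: CompactionLandscape,
    model: BinomialSedimentationModel,
    n_fragments: int,
    len_min: int,
    len_max: int,
    recovery_bias: dict[int, float] | None = None,
    seed: int = 0,
) -> FragmentSet:
    """Drop fragments uniformly on the genome and sediment them.

    Each fragment gets a uniform start, a uniform length in
    [len_min, len_max], and a fraction label drawn from the sedimentation
    model at its mean landscape compaction.  ``recovery_bias`` optionally
    thins fractions (keep probability per fraction, <= 1), emulating unequal
    DNA recovery from the gradient.
    """
    if not (0 < len_min <= len_max):
        raise ValueError("need 0 < len_min <= len_max")
    if any(len_max > genome.length(c) for c in genome):
        raise ValueError("len_max exceeds a chromosome length")
    if recovery_bias is not None:
        bad = [f for f, p in recovery_bias.items() if f not in FRACTIONS or not 0 < p <= 1]
        if bad:
            raise ValueError(f"recovery_bias must map fractions 1..5 to (0, 1]: {bad}")
    rng = _spawn_seed(seed, 3)
    lens = np.asarray(genome.chrom_lengths, dtype=float)
    chrom_idx = rng.choice(len(lens), size=n_fragments, p=lens / lens.sum())
    frag_len = rng.integers(len_min, len_max + 1, size=n_fragments)
    starts = np.empty(n_fragments, dtype=np.int64)
    cbar = np.empty(n_fragments, dtype=float)
    for ci, chrom in enumerate(genome):
        mask = chrom_idx == ci
        if not mask.any():
            continue
        L = genome.length(chrom)
        s = rng.integers(0, L - frag_len[mask] + 1)
        starts[mask] = s
        cs = np.concatenate(([0.0], np.cumsum(landscape[chrom])))
        e = s + frag_len[mask]
        cbar[mask] = (cs[e] - cs[s]) / frag_len[mask]
    # numerical safety: cumsum differences can drift a hair outside [0, 1]
    np.clip(cbar, 0.0, 1.0, out=cbar)
    fractions = model.sample(cbar, rng)
    frame = pd.DataFrame(
        {
            "chrom": pd.Categorical.from_codes(chrom_idx, categories=list(genome)).astype(str),
            "start": starts,
            "end": starts + frag_len,
            "fraction": fractions.astype(np.int8),
        }
    )
    if recovery_bias:
        keep_p = frame["fraction"].map(lambda f: recovery_bias.get(int(f), 1.0)).to_numpy()
        keep = rng.random(len(frame)) < keep_p
        frame = frame[keep].reset_index(drop=True)
    return FragmentSet(genome, frame)


def _valley_track(
    genome: GenomeAssembly,
    genes: list[GeneModel],
    baseline: float,
    depths: np.ndarray,
    width: float,
    truncate_sigmas: float = 4.0,
) -> dict[str, np.ndarray]:
    values = {c: np.full(genome.length(c), baseline) for c in genome}
    for gene, depth in zip(genes, depths):
        if depth == 0:
            continue
        center = tss_position(gene)
        half = int(np.ceil(truncate_sigmas * max(width, 1.0)))
        lo = max(0, center - half)
        hi = min(genome.length(gene.chrom), center + half + 1)
        x = np.arange(lo, hi)
        if width > 0:
            values[gene.chrom][lo:hi] -= depth * np.exp(-0.5 * ((x - center) / width) ** 2)
        else:
            values[gene.chrom][center] -= depth
    return values


def simulate_mnase_occupancy(
    genome: GenomeAssembly,
    genes: list[GeneModel],
    baseline_occ: float,
    nfr_depths: float | np.ndarray,
    valley_width: float,
    noise_sd: float,
    seed: int = 0,
) -> DepthTrack:
    """Nucleosome occupancy: flat baseline with Gaussian NFR valleys at TSSs.

    ``nfr_depths`` (scalar or per gene) are independent of the compaction
    landscape by construction, so the generator can reproduce either a
    coupled or a null relationship between NFR depth and compaction.  Noise
    is Gaussian, and the track is truncated at zero.
    """
    if baseline_occ < 0 or noise_sd < 0:
        raise ValueError("baseline_occ and noise_sd must be >= 0")
    depths = np.broadcast_to(np.asarray(nfr_depths, dtype=float), (len(genes),)).copy()
    if (depths < 0).any() or (depths > baseline_occ + 1e-12).any():
        raise ValueError("nfr depths must lie in [0, baseline_occ]")
    values = _valley_track(genome, genes, baseline_occ, depths, valley_width)
    if noise_sd > 0:
        rng = _spawn_seed(seed, 4)
        for chrom in values:
            values[chrom] = values[chrom] + rng.normal(0.0, noise_sd, size=values[chrom].shape)
    for chrom in values:
        np.clip(values[chrom], 0.0, None, out=values[chrom])
    return DepthTrack(genome, values)


def simulate_rnap_track(
    genome: GenomeAssembly,
    genes: list[GeneModel],
    landscape: CompactionLandscape,
    peak_scale: float,
    peak_width: float,
    noise_sd: float,
    seed: int = 0,
) -> DepthTrack:
    """RNAP binding signal: Gaussian TSS peaks whose height grows with openness.

    Peak height for gene g is ``peak_scale * (1 - c(TSS_g))``, planting the
    inverse association between compaction and polymerase binding.
    """
    if peak_scale < 0 or noise_sd < 0 or peak_width < 0:
        raise ValueError("peak_scale, peak_width and noise_sd must be >= 0")
    heights = np.array([peak_scale * (1.0 - landscape.tss_compaction(g)) for g in genes])
    values = _valley_track(genome, genes, 0.0, -heights, peak_width)  # negative depth = peak
    if noise_sd > 0:
        rng = _spawn_seed(seed, 5)
        for chrom in values:
            values[chrom] = values[chrom] + rng.normal(0.0, noise_sd, size=values[chrom].shape)
    for chrom in values:
        np.clip(values[chrom], 0.0, None, out=values[chrom])
    return DepthTrack(genome, values)


def gen_repeats(
    genome: GenomeAssembly,
    n_repeats: int,
    len_range: tuple[int, int],
    seed: int,
) -> IntervalSet:
    """Scatter repeat intervals uniformly (they may overlap genes or each other)."""
    lo, hi = len_range
    if not 0 < lo <= hi:
        raise ValueError("invalid repeat length range")
    rng = _spawn_seed(seed, 6)
    lens = np.asarray(genome.chrom_lengths, dtype=float)
    chrom_idx = rng.choice(len(lens), size=n_repeats, p=lens / lens.sum())
    recs = []
    names = list(genome)
    for ci, L in zip(chrom_idx, (genome.length(names[i]) for i in chrom_idx)):
        rl = int(rng.integers(lo, hi + 1))
        rl = min(rl, L)
        s = int(rng.integers(0, L - rl + 1))
        recs.append((names[ci], s, s + rl))
    out = IntervalSet.from_records(recs)
    out.frame.sort_values(["chrom", "start"], inplace=True, ignore_index=True)
    return out


def gen_tads(
    genome: GenomeAssembly,
    size_range: tuple[int, int],
    seed: int,
) -> IntervalSet:
    """Partition each chromosome into contiguous TADs with random sizes."""
    lo, hi = size_range
    if not 0 < lo <= hi:
        raise ValueError("invalid TAD size range")
    rng = _spawn_seed(seed, 7)
    recs = []
    for chrom in genome:
        L = genome.length(chrom)
        pos = 0
        while pos < L:
            size = int(rng.integers(lo, hi + 1))
            end = min(pos + size, L)
            if L - end < lo:  # absorb a too-small remainder into the last TAD
                end = L
            recs.append((chrom, pos, end))
            pos = end
    return IntervalSet.from_records(recs)
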