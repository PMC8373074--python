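"""End-to-end orchestration: simulate -> score -> annotate -> associate.

A single :class:`RunConfig` (constructible from YAML) drives the whole run.
``run_analysis`` performs every stage in memory and returns all intermediate
and final objects; ``run_end_to_end`` additionally writes the declared
output files plus a machine-readable manifest.  The pipeline is a pure
function of (config, seed): identical configs give byte-identical outputs.

The default configuration is the package's demo study: one 1 Mb chromosome
carrying 200 genes, a planted compaction landscape with baseline c = 0.8 and
Gaussian TSS valleys of depth uniform in [0.2, 0.8], a million sequenced
fragments of 300-500 bp, expression coupled negatively to TSS compaction,
and nucleosome occupancy whose NFR depths are drawn independently of the
landscape (so NFR-vs-compaction correlations are null by construction).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from .annotation import (
    RegionWindow,
    _rcpm_table,
    anchor_window,
    filter_repeat_overlap,
    metagene_profiles,
    window_mean,
)
from .association import (
    ExpressionCategoryConfig,
    FitResult,
    QualificationConfig,
    TADSummary,
    categorize_expression_array,
    pearson_fit,
    qualify_genes,
    rnap_association,
    tad_summary,
)
from .genome import GeneModel, GenomeAssembly, IntervalSet
from .nucleosome import nfr_depth_table, tss_occupancy_curve
from .scoring import (
    ClassificationResult,
    CompactionBinConfig,
    NormalizationConfig,
    classify_compaction,
    compaction_score,
    coverage_from_fragments,
    normalize_track,
)
from .simulate import (
    BinomialSedimentationModel,
    CompactionLandscape,
    FragmentSet,
    gen_genome_and_genes,
    gen_repeats,
    gen_tads,
    plant_compaction_landscape,
    simulate_expression,
    simulate_fraction_fragments,
    simulate_mnase_occupancy,
    simulate_rnap_track,
    uniform_depths,
)
from .tracks import FRACTIONS, DepthTrack, ScoreTrack

__all__ = ["RunConfig", "AnalysisResult", "run_analysis", "run_end_to_end"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """All generator and analysis parameters for one reproducible run."""

    seed: int = 1
    # genome and genes
    n_chroms: int = 1
    chrom_len: int = 1_000_000
    n_genes: int = 200
    min_spacing: int = 1000
    gene_len_range: tuple[int, int] = (1000, 3000)
    # planted compaction landscape
    baseline_c: float = 0.8
    valley_depth_range: tuple[float, float] = (0.2, 0.8)
    valley_width: float = 150.0
    # expression coupling: log10(TPM+1) = max(0, a - b*c(TSS) + noise)
    expr_intercept: float = 2.5
    expr_slope: float = 2.5
    expr_noise_sd: float = 0.3
    # sequencing fragments
    n_fragments: int = 1_000_000
    frag_len_range: tuple[int, int] = (300, 500)
    recovery_bias: dict[int, float] | None = None
    # nucleosome occupancy (NFR depths independent of the landscape)
    mnase_baseline: float = 0.8
    nfr_depth_range: tuple[float, float] = (0.0, 0.6)
    mnase_valley_width: float = 150.0
    mnase_noise_sd: float = 0.05
    # RNAP binding (coupled to openness)
    rnap_peak_scale: float = 10.0
    rnap_peak_width: float = 200.0
    rnap_noise_sd: float = 0.2
    # repeats and TADs
    n_repeats: int = 120
    repeat_len_range: tuple[int, int] = (200, 2000)
    tad_size_range: tuple[int, int] = (20_000, 80_000)
    # normalization and scoring
    wigsum: float = 8.5e9
    epsilon: float = 0.001
    recovery_factors: tuple[float, float, float, float, float] = (1.0,) * 5
    bin_edges: tuple[float, float, float, float] = (-4.5, -3.5, -2.5, -1.5)
    compaction_threshold: float = -3.5
    # windows and association
    tss_window_bp: int = 250
    open_threshold: float = -2.5
    boundary_window: int = 2000
    rcpm_min: float = 0.05

    def normalization(self) -> NormalizationConfig:
        return NormalizationConfig(self.wigsum, tuple(self.recovery_factors), self.epsilon)

    def bins(self) -> CompactionBinConfig:
        return CompactionBinConfig(tuple(self.bin_edges))

    def with_seed(self, seed: int) -> "RunConfig":
        return dataclasses.replace(self, seed=int(seed))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key, val in raw.items():
            if isinstance(val, list):
                raw[key] = tuple(val)
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class AnalysisResult:
    """Everything one run computes, in memory."""

    config: RunConfig
    genome: GenomeAssembly
    genes: list[GeneModel]
    landscape: CompactionLandscape
    planted_nfr_depths: np.ndarray
    fragments: FragmentSet
    norm_tracks: dict[int, DepthTrack]
    score: ScoreTrack
    classification: ClassificationResult
    mnase: DepthTrack
    rnap: DepthTrack
    repeats: IntervalSet
    tads: IntervalSet
    tss_windows: list[RegionWindow]
    tes_windows: list[RegionWindow]
    table: pd.DataFrame
    fits: dict[str, FitResult | None]
    metagene: dict[str, "object"]
    occupancy_curves: dict[str, np.ndarray]
    tad_stats: TADSummary

    def qualified(self) -> pd.DataFrame:
        return self.table[self.table["qualified"]]


def _fit_or_none(x, y) -> FitResult | None:
    try:
        return pearson_fit(x, y)
    except ValueError as exc:
        logger.warning("correlation undefined: %s", exc)
        return None


def run_analysis(config: RunConfig) -> AnalysisResult:
    """Run every stage in memory and return the full result bundle."""
    t0 = time.perf_counter()
    seed = config.seed

    # --- simulate ---------------------------------------------------------
    genome, genes = gen_genome_and_genes(
        config.n_chroms, config.chrom_len, config.n_genes,
        config.min_spacing, seed, config.gene_len_range,
    )
    depths = uniform_depths(len(genes), *config.valley_depth_range, seed)
    landscape = plant_compaction_landscape(
        genome, genes, config.baseline_c, depths, config.valley_width
    )
    genes = simulate_expression(
        genes, landscape, config.expr_intercept, config.expr_slope,
        config.expr_noise_sd, seed,
    )
    fragments = simulate_fraction_fragments(
        genome, landscape, BinomialSedimentationModel(), config.n_fragments,
        config.frag_len_range[0], config.frag_len_range[1],
        config.recovery_bias, seed,
    )
    nfr_depths = uniform_depths(len(genes), *config.nfr_depth_range, seed + 7)
    mnase = simulate_mnase_occupancy(
        genome, genes, config.mnase_baseline, nfr_depths,
        config.mnase_valley_width, config.mnase_noise_sd, seed,
    )
    rnap = simulate_rnap_track(
        genome, genes, landscape, config.rnap_peak_scale,
        config.rnap_peak_width, config.rnap_noise_sd, seed,
    )
    repeats = gen_repeats(genome, config.n_repeats, config.repeat_len_range, seed)
    tads = gen_tads(genome, config.tad_size_range, seed)
    logger.info("simulate: %d genes, %d fragments (%.1fs)",
                len(genes), len(fragments), time.perf_counter() - t0)

    # --- score ------------------------------------------------------------
    norm_cfg = config.normalization()
    norm_tracks = {}
    for f in FRACTIONS:
        cov = coverage_from_fragments(fragments, genome, fraction=f)
        norm_tracks[f] = normalize_track(cov, norm_cfg, fraction=f)
    score = compaction_score(norm_tracks[1], norm_tracks[5], norm_cfg.epsilon)
    classification = classify_compaction(score, config.bins(), config.compaction_threshold)

    # --- annotate ---------------------------------------------------------
    tss_windows = [anchor_window(g, "TSS", config.tss_window_bp, genome) for g in genes]
    tes_windows = [anchor_window(g, "TES", config.tss_window_bp, genome) for g in genes]
    tss_clean = {w.gene_id for w in filter_repeat_overlap(tss_windows, repeats)}
    tes_clean = {w.gene_id for w in filter_repeat_overlap(tes_windows, repeats)}
    tss_by_gene = {w.gene_id: w for w in tss_windows}
    tes_by_gene = {w.gene_id: w for w in tes_windows}

    rcpm_tss = _rcpm_table(fragments, tss_windows)
    rcpm_tes = _rcpm_table(fragments, tes_windows)
    nfr = nfr_depth_table(mnase, tss_windows).set_index("gene_id")

    tpm = np.array([g.tpm for g in genes])
    table = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "strand": [g.strand for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "tpm": tpm,
            "log_tpm": np.log10(tpm + 1.0),
            "expr_class": categorize_expression_array(tpm),
            "tss_score": [window_mean(score, tss_by_gene[g.gene_id]) for g in genes],
            "tes_score": [window_mean(score, tes_by_gene[g.gene_id]) for g in genes],
            "rcpm_tss": rcpm_tss.reindex([g.gene_id for g in genes]).to_numpy(),
            "rcpm_tes": rcpm_tes.reindex([g.gene_id for g in genes]).to_numpy(),
            "nfr_depth": nfr["nfr_depth"].reindex([g.gene_id for g in genes]).to_numpy(),
            "rnap_tss_level": [window_mean(rnap, tss_by_gene[g.gene_id]) for g in genes],
            "tss_repeat_free": [g.gene_id in tss_clean for g in genes],
            "tes_repeat_free": [g.gene_id in tes_clean for g in genes],
            "planted_c_tss": [landscape.tss_compaction(g) for g in genes],
            "planted_nfr_depth": nfr_depths,
        }
    )
    qual = qualify_genes(table, QualificationConfig(config.rcpm_min))
    table["qualified"] = table["gene_id"].isin(qual["gene_id"])
    logger.info("annotate: %d/%d genes qualified, %d/%d TSS windows repeat-free",
                int(table["qualified"].sum()), len(table), len(tss_clean), len(genes))

    # --- associate --------------------------------------------------------
    tss_set = table[table["qualified"] & table["tss_repeat_free"]]
    tes_set = table[table["qualified"] & table["tes_repeat_free"]]
    fits: dict[str, FitResult | None] = {
        "planted_recovery": _fit_or_none(tss_set["planted_c_tss"], tss_set["tss_score"]),
        "tss_expression": _fit_or_none(tss_set["tss_score"], tss_set["log_tpm"]),
        "tes_expression": _fit_or_none(tes_set["tes_score"], tes_set["log_tpm"]),
        "nfr_expression": _fit_or_none(tss_set["nfr_depth"], tss_set["log_tpm"]),
        "nfr_score": _fit_or_none(tss_set["nfr_depth"], tss_set["tss_score"]),
    }
    rnap_scores = tss_set.set_index("gene_id")["tss_score"]
    rnap_tbl, rnap_fit = rnap_association(
        rnap, [tss_by_gene[g] for g in rnap_scores.index], rnap_scores
    )
    fits["rnap_score"] = rnap_fit

    genes_by_class: dict[str, list[GeneModel]] = {"Low": [], "Mid": [], "High": []}
    cls_by_gene = dict(zip(table["gene_id"], table["expr_class"]))
    qualified_ids = set(qual["gene_id"])
    for g in genes:
        cls = cls_by_gene.get(g.gene_id)
        if cls in genes_by_class and g.gene_id in qualified_ids:
            genes_by_class[cls].append(g)
    metagene = metagene_profiles(norm_tracks, genes_by_class)
    occupancy_curves = tss_occupancy_curve(mnase, genes_by_class)
    tad_stats = tad_summary(score, tads, config.open_threshold, config.boundary_window)
    logger.info("associate: done (%.1fs total)", time.perf_counter() - t0)

    return AnalysisResult(
        config=config, genome=genome, genes=genes, landscape=landscape,
        planted_nfr_depths=nfr_depths, fragments=fragments,
        norm_tracks=norm_tracks, score=score, classification=classification,
        mnase=mnase, rnap=rnap, repeats=repeats, tads=tads,
        tss_windows=tss_windows, tes_windows=tes_windows, table=table,
        fits=fits, metagene=metagene, occupancy_curves=occupancy_curves,
        tad_stats=tad_stats,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _fits_frame(fits: dict[str, FitResult | None]) -> pd.DataFrame:
    rows = []
    for name, fit in fits.items():
        if fit is None:
            rows.append((name, np.nan, np.nan, np.nan, np.nan, 0))
        else:
            rows.append((name, fit.r, fit.slope, fit.intercept, fit.pvalue, fit.n))
    return pd.DataFrame(rows, columns=["test", "r", "slope", "intercept", "pvalue", "n"])


def run_end_to_end(config: RunConfig, outdir: str | Path) -> Path:
    """Run the pipeline and write all declared outputs plus a manifest.

    Any stage failure aborts with the stage name; files already written are
    retained.  Returns the run directory.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("fracscore")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    declared: dict[str, dict] = {}

    def emit(name: str, fmt: str, writer) -> None:
        path = outdir / name
        writer(path)
        declared[name] = {"format": fmt, "sha256": _sha256(path)}

    stage = "simulate+analyse"
    try:
        res = run_analysis(config)
        stage = "write-outputs"
        emit("chrom.sizes", "chrom-sizes-tsv", lambda p: fio.write_chrom_sizes(res.genome, p))
        emit("genes.tsv", "gene-tsv", lambda p: fio.write_genes_tsv(res.genes, p))
        for f in FRACTIONS:
            emit(f"fr{f}.bed", "bed3",
                 lambda p, f=f: fio.write_fragments_bed(res.fragments, p, fraction=f))
        emit("landscape.bedgraph", "bedgraph",
             lambda p: fio.write_bedgraph(DepthTrack(res.genome, dict(res.landscape.values)), p))
        emit("mnase.bedgraph", "bedgraph", lambda p: fio.write_bedgraph(res.mnase, p))
        emit("rnap.bedgraph", "bedgraph", lambda p: fio.write_bedgraph(res.rnap, p))
        emit("score.bedgraph", "bedgraph", lambda p: fio.write_bedgraph(res.score, p))
        emit("repeats.bed", "bed3", lambda p: fio.write_bed(res.repeats, p))
        emit("tads.bed", "bed3", lambda p: fio.write_bed(res.tads, p))
        emit("class_percentages.tsv", "tsv",
             lambda p: res.classification.as_frame().to_csv(p, sep="\t", index=False))
        emit("gene_association.tsv", "tsv",
             lambda p: res.table.to_csv(p, sep="\t", index=False))
        emit("nfr.tsv", "tsv",
             lambda p: nfr_depth_table(res.mnase, res.tss_windows).to_csv(p, sep="\t", index=False))
        for cls, prof in res.metagene.items():
            emit(f"metagene_{cls}.tsv", "tsv",
                 lambda p, prof=prof: prof.as_frame().to_csv(p, sep="\t"))
        emit("tad_summary.tsv", "tsv",
             lambda p: res.tad_stats.tad_table.to_csv(p, sep="\t", index=False))
        emit("tad_boundaries.tsv", "tsv",
             lambda p: res.tad_stats.boundary_table.to_csv(p, sep="\t", index=False))
        emit("correlations.tsv", "tsv",
             lambda p: _fits_frame(res.fits).to_csv(p, sep="\t", index=False))
        stage = "manifest"
        from . import __version__

        manifest = {
            "package": "fracscore",
            "version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "outputs": declared,
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
    return outdir
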