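import numpy as np
import pytest

from fracscore import DepthTrack, GenomeAssembly, RunConfig, run_analysis


@pytest.fixture(scope="session")
def demo():
    """The default demo study: 1 Mb, 200 genes, 1e6 fragments, seed 1."""
    return run_analysis(RunConfig(seed=1))


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down configuration for fast pipeline tests."""
    return RunConfig(
        seed=11,
        chrom_len=200_000,
        n_genes=40,
        n_fragments=50_000,
        n_repeats=30,
        tad_size_range=(10_000, 30_000),
    )


@pytest.fixture
def tiny_genome():
    return GenomeAssembly(("chrT",), (5,))


def make_track(genome, values_by_chrom):
    return DepthTrack(genome, {c: np.asarray(v, dtype=float) for c, v in values_by_chrom.items()})
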