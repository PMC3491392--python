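import numpy as np
import pytest

from chromclass.genome import BinGrid, GenomeSpec, Interval
from chromclass.pipeline import PipelineConfig, stage_bar_bir, stage_cooccurrence, \
    stage_hot_lot, stage_prm_drm
from chromclass.synth import SynthConfig, generate_dataset


@pytest.fixture
def tiny_grid() -> BinGrid:
    return BinGrid(GenomeSpec(("chr1", "chr2"), (1000, 550)), width=100)


@pytest.fixture(scope="session")
def small_dataset():
    """A 1.2 Mbp, 3-cell-line dataset for fast module-level tests."""
    cfg = SynthConfig(
        seed=11, n_chroms=1, chrom_length=1_200_000, n_cell_lines=3, n_trfs=8,
        n_active_loci=50, n_distal_loci=12, n_hot_loci=8, n_repeats=8,
        block_sizes=(3,), n_private_loci=20, n_couplings=5,
    )
    return generate_dataset(cfg)


# ---------------------------------------------------------------------------
# Default-scale fixtures shared by the acceptance tests (computed once)

DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def default_dataset():
    """The default study conditions: 5 cell lines, 10 Mbp, 20 TRFs."""
    return generate_dataset(SynthConfig(seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def default_config():
    return PipelineConfig(seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def bar_prm_results(default_dataset, default_config):
    """BAR/BIR and PRM/DRM stage results for every cell line."""
    out = {}
    for cl in default_dataset.cell_lines:
        bb = stage_bar_bir(default_dataset, default_config, cl)
        pp = stage_prm_drm(default_dataset, default_config, cl, bb["bars"])
        out[cl] = {"bar": bb, "prm": pp}
    return out


@pytest.fixture(scope="session")
def hot_results(default_dataset, default_config):
    """Co-occurrence matrices and HOT/LOT calls for every cell line."""
    out = {}
    for cl in default_dataset.cell_lines:
        Z = stage_cooccurrence(default_dataset, default_config, cl)
        hl = stage_hot_lot(default_dataset, default_config, cl, Z)
        out[cl] = {"coocc": Z, **hl}
    return out
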