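import numpy as np
import pytest

from neuromorph.synthdata import default_study_config, generate_study


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    """A small but complete two-genotype study on disk (2 WT + 5 HET)."""
    cfg = default_study_config(seed=7)
    cfg.lattice.n_cells = 60
    path = tmp_path_factory.mktemp("study") / "s7"
    generate_study(cfg, path)
    return path, cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
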