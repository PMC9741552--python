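import numpy as np
import pytest

from uhpscan.alignment import load_mclachlan
from uhpscan.annotation import parse_annotation
from uhpscan.events import detect_events
from uhpscan.simulate import SimulationConfig, simulate_annotation


@pytest.fixture(scope="session")
def mclachlan():
    return load_mclachlan()


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A small simulated study parsed and detected once per session."""
    cfg = SimulationConfig(seed=11, n_genes=30, frac_with_event=0.5, n_decoys_per_class=3)
    out = tmp_path_factory.mktemp("smallsim")
    gtf, fasta, truth = simulate_annotation(cfg, out)
    genes = parse_annotation(gtf, fasta)
    events = detect_events(genes, seed=cfg.seed)
    return {"cfg": cfg, "truth": truth, "genes": genes, "events": events, "dir": out}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
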