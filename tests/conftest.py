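import numpy as np
import pytest

from ssrpop import simulate
from ssrpop.io import SSRPanel


def make_random_panel(rng: np.random.Generator, n: int = 8, n_markers: int = 4,
                      missing_rate: float = 0.1) -> SSRPanel:
    """Small random band panel with 2-3 allele-loci per marker."""
    loci = []
    for m in range(n_markers):
        k = int(rng.integers(2, 4))
        loci += [f"MK{m + 1:02d}_{100 + 20 * a}" for a in range(k)]
    calls = rng.integers(0, 2, size=(n, len(loci))).astype(float)
    if missing_rate > 0:
        calls[rng.random(calls.shape) < missing_rate] = np.nan
    return SSRPanel([f"acc{i + 1}" for i in range(n)], loci, calls)


@pytest.fixture(scope="session")
def structured_sim():
    """Moderate planted-K=3 panel with phenotypes, shared across tests."""
    cfg = simulate.SimConfig(
        n_accessions=150, n_markers=60, K_true=3, alpha=0.05, F_st_target=0.25,
        seed=42, qtl_spec=[simulate.QTL("M005_150", "FS", 1.2)],
    )
    panel, gmap, labels, pheno, truth = simulate.simulate_dataset(cfg)
    return {"cfg": cfg, "panel": panel, "map": gmap, "labels": labels,
            "pheno": pheno, "truth": truth}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
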