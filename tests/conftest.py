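import numpy as np
import pytest

from nichephylo.core_io import SequenceRecord
from nichephylo.synthetic_data import (
    SimulationConfig,
    evolve_sequences,
    simulate_abundances,
    simulate_env_factors,
    simulate_study,
    simulate_tree_pair,
)


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic dual-marker study shared across tests."""
    cfg = SimulationConfig(n_taxa=16, n_soils=30, depth=5000,
                           seq_length=250, seed=11)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def tree16():
    tree, _, _ = simulate_tree_pair(16, 0, seed=1)
    return tree


@pytest.fixture(scope="session")
def amoa_toolkit():
    """Tree + aligned sequences + env + niche abundances for one marker."""
    tree, _, _ = simulate_tree_pair(16, 0, seed=3)
    seqs = {r.id: r.residues
            for r in evolve_sequences(tree, 250, 0.06, seed=3, marker="amoA")}
    env = simulate_env_factors(30, seed=3)
    counts, optima = simulate_abundances(tree, env, 0.8, 0.5, 10_000, seed=3)
    records = [
        SequenceRecord(id=f"{t}.{s}", marker="amoA", residues=seqs[t],
                       sample_id=str(s), count=int(c))
        for s in counts.index for t, c in counts.loc[s].items() if c > 0]
    return {"tree": tree, "seqs": seqs, "env": env, "counts": counts,
            "optima": optima, "records": records}


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])
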