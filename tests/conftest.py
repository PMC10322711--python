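import numpy as np
import pytest

from trarep import (
    Molecule,
    Repertoire,
    SimConfig,
    generate_germline,
    simulate_recombination,
)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(n_v=10, n_j=8, n_cells=3000, clone_alpha=8.0, seed=42)


@pytest.fixture(scope="session")
def small_locus(small_config):
    return generate_germline(small_config)


@pytest.fixture(scope="session")
def small_assemblies(small_locus, small_config):
    return simulate_recombination(small_locus, small_config)


@pytest.fixture(scope="session")
def lookups(small_locus):
    v = {s.id: s.v_terminus for s in small_locus.v_segments}
    j = {s.id: s.j_cdr3_part for s in small_locus.j_segments}
    return v, j


def repertoire_from_assemblies(assemblies, individual_id="ind1",
                               seed=0) -> Repertoire:
    """Molecules straight from ground truth (bypasses read simulation)."""
    rng = np.random.default_rng(seed)
    mols = []
    for ai, asm in enumerate(assemblies):
        for k in range(asm.clone_size):
            umi = "".join("ACGT"[c] for c in rng.integers(0, 4, size=12))
            mols.append(Molecule(umi=umi, v_id=asm.v_id, j_id=asm.j_id,
                                 cdr3=asm.cdr3, reads=1))
    return Repertoire(individual_id=individual_id, molecules=mols)
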