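import numpy as np
import pytest

import mitocub as mc


@pytest.fixture(scope="session")
def genome_and_truth():
    """One default synthetic mitogenome with its planted truth bundle."""
    config = mc.GeneratorConfig(seed=11)
    return mc.generate_mitogenome(config)


@pytest.fixture(scope="session")
def small_cohort():
    """Four synthetic genomes for cohort-level statistics."""
    config = mc.GeneratorConfig(seed=7, n_taxa=4)
    return mc.generate_cohort(config)


@pytest.fixture(scope="session")
def f3x4_freqs():
    """Sense-codon frequencies with exact F3X4 product structure, so the
    simulator and the F3X4 fit share a frequency model."""
    pos = np.array([
        [0.30, 0.31, 0.15, 0.24],
        [0.28, 0.30, 0.16, 0.26],
        [0.35, 0.30, 0.10, 0.25],
    ])
    idx = {b: i for i, b in enumerate("ACGT")}
    code = mc.VERTEBRATE_MITO
    f = np.array([
        pos[0, idx[c[0]]] * pos[1, idx[c[1]]] * pos[2, idx[c[2]]]
        for c in code.sense_codons
    ])
    return f / f.sum()
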