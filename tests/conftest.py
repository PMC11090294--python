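import numpy as np
import pytest

from ailqtl.io import GenotypeMatrix, SampleRecord
from ailqtl.sim import SimConfig, TraitArchitecture, simulate


def make_genotypes(calls, phase=None, prefix="s", marker_prefix="m"):
    """GenotypeMatrix from a raw array, with generated ids."""
    calls = np.asarray(calls)
    n, m = calls.shape
    return GenotypeMatrix(
        [f"{prefix}{i}" for i in range(n)],
        [f"{marker_prefix}{j}" for j in range(m)],
        calls,
        phase,
    )


def make_samples(n, sexes=None, generations=None, bw8=None, prefix="s"):
    sexes = sexes if sexes is not None else ["F"] * n
    generations = generations if generations is not None else [2] * n
    bw8 = bw8 if bw8 is not None else [None] * n
    return [
        SampleRecord(f"{prefix}{i}", sexes[i], int(generations[i]), bw8=bw8[i])
        for i in range(n)
    ]


@pytest.fixture(scope="session")
def small_sim():
    """A small but non-trivial AIL: 60 markers, ~400 intercross birds."""
    cfg = SimConfig(
        seed=11,
        n_markers=60,
        n_per_generation={g: 80 for g in range(2, 7)},
        n_f1=60,
        architecture=TraitArchitecture(
            generation_effects={g: -2.0 * (g - 2) for g in range(2, 7)}
        ),
    )
    return simulate(cfg)


@pytest.fixture
def phenotyped(small_sim):
    """(samples, y_norm, genotypes) restricted to phenotyped individuals."""
    from ailqtl.gwas import normalize_by_group

    ph = [s for s in small_sim.samples if s.bw8 is not None]
    y = normalize_by_group(ph)
    g = small_sim.genotypes.subset_samples([s.sample_id for s in ph])
    return ph, y, g
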