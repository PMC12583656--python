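import pytest

from metabolon.matrix import symmetrize
from metabolon.synth import (MatrixGeneratorSpec, PlantedSurface,
                             StructureGeneratorSpec, default_cluster_spec,
                             synth_mfi, synth_structure)


@pytest.fixture(scope="session")
def planted_spec():
    return default_cluster_spec(seed=11)


@pytest.fixture(scope="session")
def planted_matrix(planted_spec):
    """Symmetric 35x35 MFI matrix with a planted 5-protein cluster."""
    return symmetrize(synth_mfi(planted_spec), min_cells=planted_spec.min_cells)


@pytest.fixture(scope="session")
def clusterless_matrix():
    spec = MatrixGeneratorSpec(seed=23)
    return symmetrize(synth_mfi(spec), min_cells=spec.min_cells)


@pytest.fixture(scope="session")
def overlapping_surfaces():
    """Chain with four fully shared planted surfaces."""
    spec = StructureGeneratorSpec(
        chain_length=60, seed=7,
        surfaces=tuple(PlantedSurface(center=30, radius=10.0,
                                      shared_fraction=1.0 if k else 0.0)
                       for k in range(4)))
    return synth_structure(spec)
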