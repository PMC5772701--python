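import numpy as np
import pytest

from smkbnct.geometry import CellLattice
from smkbnct.microdose import DomainSpec, domain_pd_from_tracks
from smkbnct.survival import SMKParams
from smkbnct.transport import compute_dose_coefficients


@pytest.fixture(scope="session")
def lattice():
    return CellLattice()


@pytest.fixture(scope="session")
def params():
    return SMKParams.reference()


@pytest.fixture(scope="session")
def offset_sim(lattice):
    """Boron-component coefficients + per-compartment results, offset nuclei."""
    return compute_dose_coefficients(lattice, n_histories=100_000,
                                     seed=20250930, collect_segments=True)


@pytest.fixture(scope="session")
def concentric_sim():
    lat = CellLattice(nucleus_offset=0.0)
    return lat, compute_dose_coefficients(lat, n_histories=100_000,
                                          seed=20250931)


@pytest.fixture(scope="session")
def boron_pds(offset_sim):
    """Per-compartment nucleus and domain (r_d = 0.24 um) PDs."""
    _, res = offset_sim
    comps = ("nucleus", "cytoplasm", "surface", "extracellular")
    nuc = {k: res[k].pd for k in comps}
    dom = {k: domain_pd_from_tracks(res[k].segments, DomainSpec(0.24),
                                    n_samples=150_000, rng=101 + i)
           for i, k in enumerate(comps)}
    return nuc, dom
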