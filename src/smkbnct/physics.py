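"""Stopping power, CSDA range and along-track energy loss in unit-density water.

Charged-particle transport in the cellular lattice runs in the continuous
slowing-down approximation (CSDA): a particle travels on a straight line and
its residual energy after a path s is obtained from the inverse of the
range-energy relation, E' = R^-1(R(E) - s).  Both R and its inverse are
piecewise log-log linear interpolants of the bundled tables, so range
additivity E'(s1 + s2) = E'(E'(s1), s2) holds to interpolation round-off.

Species covered: the boron-capture fragments (alpha, 7Li), protons and 14C
recoils from 14N(n,p), and a crude electron option for the photon component.
Stopping data are bundled TSV tables for water at 1 g/cm^3 (see
scripts/make_stopping_tables.py for their provenance).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np

__all__ = [
    "ParticleSpecies",
    "StoppingTable",
    "SPECIES",
    "get_table",
    "stopping_power",
    "csda_range",
    "energy_of_range",
    "energy_after_path",
    "deposit_on_segment",
]


@dataclass(frozen=True)
class ParticleSpecies:
    """A charged-particle species transported by the lattice simulator."""

    name: str
    mass_amu: float
    charge: int

    def __post_init__(self) -> None:
        if self.mass_amu <= 0 or self.charge <= 0:
            raise ValueError("mass and charge must be strictly positive")


#: The complete species inventory: boron-capture fragments, nitrogen-capture
#: fragments, recoil protons, and electrons for the photon component.
SPECIES: dict[str, ParticleSpecies] = {
    "proton": ParticleSpecies("proton", 1.007276, 1),
    "alpha": ParticleSpecies("alpha", 4.001506, 2),
    "li7": ParticleSpecies("li7", 7.016004, 3),
    "carbon": ParticleSpecies("carbon", 14.003242, 6),
    "electron": ParticleSpecies("electron", 5.48580e-4, 1),
}


class StoppingTable:
    """Tabulated LET and CSDA range for one species, with log-log interpolation.

    The range interpolant is extended below the table floor with the power law
    matching the first tabulated segment (so R(E) -> 0 as E -> 0) and above the
    ceiling with the last segment's slope; the inverse uses the same nodes, so
    the pair is exactly self-consistent.
    """

    def __init__(self, species: ParticleSpecies, energy_grid: np.ndarray,
                 let_values: np.ndarray, range_um: np.ndarray):
        energy_grid = np.asarray(energy_grid, float)
        let_values = np.asarray(let_values, float)
        range_um = np.asarray(range_um, float)
        if np.any(np.diff(energy_grid) <= 0) or np.any(energy_grid <= 0):
            raise ValueError("energy grid must be strictly increasing and > 0")
        if np.any(let_values <= 0):
            raise ValueError("LET must be positive everywhere")
        if np.any(np.diff(range_um) <= 0):
            raise ValueError("csda range must be strictly increasing")
        self.species = species
        self.energy_grid = energy_grid
        self.let_values = let_values
        self.range_um = range_um
        self._log_e = np.log(energy_grid)
        self._log_let = np.log(let_values)
        # extend the (logE, logR) nodes one decade past both ends
        log_r = np.log(range_um)
        q_lo = (log_r[1] - log_r[0]) / (self._log_e[1] - self._log_e[0])
        q_hi = (log_r[-1] - log_r[-2]) / (self._log_e[-1] - self._log_e[-2])
        self._rx = np.concatenate([
            [self._log_e[0] - 30.0], self._log_e, [self._log_e[-1] + 10.0]])
        self._ry = np.concatenate([
            [log_r[0] - 30.0 * q_lo], log_r, [log_r[-1] + 10.0 * q_hi]])

    def let(self, energy_mev):
        """LET in keV/um; clamped to the lowest tabulated value below the floor."""
        e = np.asarray(energy_mev, float)
        if np.any(e <= 0):
            raise ValueError("energy must be positive")
        return np.exp(np.interp(np.log(e), self._log_e, self._log_let))

    def range_of_energy(self, energy_mev):
        """CSDA range in um; range(0) = 0."""
        e = np.asarray(energy_mev, float)
        if np.any(e < 0):
            raise ValueError("energy must be non-negative")
        out = np.zeros_like(e, dtype=float)
        pos = e > 0
        out[pos] = np.exp(np.interp(np.log(e[pos]), self._rx, self._ry))
        return out if out.ndim else float(out)

    def energy_of_range(self, range_um):
        """Inverse range-energy relation; 0 for non-positive residual range."""
        r = np.asarray(range_um, float)
        out = np.zeros_like(r, dtype=float)
        pos = r > 0
        out[pos] = np.exp(np.interp(np.log(r[pos]), self._ry, self._rx))
        return out if out.ndim else float(out)


def _resolve(species) -> ParticleSpecies:
    if isinstance(species, ParticleSpecies):
        return species
    try:
        return SPECIES[species]
    except KeyError:
        raise ValueError(f"unknown species {species!r}; "
                         f"expected one of {sorted(SPECIES)}") from None


@lru_cache(maxsize=None)
def _load_table(name: str) -> StoppingTable:
    ref = resources.files("smkbnct.data") / f"stopping_{name}.tsv"
    with ref.open() as fh:
        rows = [ln.split() for ln in fh
                if not ln.startswith("#") and not ln.startswith("energy")]
    data = np.array(rows, dtype=float)
    return StoppingTable(SPECIES[name], data[:, 0], data[:, 1], data[:, 2])


def get_table(species) -> StoppingTable:
    return _load_table(_resolve(species).name)


def stopping_power(species, energy_mev):
    """LET of *species* at *energy_mev*, keV/um in unit-density water."""
    return get_table(species).let(energy_mev)


def csda_range(species, energy_mev):
    """CSDA range in um; monotone in energy with csda_range(·, 0) = 0."""
    return get_table(species).range_of_energy(energy_mev)


def energy_of_range(species, range_um):
    return get_table(species).energy_of_range(range_um)


def energy_after_path(species, energy_mev, path_um):
    """Residual energy after travelling *path_um*; 0 once the range is spent."""
    path = np.asarray(path_um, float)
    if np.any(path < 0):
        raise ValueError("path must be non-negative")
    tab = get_table(species)
    return tab.energy_of_range(tab.range_of_energy(energy_mev) - path)


def deposit_on_segment(species, energy_mev, seg_length_um):
    """Energy deposited over a straight segment; never exceeds energy_in."""
    e_in = np.asarray(energy_mev, float)
    seg = np.asarray(seg_length_um, float)
    dep = np.clip(e_in - energy_after_path(species, energy_mev, seg), 0.0, None)
    out = np.where(seg == 0, 0.0, dep)
    return out if out.ndim else float(out)
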