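"""Monte Carlo transport of capture-reaction fragments through the cell lattice.

A history is one neutron-capture event: the emitted charged particles start at
a sampled source position (back-to-back with isotropic orientation for the
two-body 10B(n,a)7Li and 14N(n,p)14C reactions, or a single particle drawn
from a charged-particle spectrum file for the hydrogen/photon components) and
travel on straight CSDA tracks.  The energy each track deposits inside every
cell nucleus of the 11^3 lattice is scored per history, giving

* the single-event nucleus PD f_n,1(z_n)  (an event is a history depositing
  nonzero energy in a given nucleus),
* the mean nucleus-summed specific energy per history m_x for sources in each
  compartment x, from which the kerma-to-nucleus-dose conversion factor

      kappa_B = (N_n m_n + N_c m_c + N_s m_s + N_e m_e) / m_uniform

  follows for a compound with relative 10B numbers N_x, and
* optionally the track segments inside nuclei, the input for the domain PDs.

Sources are confined to the central lattice cell; all 1331 nuclei are scored.
By lattice symmetry this equals scoring one nucleus with sources everywhere,
and edge effects are negligible because fragment ranges are well below five
lattice pitches.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from types import SimpleNamespace

import numpy as np

from . import physics
from .geometry import CellLattice, intracellular_volume_fraction, sample_source_position
from .microdose import SpecificEnergyPD, TrackSegments, default_z_bins

__all__ = [
    "EmissionChannel",
    "boron_channels",
    "nitrogen_channel",
    "CompartmentWeights",
    "boron_weights",
    "SpectrumSource",
    "TransportResult",
    "simulate_component_pd",
    "NucleusDoseCoefficients",
    "compute_dose_coefficients",
    "kappa_B",
    "kappa_total",
]

MEV_TO_J = 1.602176634e-13


@dataclass(frozen=True)
class EmissionChannel:
    """One decay branch: fragments emitted back-to-back, isotropically."""

    branch_probability: float
    fragments: tuple  # ((species_name, energy_MeV), ...)

    def __post_init__(self) -> None:
        if not 0 < self.branch_probability <= 1:
            raise ValueError("branch probability must be in (0, 1]")
        if len(self.fragments) == 2:
            (s1, e1), (s2, e2) = self.fragments
            p1 = e1 * physics.SPECIES[s1].mass_amu
            p2 = e2 * physics.SPECIES[s2].mass_amu
            if abs(p1 - p2) / max(p1, p2) > 0.01:
                raise ValueError("fragment energies violate two-body momentum "
                                 f"balance: {p1:.4f} vs {p2:.4f}")


def boron_channels() -> list[EmissionChannel]:
    """The two 10B(n,a)7Li branches.

    93.7% of captures feed the 7Li first excited state (Q = 2.31 MeV,
    alpha 1.47 MeV + 7Li 0.84 MeV); 6.3% go to the ground state
    (alpha 1.78 MeV + 7Li 1.01 MeV).  The 0.478 MeV de-excitation photon is
    not emitted here -- its dose belongs to the photon component.  Fragment
    energies are the exact two-body momentum split (they round to the
    customary printed values).
    """
    return [
        EmissionChannel(0.937, (("alpha", 1.4723), ("li7", 0.8397))),
        EmissionChannel(0.063, (("alpha", 1.7766), ("li7", 1.0132))),
    ]


def nitrogen_channel() -> list[EmissionChannel]:
    """14N(n,p)14C: Q = 0.626 MeV split as p 0.584 + 14C 0.042 MeV."""
    return [EmissionChannel(1.0, (("proton", 0.5840), ("carbon", 0.0420)))]


@dataclass(frozen=True)
class CompartmentWeights:
    """Relative 10B numbers per compartment, normalized to one."""

    n: float = 0.0
    c: float = 0.0
    s: float = 0.0
    e: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.n, self.c, self.s, self.e)
        if any(v < 0 for v in vals):
            raise ValueError("compartment weights must be non-negative")
        if abs(sum(vals) - 1.0) > 1e-6:
            raise ValueError("compartment weights must sum to 1")

    def scaled(self, x: float) -> SimpleNamespace:
        """Intracellular weights multiplied by a concentration factor x
        (deliberately left unnormalized)."""
        return SimpleNamespace(n=x * self.n, c=x * self.c, s=x * self.s, e=self.e)

    def as_dict(self) -> dict:
        return {"nucleus": self.n, "cytoplasm": self.c,
                "surface": self.s, "extracellular": self.e}


#: measured intra/extracellular 10B concentration ratios for malignant cells
INTRA_EXTRA_RATIO = {"BPA": 3.2, "BSH": 0.86}


def boron_weights(compound: str, intra_extra_ratio: float | None = None,
                  lattice: CellLattice | None = None) -> CompartmentWeights:
    """Compartment weights for a named compound.

    BPA permeates the cell membrane (cytoplasmic), BSH binds to the surface;
    the intracellular share follows from the concentration ratio R and the
    lattice's intracellular volume fraction v as R v / (R v + 1 - v).  The
    "ideal" compound is homogeneously distributed, i.e. volume-proportional.
    """
    lattice = lattice or CellLattice()
    v = intracellular_volume_fraction(lattice)
    if compound in ("BPA", "BSH"):
        ratio = intra_extra_ratio if intra_extra_ratio is not None \
            else INTRA_EXTRA_RATIO[compound]
        if ratio <= 0:
            raise ValueError("intra/extracellular concentration ratio must be > 0")
        intra = ratio * v / (ratio * v + (1.0 - v))
        if compound == "BPA":
            return CompartmentWeights(c=intra, e=1.0 - intra)
        return CompartmentWeights(s=intra, e=1.0 - intra)
    if compound == "ideal":
        v_n = (4.0 / 3.0) * np.pi * lattice.nucleus_radius**3 / lattice.pitch**3
        return CompartmentWeights(n=v_n, c=v - v_n, e=1.0 - v)
    raise ValueError(f"unknown compound {compound!r}; use BPA, BSH or ideal "
                     "(or construct CompartmentWeights directly)")


@dataclass
class SpectrumSource:
    """Discrete charged-particle source spectrum (species, energy, weight)."""

    species: list
    energy_mev: np.ndarray
    weight: np.ndarray

    def __post_init__(self) -> None:
        self.energy_mev = np.asarray(self.energy_mev, float)
        self.weight = np.asarray(self.weight, float)
        if np.any(self.energy_mev <= 0) or np.any(self.weight < 0) \
                or self.weight.sum() <= 0:
            raise ValueError("spectrum needs positive energies and weights")
        for s in self.species:
            physics.SPECIES[s]  # noqa: B018 -- validate names

    @property
    def probabilities(self) -> np.ndarray:
        return self.weight / self.weight.sum()


@dataclass
class TransportResult:
    """Output of one component simulation."""

    pd: SpecificEnergyPD
    m_coeff: float          # mean nucleus-summed specific energy per history, Gy
    m_err: float
    n_histories: int
    n_events: int
    max_zn: float
    segments: TrackSegments | None = None


def _candidate_cells(lattice: CellLattice, reach_um: float) -> np.ndarray:
    """Cell indices whose nucleus can be reached from the central cube."""
    margin = lattice.nucleus_radius + lattice.nucleus_offset
    half = lattice.pitch / 2.0
    m = min(int(np.ceil((reach_um + margin + half) / lattice.pitch)),
            lattice.half_index)
    out = []
    for ijk in itertools.product(range(-m, m + 1), repeat=3):
        d_axis = np.maximum(np.abs(np.array(ijk)) * lattice.pitch - half, 0.0)
        if np.linalg.norm(d_axis) <= reach_um + margin:
            out.append(ijk)
    return np.array(out, int)


def _isotropic(rng: np.random.Generator, n: int) -> np.ndarray:
    u = rng.normal(size=(n, 3))
    return u / np.linalg.norm(u, axis=1, keepdims=True)


class _Scorer:
    """Accumulates per-(history, nucleus) deposits for one chunk."""

    def __init__(self, lattice: CellLattice, n: int, species_names: tuple,
                 collect_segments: bool):
        self.lattice = lattice
        self.n = n
        self.species_names = species_names
        self.collect = collect_segments
        self.dep = {}          # cell key -> (n,) deposit MeV
        self.segs = []         # (code, e_mid, length) arrays

    def add_group(self, rows: np.ndarray, pos: np.ndarray, dirs: np.ndarray,
                  species: str, e0: float) -> None:
        """Score one mono-energetic fragment group (histories *rows*)."""
        tab = physics.get_table(species)
        r0 = float(tab.range_of_energy(e0))
        code = self.species_names.index(species)
        r_n = self.lattice.nucleus_radius
        for ijk in _candidate_cells(self.lattice, r0):
            center = self.lattice.nucleus_center(ijk)
            b = center - pos
            proj = np.einsum("ij,ij->i", b, dirs)
            d2 = np.einsum("ij,ij->i", b, b) - proj**2
            hit = d2 < r_n**2
            if not np.any(hit):
                continue
            half = np.sqrt(r_n**2 - d2[hit])
            t1 = np.clip(proj[hit] - half, 0.0, r0)
            t2 = np.clip(proj[hit] + half, 0.0, r0)
            ok = t2 > t1
            if not np.any(ok):
                continue
            t1, t2 = t1[ok], t2[ok]
            sub = rows[hit][ok]
            e_in = tab.energy_of_range(r0 - t1)
            e_out = tab.energy_of_range(r0 - t2)
            dep = e_in - e_out
            key = tuple(ijk)
            if key not in self.dep:
                self.dep[key] = np.zeros(self.n)
            np.add.at(self.dep[key], sub, dep)
            if self.collect:
                e_mid = tab.energy_of_range(r0 - 0.5 * (t1 + t2))
                self.segs.append((np.full(len(t1), code, dtype=np.int8),
                                  e_mid, t2 - t1))


def simulate_component_pd(lattice: CellLattice, source, n_histories: int,
                          seed=None, *, channels=None,
                          spectrum: SpectrumSource | None = None,
                          bins=None, collect_segments: bool = False,
                          chunk_size: int = 200_000) -> TransportResult:
    """Simulate one dose component and score the nucleus specific-energy PD.

    *source* is a compartment name ('nucleus', 'cytoplasm', 'surface',
    'extracellular', 'uniform') or a :class:`CompartmentWeights` (sources are
    then sampled from the compartments in proportion to the weights).
    Exactly one of *channels* (capture-reaction branches, sources per
    *source*) or *spectrum* (single particles, customarily with
    source='uniform') must be given.
    """
    if (channels is None) == (spectrum is None):
        raise ValueError("give exactly one of channels= or spectrum=")
    if n_histories < 1:
        raise ValueError("n_histories must be >= 1")
    rng = np.random.default_rng(seed)
    bins = default_z_bins() if bins is None else np.asarray(bins, float)
    mass_kg = lattice.nucleus_mass_kg
    to_gray = MEV_TO_J / mass_kg

    counts = np.zeros(len(bins) - 1, dtype=np.int64)
    n_events = 0
    max_zn = 0.0
    sum_m = 0.0
    sum_m2 = 0.0
    seg_parts = []
    species_names = tuple(sorted(physics.SPECIES))

    done = 0
    while done < n_histories:
        n = min(chunk_size, n_histories - done)
        pos = _sample_positions(lattice, source, rng, n)
        dirs = _isotropic(rng, n)
        scorer = _Scorer(lattice, n, species_names, collect_segments)
        if channels is not None:
            probs = np.array([ch.branch_probability for ch in channels])
            if abs(probs.sum() - 1.0) > 1e-9:
                raise ValueError("branch probabilities must sum to 1")
            which = rng.choice(len(channels), size=n, p=probs)
            for ci, ch in enumerate(channels):
                rows = np.flatnonzero(which == ci)
                if len(rows) == 0:
                    continue
                for frag_i, (sp, e0) in enumerate(ch.fragments):
                    sign = 1.0 if frag_i == 0 else -1.0
                    scorer.add_group(rows, pos[rows], sign * dirs[rows], sp, e0)
        else:
            which = rng.choice(len(spectrum.energy_mev), size=n,
                               p=spectrum.probabilities)
            for gi in range(len(spectrum.energy_mev)):
                rows = np.flatnonzero(which == gi)
                if len(rows) == 0:
                    continue
                scorer.add_group(rows, pos[rows], dirs[rows],
                                 spectrum.species[gi],
                                 float(spectrum.energy_mev[gi]))

        per_hist = np.zeros(n)
        for arr in scorer.dep.values():
            z = arr * to_gray
            nz = z[z > 0]
            if len(nz):
                counts += np.histogram(nz, bins=bins)[0]
                n_events += len(nz)
                max_zn = max(max_zn, float(nz.max()))
            per_hist += z
        sum_m += per_hist.sum()
        sum_m2 += (per_hist**2).sum()
        if collect_segments and scorer.segs:
            seg_parts.append(scorer.segs)
        done += n

    if n_events == 0:
        raise RuntimeError(
            "no energy deposition events scored in any nucleus: the source "
            f"({source!r}) cannot reach a nucleus within the fragment ranges")

    m = sum_m / n_histories
    var = max(sum_m2 / n_histories - m**2, 0.0)
    m_err = np.sqrt(var / n_histories)
    density = counts / (counts.sum() * np.diff(bins))
    pd = SpecificEnergyPD(bins, density, n_events=n_events,
                          n_histories=n_histories,
                          event_rate=n_events / n_histories,
                          meta={"site": "nucleus", "source": str(source)})

    segments = None
    if collect_segments:
        flat = [s for part in seg_parts for s in part]
        if flat:
            segments = TrackSegments(
                np.concatenate([f[0] for f in flat]),
                np.concatenate([f[1] for f in flat]),
                np.concatenate([f[2] for f in flat]),
                species_names, n_histories)
    return TransportResult(pd, m, m_err, n_histories, n_events, max_zn, segments)


def _sample_positions(lattice, source, rng, n) -> np.ndarray:
    if isinstance(source, str):
        return sample_source_position(lattice, source, (0, 0, 0), rng, n)
    if isinstance(source, CompartmentWeights):
        comps = list(source.as_dict().items())
        probs = np.array([w for _, w in comps])
        which = rng.choice(len(comps), size=n, p=probs / probs.sum())
        pos = np.empty((n, 3))
        for ci, (name, _) in enumerate(comps):
            rows = which == ci
            if np.any(rows):
                pos[rows] = sample_source_position(lattice, name, (0, 0, 0),
                                                   rng, int(rows.sum()))
        return pos
    raise ValueError(f"unsupported source specification {source!r}")


@dataclass
class NucleusDoseCoefficients:
    """Mean nucleus dose per source history for each source localization."""

    m_n: float
    m_c: float
    m_s: float
    m_e: float
    m_uniform: float
    errors: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(self.m_n, self.m_c, self.m_s, self.m_e, self.m_uniform) < 0:
            raise ValueError("dose coefficients must be non-negative")
        if not (self.m_n > self.m_c > self.m_e):
            raise ValueError("expected proximity ordering m_n > m_c > m_e")

    def by_compartment(self) -> dict:
        return {"n": self.m_n, "c": self.m_c, "s": self.m_s, "e": self.m_e}


def compute_dose_coefficients(lattice: CellLattice, n_histories: int = 100_000,
                              seed=None, channels=None,
                              collect_segments: bool = False,
                              bins=None):
    """Run the five source localizations (n, c, s, e, uniform).

    Returns ``(coeffs, results)`` where *results* maps the compartment name
    to its :class:`TransportResult` (PDs, segments, max z_n).
    """
    channels = channels or boron_channels()
    ss = np.random.SeedSequence(seed)
    kids = ss.spawn(5)
    results = {}
    for comp, child in zip(("nucleus", "cytoplasm", "surface",
                            "extracellular", "uniform"), kids):
        results[comp] = simulate_component_pd(
            lattice, comp, n_histories, np.random.default_rng(child),
            channels=channels, bins=bins, collect_segments=collect_segments)
    coeffs = NucleusDoseCoefficients(
        m_n=results["nucleus"].m_coeff,
        m_c=results["cytoplasm"].m_coeff,
        m_s=results["surface"].m_coeff,
        m_e=results["extracellular"].m_coeff,
        m_uniform=results["uniform"].m_coeff,
        errors={k: r.m_err for k, r in zip("ncseu", results.values())},
    )
    return coeffs, results


def kappa_B(coeffs: NucleusDoseCoefficients, weights: CompartmentWeights,
            x: float = 1.0) -> float:
    """Kerma-to-nucleus-dose conversion factor for the boron component.

    With a concentration factor x the intracellular 10B numbers are scaled by
    x without renormalization, so kappa_B(x) is linear in x.
    """
    if coeffs.m_uniform <= 0:
        raise ValueError("m_uniform must be positive")
    w = weights.scaled(x)
    num = (w.n * coeffs.m_n + w.c * coeffs.m_c
           + w.s * coeffs.m_s + w.e * coeffs.m_e)
    return num / coeffs.m_uniform


def kappa_total(kappa_b: float, component_kerma: dict) -> float:
    """Field conversion factor: (kappa_B D_B + D_H + D_N + D_gamma) / D."""
    d_b = component_kerma.get("boron", 0.0)
    others = sum(v for k, v in component_kerma.items() if k != "boron")
    total = d_b + others
    if total <= 0:
        raise ValueError("total kerma dose must be positive")
    if min(component_kerma.values()) < 0:
        raise ValueError("kerma doses must be non-negative")
    return (kappa_b * d_b + others) / total
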